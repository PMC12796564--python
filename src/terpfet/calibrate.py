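"""Unweighted linear calibration with statistical model testing.

Forensic guidelines favour unweighted linear calibration. Two tests decide
whether a single line over the full 11-level ladder is adequate:

* Cochran's test for variance homogeneity across concentration levels
  (largest group variance over the sum of group variances, 99 % significance);
* Mandel's fitting test for linearity: the residual-variance reduction when
  moving from a linear to a quadratic fit, DS^2 = (n-2) s1^2 - (n-3) s2^2,
  referred to F(1, n-3) at 99 % significance.

When the full range fails, the range is restricted (top levels dropped, for
detector saturation) and/or split into two sub-ranges sharing a boundary
calibrator (for slope changes), each side holding at least five calibrators.
The response variable throughout is the ISTD-normalised area ratio
(analyte target area / assigned alkane target area).

Cochran critical values are computed by Monte Carlo at first use and cached,
because printed tables vary between sources; Mandel uses the exact F
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats

from .panel import CalibrationDesign, NOMINAL_LEVELS_UG

SIGNIFICANCE = 0.99
MIN_LEVELS_PER_FIT = 5
MAX_DROPPED_TOP_LEVELS = 2
#: split boundaries considered, as nominal ug positions on the ladder
SPLIT_BOUNDARIES_UG = (0.500, 1.00, 1.75)
#: relative half-width of the transition zone around a split boundary response
TRANSITION_ZONE = 0.10

_COCHRAN_MC_SIMS = 200_000
_COCHRAN_MC_SEED = 987654321


class ModelSelectionError(RuntimeError):
    """No admissible calibration model for the supplied responses."""


@dataclass(frozen=True)
class CalibrationFit:
    """Unweighted OLS line over pooled calibrator replicates."""

    slope: float
    intercept: float
    s_yx: float        # residual standard deviation, sqrt(SSE / (n-2))
    r: float           # correlation coefficient, signed
    n: int             # pooled points
    x_mean: float
    q_x: float         # sum of squared x deviations
    x_range: tuple[float, float]
    sse: float = 0.0

    def predict(self, amount: float) -> float:
        return self.intercept + self.slope * amount

    def invert(self, response: float) -> float:
        if self.slope == 0:
            raise ZeroDivisionError("cannot invert a zero-slope calibration")
        return (response - self.intercept) / self.slope


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    critical_value: float
    significance: float = SIGNIFICANCE

    @property
    def passed(self) -> bool:
        return self.statistic <= self.critical_value


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the entire/restricted/split decision procedure."""

    kind: str                      # entire | split | restricted | split_restricted
    fits: tuple[CalibrationFit, ...]
    split_point: float | None
    dropped_top_levels: int
    tests: tuple[TestResult, ...] = ()

    @property
    def x_range(self) -> tuple[float, float]:
        return self.fits[0].x_range[0], self.fits[-1].x_range[1]


def fit_line(levels, responses) -> CalibrationFit:
    """OLS over pooled replicate points (one x entry per measured response)."""
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("levels and responses must have matching shapes")
    if np.unique(x).size < MIN_LEVELS_PER_FIT:
        raise ValueError(f"calibration needs >= {MIN_LEVELS_PER_FIT} distinct levels")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in calibration levels")
    n = x.size
    x_mean = float(x.mean())
    q_x = float(np.sum((x - x_mean) ** 2))
    slope = float(np.sum((x - x_mean) * (y - y.mean())) / q_x)
    intercept = float(y.mean() - slope * x_mean)
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid ** 2))
    s_yx = math.sqrt(sse / (n - 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r = float(np.sign(slope)) if sst == 0 else float(slope * math.sqrt(q_x / sst))
    return CalibrationFit(slope=slope, intercept=intercept, s_yx=s_yx, r=r,
                          n=n, x_mean=x_mean, q_x=q_x,
                          x_range=(float(x.min()), float(x.max())), sse=sse)


@lru_cache(maxsize=None)
def cochran_critical(k: int, nu: int, alpha: float = 0.01,
                     n_sims: int = _COCHRAN_MC_SIMS) -> float:
    """Upper critical value of Cochran's C for k groups with nu df each.

    Estimated once per (k, nu, alpha) by Monte Carlo under the normal
    homoscedastic null and cached for the process lifetime.
    """
    rng = np.random.default_rng(_COCHRAN_MC_SEED)
    draws = rng.chisquare(nu, size=(n_sims, k))
    c = draws.max(axis=1) / draws.sum(axis=1)
    return float(np.quantile(c, 1.0 - alpha))


def cochran_statistic(variances) -> float:
    v = np.asarray(variances, dtype=float)
    return float(v.max() / v.sum())


def cochran_test(replicate_groups: Sequence[Sequence[float]],
                 significance: float = SIGNIFICANCE) -> TestResult:
    """Cochran variance-homogeneity test across calibrator levels.

    All groups must share a common replicate count. A degenerate all-zero
    variance set passes trivially with the statistic reported as 1/k.
    """
    groups = [np.asarray(g, dtype=float) for g in replicate_groups]
    if len(groups) < 2:
        raise ValueError("Cochran test needs >= 2 groups")
    sizes = {g.size for g in groups}
    if len(sizes) != 1 or min(sizes) < 2:
        raise ValueError("Cochran test needs a balanced design with >= 2 replicates")
    nu = groups[0].size - 1
    variances = np.array([g.var(ddof=1) for g in groups])
    crit = cochran_critical(len(groups), nu, round(1.0 - significance, 10))
    if variances.sum() == 0:
        return TestResult("cochran", 1.0 / len(groups), crit, significance)
    return TestResult("cochran", cochran_statistic(variances), crit, significance)


def mandel_test(levels, responses, significance: float = SIGNIFICANCE) -> TestResult:
    """Mandel's fitting (linearity) test on pooled calibration points.

    Fits linear and quadratic models; DS^2 = SSE_lin - SSE_quad is referred
    to F(1, n-3) via F = DS^2 / s2^2. Passing means the linear model is
    adequate. A perfect quadratic (s2 = 0 with DS^2 > 0) fails with an
    infinite statistic; a perfect line (both zero) passes with F = 0.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 6:
        raise ValueError("Mandel test needs >= 6 points")
    n = x.size
    res_lin = y - np.polyval(np.polyfit(x, y, 1), x)
    res_quad = y - np.polyval(np.polyfit(x, y, 2), x)
    sse1 = float(np.sum(res_lin ** 2))
    sse2 = float(np.sum(res_quad ** 2))
    ds2 = max(sse1 - sse2, 0.0)
    crit = float(stats.f.ppf(significance, 1, n - 3))
    eps = 1e-14 * float(np.sum(y ** 2))  # numerically-zero residual floor
    if sse2 <= eps:
        statistic = 0.0 if ds2 <= eps else math.inf
        return TestResult("mandel", statistic, crit, significance)
    f_stat = ds2 / (sse2 / (n - 3))
    return TestResult("mandel", float(f_stat), crit, significance)


def _pooled(levels: np.ndarray, y2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.repeat(levels, y2d.shape[1])
    return x, y2d.reshape(-1)


def _try_range(levels: np.ndarray, y2d: np.ndarray,
               r_threshold: float = 0.99) -> tuple[CalibrationFit, TestResult, bool]:
    x, y = _pooled(levels, y2d)
    fit = fit_line(x, y)
    mandel = mandel_test(x, y)
    ok = mandel.passed and fit.r > r_threshold
    return fit, mandel, ok


def select_model(design: CalibrationDesign, responses,
                 r_threshold: float = 0.99) -> ModelSelection:
    """Entire / restricted / split decision for one analyte.

    ``responses``: array of shape (n_levels, n_replicates) aligned with
    ``design.adjusted_levels``. Procedure: (1) fit the entire ladder; accept
    if Mandel passes and r exceeds the threshold; (2) otherwise drop up to
    two top levels and retest (restricted range, for saturation); (3)
    otherwise split at one of the ladder's published boundary positions,
    both sides sharing the boundary calibrator and holding >= 5 levels, the
    high side optionally dropping top levels; among admissible splits the one
    with the smallest summed residual SSE wins. Raises
    :class:`ModelSelectionError` when nothing is admissible.
    """
    levels = np.asarray(design.adjusted_levels, dtype=float)
    y2d = np.asarray(responses, dtype=float)
    if y2d.ndim != 2 or y2d.shape[0] != levels.size:
        raise ValueError("responses must be (n_levels, n_replicates) matching the design")

    cochran = cochran_test(list(y2d)) if y2d.shape[1] >= 2 else None
    base_tests = (cochran,) if cochran is not None else ()

    fit, mandel, ok = _try_range(levels, y2d, r_threshold)
    if ok:
        return ModelSelection("entire", (fit,), None, 0, base_tests + (mandel,))

    for n_drop in range(1, MAX_DROPPED_TOP_LEVELS + 1):
        if levels.size - n_drop < MIN_LEVELS_PER_FIT:
            break
        fit, mandel, ok = _try_range(levels[:-n_drop], y2d[:-n_drop], r_threshold)
        if ok:
            return ModelSelection("restricted", (fit,), None, n_drop,
                                  base_tests + (mandel,))

    nominal = np.asarray(design.nominal_levels, dtype=float)
    candidates = []
    for boundary in SPLIT_BOUNDARIES_UG:
        idx = np.flatnonzero(np.isclose(nominal, boundary))
        if idx.size != 1:
            continue
        b = int(idx[0])
        if b + 1 < MIN_LEVELS_PER_FIT:
            continue
        low_fit, low_mandel, low_ok = _try_range(levels[:b + 1], y2d[:b + 1], r_threshold)
        if not low_ok:
            continue
        for n_drop in range(0, MAX_DROPPED_TOP_LEVELS + 1):
            hi = levels.size - n_drop
            if hi - b < MIN_LEVELS_PER_FIT:
                break
            high_fit, high_mandel, high_ok = _try_range(levels[b:hi], y2d[b:hi],
                                                        r_threshold)
            if high_ok:
                candidates.append((low_fit.sse + high_fit.sse, levels[b], n_drop,
                                   (low_fit, high_fit), (low_mandel, high_mandel)))
                break

    if not candidates:
        raise ModelSelectionError(
            "no admissible calibration model: entire, restricted and all "
            "split candidates failed the linearity criteria")
    sse, split_at, n_drop, fits, mandels = min(candidates, key=lambda c: c[0])
    kind = "split_restricted" if n_drop else "split"
    return ModelSelection(kind, fits, float(split_at), n_drop, base_tests + mandels)


def predict_amount(selection: ModelSelection, response: float) -> tuple[float, set[str]]:
    """Inverse prediction with range and transition-zone flags.

    For split models the sub-range whose fitted response interval contains
    the response is used; the boundary response itself belongs to the low
    range. Responses within +/-10 % of the boundary response are flagged
    ``transition_zone``; responses outside the overall fitted interval are
    flagged ``below_range`` / ``above_range`` (the nearest fit extrapolates).
    """
    flags: set[str] = set()
    fits = selection.fits
    first, last = fits[0], fits[-1]
    y_bottom = first.predict(first.x_range[0])
    y_top = last.predict(last.x_range[1])
    if response < y_bottom:
        flags.add("below_range")
    if response > y_top:
        flags.add("above_range")

    fit = first
    if len(fits) == 2:
        boundary_y = first.predict(first.x_range[1])  # shared boundary level
        if response > boundary_y:
            fit = last
        if boundary_y != 0 and abs(response - boundary_y) <= TRANSITION_ZONE * abs(boundary_y):
            flags.add("transition_zone")
    amount = fit.invert(response)
    return float(amount), flags


# ---------------------------------------------------------------------------
# operating-characteristic utilities (empirical type-I error under the null)

def cochran_type1_error(k: int = 11, nu: int = 2, n_sims: int = 100_000,
                        seed: int = 0, alpha: float = 0.01) -> float:
    """Empirical rejection rate of the Cochran test under equal variances.

    Simulates balanced normal replicate groups (vectorised as chi-square
    variance draws, the exact sampling distribution of group variances) and
    compares against the cached Monte-Carlo critical value, which comes from
    an independent random stream.
    """
    rng = np.random.default_rng(seed)
    draws = rng.chisquare(nu, size=(n_sims, k))
    c = draws.max(axis=1) / draws.sum(axis=1)
    crit = cochran_critical(k, nu, alpha)
    return float(np.mean(c > crit))


def mandel_type1_error(levels=NOMINAL_LEVELS_UG, n_rep: int = 3,
                       n_sims: int = 100_000, seed: int = 0,
                       alpha: float = 0.01) -> float:
    """Empirical rejection rate of the Mandel test on true-linear normal data.

    The statistic is invariant to the underlying line, so pure noise around
    zero is simulated; residual sums of squares are computed through QR
    projections of the fixed design, vectorised over simulations.
    """
    x = np.repeat(np.asarray(levels, dtype=float), n_rep)
    n = x.size
    q1, _ = np.linalg.qr(np.column_stack([np.ones_like(x), x]))
    q2, _ = np.linalg.qr(np.column_stack([np.ones_like(x), x, x ** 2]))
    rng = np.random.default_rng(seed)
    rejected = 0
    crit = float(stats.f.ppf(1.0 - alpha, 1, n - 3))
    chunk = 20_000
    for start in range(0, n_sims, chunk):
        m = min(chunk, n_sims - start)
        y = rng.standard_normal((m, n))
        tot = np.einsum("ij,ij->i", y, y)
        p1 = y @ q1
        p2 = y @ q2
        sse1 = tot - np.einsum("ij,ij->i", p1, p1)
        sse2 = tot - np.einsum("ij,ij->i", p2, p2)
        f = (sse1 - sse2) / (sse2 / (n - 3))
        rejected += int(np.sum(f > crit))
    return rejected / n_sims
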