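"""Experimental verification of full evaporation.

Full-evaporation headspace sampling is only quantitative once the entire
analyte amount in the vial has transferred to the gas phase and no saturation
or matrix adsorption remains. Verification proceeds along four checks:

1. temperature and time scans, normalised to a reference condition, with a
   +/-30 % acceptance band (the measurement-uncertainty limit of the forensic
   guidelines) and plateau detection;
2. sample-size linearity (peak area vs flower weight, r^2 > 0.99);
3. multiple headspace extraction (MHE): repeated injections of one vial must
   deplete geometrically, i.e. log-linearly, and
4. comparison of the MHE depletion slope of real samples against standard
   solutions: a relative deviation < 30 % rules out adsorption by
   non-evaporated matrix residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import stats

#: acceptance band on normalised abundances (forensic +/-30 % uncertainty)
SCAN_BAND = (0.7, 1.3)
#: target sample weight (mg) for rule-of-three weight normalisation
TARGET_WEIGHT_MG = 5.0
#: slope-deviation acceptance limit for MHE comparison, percent
MHE_DEVIATION_LIMIT = 30.0

_AXIS_COLUMN = {
    "temperature": "thermostat_temp_c",
    "time": "thermostat_time_min",
    "weight": "sample_weight_mg",
}


@dataclass(frozen=True)
class ScanSeries:
    """Replicate-averaged, reference-normalised response along one scan axis."""

    axis: str
    conditions: tuple[float, ...]
    mean_areas: tuple[float, ...]
    normalized: tuple[float, ...]
    reference_condition: float
    band: tuple[float, float] = SCAN_BAND

    @property
    def in_band(self) -> tuple[bool, ...]:
        lo, hi = self.band
        return tuple(lo <= v <= hi for v in self.normalized)


@dataclass(frozen=True)
class MHEFit:
    """Log-linear depletion fit over sequential injections of one vial."""

    slope: float       # per-injection decrement of ln(area)
    intercept: float   # ln(area) at the first injection
    r_squared: float
    q_hat: float       # recovered per-injection extraction fraction
    q_defined: bool    # False when the slope is non-negative
    n_points: int
    total_area: float  # geometric-series estimate of the recoverable area

    @property
    def valid(self) -> bool:
        return self.q_defined and self.n_points >= 3


def normalize_scan(table: pd.DataFrame, analyte: str, axis: str,
                   reference_condition: float) -> ScanSeries:
    """Average replicates per condition and normalise to the reference point.

    Flower-sample areas are first rescaled to the 5 mg target weight by the
    rule of three (area * target / actual weight) so that conditions measured
    at slightly different weighed masses are comparable; for weight-axis
    scans the weight IS the condition and no rescaling is applied. The
    normalised abundance at the reference condition is exactly 1.
    """
    if axis not in _AXIS_COLUMN:
        raise ValueError(f"unknown scan axis {axis!r}")
    col = _AXIS_COLUMN[axis]
    sub = table[table["analyte"] == analyte].copy()
    if sub.empty:
        raise ValueError(f"no records for analyte {analyte!r}")
    area = sub["area_target"].astype(float)
    if axis != "weight":
        flower = sub["sample_type"] == "flower"
        area = area.where(~flower, area * TARGET_WEIGHT_MG / sub["sample_weight_mg"])
    sub = sub.assign(_area=area)
    means = sub.groupby(col)["_area"].mean().sort_index()
    if reference_condition not in means.index:
        raise ValueError(f"reference condition {reference_condition} not in scan grid")
    ref = means.loc[reference_condition]
    if ref == 0:
        raise ValueError("zero mean area at the reference condition")
    normalized = means / ref
    return ScanSeries(
        axis=axis,
        conditions=tuple(float(c) for c in means.index),
        mean_areas=tuple(float(v) for v in means),
        normalized=tuple(float(v) for v in normalized),
        reference_condition=float(reference_condition),
    )


def find_plateau(series: ScanSeries, tolerance: float = 0.30) -> float | None:
    """Earliest condition from which the response stays near its final value.

    Returns the smallest grid value c such that every normalised abundance at
    c and beyond lies within ``[1 - tol, 1 + tol]`` times the final value, or
    ``None`` if the series never stabilises. The final point alone does not
    constitute a plateau: the onset must precede the last grid value.
    """
    values = np.asarray(series.normalized, dtype=float)
    if values.size < 3:
        raise ValueError("plateau detection needs at least 3 scan points")
    final = values[-1]
    lo, hi = (1.0 - tolerance) * final, (1.0 + tolerance) * final
    ok = (values >= min(lo, hi)) & (values <= max(lo, hi))
    # walk backwards: find the first index from which all later points are ok
    onset = None
    for i in range(values.size - 1, -1, -1):
        if ok[i]:
            onset = i
        else:
            break
    if onset is None or onset == values.size - 1:
        return None
    return series.conditions[onset]


def size_linearity(weights_mg, areas) -> tuple[float, bool]:
    """OLS of area on sample weight; flag saturation at the top of the range.

    Returns (r_squared over the full range, saturation_flag). The flag is set
    when the full range fails the r^2 > 0.99 linearity criterion but dropping
    the largest weight(s) (while keeping >= 3 points) restores it.
    """
    w = np.asarray(weights_mg, dtype=float)
    a = np.asarray(areas, dtype=float)
    if np.unique(w).size < 3:
        raise ValueError("size linearity needs at least 3 distinct weights")
    order = np.argsort(w, kind="stable")
    w, a = w[order], a[order]
    r2_full = _r_squared(w, a)
    if r2_full > 0.99:
        return r2_full, False
    top_weights = np.unique(w)[::-1]
    for n_drop in range(1, top_weights.size - 2):
        keep = ~np.isin(w, top_weights[:n_drop])
        if np.unique(w[keep]).size < 3:
            break
        if _r_squared(w[keep], a[keep]) > 0.99:
            return r2_full, True
    return r2_full, False


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)


def mhe_fit(areas) -> MHEFit:
    """Fit ln(area) against injection number (0-based) by OLS.

    For an ideal MHE the areas decay geometrically, A_i = A_1 (1-q)^(i-1),
    so the log-slope recovers q = 1 - exp(slope) and the total recoverable
    area is the geometric series sum A_1 / q.
    """
    a = np.asarray(areas, dtype=float)
    if a.size < 3:
        raise ValueError("MHE fit needs at least 3 injections")
    if np.any(a <= 0):
        raise ValueError("MHE areas must all be positive")
    x = np.arange(a.size, dtype=float)
    res = stats.linregress(x, np.log(a))
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue ** 2) if a.size > 2 else 1.0
    if slope < 0:
        q_hat = 1.0 - math.exp(slope)
        total = float(a[0] / q_hat)
        defined = True
    else:
        q_hat = float("nan")
        total = float("nan")
        defined = False
    return MHEFit(slope=slope, intercept=intercept, r_squared=r2,
                  q_hat=q_hat, q_defined=defined, n_points=int(a.size),
                  total_area=total)


def compare_mhe(sample_fit: MHEFit, standard_fit: MHEFit,
                limit: float = MHE_DEVIATION_LIMIT) -> tuple[float, bool]:
    """Relative deviation (%) between sample and standard depletion slopes.

    A deviation below the limit (strictly) indicates that the flower matrix
    does not retain analyte between injections, i.e. evaporation is complete.
    The metric is invariant to the logarithm base used for fitting since both
    slopes scale by the same constant.
    """
    if not (sample_fit.valid and standard_fit.valid):
        raise ValueError("both MHE fits must be valid with negative slopes")
    deviation = abs(sample_fit.slope - standard_fit.slope) / abs(standard_fit.slope) * 100.0
    return float(deviation), bool(deviation < limit)


def mhe_fit_from_table(table: pd.DataFrame, analyte: str,
                       sample_type: str) -> MHEFit:
    """MHE fit for one analyte/sample type from a peak table, averaging
    replicate areas per injection index."""
    sub = table[(table["analyte"] == analyte) & (table["sample_type"] == sample_type)]
    if sub.empty:
        raise ValueError(f"no MHE records for {analyte!r} / {sample_type!r}")
    means = sub.groupby("injection_index")["area_target"].mean().sort_index()
    return mhe_fit(means.to_numpy())


def verify_analyte(scan_tables: dict[str, pd.DataFrame], mhe_table: pd.DataFrame,
                   analyte: str, reference: dict[str, float] | None = None,
                   plateau_tolerance: float = 0.30) -> dict:
    """Run the complete verification workflow for one analyte.

    ``scan_tables`` maps axis name -> scan peak table; ``reference`` maps
    axis -> reference condition (defaults: 100 C, 20 min). Returns a flat
    report dict suitable for CSV/JSON export.
    """
    reference = {"temperature": 100.0, "time": 20.0, **(reference or {})}
    report: dict = {"analyte": analyte}
    for axis in ("temperature", "time"):
        if axis not in scan_tables:
            continue
        series = normalize_scan(scan_tables[axis], analyte, axis, reference[axis])
        report[f"{axis}_plateau"] = find_plateau(series, plateau_tolerance)
        report[f"{axis}_n_out_of_band"] = int(sum(not b for b in series.in_band))
    if "weight" in scan_tables:
        sub = scan_tables["weight"]
        sub = sub[(sub["analyte"] == analyte) & (sub["sample_type"] == "flower")]
        r2, flag = size_linearity(sub["sample_weight_mg"], sub["area_target"])
        report["weight_r_squared"] = r2
        report["weight_saturation_flag"] = flag
    sample = mhe_fit_from_table(mhe_table, analyte, "flower")
    standard = mhe_fit_from_table(mhe_table, analyte, "standard")
    deviation, ok = compare_mhe(sample, standard)
    report.update(
        mhe_slope_sample=sample.slope, mhe_slope_standard=standard.slope,
        mhe_r2_sample=sample.r_squared, mhe_r2_standard=standard.r_squared,
        mhe_q_hat_sample=sample.q_hat, mhe_q_hat_standard=standard.q_hat,
        mhe_slope_deviation_pct=deviation, mhe_pass=ok,
    )
    return report
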