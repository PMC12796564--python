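"""Identity confirmation: retention indices and SIM qualifier-ion ratios.

Because terpene isomers share near-identical electron-impact spectra,
identity rests on two legs: the retention index against the co-injected
n-alkane ladder (linear, temperature-programmed convention: RI = 100 n at
the alkanes themselves), and the ratio of qualifier- to target-ion areas,
which must match the reference ratio within a relative tolerance and both
qualifiers must actually be present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel import AlkaneLadder, AnalyteSpec

#: default relative tolerance on qualifier/target area ratios
QUALIFIER_TOLERANCE = 0.30
#: default retention-time match window, minutes
RT_WINDOW_MIN = 0.15


@dataclass(frozen=True)
class RIResult:
    rt: float
    bracket: tuple[int, int]      # carbon numbers of the bracketing alkanes
    retention_index: float
    extrapolated: bool


def retention_index(rt: float, ladder: AlkaneLadder) -> RIResult:
    """Linear (van den Dool-Kratz style) retention index for a peak at ``rt``.

    RI = 100 * (n + (rt - rt_n) / (rt_{n+1} - rt_n)) with (n, n+1) the
    bracketing alkane carbon numbers. Outside the ladder span the nearest
    alkane pair is extended linearly and the result flagged extrapolated.
    """
    carbons = ladder.carbons
    rts = ladder.rts
    if len(rts) < 2:
        raise ValueError("retention index needs a ladder with >= 2 alkanes")
    if len(set(rts)) != len(rts):
        raise ValueError("degenerate ladder: duplicate alkane retention times")
    if rt <= rts[0]:
        i, extrapolated = 0, rt < rts[0]
    elif rt >= rts[-1]:
        i, extrapolated = len(rts) - 2, rt > rts[-1]
    else:
        i = int(np.searchsorted(rts, rt, side="right")) - 1
        extrapolated = False
    n_lo, n_hi = carbons[i], carbons[i + 1]
    frac = (rt - rts[i]) / (rts[i + 1] - rts[i])
    ri = 100.0 * (n_lo + frac * (n_hi - n_lo))
    return RIResult(rt=float(rt), bracket=(n_lo, n_hi),
                    retention_index=float(ri), extrapolated=bool(extrapolated))


def qualifier_check(area_target: float, area_q1: float, area_q2: float,
                    reference_ratios: tuple[float, float],
                    tolerance: float = QUALIFIER_TOLERANCE) -> tuple[bool, str]:
    """Confirm identity from qualifier/target area ratios.

    Returns (identified, reason) with reason in {ok, missing_target,
    missing_qualifier, ratio_deviation}. Identified requires both qualifier
    areas positive and both ratios within +/- ``tolerance`` (relative) of the
    reference ratios.
    """
    if min(reference_ratios) <= 0:
        raise ValueError("reference ratios must be positive")
    if area_target <= 0:
        return False, "missing_target"
    if area_q1 <= 0 or area_q2 <= 0:
        return False, "missing_qualifier"
    for area_q, ref in ((area_q1, reference_ratios[0]), (area_q2, reference_ratios[1])):
        ratio = area_q / area_target
        if abs(ratio - ref) > tolerance * ref:
            return False, "ratio_deviation"
    return True, "ok"


def match_peak(rt: float, panel: Sequence[AnalyteSpec],
               rt_window: float = RT_WINDOW_MIN) -> AnalyteSpec | None:
    """Nearest panel analyte within the retention-time window.

    Ties (equidistant analytes, e.g. co-eluting pairs printed at the same
    retention time) resolve to the smaller panel index; such pairs need
    distinct target masses to be told apart and should be assigned from
    fixtures rather than retention time alone.
    """
    if rt_window <= 0:
        raise ValueError("rt_window must be positive")
    best: AnalyteSpec | None = None
    best_d = float("inf")
    for spec in sorted(panel, key=lambda a: a.index):
        d = abs(spec.reference_rt - rt)
        if d <= rt_window and d < best_d:  # ties keep the earlier index
            best, best_d = spec, d
    return best
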