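"""Sample quantification and strain-profile summaries.

Identified peaks are converted to absolute vial amounts through the
ISTD-normalised response ratio and the selected calibration model, then to
contents in ug per g of flower via the actual weighed sample mass. Flags
propagate analytical limits (below LOD / LOQ) and calibration-range issues.
Samples whose response exceeded the calibration range are re-measured at a
smaller weight; a deviation beyond +30 % between the original and the
re-weighed content marks suspected detector saturation.

Profiles aggregate per-sample contents into a samples x analytes matrix,
compound-class sums, total terpene weight percent and the radar-chart subset
(analytes exceeding 100 ug/g in at least one sample).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .calibrate import ModelSelection, predict_amount
from .panel import AnalyteSpec, amount_to_content

RADAR_THRESHOLD_UG_G = 100.0
REWEIGH_LIMIT = 30.0


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    analyte: str
    amount_in_vial: float  # ug
    content: float         # ug/g
    sample_weight_mg: float
    flags: frozenset[str] = frozenset()

    @property
    def quantifiable(self) -> bool:
        return not ({"below_loq", "below_lod"} & self.flags)


class MissingISTDError(KeyError):
    """An assigned alkane ISTD peak is absent from the injection."""


def response_ratios(table: pd.DataFrame, panel: Sequence[AnalyteSpec],
                    collapse_replicates: bool = True) -> pd.DataFrame:
    """ISTD-normalised response per analyte per sample.

    Duplicate measurements of one sample (repeat injections, or replicate
    vials following the ``<sample>_r<k>`` naming convention when
    ``collapse_replicates`` is set) are averaged on the ratio scale. Returns
    a frame with columns sample_id, analyte, ratio, sample_weight_mg.
    Raises :class:`MissingISTDError` naming the alkane when an assigned ISTD
    peak is missing from an injection.
    """
    by_name = {a.name: a for a in panel}
    rows = []
    for (vial, injection), group in table.groupby(["sample_id", "injection_index"]):
        areas = group.set_index("analyte")["area_target"]
        weight = float(group["sample_weight_mg"].iloc[0])
        sample_id = re.sub(r"_r\d+$", "", vial) if collapse_replicates else vial
        for name, spec in by_name.items():
            if name not in areas.index:
                continue
            if spec.assigned_istd not in areas.index:
                raise MissingISTDError(
                    f"sample {vial!r} injection {injection}: missing ISTD "
                    f"peak for alkane {spec.assigned_istd!r}")
            istd_area = float(areas[spec.assigned_istd])
            if istd_area <= 0:
                raise MissingISTDError(
                    f"sample {vial!r}: non-positive area for ISTD "
                    f"{spec.assigned_istd!r}")
            rows.append({
                "sample_id": sample_id,
                "analyte": name,
                "ratio": float(areas[name]) / istd_area,
                "sample_weight_mg": weight,
            })
    if not rows:
        return pd.DataFrame(columns=["sample_id", "analyte", "ratio", "sample_weight_mg"])
    df = pd.DataFrame(rows)
    return (df.groupby(["sample_id", "analyte"], as_index=False)
              .agg(ratio=("ratio", "mean"), sample_weight_mg=("sample_weight_mg", "mean")))


def quantify_sample(table: pd.DataFrame, models: Mapping[str, ModelSelection],
                    panel: Sequence[AnalyteSpec],
                    limits: Mapping[str, tuple[float, float]] | None = None,
                    ) -> list[QuantResult]:
    """Quantify every calibrated analyte in a peak table.

    ``models`` maps analyte name -> selected calibration model; ``limits``
    optionally maps analyte name -> (LOD, LOQ) in ug for limit flags.
    Analytes without a model are skipped. Replicate injections per sample are
    averaged before inverse prediction.
    """
    ratios = response_ratios(table, panel)
    results: list[QuantResult] = []
    for row in ratios.itertuples(index=False):
        if row.analyte not in models:
            continue
        amount, flags = predict_amount(models[row.analyte], row.ratio)
        if limits and row.analyte in limits:
            lod, loq = limits[row.analyte]
            if amount < lod:
                flags = flags | {"below_lod", "below_loq"}
            elif amount < loq:
                flags = flags | {"below_loq"}
        results.append(QuantResult(
            sample_id=row.sample_id,
            analyte=row.analyte,
            amount_in_vial=float(amount),
            content=amount_to_content(amount, row.sample_weight_mg),
            sample_weight_mg=float(row.sample_weight_mg),
            flags=frozenset(flags),
        ))
    return results


def reweigh_check(original: QuantResult, reweighed: QuantResult) -> tuple[float, bool]:
    """Verify an above-range quantification by a smaller-weight re-analysis.

    Returns (deviation %, saturation_suspect). The original (larger-weight)
    content is compared against the re-weighed one; a deviation beyond +30 %
    suggests the original response sat in the detector-saturation regime.
    """
    if original.analyte != reweighed.analyte:
        raise ValueError("reweigh_check compares the same analyte")
    if reweighed.content == 0:
        raise ValueError("re-weighed content is zero")
    deviation = 100.0 * (original.content - reweighed.content) / reweighed.content
    return float(deviation), bool(deviation > REWEIGH_LIMIT)


@dataclass(frozen=True)
class ProfileMatrix:
    """Samples x analytes content matrix with class and total summaries."""

    contents: pd.DataFrame          # ug/g, zero where below LOQ / undetected
    class_sums: pd.DataFrame        # per sample per compound class, ug/g
    total_wt_percent: pd.Series     # per sample
    radar_analytes: tuple[str, ...]  # > 100 ug/g in at least one sample


def build_profiles(results: Sequence[QuantResult],
                   panel: Sequence[AnalyteSpec],
                   include_below_loq: bool = False) -> ProfileMatrix:
    """Aggregate quantification results into per-strain profiles.

    Below-LOQ values enter the matrix (and all sums) as zero unless
    ``include_below_loq`` is set; the radar subset applies the
    at-least-once > 100 ug/g rule across samples.
    """
    if not results:
        raise ValueError("no quantification results to profile")
    classes = {a.name: a.compound_class for a in panel}
    order = [a.name for a in sorted(panel, key=lambda a: a.index)]
    rows = []
    for r in results:
        value = r.content if (r.quantifiable or include_below_loq) else 0.0
        rows.append({"sample_id": r.sample_id, "analyte": r.analyte, "content": value})
    long = pd.DataFrame(rows)
    wide = (long.pivot_table(index="sample_id", columns="analyte",
                             values="content", aggfunc="mean", fill_value=0.0)
                .reindex(columns=[n for n in order if n in long["analyte"].unique()],
                         fill_value=0.0))
    class_of = pd.Series({c: classes.get(c, "other") for c in wide.columns})
    class_sums = wide.T.groupby(class_of).sum().T
    total = wide.sum(axis=1) / 1.0e4  # ug/g -> weight percent
    total.name = "total_wt_percent"
    radar = tuple(c for c in wide.columns if (wide[c] > RADAR_THRESHOLD_UG_G).any())
    return ProfileMatrix(contents=wide, class_sums=class_sums,
                         total_wt_percent=total, radar_analytes=radar)


def profile_long_table(profile: ProfileMatrix,
                       panel: Sequence[AnalyteSpec]) -> pd.DataFrame:
    """Tidy long-format export: sample, analyte, class, content, radar flag."""
    classes = {a.name: a.compound_class for a in panel}
    long = (profile.contents.reset_index()
            .melt(id_vars="sample_id", var_name="analyte", value_name="content_ug_g"))
    long["compound_class"] = long["analyte"].map(classes)
    long["in_radar_subset"] = long["analyte"].isin(profile.radar_analytes)
    return long.sort_values(["sample_id", "analyte"], ignore_index=True)
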