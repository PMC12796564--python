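"""Analyte panel registry for the 45-terpene / 8-alkane HS-FET-GC/MS method.

The panel bundles, per analyte, everything the downstream stages need:
compound class, SIM target and qualifier masses, the commercial standard mix
used for calibration, the certified isomer fraction of that standard, the
reference retention time, the assigned n-alkane internal standard (ISTD) and
the published calibration-model kind (entire / split / restricted range).

The canonical internal unit for analyte quantities is the absolute amount in
the headspace vial in micrograms; contents in ug/g of flower material and
concentrations in ug/mL of the spiking solution are derived views.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

COMPOUND_CLASSES = ("monoterpene", "monoterpenoid", "sesquiterpene", "sesquiterpenoid")
CALIBRATION_MIXES = ("mix1", "mix2", "mix3", "mix4", "spike")
MODEL_KINDS = ("entire", "split", "restricted", "split_restricted")

#: 11-point calibration ladder, absolute ug in the vial (Cal1..Cal11).
NOMINAL_LEVELS_UG = (0.050, 0.0750, 0.125, 0.375, 0.500, 1.00, 1.75, 2.50, 5.00, 7.50, 10.0)
QC_LOW_UG = 0.0625
QC_HIGH_UG = 3.75
#: reference sample weight (mg of ground flower) that maps the ladder onto ug/g.
SAMPLE_WEIGHT_REF_MG = 5.0
#: volume (uL) of standard solution pipetted per vial; links ug in vial to ug/mL.
STANDARD_VOLUME_UL = 10.0


class PanelError(ValueError):
    """Raised when packaged panel fixtures are missing or inconsistent."""


@dataclass(frozen=True)
class AnalyteSpec:
    """One member of the terpene panel."""

    index: int
    name: str
    compound_class: str
    target_mz: int
    qualifier_mz: tuple[int, int]
    calibration_mix: str
    isomer_fraction: float
    reference_rt: float  # minutes
    assigned_istd: str
    model_kind: str
    split_point: float | None = None  # ug, for split models
    range_top: float = 10.0  # ug, highest calibrator of the published model

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise PanelError(f"{self.name}: unknown compound_class {self.compound_class!r}")
        if self.calibration_mix not in CALIBRATION_MIXES:
            raise PanelError(f"{self.name}: unknown calibration_mix {self.calibration_mix!r}")
        if self.model_kind not in MODEL_KINDS:
            raise PanelError(f"{self.name}: unknown model_kind {self.model_kind!r}")
        if self.target_mz in self.qualifier_mz:
            raise PanelError(f"{self.name}: target m/z duplicated among qualifiers")
        if not 0.0 < self.isomer_fraction <= 1.0:
            raise PanelError(f"{self.name}: isomer_fraction outside (0, 1]")
        if self.reference_rt <= 0:
            raise PanelError(f"{self.name}: non-positive reference retention time")


@dataclass(frozen=True)
class AlkaneLadder:
    """Ordered n-alkane retention-index ladder (C10..C17) used as ISTD."""

    entries: tuple[tuple[int, str, float, float], ...]
    # each entry: (carbon_number, name, reference_rt_min, vial_amount_ug)

    def __post_init__(self) -> None:
        rts = [rt for _, _, rt, _ in self.entries]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise PanelError("alkane ladder retention times not strictly increasing")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name, _, _ in self.entries)

    @property
    def carbons(self) -> tuple[int, ...]:
        return tuple(c for c, _, _, _ in self.entries)

    @property
    def rts(self) -> tuple[float, ...]:
        return tuple(rt for _, _, rt, _ in self.entries)

    def rt_of(self, name: str) -> float:
        for _, n, rt, _ in self.entries:
            if n == name:
                return rt
        raise PanelError(f"unknown alkane {name!r}")

    def amount_of(self, name: str) -> float:
        for _, n, _, amt in self.entries:
            if n == name:
                return amt
        raise PanelError(f"unknown alkane {name!r}")


@dataclass(frozen=True)
class CalibrationDesign:
    """Calibration ladder for one analyte, purity-adjusted where certified."""

    nominal_levels: tuple[float, ...] = NOMINAL_LEVELS_UG
    qc_low: float = QC_LOW_UG
    qc_high: float = QC_HIGH_UG
    isomer_fraction: float = 1.0
    sample_weight_ref: float = SAMPLE_WEIGHT_REF_MG  # mg

    def __post_init__(self) -> None:
        lv = self.nominal_levels
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise PanelError("calibration levels not strictly increasing")
        if not lv[0] < self.qc_low < lv[1]:
            raise PanelError("qc_low must fall between the first two calibrators")

    @property
    def adjusted_levels(self) -> tuple[float, ...]:
        """Nominal levels scaled by the certified isomer fraction, exactly."""
        return tuple(x * self.isomer_fraction for x in self.nominal_levels)

    @property
    def adjusted_qc_low(self) -> float:
        return self.qc_low * self.isomer_fraction

    @property
    def adjusted_qc_high(self) -> float:
        return self.qc_high * self.isomer_fraction


_PANEL_COLUMNS = [
    "index", "name", "compound_class", "target_mz", "qualifier_mz1", "qualifier_mz2",
    "calibration_mix", "isomer_fraction", "reference_rt_min", "assigned_istd",
    "model_kind", "split_point_ug", "range_top_ug",
]
_ALKANE_COLUMNS = [
    "carbon_number", "name", "reference_rt_min", "vial_amount_ug", "target_mz", "qualifier_mz",
]


def _read_fixture(filename: str, required: Sequence[str]) -> pd.DataFrame:
    with resources.files("terpfet.data").joinpath(filename).open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelError(f"{filename}: missing required column(s) {missing}")
    if df[required].isna().any().any():
        bad = df.columns[df[required].isna().any()].tolist()
        raise PanelError(f"{filename}: empty values in column(s) {bad}")
    return df


def load_panel() -> tuple[list[AnalyteSpec], AlkaneLadder]:
    """Load the packaged 45-analyte panel and the C10-C17 alkane ladder.

    Returns analytes ordered by panel index. Raises :class:`PanelError`
    naming the offending field if a fixture is incomplete.
    """
    pdf = _read_fixture("panel.tsv", [c for c in _PANEL_COLUMNS if c != "split_point_ug"])
    analytes = []
    for row in pdf.sort_values("index").itertuples(index=False):
        split = getattr(row, "split_point_ug")
        analytes.append(AnalyteSpec(
            index=int(row.index),
            name=str(row.name),
            compound_class=str(row.compound_class),
            target_mz=int(row.target_mz),
            qualifier_mz=(int(row.qualifier_mz1), int(row.qualifier_mz2)),
            calibration_mix=str(row.calibration_mix),
            isomer_fraction=float(row.isomer_fraction),
            reference_rt=float(row.reference_rt_min),
            assigned_istd=str(row.assigned_istd),
            model_kind=str(row.model_kind),
            split_point=None if pd.isna(split) else float(split),
            range_top=float(row.range_top_ug),
        ))
    if len(analytes) != len({a.index for a in analytes}):
        raise PanelError("panel.tsv: duplicate analyte indices")

    adf = _read_fixture("alkanes.tsv", _ALKANE_COLUMNS)
    ladder = AlkaneLadder(entries=tuple(
        (int(r.carbon_number), str(r.name), float(r.reference_rt_min), float(r.vial_amount_ug))
        for r in adf.sort_values("carbon_number").itertuples(index=False)
    ))
    return analytes, ladder


def load_validation_reference() -> pd.DataFrame:
    """Published per-analyte LOD/LOQ (ug), bias (%) and precision (RSD %).

    These are instrument-derived reference values shipped as fixture data;
    the package cannot recompute them without the original raw runs.
    """
    return _read_fixture("validation.tsv", [
        "index", "name", "lod_ug", "loq_ug", "bias_low", "bias_high",
        "intra_low", "intra_high", "inter_low", "inter_high",
    ])


def class_counts(analytes: Sequence[AnalyteSpec]) -> dict[str, int]:
    counts = {c: 0 for c in COMPOUND_CLASSES}
    for a in analytes:
        counts[a.compound_class] += 1
    return counts


def assign_istd(analyte_rt: float, ladder: AlkaneLadder) -> str:
    """Alkane ISTD by the elutes-closest-before rule.

    Returns the latest alkane whose retention time is <= ``analyte_rt``.
    Analytes eluting before the first alkane (e.g. the earliest monoterpenes,
    which precede decane) fall back to the first ladder entry, matching the
    published assignments. For packaged analytes the fixture value is
    authoritative; this rule is for novel peaks.
    """
    if not ladder.entries:
        raise PanelError("empty alkane ladder")
    chosen = None
    for _, name, rt, _ in ladder.entries:
        if rt <= analyte_rt:
            chosen = name
    return chosen if chosen is not None else ladder.entries[0][1]


def amount_to_content(amount_ug: float, sample_weight_mg: float) -> float:
    """Absolute vial amount (ug) -> content in ug per g of sample."""
    if sample_weight_mg <= 0:
        raise ValueError(f"non-positive sample weight: {sample_weight_mg}")
    return amount_ug / (sample_weight_mg / 1000.0)


def content_to_amount(content_ug_g: float, sample_weight_mg: float) -> float:
    """Inverse of :func:`amount_to_content`; exact round trip."""
    if sample_weight_mg <= 0:
        raise ValueError(f"non-positive sample weight: {sample_weight_mg}")
    return content_ug_g * (sample_weight_mg / 1000.0)


def amount_to_solution_conc(amount_ug: float, volume_ul: float = STANDARD_VOLUME_UL) -> float:
    """Vial amount (ug) -> concentration (ug/mL) of the pipetted standard."""
    if volume_ul <= 0:
        raise ValueError("non-positive standard volume")
    return amount_ug / (volume_ul / 1000.0)


def build_calibration_design(analyte: AnalyteSpec) -> CalibrationDesign:
    """The 11-level ladder plus QCs for one analyte, isomer-fraction adjusted."""
    return CalibrationDesign(isomer_fraction=analyte.isomer_fraction)
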