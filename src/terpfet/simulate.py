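"""Synthetic peak-table generator emulating full-evaporation headspace GC-MS.

The generator produces per-injection peak records with the statistical and
physical structure the downstream analysis assumes:

* linear detector response: target-ion area proportional to the absolute
  amount of analyte in the vial (``response_factor`` counts per ug);
* first-order evaporation kinetics during thermostatting, with an Arrhenius-
  like temperature dependence, so peak areas rise with temperature and hold
  time until the vial content is fully transferred to the gas phase;
* first-order thermal degradation of an analyte once the thermostatting
  temperature exceeds a sharp per-analyte onset, producing the characteristic
  rise-then-fall temperature profiles of high-boiling terpenes;
* reproducible matrix suppression of alkane internal standards on flower
  samples, drawn once per sample, increasingly severe for higher-boiling
  alkanes (mean retained fraction down to 0.218 for heptadecane, i.e. a
  -78.2 % reduction); analytes assigned to an alkane share its factor by
  default so that the area ratio cancels the effect;
* constant-fraction depletion per injection for multiple headspace
  extraction (MHE), with an optional extra adsorption loss on flower matrix;
* smooth detector saturation above a per-analyte vial amount; and
* multiplicative lognormal measurement noise (unit mean).

All randomness is derived from a single integer seed combined with stable
per-sample keys, so identical (config, seed) pairs yield byte-identical
tables regardless of the order in which samples are simulated.

The kinetic defaults are illustrative package choices tuned only for
qualitative realism (lower-boiling compounds evaporate faster and degrade at
lower onsets); they are not measured constants.
"""

from __future__ import annotations

import dataclasses
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import load_panel

#: canonical peak-table schema (one row per detected peak per injection)
PEAK_COLUMNS = [
    "sample_id", "analyte", "rt_min", "area_target", "area_q1", "area_q2",
    "sample_weight_mg", "thermostat_temp_c", "thermostat_time_min",
    "injection_index", "sample_type",
]

SAMPLE_TYPES = ("standard", "flower")


@dataclass(frozen=True)
class AnalyteKinetics:
    """Per-analyte physical parameters of the forward model."""

    response_factor: float          # detector area per ug at full transfer
    evap_rate_ref: float            # 1/min at the reference temperature
    evap_temp_coeff: float = 1.08   # multiplier on the rate per degree C
    degradation_onset: float = 120.0   # C; no degradation at or below this
    degradation_rate: float = 0.0   # 1/min applied over the hold when T > onset
    saturation_amount: float = math.inf  # ug; inf = no detector saturation
    saturation_sharpness: float = 10.0   # exponent of the smooth-minimum cap
    kink_amount: float = math.inf        # ug; onset of a second response regime
    kink_slope_ratio: float = 1.0        # relative slope above the kink
    qual_ratios: tuple[float, float] = (0.6, 0.3)  # (q1/target, q2/target)

    def __post_init__(self) -> None:
        if min(self.response_factor, self.evap_rate_ref, self.degradation_rate) < 0:
            raise ValueError("kinetic rates and response factors must be >= 0")


# class-level defaults: lower-boiling classes evaporate faster and start
# degrading at lower temperatures (illustrative, qualitative ordering only)
_CLASS_KINETICS = {
    "monoterpene": dict(response_factor=5.0e5, evap_rate_ref=0.30,
                        degradation_onset=105.0, degradation_rate=0.04),
    "monoterpenoid": dict(response_factor=4.0e5, evap_rate_ref=0.15,
                          degradation_onset=110.0, degradation_rate=0.04),
    "sesquiterpene": dict(response_factor=3.0e5, evap_rate_ref=0.08,
                          degradation_onset=115.0, degradation_rate=0.03),
    "sesquiterpenoid": dict(response_factor=3.0e5, evap_rate_ref=0.05,
                            degradation_onset=120.0, degradation_rate=0.03),
}

# typical flower contents (ug per g) by class, used by the scan designs
_CLASS_FLOWER_CONTENT = {
    "monoterpene": 800.0,
    "monoterpenoid": 200.0,
    "sesquiterpene": 400.0,
    "sesquiterpenoid": 150.0,
}

# mean retained fraction of alkane ISTD response on flower matrix, C10..C17;
# heptadecane at 0.218 mirrors the strongest observed suppression (-78.2 %)
_ALKANE_SUPPRESSION = {
    "decane": 1.00, "undecane": 0.888, "dodecane": 0.777, "tridecane": 0.665,
    "tetradecane": 0.553, "pentadecane": 0.441, "hexadecane": 0.330,
    "heptadecane": 0.218,
}


@dataclass
class SyntheticConfig:
    """Full parameterisation of the synthetic instrument."""

    kinetics: dict[str, AnalyteKinetics]
    rts: dict[str, float]                    # reference retention times, min
    istd_map: dict[str, str]                 # analyte -> assigned alkane
    istd_amounts: dict[str, float]           # alkane -> ug spiked per vial
    flower_content: dict[str, float]         # analyte -> ug/g in flower scans
    istd_suppression_mean: dict[str, float]  # alkane -> mean retained fraction
    istd_suppression_sd: float = 0.08        # absolute SD of the per-sample draw
    extraction_fraction: float = 0.30        # q, per-injection transfer fraction
    adsorption_excess: float = 0.0           # extra per-injection loss on flower
    noise_rsd: float = 0.03                  # relative SD of multiplicative noise
    analytes_share_suppression: bool = True
    reference_temp: float = 100.0            # C, where evap_rate_ref applies
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.extraction_fraction < 1.0:
            raise ValueError("extraction_fraction must lie in (0, 1)")
        if not 0.0 <= self.adsorption_excess < 1.0:
            raise ValueError("adsorption_excess must lie in [0, 1)")
        if self.noise_rsd < 0:
            raise ValueError("noise_rsd must be >= 0")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Config covering the packaged panel plus the alkane ladder."""
    analytes, ladder = load_panel()
    kinetics: dict[str, AnalyteKinetics] = {}
    rts: dict[str, float] = {}
    istd_map: dict[str, str] = {}
    flower_content: dict[str, float] = {}
    for a in analytes:
        kinetics[a.name] = AnalyteKinetics(**_CLASS_KINETICS[a.compound_class])
        rts[a.name] = a.reference_rt
        istd_map[a.name] = a.assigned_istd
        flower_content[a.name] = _CLASS_FLOWER_CONTENT[a.compound_class]
    # alkanes: volatility (and hence evaporation rate) falls with chain length
    for carbon, name, rt, _amount in ladder.entries:
        kinetics[name] = AnalyteKinetics(
            response_factor=6.0e5,
            evap_rate_ref=0.5 * 0.75 ** (carbon - 10),
            degradation_onset=130.0,
            degradation_rate=0.02,
        )
        rts[name] = rt
        istd_map[name] = name
    istd_amounts = {name: ladder.amount_of(name) for name in ladder.names}
    cfg = SyntheticConfig(
        kinetics=kinetics,
        rts=rts,
        istd_map=istd_map,
        istd_amounts=istd_amounts,
        flower_content=flower_content,
        istd_suppression_mean=dict(_ALKANE_SUPPRESSION),
        seed=seed,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown SyntheticConfig field {key!r}")
        setattr(cfg, key, value)
    cfg.__post_init__()
    return cfg


def update_kinetics(config: SyntheticConfig, name: str, **changes) -> SyntheticConfig:
    """Copy of ``config`` with kinetic fields of one analyte replaced."""
    if name not in config.kinetics:
        raise ValueError(f"unknown analyte {name!r}")
    cfg = dataclasses.replace(config, kinetics=dict(config.kinetics))
    cfg.kinetics[name] = dataclasses.replace(cfg.kinetics[name], **changes)
    return cfg


@dataclass(frozen=True)
class InjectionMeta:
    """Acquisition metadata attached to every record of one injection."""

    sample_id: str
    sample_weight_mg: float = 5.0
    thermostat_temp_c: float = 100.0
    thermostat_time_min: float = 20.0
    injection_index: int = 1
    sample_type: str = "standard"

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"sample_type must be one of {SAMPLE_TYPES}")
        if self.injection_index < 1:
            raise ValueError("injection_index must be >= 1")


def evaporated_fraction(kin: AnalyteKinetics, temp_c: float, time_min: float,
                        reference_temp: float = 100.0) -> float:
    """Fraction of the vial content present in the vapor phase, post-degradation.

    E(T, t) = (1 - exp(-k(T) t)) * exp(-d t * 1[T > onset]) with
    k(T) = evap_rate_ref * evap_temp_coeff**(T - reference_temp).
    """
    k = kin.evap_rate_ref * kin.evap_temp_coeff ** (temp_c - reference_temp)
    evaporated = 1.0 - math.exp(-k * time_min)
    if temp_c > kin.degradation_onset:
        evaporated *= math.exp(-kin.degradation_rate * time_min)
    return evaporated


def _stable_key(sample_id: str) -> int:
    return zlib.crc32(sample_id.encode("utf-8"))


def suppression_factors(config: SyntheticConfig, sample_id: str,
                        seed: int | None = None) -> dict[str, float]:
    """Per-sample matrix suppression factors for each alkane ISTD.

    Drawn once per flower sample from a normal distribution around the
    configured mean retained fraction (clipped into (0, 1]); deterministic in
    (seed, sample_id) so repeated injections of one vial share the factors.
    """
    base = config.seed if seed is None else seed
    rng = np.random.default_rng([base & 0x7FFFFFFF, _stable_key(sample_id)])
    factors = {}
    for name in sorted(config.istd_suppression_mean):
        mean = config.istd_suppression_mean[name]
        draw = rng.normal(mean, config.istd_suppression_sd)
        factors[name] = float(np.clip(draw, 0.01, 1.0))
    return factors


def _noise_sigma(rsd: float) -> float:
    return math.sqrt(math.log1p(rsd * rsd))


def simulate_injection(amounts: Mapping[str, float], meta: InjectionMeta,
                       config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate one headspace injection of a vial containing ``amounts`` (ug).

    The target-ion area follows
    ``response_factor * q * C(K(amount) * E(T,t) * S * D(i)) * noise`` where
    ``E`` is the evaporated-and-surviving fraction, ``S`` the per-sample
    matrix suppression (1 for standards), ``D(i) = ((1-q)(1-adsorption))**(i-1)``
    the MHE depletion, ``K`` an optional two-regime (piecewise-linear,
    continuous) transform of the vial amount emulating a sample-side slope
    change, and ``C`` the smooth-minimum detector
    saturation cap ``C(x) = x (1 + (x/A_sat)^p)^(-1/p)``: essentially linear
    below the cap, compressing sharply around it. Qualifier areas are fixed
    reference ratios of the target area with independent noise.
    """
    unknown = [n for n in amounts if n not in config.kinetics]
    if unknown:
        raise ValueError(f"unknown analyte name(s): {unknown}")
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(
        [base & 0x7FFFFFFF, _stable_key(meta.sample_id), meta.injection_index])
    is_flower = meta.sample_type == "flower"
    supp = suppression_factors(config, meta.sample_id, seed) if is_flower else None

    q = config.extraction_fraction
    retain = (1.0 - q)
    if is_flower:
        retain *= (1.0 - config.adsorption_excess)
    depletion = retain ** (meta.injection_index - 1)
    sigma = _noise_sigma(config.noise_rsd)

    rows = []
    for name in sorted(amounts):
        amount = float(amounts[name])
        if amount < 0:
            raise ValueError(f"negative amount for {name!r}")
        kin = config.kinetics[name]
        frac = evaporated_fraction(kin, meta.thermostat_temp_c,
                                   meta.thermostat_time_min, config.reference_temp)
        s_factor = 1.0
        if is_flower and (config.analytes_share_suppression or name in config.istd_amounts):
            alkane = config.istd_map.get(name, name)
            if alkane in supp:
                s_factor = supp[alkane]
        if math.isfinite(kin.kink_amount):
            amount = (min(amount, kin.kink_amount)
                      + kin.kink_slope_ratio * max(0.0, amount - kin.kink_amount))
        effective = amount * frac * s_factor * depletion
        if math.isfinite(kin.saturation_amount):
            a_sat, p = kin.saturation_amount, kin.saturation_sharpness
            effective = effective * (1.0 + (effective / a_sat) ** p) ** (-1.0 / p)
        area_lin = kin.response_factor * q * effective
        if sigma > 0:
            noises = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=3))
        else:
            noises = np.ones(3)
        area = area_lin * noises[0]
        rows.append({
            "sample_id": meta.sample_id,
            "analyte": name,
            "rt_min": config.rts.get(name, float("nan")),
            "area_target": area,
            "area_q1": area * kin.qual_ratios[0] * noises[1],
            "area_q2": area * kin.qual_ratios[1] * noises[2],
            "sample_weight_mg": meta.sample_weight_mg,
            "thermostat_temp_c": meta.thermostat_temp_c,
            "thermostat_time_min": meta.thermostat_time_min,
            "injection_index": meta.injection_index,
            "sample_type": meta.sample_type,
        })
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def _vial_amounts(config: SyntheticConfig, sample_type: str,
                  weight_mg: float, standard_amount_ug: float) -> dict[str, float]:
    """Vial loadings for scan designs: flower content x weight, or standard."""
    amounts: dict[str, float] = {}
    for name in config.flower_content:
        if sample_type == "flower":
            amounts[name] = config.flower_content[name] * weight_mg / 1000.0
        else:
            amounts[name] = standard_amount_ug
    amounts.update(config.istd_amounts)
    return amounts


def simulate_fet_scan(axis: str, grid: Sequence[float], n_rep: int,
                      config: SyntheticConfig, seed: int | None = None,
                      standard_amount_ug: float = 1.0) -> pd.DataFrame:
    """Full-evaporation verification scan over one acquisition axis.

    ``axis`` is one of ``temperature`` (thermostatting C), ``time``
    (thermostatting min) or ``weight`` (flower sample mass mg). Produces the
    full grid x replicate design for both sample types (weight scans apply to
    flower samples only, standards carry a fixed loading).
    """
    if axis not in ("temperature", "time", "weight"):
        raise ValueError(f"unknown scan axis {axis!r}")
    if not grid:
        raise ValueError("empty scan grid")
    if list(grid) != sorted(grid):
        raise ValueError("scan grid must be sorted ascending")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")

    frames = []
    sample_types = ("flower",) if axis == "weight" else SAMPLE_TYPES
    for sample_type in sample_types:
        for value in grid:
            for rep in range(1, n_rep + 1):
                temp, time, weight = 100.0, 20.0, 5.0
                if axis == "temperature":
                    temp = float(value)
                elif axis == "time":
                    time = float(value)
                else:
                    weight = float(value)
                meta = InjectionMeta(
                    sample_id=f"{sample_type}_{axis}_{value:g}_r{rep}",
                    sample_weight_mg=weight,
                    thermostat_temp_c=temp,
                    thermostat_time_min=time,
                    sample_type=sample_type,
                )
                amounts = _vial_amounts(config, sample_type, weight, standard_amount_ug)
                frames.append(simulate_injection(amounts, meta, config, seed))
    return pd.concat(frames, ignore_index=True)


def simulate_mhe(amounts: Mapping[str, float], n_injections: int,
                 config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Multiple headspace extraction: repeated injections of single vials.

    One standard vial and one flower vial, each injected ``n_injections``
    times; areas deplete geometrically by (1-q) per injection, flower vials
    additionally by (1 - adsorption_excess).
    """
    if n_injections < 2:
        raise ValueError("MHE needs at least 2 injections")
    frames = []
    for sample_type in SAMPLE_TYPES:
        vial = dict(amounts)
        vial.update(config.istd_amounts)
        for i in range(1, n_injections + 1):
            meta = InjectionMeta(
                sample_id=f"{sample_type}_mhe",
                injection_index=i,
                sample_type=sample_type,
            )
            frames.append(simulate_injection(vial, meta, config, seed))
    return pd.concat(frames, ignore_index=True)


def simulate_calibration(config: SyntheticConfig,
                         levels: Mapping[str, Sequence[float]],
                         n_rep: int = 3, seed: int | None = None) -> pd.DataFrame:
    """Calibration series: per level index, one vial holding every analyte at
    its (purity-adjusted) level amount plus the ISTD spike, measured
    ``n_rep``-fold. ``levels`` maps analyte name -> ladder of vial amounts;
    all ladders must share a common length.
    """
    lengths = {len(v) for v in levels.values()}
    if len(lengths) != 1:
        raise ValueError("all analyte level ladders must have equal length")
    n_levels = lengths.pop()
    frames = []
    for li in range(n_levels):
        amounts = {name: ladder[li] for name, ladder in levels.items()}
        amounts.update(config.istd_amounts)
        for rep in range(1, n_rep + 1):
            meta = InjectionMeta(sample_id=f"cal_L{li + 1}_r{rep}")
            frames.append(simulate_injection(amounts, meta, config, seed))
    return pd.concat(frames, ignore_index=True)


def simulate_flower_sample(config: SyntheticConfig, sample_id: str,
                           contents_ug_g: Mapping[str, float], weight_mg: float = 5.0,
                           n_rep: int = 2, seed: int | None = None) -> pd.DataFrame:
    """Flower measurement with known true contents (ug/g), in duplicate."""
    amounts = {name: c * weight_mg / 1000.0 for name, c in contents_ug_g.items()}
    amounts.update(config.istd_amounts)
    frames = []
    for rep in range(1, n_rep + 1):
        meta = InjectionMeta(sample_id=f"{sample_id}_r{rep}",
                             sample_weight_mg=weight_mg, sample_type="flower")
        frames.append(simulate_injection(amounts, meta, config, seed))
    return pd.concat(frames, ignore_index=True)
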