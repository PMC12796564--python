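"""End-to-end orchestration: simulate, verify, calibrate, quantify, profile.

The stages operate on peak tables whose calibration samples follow the
``cal_L<level>_r<replicate>`` sample-id convention used by the synthetic
generator, so a complete analysis can run from a single seeded configuration
without instrument data.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calibrate as cal
from . import fet, quantify, simulate
from .io import RunConfig, write_peak_table, write_provenance
from .panel import (AnalyteSpec, build_calibration_design, load_panel,
                    load_validation_reference)

_CAL_ID = re.compile(r"^cal_L(\d+)_r(\d+)$")


def calibration_response_matrix(table: pd.DataFrame, analyte: AnalyteSpec,
                                n_levels: int) -> np.ndarray:
    """(n_levels, n_rep) ISTD-normalised responses for one analyte.

    Calibration injections are recognised by the ``cal_L<i>_r<j>`` sample-id
    convention; every level must carry the same replicate count.
    """
    sub = table[table["sample_id"].str.match(_CAL_ID)]
    if sub.empty:
        raise ValueError("no calibration samples (cal_L<i>_r<j>) in table")
    cells: dict[tuple[int, int], float] = {}
    for sample_id, group in sub.groupby("sample_id"):
        m = _CAL_ID.match(sample_id)
        level, rep = int(m.group(1)), int(m.group(2))
        areas = group.set_index("analyte")["area_target"]
        if analyte.name not in areas.index or analyte.assigned_istd not in areas.index:
            continue
        cells[(level, rep)] = float(areas[analyte.name] / areas[analyte.assigned_istd])
    levels = sorted({k[0] for k in cells})
    reps = sorted({k[1] for k in cells})
    if levels != list(range(1, n_levels + 1)):
        raise ValueError(f"{analyte.name}: incomplete calibration ladder {levels}")
    out = np.full((n_levels, len(reps)), np.nan)
    for (level, rep), value in cells.items():
        out[level - 1, reps.index(rep)] = value
    if np.isnan(out).any():
        raise ValueError(f"{analyte.name}: unbalanced calibration replicates")
    return out


def calibrate_panel(table: pd.DataFrame, panel: Sequence[AnalyteSpec]
                    ) -> tuple[dict[str, cal.ModelSelection], dict[str, str]]:
    """Select a calibration model per analyte; failures land in the report."""
    models: dict[str, cal.ModelSelection] = {}
    failures: dict[str, str] = {}
    for analyte in panel:
        design = build_calibration_design(analyte)
        try:
            responses = calibration_response_matrix(
                table, analyte, len(design.nominal_levels))
            models[analyte.name] = cal.select_model(design, responses)
        except (ValueError, cal.ModelSelectionError) as exc:
            failures[analyte.name] = str(exc)
    return models, failures


def models_to_json(models: Mapping[str, cal.ModelSelection]) -> dict:
    out = {}
    for name, sel in models.items():
        out[name] = {
            "kind": sel.kind,
            "split_point_ug": sel.split_point,
            "dropped_top_levels": sel.dropped_top_levels,
            "fits": [dataclasses.asdict(f) for f in sel.fits],
            "tests": [{"name": t.name, "statistic": t.statistic,
                       "critical_value": t.critical_value, "passed": t.passed}
                      for t in sel.tests],
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a summary dict.

    Every artifact directory carries a provenance stamp (config hash +
    seed). Stage failures raise after partial outputs are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_provenance(config, out / "provenance.json")
    summary: dict = {"config_hash": config.config_hash, "seed": config.seed}

    panel, ladder = load_panel()
    cfg = simulate.default_config(
        seed=config.seed,
        noise_rsd=config.noise_rsd,
        extraction_fraction=config.extraction_fraction,
        adsorption_excess=config.adsorption_excess,
    )

    cal_table = flower_table = None
    if "simulate" in config.stages:
        levels = {a.name: build_calibration_design(a).adjusted_levels for a in panel}
        cal_table = simulate.simulate_calibration(
            cfg, levels, n_rep=config.calibration_replicates)
        write_peak_table(cal_table, out / "calibration_peaks.csv")
        rng = np.random.default_rng(config.seed)
        frames = []
        for s in range(1, 4):
            contents = {a.name: float(rng.uniform(50.0, 1500.0)) for a in panel}
            frames.append(simulate.simulate_flower_sample(
                cfg, f"strain{s}", contents, n_rep=2))
        flower_table = pd.concat(frames, ignore_index=True)
        write_peak_table(flower_table, out / "flower_peaks.csv")
        summary["simulate"] = {"calibration_rows": len(cal_table),
                               "flower_rows": len(flower_table)}

    if "verify-fet" in config.stages:
        scans = {
            "temperature": simulate.simulate_fet_scan(
                "temperature", list(range(70, 171, 10)), 2, cfg),
            "time": simulate.simulate_fet_scan(
                "time", [2.5, 5, 10, 15, 20, 25, 30, 35, 40], 2, cfg),
        }
        mhe_amounts = {a.name: 1.0 for a in panel}
        mhe_table = simulate.simulate_mhe(mhe_amounts, 5, cfg)
        reports = [fet.verify_analyte(scans, mhe_table, a.name,
                                      plateau_tolerance=config.plateau_tolerance)
                   for a in panel]
        pd.DataFrame(reports).to_csv(out / "fet_verification.csv", index=False)
        summary["verify-fet"] = {
            "n_analytes": len(reports),
            "mhe_pass_fraction": float(np.mean([r["mhe_pass"] for r in reports])),
        }

    models: dict[str, cal.ModelSelection] = {}
    if "calibrate" in config.stages:
        if cal_table is None:
            raise RuntimeError("calibrate stage requires simulated or loaded calibration peaks")
        models, failures = calibrate_panel(cal_table, panel)
        (out / "calibration_models.json").write_text(
            json.dumps(models_to_json(models), indent=2, default=float),
            encoding="utf-8")
        summary["calibrate"] = {
            "n_models": len(models), "n_failures": len(failures),
            "kinds": pd.Series([m.kind for m in models.values()])
                       .value_counts().to_dict(),
        }

    results = []
    if "quantify" in config.stages and models and flower_table is not None:
        ref = load_validation_reference()
        limits = {r["name"]: (r["lod_ug"], r["loq_ug"]) for _, r in ref.iterrows()}
        results = quantify.quantify_sample(flower_table, models, panel, limits)
        pd.DataFrame([dataclasses.asdict(r) | {"flags": sorted(r.flags)}
                      for r in results]).to_csv(out / "quantification.csv", index=False)
        summary["quantify"] = {"n_results": len(results)}

    if "profile" in config.stages and results:
        profile = quantify.build_profiles(results, panel)
        quantify.profile_long_table(profile, panel).to_csv(
            out / "profile_long.csv", index=False)
        profile.contents.to_csv(out / "profile_wide.csv")
        summary["profile"] = {
            "n_samples": int(profile.contents.shape[0]),
            "radar_analytes": len(profile.radar_analytes),
            "total_wt_percent": profile.total_wt_percent.round(4).to_dict(),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float),
                                      encoding="utf-8")
    return summary
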