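"""Configuration, validation, and end-to-end demonstration pipeline.

A single TOML file selects stages and parameters; :func:`run_pipeline`
chains the synthetic generators into the analysis stages (tension-sensor
force mapping, migration tracking, detachment, niche geometry, signature
scoring) and emits a reproducibility report: every seed, parameter, and
statistic, byte-stable under a fixed configuration.
"""

from __future__ import annotations

import difflib
import json
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .fret import (
    CalibrationCurve,
    compute_efficiency,
    force_from_efficiency,
    match_adhesions,
    profile_cell,
    segment_adhesions,
)
from .image_quant import percent_remaining
from .niche import filter_band, per_animal_distance_summary
from .signatures import compare_signature, lognormalize_cp10k, signature_score
from .synth import (
    SimConfig,
    simulate_counts,
    simulate_detachment,
    simulate_section,
    simulate_tension_images,
    simulate_tracks,
)
from .tracking import link_detections, summarize_by_animal, track_speed

__all__ = ["RunConfig", "validate_config", "run_pipeline", "save_report"]

ALL_STAGES = ("tension", "migration", "detachment", "section", "signatures")

#: recognized keys per config table, for validation and typo suggestions
_SCHEMA = {
    "": {"seed", "stages", "output_dir"},
    "tension": {
        "n_cells", "adhesions_per_cell", "force_mean", "min_area",
        "sensor_photons", "background_photons", "pixel_size", "image_shape",
        "noise", "force_threshold",
    },
    "migration": {
        "n_cells", "mean_speed", "persistence_time", "dt", "duration",
        "positional_noise", "max_displacement", "min_frames",
    },
    "detachment": {"n_before", "p_retain"},
    "section": {"n_per_group", "band_um", "distance_means", "distance_sds"},
    "signatures": {
        "n_per_group", "n_genes", "gene_set_size", "log_fold_effect",
        "dispersion",
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (one stochastic seed per run)."""

    seed: int = 0
    stages: tuple = ALL_STAGES
    output_dir: str | None = None
    params: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        ok, errors, _ = validate_config(path)
        if not ok:
            raise ValueError("invalid config:\n" + "\n".join(errors))
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            output_dir=raw.get("output_dir"),
            params={k: v for k, v in raw.items() if isinstance(v, dict)},
        )

    def stage_params(self, stage) -> dict:
        return dict(self.params.get(stage, {}))


def validate_config(path):
    """Schema and range checks; returns (ok, errors, warnings).

    Unknown keys are warnings with a nearest-valid-key suggestion; range
    violations (negative areas, probabilities outside [0, 1], margins that
    do not fit) are errors.
    """
    errors, warnings_ = [], []
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except (OSError, tomllib.TOMLDecodeError) as exc:
        return False, [f"cannot parse config: {exc}"], []

    def check_keys(table, keys, valid):
        for key in keys:
            if key not in valid:
                hint = difflib.get_close_matches(key, sorted(valid), n=1)
                suffix = f"; did you mean {hint[0]!r}?" if hint else ""
                warnings_.append(
                    f"unknown key {key!r} in [{table or 'top level'}]{suffix}"
                )

    top_keys = [k for k, v in raw.items() if not isinstance(v, dict)]
    check_keys("", top_keys, _SCHEMA[""])
    stages = raw.get("stages", list(ALL_STAGES))
    for stage in stages:
        if stage not in ALL_STAGES:
            errors.append(f"unknown stage {stage!r}; valid: {ALL_STAGES}")
    for table, content in raw.items():
        if not isinstance(content, dict):
            continue
        if table not in _SCHEMA:
            hint = difflib.get_close_matches(table, ALL_STAGES, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            warnings_.append(f"unknown table [{table}]{suffix}")
            continue
        check_keys(table, content.keys(), _SCHEMA[table])

    t = raw.get("tension", {})
    if t.get("min_area", 0.5) <= 0:
        errors.append("tension.min_area must be > 0")
    if t.get("sensor_photons", 1) <= 0:
        errors.append("tension.sensor_photons must be > 0")
    d = raw.get("detachment", {})
    if not 0 <= d.get("p_retain", 0.5) <= 1:
        errors.append("detachment.p_retain must be in [0, 1]")
    m = raw.get("migration", {})
    for key in ("dt", "duration", "persistence_time"):
        if m.get(key, 1) <= 0:
            errors.append(f"migration.{key} must be > 0")
    s = raw.get("section", {})
    if s.get("band_um", 200) <= 0:
        errors.append("section.band_um must be > 0")
    g = raw.get("signatures", {})
    if g.get("dispersion", 0.3) < 0:
        errors.append("signatures.dispersion must be >= 0")
    return (not errors), errors, warnings_


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_tension(seed, p):
    cal = CalibrationCurve.default_synthetic()
    sim = SimConfig(
        seed=seed,
        image_shape=tuple(p.get("image_shape", (512, 512))),
        pixel_size=p.get("pixel_size", 0.16),
        background_photons=p.get("background_photons", 100.0),
        sensor_photons=p.get("sensor_photons", 2000.0),
        calibration=cal,
        noise=bool(p.get("noise", True)),
    )
    imgs = simulate_tension_images(
        sim,
        n_cells=int(p.get("n_cells", 6)),
        adhesions_per_cell=p.get("adhesions_per_cell", 3),
        force_distribution=lambda rng: rng.uniform(2.0, 8.0),
    )
    emap = compute_efficiency(
        imgs.donor,
        imgs.acceptor,
        bg_donor=sim.background_photons,
        bg_acceptor=sim.background_photons,
        intensity_floor=sim.sensor_photons / 2.0,
        pixel_size=sim.pixel_size,
    )
    fmap = force_from_efficiency(emap, cal)
    # default threshold: efficiency drop of 0.1 below resting
    f_thresh = p.get(
        "force_threshold", float(cal.force_at(sim.resting_efficiency - 0.1))
    )
    adhesions = segment_adhesions(
        fmap, imgs.cell_mask, f_thresh, min_area=p.get("min_area", 0.5)
    )
    profiles = [
        profile_cell(adhesions, cid) for cid in sorted(adhesions.cell_ids)
    ]
    producing = [pr for pr in profiles if pr.force_producing]
    match = match_adhesions(adhesions, imgs.gt_labels)
    merged = match["pairs"].merge(
        imgs.ground_truth, left_on="reference_id", right_on="adhesion_id"
    ).merge(adhesions.table, left_on="detected_label", right_on="label")
    rel_err = (
        float(
            np.mean(
                np.abs(merged["mean_force_pN"] - merged["force_pN"])
                / merged["force_pN"]
            )
        )
        if len(merged)
        else float("nan")
    )
    return {
        "parameters": {
            "force_threshold_pN": f_thresh,
            "min_area_um2": p.get("min_area", 0.5),
            "sensor_photons": sim.sensor_photons,
            "background_photons": sim.background_photons,
        },
        "statistics": {
            "n_cells": len(profiles),
            "n_adhesions_detected": int(len(adhesions)),
            "n_adhesions_true": int(len(imgs.ground_truth)),
            "fraction_force_producing": round(
                len(producing) / len(profiles), 10
            ),
            "mean_force_relative_error": round(rel_err, 10),
            "detection_precision": round(match["precision"], 10),
            "detection_recall": round(match["recall"], 10),
            "mean_adhesion_force_pN": round(
                float(adhesions.table["mean_force_pN"].mean()), 10
            ),
        },
    }


def _stage_migration(seed, p):
    mean_speed = p.get("mean_speed", 10.0)
    dt = p.get("dt", 0.5)
    det = simulate_tracks(
        n_cells=int(p.get("n_cells", 100)),
        mean_speed=mean_speed,
        persistence_time=p.get("persistence_time", 4.0),
        dt=dt,
        duration=p.get("duration", 20.0),
        positional_noise=p.get("positional_noise", 0.0),
        seed=seed,
    )
    tracks = link_detections(
        det,
        max_displacement=p.get("max_displacement", max(4 * mean_speed * dt, 1.0)),
    )
    min_frames = int(p.get("min_frames", 5))
    stats = [
        track_speed(tr, min_frames=min_frames)
        for tr in tracks
        if len(tr) >= min_frames
    ]
    speeds = np.array([s.mean_speed for s in stats])
    return {
        "parameters": {"mean_speed_um_h": mean_speed, "dt_h": dt},
        "statistics": {
            "n_tracks": len(stats),
            "mean_speed_um_h": round(float(speeds.mean()), 10),
            "speed_recovery_error": round(
                float(abs(speeds.mean() - mean_speed) / mean_speed)
                if mean_speed
                else 0.0,
                10,
            ),
        },
    }


def _stage_detachment(seed, p):
    before, after = simulate_detachment(
        int(p.get("n_before", 500)), p.get("p_retain", 0.6), seed=seed
    )
    pct = percent_remaining(len(before), len(after))
    return {
        "parameters": {"n_before": len(before), "p_retain": p.get("p_retain", 0.6)},
        "statistics": {"percent_remaining": round(pct, 10)},
    }


def _stage_section(seed, p):
    band = p.get("band_um", 200.0)
    n_per_group = dict(p.get("n_per_group", {"young": 60, "old": 60}))
    means = dict(p.get("distance_means", {"young": 40.0, "old": 20.0}))
    sds = dict(p.get("distance_sds", {"young": 15.0, "old": 8.0}))
    border = np.array([[0.0, 0.0], [500.0, 0.0]])
    section = simulate_section(
        n_per_group,
        {g: (means[g], sds[g]) for g in n_per_group},
        border,
        marker_scheme={g: {"GFAP": True, "Ki67": False} for g in n_per_group},
        seed=seed,
        animals_per_group=int(p.get("animals_per_group", 4)) if "animals_per_group" in p else 4,
    )
    cells = section.cells.assign(cell_type="qNSC/astrocyte")
    in_band = filter_band(cells, border, band)
    summary = per_animal_distance_summary(in_band, border)
    stats = {
        "n_cells": int(len(cells)),
        "n_in_band": int(len(in_band)),
    }
    for group in n_per_group:
        sel = in_band["group"] == group
        stats[f"mean_distance_{group}_um"] = round(
            float(in_band.loc[sel, "true_distance"].mean()), 10
        )
    comp = summary["comparisons"].get("qNSC/astrocyte")
    if comp is not None:
        stats["mwu_p_distance"] = round(comp.pvalue, 10)
    return {
        "parameters": {"band_um": band, "distance_means": means},
        "statistics": stats,
    }


def _stage_signatures(seed, p):
    n_per_group = dict(p.get("n_per_group", {"young": 200, "old": 120}))
    counts, labels, gene_set = simulate_counts(
        n_per_group,
        n_genes=int(p.get("n_genes", 300)),
        gene_set=int(p.get("gene_set_size", 30)),
        log_fold_effect=p.get("log_fold_effect", 0.5),
        dispersion=p.get("dispersion", 0.3),
        seed=seed,
    )
    matrix = lognormalize_cp10k(counts)
    scores = signature_score(matrix, gene_set)
    report = compare_signature(
        scores.scores.to_numpy(), labels.to_numpy()
    )
    g1, g2 = report["groups"]
    return {
        "parameters": {
            "n_genes": int(p.get("n_genes", 300)),
            "gene_set_size": len(gene_set),
            "log_fold_effect": p.get("log_fold_effect", 0.5),
        },
        "statistics": {
            f"mean_score_{g1}": round(report["means"][g1], 10),
            f"mean_score_{g2}": round(report["means"][g2], 10),
            "mwu_p_per_cell": round(report["per_cell"].pvalue, 10),
        },
    }


_STAGE_FUNCS = {
    "tension": _stage_tension,
    "migration": _stage_migration,
    "detachment": _stage_detachment,
    "section": _stage_section,
    "signatures": _stage_signatures,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages and return the reproducibility report.

    Stage seeds derive deterministically from the run seed, so per-stage
    results do not depend on which other stages run.  Identical configs
    produce identical reports (numeric fields rounded to a fixed number of
    digits before serialization).
    """
    report = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    for stage in config.stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        stage_seed = (config.seed * 1000003 + ALL_STAGES.index(stage)) % (2**31)
        result = _STAGE_FUNCS[stage](stage_seed, config.stage_params(stage))
        result["seed"] = stage_seed
        report["stages"][stage] = result
    return report


def save_report(report, json_path, md_path=None) -> None:
    """Write the report as JSON and an optional Markdown summary.

    The timestamp lives only in the Markdown rendering; the JSON payload
    stays byte-stable for determinism checks.
    """
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if md_path:
        lines = [
            "# nichemech run report",
            "",
            f"- generated: {datetime.now(timezone.utc).isoformat()}",
            f"- version: {report['version']}",
            f"- seed: {report['seed']}",
            "",
        ]
        for stage, res in report["stages"].items():
            lines.append(f"## {stage}")
            lines.append("")
            for key, val in res.get("statistics", {}).items():
                lines.append(f"- {key}: {val}")
            lines.append("")
        with open(md_path, "w") as fh:
            fh.write("\n".join(lines))
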