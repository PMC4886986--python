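"""End-to-end pipeline: simulate -> resolve -> scale -> analyze -> report.

Stages are plain functions over in-memory tables so they compose in tests;
:func:`run_pipeline` wires them together, writes reflection files, CSV tables
and a single JSON report, and logs stage timings to stderr.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ambiguity import ModeAssignment, merged_partial, resolve_modes
from .damage import (
    CRYO_REFERENCE_HALF_DOSE,
    DecayFit,
    DoseSchedule,
    SubsetStats,
    fit_decay,
    split_subsets,
    subset_summary,
    summarize_cohort,
)
from .merging import cc_half, completeness_multiplicity, merge, r_factors
from .reflections import (
    ReindexOperator,
    UnitCell,
    apply_reindex,
    point_group_ops,
    write_reflections,
)
from .scaling import fit_relative_scale
from .simulate import (
    DEFAULT_DECAY_PRESETS,
    CrystalFrames,
    ExperimentConfig,
    simulate_experiment,
)

__all__ = ["RunConfig", "run_pipeline", "analyze_crystals", "merging_report"]

log = logging.getLogger("sxdamage")


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run."""

    cell_a: float = 78.8
    point_group: str = "23"
    reindex_matrix: tuple = ((0, 1, 0), (1, 0, 0), (0, 0, -1))
    dose_per_frame: float = 0.808
    n_frames: int = 700
    quality_subset_size: int = 50
    merge_subset_size: int = 100
    d_min: float = 1.9
    d_max: float = 30.0
    shell: tuple = (2.4, 1.9)
    wilson_b: float = 24.58
    mean_intensity: float = 100.0
    n_crystals: int = 5
    decay_params: tuple = DEFAULT_DECAY_PRESETS
    obs_per_frame: int = 200
    noise_gain: float | None = 1.0
    sigma_bg: float = 0.5
    mode_probability: float = 0.5
    min_common: int = 10
    cryo_reference_half_dose: float = CRYO_REFERENCE_HALF_DOSE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "cell_a",
            "dose_per_frame",
            "d_min",
            "d_max",
            "wilson_b",
            "mean_intensity",
            "sigma_bg",
            "cryo_reference_half_dose",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        d_hi, d_lo = max(self.shell), min(self.shell)
        if d_lo < self.d_min or d_hi > self.d_max:
            raise ValueError("high-resolution shell must lie within the limits")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("reindex_matrix", "decay_params", "shell"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in raw[key]
                )
        return cls(**raw)

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            cell=UnitCell(self.cell_a),
            group_name=self.point_group,
            d_min=self.d_min,
            d_max=self.d_max,
            wilson_b=self.wilson_b,
            mean_intensity=self.mean_intensity,
            n_crystals=self.n_crystals,
            decay_params=tuple(tuple(p) for p in self.decay_params),
            n_frames=self.n_frames,
            dose_per_frame=self.dose_per_frame,
            obs_per_frame=self.obs_per_frame,
            noise_gain=self.noise_gain,
            sigma_bg=self.sigma_bg,
            reindex_matrix=self.reindex_matrix,
            mode_probability=self.mode_probability,
        )


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: started", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: %.2f s", stage, time.perf_counter() - self.t0)

    return _Timer()


def resolve_experiment(
    crystals: list[CrystalFrames], config: RunConfig
) -> tuple[list[pd.DataFrame], ModeAssignment]:
    """Assign indexing modes and return reindexed observation tables."""
    group = point_group_ops(config.point_group)
    op = ReindexOperator(np.asarray(config.reindex_matrix), group)
    partials = [merged_partial(c.observations, group, c.crystal_id) for c in crystals]
    assignment = resolve_modes(partials, op, group, min_common=config.min_common)
    resolved: list[pd.DataFrame] = []
    for crystal in crystals:
        if crystal.crystal_id in assignment.excluded:
            continue
        df = crystal.observations
        if assignment.modes[crystal.crystal_id] == 1:
            df = df.copy()
            df[["h", "k", "l"]] = apply_reindex(df[["h", "k", "l"]].to_numpy(), op)
        resolved.append(df)
    return resolved, assignment


def analyze_crystals(
    resolved: list[pd.DataFrame], config: RunConfig
) -> tuple[list[list[SubsetStats]], list[DecayFit], pd.DataFrame]:
    """Per-crystal dose-wedge statistics, decay fits and relative scale fits."""
    cell = UnitCell(config.cell_a)
    group = point_group_ops(config.point_group)
    schedule = DoseSchedule(config.dose_per_frame, config.quality_subset_size)
    all_stats: list[list[SubsetStats]] = []
    fits: list[DecayFit] = []
    scale_rows: list[dict] = []
    for df in resolved:
        crystal_id = str(df["crystal_id"].iloc[0])
        subsets = split_subsets(df, schedule)
        first = subset_summary(subsets[0], 1, schedule, cell, shell=config.shell)
        stats = [first] + [
            subset_summary(s, i + 2, schedule, cell, shell=config.shell, first=first)
            for i, s in enumerate(subsets[1:])
        ]
        all_stats.append(stats)
        fits.append(
            fit_decay(
                [s.dose for s in stats],
                [s.mean_intensity_norm for s in stats],
                sigma=[s.mean_intensity_norm_sem for s in stats],
            )
        )
        partials = [merged_partial(s, group, crystal_id) for s in subsets]
        reference = partials[0]
        for i, partial in enumerate(partials):
            fit = fit_relative_scale(partial, reference, cell)
            scale_rows.append(
                {
                    "crystal_id": crystal_id,
                    "subset_index": i + 1,
                    "dose": stats[i].dose,
                    "K": fit.K,
                    "B": fit.B,
                    "n_common": fit.n_common,
                }
            )
    return all_stats, fits, pd.DataFrame(scale_rows)


def merging_report(
    resolved: list[pd.DataFrame], config: RunConfig, seed: int
) -> pd.DataFrame:
    """Cross-crystal merging statistics for each merge-size dose wedge."""
    cell = UnitCell(config.cell_a)
    group = point_group_ops(config.point_group)
    schedule = DoseSchedule(config.dose_per_frame, config.merge_subset_size)
    pooled = pd.concat(resolved, ignore_index=True)
    rows = []
    for i, subset in enumerate(split_subsets(pooled, schedule)):
        merged = merge(subset, group, cell)
        r_merge, r_meas = r_factors(subset, group)
        cchalf, ccstar = cc_half(subset, group, seed=seed)
        completeness, multiplicity = completeness_multiplicity(
            merged, cell, group, config.d_min, config.d_max
        )
        rows.append(
            {
                "subset_index": i + 1,
                "dose": (i + 1) * config.merge_subset_size * config.dose_per_frame,
                "total_observations": merged.total_observations,
                "unique_reflections": merged.unique_reflections,
                "multiplicity": multiplicity,
                "completeness": completeness,
                "mean_i_over_sigma": float(
                    (subset["intensity"] / subset["sigma"]).mean()
                ),
                "r_merge": r_merge,
                "r_meas": r_meas,
                "cc_half": cchalf,
                "cc_star": ccstar,
            }
        )
    return pd.DataFrame(rows)


def _fit_row(crystal_id: str, fit: DecayFit) -> dict:
    return {
        "crystal_id": crystal_id,
        "i0": fit.i0,
        "i0_err": fit.i0_err,
        "i1": fit.i1,
        "i1_err": fit.i1_err,
        "beta_tot": fit.beta_tot,
        "beta_err": fit.beta_err,
        "d_star": fit.d_star,
        "d_half": fit.d_half,
        "undamaged_fraction": fit.undamaged_fraction,
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write the full report under ``out_dir``.

    Outputs: per-crystal reflection files and ``manifest.json`` (simulate),
    ``subset_stats.csv``, ``scale_fits.csv``, ``decay_fits.csv``,
    ``merging_stats.csv`` and the machine-readable ``report.json``. The JSON
    report is byte-identical across reruns with the same config and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cell = UnitCell(config.cell_a)

    with _timed("simulate"):
        crystals, manifest = simulate_experiment(
            config.experiment_config(), seed=config.seed
        )
        for crystal in crystals:
            write_reflections(
                crystal.observations,
                out / f"{crystal.crystal_id}.refl",
                cell=cell,
                group_name=config.point_group,
                dose_per_frame=config.dose_per_frame,
            )
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    with _timed("resolve"):
        resolved, assignment = resolve_experiment(crystals, config)

    with _timed("analyze"):
        all_stats, fits, scale_table = analyze_crystals(resolved, config)
        cohort = summarize_cohort(fits, config.cryo_reference_half_dose)

    with _timed("stats"):
        merging_table = merging_report(resolved, config, seed=config.seed)

    with _timed("report"):
        stats_rows = [vars(s) for stats in all_stats for s in stats]
        stats_table = pd.DataFrame(stats_rows)
        fit_table = pd.DataFrame(
            [
                _fit_row(str(df["crystal_id"].iloc[0]), fit)
                for df, fit in zip(resolved, fits)
            ]
        )
        stats_table.to_csv(out / "subset_stats.csv", index=False)
        scale_table.to_csv(out / "scale_fits.csv", index=False)
        fit_table.to_csv(out / "decay_fits.csv", index=False)
        merging_table.to_csv(out / "merging_stats.csv", index=False)
        report = {
            "version": __version__,
            "seed": config.seed,
            "config": _jsonable(asdict(config)),
            "modes": {
                "assignment": assignment.modes,
                "excluded": list(assignment.excluded),
                "note": "modes are defined modulo a global flip",
                "report": [list(row) for row in assignment.report],
            },
            "decay_fits": fit_table.to_dict(orient="records"),
            "cohort": _jsonable(vars(cohort)),
            "subset_stats": stats_table.to_dict(orient="records"),
            "scale_fits": scale_table.to_dict(orient="records"),
            "merging_stats": merging_table.to_dict(orient="records"),
        }
        with (out / "report.json").open("w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
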