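"""Synthetic ground truth and per-frame observation generation.

Produces data with the statistical structure the downstream analysis assumes:
Wilson-distributed (exponential) true intensities with a resolution-dependent
mean, per-frame exponential dose decay with a dose-insensitive floor, Poisson
counting noise, and an optional hidden two-state indexing mode per crystal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reflections import (
    ReindexOperator,
    SymmetryGroup,
    UnitCell,
    apply_reindex,
    d_spacing,
    default_reindex_operator,
    point_group_ops,
    unique_reflections,
)

__all__ = [
    "GroundTruth",
    "CrystalSimParams",
    "CrystalFrames",
    "ExperimentConfig",
    "DEFAULT_DECAY_PRESETS",
    "generate_truth",
    "simulate_crystal",
    "simulate_experiment",
]

#: (i0, i1, beta [1/kGy]) decay presets for the default five-crystal cohort,
#: matching the fitted room-temperature decay of five cubic insulin crystals.
DEFAULT_DECAY_PRESETS: tuple[tuple[float, float, float], ...] = (
    (1.04, 0.236, 0.0067),
    (1.06, 0.188, 0.0061),
    (1.02, 0.249, 0.0055),
    (1.03, 0.257, 0.0083),
    (0.97, 0.280, 0.0067),
)


@dataclass(frozen=True)
class GroundTruth:
    """True merged intensities, one per ASU reflection within ``d_min``."""

    cell: UnitCell
    group: SymmetryGroup
    d_min: float
    wilson_b: float
    indices: np.ndarray  # (N, 3) ASU representatives
    intensities: np.ndarray  # (N,) nonnegative

    @property
    def n_reflections(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class CrystalSimParams:
    """Per-crystal simulation parameters.

    ``i0_frac``/``i1_frac`` are the decaying and dose-insensitive amplitudes
    of the decay model ``i0*exp(-beta*D) + i1`` applied multiplicatively to
    every true intensity. ``noise_gain`` is detector counts per intensity
    unit; ``None`` disables counting noise entirely (the infinite-gain
    limit). ``indexing_mode`` 1 writes every index through the reindex
    operator, hiding the crystal's true orientation convention.
    """

    beta_true: float
    i0_frac: float = 1.0
    i1_frac: float = 0.0
    n_frames: int = 700
    dose_per_frame: float = 0.808
    obs_per_frame: int = 200
    noise_gain: float | None = 1.0
    sigma_bg: float = 0.5
    indexing_mode: int = 0
    #: int seed or a numpy SeedSequence (as handed out by simulate_experiment)
    seed: "int | np.random.SeedSequence" = 0

    def __post_init__(self) -> None:
        if self.beta_true <= 0:
            raise ValueError("beta_true must be positive")
        if self.i0_frac < 0 or self.i1_frac < 0:
            raise ValueError("decay amplitudes must be nonnegative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be at least 1")
        if self.indexing_mode not in (0, 1):
            raise ValueError("indexing_mode must be 0 or 1")
        if self.sigma_bg <= 0:
            raise ValueError("sigma_bg must be positive")


@dataclass(frozen=True)
class CrystalFrames:
    """All observations of one crystal plus its hidden simulation manifest."""

    crystal_id: str
    observations: pd.DataFrame
    params_hidden: CrystalSimParams


def generate_truth(
    cell: UnitCell,
    group: SymmetryGroup,
    d_min: float,
    wilson_b: float = 24.58,
    mean_intensity: float = 100.0,
    seed: int = 0,
    d_max: float | None = None,
    centering: str = "I",
) -> GroundTruth:
    """Draw one true intensity per ASU reflection out to ``d_min``.

    Intensities follow the acentric Wilson distribution: exponential with
    mean ``mean_intensity * exp(-2 * wilson_b * s^2)`` where
    ``s = sin(theta)/lambda = 1/(2d)``. Systematic absences of the I-centred
    lattice (h+k+l odd) are excluded by default. Deterministic per seed.
    """
    if d_min <= 0 or mean_intensity <= 0:
        raise ValueError("d_min and mean_intensity must be positive")
    indices = unique_reflections(cell, group, d_min, d_max=d_max, centering=centering)
    if len(indices) == 0:
        return GroundTruth(cell, group, d_min, wilson_b,
                           indices, np.empty(0, dtype=float))
    d = d_spacing(indices, cell)
    s2 = 1.0 / (4.0 * d * d)
    means = mean_intensity * np.exp(-2.0 * wilson_b * s2)
    rng = np.random.default_rng(seed)
    intensities = rng.exponential(means)
    return GroundTruth(cell, group, d_min, wilson_b, indices, intensities)


def _sample_reflections(rng, n_frames: int, n_avail: int, n_obs: int) -> np.ndarray:
    """Per-frame sample of distinct reflection rows, shape (n_frames, n_obs)."""
    ranks = rng.random((n_frames, n_avail))
    return np.argpartition(ranks, n_obs - 1, axis=1)[:, :n_obs] if n_obs < n_avail \
        else np.tile(np.arange(n_avail), (n_frames, 1))


def simulate_crystal(
    truth: GroundTruth,
    params: CrystalSimParams,
    crystal_id: str = "xtal1",
    reindex_op: ReindexOperator | None = None,
) -> CrystalFrames:
    """Simulate all frames of one crystal.

    Frame ``f`` (1-based) carries cumulative dose ``f * dose_per_frame``;
    every sampled reflection has expected intensity
    ``I_true(h) * (i0*exp(-beta*D_f) + i1)``. With finite ``noise_gain`` the
    observed value is a scaled Poisson draw and sigma the counting-statistics
    estimate ``sqrt(max(I,0)/gain + sigma_bg^2)``; with ``noise_gain=None``
    observations equal their expectations and sigma is the background floor.
    """
    if truth.n_reflections == 0:
        raise ValueError("cannot simulate from an empty ground truth")
    n_avail = truth.n_reflections
    n_obs = params.obs_per_frame
    if n_obs > n_avail:
        warnings.warn(
            f"obs_per_frame={n_obs} exceeds the {n_avail} available reflections; capping",
            stacklevel=2,
        )
        n_obs = n_avail
    rng = np.random.default_rng(params.seed)
    nf = params.n_frames
    sel = _sample_reflections(rng, nf, n_avail, n_obs)

    doses = np.arange(1, nf + 1, dtype=float) * params.dose_per_frame
    decay = params.i0_frac * np.exp(-params.beta_true * doses) + params.i1_frac
    expected = truth.intensities[sel] * decay[:, None]

    if params.noise_gain is None or np.isinf(params.noise_gain):
        observed = expected
        sigma = np.full_like(observed, params.sigma_bg)
    else:
        gain = params.noise_gain
        counts = rng.poisson(expected * gain)
        observed = counts / gain
        sigma = np.sqrt(np.maximum(observed, 0.0) / gain + params.sigma_bg**2)

    indices = truth.indices[sel.ravel()]
    if params.indexing_mode == 1:
        op = reindex_op if reindex_op is not None else default_reindex_operator(truth.group)
        indices = apply_reindex(indices, op)

    frames = np.repeat(np.arange(1, nf + 1, dtype=np.int64), n_obs)
    df = pd.DataFrame(
        {
            "h": indices[:, 0],
            "k": indices[:, 1],
            "l": indices[:, 2],
            "intensity": observed.ravel(),
            "sigma": sigma.ravel(),
            "frame": frames,
            "crystal_id": pd.Series([crystal_id] * len(frames), dtype=object),
        }
    )
    return CrystalFrames(crystal_id, df, params)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration for a multi-crystal synthetic experiment."""

    cell: UnitCell = UnitCell(78.8)
    group_name: str = "23"
    d_min: float = 1.9
    d_max: float | None = 30.0
    wilson_b: float = 24.58
    mean_intensity: float = 100.0
    n_crystals: int = 5
    decay_params: tuple[tuple[float, float, float], ...] = DEFAULT_DECAY_PRESETS
    n_frames: int = 700
    dose_per_frame: float = 0.808
    obs_per_frame: int = 200
    noise_gain: float | None = 1.0
    sigma_bg: float = 0.5
    reindex_matrix: tuple = ((0, 1, 0), (1, 0, 0), (0, 0, -1))
    mode_probability: float = 0.5
    centering: str = "I"


def simulate_experiment(
    config: ExperimentConfig, seed: int = 0
) -> tuple[list[CrystalFrames], dict]:
    """Simulate a cohort of crystals sharing one ground truth.

    Indexing modes are assigned independently at random (probability
    ``mode_probability`` of mode 1). Returns the crystals and a manifest
    recording the hidden truth: per-crystal decay parameters, modes and
    seeds. Fully deterministic for a fixed ``seed``.
    """
    if config.n_crystals < 1:
        raise ValueError("need at least one crystal")
    group = point_group_ops(config.group_name)
    op = ReindexOperator(np.asarray(config.reindex_matrix), group)
    ss = np.random.SeedSequence(seed)
    truth_seed, modes_seed, *crystal_seeds = ss.spawn(2 + config.n_crystals)
    truth = generate_truth(
        config.cell,
        group,
        config.d_min,
        wilson_b=config.wilson_b,
        mean_intensity=config.mean_intensity,
        seed=truth_seed,
        d_max=config.d_max,
        centering=config.centering,
    )
    mode_rng = np.random.default_rng(modes_seed)
    modes = (mode_rng.random(config.n_crystals) < config.mode_probability).astype(int)

    crystals: list[CrystalFrames] = []
    manifest: dict = {"seed": seed, "n_crystals": config.n_crystals, "crystals": []}
    for i in range(config.n_crystals):
        i0, i1, beta = config.decay_params[i % len(config.decay_params)]
        params = CrystalSimParams(
            beta_true=beta,
            i0_frac=i0,
            i1_frac=i1,
            n_frames=config.n_frames,
            dose_per_frame=config.dose_per_frame,
            obs_per_frame=config.obs_per_frame,
            noise_gain=config.noise_gain,
            sigma_bg=config.sigma_bg,
            indexing_mode=int(modes[i]),
            seed=crystal_seeds[i],
        )
        crystal_id = f"xtal{i + 1}"
        crystals.append(simulate_crystal(truth, params, crystal_id, reindex_op=op))
        manifest["crystals"].append(
            {
                "crystal_id": crystal_id,
                "indexing_mode": int(modes[i]),
                "beta_true": beta,
                "i0_frac": i0,
                "i1_frac": i1,
            }
        )
    manifest["truth"] = {
        "n_reflections": truth.n_reflections,
        "wilson_b": config.wilson_b,
        "d_min": config.d_min,
        "mean_intensity": config.mean_intensity,
    }
    return crystals, manifest
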