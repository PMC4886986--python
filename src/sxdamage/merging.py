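"""Cross-crystal merging and standard data-quality statistics.

Observations (with indexing modes already resolved) are pooled, mapped to the
ASU and merged by unweighted mean per unique index. On the unmerged pool the
module computes R_merge, R_meas, the random half-dataset correlation CC_1/2
with its signal estimate CC*, completeness against the theoretically possible
I-centred reflection set, and mean multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ambiguity import pearson_r
from .reflections import (
    SymmetryGroup,
    UnitCell,
    map_to_asu,
    pack_indices,
    unique_reflections,
    unpack_indices,
)

__all__ = [
    "MergedDataset",
    "merge",
    "r_factors",
    "cc_half",
    "cc_star",
    "completeness_multiplicity",
]


@dataclass(frozen=True)
class MergedDataset:
    """Per-unique-index merged intensities plus bookkeeping totals."""

    table: pd.DataFrame  # columns h, k, l, intensity, sigma, multiplicity
    total_observations: int
    unique_reflections: int
    d_min: float
    d_max: float


def _asu_groups(observations: pd.DataFrame, group: SymmetryGroup):
    """ASU-mapped unique indices plus the inverse map onto observations."""
    hkl = observations[["h", "k", "l"]].to_numpy()
    asu = map_to_asu(hkl, group)
    codes, inverse = np.unique(pack_indices(asu), return_inverse=True)
    return unpack_indices(codes), inverse


def merge(observations: pd.DataFrame, group: SymmetryGroup, cell: UnitCell | None = None) -> MergedDataset:
    """Unweighted mean merge after ASU mapping.

    Merged sigma is the propagated standard error of the unweighted mean,
    ``sqrt(sum sigma_i^2) / n``.
    """
    if len(observations) == 0:
        raise ValueError("no observations to merge")
    uniq, inverse = _asu_groups(observations, group)
    counts = np.bincount(inverse)
    mean_i = np.bincount(inverse, weights=observations["intensity"].to_numpy()) / counts
    var_sum = np.bincount(inverse, weights=observations["sigma"].to_numpy() ** 2)
    merged_sigma = np.sqrt(var_sum) / counts
    table = pd.DataFrame(
        {
            "h": uniq[:, 0],
            "k": uniq[:, 1],
            "l": uniq[:, 2],
            "intensity": mean_i,
            "sigma": merged_sigma,
            "multiplicity": counts,
        }
    )
    if cell is not None:
        from .reflections import d_spacing

        d = d_spacing(uniq, cell)
        d_lo, d_hi = float(d.min()), float(d.max())
    else:
        d_lo = d_hi = float("nan")
    return MergedDataset(
        table=table,
        total_observations=int(len(observations)),
        unique_reflections=int(len(uniq)),
        d_min=d_lo,
        d_max=d_hi,
    )


def r_factors(
    observations: pd.DataFrame, group: SymmetryGroup
) -> tuple[float | None, float | None]:
    """(R_merge, R_meas) over indices observed at least twice.

    R_merge sums ``|I_i - <I_h>|`` over all observations of multiply-measured
    indices, divided by the summed intensities of those observations; R_meas
    scales each index's deviations by ``sqrt(n_h / (n_h - 1))``. Returns
    ``(None, None)`` when no index has multiplicity >= 2.
    """
    _, inverse = _asu_groups(observations, group)
    intensity = observations["intensity"].to_numpy()
    counts = np.bincount(inverse)
    multi = counts[inverse] >= 2
    if not multi.any():
        return None, None
    means = np.bincount(inverse, weights=intensity) / counts
    dev = np.abs(intensity - means[inverse])[multi]
    denom = intensity[multi].sum()
    n_h = counts[inverse][multi]
    r_merge = float(dev.sum() / denom)
    r_meas = float((np.sqrt(n_h / (n_h - 1.0)) * dev).sum() / denom)
    return r_merge, r_meas


def cc_star(cc_half_value: float) -> float | None:
    """``CC* = sqrt(2*CC_1/2 / (1 + CC_1/2))``; None for a nonpositive radicand."""
    radicand = 2.0 * cc_half_value / (1.0 + cc_half_value)
    if radicand < 0:
        return None
    return float(np.sqrt(radicand))


def cc_half(
    observations: pd.DataFrame, group: SymmetryGroup, seed: int = 0
) -> tuple[float, float | None]:
    """Random half-dataset correlation (CC_1/2, CC*).

    Observations of each multiply-measured index are shuffled with a
    generator keyed on ``(index, seed)`` — the split therefore does not
    depend on input row order — and assigned alternately to two halves;
    CC_1/2 is the Pearson correlation between the half-set means.
    """
    uniq, inverse = _asu_groups(observations, group)
    intensity = observations["intensity"].to_numpy()
    # one global sort keyed on observation identity -> row order cannot matter
    _, id_codes = np.unique(observations["crystal_id"].to_numpy(), return_inverse=True)
    order = np.lexsort(
        (
            observations["sigma"].to_numpy(),
            intensity,
            observations["frame"].to_numpy(),
            id_codes,
            inverse,
        )
    )
    sorted_inverse = inverse[order]
    bounds = np.flatnonzero(np.diff(sorted_inverse)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [len(sorted_inverse)]])
    half_a: list[float] = []
    half_b: list[float] = []
    for start, stop in zip(starts, stops):
        if stop - start < 2:
            continue
        rows = order[start:stop]
        h, k, l = (int(v) for v in uniq[sorted_inverse[start]])
        rng = np.random.default_rng([seed, h + 1024, k + 1024, l + 1024])
        perm = rng.permutation(len(rows))
        half_a.append(float(intensity[rows[perm[0::2]]].mean()))
        half_b.append(float(intensity[rows[perm[1::2]]].mean()))
    if len(half_a) < 3:
        raise ValueError(
            f"need >= 3 indices with multiplicity >= 2 for CC_1/2, got {len(half_a)}"
        )
    keys = list(range(len(half_a)))
    res = pearson_r(dict(zip(keys, half_a)), dict(zip(keys, half_b)), min_common=3)
    return res.r, cc_star(res.r)


def completeness_multiplicity(
    merged: MergedDataset,
    cell: UnitCell,
    group: SymmetryGroup,
    d_min: float,
    d_max: float,
    centering: str = "I",
) -> tuple[float, float]:
    """(completeness %, mean multiplicity) against the theoretical ASU set.

    Completeness counts observed unique indices inside ``[d_min, d_max]``
    over the brute-force-enumerated theoretically possible set for the given
    centering.
    """
    theory = unique_reflections(cell, group, d_min, d_max=d_max, centering=centering)
    if len(theory) == 0:
        raise ValueError("theoretical reflection set is empty for this range")
    from .reflections import d_spacing

    uniq = merged.table[["h", "k", "l"]].to_numpy()
    d = d_spacing(uniq, cell)
    in_range = uniq[(d >= d_min) & (d <= d_max)]
    theory_set = {tuple(t) for t in theory.tolist()}
    observed = sum(tuple(row) in theory_set for row in in_range.tolist())
    completeness = 100.0 * observed / len(theory)
    multiplicity = merged.total_observations / merged.unique_reflections
    return float(completeness), float(multiplicity)
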