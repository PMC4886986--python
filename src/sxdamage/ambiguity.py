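"""Two-state indexing-ambiguity resolution by intensity correlation.

Crystals indexed in different modes of an ambiguous lattice disagree on which
orbit a reflection belongs to; merging them naively destroys the signal. The
resolver merges each crystal's observations to per-ASU-index means, then
greedily assigns each crystal the mode (keep or reindex) that maximizes the
Pearson correlation of common reflections against an accumulating reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reflections import (
    ReindexOperator,
    SymmetryGroup,
    apply_reindex,
    map_to_asu,
    pack_indices,
    unpack_indices,
)

__all__ = [
    "MergedPartial",
    "PearsonResult",
    "ModeAssignment",
    "merged_partial",
    "reindex_partial",
    "pearson_r",
    "resolve_modes",
]

#: below this many common reflections a correlation is flagged untrustworthy
MIN_COMMON_DEFAULT = 10


@dataclass(frozen=True)
class MergedPartial:
    """Per-crystal mean intensity for each ASU Miller index."""

    crystal_id: str
    intensities: dict[tuple[int, int, int], float]

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class PearsonResult:
    r: float
    n_common: int
    reliable: bool


@dataclass(frozen=True)
class ModeAssignment:
    """Resolved indexing modes, valid modulo a global flip of all modes."""

    modes: dict[str, int]
    excluded: tuple[str, ...] = ()
    #: rows (crystal_id, r_keep, r_reindex, n_common_keep, n_common_reindex, mode)
    report: tuple[tuple, ...] = ()


def merged_partial(
    observations: pd.DataFrame, group: SymmetryGroup, crystal_id: str | None = None
) -> MergedPartial:
    """Collapse one crystal's observations to unweighted per-ASU-index means."""
    if crystal_id is None:
        ids = observations["crystal_id"].unique()
        crystal_id = str(ids[0]) if len(ids) == 1 else "merged"
    hkl = observations[["h", "k", "l"]].to_numpy()
    if len(hkl) == 0:
        return MergedPartial(crystal_id, {})
    asu = map_to_asu(hkl, group)
    codes, inverse = np.unique(pack_indices(asu), return_inverse=True)
    uniq = unpack_indices(codes)
    sums = np.bincount(inverse, weights=observations["intensity"].to_numpy())
    counts = np.bincount(inverse)
    means = sums / counts
    table = {tuple(int(v) for v in idx): float(m) for idx, m in zip(uniq, means)}
    return MergedPartial(crystal_id, table)


def reindex_partial(
    partial: MergedPartial, op: ReindexOperator, group: SymmetryGroup
) -> MergedPartial:
    """Apply the reindexing operator to every index and re-map to the ASU."""
    if not partial.intensities:
        return partial
    idx = np.array(list(partial.intensities), dtype=np.int64)
    new_idx = map_to_asu(apply_reindex(idx, op), group)
    values = list(partial.intensities.values())
    return MergedPartial(
        partial.crystal_id,
        {tuple(int(v) for v in ix): val for ix, val in zip(new_idx, values)},
    )


def pearson_r(
    a: MergedPartial | dict,
    b: MergedPartial | dict,
    min_common: int = MIN_COMMON_DEFAULT,
) -> PearsonResult:
    """Product-moment correlation of common-reflection mean intensities.

    Raises ``ValueError`` when fewer than two common indices exist or either
    side has zero variance on the intersection. Results computed on fewer
    than ``min_common`` reflections carry ``reliable=False``.
    """
    da = a.intensities if isinstance(a, MergedPartial) else a
    db = b.intensities if isinstance(b, MergedPartial) else b
    common = sorted(da.keys() & db.keys())
    n = len(common)
    if n < 2:
        raise ValueError(f"need at least 2 common reflections, got {n}")
    x = np.array([da[h] for h in common])
    y = np.array([db[h] for h in common])
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on the common reflection set")
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return PearsonResult(r, n, n >= min_common)


def _try_pearson(ref: dict, cand: dict, min_common: int) -> PearsonResult | None:
    try:
        return pearson_r(ref, cand, min_common)
    except ValueError:
        return None


def resolve_modes(
    crystals: list[MergedPartial],
    op: ReindexOperator,
    group: SymmetryGroup,
    min_common: int = MIN_COMMON_DEFAULT,
) -> ModeAssignment:
    """Greedy sequential mode assignment against an accumulating reference.

    The first crystal anchors mode 0. Each subsequent crystal is correlated
    against the running reference both as-is and reindexed; the better mode
    wins and the crystal's means join the reference (mean of per-crystal
    means per index). Crystals that cannot be compared reliably in either
    mode are excluded with a warning. The assignment is unique only up to a
    global flip of every mode.
    """
    if not crystals:
        raise ValueError("need at least one crystal")
    ref_sum: dict[tuple, float] = {}
    ref_cnt: dict[tuple, int] = {}

    def absorb(partial: MergedPartial) -> None:
        for h, v in partial.intensities.items():
            ref_sum[h] = ref_sum.get(h, 0.0) + v
            ref_cnt[h] = ref_cnt.get(h, 0) + 1

    modes: dict[str, int] = {crystals[0].crystal_id: 0}
    report: list[tuple] = []
    excluded: list[str] = []
    absorb(crystals[0])

    for partial in crystals[1:]:
        ref_mean = {h: ref_sum[h] / ref_cnt[h] for h in ref_sum}
        flipped = reindex_partial(partial, op, group)
        res0 = _try_pearson(ref_mean, partial.intensities, min_common)
        res1 = _try_pearson(ref_mean, flipped.intensities, min_common)
        ok0 = res0 is not None and res0.reliable
        ok1 = res1 is not None and res1.reliable
        if not ok0 and not ok1:
            warnings.warn(
                f"crystal {partial.crystal_id}: fewer than {min_common} common "
                "reflections in both modes; excluded from the assignment",
                stacklevel=2,
            )
            excluded.append(partial.crystal_id)
            continue
        r0 = res0.r if ok0 else -np.inf
        r1 = res1.r if ok1 else -np.inf
        if r0 == r1:
            warnings.warn(
                f"crystal {partial.crystal_id}: correlation tie (r={r0:.4f}); "
                "keeping mode 0",
                stacklevel=2,
            )
            mode = 0
        else:
            mode = int(r1 > r0)
        modes[partial.crystal_id] = mode
        absorb(flipped if mode == 1 else partial)
        report.append(
            (
                partial.crystal_id,
                None if res0 is None else res0.r,
                None if res1 is None else res1.r,
                0 if res0 is None else res0.n_common,
                0 if res1 is None else res1.n_common,
                mode,
            )
        )
    return ModeAssignment(modes, tuple(excluded), tuple(report))
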