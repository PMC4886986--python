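"""Miller-index arithmetic, point-group symmetry and unmerged reflection I/O.

Supports the cubic setting needed for the damage analysis: resolution from a
cubic cell, the proper rotations of point groups ``1`` and ``23``, mapping of
indices to a canonical asymmetric-unit (ASU) representative under the point
group plus Friedel symmetry, the two-fold reindexing operator that converts
between the two indexing modes of an ambiguous lattice, and a plain-text
column format for unmerged per-frame observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReflectionError",
    "UnitCell",
    "SymmetryGroup",
    "ReindexOperator",
    "Observation",
    "OBS_COLUMNS",
    "d_spacing",
    "point_group_ops",
    "sym_equivalents",
    "map_to_asu",
    "apply_reindex",
    "default_reindex_operator",
    "unique_reflections",
    "read_reflections",
    "write_reflections",
]

#: column order of the unmerged reflection text format
OBS_COLUMNS = ["h", "k", "l", "intensity", "sigma", "frame", "crystal_id"]


class ReflectionError(ValueError):
    """Raised for invalid Miller indices, malformed files or bad symmetry input."""


@dataclass(frozen=True)
class UnitCell:
    """Cubic unit cell: ``b = c = a``, all angles 90 degrees.

    Parameters
    ----------
    a : float
        Lattice constant in Angstrom; must be positive.
    """

    a: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ReflectionError(f"cell edge must be positive, got {self.a}")


@dataclass(frozen=True)
class SymmetryGroup:
    """A rotational point group given by its proper rotation matrices.

    ``rotations`` has shape ``(n, 3, 3)``, integer entries, determinant +1,
    and always contains the identity.
    """

    name: str
    rotations: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotations, dtype=np.int64)
        object.__setattr__(self, "rotations", rot)
        if rot.ndim != 3 or rot.shape[1:] != (3, 3):
            raise ReflectionError("rotations must have shape (n, 3, 3)")

    @property
    def order(self) -> int:
        return len(self.rotations)

    def contains(self, matrix: np.ndarray) -> bool:
        """True if ``matrix`` equals one of the group rotations."""
        m = np.asarray(matrix, dtype=np.int64)
        return bool(np.any(np.all(self.rotations == m, axis=(1, 2))))

    def laue_contains(self, matrix: np.ndarray) -> bool:
        """True if ``matrix`` is in the Laue group (rotations plus inversion)."""
        return self.contains(matrix) or self.contains(-np.asarray(matrix))


@dataclass(frozen=True)
class Observation:
    """One measured reflection on one frame of one crystal."""

    h: int
    k: int
    l: int
    intensity: float
    sigma: float
    frame: int
    crystal_id: str

    def __post_init__(self) -> None:
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ReflectionError("(0,0,0) is not a valid observation index")
        if not self.sigma > 0:
            raise ReflectionError(f"sigma must be positive, got {self.sigma}")
        if self.frame < 1:
            raise ReflectionError(f"frame numbers are 1-based, got {self.frame}")


def _closure(generators: list[np.ndarray]) -> np.ndarray:
    """All products of the generators (breadth-first until stable)."""
    seen: dict[bytes, np.ndarray] = {}
    frontier = [np.eye(3, dtype=np.int64)] + [g.astype(np.int64) for g in generators]
    for m in frontier:
        seen.setdefault(m.tobytes(), m)
    frontier = list(seen.values())
    while frontier:
        new = []
        for a in frontier:
            for g in list(seen.values()):
                for prod in (a @ g, g @ a):
                    key = prod.tobytes()
                    if key not in seen:
                        seen[key] = prod
                        new.append(prod)
        frontier = new
    return np.stack(sorted(seen.values(), key=lambda m: m.tobytes()))


def point_group_ops(name: str) -> SymmetryGroup:
    """Proper rotations of a supported point group.

    ``"1"`` gives the identity only; ``"23"`` gives the 12 rotations of the
    cubic tetartoidal group (identity, three two-folds along the cell axes and
    eight three-folds along the body diagonals), generated by closure from a
    two-fold about z and a three-fold about (1,1,1).
    """
    if name == "1":
        return SymmetryGroup("1", np.eye(3, dtype=np.int64)[None])
    if name == "23":
        twofold_z = np.diag([-1, -1, 1]).astype(np.int64)
        threefold_111 = np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]], dtype=np.int64)
        rotations = _closure([twofold_z, threefold_111])
        if len(rotations) != 12:  # pragma: no cover - structural sanity
            raise ReflectionError("point group 23 closure did not yield 12 rotations")
        return SymmetryGroup("23", rotations)
    raise ReflectionError(f"unsupported point group: {name!r}")


def _as_index_array(hkl) -> tuple[np.ndarray, bool]:
    """Coerce to an (N, 3) int array; report whether input was a single triple."""
    arr = np.asarray(hkl, dtype=np.int64)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 3:
        raise ReflectionError(f"Miller indices must be triples, got shape {arr.shape}")
    return arr, single


def d_spacing(hkl, cell: UnitCell):
    """Resolution in Angstrom of reflection(s) ``hkl`` in a cubic cell.

    ``d = a / sqrt(h^2 + k^2 + l^2)``. The zero index is forbidden.
    """
    arr, single = _as_index_array(hkl)
    norm2 = np.sum(arr * arr, axis=-1)
    if np.any(norm2 == 0):
        raise ReflectionError("(0,0,0) has no d-spacing")
    d = cell.a / np.sqrt(norm2)
    return float(d[0]) if single else d


def sym_equivalents(hkl, group: SymmetryGroup, friedel: bool = True) -> np.ndarray:
    """All symmetry images of ``hkl``: shape ``(n_ops[*2], N, 3)``."""
    arr, _ = _as_index_array(hkl)
    images = np.einsum("oij,nj->oni", group.rotations, arr)
    if friedel:
        images = np.concatenate([images, -images], axis=0)
    return images

_ASU_CHUNK = 200_000


def map_to_asu(hkl, group: SymmetryGroup, friedel: bool = True):
    """Canonical ASU representative of each index.

    The representative is the lexicographically greatest ``(h, k, l)`` over
    the full orbit under the group rotations (and Friedel inversion unless
    ``friedel=False``).  Idempotent; every member of an orbit maps to the
    same triple.
    """
    arr, single = _as_index_array(hkl)
    if np.any(np.all(arr == 0, axis=-1)):
        raise ReflectionError("(0,0,0) cannot be mapped to the ASU")
    out = np.empty_like(arr)
    for start in range(0, len(arr), _ASU_CHUNK):
        chunk = arr[start:start + _ASU_CHUNK]
        images = sym_equivalents(chunk, group, friedel=friedel)
        # lexicographic max via a signed base-M positional code
        m = 2 * int(np.abs(images).max()) + 1
        code = (images[..., 0].astype(np.int64) * m + images[..., 1]) * m + images[..., 2]
        best = code.argmax(axis=0)
        out[start:start + _ASU_CHUNK] = images[best, np.arange(len(chunk))]
    return tuple(int(v) for v in out[0]) if single else out


@dataclass(frozen=True)
class ReindexOperator:
    """Integer matrix converting one indexing mode into the other.

    The operator must have determinant +-1, must not itself belong to the
    Laue group of ``group`` (otherwise it would change nothing), and its
    square must land back in the Laue group (a two-state ambiguity).
    Validation runs at construction when a group is supplied.
    """

    matrix: np.ndarray
    group: SymmetryGroup | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.int64)
        object.__setattr__(self, "matrix", m)
        if m.shape != (3, 3):
            raise ReflectionError("reindex operator must be a 3x3 matrix")
        det = int(round(np.linalg.det(m)))
        if det not in (-1, 1):
            raise ReflectionError(f"reindex operator must have det +-1, got {det}")
        if self.group is not None:
            if self.group.laue_contains(m):
                raise ReflectionError(
                    "reindex operator lies in the Laue group; it resolves nothing"
                )
            if not self.group.laue_contains(m @ m):
                raise ReflectionError(
                    "square of the reindex operator must lie in the Laue group"
                )

    def apply(self, hkl):
        return apply_reindex(hkl, self)


def default_reindex_operator(group: SymmetryGroup | None = None) -> ReindexOperator:
    """The two-fold (h,k,l) -> (k,h,-l), the standard choice for point group 23.

    It is a coset representative of the cubic holohedry over the Laue group
    m-3: determinant +1, not in the Laue group, square equal to the identity.
    """
    m = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]], dtype=np.int64)
    return ReindexOperator(m, group)


def apply_reindex(hkl, op: ReindexOperator):
    """Apply the reindexing matrix to index/indices ``hkl``."""
    arr, single = _as_index_array(hkl)
    out = arr @ op.matrix.T
    return tuple(int(v) for v in out[0]) if single else out


_PACK_BASE = 4096
_PACK_HALF = 2048


def pack_indices(hkl: np.ndarray) -> np.ndarray:
    """Encode (N, 3) Miller indices as single int64 keys (|index| < 2048)."""
    arr = np.asarray(hkl, dtype=np.int64)
    if np.abs(arr).max(initial=0) >= _PACK_HALF:
        raise ReflectionError("indices too large to pack")
    return (
        (arr[:, 0] + _PACK_HALF) * _PACK_BASE + (arr[:, 1] + _PACK_HALF)
    ) * _PACK_BASE + (arr[:, 2] + _PACK_HALF)


def unpack_indices(codes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_indices`."""
    codes = np.asarray(codes, dtype=np.int64)
    l = codes % _PACK_BASE - _PACK_HALF
    rest = codes // _PACK_BASE
    k = rest % _PACK_BASE - _PACK_HALF
    h = rest // _PACK_BASE - _PACK_HALF
    return np.stack([h, k, l], axis=1)


#: memo for the brute-force enumeration; keyed on all scalar arguments plus
#: the group name (group names are assumed to identify their rotation sets)
_REFLECTION_CACHE: dict[tuple, np.ndarray] = {}


def unique_reflections(
    cell: UnitCell,
    group: SymmetryGroup,
    d_min: float,
    d_max: float | None = None,
    centering: str = "I",
) -> np.ndarray:
    """All distinct ASU representatives within a resolution range.

    Enumerates the full index ball out to ``d_min``, applies the lattice
    centering condition (``"I"``: h+k+l even; ``"P"``: none), maps every
    surviving index to its ASU representative and deduplicates.

    Returns an ``(N, 3)`` integer array sorted lexicographically. Empty (with
    a warning) when no reflection satisfies the constraints.
    """
    if d_min <= 0:
        raise ReflectionError("d_min must be positive")
    if centering not in ("I", "P"):
        raise ReflectionError(f"unsupported centering: {centering!r}")
    cache_key = (cell.a, group.name, d_min, d_max, centering)
    if cache_key in _REFLECTION_CACHE:
        return _REFLECTION_CACHE[cache_key].copy()
    hmax = int(np.floor(cell.a / d_min))
    if hmax < 1:
        warnings.warn("resolution cutoff excludes every reflection", stacklevel=2)
        return np.empty((0, 3), dtype=np.int64)
    rng1 = np.arange(-hmax, hmax + 1, dtype=np.int64)
    grid = np.stack(np.meshgrid(rng1, rng1, rng1, indexing="ij"), axis=-1).reshape(-1, 3)
    norm2 = np.sum(grid * grid, axis=1)
    mask = norm2 > 0
    mask &= cell.a * cell.a >= d_min * d_min * norm2  # d >= d_min
    if d_max is not None:
        mask &= cell.a * cell.a <= d_max * d_max * norm2  # d <= d_max
    if centering == "I":
        mask &= (grid.sum(axis=1) % 2) == 0
    grid = grid[mask]
    if len(grid) == 0:
        warnings.warn("resolution cutoff excludes every reflection", stacklevel=2)
        return np.empty((0, 3), dtype=np.int64)
    asu = map_to_asu(grid, group)
    result = unpack_indices(np.unique(pack_indices(asu)))
    _REFLECTION_CACHE[cache_key] = result
    return result.copy()


# ---------------------------------------------------------------------------
# unmerged reflection text format
# ---------------------------------------------------------------------------

def write_reflections(
    observations: pd.DataFrame,
    path,
    cell: UnitCell | None = None,
    group_name: str | None = None,
    dose_per_frame: float | None = None,
) -> None:
    """Write observations as `H K L INTENSITY SIGMA FRAME CRYSTAL_ID` lines.

    A ``#``-prefixed header records the cell, point group and dose per frame
    when given. Intensities and sigmas are printed with enough digits to
    round-trip through :func:`read_reflections`.
    """
    df = observations
    path = Path(path)
    with path.open("w") as fh:
        if cell is not None:
            fh.write(f"# cell_a {cell.a!r}\n")
        if group_name is not None:
            fh.write(f"# point_group {group_name}\n")
        if dose_per_frame is not None:
            fh.write(f"# dose_per_frame {dose_per_frame!r}\n")
        fh.write("# h k l intensity sigma frame crystal_id\n")
        if len(df) == 0:
            return
        cols = [df[c].to_numpy() for c in OBS_COLUMNS]
        for h, k, l, i, s, f, cid in zip(*cols):
            fh.write(f"{h} {k} {l} {float(i)!r} {float(s)!r} {f} {cid}\n")


def read_reflections(path) -> tuple[pd.DataFrame, dict]:
    """Read the unmerged reflection text format.

    Returns ``(observations, meta)`` where ``meta`` holds any ``key value``
    pairs found in header comments. Malformed lines and non-positive sigmas
    raise :class:`ReflectionError` naming the offending line number.
    """
    path = Path(path)
    meta: dict[str, object] = {}
    h, k, l, inten, sig, frm, cid = [], [], [], [], [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                tokens = line[1:].split()
                if len(tokens) == 2:
                    key, value = tokens
                    try:
                        meta[key] = float(value)
                    except ValueError:
                        meta[key] = value
                continue
            tokens = line.split()
            if len(tokens) != 7:
                raise ReflectionError(
                    f"{path.name}, line {lineno}: expected 7 columns, got {len(tokens)}"
                )
            try:
                h.append(int(tokens[0]))
                k.append(int(tokens[1]))
                l.append(int(tokens[2]))
                inten.append(float(tokens[3]))
                sig.append(float(tokens[4]))
                frm.append(int(tokens[5]))
            except ValueError as exc:
                raise ReflectionError(f"{path.name}, line {lineno}: {exc}") from exc
            if sig[-1] <= 0:
                raise ReflectionError(
                    f"{path.name}, line {lineno}: sigma must be positive, got {sig[-1]}"
                )
            if frm[-1] < 1:
                raise ReflectionError(
                    f"{path.name}, line {lineno}: frames are 1-based, got {frm[-1]}"
                )
            cid.append(tokens[6])
    df = pd.DataFrame(
        {
            "h": np.asarray(h, dtype=np.int64),
            "k": np.asarray(k, dtype=np.int64),
            "l": np.asarray(l, dtype=np.int64),
            "intensity": np.asarray(inten, dtype=float),
            "sigma": np.asarray(sig, dtype=float),
            "frame": np.asarray(frm, dtype=np.int64),
            "crystal_id": pd.Series(cid, dtype=object),
        }
    )
    return df, meta


def observations_to_frame(observations: list[Observation]) -> pd.DataFrame:
    """Convert a list of :class:`Observation` records to the table layout."""
    return pd.DataFrame([vars(o) for o in observations], columns=OBS_COLUMNS)
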