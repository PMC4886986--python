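"""Relative scaling of dose subsets against a reference subset.

Each subset of one crystal is placed on the scale of that crystal's first
subset through ``I_scaled(h) = K * exp(-2*B*s^2) * I_meas(h)`` with
``s = sin(theta)/lambda = 1/(2d)``: an overall scale ``K`` and a relative B
factor ``B`` describing the resolution-dependent intensity loss of the
damaged subset. The fit is a closed-form log-linear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ambiguity import MergedPartial
from .reflections import UnitCell, d_spacing

__all__ = ["ScaleFit", "fit_relative_scale", "apply_scale"]


@dataclass(frozen=True)
class ScaleFit:
    """Result of scaling one subset against a reference.

    Positive ``B`` means the subset's high-resolution intensities have
    fallen relative to the reference. ``residual`` is the sum of squared
    log-intensity differences after scaling.
    """

    K: float
    B: float
    n_common: int
    residual: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"scale factor must be positive, got {self.K}")


def _common_positive(subset: MergedPartial, reference: MergedPartial):
    common = sorted(
        h
        for h in subset.intensities.keys() & reference.intensities.keys()
        if subset.intensities[h] > 0 and reference.intensities[h] > 0
    )
    i_sub = np.array([subset.intensities[h] for h in common])
    i_ref = np.array([reference.intensities[h] for h in common])
    return common, i_sub, i_ref


def fit_relative_scale(
    subset: MergedPartial, reference: MergedPartial, cell: UnitCell
) -> ScaleFit:
    """Fit (K, B) so that ``K*exp(-2B*s^2)*I_subset`` best matches the reference.

    Equivalent to the straight-line fit of ``ln(I_ref/I_subset)`` against
    ``2*s^2``: slope ``B``, intercept ``ln K``. Non-positive intensities are
    excluded; fewer than three surviving common reflections is an error.
    Fitting a subset against itself returns exactly ``K=1, B=0``.
    """
    common, i_sub, i_ref = _common_positive(subset, reference)
    if len(common) < 3:
        raise ValueError(
            f"need at least 3 common positive reflections, got {len(common)}"
        )
    d = d_spacing(np.array(common, dtype=np.int64), cell)
    x = 2.0 / (4.0 * d * d)  # 2*s^2
    y = np.log(i_ref) - np.log(i_sub)
    if np.ptp(y) == 0 and y[0] == 0:
        # exact self-scaling short circuit keeps the invariant K=1, B=0 exact
        return ScaleFit(1.0, 0.0, len(common), 0.0)
    slope, intercept = np.polyfit(x, y, 1)
    residual = float(np.sum((y - (slope * x + intercept)) ** 2))
    return ScaleFit(float(np.exp(intercept)), float(slope), len(common), residual)


def apply_scale(subset: MergedPartial, fit: ScaleFit, cell: UnitCell) -> MergedPartial:
    """Scale the subset onto the reference: ``I -> K * exp(2B*s^2) * I``.

    The positive exponent undoes the subset's Wilson-type smearing
    ``exp(-2B*s^2)`` relative to the reference, so applying the fit obtained
    against a reference and re-fitting yields exactly ``(K, B) = (1, 0)``.
    """
    if not subset.intensities:
        return subset
    idx = np.array(list(subset.intensities), dtype=np.int64)
    values = np.array(list(subset.intensities.values()))
    d = d_spacing(idx, cell)
    s2 = 1.0 / (4.0 * d * d)
    scaled = fit.K * np.exp(2.0 * fit.B * s2) * values
    return MergedPartial(
        subset.crystal_id,
        {tuple(int(v) for v in ix): float(val) for ix, val in zip(idx, scaled)},
    )
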