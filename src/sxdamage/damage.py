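"""Dose-wedge subsetting, decay fitting and derived damage metrics.

The frames of each crystal are split into consecutive equal-size dose wedges;
per-wedge mean intensities (normalized to the first wedge) are fitted with

    I(D) = I0 * exp(-beta_tot * D) + I1

by nonlinear least squares. Derived quantities: the specific dose
``D* = 1/beta_tot`` (dose to reduce the decaying component to 1/e), the
half-dose ``D_1/2 = D* * ln[2*I0/(I0 - I1)]`` (dose to halve the initial
intensity ``I0 + I1``), and the undamaged fraction ``I1/(I0 + I1)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm as norm_dist
from scipy.stats import t as student_t

from .reflections import UnitCell, d_spacing

__all__ = [
    "DoseSchedule",
    "SubsetStats",
    "DecayFit",
    "CohortSummary",
    "DecayFitError",
    "split_subsets",
    "subset_dose",
    "subset_summary",
    "fit_decay",
    "half_dose",
    "undamaged_fraction",
    "derived_doses",
    "decay_fit_from_parameters",
    "summarize_cohort",
]

#: default cryogenic reference half-dose, kGy (43 MGy)
CRYO_REFERENCE_HALF_DOSE = 43_000.0


class DecayFitError(RuntimeError):
    """Raised when the decay model cannot be fitted to the given points."""


@dataclass(frozen=True)
class DoseSchedule:
    """Per-frame dose and wedge size; trailing frames that do not fill a
    complete wedge are dropped."""

    dose_per_frame: float = 0.808
    subset_size: int = 50

    def __post_init__(self) -> None:
        if self.dose_per_frame <= 0:
            raise ValueError("dose_per_frame must be positive")
        if self.subset_size < 1:
            raise ValueError("subset_size must be at least 1")


def subset_dose(subset_index: int, schedule: DoseSchedule) -> float:
    """Cumulative dose (kGy) at the END of 1-based wedge ``subset_index``."""
    if subset_index < 1:
        raise ValueError("subset_index is 1-based")
    return subset_index * schedule.subset_size * schedule.dose_per_frame


def split_subsets(
    observations: pd.DataFrame, schedule: DoseSchedule
) -> list[pd.DataFrame]:
    """Split observations into consecutive non-overlapping frame wedges.

    Wedge ``i`` (1-based) holds frames ``(i-1)*size+1 .. i*size``; the count
    is ``floor(n_frames / size)`` with the remainder dropped.
    """
    n_frames = int(observations["frame"].max())
    size = schedule.subset_size
    if n_frames < size:
        raise ValueError(
            f"{n_frames} frames cannot fill a single subset of {size} frames"
        )
    n_subsets = n_frames // size
    frame = observations["frame"]
    return [
        observations[(frame > i * size) & (frame <= (i + 1) * size)]
        for i in range(n_subsets)
    ]


@dataclass(frozen=True)
class SubsetStats:
    """Summary of one dose wedge, normalized to the first wedge.

    ``mean_intensity_sem`` is the standard error of the wedge mean
    (``std/sqrt(n)``); the ``_norm`` variants divide by the first wedge's
    mean intensity.
    """

    crystal_id: str
    subset_index: int
    dose: float
    mean_intensity: float
    mean_intensity_norm: float
    mean_intensity_sem: float
    mean_intensity_norm_sem: float
    shell_i_over_sigma: float | None
    shell_i_over_sigma_norm: float | None
    n_obs: int


def _shell_i_over_sigma(
    observations: pd.DataFrame, cell: UnitCell, shell: tuple[float, float]
) -> float | None:
    d_max, d_min = max(shell), min(shell)
    d = d_spacing(observations[["h", "k", "l"]].to_numpy(), cell)
    mask = (d >= d_min) & (d < d_max)
    if not mask.any():
        return None
    sub = observations[mask]
    return float((sub["intensity"] / sub["sigma"]).mean())


def subset_summary(
    observations: pd.DataFrame,
    subset_index: int,
    schedule: DoseSchedule,
    cell: UnitCell,
    shell: tuple[float, float] = (2.4, 1.9),
    first: "SubsetStats | None" = None,
    crystal_id: str | None = None,
) -> SubsetStats:
    """Mean intensity and high-resolution-shell I/sigma of one wedge.

    Normalized fields divide by the first wedge's values (pass ``first=None``
    for the first wedge itself, whose normalized values are exactly 1). An
    empty resolution shell reports ``None`` rather than zero.
    """
    if len(observations) == 0:
        raise ValueError("subset is empty")
    if crystal_id is None:
        crystal_id = str(observations["crystal_id"].iloc[0])
    mean_i = float(observations["intensity"].mean())
    n = len(observations)
    sem = float(observations["intensity"].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    shell_ios = _shell_i_over_sigma(observations, cell, shell)
    if first is None:
        norm_i, norm_ios = 1.0, None if shell_ios is None else 1.0
        norm_sem = sem / mean_i if mean_i != 0 else float("nan")
    else:
        norm_i = mean_i / first.mean_intensity
        norm_sem = sem / first.mean_intensity
        norm_ios = (
            None
            if shell_ios is None or first.shell_i_over_sigma in (None, 0)
            else shell_ios / first.shell_i_over_sigma
        )
    return SubsetStats(
        crystal_id=crystal_id,
        subset_index=subset_index,
        dose=subset_dose(subset_index, schedule),
        mean_intensity=mean_i,
        mean_intensity_norm=norm_i,
        mean_intensity_sem=sem,
        mean_intensity_norm_sem=norm_sem,
        shell_i_over_sigma=shell_ios,
        shell_i_over_sigma_norm=norm_ios,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# decay model
# ---------------------------------------------------------------------------

def half_dose(i0: float, i1: float, d_star: float) -> float | None:
    """``D* * ln[2*I0/(I0 - I1)]``; undefined (None) when ``I0 <= I1``.

    This is the dose reducing ``I0*exp(-D/D*) + I1`` from its initial value
    ``I0 + I1`` to half of it, which requires the minus sign in the
    denominator.
    """
    if i0 <= i1:
        return None
    return d_star * math.log(2.0 * i0 / (i0 - i1))


def undamaged_fraction(i0: float, i1: float) -> float:
    """Apparent dose-insensitive share ``I1/(I0 + I1)`` of initial intensity."""
    return i1 / (i0 + i1)


def derived_doses(
    i0: float, i1: float, beta_tot: float
) -> tuple[float, float | None, float]:
    """(D*, D_1/2, undamaged fraction) from the three decay parameters."""
    if beta_tot <= 0:
        raise ValueError("beta_tot must be positive")
    d_star = 1.0 / beta_tot
    return d_star, half_dose(i0, i1, d_star), undamaged_fraction(i0, i1)


@dataclass(frozen=True)
class DecayFit:
    """Fitted decay parameters with 1-sigma uncertainties and derived doses."""

    i0: float
    i1: float
    beta_tot: float
    i0_err: float
    i1_err: float
    beta_err: float
    d_star: float
    d_half: float | None
    undamaged_fraction: float
    n_points: int = 0
    residual: float = float("nan")
    #: True when the fit used externally supplied point uncertainties, in
    #: which case the covariance is absolute and intervals use the normal
    #: quantile; otherwise the variance was estimated from residuals and
    #: intervals use Student-t with n-3 degrees of freedom.
    weighted: bool = False

    def beta_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for beta_tot."""
        if self.weighted:
            q = float(norm_dist.ppf(0.5 + level / 2.0))
        else:
            dof = max(self.n_points - 3, 1)
            q = float(student_t.ppf(0.5 + level / 2.0, dof))
        return self.beta_tot - q * self.beta_err, self.beta_tot + q * self.beta_err


def decay_fit_from_parameters(
    i0: float, i1: float, beta_tot: float | None = None, d_star: float | None = None
) -> DecayFit:
    """Build a :class:`DecayFit` from externally determined parameters.

    Exactly one of ``beta_tot`` or ``d_star`` must be given; uncertainties
    are set to NaN. Used to evaluate derived metrics for parameter tables
    obtained elsewhere.
    """
    if (beta_tot is None) == (d_star is None):
        raise ValueError("give exactly one of beta_tot or d_star")
    if beta_tot is None:
        beta_tot = 1.0 / d_star
    ds, dh, frac = derived_doses(i0, i1, beta_tot)
    if d_star is not None:
        ds = d_star  # keep the caller's value exact rather than 1/(1/d_star)
        dh = half_dose(i0, i1, ds)
    nan = float("nan")
    return DecayFit(i0, i1, beta_tot, nan, nan, nan, ds, dh, frac)


def _model(d, i0, i1, beta):
    return i0 * np.exp(-beta * d) + i1


def fit_decay(doses, values, sigma=None) -> DecayFit:
    """Nonlinear least-squares fit of the three-parameter decay.

    Unweighted by default. When per-point uncertainties ``sigma`` are given
    the fit is inverse-variance weighted and the parameter covariance is
    taken as absolute (the unweighted covariance, which rescales residuals
    to a common variance, undercovers when the points are heteroscedastic).

    Initial values: ``I1`` from the smallest point, ``beta`` from a
    log-linear fit of the floored points against dose, ``I0`` from the first
    point. Bounds: ``I0 > 0``, ``I1 >= 0``, ``beta > 0``. Raises
    :class:`DecayFitError` for degenerate (constant) input, non-increasing
    doses or non-convergence.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(d) < 4:
        raise DecayFitError(f"need at least 4 points for 3 parameters, got {len(d)}")
    if np.any(np.diff(d) <= 0):
        raise DecayFitError("doses must be strictly increasing")
    if np.ptp(y) == 0:
        raise DecayFitError(
            "constant intensities: beta_tot is not identifiable from these points"
        )
    i1_init = float(y.min())
    i0_init = max(float(y[0]) - i1_init, 1e-6)
    floored = y - i1_init
    pos = floored > 0
    if pos.sum() >= 2:
        slope = np.polyfit(d[pos], np.log(floored[pos]), 1)[0]
        beta_init = max(-float(slope), 1e-6)
    else:
        beta_init = 1.0 / max(float(d[-1]), 1.0)
    p0 = (i0_init, max(i1_init, 1e-12), beta_init)
    weighted = sigma is not None
    try:
        popt, pcov = curve_fit(
            _model,
            d,
            y,
            p0=p0,
            sigma=None if sigma is None else np.asarray(sigma, dtype=float),
            absolute_sigma=weighted,
            bounds=([1e-12, 0.0, 1e-12], [np.inf, np.inf, np.inf]),
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise DecayFitError(
            f"decay fit did not converge (initial values {p0}): {exc}"
        ) from exc
    i0, i1, beta = (float(v) for v in popt)
    errs = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    d_star, d_half, frac = derived_doses(i0, i1, beta)
    if d_half is None:
        warnings.warn(
            f"fitted I0={i0:.4g} <= I1={i1:.4g}: half-dose undefined", stacklevel=2
        )
    residual = float(np.sum((y - _model(d, *popt)) ** 2))
    return DecayFit(
        i0,
        i1,
        beta,
        float(errs[0]),
        float(errs[1]),
        float(errs[2]),
        d_star,
        d_half,
        frac,
        n_points=len(d),
        residual=residual,
        weighted=weighted,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Cross-crystal averages of the derived damage metrics.

    Standard deviations use the n-1 denominator and are ``None`` for a
    single crystal. ``cryo_ratio`` is the configured cryogenic reference
    half-dose divided by the cohort mean half-dose, also reported rounded as
    the label ``1/N``.
    """

    n_crystals: int
    mean_d_star: float
    sd_d_star: float | None
    mean_d_half: float | None
    sd_d_half: float | None
    mean_fraction: float
    sd_fraction: float | None
    cryo_ratio: float | None
    cryo_ratio_label: str | None


def _mean_sd(values: list[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return float(arr.mean()), sd


def summarize_cohort(
    fits: list[DecayFit],
    cryo_reference_half_dose: float = CRYO_REFERENCE_HALF_DOSE,
) -> CohortSummary:
    """Arithmetic means and n-1 standard deviations over per-crystal fits.

    Fits with an undefined half-dose are skipped for the half-dose average
    (and consequently for the cryo ratio).
    """
    if not fits:
        raise ValueError("need at least one fit")
    mean_ds, sd_ds = _mean_sd([f.d_star for f in fits])
    mean_fr, sd_fr = _mean_sd([f.undamaged_fraction for f in fits])
    halves = [f.d_half for f in fits if f.d_half is not None]
    if halves:
        mean_dh, sd_dh = _mean_sd(halves)
        ratio = cryo_reference_half_dose / mean_dh
        label = f"1/{round(ratio)}"
    else:
        mean_dh = sd_dh = ratio = label = None
    return CohortSummary(
        n_crystals=len(fits),
        mean_d_star=mean_ds,
        sd_d_star=sd_ds,
        mean_d_half=mean_dh,
        sd_d_half=sd_dh,
        mean_fraction=mean_fr,
        sd_fraction=sd_fr,
        cryo_ratio=ratio,
        cryo_ratio_label=label,
    )
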