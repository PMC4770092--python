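"""Dwell-time rate estimation and global Bell-model fits.

Closing rates come from open-dwell lifetimes (and vice versa);
force-dependent rates follow the Bell law k(F) = k0·exp(F·Δx/kBT).
The global fits share one distance to the transition state Δx across
ligand concentrations; closing fits keep one zero-force rate per
concentration (binding is bimolecular) while opening fits share a
single zero-force rate (opening is concentration independent).  Fits
are weighted least squares on log-rates via Levenberg–Marquardt, with
1 s.d. statistical errors from the fit covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS
from .dwells import CLOSED, OPEN, DwellSet


@dataclass(frozen=True)
class RatePoint:
    """One measured rate at one force bias and ligand concentration."""

    force: float  # pN, mean force of the originating state's dwells
    rate: float  # s^-1
    se: float  # s^-1, bootstrap standard error
    concentration: float
    concentration_unit: str
    n_dwells: int
    direction: str  # "closing" | "opening"

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be > 0")
        if self.direction not in ("closing", "opening"):
            raise ValueError("direction must be 'closing' or 'opening'")


class InsufficientDwellsError(ValueError):
    pass


def rates_from_dwells(
    dwells: DwellSet,
    min_dwells: int = 5,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> tuple[RatePoint, RatePoint]:
    """Exponential-MLE rates from uncensored dwells.

    The closing rate is 1/mean(open dwell durations) reported at the
    mean open-state force, and conversely for opening.  Standard errors
    are nonparametric bootstrap over dwells (seeded).
    """
    rng = np.random.default_rng(seed)
    points = {}
    for state, direction in ((OPEN, "closing"), (CLOSED, "opening")):
        sub = dwells.usable(state)
        n = len(sub)
        if n < min_dwells:
            raise InsufficientDwellsError(
                f"only {n} uncensored {'open' if state == OPEN else 'closed'} dwells "
                f"(need >= {min_dwells})"
            )
        mean = sub.duration.mean()
        boot = rng.choice(sub.duration, size=(n_bootstrap, n), replace=True).mean(axis=1)
        se = float(np.std(1.0 / boot, ddof=1))
        force = float(np.nanmean(sub.mean_force)) if np.any(np.isfinite(sub.mean_force)) else np.nan
        points[direction] = RatePoint(
            force=force,
            rate=float(1.0 / mean),
            se=se,
            concentration=float(dwells.meta.get("concentration", np.nan)),
            concentration_unit=str(dwells.meta.get("concentration_unit", "")),
            n_dwells=n,
            direction=direction,
        )
    return points["closing"], points["opening"]


@dataclass
class BellFit:
    """Global Bell fit: shared Δx, per-group (or shared) zero-force rate."""

    direction: str
    delta_x: float  # nm
    delta_x_se: float
    k0: dict  # concentration -> s^-1
    k0_se: dict
    covar: np.ndarray | None
    result: lmfit.minimizer.MinimizerResult = field(repr=False, default=None)
    concentration_unit: str = ""

    def rate(self, force: float, concentration: float,
             constants: Constants = DEFAULT_CONSTANTS) -> float:
        return self.k0[concentration] * np.exp(force * self.delta_x / constants.kBT)


def _group_points(points: list[RatePoint]) -> dict:
    groups: dict = {}
    for p in points:
        groups.setdefault(p.concentration, []).append(p)
    return groups


def _check_identifiable(points: list[RatePoint]) -> None:
    forces = np.array([p.force for p in points])
    if np.unique(np.round(forces, 9)).size < 2:
        raise ValueError("Δx unidentifiable: need rates at >= 2 distinct forces")


def _fit_bell(
    points: list[RatePoint],
    direction: str,
    shared_k0: bool,
    constants: Constants,
    weighted: bool = True,
) -> BellFit:
    if not points:
        raise ValueError("no rate points")
    if any(p.direction != direction for p in points):
        raise ValueError(f"all points must have direction {direction!r}")
    _check_identifiable(points)
    groups = _group_points(points)
    concs = sorted(groups)
    params = lmfit.Parameters()
    params.add("delta_x", value=0.0)
    names = {}
    for i, c in enumerate(concs):
        name = "lnk0" if shared_k0 else f"lnk0_{i}"
        if name not in params:
            guess = float(np.mean([np.log(p.rate) for p in groups[c]]))
            params.add(name, value=guess)
        names[c] = name

    F = np.array([p.force for p in points])
    lnk = np.array([np.log(p.rate) for p in points])
    w = np.array([p.se / p.rate for p in points]) if weighted else np.ones(len(points))
    w = np.where(w > 0, w, np.median(w[w > 0]) if np.any(w > 0) else 1.0)
    conc_of = np.array([p.concentration for p in points])

    def residual(pars):
        dx = pars["delta_x"].value
        model = np.array([pars[names[c]].value for c in conc_of]) + F * dx / constants.kBT
        return (lnk - model) / w

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    k0 = {c: float(np.exp(p[names[c]].value)) for c in concs}
    k0_se = {
        c: float(k0[c] * p[names[c]].stderr) if p[names[c]].stderr is not None else np.nan
        for c in concs
    }
    return BellFit(
        direction=direction,
        delta_x=float(p["delta_x"].value),
        delta_x_se=float(p["delta_x"].stderr) if p["delta_x"].stderr is not None else np.nan,
        k0=k0,
        k0_se=k0_se,
        covar=getattr(result, "covar", None),
        result=result,
        concentration_unit=points[0].concentration_unit,
    )


def fit_bell_global_closing(
    points: list[RatePoint],
    constants: Constants = DEFAULT_CONSTANTS,
    weighted: bool = True,
) -> BellFit:
    """Global closing fit: one shared Δx, one zero-force rate per concentration."""
    return _fit_bell(points, "closing", shared_k0=False, constants=constants,
                     weighted=weighted)


def fit_bell_global_opening(
    points: list[RatePoint],
    constants: Constants = DEFAULT_CONSTANTS,
    weighted: bool = True,
) -> BellFit:
    """Global opening fit: shared Δx and one shared zero-force rate."""
    return _fit_bell(points, "opening", shared_k0=True, constants=constants,
                     weighted=weighted)


def extrapolate_zero_force(fit: BellFit) -> dict:
    """Zero-force rates with 1 s.d. errors (the fitted intercepts).

    Returns {concentration: (k0, se)}.  For a bimolecular closing fit,
    dividing k0 by concentration collapses the groups onto the
    per-concentration-unit association rate.
    """
    return {c: (fit.k0[c], fit.k0_se[c]) for c in fit.k0}
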