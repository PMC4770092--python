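"""Substrate-induced partial lid closing: the fraction-of-full-closing model.

In the competition assay the open-dwell level shifts toward the closed
level when substrate occupies the enzyme.  The observable is the
fraction of full closing,

    fraction(F) = (L_full(F) − L_comp(F)) / L_full(F),

where L_full is the inhibitor-only (full, cooperative two-lid) closing
distance and L_comp the apparent closing distance in competition.  The
unresolved fast substrate-induced fluctuations are modelled as a
two-state open/partially-closed equilibrium with Bell-form rates, so

    p_closed(F) = 1 / (1 + (k0_open/k0_close) · exp(F·Δx/kBT)),
    fraction(F) = (Δx / L_full(F)) · p_closed(F),

with one substrate-induced conformational change Δx shared across
concentrations and a concentration-dependent zero-force rate ratio.
The concentration dependence of the zero-force fraction follows a
four-state binding scheme (open/closed × bound/unbound) with the
unbound closed state negligible under load, parameterised by the
substrate dissociation constants to the open (K_open) and closed
(K_close) conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS

#: Unbound conformational rates (opening, closing) in s⁻¹ from
#: single-molecule fluorescence: the apo equilibrium lies on the open
#: side at 6,500:2,000.
DEFAULT_UNBOUND_RATES = (6500.0, 2000.0)


def fraction_of_full_closing(l_full: float, l_comp: float) -> float:
    """Fraction of full closing from level separations (both nm)."""
    if not l_full > 0:
        raise ValueError("l_full must be > 0")
    if l_comp < 0 or l_comp > l_full:
        raise ValueError(f"l_comp must be in [0, l_full], got {l_comp} vs {l_full}")
    return (l_full - l_comp) / l_full


def p_closed(force: float, k0_close: float, k0_open: float, delta_x: float,
             constants: Constants = DEFAULT_CONSTANTS):
    """Force-dependent closed-state occupancy of the two-state model."""
    if not (k0_close > 0 and k0_open > 0):
        raise ValueError("rates must be > 0")
    ratio = k0_open / k0_close
    return 1.0 / (1.0 + ratio * np.exp(np.asarray(force) * delta_x / constants.kBT))


def saturating_fraction(delta_x: float, l_full: float,
                        closed_occupancy: float = 1.0) -> float:
    """Limiting fraction of full closing at full closed-state occupancy.

    With the substrate-induced conformational change Δx and full
    closing distance L_full, the fraction saturates at Δx/L_full; full
    single-lid closure (Δx = L_full/2) therefore saturates at 0.5.
    """
    return (delta_x / l_full) * closed_occupancy


@dataclass(frozen=True)
class FractionPoint:
    """One measured fraction of full closing."""

    force: float  # pN
    fraction: float
    se: float
    concentration: float
    concentration_unit: str = "uM"


def _as_l_full(l_full):
    """Normalise L_full input: scalar, callable, or (force, L) table."""
    if callable(l_full):
        return l_full
    if np.isscalar(l_full):
        return lambda F: float(l_full)
    table = np.asarray(l_full, dtype=float)
    F_tab, L_tab = table[:, 0], table[:, 1]
    order = np.argsort(F_tab)
    return lambda F: np.interp(F, F_tab[order], L_tab[order])


@dataclass
class FractionForceFit:
    """Global force-dependence fit of the fraction of full closing."""

    delta_x: float  # nm, shared
    delta_x_se: float
    rate_ratio: dict  # concentration -> k0_open/k0_close
    rate_ratio_se: dict
    l_full: object  # callable F -> nm
    ssr: float  # weighted residual sum of squares, free-Δx model
    ssr_full_one_lid: float  # alternative model with Δx fixed to L_full/2
    preferred_model: str  # "partial_closing" | "full_one_lid"
    covar: np.ndarray | None = None
    var_names: list = field(default_factory=list)
    result: lmfit.minimizer.MinimizerResult = field(default=None, repr=False)
    constants: Constants = DEFAULT_CONSTANTS

    def fraction(self, force, concentration) -> np.ndarray:
        L = self.l_full(force)
        ratio = self.rate_ratio[concentration]
        p = 1.0 / (1.0 + ratio * np.exp(np.asarray(force) * self.delta_x / self.constants.kBT))
        return (self.delta_x / L) * p


def _fraction_residual(pars, points, names, l_full_fn, kBT, fixed_dx=None):
    dx = fixed_dx if fixed_dx is not None else pars["delta_x"].value
    out = np.empty(len(points))
    for i, pt in enumerate(points):
        ratio = np.exp(pars[names[pt.concentration]].value)
        L = l_full_fn(pt.force)
        model = (dx / L) * 1.0 / (1.0 + ratio * np.exp(pt.force * dx / kBT))
        w = pt.se if pt.se > 0 else 1.0
        out[i] = (pt.fraction - model) / w
    return out


def fit_fraction_force(
    points: list[FractionPoint],
    l_full=1.6,
    constants: Constants = DEFAULT_CONSTANTS,
) -> FractionForceFit:
    """Global Levenberg–Marquardt fit of fraction(F) at all concentrations.

    One shared Δx, one zero-force rate ratio per concentration.  The
    fixed alternative with complete single-lid closure (Δx = L_full/2,
    evaluated at zero force) is fitted alongside and the model with the
    lower weighted residual sum is flagged as preferred.
    """
    if not points:
        raise ValueError("no fraction points")
    forces = np.unique(np.round([p.force for p in points], 9))
    if forces.size < 2:
        raise ValueError("Δx unidentifiable: need fractions at >= 2 distinct forces")
    l_full_fn = _as_l_full(l_full)
    concs = sorted({p.concentration for p in points})
    names = {c: f"lnratio_{i}" for i, c in enumerate(concs)}
    kBT = constants.kBT

    params = lmfit.Parameters()
    params.add("delta_x", value=0.5 * l_full_fn(0.0) / 2)
    for c in concs:
        params.add(names[c], value=np.log(3.0))
    result = lmfit.minimize(
        _fraction_residual, params, args=(points, names, l_full_fn, kBT),
        method="leastsq",
    )
    ssr = float(np.sum(result.residual**2))

    # alternative: full closure of exactly one lid
    dx_fixed = l_full_fn(0.0) / 2.0
    alt = lmfit.Parameters()
    for c in concs:
        alt.add(names[c], value=np.log(3.0))
    alt_result = lmfit.minimize(
        _fraction_residual, alt, args=(points, names, l_full_fn, kBT),
        kws={"fixed_dx": dx_fixed}, method="leastsq",
    )
    ssr_alt = float(np.sum(alt_result.residual**2))

    p = result.params
    ratio = {c: float(np.exp(p[names[c]].value)) for c in concs}
    ratio_se = {
        c: float(ratio[c] * p[names[c]].stderr) if p[names[c]].stderr is not None else np.nan
        for c in concs
    }
    return FractionForceFit(
        delta_x=float(p["delta_x"].value),
        delta_x_se=float(p["delta_x"].stderr) if p["delta_x"].stderr is not None else np.nan,
        rate_ratio=ratio,
        rate_ratio_se=ratio_se,
        l_full=l_full_fn,
        ssr=ssr,
        ssr_full_one_lid=ssr_alt,
        preferred_model="partial_closing" if ssr <= ssr_alt else "full_one_lid",
        covar=getattr(result, "covar", None),
        var_names=list(result.var_names),
        result=result,
        constants=constants,
    )


def zero_force_fraction(fit: FractionForceFit, concentration: float) -> tuple[float, float]:
    """Fraction of full closing extrapolated to zero force, with 1 s.d. error.

    Evaluates the fitted model at F = 0; the error is propagated from
    the (Δx, ln ratio) covariance by the delta method.
    """
    if concentration not in fit.rate_ratio:
        raise KeyError(f"concentration {concentration} not in fit")
    L0 = fit.l_full(0.0)
    dx = fit.delta_x
    r = fit.rate_ratio[concentration]
    f0 = (dx / L0) / (1.0 + r)
    if fit.covar is None:
        return f0, np.nan
    concs = sorted(fit.rate_ratio)
    name = f"lnratio_{concs.index(concentration)}"
    grad = np.zeros(len(fit.var_names))
    for i, vn in enumerate(fit.var_names):
        if vn == "delta_x":
            grad[i] = 1.0 / (L0 * (1.0 + r))
        elif vn == name:
            grad[i] = -(dx / L0) * r / (1.0 + r) ** 2
    se = float(np.sqrt(grad @ fit.covar @ grad))
    return f0, se


@dataclass
class ConcentrationClosingFit:
    """Binding model for the zero-force fraction versus concentration."""

    K_open: float
    K_open_se: float
    K_close: float
    K_close_se: float
    scale: float  # Δx / L_full, fixed from the force fits
    unbound_rates: tuple  # (opening, closing) s^-1
    f_max: float  # saturation plateau of the fitted fraction curve
    saturating: bool
    result: lmfit.minimizer.MinimizerResult = field(default=None, repr=False)

    def fraction(self, concentration) -> np.ndarray:
        return self.scale * concentration_p_closed(
            np.asarray(concentration, dtype=float),
            self.K_open, self.K_close, self.unbound_rates,
        )


def concentration_p_closed(
    concentration,
    K_open: float,
    K_close: float,
    unbound_rates: tuple = DEFAULT_UNBOUND_RATES,
):
    """Closed-state occupancy versus ligand concentration.

    Four-state scheme (open/closed × unbound/bound) with the unbound
    closed state negligible under load.  With the unbound closed:open
    ratio c = k_close/k_open fixed from the apo conformational rates,

        p_closed([L]) = (c·[L]/K_close) / (c·[L]/K_close + [L]/K_open + 1).
    """
    k_open_u, k_close_u = unbound_rates
    c = k_close_u / k_open_u
    L = np.asarray(concentration, dtype=float)
    bc = c * L / K_close
    bo = L / K_open
    return bc / (bc + bo + 1.0)


def fit_concentration_model(
    points: list[tuple[float, float]] | list[tuple[float, float, float]],
    scale: float,
    unbound_rates: tuple = DEFAULT_UNBOUND_RATES,
) -> ConcentrationClosingFit:
    """Fit (K_open, K_close) to zero-force fractions versus concentration.

    ``points`` are ([L], fraction[, se]); ``scale`` = Δx/L_full from
    the force-dependence fits.  Requires >= 4 concentrations spanning
    >= 2 decades.  If the data do not approach saturation the fitted
    K_close is only a bound and the result is flagged.
    """
    arr = np.asarray(points, dtype=float)
    conc, frac = arr[:, 0], arr[:, 1]
    se = arr[:, 2] if arr.shape[1] > 2 else np.ones_like(frac)
    se = np.where(se > 0, se, 1.0)
    positive = conc[conc > 0]
    if np.unique(positive).size < 4:
        raise ValueError("need >= 4 nonzero concentrations")
    if np.max(positive) / np.min(positive) < 100:
        raise ValueError("concentrations must span >= 2 decades")

    params = lmfit.Parameters()
    med = float(np.median(positive))
    params.add("lnK_open", value=np.log(med))
    params.add("lnK_close", value=np.log(med))

    def residual(p):
        model = scale * concentration_p_closed(
            conc, np.exp(p["lnK_open"].value), np.exp(p["lnK_close"].value),
            unbound_rates,
        )
        return (frac - model) / se

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    K_open = float(np.exp(p["lnK_open"].value))
    K_close = float(np.exp(p["lnK_close"].value))
    k_open_u, k_close_u = unbound_rates
    c = k_close_u / k_open_u
    f_max = float(scale * (c / K_close) / (c / K_close + 1.0 / K_open))
    model_at_max = scale * concentration_p_closed(np.max(positive), K_open, K_close,
                                                  unbound_rates)
    saturating = bool(model_at_max >= 0.8 * f_max)
    if not saturating:
        import warnings

        warnings.warn("data do not approach saturation; K_close is a bound only",
                      stacklevel=2)
    return ConcentrationClosingFit(
        K_open=K_open,
        K_open_se=float(K_open * p["lnK_open"].stderr) if p["lnK_open"].stderr else np.nan,
        K_close=K_close,
        K_close_se=float(K_close * p["lnK_close"].stderr) if p["lnK_close"].stderr else np.nan,
        scale=scale,
        unbound_rates=tuple(unbound_rates),
        f_max=f_max,
        saturating=saturating,
        result=result,
    )
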