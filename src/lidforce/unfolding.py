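"""Equilibrium lid-unfolding free energy from force–distance curves.

Stretching the tethered enzyme produces a continuous hump-like
equilibrium transition (folding/unfolding of the ATP lid, fast
exchange, default window 13–20 pN around a midpoint near 17 pN).
The transition free energy is obtained by curve integration over trap
distance: the total-system energy is the area under the folded-branch
WLC fit up to a crossover force (default 10 pN, reducing low-force
noise) plus the area under the measured curve above it; subtracting
the area under the unfolded-branch fit over the same distance range
leaves the free energy of the folding/unfolding transition.  Substrate
binding stabilises the folded lid, raising this energy by
kBT·ln(1 + [L]/K_D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq

from .elasticity import TetherModel, WLCParams, polypeptide_wlc, wlc_extension_table
from .energetics import BindingFit, _fit_log_binding
from .synthetic import ForceExtensionCurve


@dataclass
class BranchFits:
    """WLC branch models of the folded and unfolded states, F(d)."""

    dna: WLCParams
    polypeptide: WLCParams  # unfolded contour gain lives here
    tether: TetherModel
    contour_gain: float  # nm
    contour_gain_se: float
    dna_contour: float
    dna_contour_se: float
    transition_window: tuple
    result_folded: lmfit.minimizer.MinimizerResult = field(default=None, repr=False)
    result_unfolded: lmfit.minimizer.MinimizerResult = field(default=None, repr=False)

    def folded_force(self, d) -> np.ndarray:
        return _branch_force(d, self.tether, self.dna, None)

    def unfolded_force(self, d) -> np.ndarray:
        return _branch_force(d, self.tether, self.dna, self.polypeptide)


def _branch_force(d, tether: TetherModel, dna: WLCParams,
                  pep: WLCParams | None) -> np.ndarray:
    """Force at trap distance d for a branch (folded: DNA only)."""
    constants = tether.constants
    tF, tx = wlc_extension_table(dna, constants)
    if pep is not None:
        _, tx_pep = wlc_extension_table(pep, constants)
        tx = tx + tx_pep
    d_of_F = tx + tF / tether.k_eff
    return np.interp(np.asarray(d, dtype=float), d_of_F, tF)


@dataclass
class UnfoldingEnergyResult:
    """Folding/unfolding transition free energy from curve integration."""

    dG_transition: float  # kBT
    dG_se: float  # kBT, from force noise over the integration span
    branches: BranchFits
    crossover_force: float  # pN
    integration_range: tuple  # nm trap distance
    total_area_kBT: float
    unfolded_area_kBT: float


def fit_branches(
    fec: ForceExtensionCurve,
    tether: TetherModel,
    transition_window: tuple = (13.0, 20.0),
    fit_margin: float = 3.0,
    fit_dna_contour: bool = True,
) -> BranchFits:
    """Fit folded (DNA WLC) and unfolded (DNA + polypeptide) branches.

    The folded branch is fitted to points below the transition window,
    the unfolded branch (polypeptide contour gain) to points above it;
    the window itself, widened by ``fit_margin`` (pN) on each side to
    keep residual mixed-occupancy points out, is excluded from both
    fits.  The curve must span both sides of the window.
    """
    d = np.asarray(fec.trap_distance, dtype=float)
    F = np.asarray(fec.force, dtype=float)
    lo, hi = transition_window
    below = F < lo - fit_margin
    above = F > hi + fit_margin
    if below.sum() < 5 or above.sum() < 5:  # fall back to the bare window
        below = F < lo
        above = F > hi
    if below.sum() < 5 or above.sum() < 5:
        raise ValueError(
            f"curve does not span both branches around the {transition_window} pN "
            f"transition window ({below.sum()} pts below, {above.sum()} above)"
        )

    # folded branch: DNA contour (optionally persistence) free
    params = lmfit.Parameters()
    params.add("contour", value=tether.dna.contour_length, min=1.0)
    params.add("persistence", value=tether.dna.persistence_length, vary=False)
    if not fit_dna_contour:
        params["contour"].vary = False

    def fold_residual(p):
        dna = WLCParams(p["persistence"].value, p["contour"].value,
                        tether.dna.stretch_modulus)
        return F[below] - _branch_force(d[below], tether, dna, None)

    res_f = lmfit.minimize(fold_residual, params, method="leastsq")
    dna = WLCParams(
        res_f.params["persistence"].value,
        res_f.params["contour"].value,
        tether.dna.stretch_modulus,
    )

    # unfolded branch: polypeptide contour gain free, DNA fixed
    params_u = lmfit.Parameters()
    params_u.add("gain", value=10.0, min=0.1)

    def unfold_residual(p):
        pep = polypeptide_wlc(contour_nm=p["gain"].value)
        return F[above] - _branch_force(d[above], tether, dna, pep)

    res_u = lmfit.minimize(unfold_residual, params_u, method="leastsq")
    gain = float(res_u.params["gain"].value)
    pep = polypeptide_wlc(contour_nm=gain)
    return BranchFits(
        dna=dna,
        polypeptide=pep,
        tether=tether,
        contour_gain=gain,
        contour_gain_se=float(res_u.params["gain"].stderr)
        if res_u.params["gain"].stderr is not None else np.nan,
        dna_contour=float(res_f.params["contour"].value),
        dna_contour_se=float(res_f.params["contour"].stderr)
        if res_f.params["contour"].stderr is not None else np.nan,
        transition_window=tuple(transition_window),
        result_folded=res_f,
        result_unfolded=res_u,
    )


def transition_free_energy(
    fec: ForceExtensionCurve,
    branches: BranchFits,
    crossover_force: float = 10.0,
) -> UnfoldingEnergyResult:
    """Integrate the curve to the folding/unfolding free energy (kBT).

    Trapezoidal integration over trap distance.  Total-system energy =
    area under the folded-branch fit up to the distance where it
    reaches ``crossover_force`` + area under the measured curve above;
    minus the area under the unfolded-branch fit over the full range.
    """
    d = np.asarray(fec.trap_distance, dtype=float)
    F = np.asarray(fec.force, dtype=float)
    if fec.direction == "relax" or d[0] > d[-1]:
        d, F = d[::-1], F[::-1]
    d_min, d_max = d[0], d[-1]
    constants = branches.tether.constants

    f_at = lambda x: float(branches.folded_force(np.array([x]))[0])  # noqa: E731
    if f_at(d_min) > crossover_force or f_at(d_max) < crossover_force:
        raise ValueError(
            f"crossover force {crossover_force} pN outside the folded-branch "
            f"range of the data"
        )
    d_star = brentq(lambda x: f_at(x) - crossover_force, d_min, d_max,
                    xtol=1e-10, rtol=1e-12)

    dense = np.linspace(d_min, d_star, 2000)
    area_folded = np.trapezoid(branches.folded_force(dense), dense)

    above = d >= d_star
    d_above = np.concatenate([[d_star], d[above]])
    F_above = np.concatenate([[np.interp(d_star, d, F)], F[above]])
    area_data = np.trapezoid(F_above, d_above)

    dense_all = np.linspace(d_min, d_max, 4000)
    area_unfolded = np.trapezoid(branches.unfolded_force(dense_all), dense_all)

    total = (area_folded + area_data) / constants.kBT
    baseline = area_unfolded / constants.kBT
    dG = total - baseline

    # error: force noise estimated from the post-transition tail (where
    # the data should sit on the unfolded branch) propagated through the
    # trapezoid weights of the measured segment
    tail = F > branches.transition_window[1]
    if tail.sum() > 2:
        resid = F[tail] - branches.unfolded_force(d[tail])
        resid_sd = float(np.std(resid, ddof=1))
    else:
        resid_sd = 0.0
    seg = np.diff(d_above)
    dG_se = resid_sd * float(np.sqrt(np.sum(seg**2))) / constants.kBT

    return UnfoldingEnergyResult(
        dG_transition=float(dG),
        dG_se=dG_se,
        branches=branches,
        crossover_force=crossover_force,
        integration_range=(float(d_min), float(d_max)),
        total_area_kBT=float(total),
        unfolded_area_kBT=float(baseline),
    )


def fit_nucleotide_stabilization(
    points: list[tuple[float, float]] | list[tuple[float, float, float]],
    concentration_unit: str = "uM",
    dG0: float | None = None,
) -> BindingFit:
    """Fit K_D from unfolding energies: ΔG([L]) = ΔG0 + kBT·ln(1 + [L]/K_D).

    ``points`` are ([L], ΔG[, se]) with ΔG in kBT.  The apo value ΔG0
    is fitted when not supplied, which requires an [L] = 0 point (or a
    spread of low concentrations anchoring the offset).
    """
    arr = np.asarray(points, dtype=float)
    conc, E = arr[:, 0], arr[:, 1]
    se = arr[:, 2] if arr.shape[1] > 2 else None
    if dG0 is None and not np.any(conc == 0):
        raise ValueError("supply dG0 or include an apo ([L]=0) point")
    positive = conc[conc > 0]
    if np.unique(positive).size < 3:
        raise ValueError("need >= 3 nonzero concentrations")
    if np.max(positive) / np.min(positive) < 10:
        raise ValueError("concentrations must span >= 1 decade")
    return _fit_log_binding(
        conc, E, se, concentration_unit,
        fit_offset=dG0 is None, dG0=0.0 if dG0 is None else dG0,
    )
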