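"""Equilibrium free energies and competition-assay binding analysis.

The two-state equilibrium free energy follows from the rate ratio,
ΔG(open→closed) = −kBT·ln(k_close/k_open).  In the competition assay a
substrate at concentration [L] occupies the open enzyme and blocks
inhibitor rebinding, lengthening the open dwells; the apparent loss of
inhibitor binding free energy is

    ΔΔG([L]) = kBT · ln(1 + [L]/K_D),

from which the substrate dissociation constant K_D is fitted.

All energies are in units of kBT (ΔG(open→closed) convention, negative
when closing is favoured).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS


def dG_from_rates(k_close: float, k_open: float,
                  constants: Constants = DEFAULT_CONSTANTS) -> float:
    """ΔG(open→closed) in kBT from the closing and opening rates."""
    if not (k_close > 0 and k_open > 0):
        raise ValueError(f"rates must be > 0, got k_close={k_close}, k_open={k_open}")
    return -float(np.log(k_close / k_open))


def ddG_competition(dG_ref: float, dG_with_ligand: float,
                    conditions_ref: dict | None = None,
                    conditions_ligand: dict | None = None) -> float:
    """Signed loss of apparent inhibitor binding free energy, in kBT.

    Positive = the nucleotide destabilises apparent inhibitor binding.
    Both inputs must come from matched inhibitor concentration and
    force treatment; mismatched condition metadata is an error.
    """
    if conditions_ref is not None and conditions_ligand is not None:
        keys = ("inhibitor", "inhibitor_concentration", "force_treatment")
        for key in keys:
            if key in conditions_ref or key in conditions_ligand:
                if conditions_ref.get(key) != conditions_ligand.get(key):
                    raise ValueError(
                        f"mismatched competition conditions: {key} "
                        f"{conditions_ref.get(key)!r} vs {conditions_ligand.get(key)!r}"
                    )
    return float(dG_with_ligand - dG_ref)


def blocked_fraction(tau_open_ref: float, tau_open_ligand: float) -> float:
    """Fraction of the open dwell during which substrate blocks rebinding.

    With mean open lifetime tau_ref in the absence of substrate and
    tau_ligand with substrate, the inhibitor can only rebind during the
    unoccupied fraction, so the occupied (blocked) fraction is
    1 − tau_ref/tau_ligand.
    """
    if not (tau_open_ref > 0 and tau_open_ligand > 0):
        raise ValueError("lifetimes must be > 0")
    if tau_open_ligand < tau_open_ref:
        raise ValueError(
            "tau_open_ligand < tau_open_ref: substrate cannot shorten the "
            "reference open dwell in this model"
        )
    return 1.0 - tau_open_ref / tau_open_ligand


@dataclass
class BindingFit:
    """Fitted dissociation constant from a binding free-energy series."""

    KD: float
    KD_se: float
    concentration_unit: str
    dG0: float = 0.0  # kBT offset (0 for ΔΔG fits)
    dG0_se: float = 0.0
    residuals: np.ndarray = field(default=None, repr=False)
    result: lmfit.minimizer.MinimizerResult = field(default=None, repr=False)
    lower_bound_only: bool = False

    def ddG(self, concentration: float) -> float:
        """Model ΔΔG at a concentration, kBT."""
        return self.dG0 + float(np.log1p(concentration / self.KD))


def _fit_log_binding(
    concentrations: np.ndarray,
    energies: np.ndarray,
    se: np.ndarray | None,
    concentration_unit: str,
    fit_offset: bool,
    dG0: float = 0.0,
) -> BindingFit:
    """Shared least-squares machinery for ΔΔG([L]) = ΔG0 + ln(1+[L]/KD)."""
    conc = np.asarray(concentrations, dtype=float)
    E = np.asarray(energies, dtype=float)
    if conc.size != E.size:
        raise ValueError("concentration and energy arrays must match")
    w = np.ones_like(E) if se is None else np.asarray(se, dtype=float)
    w = np.where(w > 0, w, np.median(w[w > 0]) if np.any(w > 0) else 1.0)

    params = lmfit.Parameters()
    positive = conc[conc > 0]
    params.add("lnKD", value=float(np.log(np.median(positive))))
    if fit_offset:
        params.add("dG0", value=float(E[np.argmin(conc)]))

    def residual(p):
        offset = p["dG0"].value if fit_offset else dG0
        model = offset + np.log1p(conc / np.exp(p["lnKD"].value))
        return (E - model) / w

    result = lmfit.minimize(residual, params, method="leastsq")
    p = result.params
    KD = float(np.exp(p["lnKD"].value))
    KD_se = float(KD * p["lnKD"].stderr) if p["lnKD"].stderr is not None else np.nan
    lower_bound_only = bool(np.max(conc) < 0.1 * KD)
    if lower_bound_only:
        import warnings

        warnings.warn(
            f"all concentrations << fitted KD ({KD:.3g} {concentration_unit}); "
            "KD is a lower bound only", stacklevel=3,
        )
    fitted_dG0 = float(p["dG0"].value) if fit_offset else dG0
    dG0_se = (
        float(p["dG0"].stderr) if fit_offset and p["dG0"].stderr is not None else 0.0
    )
    return BindingFit(
        KD=KD, KD_se=KD_se, concentration_unit=concentration_unit,
        dG0=fitted_dG0, dG0_se=dG0_se,
        residuals=residual(p) * w, result=result,
        lower_bound_only=lower_bound_only,
    )


def fit_kd_from_ddG(
    points: list[tuple[float, float]] | list[tuple[float, float, float]],
    concentration_unit: str = "uM",
) -> BindingFit:
    """Fit K_D from ([L], ΔΔG[, se]) points, energies in kBT.

    Requires at least 3 concentrations spanning at least one decade.
    """
    arr = np.asarray(points, dtype=float)
    conc, E = arr[:, 0], arr[:, 1]
    se = arr[:, 2] if arr.shape[1] > 2 else None
    positive = conc[conc > 0]
    if np.unique(positive).size < 3:
        raise ValueError("need >= 3 nonzero concentrations")
    if np.max(positive) / np.min(positive) < 10:
        raise ValueError("concentrations must span >= 1 decade")
    return _fit_log_binding(conc, E, se, concentration_unit, fit_offset=False)
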