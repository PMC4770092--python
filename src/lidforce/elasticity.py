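"""Polymer elasticity and dual-trap tether mechanics.

The tethered construct is a protein held between two optically trapped
beads through double-stranded DNA handles.  At a fixed trap separation
the tension in the tether is set by a force balance between the traps
(Hookean, series stiffness ``k_eff``) and the non-Hookean worm-like
chain (WLC) elasticity of the linkers.  The routines here provide

* the Marko–Siggia WLC interpolation force (optionally extensible),
* its numerical inverse,
* the self-consistent tether force balance at fixed trap separation,
* the "constant-force" linker correction that subtracts the DNA handle
  extension from each data point so that conformational level
  separations become comparable across force biases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .constants import Constants, DEFAULT_CONSTANTS
from .trace import Trace


class SlackTetherWarning(UserWarning):
    """The geometry leaves the tether without tension."""


@dataclass(frozen=True)
class WLCParams:
    """Worm-like chain parameters.

    persistence_length and contour_length in nm; stretch_modulus in pN
    (None = inextensible chain).
    """

    persistence_length: float
    contour_length: float
    stretch_modulus: float | None = None

    def __post_init__(self) -> None:
        if not self.persistence_length > 0:
            raise ValueError(f"persistence_length must be > 0, got {self.persistence_length}")
        if not self.contour_length > 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if self.stretch_modulus is not None and not self.stretch_modulus > 0:
            raise ValueError(f"stretch_modulus must be > 0, got {self.stretch_modulus}")


#: Field-standard defaults: dsDNA handles of ~360 nm contour, and an
#: unfolded polypeptide chain (0.7 nm persistence, 0.365 nm/residue).
DEFAULT_DNA = WLCParams(persistence_length=50.0, contour_length=360.0)
POLYPEPTIDE_PERSISTENCE_NM = 0.7
CONTOUR_PER_RESIDUE_NM = 0.365


def polypeptide_wlc(n_residues: int | None = None, contour_nm: float | None = None) -> WLCParams:
    """WLC parameters for an unfolded polypeptide segment."""
    if contour_nm is None:
        if n_residues is None:
            raise ValueError("give n_residues or contour_nm")
        contour_nm = n_residues * CONTOUR_PER_RESIDUE_NM
    return WLCParams(persistence_length=POLYPEPTIDE_PERSISTENCE_NM, contour_length=contour_nm)


@dataclass(frozen=True)
class TetherModel:
    """Series mechanical model: trap 1 – DNA handle(s) – protein – trap 2."""

    dna: WLCParams
    trap_stiffness_1: float
    trap_stiffness_2: float
    polypeptide: WLCParams | None = None
    constants: Constants = DEFAULT_CONSTANTS

    def __post_init__(self) -> None:
        for name in ("trap_stiffness_1", "trap_stiffness_2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def k_eff(self) -> float:
        """Series stiffness of the two traps, pN/nm."""
        return 1.0 / (1.0 / self.trap_stiffness_1 + 1.0 / self.trap_stiffness_2)


def _ms_force_fraction(frac: float, params: WLCParams, kBT: float) -> float:
    """Marko–Siggia interpolation force at relative extension frac = x/L."""
    return (kBT / params.persistence_length) * (
        0.25 / (1.0 - frac) ** 2 - 0.25 + frac
    )


def wlc_force(
    extension: float,
    params: WLCParams,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """WLC force (pN) at a given end-to-end extension (nm).

    Uses the Marko–Siggia interpolation formula; when a stretch modulus
    is present, the enthalpic extensible form F = MS(x/L − F/S) is
    solved self-consistently.
    """
    if extension < 0:
        raise ValueError(f"extension must be >= 0, got {extension}")
    L = params.contour_length
    if params.stretch_modulus is None:
        if extension >= L:
            raise ValueError(
                f"extension {extension} nm >= contour length {L} nm (inextensible WLC)"
            )
        return _ms_force_fraction(extension / L, params, constants.kBT)

    S = params.stretch_modulus

    def residual(F: float) -> float:
        frac = extension / L - F / S
        if frac >= 1.0:
            return -math.inf
        if frac <= 0.0:
            # fully enthalpic regime
            return F - S * (extension / L - frac)  # unreachable for F>=0
        return F - _ms_force_fraction(frac, params, constants.kBT)

    if extension == 0:
        return 0.0
    hi = 1.0
    while residual(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("failed to bracket extensible WLC force")
    return brentq(residual, 0.0, hi, xtol=1e-12, rtol=1e-13)


def wlc_extension(
    force: float,
    params: WLCParams,
    constants: Constants = DEFAULT_CONSTANTS,
) -> float:
    """Inverse of :func:`wlc_force`: extension (nm) at a given force (pN)."""
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    if force == 0:
        return 0.0
    kBT = constants.kBT
    L = params.contour_length

    def residual(frac: float) -> float:
        return _ms_force_fraction(frac, params, kBT) - force

    frac = brentq(residual, 0.0, 1.0 - 1e-12, xtol=1e-16, rtol=8.9e-16)
    x = frac * L
    if params.stretch_modulus is not None:
        x += force / params.stretch_modulus * L
    return x


def wlc_extension_table(
    params: WLCParams,
    constants: Constants = DEFAULT_CONSTANTS,
    max_fraction: float = 1.0 - 1e-6,
    n: int = 20000,
):
    """Dense (force, extension) lookup table for vectorised inversion.

    The table is monotone in force, suitable for ``np.interp``.
    """
    frac = np.linspace(0.0, max_fraction, n)
    force = (constants.kBT / params.persistence_length) * (
        0.25 / (1.0 - frac) ** 2 - 0.25 + frac
    )
    ext = frac * params.contour_length
    if params.stretch_modulus is not None:
        ext = ext + force / params.stretch_modulus * params.contour_length
    return force, ext


class TetherEquilibrium(NamedTuple):
    force: float  # pN, tension in the tether
    bead_deflection_sum: float  # nm, = force / k_eff
    slack: bool


def solve_tether_equilibrium(
    trap_separation: float,
    protein_extension: float,
    model: TetherModel,
    slack_threshold: float = 0.01,
) -> TetherEquilibrium:
    """Tether tension at fixed trap separation.

    Solves F = k_eff · (d_sep − x_protein − x_DNA(F)) for the unique
    tension F ≥ 0.  When the solution falls below ``slack_threshold``
    (pN) the tether is effectively slack and F = 0 is returned with
    ``slack=True``.
    """
    if not trap_separation > protein_extension:
        raise ValueError(
            f"trap_separation ({trap_separation}) must exceed protein_extension "
            f"({protein_extension})"
        )
    k_eff = model.k_eff
    gap = trap_separation - protein_extension

    def residual(F: float) -> float:
        return F / k_eff + wlc_extension(F, model.dna, model.constants) - gap

    if residual(0.0) >= 0.0:
        return TetherEquilibrium(force=0.0, bead_deflection_sum=0.0, slack=True)
    hi = 1.0
    while residual(hi) < 0.0:
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("failed to bracket tether equilibrium force")
    F = brentq(residual, 0.0, hi, xtol=1e-12, rtol=1e-13)
    if F < slack_threshold:
        return TetherEquilibrium(force=0.0, bead_deflection_sum=0.0, slack=True)
    return TetherEquilibrium(force=F, bead_deflection_sum=F / k_eff, slack=False)


def constant_force_transform(
    trace: Trace,
    model: TetherModel,
    params: WLCParams | None = None,
    force: bool = False,
) -> Trace:
    """Subtract the DNA handle extension and bead deflection per point.

    The raw passive-mode observable is the bead deflection signal at a
    fixed trap separation; because the DNA handles are compliant, the
    apparent size of a protein conformational change depends on the
    force bias.  This transformation computes, for every sample, the
    tension from the deflection signal, subtracts the corresponding WLC
    handle extension and the trap deflection from the trap separation,
    and returns the protein extension coordinate — a "constant force"
    view in which level separations are directly comparable across
    biases.

    The per-sample force is taken from the trace's force channel when
    present, otherwise inferred as ``k_eff × signal``.  Re-application
    to an already corrected trace is refused unless ``force=True``.
    """
    if params is None:
        params = model.dna
    if trace.history_contains("constant_force_transform") and not force:
        raise ValueError(
            "trace has already been constant-force transformed "
            "(pass force=True to override)"
        )
    meta = trace.meta
    try:
        trap_separation = float(meta["trap_separation_nm"])
    except KeyError as exc:
        raise KeyError(
            "constant_force_transform requires trap_separation_nm metadata"
        ) from exc
    k_eff = model.k_eff

    if trace.force is not None:
        F = np.asarray(trace.force, dtype=float)
    else:
        F = k_eff * np.asarray(trace.signal, dtype=float)
    F = np.clip(F, 0.0, None)

    table_F, table_x = wlc_extension_table(params, model.constants)
    if F.max() > table_F[-1]:
        raise ValueError(f"force {F.max():.3g} pN outside WLC inversion table")
    x_dna = np.interp(F, table_F, table_x)
    corrected = trap_separation - x_dna - F / k_eff
    return trace.with_signal(corrected, history_entry="constant_force_transform")
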