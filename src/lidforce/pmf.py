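"""Projection of 2D lid-opening free-energy landscapes under load.

The input is a 2D potential of mean force (PMF) over the opening
coordinates of the two substrate lids (AMP-lid and ATP-lid centre-of-
mass distances, in Å).  To compare with single-molecule pulling
experiments the surface is projected onto a 1D coordinate resembling
the lid-to-lid distance,

    d = (d_AMP − d0_AMP) + (d_ATP − d0_ATP),

the sum of the displacements of both lid coordinates from the global
minimum of the landscape (the lid motions are assumed mainly
orthogonal), and a mechanical bias −F·d for the external load is added,
after which the new minimum is shifted to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS


@dataclass
class PMFGrid:
    """Rectangular 2D free-energy grid in kBT; NaN cells are masked."""

    d_amp_axis: np.ndarray  # Å, strictly increasing
    d_atp_axis: np.ndarray  # Å, strictly increasing
    free_energy: np.ndarray  # kBT, shape (len(amp), len(atp))

    def __post_init__(self) -> None:
        self.d_amp_axis = np.asarray(self.d_amp_axis, dtype=float)
        self.d_atp_axis = np.asarray(self.d_atp_axis, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        for name, ax in (("d_amp_axis", self.d_amp_axis), ("d_atp_axis", self.d_atp_axis)):
            if ax.ndim != 1 or (ax.size >= 2 and not np.all(np.diff(ax) > 0)):
                raise ValueError(f"{name} must be 1D strictly increasing")
        if self.free_energy.shape != (self.d_amp_axis.size, self.d_atp_axis.size):
            raise ValueError("free_energy shape does not match axes")
        if not np.any(np.isfinite(self.free_energy)):
            raise ValueError("grid has no finite cells")


@dataclass
class PMFProfile:
    """1D projected free-energy profile over the lid-to-lid-like coordinate."""

    coordinate: np.ndarray  # Å
    free_energy: np.ndarray  # kBT
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if self.coordinate.shape != self.free_energy.shape:
            raise ValueError("coordinate and free_energy must have equal length")


def find_global_minimum(grid: PMFGrid) -> tuple[float, float]:
    """Coordinates (Å) of the lowest finite cell.

    Ties are broken deterministically toward the smallest coordinates
    (row-major order); a tie is recorded by the caller's provenance.
    """
    G = grid.free_energy
    if not np.any(np.isfinite(G)):
        raise ValueError("all-masked grid")
    gmin = np.nanmin(G)
    locs = np.argwhere(G == gmin)
    i, j = locs[np.lexsort((locs[:, 1], locs[:, 0]))][0]
    return float(grid.d_amp_axis[i]), float(grid.d_atp_axis[j])


def _lid_displacement_sum(amp: np.ndarray, atp: np.ndarray,
                          d0_amp: float, d0_atp: float) -> np.ndarray:
    return (amp - d0_amp) + (atp - d0_atp)


#: Swappable strategies for combining the two lid displacements into the
#: 1D projection coordinate.
COMBINATIONS = {"sum": _lid_displacement_sum}


def project_to_1d(
    grid: PMFGrid,
    method: str = "boltzmann",
    bin_width: float | None = None,
    combination: str = "sum",
) -> PMFProfile:
    """Project the 2D PMF onto the 1D lid-to-lid-like coordinate.

    Cells are binned on ``d``; within each bin the reduction is either
    Boltzmann marginalisation, −ln Σ exp(−G) (default), or the minimum
    free energy.  ``bin_width`` defaults to the larger axis spacing.
    The profile is shifted so its minimum is zero.
    """
    if method not in ("boltzmann", "min"):
        raise ValueError(f"unknown projection method {method!r}")
    if combination not in COMBINATIONS:
        raise ValueError(f"unknown combination strategy {combination!r}")
    d0_amp, d0_atp = find_global_minimum(grid)
    gmin = np.nanmin(grid.free_energy)
    n_ties = int(np.sum(grid.free_energy == gmin))

    A, B = np.meshgrid(grid.d_amp_axis, grid.d_atp_axis, indexing="ij")
    d = COMBINATIONS[combination](A, B, d0_amp, d0_atp).ravel()
    G = grid.free_energy.ravel()
    finite = np.isfinite(G)
    d, G = d[finite], G[finite]

    if bin_width is None:
        spacings = []
        for ax in (grid.d_amp_axis, grid.d_atp_axis):
            if ax.size >= 2:
                spacings.append(np.max(np.diff(ax)))
        bin_width = max(spacings) if spacings else 1.0
    edges = np.arange(d.min() - bin_width / 2, d.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(d, edges) - 1, 0, edges.size - 2)
    centers = 0.5 * (edges[:-1] + edges[1:])

    profile_d, profile_G = [], []
    for b in np.unique(idx):
        Gb = G[idx == b]
        if method == "min":
            val = float(np.min(Gb))
        else:
            ref = np.min(Gb)
            val = float(ref - np.log(np.sum(np.exp(-(Gb - ref)))))
        profile_d.append(centers[b])
        profile_G.append(val)
    profile_G = np.asarray(profile_G)
    profile_G = profile_G - profile_G.min()
    return PMFProfile(
        coordinate=np.asarray(profile_d),
        free_energy=profile_G,
        provenance={
            "method": method,
            "combination": combination,
            "bin_width_A": float(bin_width),
            "minimum_A": (d0_amp, d0_atp),
            "degenerate_minimum": n_ties > 1,
            "force_pN": 0.0,
        },
    )


def apply_external_force(
    profile: PMFProfile,
    force: float,
    constants: Constants = DEFAULT_CONSTANTS,
) -> PMFProfile:
    """Tilt the profile by an external load: G'(d) = G(d) − F·d.

    The mechanical work F·d (pN·Å) is converted to kBT, and the biased
    profile is shifted so its new minimum is zero.
    """
    if not np.all(np.isfinite(profile.free_energy)):
        raise ValueError("profile must be finite")
    bias = np.array([constants.pN_angstrom_to_kBT(force, d) for d in profile.coordinate])
    G = profile.free_energy - bias
    G = G - G.min()
    provenance = dict(profile.provenance)
    provenance["force_pN"] = float(provenance.get("force_pN", 0.0)) + float(force)
    return PMFProfile(coordinate=profile.coordinate.copy(), free_energy=G,
                      provenance=provenance)
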