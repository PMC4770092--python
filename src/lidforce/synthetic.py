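"""Synthetic passive-mode traces and force–distance curves.

The generator emulates the statistical structure of dual-trap
equilibrium recordings of enzyme lid closing:

* a continuous-time two-state Markov (telegraph) process whose
  closing/opening rates follow the Bell law ``k(F) = k0·exp(F·Δx/kBT)``
  evaluated at the self-consistent tether tension of each state, with a
  closing propensity proportional to ligand concentration (bimolecular
  binding-and-closing, as observed for bisubstrate inhibitors);
* bead/tether noise modelled as a single Ornstein–Uhlenbeck process,
  sampled at the acquisition rate (150 kHz) and block-averaged to the
  storage rate (30 kHz);
* quasi-equilibrium constant-velocity force–distance curves in which a
  protein segment unfolds/refolds in fast exchange, producing a
  hump-like equilibrium transition between the folded- and
  unfolded-branch WLC curves.

Default parameter values are the conditions of the lid-closing study:
zero-force closing 0.18 s⁻¹ per nM, zero-force opening 1 s⁻¹, full
open→closed contraction 1.6 nm, apo lid-unfolding free energy 11.7 kBT
with the unfolding hump near 17 pN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import Constants, DEFAULT_CONSTANTS
from .dwells import CLOSED, OPEN, DwellSet
from .elasticity import (
    DEFAULT_DNA,
    TetherModel,
    polypeptide_wlc,
    solve_tether_equilibrium,
    wlc_extension_table,
)
from .trace import Trace

DEFAULT_TETHER = TetherModel(
    dna=DEFAULT_DNA, trap_stiffness_1=0.3, trap_stiffness_2=0.3
)


def bell_rate(k0: float, force: float, delta_x: float, constants: Constants) -> float:
    """Bell-model rate k(F) = k0·exp(F·Δx/kBT); Δx > 0 accelerates with force."""
    return k0 * np.exp(force * delta_x / constants.kBT)


@dataclass(frozen=True)
class TraceSimConfig:
    """Ground-truth parameters of a simulated passive-mode recording.

    ``k_close_zero_force`` is bimolecular (s⁻¹ per concentration unit)
    when ``bimolecular=True``, so the zero-force closing propensity is
    ``k_close_zero_force × ligand_concentration``; otherwise it is used
    as-is (fixed-concentration mode).
    """

    seed: int
    duration: float = 10.0  # s
    k_close_zero_force: float = 0.18  # s^-1 per conc unit (bimolecular) or s^-1
    delta_x_close: float = -0.1  # nm; negative = closing slowed by force
    k_open_zero_force: float = 1.0  # s^-1
    delta_x_open: float = 1.5  # nm
    ligand_concentration: float = 25.0
    concentration_unit: str = "nM"
    ligand: str = "AP5A"
    bimolecular: bool = True
    protein_contraction: float = 1.6  # nm, open -> closed length change
    protein_extension_open: float = 1.6  # nm along the pulling axis
    trap_separation: float = 400.0  # nm
    tether: TetherModel = DEFAULT_TETHER
    sampling_rate: float = 150_000.0  # Hz
    average_to: float = 30_000.0  # Hz
    noise_amplitude: float = 0.4  # nm, OU stationary s.d. at acquisition rate
    noise_corner_hz: float = 5_000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        positive = (
            "duration", "k_close_zero_force", "k_open_zero_force",
            "protein_contraction", "trap_separation", "sampling_rate",
            "average_to", "noise_corner_hz",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.ligand_concentration < 0:
            raise ValueError("ligand_concentration must be >= 0")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.average_to > self.sampling_rate:
            raise ValueError("average_to must not exceed sampling_rate")
        if self.protein_extension_open < self.protein_contraction:
            raise ValueError("protein_extension_open must be >= protein_contraction")

    @property
    def k_close_effective(self) -> float:
        """Zero-force closing propensity at this ligand concentration, s⁻¹."""
        if self.bimolecular:
            return self.k_close_zero_force * self.ligand_concentration
        return self.k_close_zero_force

    def state_forces(self) -> tuple[float, float]:
        """Self-consistent tether tension (pN) of the open and closed state."""
        open_eq = solve_tether_equilibrium(
            self.trap_separation, self.protein_extension_open, self.tether
        )
        closed_eq = solve_tether_equilibrium(
            self.trap_separation,
            self.protein_extension_open - self.protein_contraction,
            self.tether,
        )
        return open_eq.force, closed_eq.force


@dataclass
class SyntheticTrace:
    """Rendered trace plus the generating ground truth."""

    time: np.ndarray  # s
    signal: np.ndarray  # nm, bead deflection sum
    true_state_path: np.ndarray  # OPEN/CLOSED per sample
    true_force_per_state: dict  # state -> pN
    config: TraceSimConfig
    force: np.ndarray | None = None  # pN per sample (inferred from signal)

    def to_trace(self) -> Trace:
        c = self.config
        meta = {
            "ligand": c.ligand,
            "concentration": c.ligand_concentration,
            "concentration_unit": c.concentration_unit,
            "trap_k1_pN_per_nm": c.tether.trap_stiffness_1,
            "trap_k2_pN_per_nm": c.tether.trap_stiffness_2,
            "trap_separation_nm": c.trap_separation,
            "sampling_rate_hz": c.average_to,
            "seed": c.seed,
            "history": ["synthetic"],
        }
        return Trace(time=self.time, signal=self.signal, force=self.force, meta=meta)


def simulate_state_path(config: TraceSimConfig, rng: np.random.Generator | None = None) -> DwellSet:
    """Gillespie simulation of the open/closed telegraph process.

    Rates are constant within a dwell, evaluated at the state's
    self-consistent force; exact event times are retained.  The first
    and last dwells are censored.  With zero ligand concentration the
    path stays open for the whole duration.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    constants = config.tether.constants
    F_open, F_closed = config.state_forces()
    k_close = bell_rate(config.k_close_effective, F_open, config.delta_x_close, constants)
    k_open = bell_rate(config.k_open_zero_force, F_closed, config.delta_x_open, constants)

    states, durations, starts = [], [], []
    t = 0.0
    state = OPEN
    while t < config.duration:
        rate = k_close if state == OPEN else k_open
        if rate <= 0:
            dt = config.duration - t
        else:
            dt = rng.exponential(1.0 / rate)
        dt = min(dt, config.duration - t)
        states.append(state)
        durations.append(dt)
        starts.append(t)
        t += dt
        state = CLOSED if state == OPEN else OPEN

    states = np.array(states)
    durations = np.array(durations)
    censored = np.zeros(states.size, dtype=bool)
    censored[0] = True
    censored[-1] = True
    forces = np.where(states == OPEN, F_open, F_closed)
    return DwellSet(
        state=states,
        duration=durations,
        mean_force=forces,
        censored=censored,
        t_start=np.array(starts),
        meta={
            "ligand": config.ligand,
            "concentration": config.ligand_concentration,
            "concentration_unit": config.concentration_unit,
            "trap_separation_nm": config.trap_separation,
            "seed": config.seed,
            "true_forces": {"open": F_open, "closed": F_closed},
        },
    )


def _ou_noise(
    n: int, amplitude: float, corner_hz: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact discretisation of a stationary OU process.

    ``amplitude`` is the stationary standard deviation; ``corner_hz``
    the Lorentzian corner frequency (relaxation rate / 2π).
    """
    from scipy.signal import lfilter

    theta = 2.0 * np.pi * corner_hz
    rho = np.exp(-theta * dt)
    innovations = rng.standard_normal(n) * amplitude * np.sqrt(1.0 - rho**2)
    innovations[0] = rng.standard_normal() * amplitude  # stationary start
    return lfilter([1.0], [1.0, -rho], innovations)


def render_trace(dwells: DwellSet, config: TraceSimConfig) -> SyntheticTrace:
    """Render a dwell path to a sampled, noisy, block-averaged trace.

    The two signal levels are the bead-deflection sums of the tether
    force balance in each state; additive OU noise is applied at the
    acquisition rate; samples are block-averaged down to the storage
    rate, and the ground-truth state path is resampled to the output
    grid (majority state within each block).
    """
    if config.noise_corner_hz >= config.sampling_rate / 2:
        raise ValueError("noise corner frequency must be below the acquisition Nyquist")
    total = float(np.sum(dwells.duration))
    if total < config.duration - 1e-9:
        raise ValueError("dwell set does not cover the configured duration")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    F_open, F_closed = config.state_forces()
    k_eff = config.tether.k_eff
    level = {OPEN: F_open / k_eff, CLOSED: F_closed / k_eff}

    dt = 1.0 / config.sampling_rate
    n_fast = int(round(config.duration * config.sampling_rate))
    t_fast = (np.arange(n_fast) + 0.5) * dt
    edges = np.concatenate([[0.0], np.cumsum(dwells.duration)])
    idx = np.clip(np.searchsorted(edges, t_fast, side="right") - 1, 0, len(dwells) - 1)
    state_fast = dwells.state[idx]
    signal_fast = np.where(state_fast == OPEN, level[OPEN], level[CLOSED])
    if config.noise_amplitude > 0:
        signal_fast = signal_fast + _ou_noise(
            n_fast, config.noise_amplitude, config.noise_corner_hz, dt, rng
        )

    block = int(round(config.sampling_rate / config.average_to))
    n_out = n_fast // block
    signal = signal_fast[: n_out * block].reshape(n_out, block).mean(axis=1)
    state_blocks = state_fast[: n_out * block].reshape(n_out, block)
    state_out = (state_blocks.mean(axis=1) > 0.5).astype(int)
    time = (np.arange(n_out) + 0.5) * block * dt
    force = k_eff * signal
    return SyntheticTrace(
        time=time,
        signal=signal,
        true_state_path=state_out,
        true_force_per_state={"open": F_open, "closed": F_closed},
        config=config,
        force=force,
    )


def simulate_trace(config: TraceSimConfig) -> SyntheticTrace:
    """Convenience: Gillespie path + rendering in one call."""
    return render_trace(simulate_state_path(config), config)


# ---------------------------------------------------------------------------
# Force–distance curves with an equilibrium unfolding hump
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FECSimConfig:
    """Constant-velocity stretch of a tether with a two-state folding unit.

    In the fast-exchange (equilibrium) limit the measured force at each
    trap distance is the Boltzmann-weighted mixture of the folded and
    unfolded branches.  ``unfolded_contour_gain`` is the polypeptide
    contour released on unfolding; its default (3.3 nm) together with
    ``folding_free_energy`` = 11.7 kBT places the equilibrium midpoint
    near 17 pN.
    """

    seed: int
    pulling_velocity: float = 100.0  # nm/s
    folding_free_energy: float = 11.7  # kBT
    unfolded_contour_gain: float = 3.3  # nm
    tether: TetherModel = DEFAULT_TETHER
    distance_range: tuple[float, float] = (330.0, 520.0)  # nm trap separation
    n_points: int = 800
    noise_pN: float = 0.0
    stochastic: bool = False  # telegraph hopping instead of mean force
    exchange_rate: float = 2000.0  # s^-1, only used when stochastic
    direction: str = "stretch"

    def __post_init__(self) -> None:
        if not self.pulling_velocity > 0:
            raise ValueError("pulling_velocity must be > 0")
        if self.folding_free_energy < 0:
            raise ValueError("folding_free_energy must be >= 0")


@dataclass
class ForceExtensionCurve:
    """Force versus trap distance sweep."""

    trap_distance: np.ndarray  # nm
    force: np.ndarray  # pN
    pulling_velocity: float  # nm/s
    direction: str = "stretch"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trap_distance = np.asarray(self.trap_distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.trap_distance.shape != self.force.shape:
            raise ValueError("trap_distance and force must have equal length")
        d = np.diff(self.trap_distance)
        if d.size and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("trap_distance must be monotone within a sweep")
        if self.direction not in ("stretch", "relax"):
            raise ValueError("direction must be 'stretch' or 'relax'")


def fec_branches(config: FECSimConfig):
    """Folded- and unfolded-branch force curves F(d) over the sweep range.

    Returns (d, F_folded, F_unfolded) on a dense grid.
    """
    d = np.linspace(*config.distance_range, config.n_points)
    pep = polypeptide_wlc(contour_nm=config.unfolded_contour_gain)
    tether = config.tether
    constants = tether.constants
    tF, tx_dna = wlc_extension_table(tether.dna, constants)
    _, tx_pep = wlc_extension_table(pep, constants)
    k_eff = tether.k_eff

    def branch(extra_extension_table):
        # invert d = x(F) + F/k_eff via the monotone tabulated map
        x_tot = tx_dna + extra_extension_table + tF / k_eff
        return np.interp(d, x_tot, tF)

    F_folded = branch(np.zeros_like(tF))
    F_unfolded = branch(tx_pep)
    return d, F_folded, F_unfolded


def simulate_fec(config: FECSimConfig) -> ForceExtensionCurve:
    """Quasi-equilibrium force–distance curve with an unfolding hump.

    The system free energy of each branch at trap distance d is the
    integral of its force curve plus the folding free energy offset for
    the unfolded branch; occupancies are Boltzmann weights of these two
    energies and the rendered force is their occupancy-weighted mean
    (fast-exchange limit).  A stochastic telegraph mode is available for
    detection stress tests.
    """
    rng = np.random.default_rng(config.seed)
    constants = config.tether.constants
    kBT = constants.kBT
    d, F_f, F_u = fec_branches(config)
    from scipy.integrate import cumulative_trapezoid

    G_f = cumulative_trapezoid(F_f, d, initial=0.0) / kBT  # kBT
    G_u = cumulative_trapezoid(F_u, d, initial=0.0) / kBT + config.folding_free_energy
    delta = G_u - G_f  # kBT; positive = folded favoured
    p_f = 1.0 / (1.0 + np.exp(-np.clip(delta, -500, 500)))
    if config.stochastic:
        # dwell-to-dwell hopping resolved at the sweep sampling times
        dt = np.gradient(d) / config.pulling_velocity
        state = np.empty(d.size, dtype=int)
        state[0] = 0 if p_f[0] > 0.5 else 1
        for i in range(1, d.size):
            k_uf = config.exchange_rate / (1.0 + np.exp(delta[i]))
            k_fold = config.exchange_rate - k_uf
            p_switch = (k_uf if state[i - 1] == 0 else k_fold) * dt[i]
            state[i] = state[i - 1] ^ (rng.random() < min(p_switch, 1.0))
        force = np.where(state == 0, F_f, F_u)
    else:
        force = p_f * F_f + (1.0 - p_f) * F_u
    if config.noise_pN > 0:
        force = force + rng.normal(0.0, config.noise_pN, size=force.size)
    if config.direction == "relax":
        d, force = d[::-1], force[::-1]
    return ForceExtensionCurve(
        trap_distance=d,
        force=force,
        pulling_velocity=config.pulling_velocity,
        direction=config.direction,
        meta={
            "seed": config.seed,
            "folding_free_energy_kBT": config.folding_free_energy,
            "unfolded_contour_gain_nm": config.unfolded_contour_gain,
        },
    )


def make_fraction_points(
    delta_x: float,
    rate_ratios: dict,
    forces: np.ndarray,
    l_full,
    noise: float,
    seed: int,
    constants: Constants = DEFAULT_CONSTANTS,
):
    """Synthetic fraction-of-full-closing points from the two-state model.

    ``rate_ratios`` maps concentration -> k0_open/k0_close; ``l_full``
    is the full closing distance, a scalar or callable of force.
    Returns a list of (force, fraction, se, concentration) tuples with
    multiplicative Gaussian noise of relative size ``noise``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for conc, ratio in rate_ratios.items():
        for F in np.asarray(forces, dtype=float):
            L = l_full(F) if callable(l_full) else float(l_full)
            p = 1.0 / (1.0 + ratio * np.exp(F * delta_x / constants.kBT))
            frac = (delta_x / L) * p
            obs = frac * (1.0 + noise * rng.standard_normal())
            se = max(abs(frac) * noise, 1e-6)
            out.append((F, obs, se, conc))
    return out
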