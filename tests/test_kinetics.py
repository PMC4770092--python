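"""Dwell-time rates and global Bell fits with zero-force extrapolation."""

import numpy as np
import pytest

from lidforce.constants import DEFAULT_CONSTANTS
from lidforce.dwells import CLOSED, OPEN, DwellSet
from lidforce.kinetics import (
    InsufficientDwellsError,
    RatePoint,
    extrapolate_zero_force,
    fit_bell_global_closing,
    fit_bell_global_opening,
    rates_from_dwells,
)

kBT = DEFAULT_CONSTANTS.kBT


def dwell_set(open_durations, closed_durations, force_open=8.0, force_closed=8.2,
              conc=25.0):
    n = len(open_durations) + len(closed_durations)
    states = np.empty(n, dtype=int)
    durations = np.empty(n)
    states[0::2], states[1::2] = OPEN, CLOSED
    durations[0::2], durations[1::2] = open_durations, closed_durations
    # pad with censored boundary dwells so interior dwells stay usable
    states = np.concatenate([[CLOSED], states, [OPEN if states[-1] == CLOSED else CLOSED]])
    durations = np.concatenate([[1.0], durations, [1.0]])
    censored = np.zeros(states.size, dtype=bool)
    censored[0] = censored[-1] = True
    forces = np.where(states == OPEN, force_open, force_closed)
    return DwellSet(state=states, duration=durations, mean_force=forces,
                    censored=censored,
                    meta={"concentration": conc, "concentration_unit": "nM"})


class TestRatesFromDwells:
    def test_constant_dwells_give_exact_rate_and_zero_se(self):
        dwells = dwell_set([0.1] * 20, [0.05] * 20)
        closing, opening = rates_from_dwells(dwells, seed=1)
        assert closing.rate == pytest.approx(10.0)
        assert closing.se == 0.0
        assert opening.rate == pytest.approx(20.0)
        assert closing.force == pytest.approx(8.0)
        assert opening.force == pytest.approx(8.2)

    def test_exponential_sample_recovered_within_three_se(self, rng):
        k = 50.0
        dwells = dwell_set(rng.exponential(1 / k, 1000), rng.exponential(1 / 20, 1000))
        closing, _ = rates_from_dwells(dwells, seed=2)
        assert abs(closing.rate - k) < 3 * closing.se
        # bootstrap se close to the exponential-theory se k/sqrt(n)
        assert closing.se == pytest.approx(k / np.sqrt(1000), rel=0.2)

    def test_censored_dwells_do_not_contribute(self, rng):
        dwells = dwell_set(rng.exponential(0.02, 100), rng.exponential(0.05, 100))
        closing, opening = rates_from_dwells(dwells, seed=3)
        # censor two interior open dwells and give them absurd durations
        tampered = DwellSet(
            state=dwells.state.copy(),
            duration=np.where(
                np.isin(np.arange(len(dwells)), [1, 3]), 1e6, dwells.duration
            ),
            mean_force=dwells.mean_force.copy(),
            censored=dwells.censored | np.isin(np.arange(len(dwells)), [1, 3]),
            meta=dict(dwells.meta),
        )
        closing2, _ = rates_from_dwells(tampered, seed=3)
        n = dwells.n_usable(OPEN)
        # removing 2 of n dwells changes the estimate only by the sample shrinkage
        assert closing2.rate == pytest.approx(
            1.0 / dwells.usable(OPEN).duration[
                ~np.isin(np.arange(n), [0, 1])].mean(), rel=1e-12)

    def test_insufficient_dwells_error_names_state(self):
        dwells = dwell_set([0.1] * 2, [0.1] * 2)
        with pytest.raises(InsufficientDwellsError, match="open"):
            rates_from_dwells(dwells)


def bell_points(direction, k0_map, delta_x, forces, noise, seed, shared=False):
    rng = np.random.default_rng(seed)
    pts = []
    for conc, k0 in k0_map.items():
        for F in forces:
            k = k0 * np.exp(F * delta_x / kBT) * (1 + noise * rng.standard_normal())
            pts.append(RatePoint(force=F, rate=k, se=max(noise * k, 1e-12),
                                 concentration=conc, concentration_unit="nM",
                                 n_dwells=500, direction=direction))
    return pts


class TestBellFits:
    forces = (6.0, 8.0, 10.0, 12.0)

    def test_noise_free_closing_fit_is_exact(self):
        pts = bell_points("closing", {10.0: 1.8, 25.0: 4.5, 100.0: 18.0}, -0.1,
                          self.forces, 0.0, seed=1)
        fit = fit_bell_global_closing(pts)
        assert fit.delta_x == pytest.approx(-0.1, abs=1e-8)
        for conc, k0 in {10.0: 1.8, 25.0: 4.5, 100.0: 18.0}.items():
            assert fit.k0[conc] == pytest.approx(k0, rel=1e-8)
        for p in pts:
            assert fit.rate(p.force, p.concentration) == pytest.approx(p.rate, rel=1e-8)

    def test_noisy_closing_fit_recovers_truth_within_2sd(self):
        truth = {10.0: 1.8, 25.0: 4.5, 100.0: 18.0}
        pts = bell_points("closing", truth, -0.1, self.forces, 0.05, seed=7)
        fit = fit_bell_global_closing(pts)
        assert abs(fit.delta_x - (-0.1)) < 2 * fit.delta_x_se
        for conc, k0 in truth.items():
            assert abs(fit.k0[conc] - k0) < 2 * fit.k0_se[conc]

    def test_bimolecular_k0_scales_with_concentration(self):
        truth = {10.0: 1.8, 25.0: 4.5, 100.0: 18.0}
        pts = bell_points("closing", truth, -0.1, self.forces, 0.03, seed=8)
        fit = fit_bell_global_closing(pts)
        normalised = [fit.k0[c] / c for c in truth]
        assert np.ptp(normalised) / np.mean(normalised) < 0.1

    def test_noise_free_opening_fit_is_exact(self):
        pts = bell_points("opening", {10.0: 1.0, 25.0: 1.0, 100.0: 1.0}, 1.5,
                          self.forces, 0.0, seed=2)
        fit = fit_bell_global_opening(pts)
        assert fit.delta_x == pytest.approx(1.5, abs=1e-8)
        assert list(fit.k0.values())[0] == pytest.approx(1.0, rel=1e-8)

    def test_opening_fit_invariant_to_concentration_tags(self):
        pts = bell_points("opening", {10.0: 1.0, 25.0: 1.0, 100.0: 1.0}, 1.5,
                          self.forces, 0.04, seed=3)
        fit = fit_bell_global_opening(pts)
        permuted = [
            RatePoint(force=p.force, rate=p.rate, se=p.se,
                      concentration={10.0: 100.0, 25.0: 10.0, 100.0: 25.0}[p.concentration],
                      concentration_unit=p.concentration_unit,
                      n_dwells=p.n_dwells, direction=p.direction)
            for p in pts
        ]
        fit2 = fit_bell_global_opening(permuted)
        assert fit.delta_x == pytest.approx(fit2.delta_x, rel=1e-9)
        assert list(fit.k0.values())[0] == pytest.approx(
            list(fit2.k0.values())[0], rel=1e-9)

    def test_single_force_is_unidentifiable(self):
        pts = bell_points("closing", {25.0: 4.5}, -0.1, (8.0,), 0.0, seed=4)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_bell_global_closing(pts)

    def test_zero_force_extrapolation_equals_fitted_intercept(self):
        pts = bell_points("closing", {10.0: 1.8, 100.0: 18.0}, -0.1,
                          self.forces, 0.05, seed=5)
        fit = fit_bell_global_closing(pts)
        extrap = extrapolate_zero_force(fit)
        for conc in (10.0, 100.0):
            assert extrap[conc][0] == fit.k0[conc]
            assert extrap[conc][1] == fit.k0_se[conc]
            assert np.isfinite(extrap[conc][1]) and extrap[conc][1] > 0


class TestTwoStateConsistency:
    """Cross-checks between fitted kinetics and the generator's thermodynamics."""

    @pytest.fixture(scope="class")
    @staticmethod
    def fits():
        from lidforce.synthetic import TraceSimConfig, simulate_state_path

        closing_pts, opening_pts = [], []
        truth = {}
        for conc in (100.0, 300.0):
            for i, sep in enumerate((380.0, 397.0, 412.0, 427.0)):
                config = TraceSimConfig(
                    seed=900 + i + int(conc), duration=40.0,
                    ligand_concentration=conc, trap_separation=sep,
                )
                dwells = simulate_state_path(config)
                c, o = rates_from_dwells(dwells, seed=1000 + i)
                closing_pts.append(c)
                opening_pts.append(o)
                truth[(conc, sep)] = config
        return (fit_bell_global_closing(closing_pts),
                fit_bell_global_opening(opening_pts), truth)

    def test_delta_x_sum_matches_total_contraction(self, fits):
        closing_fit, opening_fit, truth = fits
        config = next(iter(truth.values()))
        total = opening_fit.delta_x - closing_fit.delta_x
        se = np.hypot(opening_fit.delta_x_se, closing_fit.delta_x_se)
        assert abs(total - config.protein_contraction) < 2 * se

    def test_equilibrium_free_energy_matches_generator(self, fits):
        closing_fit, opening_fit, truth = fits
        (conc, sep), config = next(iter(truth.items()))
        F = np.mean(config.state_forces())
        dG_fit = np.log(
            opening_fit.k0[conc] * np.exp(F * opening_fit.delta_x / kBT)
        ) - np.log(closing_fit.k0[conc] * np.exp(F * closing_fit.delta_x / kBT))
        F_open, F_closed = config.state_forces()
        from lidforce.synthetic import bell_rate

        dG_true = np.log(
            bell_rate(config.k_open_zero_force, F_closed, config.delta_x_open,
                      DEFAULT_CONSTANTS)
        ) - np.log(
            bell_rate(config.k_close_effective, F_open, config.delta_x_close,
                      DEFAULT_CONSTANTS)
        )
        assert dG_fit == pytest.approx(dG_true, abs=0.4)

    def test_induced_fit_vs_conformational_selection_discrimination(self):
        """Force-independent closing (induced fit) vs strongly force-dependent
        closing (conformational selection) must separate in the fitted Δx."""
        induced = bell_points("closing", {100.0: 18.0}, -0.1,
                              (6.0, 8.0, 10.0, 12.0), 0.05, seed=11)
        selection = bell_points("closing", {100.0: 18.0}, -1.5,
                                (6.0, 8.0, 10.0, 12.0), 0.05, seed=12)
        fit_if = fit_bell_global_closing(induced)
        fit_cs = fit_bell_global_closing(selection)
        assert abs(fit_if.delta_x) < 0.3
        assert fit_cs.delta_x < -1.0
        assert abs(fit_cs.delta_x) > abs(fit_if.delta_x) + 3 * np.hypot(
            fit_cs.delta_x_se, fit_if.delta_x_se)
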