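"""Fraction-of-full-closing observable, force fits, concentration model."""

import numpy as np
import pytest

from lidforce.constants import DEFAULT_CONSTANTS
from lidforce.dwells import CLOSED
from lidforce.fraction import (
    FractionPoint,
    concentration_p_closed,
    fit_concentration_model,
    fit_fraction_force,
    fraction_of_full_closing,
    p_closed,
    saturating_fraction,
    zero_force_fraction,
)
from lidforce.synthetic import TraceSimConfig, make_fraction_points, simulate_state_path

kBT = DEFAULT_CONSTANTS.kBT


class TestFractionOfFullClosing:
    def test_no_shift_gives_zero(self):
        assert fraction_of_full_closing(1.6, 1.6) == 0.0

    def test_full_shift_gives_one(self):
        assert fraction_of_full_closing(1.6, 0.0) == 1.0

    def test_partial_shift(self):
        # a 0.32 nm shift of the open level against a 1.6 nm full change
        assert fraction_of_full_closing(1.6, 1.28) == pytest.approx(0.2)

    def test_overshoot_rejected(self):
        with pytest.raises(ValueError):
            fraction_of_full_closing(1.6, 1.7)


class TestPClosed:
    def test_symmetric_rates_at_zero_force(self):
        assert p_closed(0.0, 3.0, 3.0, 0.5) == pytest.approx(0.5)

    def test_large_force_empties_closed_state(self):
        assert p_closed(500.0, 3.0, 3.0, 0.5) == pytest.approx(0.0, abs=1e-10)

    def test_decreasing_in_force_for_positive_delta_x(self):
        F = np.linspace(0, 20, 50)
        p = p_closed(F, 2.0, 4.0, 0.5)
        assert np.all(np.diff(p) < 0)

    def test_matches_gillespie_occupancy_at_fixed_force(self):
        # generator with equal-and-opposite Bell distances realises the same
        # two-state occupancy the closed form predicts
        config = TraceSimConfig(seed=41, duration=150.0, ligand_concentration=100.0,
                                delta_x_close=-0.25, delta_x_open=0.25,
                                k_open_zero_force=20.0)
        path = simulate_state_path(config)
        F_open, F_closed = config.state_forces()
        # closed form at the (nearly identical) state forces
        k_c = config.k_close_effective * np.exp(F_open * -0.25 / kBT)
        k_o = config.k_open_zero_force * np.exp(F_closed * 0.25 / kBT)
        expected = k_c / (k_c + k_o)
        occupancy = path.duration[path.state == CLOSED].sum() / config.duration
        n = path.n_usable(CLOSED)
        se = expected * (1 - expected) * np.sqrt(2.0 / n)
        assert abs(occupancy - expected) < 3 * se


class TestFitFractionForce:
    forces = np.arange(7.0, 13.5, 1.0)
    ratios = {50.0: 8.0, 200.0: 3.0, 1000.0: 1.2}

    def test_noise_free_curve_recovered_exactly(self):
        pts = make_fraction_points(0.5, self.ratios, self.forces, 1.6, 0.0, seed=1)
        fit = fit_fraction_force(
            [FractionPoint(force=F, fraction=f, se=1e-4, concentration=c)
             for F, f, se, c in pts], l_full=1.6)
        assert fit.delta_x == pytest.approx(0.5, abs=1e-6)
        for c, r in self.ratios.items():
            assert fit.rate_ratio[c] == pytest.approx(r, rel=1e-4)

    @pytest.mark.parametrize("delta_x", [0.5, 0.7])
    def test_noisy_recovery_within_2sd(self, delta_x):
        pts = make_fraction_points(delta_x, self.ratios, self.forces, 1.6, 0.05,
                                   seed=42)
        fit = fit_fraction_force(
            [FractionPoint(force=F, fraction=f, se=se, concentration=c)
             for F, f, se, c in pts], l_full=1.6)
        assert abs(fit.delta_x - delta_x) < 2 * fit.delta_x_se
        assert fit.preferred_model == "partial_closing"

    def test_full_one_lid_data_prefer_fixed_model(self):
        # generator truth: complete single-lid closure (Δx = L_full/2)
        pts = make_fraction_points(0.8, {200.0: 2.0, 1000.0: 0.8}, self.forces,
                                   1.6, 0.03, seed=43)
        fit = fit_fraction_force(
            [FractionPoint(force=F, fraction=f, se=se, concentration=c)
             for F, f, se, c in pts], l_full=1.6)
        # the free fit lands on the one-lid value, and the fixed alternative
        # describes the data essentially as well
        assert fit.delta_x == pytest.approx(0.8, abs=2 * fit.delta_x_se)
        assert fit.ssr_full_one_lid < 2.0 * fit.ssr + 1.0

    def test_partial_closing_data_reject_one_lid_model(self):
        pts = make_fraction_points(0.5, self.ratios, self.forces, 1.6, 0.05, seed=44)
        fit = fit_fraction_force(
            [FractionPoint(force=F, fraction=f, se=se, concentration=c)
             for F, f, se, c in pts], l_full=1.6)
        assert fit.preferred_model == "partial_closing"
        assert fit.ssr_full_one_lid > 5.0 * fit.ssr

    def test_single_force_unidentifiable(self):
        pts = [FractionPoint(force=8.0, fraction=0.2, se=0.01, concentration=c)
               for c in (50.0, 200.0)]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_fraction_force(pts, l_full=1.6)

    def test_force_dependent_l_full_interpolated(self):
        table = [(6.0, 1.55), (10.0, 1.6), (14.0, 1.65)]
        pts = make_fraction_points(
            0.5, self.ratios, self.forces,
            lambda F: np.interp(F, [r[0] for r in table], [r[1] for r in table]),
            0.0, seed=45)
        fit = fit_fraction_force(
            [FractionPoint(force=F, fraction=f, se=1e-4, concentration=c)
             for F, f, se, c in pts], l_full=table)
        assert fit.delta_x == pytest.approx(0.5, abs=1e-5)


class TestZeroForceFraction:
    def test_limits(self):
        pts = make_fraction_points(0.5, {200.0: 3.0}, np.arange(7.0, 13.5), 1.6,
                                   0.0, seed=2)
        fit = fit_fraction_force(
            [FractionPoint(force=F, fraction=f, se=1e-4, concentration=c)
             for F, f, se, c in pts], l_full=1.6)
        f0, se = zero_force_fraction(fit, 200.0)
        assert f0 == pytest.approx((0.5 / 1.6) / (1 + 3.0), rel=1e-4)
        assert np.isfinite(se)

    def test_unknown_concentration_rejected(self):
        pts = make_fraction_points(0.5, {200.0: 3.0}, np.arange(7.0, 13.5), 1.6,
                                   0.0, seed=3)
        fit = fit_fraction_force(
            [FractionPoint(force=F, fraction=f, se=1e-4, concentration=c)
             for F, f, se, c in pts], l_full=1.6)
        with pytest.raises(KeyError):
            zero_force_fraction(fit, 999.0)

    def test_matches_monte_carlo_zero_force_occupancy(self):
        """Model fraction at F = 0 equals Δx/L_full × closed occupancy of a
        zero-force dwell simulation within sampling error."""
        ratio = 2.5
        config = TraceSimConfig(
            seed=46, duration=100.0, ligand_concentration=1.0,
            k_close_zero_force=10.0, delta_x_close=0.0,
            k_open_zero_force=10.0 * ratio, delta_x_open=0.0,
            trap_separation=362.0,  # low tension; rates are force-free anyway
        )
        path = simulate_state_path(config)
        occupancy = path.duration[path.state == CLOSED].sum() / config.duration
        frac_mc = 0.5 / 1.6 * occupancy
        expected = (0.5 / 1.6) / (1 + ratio)
        n = path.n_usable(CLOSED)
        assert abs(frac_mc - expected) < 3 * expected * np.sqrt(2.0 / n)


class TestSaturation:
    def test_one_lid_limit_is_half(self):
        assert saturating_fraction(0.8, 1.6) == pytest.approx(0.5)

    def test_two_lid_limit_is_one(self):
        assert saturating_fraction(1.6, 1.6) == pytest.approx(1.0)


class TestConcentrationModel:
    concs = np.array([3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0])

    def test_zero_concentration_gives_zero_fraction(self):
        assert concentration_p_closed(0.0, 100.0, 50.0) == 0.0

    def test_symmetric_plateau_matches_manual_algebra(self):
        # K_open = K_close = K: p([L]) = c[L] / (c[L] + [L] + K) with
        # c = k_close/k_open; at saturation p -> c/(c+1)
        K = 100.0
        c = 2000.0 / 6500.0
        L = 1e9
        manual = c * L / (c * L + L + K)
        assert concentration_p_closed(L, K, K) == pytest.approx(manual, rel=1e-12)
        assert concentration_p_closed(L, K, K) == pytest.approx(c / (c + 1), rel=1e-6)

    def test_noisy_recovery_within_2sd(self, rng):
        Ko, Kc = 300.0, 120.0
        scale = 0.5 / 1.6
        truth = scale * concentration_p_closed(self.concs, Ko, Kc)
        obs = truth * (1 + 0.05 * rng.standard_normal(self.concs.size))
        fit = fit_concentration_model(
            list(zip(self.concs, obs, 0.05 * truth)), scale=scale)
        assert abs(fit.K_open - Ko) < 2 * fit.K_open_se
        assert abs(fit.K_close - Kc) < 2 * fit.K_close_se
        assert fit.fraction(0.0) == 0.0
        assert fit.f_max == pytest.approx(fit.fraction(1e12), rel=1e-3)

    def test_non_saturating_data_flagged(self, rng):
        Ko, Kc = 3e5, 3e5
        scale = 0.5 / 1.6
        truth = scale * concentration_p_closed(self.concs, Ko, Kc)
        with pytest.warns(UserWarning, match="saturation"):
            fit = fit_concentration_model(
                list(zip(self.concs, truth)), scale=scale)
        assert not fit.saturating

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            fit_concentration_model([(1.0, 0.0), (10.0, 0.1), (100.0, 0.2)],
                                    scale=0.3)


class TestEndToEndFractionRecovery:
    """Headline pipeline check: competition traces at several forces, level
    detection, normalisation against inhibitor-only traces, and the global
    force fit recover the substrate-induced conformational change."""

    def test_recovers_generator_delta_x(self, tether):
        from lidforce.detect import fit_hmm
        from lidforce.elasticity import constant_force_transform, solve_tether_equilibrium
        from lidforce.synthetic import render_trace

        delta_x_true = 0.5
        l_full = 1.6
        ratios = {200.0: 3.0, 1000.0: 1.2}
        separations = (380.0, 404.0, 427.0)
        points = []
        seed = 600
        for conc, ratio0 in ratios.items():
            for sep in separations:
                # inhibitor-only reference trace: full 1.6 nm transitions
                ref_cfg = TraceSimConfig(seed=seed, duration=6.0,
                                         ligand_concentration=200.0,
                                         trap_separation=sep)
                seed += 1
                ref = render_trace(simulate_state_path(ref_cfg), ref_cfg)
                ref_trace = constant_force_transform(ref.to_trace(), tether)
                hmm_ref = fit_hmm(ref_trace, open_is_high=True)
                L_ref = hmm_ref.level_open - hmm_ref.level_closed

                # competition trace: substrate occupancy shifts the open level
                # down by Δx·p_closed(F) (fast exchange, buried in noise)
                F_open = solve_tether_equilibrium(sep, ref_cfg.protein_extension_open,
                                                  tether).force
                p = float(p_closed(F_open, 1.0, ratio0, delta_x_true))
                comp_cfg = TraceSimConfig(
                    seed=seed, duration=6.0, ligand_concentration=200.0,
                    trap_separation=sep,
                    protein_extension_open=ref_cfg.protein_extension_open
                    - delta_x_true * p,
                    protein_contraction=l_full - delta_x_true * p,
                )
                seed += 1
                comp = render_trace(simulate_state_path(comp_cfg), comp_cfg)
                comp_trace = constant_force_transform(comp.to_trace(), tether)
                hmm_comp = fit_hmm(comp_trace, open_is_high=True)
                L_comp = hmm_comp.level_open - hmm_comp.level_closed

                frac = fraction_of_full_closing(L_ref, min(L_comp, L_ref))
                points.append(FractionPoint(force=F_open, fraction=frac,
                                            se=0.02, concentration=conc))
        fit = fit_fraction_force(points, l_full=l_full)
        assert abs(fit.delta_x - delta_x_true) < 2 * fit.delta_x_se
        assert fit.preferred_model == "partial_closing"
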