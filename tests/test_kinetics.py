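import numpy as np
import pytest

from chromoca.chromosome import real_time_conversion
from chromoca.damage import IRParams, SpontaneousProfile
from chromoca.dynamics import ConformationEnsemble
from chromoca.fixtures import fixture_spec
from chromoca.kinetics import (KineticsConfig, PairEvent,
                               conformational_transition_scenario,
                               contact_formation_kinetics,
                               decompose_mechanisms, simulate_breakage_first)
from chromoca.potentials import make_trial_potentials


class TestRealTime:
    def test_reference_conversions(self):
        h, s = real_time_conversion(18_000.0)
        assert h == pytest.approx(3.3, abs=0.05)
        h5, s5 = real_time_conversion(5.0)
        assert s5 == pytest.approx(3.3, abs=0.05)
        assert real_time_conversion(0.0) == (0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            real_time_conversion(-1.0)


class TestKineticsConfig:
    def test_rate_step_product_validated(self):
        with pytest.raises(ValueError):
            KineticsConfig(v_ce=5000.0)  # 5000/h * 3.3 s > 1

    def test_class_edges_must_increase(self):
        with pytest.raises(ValueError):
            KineticsConfig(v_ce=1.0, class_edges=(2.0, 1.2))

    def test_distance_classes(self):
        cfg = KineticsConfig(v_ce=1.0)
        assert cfg.distance_class(0.5) == 0
        assert cfg.distance_class(1.5) == 1
        assert cfg.distance_class(2.5) == 2
        assert cfg.distance_class(4.0) == 3
        assert cfg.distance_class(9.0) == 4


def _frozen_setup(dense_ensemble):
    """Static one-member ensemble with plenty of contacting pairs."""
    spec, _field, ens = dense_ensemble
    return spec, ConformationEnsemble(ens.positions[:1].copy())


class TestBreakageFirst:
    def test_zero_rate_zero_breakpoints(self, dense_ensemble):
        spec, field, ens = dense_ensemble
        cfg = KineticsConfig(v_ce=0.0, t_max_ps=100.0)
        res = simulate_breakage_first(spec, ens, field, IRParams(15.0), None,
                                      cfg, m_cells=3, seed=1)
        assert res.total_per_cell == 0.0
        assert len(res.conversions) == 0

    def test_frozen_dynamics_matches_geometric_oracle(self, dense_ensemble):
        """With static conformations, conversions per initially contacting
        pair follow 1 - (1 - V dt)^(n_trials)."""
        spec, ens = _frozen_setup(dense_ensemble)
        field = make_trial_potentials("coil", spec)
        gamma = SpontaneousProfile.uniform(spec.n_subunits, 0.5)
        cfg = KineticsConfig(v_ce=30.0, t_max_ps=500.0, frozen=True)
        res = simulate_breakage_first(spec, ens, field, IRParams(0.0), gamma,
                                      cfg, m_cells=40, seed=5)
        n_checks = int(500.0 / 5.0)
        p = cfg.p_convert_per_step
        p_total = 1.0 - (1.0 - p) ** (n_checks + 1)
        initial = [ev for ev in res.pair_events if ev.first_contact_ps == 0.0]
        conv = sum(1 for ev in initial if ev.converted_ps is not None)
        lam = len(initial) * p_total
        assert len(initial) > 50
        assert abs(conv - lam) < 3 * np.sqrt(lam * (1 - p_total) + 1)

    def test_decomposition_sums_to_total(self, dense_ensemble):
        spec, field, ens = dense_ensemble
        gamma = SpontaneousProfile.uniform(spec.n_subunits, 0.1)
        cfg = KineticsConfig(v_ce=100.0, t_max_ps=200.0)
        res = simulate_breakage_first(spec, ens, field, IRParams(15.0), gamma,
                                      cfg, m_cells=4, seed=9)
        cf, bf = decompose_mechanisms(res)
        assert np.allclose(cf + bf, res.values)

    def test_frozen_dynamics_forms_no_new_contacts(self, dense_ensemble):
        spec, ens = _frozen_setup(dense_ensemble)
        field = make_trial_potentials("coil", spec)
        gamma = SpontaneousProfile.uniform(spec.n_subunits, 0.4)
        cfg = KineticsConfig(v_ce=10.0, t_max_ps=200.0, frozen=True)
        res = simulate_breakage_first(spec, ens, field, IRParams(0.0), gamma,
                                      cfg, m_cells=5, seed=2)
        for ev in res.pair_events:
            if ev.first_contact_ps is not None:
                assert ev.first_contact_ps == 0.0


class TestContactFormationKinetics:
    def _events(self):
        return [
            PairEvent(0, 0, 2, 9, 0.8, 0, 0.0, None),
            PairEvent(0, 0, 2, 14, 1.5, 1, 10.0, None),
            PairEvent(0, 1, 3, 9, 2.5, 2, 25.0, None),
            PairEvent(1, 0, 2, 30, 7.0, 4, None, None),
        ]

    def test_t0_column_counts_preexisting_contacts(self):
        te = np.arange(0, 35.0, 5.0)
        lk = contact_formation_kinetics(self._events(), (1.2, 2, 3, 6), te)
        assert lk.cumulative[0, 0] == 1  # the r0 <= 1.2 d pair, at t = 0
        assert lk.differential[1, 2] == 1  # first contact at t = 10
        assert lk.differential[4].sum() == 0

    def test_cumulative_is_running_sum_and_monotone(self):
        te = np.arange(0, 35.0, 5.0)
        lk = contact_formation_kinetics(self._events(), (1.2, 2, 3, 6), te)
        assert np.allclose(lk.cumulative, np.cumsum(lk.differential, axis=1))
        assert np.all(np.diff(lk.cumulative, axis=1) >= 0)

    def test_bad_class_edges_rejected(self):
        with pytest.raises(ValueError):
            contact_formation_kinetics([], (3.0, 1.0), np.arange(3.0))


class TestTransitionScenarios:
    def test_identical_profiles_reduce_to_plain_contact_first(self):
        p = np.array([1.0, 2.0, 3.0])
        res = conformational_transition_scenario(
            "early-late", None, p, p, exp_profile=p)
        assert np.allclose(res.values, p)
        assert res.chi2 == pytest.approx(0.0)

    def test_degenerate_weight_returns_early_profile(self):
        pe = np.array([1.0, 2.0, 3.0])
        pl = np.array([5.0, 5.0, 5.0])
        res = conformational_transition_scenario(
            "early-late", None, pe, pl, weights=(1.0, 0.0))
        assert np.allclose(res.values, pe)

    def test_fitted_weight_beats_no_transition(self):
        """A profile generated with a known mixture is matched better by
        the fitted two-ensemble combination than by either endpoint."""
        rng = np.random.default_rng(0)
        pe = rng.uniform(1, 2, 30)
        pl = rng.uniform(1, 2, 30)
        truth = 0.4 * pe + 0.6 * pl
        from chromoca.aberrations import chi_square
        res = conformational_transition_scenario(
            "early-late", None, pe, pl, exp_profile=truth)
        assert res.chi2 < chi_square(pe, truth)
        assert res.chi2 < chi_square(pl, truth)
        assert res.weights[0] == pytest.approx(0.4, abs=0.01)

    def test_transition_then_dynamics_sums_parts(self):
        pe = np.array([1.0, 0.0])
        pl = np.array([0.5, 0.5])
        res = conformational_transition_scenario(
            "transition-then-dynamics", None, pe, pl, weights=(1.0, 1.0))
        assert np.allclose(res.values, pe + pl)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            conformational_transition_scenario("sudden", None,
                                               np.ones(3), np.ones(3))
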