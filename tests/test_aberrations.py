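import numpy as np
import pytest

from chromoca.aberrations import (breaksite_exclusion_mask, chi_square,
                                  contacts_to_exchanges, dose_response,
                                  fit_pce, fluctuation_stats,
                                  lesion_contact_pairs, pce_closed_form,
                                  population_breakpoints_cf)
from chromoca.damage import (DamageProfile, IRParams, SpontaneousProfile,
                             sample_damage)
from chromoca.dynamics import Conformation
from chromoca.fixtures import fixture_spec


class TestLesionContacts:
    def test_no_lesions_empty(self, rng):
        conf = Conformation(rng.uniform(-2, 2, (10, 3)))
        dmg = DamageProfile(np.array([], int), [], 10)
        assert lesion_contact_pairs(conf, dmg) == []

    def test_two_close_lesions_form_one_pair(self):
        pos = np.zeros((10, 3))
        pos[:, 0] = np.arange(10) * 5.0
        pos[7] = pos[2] + np.array([1.0, 0, 0])
        conf = Conformation(pos)
        dmg = DamageProfile(np.array([2, 7]), ["nuclease", "IR"], 10)
        assert lesion_contact_pairs(conf, dmg) == [(2, 7)]

    def test_is_bruteforce_filter_of_contacts(self, rng):
        from chromoca.contacts import conformation_contacts
        pos = rng.uniform(-2, 2, (12, 3))
        conf = Conformation(pos)
        beads = np.array([0, 3, 5, 9, 11])
        dmg = DamageProfile(beads, ["IR"] * 5, 12)
        got = set(lesion_contact_pairs(conf, dmg))
        full = conformation_contacts(conf)
        expected = {(int(a), int(b)) for ai, a in enumerate(beads)
                    for b in beads[ai + 1:]
                    if abs(int(a) - int(b)) > 1 and full[a, b]}
        assert got == expected


class TestContactsToExchanges:
    def test_zero_probability_no_exchanges(self, rng):
        assert contacts_to_exchanges([(1, 5), (2, 9)], 0.0, rng) == []

    def test_unit_probability_converts_all(self, rng):
        evs = contacts_to_exchanges([(1, 5), (2, 9)], 1.0, rng)
        assert len(evs) == 2
        assert {e.type for e in evs} <= {"symmetric", "asymmetric"}

    def test_types_equally_likely(self):
        rng = np.random.default_rng(0)
        evs = contacts_to_exchanges([(0, 2)] * 4000, 1.0, rng)
        sym = sum(1 for e in evs if e.type == "symmetric")
        assert abs(sym - 2000) < 3 * np.sqrt(1000)

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            contacts_to_exchanges([], 1.5, rng)


class TestPopulationBreakpoints:
    def test_zero_pce_all_zero(self, tiny_fixture):
        fx = tiny_fixture
        bp = population_breakpoints_cf(fx["spec"], fx["ensemble"],
                                       IRParams(5.0), None, 0.0)
        assert np.all(bp.values == 0)

    def test_per_contact_frequency_order_1e_minus_5(self):
        """Product of damage and conversion probabilities at 5 Gy."""
        f = IRParams(5.0).p_dsb * 0.0029
        assert 0.5e-5 < f < 2e-5

    def test_decoupled_matches_monte_carlo(self, tiny_fixture):
        """Expectation form agrees with the per-cell simulation to 3 SE."""
        fx = tiny_fixture
        p_ce = 0.05  # elevated conversion for counting statistics
        ana = population_breakpoints_cf(fx["spec"], fx["ensemble"],
                                        IRParams(5.0), fx["gamma_sp"], p_ce,
                                        decoupled=True)
        m = 20_000
        mc = population_breakpoints_cf(fx["spec"], fx["ensemble"],
                                       IRParams(5.0), fx["gamma_sp"], p_ce,
                                       m_cells=m, seed=17, decoupled=False)
        lam = ana.values.sum() * m  # expected bait-involving count
        observed = mc.values.sum() * m
        assert abs(observed - lam) < 3 * np.sqrt(lam)


class TestChiSquare:
    def test_zero_when_identical(self):
        assert chi_square(np.ones(5), np.ones(5)) == 0.0

    def test_two_bin_hand_case(self):
        assert chi_square(np.array([1.0, 1.0]), np.array([2.0, 0.0])) == 2.0

    def test_excluded_bins_do_not_contribute(self):
        sim = np.array([1.0, 1.0, 1.0])
        exp = np.array([1.0, 50.0, 1.0])
        excl = np.array([False, True, False])
        assert chi_square(sim, exp, excl) == 0.0

    def test_zero_sim_bin_rejected(self):
        with pytest.raises(ValueError):
            chi_square(np.array([0.0, 1.0]), np.array([1.0, 1.0]))


class TestFitPce:
    def test_recovers_known_probability(self, tiny_fixture):
        fx = tiny_fixture
        grid = np.arange(0.001, 0.006, 0.00025)
        est = fit_pce(fx["spec"], fx["ensemble"], IRParams(5.0),
                      fx["gamma_sp"], fx["profile"], grid)
        assert abs(est - fx["p_ce"]) <= 0.00025

    def test_grid_minimum_matches_closed_form(self, tiny_fixture):
        fx = tiny_fixture
        base = population_breakpoints_cf(fx["spec"], fx["ensemble"],
                                         IRParams(5.0), fx["gamma_sp"], 1.0,
                                         decoupled=True).values
        excl = breaksite_exclusion_mask(fx["spec"].n_subunits,
                                        fx["spec"].breaksite, 5)
        keep = ~excl & (base > 0)
        star = pce_closed_form(base, fx["profile"], keep)
        grid = np.linspace(0.5 * star, 2.0 * star, 201)
        est = fit_pce(fx["spec"], fx["ensemble"], IRParams(5.0),
                      fx["gamma_sp"], fx["profile"], grid)
        assert est == pytest.approx(star, rel=0.02)

    def test_zero_profile_rejected(self, tiny_fixture):
        fx = tiny_fixture
        with pytest.raises(ValueError):
            fit_pce(fx["spec"], fx["ensemble"], IRParams(5.0),
                    fx["gamma_sp"], np.zeros(fx["spec"].n_subunits),
                    [0.001, 0.01])


class TestDoseResponse:
    def test_channel_scalings_analytic(self, tiny_fixture):
        fx = tiny_fixture
        dd = dose_response(fx["spec"], fx["ensemble"], [0.0, 1.0, 2.0, 4.0],
                           fx["gamma_sp"], 0.0029)
        nucl_ir = [dd[d]["IR-nucl"] for d in (1.0, 2.0, 4.0)]
        assert nucl_ir[1] == pytest.approx(2 * nucl_ir[0], rel=1e-9)
        assert nucl_ir[2] == pytest.approx(4 * nucl_ir[0], rel=1e-9)
        ir_ir = [dd[d]["IR-IR"] for d in (1.0, 2.0)]
        assert ir_ir[1] == pytest.approx(4 * ir_ir[0], rel=1e-9)
        # no irradiation: only spontaneous-involving channels remain
        assert dd[0.0]["IR-nucl"] == 0.0
        assert dd[0.0]["IR-IR"] == 0.0
        assert dd[0.0]["nucl-spont"] > 0.0

    def test_nucl_spont_channel_dose_independent(self, tiny_fixture):
        fx = tiny_fixture
        dd = dose_response(fx["spec"], fx["ensemble"], [0.0, 5.0, 15.0],
                           fx["gamma_sp"], 0.0029)
        vals = [dd[d]["nucl-spont"] for d in (0.0, 5.0, 15.0)]
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])


class TestFluctuations:
    def test_constant_samples_zero(self):
        assert fluctuation_stats(np.full(10, 3.0)) == 0.0

    def test_poisson_samples_inverse_sqrt_lambda(self, rng):
        lam = 9.0
        x = rng.poisson(lam, size=200_000)
        assert fluctuation_stats(x) == pytest.approx(1 / np.sqrt(lam), rel=0.02)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            fluctuation_stats(np.zeros(5))
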