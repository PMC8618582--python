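import numpy as np
import pytest
from hypothesis import given, strategies as st

from chromoca.contacts import (ContactMap, ContactProfile, aggregate_contacts,
                               conformation_contacts, contact_count_pmf,
                               contact_vs_separation, pair_mask, pool_average,
                               power_exponent, pseudo4c_profile, rebin_smooth,
                               single_cell_map)
from chromoca.dynamics import Conformation, ConformationEnsemble


def brute_force_contacts(pos, r_cont):
    n = pos.shape[0]
    out = np.zeros((n, n), int)
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(pos[i] - pos[j]) <= r_cont:
                out[i, j] = 1
    return out


class TestContactDetection:
    def test_inclusive_at_cutoff(self):
        pos = np.array([[0.0, 0, 0], [1.2, 0, 0], [10, 10, 10]])
        m = conformation_contacts(Conformation(pos), 1.2)
        assert m[0, 1] == 1 and m[1, 0] == 1

    def test_exclusive_beyond_cutoff(self):
        pos = np.array([[0.0, 0, 0], [1.21, 0, 0], [10, 10, 10]])
        m = conformation_contacts(Conformation(pos), 1.2)
        assert m[0, 1] == 0

    @given(st.integers(0, 10 ** 6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(-2, 2, size=(10, 3))
        fast = conformation_contacts(Conformation(pos), 1.2)
        assert np.array_equal(fast, brute_force_contacts(pos, 1.2))


class TestAggregation:
    def _tiny_ensemble(self, rng):
        pos = rng.uniform(-2, 2, size=(8, 10, 3))
        return ConformationEnsemble(pos)

    def test_single_member_counts_equal_binary_map(self, rng):
        ens = ConformationEnsemble(rng.uniform(-2, 2, size=(1, 10, 3)))
        counts = aggregate_contacts(ens, "counts")
        assert np.array_equal(counts.values,
                              conformation_contacts(Conformation(ens.positions[0])))

    def test_relative_sums_to_one_over_unmasked(self, rng):
        ens = self._tiny_ensemble(rng)
        rel = aggregate_contacts(ens, "relative")
        mask = pair_mask(None, 10)
        iu = np.triu_indices(10, 1)
        assert rel.values[iu][mask[iu]].sum() == pytest.approx(1.0)

    def test_per_cell_is_twice_per_chromosome(self, rng):
        ens = self._tiny_ensemble(rng)
        per_chr = aggregate_contacts(ens, "per-chromosome")
        per_cell = aggregate_contacts(ens, "per-cell")
        assert np.allclose(per_cell.values, 2.0 * per_chr.values)

    def test_per_cell_rejects_odd_ensemble(self, rng):
        ens = ConformationEnsemble(rng.uniform(-2, 2, size=(3, 10, 3)))
        with pytest.raises(ValueError):
            aggregate_contacts(ens, "per-cell")

    def test_modes_are_rational_multiples_of_counts(self, rng):
        ens = self._tiny_ensemble(rng)
        counts = aggregate_contacts(ens, "counts").values
        per_chr = aggregate_contacts(ens, "per-chromosome").values
        assert np.allclose(per_chr * len(ens), counts)


class TestContactVsSeparation:
    def test_single_contact_lands_at_its_separation(self):
        vals = np.zeros((10, 10))
        vals[2, 7] = vals[7, 2] = 1.0
        f_s = contact_vs_separation(ContactMap(vals, "relative"))
        s, f = f_s
        assert f[s == 5][0] == pytest.approx(1.0)
        assert f[s != 5].sum() == 0

    def test_matches_hand_summation(self, rng):
        m = rng.random((10, 10))
        m = (m + m.T) / 2
        cmap = ContactMap(m, "relative")
        s, f = contact_vs_separation(cmap)
        for k, sep in enumerate(s):
            assert f[k] == pytest.approx(np.diagonal(m, sep).sum())

    def test_total_equals_relative_map_total(self, rng):
        pos = rng.uniform(-2, 2, size=(6, 12, 3))
        ens = ConformationEnsemble(pos)
        rel = aggregate_contacts(ens, "relative")
        s, f = contact_vs_separation(rel)
        assert f.sum() == pytest.approx(1.0)

    def test_wrong_mode_rejected(self):
        with pytest.raises(ValueError):
            contact_vs_separation(ContactMap(np.zeros((5, 5)), "counts"))


class TestPowerExponent:
    def test_exact_inverse_law(self):
        s = np.arange(2, 100)
        assert power_exponent(s, 1.0 / s) == pytest.approx(-1.0)

    def test_exact_minus_0p9(self):
        s = np.arange(2, 100)
        f = 3.0 * s ** (-0.9)
        assert power_exponent(s, f) == pytest.approx(-0.9)

    def test_matches_independent_regression(self, rng):
        s = np.arange(2, 80)
        f = np.exp(rng.normal(0, 0.05, s.shape)) * s ** (-1.2)
        from scipy.stats import linregress
        sel = (s * 100_000 >= 500_000) & (s * 100_000 <= 5_000_000)
        expected = linregress(np.log(s[sel]), np.log(f[sel])).slope
        assert power_exponent(s, f) == pytest.approx(expected)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            power_exponent(np.array([5, 6]), np.array([1.0, 1.0]))


class TestProfiles:
    def test_pseudo4c_is_row_extraction(self, rng):
        m = rng.random((10, 10))
        m = (m + m.T) / 2
        cmap = ContactMap(m, "relative")
        prof = pseudo4c_profile(cmap, 4)
        assert np.array_equal(prof.values, m[4])
        assert prof.anchor == 4

    def test_pseudo4c_masked_anchor_rejected(self, tiny_fixture):
        cmap = tiny_fixture["target_map"]
        bad = sorted(tiny_fixture["spec"].masked_bins)[0]
        with pytest.raises(ValueError):
            pseudo4c_profile(cmap, bad, tiny_fixture["spec"])

    def test_single_cell_map_doubles_identical_copies(self, rng):
        pos = rng.uniform(-1.5, 1.5, size=(8, 3))
        c = Conformation(pos)
        sc = single_cell_map(c, c)
        assert np.array_equal(sc.values, 2 * conformation_contacts(c))

    def test_single_cell_map_is_sum_of_copies(self, rng):
        a = Conformation(rng.uniform(-2, 2, size=(8, 3)))
        b = Conformation(rng.uniform(-2, 2, size=(8, 3)))
        sc = single_cell_map(a, b)
        assert np.array_equal(sc.values,
                              conformation_contacts(a) + conformation_contacts(b))


class TestPooling:
    def test_full_pool_is_population_mean(self, rng):
        items = rng.random((20, 6))
        assert np.allclose(pool_average(items, 20, seed=0), items.mean(axis=0))

    def test_single_cell_pool(self, rng):
        items = rng.random((20, 6))
        out = pool_average(items, 1, seed=3)
        assert any(np.allclose(out, row) for row in items)

    def test_variance_shrinks_like_one_over_m(self, rng):
        items = rng.normal(size=(4000, 1))
        var = {}
        for m in (10, 100, 1000):
            draws = [pool_average(items, m, seed=s)[0] for s in range(60)]
            var[m] = np.var(draws)
        assert var[10] > 4 * var[100] > 4 * var[1000]


class TestRebinSmooth:
    def test_constant_profile_unchanged(self):
        out = rebin_smooth(np.full(40, 2.0))
        assert np.allclose(out.values, 4.0)  # pairwise sum of constant bins

    def test_spike_spread_conserves_total(self):
        vals = np.zeros(40)
        vals[20] = 10.0
        out = rebin_smooth(vals)
        assert out.values.sum() == pytest.approx(10.0)
        assert (out.values > 0).sum() == 5  # 1 Mb window at 200 kb

    def test_exempt_region_passthrough(self):
        vals = np.zeros(40)
        vals[10] = 6.0
        out = rebin_smooth(vals, exempt_bins=(8, 12))
        agg = np.zeros(20)
        agg[5] = 6.0
        assert np.array_equal(out.values[4:6], agg[4:6])

    def test_window_validated(self):
        with pytest.raises(ValueError):
            rebin_smooth(np.ones(10), window_bins=0)


class TestContactCountPmf:
    def test_no_contacts_concentrates_at_zero(self):
        line = np.zeros((8, 3))
        line[:, 0] = np.arange(8) * 10.0  # beads far apart
        ens = ConformationEnsemble(np.repeat(line[None], 4, axis=0))
        support, pmf = contact_count_pmf(ens, 3)
        assert pmf[0] == pytest.approx(1.0)

    def test_pmf_normalised_and_matches_tally(self, tiny_fixture):
        ens = tiny_fixture["ensemble"]
        anchor = tiny_fixture["spec"].breaksite
        support, pmf = contact_count_pmf(ens, anchor)
        assert pmf.sum() == pytest.approx(1.0)
        # direct tally oracle on the first cell
        rc2 = 1.2 ** 2
        tot = 0
        for copy in (0, 1):
            p = ens.positions[copy]
            d2 = ((p - p[anchor]) ** 2).sum(axis=1)
            hit = d2 <= rc2
            for b in (anchor - 1, anchor, anchor + 1):
                hit[b] = False
            tot += hit.sum()
        counts = np.zeros(len(ens) // 2, int)
        # recompute the full distribution and check cell 0 is included
        assert pmf[tot] > 0
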