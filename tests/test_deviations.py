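"""Extreme-deviation maps, permutation nulls, FDR, effect sizes."""

import numpy as np
import pytest
from scipy import stats

from msnbiotype.normative import DeviationTensor
from msnbiotype.synthetic import NodeGeometry, fibonacci_sphere
from msnbiotype.deviations import (
    biotype_node_chisq,
    cohen_h,
    difference_map,
    extreme_burden_compare,
    fdr_bh,
    group_permutation_test,
    overlap_map,
    spin_permutations,
    spin_test,
)

METRICS = ("degree_centrality", "nodal_efficiency", "participation_coefficient")


def make_devs(z):
    return DeviationTensor(z=z, metric_names=METRICS[: z.shape[2]], subject_ids=[f"s{i}" for i in range(z.shape[0])])


def make_geometry(n):
    return NodeGeometry(coords=fibonacci_sphere(n), true_module=np.zeros(n, dtype=int))


class TestOverlap:
    def test_all_zero_z_gives_zero_proportions(self):
        devs = make_devs(np.zeros((10, 5, 1)))
        m = overlap_map(devs, np.arange(10), 0)
        assert np.all(m.proportion == 0)

    def test_counting(self):
        z = np.zeros((10, 4, 1))
        z[:3, 2, 0] = 2.5
        m = overlap_map(make_devs(z), np.arange(10), 0)
        assert m.proportion[2] == pytest.approx(0.30)

    def test_direction_additivity(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 1.5, (50, 8, 1))
        devs = make_devs(z)
        idx = np.arange(50)
        pos = overlap_map(devs, idx, 0, "positive").proportion
        neg = overlap_map(devs, idx, 0, "negative").proportion
        either = overlap_map(devs, idx, 0, "either").proportion
        assert np.allclose(either, pos + neg)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            overlap_map(make_devs(np.zeros((5, 3, 1))), np.array([], dtype=int), 0)


class TestDifferenceMap:
    def test_identical_maps_zero(self):
        z = np.abs(np.random.default_rng(1).normal(0, 1.5, (20, 6, 1)))
        devs = make_devs(np.vstack([z, z]))
        a = overlap_map(devs, np.arange(20), 0)
        b = overlap_map(devs, np.arange(20, 40), 0)
        assert np.allclose(difference_map(a, b), 0.0)

    def test_percentage_point_format(self):
        z = np.zeros((20, 1, 1))
        z[:2, 0, 0] = 3.0  # 10% of cases extreme
        devs = make_devs(z)
        case = overlap_map(devs, np.arange(20), 0, group="case")
        ctrl_z = np.zeros((181, 1, 1))
        ctrl_z[:4, 0, 0] = 3.0  # 2.21% of controls
        ctrl = overlap_map(make_devs(ctrl_z), np.arange(181), 0, group="control")
        d = case.proportion[0] * 100 - ctrl.proportion[0] * 100
        assert difference_map(case, ctrl)[0] == pytest.approx(d)
        assert d == pytest.approx(7.79, abs=0.01)

    def test_antisymmetric(self):
        rng = np.random.default_rng(2)
        devs = make_devs(rng.normal(0, 1.5, (40, 5, 1)))
        a = overlap_map(devs, np.arange(20), 0)
        b = overlap_map(devs, np.arange(20, 40), 0)
        assert np.allclose(difference_map(a, b), -difference_map(b, a))


class TestGroupPermutation:
    def test_add_one_lower_bound(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, (60, 4, 1))
        z[:30] += 3.0  # big group difference
        labels = np.zeros(60, bool)
        labels[:30] = True
        _, p = group_permutation_test(make_devs(z), labels, 0, n_perm=200, seed=0)
        assert np.all(p >= 1 / 201 - 1e-12)
        assert np.any(p == pytest.approx(1 / 201))

    def test_null_calibration(self):
        """Independent labels: rejection rate ~ alpha, mean p ~ 0.5.

        (The permutation statistic is lattice-valued, so the p-value
        distribution is discrete; calibration is checked on rejection
        rates rather than by a KS uniformity test.)
        """
        rng = np.random.default_rng(4)
        z = rng.normal(0, 1.3, (80, 100, 1))
        labels = np.zeros(80, bool)
        labels[:40] = True
        _, p = group_permutation_test(make_devs(z), labels, 0, n_perm=400, seed=1)
        assert np.mean(p <= 0.05) <= 0.13  # 0.05 + ~2 clustered-SE
        # ties at the lattice-valued statistic make the test conservative,
        # never anti-conservative
        assert 0.4 < p.mean() < 0.9

    def test_minimum_nperm_enforced(self):
        with pytest.raises(ValueError):
            group_permutation_test(make_devs(np.zeros((10, 2, 1))), np.zeros(10, bool), 0, n_perm=10)

    def test_within_site_stratification_preserves_sizes(self):
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1.5, (40, 6, 1))
        labels = np.zeros(40, bool)
        labels[::2] = True
        sites = np.repeat([0, 1], 20)
        _, p = group_permutation_test(
            make_devs(z), labels, 0, n_perm=150, seed=2, within=sites
        )
        assert p.shape == (6,)


class TestSpin:
    def test_identity_statistic_reproduced(self):
        rng = np.random.default_rng(6)
        geom = make_geometry(40)
        a, b = rng.normal(0, 1, (2, 40))
        r_obs, _ = spin_test(a, b, geom, n_surrogates=100, seed=0)
        assert r_obs == pytest.approx(stats.spearmanr(a, b).statistic)

    def test_equal_maps_minimal_p(self):
        geom = make_geometry(60)
        a = np.random.default_rng(7).normal(0, 1, 60)
        r, p = spin_test(a, a.copy(), geom, n_surrogates=199, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_white_noise_rejection_rate(self):
        geom = make_geometry(50)
        rng = np.random.default_rng(8)
        perms = spin_permutations(geom, 199, seed=3)
        rejections = sum(
            spin_test(rng.normal(0, 1, 50), rng.normal(0, 1, 50), geom, perms=perms)[1] < 0.05
            for _ in range(60)
        )
        # ~5% of 60 = 3; binomial(60, .05) 99th pct ~ 8
        assert rejections <= 8

    def test_hungarian_preserves_value_multiset(self):
        geom = make_geometry(30)
        a = np.random.default_rng(9).normal(0, 1, 30)
        perms = spin_permutations(geom, 20, seed=4, assignment="hungarian")
        for p in perms:
            assert np.allclose(np.sort(a[p]), np.sort(a))

    def test_duplicate_coordinates_rejected(self):
        coords = fibonacci_sphere(10)
        coords[3] = coords[7]
        geom = NodeGeometry(coords=coords, true_module=np.zeros(10, dtype=int))
        with pytest.raises(ValueError, match="duplicate"):
            spin_permutations(geom, 10, seed=0)


class TestFDRAndEffectSizes:
    def test_bh_hand_oracle(self):
        q, reject = fdr_bh(np.array([0.01, 0.02, 0.04, 0.5]), 0.05)
        assert np.allclose(q, [0.04, 0.04, 0.05333333, 0.5], atol=1e-8)
        assert list(reject) == [True, True, False, False]

    def test_all_ones_no_rejections(self):
        q, reject = fdr_bh(np.ones(10))
        assert not reject.any()

    def test_adjusted_at_least_raw(self):
        p = np.random.default_rng(10).uniform(0, 1, 30)
        q, _ = fdr_bh(p)
        assert np.all(q >= p - 1e-12)

    def test_cohen_h_closed_form(self):
        assert cohen_h(0.25, 0.09) == pytest.approx(0.4378, abs=1e-4)
        assert cohen_h(0.3, 0.3) == 0.0
        assert cohen_h(0.1, 0.4) == pytest.approx(-cohen_h(0.4, 0.1))


class TestBurden:
    def test_identical_groups_zero_d(self):
        z = np.abs(np.random.default_rng(11).normal(0, 1.5, (30, 10, 3)))
        devs = make_devs(np.vstack([z, z]))
        labels = np.concatenate([np.ones(30, bool), np.zeros(30, bool)])
        table = extreme_burden_compare(devs, labels)
        assert np.allclose(table["cohen_d"], 0.0)

    def test_counts_are_bounded_integers(self):
        rng = np.random.default_rng(12)
        devs = make_devs(rng.normal(0, 2, (40, 12, 3)))
        counts = (np.abs(devs.z) >= 2).sum(axis=1)
        assert counts.min() >= 0 and counts.max() <= 12
        assert np.issubdtype(counts.dtype, np.integer)

    def test_planted_burden_shift_recovered(self):
        """+1 extreme node on average at count SD 3 -> d ~ 0.33."""
        rng = np.random.default_rng(13)
        n, R = 500, 60
        counts = np.clip(
            np.round(np.concatenate([rng.normal(5.2, 3.0, n), rng.normal(4.2, 3.0, n)])),
            0,
            R,
        ).astype(int)
        z = np.zeros((2 * n, R, 1))
        for i, c in enumerate(counts):
            z[i, :c, 0] = 3.0
        labels = np.zeros(2 * n, bool)
        labels[:n] = True
        table = extreme_burden_compare(make_devs(z), labels)
        assert table["cohen_d"].iloc[0] == pytest.approx(0.33, abs=0.1)


class TestBiotypeChisq:
    def test_equal_frequencies_zero(self):
        z = np.zeros((30, 4, 1))
        for start in (0, 10, 20):  # 4 extreme subjects in each biotype
            z[start : start + 4, :, 0] = 3.0
        bl = np.repeat([1, 2, 3], 10)
        table = biotype_node_chisq(make_devs(z), bl, 0)
        assert np.allclose(table["chi2"], 0.0)
        assert np.allclose(table["p"], 1.0)

    def test_hand_contingency_oracle(self):
        """2x2 table [[20,80],[5,95]] -> Pearson chi2 = 10.2857 (1 df).

        Verified by hand: E = [[12.5, 87.5], [12.5, 87.5]];
        chi2 = 2*(7.5^2/12.5 + 7.5^2/87.5) = 10.2857.
        """
        z = np.zeros((200, 1, 1))
        bl = np.repeat([1, 2], 100)
        z[:20, 0, 0] = 3.0  # 20/100 extreme in biotype 1
        z[100:105, 0, 0] = 3.0  # 5/100 in biotype 2
        table = biotype_node_chisq(make_devs(z), bl, 0)
        assert table["chi2"].iloc[0] == pytest.approx(10.2857142857, abs=1e-6)
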