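import numpy as np
import pytest

from aneuqs.popstats import (
    brown_forsythe_statistic,
    distance_to_root,
    estimate_aneuploidy_rate,
    levene_variance_test,
    median_root_profile,
    pairwise_distances,
    ploidy_tail_weight,
)
from aneuqs.simulate import generate_two_site_dataset
from aneuqs.units import Karyotype


class TestDistanceToRoot:
    def test_basic_distances(self):
        root = [2, 2, 2]
        profiles = np.array([[2, 2, 2], [3, 2, 2], [5, 6, 2]])
        d = distance_to_root(profiles, root).distances
        assert d == pytest.approx([0.0, 1.0, 5.0])

    def test_unit_permutation_invariance(self):
        rng = np.random.default_rng(1)
        profiles = rng.integers(0, 6, (20, 7))
        root = rng.integers(1, 4, 7)
        perm = rng.permutation(7)
        d1 = distance_to_root(profiles, root).distances
        d2 = distance_to_root(profiles[:, perm], root[perm]).distances
        assert d1 == pytest.approx(d2)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            distance_to_root(np.ones((3, 4)), [2, 2])

    def test_median_root_profile(self):
        profiles = np.array([[2, 3], [2, 5], [2, 3], [4, 3]])
        assert median_root_profile(profiles).tolist() == [2, 3]

    def test_pairwise_distances_count(self):
        assert pairwise_distances(np.ones((5, 3))).shape == (10,)


class TestLeveneVarianceTest:
    def test_identical_deviation_sets_give_null_result(self):
        # medians 2 and 5; deviations (1,0,1) both -> F = 0, p = 1
        res = levene_variance_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_statistic_matches_scipy_f_route(self):
        import scipy.stats

        rng = np.random.default_rng(0)
        g1, g2 = rng.normal(0, 1, 30), rng.normal(0, 2, 45)
        own = brown_forsythe_statistic(g1, g2)
        ref = scipy.stats.levene(g1, g2, center="median").statistic
        assert own == pytest.approx(ref, rel=1e-12)

    def test_location_shift_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(2)
        g1, g2 = rng.normal(0, 1, 25), rng.normal(0, 3, 25)
        base = brown_forsythe_statistic(g1, g2)
        assert brown_forsythe_statistic(g1 + 7.3, g2 + 7.3) == pytest.approx(base, rel=1e-9)
        assert brown_forsythe_statistic(2.5 * g1, 2.5 * g2) == pytest.approx(base, rel=1e-9)

    def test_permutation_agrees_with_f_approximation(self):
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(0, 1, 40), rng.normal(0, 1.5, 40)
        pf = levene_variance_test(g1, g2, method="f").p_value
        pp = levene_variance_test(g1, g2, method="permutation", n_perm=4000, seed=0).p_value
        assert abs(pf - pp) <= 0.03

    def test_degenerate_deviations_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = levene_variance_test([5, 5, 5], [7, 7, 7])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            levene_variance_test([1, 2], [3, 4, 5])
        with pytest.raises(ValueError):
            levene_variance_test([2, 2, 2], [2, 2, 2])
        with pytest.raises(ValueError):
            levene_variance_test([1, 2, 3], [4, 5, 6], method="bootstrap")


class TestPloidyTailWeight:
    def test_all_cells_at_mode(self):
        assert ploidy_tail_weight([46.0] * 30, delta=0.1) == 0.0

    def test_adding_high_cells_increases_weight(self):
        base = list(np.linspace(45, 47, 50))
        w0 = ploidy_tail_weight(base, delta=0.15)
        w1 = ploidy_tail_weight(base + [60.0] * 5, delta=0.15)
        w2 = ploidy_tail_weight(base + [60.0] * 15, delta=0.15)
        assert w0 < w1 < w2

    def test_validation(self):
        with pytest.raises(ValueError):
            ploidy_tail_weight([], delta=0.1)
        with pytest.raises(ValueError):
            ploidy_tail_weight([1.0], delta=0.0)


class TestEstimateAneuploidyRate:
    def test_no_changes_gives_zero(self):
        pairs = [(Karyotype((2, 2)), Karyotype((2, 2)))] * 5
        est = estimate_aneuploidy_rate(pairs)
        assert est.estimate == 0.0
        assert est.ci_low == 0.0

    def test_single_change_over_diploid_human(self):
        parent = Karyotype((2,) * 23)
        child = Karyotype((3,) + (2,) * 22)
        est = estimate_aneuploidy_rate([(parent, child)])
        assert est.estimate == pytest.approx(1 / 46)
        assert est.ci_low < 1 / 46 < est.ci_high

    def test_zero_parent_copies_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_aneuploidy_rate([(Karyotype((0, 0)), Karyotype((0, 0)))])

    def test_unit_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_aneuploidy_rate([(Karyotype((2,)), Karyotype((2, 2)))])


class TestTwoSitePipeline:
    def test_discrimination_grows_with_rate_ratio(self):
        """Variance-test rejection climbs as the metastatic/primary rate
        ratio moves through 1, 2, 5 (the headline end-to-end property)."""
        rates = {1: 0.02, 2: 0.04, 5: 0.10}
        rej = {}
        for ratio, em in rates.items():
            hits = 0
            for s in range(30):
                ds = generate_two_site_dataset(
                    seed=1000 * ratio + s, E_metastatic=em, N=150, n_cells=60,
                    generations_primary=12, generations_metastatic=12,
                )
                root = np.array(ds.metadata["founder"])
                dp = distance_to_root(ds.primary, root).distances
                dm = distance_to_root(ds.metastasis, root).distances
                hits += levene_variance_test(dp, dm, method="f").p_value < 0.05
            rej[ratio] = hits / 30
        assert rej[1] < rej[5]
        assert rej[2] <= rej[5]
        assert rej[5] >= 0.8
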