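"""Group statistics: t-tests, FDR, partial correlation, contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from restgraph import inference as inf
from restgraph import make_geometry


class TestTwoSampleT:
    def test_identical_groups(self):
        r = inf.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == 0.0 and r.p == 1.0

    def test_hand_computed_example(self):
        # pooled variance 1, SE = sqrt(2/3), t = -3 / 0.8165
        r = inf.two_sample_t([1, 2, 3], [4, 5, 6])
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4
        assert r.direction == "A<B"

    def test_matches_textbook_formula(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=15) + 0.3
        r = inf.two_sample_t(x, y)
        sp2 = (11 * x.var(ddof=1) + 14 * y.var(ddof=1)) / 25
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 12 + 1 / 15))
        assert r.t == pytest.approx(t, abs=1e-12)
        assert r.p == pytest.approx(2 * stats.t.sf(abs(t), 25), abs=1e-12)

    def test_welch_matches_scipy(self, rng):
        x, y = rng.normal(size=10), rng.normal(scale=3.0, size=25)
        r = inf.two_sample_t(x, y, welch=True)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert r.t == pytest.approx(float(ref.statistic), abs=1e-12)
        assert r.p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_zero_variance_flagged_degenerate(self):
        r = inf.two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert r.degenerate and r.p == 1.0
        r = inf.two_sample_t([2.0, 2.0], [3.0, 3.0])
        assert r.degenerate and r.p == 0.0


class TestPairedT:
    def test_no_change(self):
        r = inf.paired_t([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0 and r.degenerate

    def test_hand_computed_example(self):
        # diffs [2, 0, 2]: mean 4/3, SE 2/3
        r = inf.paired_t([1, 2, 3], [3, 2, 5])
        assert r.t == pytest.approx(2.0, abs=1e-12)
        assert r.df == 2

    def test_matches_one_sample_oracle(self, rng):
        pre, post = rng.normal(size=20), rng.normal(size=20) + 0.5
        r = inf.paired_t(pre, post)
        d = post - pre
        t = d.mean() / (d.std(ddof=1) / np.sqrt(20))
        assert r.t == pytest.approx(t, abs=1e-12)


class TestFdrBH:
    def test_step_up_by_hand(self):
        # thresholds k/5 * 0.05; p(4) = 0.04 <= 0.04 is the last hit
        mask = inf.fdr_bh([0.01, 0.02, 0.03, 0.04, 0.5], q=0.05)
        assert mask.sum() == 4 and not mask[4]

    def test_all_ones_and_single(self):
        assert inf.fdr_bh([1.0, 1.0, 1.0]).sum() == 0
        assert inf.fdr_bh([0.04], q=0.05).all()   # m = 1: raw threshold
        assert inf.fdr_bh([], q=0.05).size == 0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.01, 0.2),
           st.floats(0.01, 0.2))
    def test_rejections_monotone_in_q(self, seed, q1, q2):
        p = np.random.default_rng(seed).uniform(size=40) ** 2
        lo, hi = sorted((q1, q2))
        assert np.all(inf.fdr_bh(p, lo) <= inf.fdr_bh(p, hi))


class TestPartialCorr:
    def test_perfect_dependence(self, rng):
        x = rng.normal(size=30)
        r, p = inf.partial_corr(x, x.copy(), covariates=rng.normal(size=30))
        assert r == pytest.approx(1.0)

    def test_shared_covariate_drives_association(self, rng):
        cov = rng.normal(size=500)
        x = cov + rng.normal(size=500)
        y = cov + rng.normal(size=500)
        r_plain, _ = inf.partial_corr(x, y)
        r_partial, _ = inf.partial_corr(x, y, covariates=cov)
        assert r_plain > 0.3          # confounded association
        assert abs(r_partial) < 0.1   # vanishes once the covariate is removed

    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.normal(size=25), rng.normal(size=25)
        r, p = inf.partial_corr(x, y)
        expected = stats.pearsonr(x, y)
        assert r == pytest.approx(expected.statistic, abs=1e-12)
        assert p == pytest.approx(expected.pvalue, abs=1e-12)

    def test_constant_covariate_collinear_with_intercept(self, rng):
        # a constant covariate adds nothing beyond the intercept
        x, y = rng.normal(size=25), rng.normal(size=25)
        r_c, _ = inf.partial_corr(x, y, covariates=np.full(25, 3.0))
        r_0, _ = inf.partial_corr(x, y)
        assert r_c == pytest.approx(r_0, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        x, y = rng.normal(size=40), rng.normal(size=40)
        z = rng.normal(size=40)
        r, p = inf.partial_corr(x, y, covariates=z)
        frame = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(frame, x="x", y="y", covar="z")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_zero_residual_variance_rejected(self, rng):
        cov = rng.normal(size=20)
        with pytest.raises(ValueError, match="zero residual variance"):
            inf.partial_corr(2 * cov + 1, rng.normal(size=20), covariates=cov)


@pytest.fixture(scope="module")
def geom():
    return make_geometry((5, 5, 4), 6, seed=0)


class TestNodalDegreeContrast:
    def test_identical_groups_reject_nothing(self, geom, rng):
        d = rng.integers(5, 40, size=(8, geom.n_nodes)).astype(float)
        res = inf.nodal_degree_contrast(d, d.copy(), geom)
        assert not res.rejected.any() and res.clusters == []

    def test_bonferroni_is_stricter_than_fdr(self, geom, rng):
        a = rng.normal(10, 1, size=(10, geom.n_nodes))
        b = rng.normal(10, 1, size=(10, geom.n_nodes))
        a[:, geom.node_regions == 1] += 3
        res_f = inf.nodal_degree_contrast(a, b, geom)
        res_b = inf.nodal_degree_contrast(a, b, geom,
                                          correction="bonferroni")
        assert res_b.rejected.sum() <= res_f.rejected.sum()

    def test_mismatched_node_counts_rejected(self, geom, rng):
        with pytest.raises(ValueError, match="mismatch"):
            inf.nodal_degree_contrast(np.zeros((4, 10)), np.zeros((4, 12)),
                                      geom)

    def test_isolated_pair_dropped_by_cluster_rule(self, geom, rng):
        """Two non-adjacent suprathreshold voxels both fall to min_cluster=3."""
        n = geom.n_nodes
        base = rng.normal(10, 1, size=(10, n))
        other = rng.normal(10, 1, size=(10, n))
        # drive two far-apart voxels strongly; nothing else differs
        coords = geom.node_coords_mm
        far = int(np.argmax(np.linalg.norm(coords - coords[0], axis=1)))
        other[:, 0] += 50
        other[:, far] += 50
        res = inf.nodal_degree_contrast(base, other, geom, min_cluster=3)
        assert res.rejected[0] and res.rejected[far]
        assert not res.surviving.any()
        assert res.clusters == []

    def test_block_effect_reported_as_one_cluster(self, geom, rng):
        n = geom.n_nodes
        a = rng.normal(10, 1, size=(12, n))
        b = rng.normal(10, 1, size=(12, n))
        region = geom.node_regions == 2
        a[:, region] += 30
        res = inf.nodal_degree_contrast(a, b, geom)
        assert len(res.clusters) >= 1
        top = max(res.clusters, key=lambda c: c.size)
        assert top.region == 2
        assert top.mean_degree_a > top.mean_degree_b


class TestSweepContrast:
    GRID = np.round(np.arange(0.36, 0.605, 0.01), 10)

    def test_identical_inputs_all_zero(self, rng):
        m = rng.normal(size=(8, len(self.GRID)))
        res = inf.sweep_contrast(m, m.copy(), self.GRID)
        assert np.all(res.table["t"] == 0)
        assert res.significant_range is None

    def test_injected_difference_above_threshold_star(self, rng):
        """A sigma difference injected only above T* yields a significant
        range starting near T*."""
        n_rep = 20
        starts = []
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            a = r.normal(1.5, 0.1, size=(16, len(self.GRID)))
            b = r.normal(1.5, 0.1, size=(16, len(self.GRID)))
            above = self.GRID >= 0.49
            a[:, above] += 0.4
            res = inf.sweep_contrast(a, b, self.GRID)
            assert res.significant_range is not None
            starts.append(res.significant_range[0])
        assert np.median(starts) == pytest.approx(0.49, abs=0.02)

    def test_null_usually_empty_range(self):
        empties = 0
        for rep in range(30):
            r = np.random.default_rng(1000 + rep)
            a = r.normal(1.5, 0.1, size=(16, len(self.GRID)))
            b = r.normal(1.5, 0.1, size=(16, len(self.GRID)))
            if inf.sweep_contrast(a, b, self.GRID).significant_range is None:
                empties += 1
        assert empties >= 27  # >= 90 % of null replicates

    def test_tie_breaks_toward_larger_threshold(self):
        a = np.tile([1.0, 2.0], (4, len(self.GRID) // 2 + 1))[:, :len(self.GRID)]
        res = inf.sweep_contrast(a, a.copy(), self.GRID)
        # all p equal (=1): the reported best threshold is the largest
        assert res.best_threshold == self.GRID[-1]
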