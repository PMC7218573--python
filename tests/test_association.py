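"""Spearman screening, PERMANOVA, BH FDR, and correlation networks."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from omixplain.association import (
    assess_microbiome_responsiveness,
    bh_fdr,
    build_correlation_network,
    metabotype_frame,
    permanova,
    screen_metabotypes,
    spearman,
    spearman_matrix,
)
from omixplain.similarity import DistanceMatrix, bray_curtis, gower_center
from omixplain.simulate import generate_microbiome_linked_cohort

from conftest import make_feature_table, make_phenotype


class TestSpearman:
    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            spearman([1, 2, 3], [3, 2, 1])

    def test_perfect_reversal(self):
        with pytest.warns(UserWarning, match="monotone"):
            rho, p = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == -1.0
        assert 0 < p < 1e-200

    def test_classic_d_squared_example(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/60 = 0.8
        rho, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert abs(rho - 0.8) < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_agrees_with_scipy_on_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert abs(rho - ref.statistic) < 1e-12
            if abs(rho) < 1.0:
                assert abs(p - ref.pvalue) < 1e-9

    def test_size_under_independence(self):
        rng = np.random.default_rng(1)
        rej = 0
        n_rep = 2000
        for _ in range(n_rep):
            _, p = spearman(rng.standard_normal(16), rng.standard_normal(16))
            rej += p < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_matrix_form_matches_scalar(self):
        rng = np.random.default_rng(2)
        a = pd.DataFrame(rng.standard_normal((10, 3)))
        b = pd.DataFrame(rng.standard_normal((10, 2)))
        rho, p = spearman_matrix(a, b)
        for i, j in itertools.product(range(3), range(2)):
            r_ij, p_ij = spearman(a[i], b[j])
            assert abs(rho.iloc[i, j] - r_ij) < 1e-12
            assert abs(p.iloc[i, j] - p_ij) < 1e-12


class TestScreenMetabotypes:
    def test_metabolite_equal_to_mpy_is_positive(self):
        mpy = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        t = make_feature_table(np.column_stack([mpy, [6, 5, 4, 3, 2, 1]]),
                               layer_kind="rumen_metabolome", value_kind="intensity")
        phen = make_phenotype(mpy)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen_metabotypes(t, phen)
        assert res[0].sign_class == "MPY-positive"
        assert res[1].sign_class == "MPY-negative"

    def test_constant_metabolite_excluded_with_warning(self):
        t = make_feature_table([[1.0], [1.0], [1.0], [1.0], [1.0]],
                               layer_kind="rumen_metabolome", value_kind="intensity")
        phen = make_phenotype([1, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="constant"):
            res = screen_metabotypes(t, phen)
        assert res == []

    def test_planted_metabotypes_recovered(self):
        _, met, phen, linked = generate_microbiome_linked_cohort(42, n_linked=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen_metabotypes(met, phen)
        positives = {r.metabolite_id for r in res if r.sign_class == "MPY-positive"}
        assert len(positives & set(linked)) >= 16


class TestPermanova:
    @staticmethod
    def _clustered_distance(per_cluster=5):
        rng = np.random.default_rng(99)
        pts = np.vstack([np.zeros((per_cluster, 2)), np.ones((per_cluster, 2)) * 10])
        pts = pts + 0.01 * rng.standard_normal(pts.shape)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        ids = [f"s{i}" for i in range(2 * per_cluster)]
        return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids))

    def test_pseudo_f_invariant_to_covariate_shift(self):
        d = self._clustered_distance()
        c = np.arange(10, dtype=float)
        f1, _ = permanova(d, c, n_perm=99, seed=0)
        f2, _ = permanova(d, c + 100.0, n_perm=99, seed=0)
        assert abs(f1 - f2) < 1e-10

    def test_p_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(3)
        t = make_feature_table(rng.uniform(0.1, 1, (8, 5)))
        d = bray_curtis(t)
        c = rng.standard_normal(8)
        perm = rng.permutation(8)
        ids = [d.sample_ids[i] for i in perm]
        d2 = DistanceMatrix(d.data.loc[ids, ids])
        f1, _ = permanova(d, c, n_perm=99, seed=1)
        f2, _ = permanova(d2, c[perm], n_perm=99, seed=1)
        assert abs(f1 - f2) < 1e-10

    def test_two_tight_clusters_reach_minimum_p(self):
        # 10+10 points: the chance a permutation recreates the partition is
        # 2/C(20,10) ~ 1e-5, so the add-one estimator hits its floor
        d = self._clustered_distance(per_cluster=10)
        indicator = np.repeat([0.0, 1.0], 10)
        _, p = permanova(d, indicator, n_perm=999, seed=2)
        assert p == pytest.approx(1.0 / (1.0 + 999.0))

    def test_hat_matrix_formula_equals_quadratic_form(self):
        """The centered-covariate shortcut equals the full H-matrix pseudo-F."""
        rng = np.random.default_rng(4)
        t = make_feature_table(rng.uniform(0.1, 1, (7, 6)))
        d = bray_curtis(t)
        c = rng.standard_normal(7)
        f, _ = permanova(d, c, n_perm=99, seed=0)
        g = gower_center(d.values)
        X = np.column_stack([np.ones(7), c])
        h = X @ np.linalg.solve(X.T @ X, X.T)
        i_h = np.eye(7) - h
        f_ref = (np.trace(h @ g @ h) / 1.0) / (np.trace(i_h @ g @ i_h) / (7 - 2))
        assert abs(f - f_ref) < 1e-10

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            permanova(self._clustered_distance(), np.ones(10), n_perm=99)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError, match="99"):
            permanova(self._clustered_distance(), np.arange(10.0), n_perm=10)


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_fdr([0.2]).tolist() == [0.2]
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=1, max_value=200))
    def test_matches_brute_force_tail_min(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, m)
        q = bh_fdr(p)
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        sorted_p = p[order]
        for i in range(m):
            brute[order[i]] = min(
                min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0
            )
        np.testing.assert_allclose(q, brute, atol=1e-12)

    def test_stable_under_input_permutation(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 37)
        perm = rng.permutation(37)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)


class TestResponsivenessComposition:
    def test_planted_linked_metabotypes_flagged(self):
        taxa, met, phen, linked = generate_microbiome_linked_cohort(6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen_metabotypes(met, phen)
            res = assess_microbiome_responsiveness(
                res, met, bray_curtis(taxa), n_perm=499, seed=6
            )
        flagged = {r.metabolite_id for r in res if r.microbiome_responsive}
        recall = len(flagged & set(linked)) / len(linked)
        assert recall >= 0.7
        frame = metabotype_frame(res)
        responsive = frame[frame["microbiome_responsive"]]
        assert (responsive["sign_class"] != "none").all()
        assert (responsive["q_permanova"] < 0.05).all()


class TestCorrelationNetwork:
    def test_duplicated_column_yields_unit_edge(self):
        rng = np.random.default_rng(7)
        a = make_feature_table(rng.uniform(1, 2, (8, 3)))
        b_vals = np.column_stack([a.values[:, 0], rng.uniform(1, 2, 8)])
        b = make_feature_table(b_vals, layer_kind="rumen_metabolome",
                               value_kind="intensity", feature_prefix="m")
        edges = build_correlation_network(a, b)
        hit = edges[(edges.source == "f1") & (edges.target == "m1")]
        assert len(hit) == 1 and hit.iloc[0].rho == 1.0

    def test_impossible_threshold_gives_empty_list(self):
        rng = np.random.default_rng(8)
        a = make_feature_table(rng.uniform(1, 2, (8, 3)))
        b = make_feature_table(rng.uniform(1, 2, (8, 3)), feature_prefix="m")
        edges = build_correlation_network(a, b, r_threshold=1.01)
        assert edges.empty

    def test_null_retention_within_binomial_bounds(self):
        """Retention of noise edges matches its simulated null probability."""
        rng = np.random.default_rng(9)
        kept = total = 0
        for _ in range(20):
            a = make_feature_table(rng.standard_normal((16, 10)) + 10)
            b = make_feature_table(rng.standard_normal((16, 10)) + 10,
                                   feature_prefix="m")
            edges = build_correlation_network(a, b)
            kept += len(edges)
            total += 100
        # null P(|rho|>0.5 and p<0.05) at n=16 is ~ P(|rho|>0.5) ~ 0.048
        rate = kept / total
        assert 0.02 <= rate <= 0.09

    def test_no_shared_samples_rejected(self):
        a = make_feature_table(np.ones((4, 2)) + np.eye(4)[:, :2])
        b = make_feature_table(np.ones((4, 2)) + np.eye(4)[:, :2], sample_prefix="x")
        with pytest.raises(ValueError, match="shared"):
            build_correlation_network(a, b)

    def test_edges_sorted_deterministically(self):
        rng = np.random.default_rng(10)
        a = make_feature_table(rng.standard_normal((12, 5)) + 10)
        b = make_feature_table(rng.standard_normal((12, 5)) + 10, feature_prefix="m")
        edges = build_correlation_network(a, b, r_threshold=0.0, alpha=1.0)
        assert len(edges) == 25
        assert edges[["source", "target"]].values.tolist() == sorted(
            edges[["source", "target"]].values.tolist()
        )
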