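"""Gene-embedded PCA, chi-squared probe attribution, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pcafe.expression import ExpressionMatrix, SampleGroups, normalize_samples
from pcafe.pca import (
    GeneEmbedding,
    bh_adjust,
    chi2_pvalues,
    decompose,
    identify_discriminative_pc,
    score_chi2,
    select_probes,
)
from pcafe.simulate import ExpressionSimConfig, gen_expression


def brute_force_bh(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        adj_sorted[rank - 1] = min(
            min(m * p[order[j - 1]] / j for j in range(rank, m + 1)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestDecompose:
    def test_diagonal_matrix(self):
        """X = diag(2, 1): eigenvalues (4, 1), axis-aligned score vectors."""
        m = ExpressionMatrix(
            pd.DataFrame([[2.0, 0.0], [0.0, 1.0]], index=["p1", "p2"], columns=["s1", "s2"])
        )
        e = decompose(m, n_components=2)
        np.testing.assert_allclose(e.eigenvalues, [4.0, 1.0])
        np.testing.assert_allclose(e.scores, [[1.0, 0.0], [0.0, 1.0]], atol=1e-12)
        np.testing.assert_allclose(e.loadings, [[2.0, 0.0], [0.0, 1.0]], atol=1e-12)

    def test_duality_against_dense_eigensolver(self, random_matrix):
        """v_k must be an eigenvector of X^T X with the same eigenvalue."""
        m = random_matrix(6, 4, seed=7)
        e = decompose(m)
        gram = m.values.T @ m.values
        lam_dense = np.sort(np.linalg.eigvalsh(gram))[::-1]
        np.testing.assert_allclose(e.eigenvalues, lam_dense, rtol=1e-10)
        for k in range(e.n_components):
            v = e.loadings[:, k]
            np.testing.assert_allclose(
                gram @ v, e.eigenvalues[k] * v, rtol=1e-6, atol=1e-9
            )

    def test_loading_is_xt_u(self, random_matrix):
        m = random_matrix(30, 5, seed=2)
        e = decompose(m)
        np.testing.assert_allclose(e.loadings, m.values.T @ e.scores, atol=1e-10)

    def test_rank_bound_and_surplus_warning(self, random_matrix):
        m = random_matrix(6, 4, seed=1)
        with pytest.warns(UserWarning, match="surplus"):
            e = decompose(m, n_components=6)
        assert np.count_nonzero(e.eigenvalues > 1e-12) <= 4
        np.testing.assert_array_equal(e.eigenvalues[4:], 0.0)

    def test_sign_convention(self, random_matrix):
        e = decompose(random_matrix(50, 6, seed=9))
        for k in range(e.n_components):
            u = e.scores[:, k]
            assert u[np.argmax(np.abs(u))] > 0


class TestIdentifyPC:
    def _embedding_with_separating_pc2(self, n_a=5, n_b=5, seed=0):
        rng = np.random.default_rng(seed)
        loadings = rng.standard_normal((n_a + n_b, 4))
        loadings[:, 1] = [-1.0] * n_a + [1.0] * n_b
        ids = [f"s{i}" for i in range(n_a + n_b)]
        emb = GeneEmbedding(
            np.array([4.0, 3.0, 2.0, 1.0]),
            np.zeros((8, 4)),
            loadings,
            [f"p{i}" for i in range(8)],
            ids,
        )
        g = SampleGroups({s: ("a" if i < n_a else "b") for i, s in enumerate(ids)})
        return emb, g

    def test_perfect_separation_on_pc2(self):
        emb, g = self._embedding_with_separating_pc2()
        ident = identify_discriminative_pc(emb, g)
        assert ident.pc_index == 2
        assert ident.pvalues[1] == min(ident.pvalues)

    def test_manual_override(self):
        emb, g = self._embedding_with_separating_pc2()
        ident = identify_discriminative_pc(emb, g, override=3)
        assert ident.pc_index == 3 and ident.overridden

    def test_small_group_rejected(self):
        emb, _ = self._embedding_with_separating_pc2()
        g = SampleGroups({s: ("a" if i < 1 else "b") for i, s in enumerate(emb.sample_ids)})
        with pytest.raises(ValueError, match="fewer than 2"):
            identify_discriminative_pc(emb, g)

    def test_null_rarely_flags_any_pc(self, balanced_groups):
        """Same-distribution groups: min p < 1e-3 in < 5% of replicates."""
        ids, g = balanced_groups(10, 9)
        flagged = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            m = ExpressionMatrix(
                pd.DataFrame(
                    rng.standard_normal((200, 19)),
                    index=[f"p{i}" for i in range(200)],
                    columns=ids,
                )
            )
            ident = identify_discriminative_pc(decompose(normalize_samples(m)), g)
            flagged += min(ident.pvalues) < 1e-3
        assert flagged / n_rep < 0.05


class TestChi2:
    def test_known_sigma_vector(self):
        """u = (1, 0, -1): sigma = 1, so stats (1, 0, 1), p (0.3173, 1, 0.3173)."""
        statistic, pvalues, sigma = score_chi2(np.array([1.0, 0.0, -1.0]))
        assert sigma == pytest.approx(1.0)
        np.testing.assert_allclose(statistic, [1.0, 0.0, 1.0])
        assert pvalues[1] == 1.0
        assert pvalues[0] == pytest.approx(0.31731, abs=1e-5)

    def test_sign_flip_invariance(self):
        u = np.random.default_rng(4).standard_normal(50)
        np.testing.assert_array_equal(score_chi2(u)[1], score_chi2(-u)[1])

    def test_too_few_probes(self):
        with pytest.raises(ValueError, match="at least 2"):
            score_chi2(np.array([1.0]))

    def test_on_embedding(self, random_matrix):
        m = random_matrix(40, 5, seed=5)
        e = decompose(m)
        sel = chi2_pvalues(e, 2)
        u = e.scores[:, 1]
        assert sel.sigma == pytest.approx(float(np.std(u, ddof=1)))
        assert sel.pc_index == 2
        assert ((sel.table["pvalue"] >= 0) & (sel.table["pvalue"] <= 1)).all()


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize(
        "p, expected",
        [([1.0, 1.0], [1.0, 1.0]), ([0.2], [0.2])],
    )
    def test_caps_and_singleton(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        p=st.lists(
            st.floats(0, 1, allow_nan=False, allow_infinity=False), min_size=1, max_size=8
        )
    )
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), rtol=1e-12, atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestSelectProbes:
    def test_threshold_monotonicity(self):
        """Selection at 0.005 is a subset of selection at 0.01."""
        sim = gen_expression(ExpressionSimConfig(n_probes=2000, n_signal_probes=50, seed=5))
        m = normalize_samples(sim.matrix)
        tight = set(select_probes(m, sim.groups, threshold=0.005).selected_probes)
        loose = set(select_probes(m, sim.groups, threshold=0.01).selected_probes)
        assert tight <= loose
        assert loose  # the injected signal is strong enough to select something

    def test_deterministic(self):
        sim = gen_expression(ExpressionSimConfig(n_probes=500, n_signal_probes=20, seed=3))
        m = normalize_samples(sim.matrix)
        a = select_probes(m, sim.groups)
        b = select_probes(m, sim.groups)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_selected_iff_below_threshold(self):
        sim = gen_expression(ExpressionSimConfig(n_probes=500, n_signal_probes=20, seed=3))
        sel = select_probes(normalize_samples(sim.matrix), sim.groups, threshold=0.01)
        expected = sel.table["adjusted_pvalue"] < 0.01
        assert (sel.table["selected"] == expected).all()

    def test_sign_flip_leaves_pvalues_unchanged(self, random_matrix, balanced_groups):
        """Flipping any eigenvector's sign cannot change the chi2 p-values."""
        ids, g = balanced_groups(5, 5)
        m = normalize_samples(random_matrix(100, 10, seed=6))
        m.data.columns = ids
        e = decompose(m)
        sel_a = chi2_pvalues(e, 1)
        e.scores[:, 0] *= -1
        e.loadings[:, 0] *= -1
        sel_b = chi2_pvalues(e, 1)
        np.testing.assert_array_equal(sel_a.table["pvalue"], sel_b.table["pvalue"])

    def test_orthonormal_scores(self, random_matrix):
        e = decompose(random_matrix(80, 8, seed=8))
        gram = e.scores.T @ e.scores
        np.testing.assert_allclose(gram, np.eye(e.n_components), atol=1e-8)
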