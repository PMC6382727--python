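import io

import numpy as np
import pandas as pd
import pytest

from quidsig.context import CONTEXT_CLASSES
from quidsig import simulate as sim
from quidsig.signatures import (
    BootstrapSignatureExtractor,
    SignatureNMF,
    compare_exposure,
    cosine_similarity,
    exposure_proportions,
    extract_signatures,
    linkage_to_newick,
    match_to_reference,
    nmf_decompose,
    refit_exposures,
    select_rank,
)


def disjoint_signatures():
    """Two signatures with non-overlapping support."""
    p1 = np.zeros(96)
    p1[:8] = 1 / 8
    p2 = np.zeros(96)
    p2[48:60] = 1 / 12
    return pd.DataFrame({"A": p1, "B": p2}, index=CONTEXT_CLASSES)


def make_matrix(P, E):
    """samples x 96 matrix from 96 x K signatures and K x samples exposures."""
    return pd.DataFrame((P.to_numpy() @ E).T, columns=CONTEXT_CLASSES)


class TestSignatureNMF:
    def test_exact_rank2_recovery(self):
        P = disjoint_signatures()
        E = np.array([[100.0, 40, 10, 80], [5, 70, 90, 20]])
        M = make_matrix(P, E)
        model = SignatureNMF(n_signatures=2, random_state=0).fit(M)
        sims = np.array(
            [
                [cosine_similarity(model.signatures_[c], P[g]) for g in P.columns]
                for c in model.signatures_.columns
            ]
        )
        # each generator is recovered by a distinct signature
        assert (sims.max(axis=1) > 0.99).all()
        assert set(sims.argmax(axis=1)) == {0, 1}

    def test_rank1_closed_form(self):
        """On exact rank-1 data the single signature is the normalised
        pooled profile and its exposure equals each sample's total."""
        p = np.abs(np.random.default_rng(0).normal(size=96)) + 0.1
        p /= p.sum()
        P = pd.DataFrame({"A": p}, index=CONTEXT_CLASSES)
        totals = np.array([[50.0, 200.0, 125.0]])
        M = make_matrix(P, totals)
        model = SignatureNMF(n_signatures=1, random_state=1).fit(M)
        pooled = M.sum(axis=0).to_numpy()
        assert cosine_similarity(model.signatures_["S1"], pooled) > 1 - 1e-8
        np.testing.assert_allclose(
            model.exposures_["S1"].to_numpy(), totals[0], rtol=1e-5
        )

    def test_determinism(self, small_cohort):
        from quidsig.context import build_context_matrix

        M = build_context_matrix(small_cohort.catalog, small_cohort.genome)
        m1 = SignatureNMF(n_signatures=2, n_restarts=2, random_state=9).fit(M)
        m2 = SignatureNMF(n_signatures=2, n_restarts=2, random_state=9).fit(M)
        assert m1.reconstruction_err_ == m2.reconstruction_err_
        assert np.array_equal(m1.components_, m2.components_)

    def test_objective_improves_with_iterations(self):
        P = disjoint_signatures()
        rng = np.random.default_rng(2)
        M = make_matrix(P, rng.uniform(10, 100, size=(2, 6)))
        M += rng.poisson(2.0, size=M.shape)
        errs = []
        for iters in (1, 10, 500):
            m = SignatureNMF(
                n_signatures=2, n_restarts=1, max_iter=iters, tol=0, random_state=3
            ).fit(M)
            errs.append(m.reconstruction_err_)
        assert errs[2] <= errs[1] <= errs[0]

    def test_error_nonincreasing_in_k(self, small_cohort):
        from quidsig.context import build_context_matrix

        M = build_context_matrix(small_cohort.catalog, small_cohort.genome)
        errs = [
            nmf_decompose(M, k, seed=4, n_restarts=4)[2] for k in (1, 2, 3, 4)
        ]
        for lo, hi in zip(errs[1:], errs[:-1]):
            assert lo <= hi * 1.01  # restart tolerance

    def test_columns_normalised(self, small_cohort):
        from quidsig.context import build_context_matrix

        M = build_context_matrix(small_cohort.catalog, small_cohort.genome)
        m = SignatureNMF(n_signatures=3, n_restarts=2, random_state=5).fit(M)
        np.testing.assert_allclose(
            m.signatures_.sum(axis=0).to_numpy(), 1.0, atol=1e-9
        )

    def test_matches_sklearn_objective(self):
        """Independent cross-check: our best-of-restarts Frobenius error is
        within a few percent of sklearn's MU solver on the same matrix."""
        from sklearn.decomposition import NMF as SkNMF

        rng = np.random.default_rng(6)
        P = disjoint_signatures()
        M = make_matrix(P, rng.uniform(20, 120, size=(2, 8)))
        M += rng.poisson(1.0, size=M.shape)
        ours = nmf_decompose(M, 2, seed=7, n_restarts=5)[2]
        sk = SkNMF(
            n_components=2, solver="mu", beta_loss="frobenius",
            init="random", max_iter=2000, tol=1e-9, random_state=0,
        )
        W = sk.fit_transform(M.to_numpy().T)
        theirs = np.linalg.norm(M.to_numpy().T - W @ sk.components_)
        assert ours <= theirs * 1.02

    def test_invalid_rank(self):
        M = make_matrix(disjoint_signatures(), np.ones((2, 3)))
        with pytest.raises(ValueError):
            SignatureNMF(n_signatures=5).fit(M)  # K > n_samples
        with pytest.raises(ValueError):
            SignatureNMF(n_signatures=1).fit(M * 0)


class TestRefitExposures:
    def test_noiseless_recovery(self):
        P = disjoint_signatures()
        E = np.array([[100.0, 40, 10], [5, 70, 90]])
        M = make_matrix(P, E)
        refit = refit_exposures(M, P)
        np.testing.assert_allclose(refit.to_numpy(), E.T, rtol=1e-6)

    def test_permutation_equivariance(self):
        P = disjoint_signatures()
        rng = np.random.default_rng(8)
        M = make_matrix(P, rng.uniform(5, 50, size=(2, 6)))
        perm = [3, 0, 5, 1, 4, 2]
        a = refit_exposures(M, P).to_numpy()
        b = refit_exposures(M.iloc[perm], P).to_numpy()
        np.testing.assert_allclose(a[perm], b)


class TestCosine:
    def test_identical(self):
        v = np.arange(1.0, 97.0)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint(self):
        a = np.zeros(96)
        a[0] = 3
        b = np.zeros(96)
        b[1] = 5
        assert cosine_similarity(a, b) == 0.0

    def test_hand_value(self):
        a = np.zeros(4)
        a[:2] = 1
        b = np.zeros(4)
        b[0] = 1
        assert cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


def naive_complete_linkage(D):
    """Brute-force agglomerative complete linkage: returns sorted merge
    heights.  Independent oracle for the scipy-based implementation."""
    clusters = [frozenset([i]) for i in range(len(D))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(D[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


class TestMatchToReference:
    def test_exact_copy_matches_at_one(self):
        ref = sim.synthetic_reference_panel(n=8, seed=1)
        query = ref[["REF03"]].rename(columns={"REF03": "Q1"})
        simm, best, _ = match_to_reference(query, ref)
        assert best.loc["Q1", "best_match"] == "REF03"
        assert best.loc["Q1", "cosine"] == pytest.approx(1.0)

    def test_reference_column_order_invariance(self):
        ref = sim.synthetic_reference_panel(n=8, seed=1)
        query = sim.generating_signatures()
        _, best1, _ = match_to_reference(query, ref)
        shuffled = ref[list(ref.columns[::-1])]
        _, best2, _ = match_to_reference(query, shuffled)
        for q in best1.index:
            if not best1.loc[q, "tie"]:
                assert best1.loc[q, "best_match"] == best2.loc[q, "best_match"]

    def test_complete_linkage_heights_match_bruteforce(self):
        rng = np.random.default_rng(10)
        sigs = pd.DataFrame(
            rng.dirichlet(np.full(96, 0.3), size=2).T,
            index=CONTEXT_CLASSES, columns=["Q1", "Q2"],
        )
        ref = pd.DataFrame(
            rng.dirichlet(np.full(96, 0.3), size=2).T,
            index=CONTEXT_CLASSES, columns=["R1", "R2"],
        )
        _, _, Z = match_to_reference(sigs, ref)
        all_vecs = np.hstack([sigs.to_numpy(), ref.to_numpy()]).T
        n = len(all_vecs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    D[i, j] = 1 - cosine_similarity(all_vecs[i], all_vecs[j])
        np.testing.assert_allclose(
            sorted(Z[:, 2]), naive_complete_linkage(D), atol=1e-12
        )

    def test_newick_roundtrip(self):
        from Bio import Phylo

        ref = sim.synthetic_reference_panel(n=5, seed=2)
        query = sim.generating_signatures()
        _, _, Z = match_to_reference(query, ref)
        labels = list(query.columns) + list(ref.columns)
        nwk = linkage_to_newick(Z, labels)
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)


class TestBootstrapExtraction:
    def test_three_signature_recovery(self):
        """Consensus signatures recover the generating processes on a
        balanced, well-powered mixture."""
        rng = np.random.default_rng(12)
        S = sim.generating_signatures()
        rows = [
            rng.multinomial(5000, S.to_numpy() @ rng.dirichlet([1.5, 1.5, 1.5]))
            for _ in range(12)
        ]
        M = pd.DataFrame(rows, columns=CONTEXT_CLASSES)
        sigs, expo, info = extract_signatures(M, 3, n_bootstrap=12, seed=3)
        _, best, _ = match_to_reference(sigs, S)
        assert set(best["best_match"]) == set(S.columns)
        assert (best["cosine"] > 0.90).all()
        assert info["stability"] > 0.5
        assert expo.shape == (12, 3)

    def test_stability_bounds(self, small_cohort):
        from quidsig.context import build_context_matrix

        M = build_context_matrix(small_cohort.catalog, small_cohort.genome)
        model = BootstrapSignatureExtractor(
            n_signatures=2, n_bootstrap=6, random_state=1
        ).fit(M)
        assert np.all(model.stability_ >= -1) and np.all(model.stability_ <= 1)
        np.testing.assert_allclose(
            model.signatures_.sum(axis=0).to_numpy(), 1.0, atol=1e-9
        )


class TestSelectRank:
    def test_three_process_simulation(self):
        rng = np.random.default_rng(5)
        S = sim.generating_signatures()
        rows = [
            rng.multinomial(5000, S.to_numpy() @ rng.dirichlet([1.5, 1.5, 1.5]))
            for _ in range(12)
        ]
        M = pd.DataFrame(rows, columns=CONTEXT_CLASSES)
        profile, k = select_rank(M, k_min=1, k_max=4, n_bootstrap=8, seed=2, n_restarts=3)
        assert k == 3
        assert profile["stability"].between(-1, 1).all()
        # reconstruction error shrinks with rank (restart tolerance)
        e = profile["reconstruction_error"]
        assert (e.diff().dropna() <= e[1] * 0.02).all()

    def test_single_process_simulation(self):
        rng = np.random.default_rng(6)
        p = sim.sig1_like().to_numpy()
        M = pd.DataFrame(
            [rng.multinomial(2000, p) for _ in range(10)], columns=CONTEXT_CLASSES
        )
        _, k = select_rank(M, k_min=1, k_max=3, n_bootstrap=8, seed=2, n_restarts=3)
        assert k == 1


class TestCompareExposure:
    @staticmethod
    def frame(vals_a, vals_b):
        n = len(vals_a) + len(vals_b)
        idx = [f"s{i}" for i in range(n)]
        cohorts = pd.DataFrame(
            {"cohort": ["A"] * len(vals_a) + ["B"] * len(vals_b)}, index=idx
        )
        props = pd.DataFrame({"sig": list(vals_a) + list(vals_b)}, index=idx)
        return cohorts, props

    def test_identical_cohorts(self):
        cohorts, props = self.frame([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        res = compare_exposure(cohorts, props, "sig", "A", "B")
        assert res["t"] == pytest.approx(0.0)
        assert res["p_value"] == pytest.approx(1.0)

    def test_pooled_t_hand_computed(self):
        # groups {0.1, 0.2} and {0.6, 0.7}: pooled var = 0.005, se = 0.0707,
        # t = -0.5/0.0707 = -7.0711
        cohorts, props = self.frame([0.1, 0.2], [0.6, 0.7])
        res = compare_exposure(cohorts, props, "sig", "A", "B")
        assert res["t"] == pytest.approx(-7.0711, abs=1e-4)

    def test_single_sample_cohort_errors(self):
        cohorts, props = self.frame([0.1], [0.2, 0.3])
        with pytest.raises(ValueError, match="A"):
            compare_exposure(cohorts, props, "sig", "A", "B")

    def test_power_at_configured_effect(self):
        """Cohort difference of the emulated size (0.09 vs 0.22, sd~0.09,
        n=15 vs 82) is detected >80% of the time at alpha=0.05."""
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(500):
            a = np.clip(rng.normal(0.09, 0.09, 15), 0, 1)
            b = np.clip(rng.normal(0.22, 0.09, 82), 0, 1)
            cohorts, props = self.frame(a, b)
            res = compare_exposure(cohorts, props, "sig", "A", "B")
            hits += res["p_value"] < 0.05
        assert hits / 500 > 0.8

    def test_proportions_normalise(self):
        E = pd.DataFrame({"a": [2.0, 1.0], "b": [2.0, 3.0]}, index=["s1", "s2"])
        P = exposure_proportions(E)
        np.testing.assert_allclose(P.sum(axis=1), 1.0)
        assert P.loc["s1", "a"] == 0.5
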