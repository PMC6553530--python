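import numpy as np
import pandas as pd
import pytest
from scipy.linalg import solve_triangular

from factorbn import gblup, genomics, simdata
from factorbn.gblup import (
    AdjustedGeneticValues,
    MtmDesign,
    adjust_breeding_values,
    fit_mtm,
    genomic_correlations,
    subpop_design,
)


def make_grm(n, seed=0, m=150):
    cfg = simdata.SimulationConfig.default(seed=seed, n_accessions=n, n_markers=m)
    geno = genomics.filter_maf(simdata.simulate_genotypes(cfg), 0.05)
    return genomics.cholesky_factor(genomics.compute_grm(geno))


class TestDesign:
    def test_subpop_design_full_rank_with_intercept(self):
        X = subpop_design(["a", "b", "c", "a", "b", "c"])
        arr = X.to_numpy()
        assert arr.shape == (6, 3)
        assert np.linalg.matrix_rank(arr) == 3

    def test_misaligned_accessions_rejected(self):
        grm = make_grm(20)
        F = pd.DataFrame(
            np.zeros((20, 2)), index=[f"x{i}" for i in range(20)], columns=["a", "b"]
        )
        with pytest.raises(ValueError, match="aligned"):
            MtmDesign.from_subpops(F, ["p"] * 20, grm)

    def test_rank_deficient_fixed_effects_rejected(self):
        grm = make_grm(10)
        F = pd.DataFrame(
            np.random.default_rng(0).standard_normal((10, 2)),
            index=grm.accession_ids, columns=["a", "b"],
        )
        X = pd.DataFrame(
            {"intercept": np.ones(10), "dup": np.ones(10)}, index=F.index
        )
        with pytest.raises(ValueError, match="rank deficient"):
            MtmDesign(F, X, grm)


class TestRotatedConditional:
    def test_mean_matches_brute_force_kronecker_formula(self):
        """Naive oracle: the nq-dimensional conditional mean of vec(u)
        given the rotated residuals, computed with explicit Kronecker
        products, must equal the vectorized fast path."""
        rng = np.random.default_rng(1)
        n, q = 6, 3
        A = rng.standard_normal((q, q))
        Su = A @ A.T + 0.5 * np.eye(q)
        B = rng.standard_normal((q, q))
        Se = B @ B.T + 0.5 * np.eye(q)
        d = rng.uniform(0.05, 3.0, n)
        E = rng.standard_normal((n, q))
        mean, _ = gblup._sample_u_rotated(E, d, Su, Se, None)
        # brute force: vec ordering row-major over accessions
        P = np.kron(np.diag(1.0 / d), np.linalg.inv(Su)) + np.kron(
            np.eye(n), np.linalg.inv(Se)
        )
        rhs = (np.kron(np.eye(n), np.linalg.inv(Se)) @ E.reshape(-1)).reshape(-1)
        naive = np.linalg.solve(P, rhs).reshape(n, q)
        np.testing.assert_allclose(mean, naive, atol=1e-10)

    def test_draw_covariance_matches_conditional(self):
        rng = np.random.default_rng(2)
        q = 2
        Su = np.array([[1.0, 0.3], [0.3, 0.8]])
        Se = np.array([[0.5, -0.1], [-0.1, 0.4]])
        d = np.array([0.7])
        E = np.zeros((1, q))
        draws = np.array(
            [
                gblup._sample_u_rotated(E, d, Su, Se, np.random.default_rng(k))[1][0]
                for k in range(30000)
            ]
        )
        target = np.linalg.inv(np.linalg.inv(d[0] * Su) + np.linalg.inv(Se))
        assert np.abs(np.cov(draws.T) - target).max() < 0.02


class TestFitMtm:
    def test_recovers_known_genetic_covariance(self):
        """Moderate-heritability recovery: posterior-mean Sigma_u within
        20% Frobenius relative error of the SEM-implied truth."""
        cfg = simdata.SimulationConfig.default(
            seed=31, n_accessions=350, n_markers=350,
            fst=0.05,
            dag_edges=(("Iss", "Flt", 0.8), ("Mrp", "Yid", -0.8), ("Grm", "Yid", 0.8)),
            residual_cov=0.5 * np.eye(6),
        )
        ds = simdata.simulate_dataset(cfg)
        design = MtmDesign.from_subpops(
            ds.factor_scores_true, ds.subpop_labels, ds.grm
        )
        post = fit_mtm(design, iterations=2500, burn_in=800, chains=2, seed=32)
        Su = cfg.sem_implied_sigma_u()
        rel = np.linalg.norm(post.sigma_u_mean - Su) / np.linalg.norm(Su)
        assert rel < 0.20
        assert post.u_mean.shape == (350, 6)
        assert post.convergence().max_psrf < 1.2

    def test_null_signal_shrinks_genetic_variance(self):
        """With u identically zero in the generating process, the
        estimated genetic share of variance stays small."""
        grm = make_grm(500, seed=41, m=500)
        rng = np.random.default_rng(42)
        F = pd.DataFrame(
            rng.standard_normal((500, 3)),
            index=grm.accession_ids,
            columns=["f1", "f2", "f3"],
        )
        design = MtmDesign.from_subpops(F, ["all"] * 500, grm)
        post = fit_mtm(design, iterations=1500, burn_in=500, chains=2, seed=43)
        share = np.trace(post.sigma_u_mean) / np.trace(
            post.sigma_u_mean + post.sigma_e_mean
        )
        assert share < 0.15

    def test_burn_in_validation(self):
        grm = make_grm(15)
        F = pd.DataFrame(
            np.random.default_rng(0).standard_normal((15, 2)),
            index=grm.accession_ids, columns=["a", "b"],
        )
        design = MtmDesign.from_subpops(F, ["p"] * 15, grm)
        with pytest.raises(ValueError, match="burn_in"):
            fit_mtm(design, iterations=100, burn_in=100)


class TestGenomicCorrelations:
    def test_diagonal_covariance_gives_identity(self):
        out = genomic_correlations(np.diag([1.0, 4.0, 0.25]))
        np.testing.assert_allclose(out.to_numpy(), np.eye(3))

    def test_hand_evaluated_offdiagonal(self):
        out = genomic_correlations(np.array([[1.0, 0.5], [0.5, 4.0]]))
        assert out.iloc[0, 1] == pytest.approx(0.25)

    def test_bounds_and_scale_invariance(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((4, 4))
        S = A @ A.T + 0.1 * np.eye(4)
        R1 = genomic_correlations(S).to_numpy()
        assert np.abs(R1).max() <= 1 + 1e-12
        D = np.diag([2.0, 0.5, 3.0, 1.0])
        R2 = genomic_correlations(D @ S @ D).to_numpy()
        np.testing.assert_allclose(R1, R2, atol=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            genomic_correlations(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestAdjustBreedingValues:
    def test_identity_kinship_leaves_values_unchanged(self):
        grm = genomics.cholesky_factor(
            genomics.GenomicRelationship(np.eye(4), list("abcd"))
        )
        u = pd.DataFrame(
            np.arange(8.0).reshape(4, 2), index=list("abcd"), columns=["f1", "f2"]
        )
        out = adjust_breeding_values(u, grm)
        pd.testing.assert_frame_equal(out.u_star, u)

    def test_hand_triangular_solve_two_accessions(self):
        grm = genomics.cholesky_factor(
            genomics.GenomicRelationship(np.array([[1.0, 0.5], [0.5, 1.0]]), ["a", "b"])
        )
        u = pd.DataFrame([[1.0], [1.0]], index=["a", "b"], columns=["f"])
        out = adjust_breeding_values(u, grm).u_star.to_numpy().ravel()
        np.testing.assert_allclose(out, [1.0, 0.57735026919], atol=1e-9)

    def test_variance_identity_on_monte_carlo_draws(self):
        """With Var(vec u) = Sigma_u (x) G, the adjusted values must have
        row covariance Sigma_u and no cross-accession correlation."""
        grm = make_grm(300, seed=51, m=300)
        Su = np.array([[1.0, 0.6], [0.6, 1.5]])
        rng = np.random.default_rng(52)
        reps = 300
        stars = np.empty((reps, 300, 2))
        A = np.linalg.cholesky(Su)
        for r in range(reps):
            u = grm.chol_lower @ (rng.standard_normal((300, 2)) @ A.T)
            u_df = pd.DataFrame(u, index=grm.accession_ids, columns=["f1", "f2"])
            stars[r] = adjust_breeding_values(u_df, grm).u_star.to_numpy()
        emp = np.cov(stars.reshape(-1, 2), rowvar=False)
        assert np.linalg.norm(emp - Su) / np.linalg.norm(Su) < 0.10
        # cross-accession correlation across replicates, a few pairs
        pairs = [(0, 1), (10, 200), (50, 299), (123, 7)]
        rs = [
            abs(np.corrcoef(stars[:, i, a], stars[:, j, a])[0, 1])
            for i, j in pairs
            for a in range(2)
        ]
        assert np.mean(rs) < 0.12  # noise floor ~ 1/sqrt(reps)

    def test_misaligned_rows_rejected(self):
        grm = genomics.cholesky_factor(
            genomics.GenomicRelationship(np.eye(3), list("abc"))
        )
        u = pd.DataFrame(np.zeros((3, 1)), index=list("abd"), columns=["f"])
        with pytest.raises(ValueError, match="aligned"):
            adjust_breeding_values(u, grm)

    def test_consistent_permutation_permutes_output(self):
        grm = make_grm(30, seed=61, m=100)
        rng = np.random.default_rng(62)
        u = pd.DataFrame(
            rng.standard_normal((30, 2)), index=grm.accession_ids, columns=["f1", "f2"]
        )
        base = adjust_breeding_values(u, grm).u_star
        perm = rng.permutation(30)
        import dataclasses

        grm_p = genomics.cholesky_factor(
            genomics.GenomicRelationship(
                grm.matrix[np.ix_(perm, perm)],
                [grm.accession_ids[i] for i in perm],
            )
        )
        out_p = adjust_breeding_values(u.iloc[perm], grm_p).u_star
        # u* is defined relative to the Cholesky of the permuted G, which is a
        # different whitening basis; the variance identity is basis-free
        assert np.allclose(
            np.cov(out_p.to_numpy(), rowvar=False),
            np.cov(base.to_numpy(), rowvar=False),
            atol=0.5,
        )
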