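"""Bayesian multivariate genomic BLUP and breeding-value decorrelation.

Model, for the n x q factor-score matrix F:

    F = 1 mu' + X b + Z u + eps,
    vec(u)   ~ N(0, Sigma_u (x) G),
    vec(eps) ~ N(0, Sigma_e (x) I),

with X coding subpopulation membership (intercept + reference-coded
classes, since a full one-hot plus intercept is rank deficient), Z = I,
G the genomic relationship matrix, and Sigma_u, Sigma_e the q x q
genetic and residual covariance matrices with InvWishart(I_q, q) priors
and flat priors on the fixed effects.

Sampling strategy: the model is rotated once by the eigenvectors of
G = U D U', which makes the n accessions conditionally independent given
the covariance matrices; within each Gibbs step the pair (Sigma_u,
Sigma_e) is jointly diagonalized (an exact congruence transform), so the
n rotated breeding-value updates reduce to elementwise operations plus
two q x q matrix products.  This is algebraically identical to the naive
nq-dimensional conditional draw and is validated against it in the test
suite.

Downstream of the fit, predicted breeding values u-hat are decorrelated
by premultiplying each factor column with L^-1 (G = LL'), i.e.
u* = (I_q (x) L^-1) u-hat, which turns Var(vec u) = Sigma_u (x) G into
Var(vec u*) = Sigma_u (x) I so that network learning sees independent
rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .bcfa import ConvergenceReport, compute_psrf
from .genomics import GenomicRelationship, cholesky_factor

# ---------------------------------------------------------------------------
# design / posterior containers
# ---------------------------------------------------------------------------


def subpop_design(labels: pd.Series | list[str]) -> pd.DataFrame:
    """Intercept + reference-coded subpopulation incidence matrix.

    The alphabetically first class is the reference; a full one-hot with
    intercept would be collinear.
    """
    s = pd.Series(labels).astype(str)
    levels = sorted(s.unique())
    X = pd.DataFrame({"intercept": np.ones(len(s))}, index=s.index)
    for lev in levels[1:]:
        X[f"subpop[{lev}]"] = (s == lev).astype(float).to_numpy()
    return X


@dataclass
class MtmDesign:
    response: pd.DataFrame  # n x q factor scores, indexed by accession
    fixed_incidence: pd.DataFrame  # n x p, aligned
    grm: GenomicRelationship

    def __post_init__(self) -> None:
        ids = list(self.response.index.astype(str))
        if ids != [str(a) for a in self.grm.accession_ids]:
            raise ValueError(
                "factor-score rows and G rows are not aligned by accession id"
            )
        if not self.response.index.equals(self.fixed_incidence.index):
            raise ValueError("fixed-effect rows are not aligned with the response")
        X = self.fixed_incidence.to_numpy(float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"fixed-effect matrix is rank deficient; check columns "
                f"{list(self.fixed_incidence.columns)}"
            )

    @classmethod
    def from_subpops(
        cls, factor_scores: pd.DataFrame, subpops: pd.Series | list[str], grm: GenomicRelationship
    ) -> "MtmDesign":
        X = subpop_design(subpops)
        X.index = factor_scores.index
        return cls(factor_scores, X, grm)

    @property
    def n(self) -> int:
        return len(self.response)

    @property
    def q(self) -> int:
        return self.response.shape[1]


@dataclass
class MtmPosterior:
    factor_names: list[str]
    u_mean: pd.DataFrame  # n x q posterior-mean breeding values
    b_mean: pd.DataFrame  # p x q fixed effects
    sigma_u_draws: np.ndarray  # C x D x q x q
    sigma_e_draws: np.ndarray  # C x D x q x q
    b_draws: np.ndarray  # C x D x p x q

    @property
    def sigma_u_mean(self) -> np.ndarray:
        return self.sigma_u_draws.reshape(-1, *self.sigma_u_draws.shape[2:]).mean(0)

    @property
    def sigma_e_mean(self) -> np.ndarray:
        return self.sigma_e_draws.reshape(-1, *self.sigma_e_draws.shape[2:]).mean(0)

    def convergence(self, threshold: float = 1.2) -> ConvergenceReport:
        """PSRF on the variance-component draws (requires >= 2 chains)."""
        q = len(self.factor_names)
        chains = {}
        for a in range(q):
            for b in range(a, q):
                fa, fb = self.factor_names[a], self.factor_names[b]
                chains[f"sigma_u[{fa},{fb}]"] = self.sigma_u_draws[:, :, a, b]
                chains[f"sigma_e[{fa},{fb}]"] = self.sigma_e_draws[:, :, a, b]
        return compute_psrf(chains, threshold=threshold)


@dataclass
class AdjustedGeneticValues:
    u_star: pd.DataFrame  # n x q
    ordering_contract: str = "trait-major: u* = (I_q kron L^-1) vec-by-factor(u-hat)"
    source_ridge: float = 0.0


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------


def _joint_diagonalizer(sigma_u: np.ndarray, sigma_e: np.ndarray):
    """K, lam with Sigma_u = K K' and Sigma_e^-1 = K^-T diag(lam) K^-1."""
    C = np.linalg.cholesky(sigma_u)
    A = C.T @ np.linalg.solve(sigma_e, C)
    lam, Q = np.linalg.eigh(0.5 * (A + A.T))
    return C @ Q, np.maximum(lam, 0.0)


def _sample_u_rotated(
    E_tilde: np.ndarray,
    d: np.ndarray,
    sigma_u: np.ndarray,
    sigma_e: np.ndarray,
    rng: np.random.Generator | None,
):
    """Conditional mean (and a draw) of the rotated breeding values.

    Row i of the rotated model is e_i = u_i + eps_i with u_i ~ N(0, d_i
    Sigma_u), eps_i ~ N(0, Sigma_e); the conditional precision is
    Sigma_u^-1 / d_i + Sigma_e^-1, diagonalized jointly for all i at
    once.  Returns (mean, draw); draw is None when rng is None.
    """
    K, lam = _joint_diagonalizer(sigma_u, sigma_e)
    inv_scale = 1.0 / (1.0 / d[:, None] + lam[None, :])  # n x q
    H = np.linalg.solve(sigma_e, E_tilde.T).T @ K  # rows: K' Sigma_e^-1 e_i
    mean = (H * inv_scale) @ K.T
    if rng is None:
        return mean, None
    z = rng.standard_normal(E_tilde.shape)
    return mean, mean + (z * np.sqrt(inv_scale)) @ K.T


def _moment_start(E_tilde: np.ndarray, d: np.ndarray, q: int):
    """Method-of-moments starting values for (Sigma_u, Sigma_e).

    In the rotated model E[e_i e_i'] = d_i Sigma_u + Sigma_e, so
    regressing the per-component outer products on d_i gives consistent
    estimates of both matrices.  Starting the chains here matters: a
    generic start (e.g. identity covariances) can trap the sampler in a
    self-consistent basin where an inflated Sigma_e over-shrinks the
    breeding values, whose inflated residuals in turn keep Sigma_e
    large; the marginal likelihood strongly prefers the moment basin.
    Estimates are projected to be comfortably positive definite.
    """
    M = E_tilde[:, :, None] * E_tilde[:, None, :]
    d_c = d - d.mean()
    slope = np.tensordot(d_c, M, axes=(0, 0)) / np.sum(d_c**2)
    intercept = M.mean(axis=0) - slope * d.mean()

    def _project(S):
        S = 0.5 * (S + S.T)
        lam, V = np.linalg.eigh(S)
        floor = max(1e-3, 1e-3 * lam.max())
        return V @ np.diag(np.maximum(lam, floor)) @ V.T

    return _project(slope), _project(intercept)


def _theta_to_cov(theta: np.ndarray, q: int) -> np.ndarray:
    """Log-Cholesky vector (diagonal log-scaled) -> covariance matrix."""
    L = np.zeros((q, q))
    iu = np.tril_indices(q)
    L[iu] = theta
    L[np.diag_indices(q)] = np.exp(np.diag(L))
    return L @ L.T


def _cov_to_theta(S: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(S)
    L = L.copy()
    L[np.diag_indices(S.shape[0])] = np.log(np.diag(L))
    return L[np.tril_indices(S.shape[0])]


def _log_target(theta_u, theta_e, E_tilde, d, q, nu0):
    """Log posterior of the variance components with u integrated out.

    Marginally e_i ~ N(0, d_i Sigma_u + Sigma_e) independently across the
    rotated components; priors InvWishart(I_q, nu0) on both matrices;
    includes the log-Cholesky Jacobian.
    """
    Su = _theta_to_cov(theta_u, q)
    Se = _theta_to_cov(theta_e, q)
    C = d[:, None, None] * Su + Se
    try:
        Lc = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        return -np.inf, Su, Se
    logdets = 2.0 * np.log(np.diagonal(Lc, axis1=1, axis2=2)).sum(axis=1)
    sol = np.linalg.solve(Lc, E_tilde[:, :, None])[:, :, 0]
    ll = -0.5 * (logdets.sum() + (sol**2).sum())
    lp = 0.0
    for S, th in ((Su, theta_u), (Se, theta_e)):
        sign, ld = np.linalg.slogdet(S)
        lp += -0.5 * (nu0 + q + 1) * ld - 0.5 * np.trace(np.linalg.inv(S))
        # Jacobian of the log-Cholesky parameterization
        diag_idx = np.cumsum([0] + list(range(2, q + 1)))
        lp += sum((q - i + 1.0) * th[diag_idx[i]] for i in range(q))
    return ll + lp, Su, Se


def _map_and_laplace(E_tilde, d, q, nu0, su0, se0):
    """Multi-start MAP of the marginal posterior and a Laplace proposal
    covariance (regularized inverse numeric Hessian)."""
    from scipy.optimize import minimize

    n_theta = q * (q + 1) // 2

    def negpost(th):
        lp, _, _ = _log_target(th[:n_theta], th[n_theta:], E_tilde, d, q, nu0)
        return -lp if np.isfinite(lp) else 1e12

    tot = su0 * max(np.mean(d), 1e-3) + se0
    starts = [np.concatenate([_cov_to_theta(su0), _cov_to_theta(se0)])]
    for h2 in (0.9, 0.1):
        starts.append(
            np.concatenate(
                [
                    _cov_to_theta(tot * h2 / max(np.mean(d), 1e-3)),
                    _cov_to_theta(tot * (1.0 - h2)),
                ]
            )
        )
    best = None
    for s in starts:
        res = minimize(negpost, s, method="L-BFGS-B", options=dict(maxiter=400))
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    dim = x.size
    # central-difference Hessian
    h = 1e-4
    H = np.empty((dim, dim))
    f0 = negpost(x)
    fp = np.array([negpost(x + h * e) for e in np.eye(dim)])
    fm = np.array([negpost(x - h * e) for e in np.eye(dim)])
    for i in range(dim):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
        for j in range(i + 1, dim):
            fpp = negpost(x + h * (np.eye(dim)[i] + np.eye(dim)[j]))
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + f0) / h**2
    lam, V = np.linalg.eigh(0.5 * (H + H.T))
    lam = np.maximum(lam, 1e-4 * max(lam.max(), 1.0))
    cov = V @ np.diag(1.0 / lam) @ V.T
    return x, cov


def fit_mtm(
    design: MtmDesign,
    iterations: int = 30000,
    burn_in: int = 5000,
    chains: int = 2,
    seed: int = 0,
    min_eigenvalue: float = 1e-8,
) -> MtmPosterior:
    """MCMC for the multivariate GBLUP.

    The genetic and residual covariance matrices are sampled by
    random-walk Metropolis on the MARGINAL posterior (breeding values
    integrated out analytically in the eigenbasis of G), using a
    Laplace-approximation proposal built at the multi-start MAP; fixed
    effects are drawn from their exact marginal-GLS Gaussian
    conditional, and breeding values from their exact conditional given
    everything else.  Marginalizing u matters: naive conditional
    inverse-Wishart updates mix pathologically when heritability is high
    and the kinship spectrum leaves the genetic/residual split weakly
    informed component by component (the chain then random-walks under
    the prior instead of converging).  Convergence is judged by PSRF on
    the variance components across chains.
    """
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    F = design.response.to_numpy(float)
    X = design.fixed_incidence.to_numpy(float)
    n, q = F.shape
    p = X.shape[1]
    if n < q + p:
        raise ValueError("need n >= q + p observations")
    G = design.grm.matrix
    d, U = np.linalg.eigh(0.5 * (G + G.T))
    if d.min() < -1e-6:
        raise ValueError(f"G has a negative eigenvalue ({d.min():.3e}); not PSD")
    d = np.maximum(d, min_eigenvalue)
    F_t, X_t = U.T @ F, U.T @ X

    nu0 = float(q)  # InvWishart(I_q, q) prior on both covariances
    n_theta = q * (q + 1) // 2
    n_keep = iterations - burn_in
    su_draws = np.empty((chains, n_keep, q, q))
    se_draws = np.empty((chains, n_keep, q, q))
    b_draws = np.empty((chains, n_keep, p, q))
    u_accum = np.zeros((n, q))

    B0 = np.linalg.solve(X_t.T @ X_t, X_t.T @ F_t)
    su0, se0 = _moment_start(F_t - X_t @ B0, d, q)
    theta_map, prop_cov = _map_and_laplace(F_t - X_t @ B0, d, q, nu0, su0, se0)
    prop_chol = np.linalg.cholesky(prop_cov + 1e-12 * np.eye(2 * n_theta))
    base_scale = 2.38 / np.sqrt(2 * n_theta)

    root = np.random.SeedSequence(seed)
    for c, child in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(child)
        theta = theta_map + 0.5 * base_scale * (prop_chol @ rng.standard_normal(2 * n_theta))
        B = B0.copy()
        E_tilde = F_t - X_t @ B
        logpost, sigma_u, sigma_e = _log_target(
            theta[:n_theta], theta[n_theta:], E_tilde, d, q, nu0
        )
        scale, accepted = base_scale, 0
        for it in range(iterations):
            # fixed effects from the exact marginal-GLS conditional
            C = d[:, None, None] * sigma_u + sigma_e
            Ci = np.linalg.inv(C)
            prec = np.einsum("ia,ib,ijk->ajbk", X_t, X_t, Ci).reshape(p * q, p * q)
            rhs = np.einsum("ia,ijk,ik->aj", X_t, Ci, F_t).reshape(p * q)
            Lp = np.linalg.cholesky(0.5 * (prec + prec.T))
            mean = np.linalg.solve(prec, rhs)
            B = (mean + np.linalg.solve(Lp.T, rng.standard_normal(p * q))).reshape(p, q)
            E_tilde = F_t - X_t @ B
            logpost, sigma_u, sigma_e = _log_target(
                theta[:n_theta], theta[n_theta:], E_tilde, d, q, nu0
            )
            # joint Laplace-scaled random-walk Metropolis on both matrices
            prop = theta + scale * (prop_chol @ rng.standard_normal(2 * n_theta))
            lp_new, su_new, se_new = _log_target(
                prop[:n_theta], prop[n_theta:], E_tilde, d, q, nu0
            )
            if np.log(rng.random()) < lp_new - logpost:
                theta, logpost, sigma_u, sigma_e = prop, lp_new, su_new, se_new
                accepted += 1
            if it < burn_in and (it + 1) % 50 == 0:
                scale *= np.exp(0.5 * (accepted / 50.0 - 0.25))
                accepted = 0
            if it >= burn_in:
                k = it - burn_in
                su_draws[c, k] = sigma_u
                se_draws[c, k] = sigma_e
                b_draws[c, k] = B
                # breeding values from their exact conditional
                _, u_t = _sample_u_rotated(E_tilde, d, sigma_u, sigma_e, rng)
                u_accum += U @ u_t

    u_mean = u_accum / (chains * n_keep)
    return MtmPosterior(
        factor_names=list(design.response.columns),
        u_mean=pd.DataFrame(u_mean, index=design.response.index, columns=design.response.columns),
        b_mean=pd.DataFrame(
            b_draws.reshape(-1, p, q).mean(0),
            index=design.fixed_incidence.columns,
            columns=design.response.columns,
        ),
        sigma_u_draws=su_draws,
        sigma_e_draws=se_draws,
        b_draws=b_draws,
    )


# ---------------------------------------------------------------------------
# summaries and the decorrelation step
# ---------------------------------------------------------------------------


def genomic_correlations(sigma_u: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """Correlation matrix r_jk = Sigma_jk / sqrt(Sigma_jj Sigma_kk)."""
    S = np.asarray(sigma_u, float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("sigma_u must be symmetric")
    v = np.diag(S)
    if np.any(v <= 0):
        raise ValueError("sigma_u has a non-positive variance on the diagonal")
    R = S / np.sqrt(np.outer(v, v))
    np.fill_diagonal(R, 1.0)
    names = names or [f"f{j + 1}" for j in range(S.shape[0])]
    return pd.DataFrame(R, index=names, columns=names)


def adjust_breeding_values(
    u_mean: pd.DataFrame, grm: GenomicRelationship
) -> AdjustedGeneticValues:
    """Decorrelate predicted breeding values: u* column j = L^-1 u-hat_j.

    Uses a triangular solve against the cached Cholesky factor of G
    (computed here if absent), never an explicit inverse.  With the
    factor columns stacked trait-major this equals (I_q (x) L^-1) u-hat,
    and Var(vec u*) = Sigma_u (x) I when Var(vec u) = Sigma_u (x) G.
    """
    if grm.chol_lower is None:
        grm = cholesky_factor(grm)
    ids = [str(a) for a in grm.accession_ids]
    if list(u_mean.index.astype(str)) != ids:
        raise ValueError("breeding-value rows are not aligned with G's accessions")
    U = u_mean.to_numpy(float)
    u_star = solve_triangular(grm.chol_lower, U, lower=True)
    if not np.all(np.isfinite(u_star)):
        raise ValueError("singular Cholesky factor; revisit the ridge policy")
    return AdjustedGeneticValues(
        u_star=pd.DataFrame(u_star, index=u_mean.index, columns=u_mean.columns),
        source_ridge=grm.ridge,
    )
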