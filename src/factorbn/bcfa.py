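"""Bayesian confirmatory factor analysis by Gibbs sampling.

Measurement model: T = Lambda F + s, with T the trait-by-accession
phenotype matrix, Lambda a loading matrix whose sparsity pattern is fixed
in advance (each trait loads on exactly one factor), F the latent factor
scores and s trait-specific effects, so that var(T) = Lambda Phi Lambda'
+ Psi with Phi the factor covariance and Psi diagonal.

Priors: free loadings Gaussian (mean 0, precision 0.01 by default, i.e.
variance 100); Phi ~ InvWishart(I_q, q + 1); psi_ii ~ InvGamma(shape 0.5,
scale 1).  Identification fixes the first listed indicator of each factor
at loading 1; reported loadings are the standardized solution
lambda * sqrt(Phi_jj) / sqrt(lambda^2 Phi_jj + Psi_ii), which is
invariant to that choice of scale.

The Gibbs cycle augments F as missing data: loadings and specific
variances are updated row-wise, Phi from its inverse-Wishart conditional
given F, F column-blocks from the multivariate-normal conditional
p(F | theta, T), and missing phenotype cells from their conditional
normal.  Phenotypes are centered and scaled to unit variance before
fitting; standardized loadings are scale-free so this only affects the
raw parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# model / prior / posterior containers
# ---------------------------------------------------------------------------


@dataclass
class MeasurementModel:
    """Trait-to-factor assignment; the first trait of each factor anchors
    identification (its loading is fixed at 1)."""

    factor_names: list[str]
    indicator_map: dict[str, str]  # trait -> factor

    def __post_init__(self) -> None:
        counts = {f: 0 for f in self.factor_names}
        for trait, fac in self.indicator_map.items():
            if fac not in counts:
                raise ValueError(f"trait {trait!r} assigned to unknown factor {fac!r}")
            counts[fac] += 1
        empty = [f for f, c in counts.items() if c == 0]
        if empty:
            raise ValueError(f"factors without indicators (not identified): {empty}")

    @property
    def trait_names(self) -> list[str]:
        return list(self.indicator_map)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def indicators(self, factor: str) -> list[str]:
        return [t for t, f in self.indicator_map.items() if f == factor]

    def anchors(self) -> dict[str, str]:
        return {f: self.indicators(f)[0] for f in self.factor_names}

    @classmethod
    def from_factor_lists(cls, factor_to_traits: dict[str, list[str]]) -> "MeasurementModel":
        imap = {t: f for f, traits in factor_to_traits.items() for t in traits}
        return cls(list(factor_to_traits), imap)


@dataclass
class CfaPriorConfig:
    loading_prior_mean: float = 0.0
    loading_prior_precision: float = 0.01
    phi_scale: np.ndarray | None = None  # default identity
    phi_df: float | None = None  # default q + 1
    psi_shape: float = 0.5
    psi_scale: float = 1.0

    def validate(self, q: int) -> None:
        if self.loading_prior_precision <= 0:
            raise ValueError("loading prior precision must be > 0")
        if self.psi_shape <= 0 or self.psi_scale <= 0:
            raise ValueError("psi prior shape/scale must be > 0")
        df = self.phi_df if self.phi_df is not None else q + 1
        if df <= q - 1:
            raise ValueError("phi_df must exceed q - 1")


@dataclass
class CfaPosterior:
    """Retained draws (chains x draws x ...) and posterior summaries."""

    model: MeasurementModel
    loadings_draws: np.ndarray  # C x D x t (raw, anchors fixed at 1)
    phi_draws: np.ndarray  # C x D x q x q
    psi_draws: np.ndarray  # C x D x t
    loadings_std_draws: np.ndarray  # C x D x t
    factor_scores_mean: pd.DataFrame  # n x q
    theta_labels: dict[str, list[str]] = field(default_factory=dict)

    @property
    def loadings_std_mean(self) -> pd.Series:
        m = self.loadings_std_draws.reshape(-1, self.loadings_std_draws.shape[-1]).mean(0)
        return pd.Series(m, index=self.model.trait_names, name="loading")

    @property
    def loadings_std_sd(self) -> pd.Series:
        s = self.loadings_std_draws.reshape(-1, self.loadings_std_draws.shape[-1]).std(0, ddof=1)
        return pd.Series(s, index=self.model.trait_names, name="psd")

    def loadings_table(self) -> pd.DataFrame:
        """Standardized loading summary, one row per trait."""
        return pd.DataFrame(
            {
                "latent_variable": [self.model.indicator_map[t] for t in self.model.trait_names],
                "trait": self.model.trait_names,
                "loading": self.loadings_std_mean.to_numpy(),
                "psd": self.loadings_std_sd.to_numpy(),
            }
        )

    def convergence(self, threshold: float = 1.2) -> "ConvergenceReport":
        chains = {}
        traits = self.model.trait_names
        for i, t in enumerate(traits):
            chains[f"lambda_std[{t}]"] = self.loadings_std_draws[:, :, i]
            chains[f"psi[{t}]"] = self.psi_draws[:, :, i]
        q = self.model.n_factors
        for a in range(q):
            for b in range(a, q):
                chains[f"phi[{self.model.factor_names[a]},{self.model.factor_names[b]}]"] = (
                    self.phi_draws[:, :, a, b]
                )
        return compute_psrf(chains, threshold=threshold)


@dataclass
class ConvergenceReport:
    psrf_per_parameter: dict[str, float]
    threshold: float = 1.2

    @property
    def converged(self) -> bool:
        return all(v < self.threshold for v in self.psrf_per_parameter.values())

    @property
    def max_psrf(self) -> float:
        return max(self.psrf_per_parameter.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": list(self.psrf_per_parameter), "psrf": list(self.psrf_per_parameter.values())}
        )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def compute_psrf(
    chains_of_draws: dict[str, np.ndarray] | np.ndarray, threshold: float = 1.2
) -> ConvergenceReport:
    """Gelman-Rubin potential scale reduction factor per parameter.

    Accepts either a single (chains x draws) array or a mapping of
    parameter name to such an array.  PSRF compares the between-chain
    variance of the chain means with the pooled within-chain variance;
    values near 1 indicate the chains explore the same distribution.
    """
    if not isinstance(chains_of_draws, dict):
        chains_of_draws = {"theta": np.asarray(chains_of_draws)}
    out = {}
    for name, arr in chains_of_draws.items():
        arr = np.asarray(arr, float)
        if arr.ndim != 2:
            raise ValueError(f"{name}: expected (chains, draws) array")
        m, n = arr.shape
        if m < 2:
            raise ValueError("PSRF needs >= 2 chains; run multiple chains")
        if n < 10:
            raise ValueError("PSRF needs >= 10 draws per chain")
        W = arr.var(axis=1, ddof=1).mean()
        B_over_n = arr.mean(axis=1).var(ddof=1)
        if W <= 1e-300:
            out[name] = 1.0 if B_over_n <= 1e-300 else np.inf
            continue
        var_plus = (n - 1) / n * W + B_over_n
        out[name] = float(np.sqrt(var_plus / W))
    return ConvergenceReport(out, threshold=threshold)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize_loadings(
    lambda_draw: np.ndarray, phi_draw: np.ndarray, psi_draw: np.ndarray, factor_index: np.ndarray
) -> np.ndarray:
    """Standardized loading per trait for one draw.

    With one factor per trait, the model-implied indicator variance is
    lambda^2 Phi_jj + Psi_ii, so the standardized loading is
    lambda sqrt(Phi_jj) / sqrt(lambda^2 Phi_jj + Psi_ii) — the implied
    correlation between indicator and factor, bounded by 1 in magnitude.
    """
    lam = np.asarray(lambda_draw, float)
    phi_jj = np.asarray(phi_draw, float)[factor_index, factor_index]
    psi = np.asarray(psi_draw, float)
    implied = lam**2 * phi_jj + psi
    if np.any(implied <= 0):
        bad = int(np.argmax(implied <= 0))
        raise ValueError(f"non-positive implied variance for trait index {bad}")
    return lam * np.sqrt(phi_jj) / np.sqrt(implied)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _init_state(T, factor_index, q, rng):
    n, t = T.shape
    F = np.zeros((n, q))
    for j in range(q):
        cols = factor_index == j
        F[:, j] = T[:, cols].mean(axis=1)
    lam = np.ones(t)
    psi = np.full(t, 0.5)
    phi = np.cov(F, rowvar=False) + 1e-6 * np.eye(q)
    if q == 1:
        phi = phi.reshape(1, 1)
    return F, lam, psi, phi


def fit_bcfa(
    phenotypes: pd.DataFrame,
    model: MeasurementModel,
    priors: CfaPriorConfig | None = None,
    chains: int = 3,
    iterations: int = 5000,
    burn_in: int = 2000,
    seed: int = 0,
) -> CfaPosterior:
    """Fit the confirmatory factor model by Gibbs sampling.

    Phenotype columns are matched to the measurement model's traits;
    missing cells are allowed and imputed by data augmentation.  Draws
    after ``burn_in`` are retained from every chain; the posterior mean
    of the factor scores is accumulated on the fly.
    """
    priors = priors or CfaPriorConfig()
    q = model.n_factors
    priors.validate(q)
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    traits = model.trait_names
    missing_cols = [c for c in traits if c not in phenotypes.columns]
    if missing_cols:
        raise ValueError(f"phenotype table lacks traits: {missing_cols[:5]}")
    raw = phenotypes[traits].to_numpy(float)
    n, t = raw.shape
    sd = np.nanstd(raw, axis=0, ddof=1)
    zero_var = np.where(~(sd > 0))[0]
    if zero_var.size:
        raise ValueError(f"trait {traits[zero_var[0]]!r} has zero variance")
    T_std = (raw - np.nanmean(raw, axis=0)) / sd
    miss_mask = ~np.isfinite(T_std)
    obs_frac = 1 - miss_mask.mean(0)
    if np.any(np.isfinite(raw).sum(0) < 2):
        raise ValueError("each trait needs >= 2 observed values")

    factor_index = np.array([model.factor_names.index(model.indicator_map[tr]) for tr in traits])
    anchors = model.anchors()
    anchor_idx = np.array([traits.index(anchors[model.factor_names[j]]) for j in range(q)])
    is_anchor = np.zeros(t, bool)
    is_anchor[anchor_idx] = True

    S0 = priors.phi_scale if priors.phi_scale is not None else np.eye(q)
    nu0 = priors.phi_df if priors.phi_df is not None else q + 1
    tau0 = priors.loading_prior_precision
    mu0 = priors.loading_prior_mean
    a0, b0 = priors.psi_shape, priors.psi_scale

    n_keep = iterations - burn_in
    lam_draws = np.empty((chains, n_keep, t))
    psi_draws = np.empty((chains, n_keep, t))
    phi_draws = np.empty((chains, n_keep, q, q))
    std_draws = np.empty((chains, n_keep, t))
    F_accum = np.zeros((n, q))

    root = np.random.SeedSequence(seed)
    for c, child in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(child)
        T = np.where(miss_mask, 0.0, T_std)
        F, lam, psi, phi = _init_state(T, factor_index, q, rng)
        # overdisperse chain starts so PSRF is a meaningful diagnostic
        F = F + 0.5 * rng.standard_normal(F.shape)
        lam = lam + 0.3 * rng.standard_normal(t)
        lam[is_anchor] = 1.0
        for it in range(iterations):
            # (v) missing cells from their conditional normal
            if miss_mask.any():
                mu_T = F[:, factor_index] * lam
                T[miss_mask] = mu_T[miss_mask] + rng.standard_normal(
                    int(miss_mask.sum())
                ) * np.sqrt(psi[np.nonzero(miss_mask)[1]])
            # (i) free loadings, trait by trait (vectorized pieces)
            FtT = F.T @ T  # q x t
            ss = (F**2).sum(axis=0)  # q
            prec = ss[factor_index] / psi + tau0
            mean = (FtT[factor_index, np.arange(t)] / psi + tau0 * mu0) / prec
            lam = mean + rng.standard_normal(t) / np.sqrt(prec)
            lam[is_anchor] = 1.0
            # (ii) specific variances, inverse-gamma conditionals
            R = T - F[:, factor_index] * lam
            rss = (R**2).sum(axis=0)
            psi = (b0 + 0.5 * rss) / rng.gamma(a0 + 0.5 * n, 1.0, size=t)
            # (iii) factor covariance, inverse-Wishart given F
            phi = stats.invwishart.rvs(df=nu0 + n, scale=S0 + F.T @ F, random_state=rng)
            phi = np.atleast_2d(phi)
            # (iv) factor scores from p(F | theta, T)
            Lam = np.zeros((t, q))
            Lam[np.arange(t), factor_index] = lam
            LtPsiInv = Lam.T / psi  # q x t
            M = LtPsiInv @ Lam + np.linalg.inv(phi)
            V = np.linalg.inv(M)
            V = 0.5 * (V + V.T)
            F = T @ LtPsiInv.T @ V.T + rng.standard_normal((n, q)) @ np.linalg.cholesky(V).T
            if it >= burn_in:
                k = it - burn_in
                lam_draws[c, k] = lam
                psi_draws[c, k] = psi
                phi_draws[c, k] = phi
                std_draws[c, k] = standardize_loadings(lam, phi, psi, factor_index)
                F_accum += F

    F_mean = F_accum / (chains * n_keep)
    theta_labels = {
        "lambda": [f"lambda[{tr}]" for tr in traits],
        "psi": [f"psi[{tr}]" for tr in traits],
        "phi": [
            f"phi[{a},{b}]" for a in model.factor_names for b in model.factor_names
        ],
    }
    return CfaPosterior(
        model=model,
        loadings_draws=lam_draws,
        phi_draws=phi_draws,
        psi_draws=psi_draws,
        loadings_std_draws=std_draws,
        factor_scores_mean=pd.DataFrame(F_mean, index=phenotypes.index, columns=model.factor_names),
        theta_labels=theta_labels,
    )


def estimate_factor_scores(posterior: CfaPosterior, phenotypes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Posterior-mean factor scores, one row per accession.

    The mean is accumulated across all retained draws of all chains
    during fitting; ``phenotypes`` is accepted for interface symmetry and
    row-alignment checking only.
    """
    fsm = posterior.factor_scores_mean
    if fsm is None or len(fsm) == 0:
        raise ValueError("posterior holds no retained factor-score draws")
    if phenotypes is not None and not fsm.index.equals(phenotypes.index):
        raise ValueError("factor-score rows do not align with the phenotype table")
    return fsm
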