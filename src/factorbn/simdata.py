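"""Synthetic data with the exact structure the pipeline assumes.

The generator emulates a diversity panel of inbred-line accessions drawn
from differentiated subpopulations, phenotyped for many traits that each
load on exactly one latent factor, where the genetic part of the factors
follows a known structural DAG.  The generative chain inverts the
inference chain stage by stage:

1. genotypes: Balding-Nichols subpopulation allele frequencies around an
   ancestral frequency (differentiation controlled by ``fst``), dosages
   Binomial(2, p_subpop);
2. "adjusted" genetic values w: rows i.i.d., propagated through the DAG
   (w_child = sum beta * w_parent + exogenous noise) so their covariance
   is the SEM-implied Sigma_u;
3. genetic values u = L w with L the Cholesky factor of the genomic
   relationship matrix, giving Var(vec u) = Sigma_u (x) G;
4. factor scores F = subpopulation fixed effects + u + factor-level
   residual with covariance Sigma_eps;
5. phenotypes T = F Lambda' + specific noise with diagonal Psi, with
   optional missing-at-random masking.

Because the DAG is placed on the decorrelated level w, recovering it
after the Cholesky adjustment is a well-posed test of the full pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import (
    GenomicRelationship,
    GenotypeMatrix,
    cholesky_factor,
    compute_grm,
    filter_maf,
)

FACTOR_NAMES = ("Flt", "Mrp", "Yid", "Grm", "Iss", "Msr")
#: indicators per factor: flowering time 7, morphology 14, yield 5,
#: grain morphology 11, ionic salt-stress components 6, salt response 5
INDICATOR_COUNTS = (7, 14, 5, 11, 6, 5)
#: subpopulation sizes of the rice diversity panel (n = 374): temperate
#: japonica, tropical japonica, indica, aus, aromatic, admixed
SUBPOP_SIZES = (92, 85, 77, 52, 12, 56)

# default genetic-level DAG among the factors (parent, child, path coefficient);
# topology mirrors the consensus structure a score-based learner finds on the
# real panel, signs follow the signs of the reported genomic correlations
DEFAULT_DAG_EDGES = (
    ("Iss", "Flt", 0.6),
    ("Msr", "Flt", -0.5),
    ("Mrp", "Flt", 0.5),
    ("Mrp", "Yid", -0.6),
    ("Grm", "Yid", 0.6),
    ("Iss", "Grm", 0.5),
    ("Grm", "Msr", -0.7),
)

# deterministic cycles used to fill in free loading values and specific
# variances for the default 48-trait measurement pattern
_LOADING_CYCLE = (0.9, 0.8, -0.5, 0.7, 0.85, -0.4, 0.75, 0.6)
_PSI_CYCLE = (0.25, 0.45, 0.35, 0.6, 0.5, 0.3)


def _default_subpop_effects(n_subpops: int, n_factors: int) -> np.ndarray:
    """Fixed subpopulation shifts on the factor scale, ~1 SD spread."""
    offsets = np.linspace(-1.0, 1.0, n_subpops)
    signs = np.array([(-1.0) ** j for j in range(n_factors)])
    return 0.8 * np.outer(offsets, signs)


@dataclass
class SimulationConfig:
    """Ground truth for one synthetic dataset.

    ``true_loadings`` is the t x q loading matrix Lambda with exactly one
    nonzero per row; ``dag_edges`` the acyclic genetic-level structure;
    ``genetic_variances`` the exogenous variance of each factor's genetic
    node; ``residual_cov`` the factor-level residual covariance.
    """

    n_accessions: int
    n_markers: int
    factor_names: tuple[str, ...]
    trait_names: tuple[str, ...]
    true_loadings: np.ndarray  # t x q
    specific_variances: np.ndarray  # (t,)
    dag_edges: tuple[tuple[str, str, float], ...]
    genetic_variances: np.ndarray  # (q,)
    residual_cov: np.ndarray  # q x q
    subpop_effects: np.ndarray  # n_subpops x q
    subpop_proportions: tuple[float, ...]
    fst: float = 0.25
    ancestral_maf_range: tuple[float, float] = (0.1, 0.5)
    maf_filter: float = 0.05  # QC threshold applied before the G matrix
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_loadings = np.asarray(self.true_loadings, float)
        self.specific_variances = np.asarray(self.specific_variances, float)
        self.genetic_variances = np.asarray(self.genetic_variances, float)
        self.residual_cov = np.asarray(self.residual_cov, float)
        self.subpop_effects = np.asarray(self.subpop_effects, float)
        if min(self.n_accessions, self.n_markers, self.n_traits, self.n_factors) <= 0:
            raise ValueError("all dimensions must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if self.true_loadings.shape != (self.n_traits, self.n_factors):
            raise ValueError("true_loadings shape mismatch")
        if np.any((self.true_loadings != 0).sum(axis=1) != 1):
            raise ValueError("every trait must load on exactly one factor")
        if np.any(self.specific_variances < 0):
            raise ValueError("specific variances must be >= 0")
        if np.any(self.genetic_variances <= 0):
            raise ValueError("genetic variances must be > 0")
        self.topological_order()  # raises on cycles
        if abs(sum(self.subpop_proportions) - 1.0) > 1e-8:
            raise ValueError("subpop proportions must sum to 1")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_proportions)

    def topological_order(self) -> list[str]:
        """Topological order of the factor DAG; ValueError on a cycle."""
        parents: dict[str, set[str]] = {f: set() for f in self.factor_names}
        for p, c, _ in self.dag_edges:
            if p not in parents or c not in parents:
                raise ValueError(f"dag edge ({p}, {c}) names unknown factor")
            parents[c].add(p)
        order, placed = [], set()
        while len(order) < len(self.factor_names):
            ready = [f for f in self.factor_names if f not in placed and parents[f] <= placed]
            if not ready:
                raise ValueError("dag_edges contain a cycle")
            order.extend(ready)
            placed.update(ready)
        return order

    def sem_implied_sigma_u(self) -> np.ndarray:
        """SEM-implied genetic covariance Sigma_u = (I-B)^-1 V (I-B)^-T."""
        q = self.n_factors
        idx = {f: j for j, f in enumerate(self.factor_names)}
        B = np.zeros((q, q))
        for p, c, beta in self.dag_edges:
            B[idx[c], idx[p]] = beta
        inv = np.linalg.inv(np.eye(q) - B)
        return inv @ np.diag(self.genetic_variances) @ inv.T

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Panel-shaped default: 374 accessions in 6 subpopulations,
        48 traits on 6 factors with the 7/14/5/11/6/5 indicator split."""
        q = len(FACTOR_NAMES)
        t = sum(INDICATOR_COUNTS)
        trait_names, loadings, psis = [], np.zeros((t, q)), np.zeros(t)
        row = 0
        for j, (fac, cnt) in enumerate(zip(FACTOR_NAMES, INDICATOR_COUNTS)):
            for k in range(cnt):
                trait_names.append(f"{fac}_{k + 1:02d}")
                # first indicator anchors the factor's scale at loading 1
                loadings[row, j] = 1.0 if k == 0 else _LOADING_CYCLE[(row + j) % len(_LOADING_CYCLE)]
                psis[row] = _PSI_CYCLE[row % len(_PSI_CYCLE)]
                row += 1
        n = sum(SUBPOP_SIZES)
        cfg = dict(
            n_accessions=n,
            n_markers=4000,
            factor_names=FACTOR_NAMES,
            trait_names=tuple(trait_names),
            true_loadings=loadings,
            specific_variances=psis,
            dag_edges=DEFAULT_DAG_EDGES,
            genetic_variances=np.ones(q),
            residual_cov=np.eye(q),
            subpop_effects=_default_subpop_effects(len(SUBPOP_SIZES), q),
            subpop_proportions=tuple(s / n for s in SUBPOP_SIZES),
            seed=seed,
        )
        cfg.update(overrides)
        return cls(**cfg)


@dataclass
class SyntheticDataset:
    """One simulated panel plus its generative truth."""

    genotypes: GenotypeMatrix
    grm: GenomicRelationship
    subpop_labels: list[str]
    factor_scores_true: pd.DataFrame  # n x q (F)
    genetic_values_true: pd.DataFrame  # n x q (u)
    adjusted_genetic_true: pd.DataFrame  # n x q (w = L^-1 u)
    phenotypes: pd.DataFrame  # n x t (T)
    truth: SimulationConfig


def _stage_rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def subpop_labels(config: SimulationConfig) -> list[str]:
    """Deterministic subpopulation assignment matching the proportions."""
    counts = np.floor(np.asarray(config.subpop_proportions) * config.n_accessions).astype(int)
    while counts.sum() < config.n_accessions:
        counts[int(np.argmax(np.asarray(config.subpop_proportions) * config.n_accessions - counts))] += 1
    labels = []
    for s, c in enumerate(counts):
        labels.extend([f"pop{s + 1}"] * c)
    return labels


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Balding-Nichols genotypes for differentiated subpopulations.

    Each marker's ancestral frequency is uniform on ``ancestral_maf_range``;
    subpopulation frequencies are Beta with that mean and variance
    ``fst * p * (1 - p)`` (exactly the ancestral p when fst = 0); dosages
    are Binomial(2, p_subpop).
    """
    rng = _stage_rng(config, 0)
    n, m = config.n_accessions, config.n_markers
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    labels = subpop_labels(config)
    pop_idx = np.array([int(l[3:]) - 1 for l in labels])
    if config.fst > 0:
        a = p_anc * (1.0 - config.fst) / config.fst
        b = (1.0 - p_anc) * (1.0 - config.fst) / config.fst
        p_sub = rng.beta(a, b, size=(config.n_subpops, m))
    else:
        p_sub = np.tile(p_anc, (config.n_subpops, 1))
    dosages = rng.binomial(2, p_sub[pop_idx, :]).astype(float)
    ids = [f"acc{i + 1:04d}" for i in range(n)]
    markers = [f"snp{j + 1:05d}" for j in range(m)]
    return GenotypeMatrix(ids, markers, dosages)


def simulate_latent_system(
    config: SimulationConfig, grm: GenomicRelationship
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (F, u, w) given the genomic relationship matrix.

    w has i.i.d. rows with covariance Sigma_u (the SEM-implied factor
    covariance from the DAG); u = L w colors them by kinship, so
    Var(vec u) = Sigma_u (x) G; F adds subpopulation fixed effects and a
    factor-level residual with covariance Sigma_eps.
    """
    rng = _stage_rng(config, 1)
    n, q = config.n_accessions, config.n_factors
    if grm.matrix.shape[0] != n:
        raise ValueError("G dimension does not match n_accessions")
    if grm.chol_lower is None:
        grm = cholesky_factor(grm)
    idx = {f: j for j, f in enumerate(config.factor_names)}
    parents: dict[str, list[tuple[str, float]]] = {f: [] for f in config.factor_names}
    for p, c, beta in config.dag_edges:
        parents[c].append((p, beta))
    w = np.zeros((n, q))
    noise = rng.standard_normal((n, q))
    for f in config.topological_order():
        j = idx[f]
        w[:, j] = noise[:, j] * np.sqrt(config.genetic_variances[j])
        for p, beta in parents[f]:
            w[:, j] += beta * w[:, idx[p]]
    u = grm.chol_lower @ w
    labels = subpop_labels(config)
    pop_idx = np.array([int(l[3:]) - 1 for l in labels])
    fixed = config.subpop_effects[pop_idx, :]
    L_eps = np.linalg.cholesky(config.residual_cov)
    eps = rng.standard_normal((n, q)) @ L_eps.T
    F = fixed + u + eps
    return F, u, w


def simulate_phenotypes(config: SimulationConfig, factor_scores: np.ndarray) -> np.ndarray:
    """T = F Lambda' + specific noise with diagonal Psi (+ MAR masking)."""
    F = np.asarray(factor_scores, float)
    if F.shape[1] != config.n_factors:
        raise ValueError(
            f"factor scores have {F.shape[1]} columns, expected {config.n_factors}"
        )
    rng = _stage_rng(config, 2)
    T = F @ config.true_loadings.T
    T = T + rng.standard_normal(T.shape) * np.sqrt(config.specific_variances)
    if config.missing_rate > 0:
        mask = rng.random(T.shape) < config.missing_rate
        T = T.copy()
        T[mask] = np.nan
    return T


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generative chain for one config."""
    geno = simulate_genotypes(config)
    # subpopulation drift can fix markers; apply the standard QC filter
    geno = filter_maf(geno, config.maf_filter)
    grm = cholesky_factor(compute_grm(geno))
    F, u, w = simulate_latent_system(config, grm)
    T = simulate_phenotypes(config, F)
    ids = geno.accession_ids
    fac = list(config.factor_names)
    return SyntheticDataset(
        genotypes=geno,
        grm=grm,
        subpop_labels=subpop_labels(config),
        factor_scores_true=pd.DataFrame(F, index=ids, columns=fac),
        genetic_values_true=pd.DataFrame(u, index=ids, columns=fac),
        adjusted_genetic_true=pd.DataFrame(w, index=ids, columns=fac),
        phenotypes=pd.DataFrame(T, index=ids, columns=list(config.trait_names)),
        truth=config,
    )


# ---------------------------------------------------------------------------
# bundle IO (dosage/phenotype/subpop CSV + truth sidecar)
# ---------------------------------------------------------------------------

def write_bundle(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.csv",
        "phenotypes": outdir / "phenotypes.csv",
        "subpops": outdir / "subpops.csv",
        "measurement_model": outdir / "measurement_model.json",
        "truth": outdir / "truth.json",
    }
    dataset.genotypes.to_frame().to_csv(paths["genotypes"])
    dataset.phenotypes.to_csv(paths["phenotypes"])
    pd.DataFrame(
        {"accession": dataset.genotypes.accession_ids, "subpop": dataset.subpop_labels}
    ).to_csv(paths["subpops"], index=False)
    cfg = dataset.truth
    mm = {
        f: [t for t, lam in zip(cfg.trait_names, cfg.true_loadings[:, j]) if lam != 0]
        for j, f in enumerate(cfg.factor_names)
    }
    paths["measurement_model"].write_text(json.dumps(mm, indent=1))
    truth = {
        "factor_names": list(cfg.factor_names),
        "trait_names": list(cfg.trait_names),
        "true_loadings": cfg.true_loadings.tolist(),
        "specific_variances": cfg.specific_variances.tolist(),
        "dag_edges": [list(e) for e in cfg.dag_edges],
        "genetic_variances": cfg.genetic_variances.tolist(),
        "residual_cov": cfg.residual_cov.tolist(),
        "subpop_effects": cfg.subpop_effects.tolist(),
        "sem_implied_sigma_u": cfg.sem_implied_sigma_u().tolist(),
        "fst": cfg.fst,
        "seed": cfg.seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
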