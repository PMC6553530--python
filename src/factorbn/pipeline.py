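"""End-to-end orchestration: genotype QC -> factor analysis -> GBLUP ->
decorrelation -> network learning.

Stages communicate through plain CSV/JSON artifacts in the output
directory so any stage can be rerun from the previous stage's output.
Accessions are aligned to the intersection of genotype, phenotype and
subpopulation tables (dropped counts logged).  Before network learning,
the latent variables get a numeric normality screen (skewness / excess
kurtosis with soft warnings), since Gaussian network scores assume
approximately normal inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import bcfa, bn, gblup, genomics

logger = logging.getLogger(__name__)

ALGORITHMS = ("hc", "tabu", "mmhc", "rsmax2")


@dataclass
class PipelineConfig:
    genotypes: str
    phenotypes: str
    subpops: str
    measurement_model: str
    outdir: str
    genotype_format: str = "csv"
    maf_threshold: float = 0.05
    cfa: dict = field(default_factory=lambda: {"chains": 3, "iterations": 5000, "burn_in": 2000})
    mtm: dict = field(default_factory=lambda: {"chains": 2, "iterations": 30000, "burn_in": 5000})
    network: dict = field(
        default_factory=lambda: {
            "algorithms": list(ALGORITHMS),
            "n_boot": 500,
            "strength_threshold": 0.85,
            "direction_threshold": 0.5,
            "alpha": 0.05,
            "tabu_len": 10,
        }
    )
    seeds: dict = field(default_factory=lambda: {"cfa": 1, "mtm": 2, "network": 3})

    def __post_init__(self) -> None:
        if not 0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        for key in ("genotypes", "phenotypes", "subpops", "measurement_model"):
            if not Path(getattr(self, key)).exists():
                raise FileNotFoundError(f"{key} file not found: {getattr(self, key)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def load_measurement_model(path: str | Path) -> bcfa.MeasurementModel:
    """Measurement model file: mapping factor name -> ordered trait list
    (JSON or YAML); the first trait per factor anchors the scale."""
    text = Path(path).read_text()
    mapping = yaml.safe_load(text)
    return bcfa.MeasurementModel.from_factor_lists(
        {str(f): [str(t) for t in traits] for f, traits in mapping.items()}
    )


def normality_screen(values: pd.DataFrame, warn_skew: float = 1.0, warn_kurt: float = 3.0) -> pd.DataFrame:
    """Skewness / excess-kurtosis table with soft warnings, not a gate."""
    rows = []
    for col in values.columns:
        x = values[col].dropna().to_numpy(float)
        skew = float(sps.skew(x))
        kurt = float(sps.kurtosis(x))
        flagged = abs(skew) > warn_skew or abs(kurt) > warn_kurt
        if flagged:
            logger.warning(
                "latent variable %s departs from normality (skew %.2f, excess kurtosis %.2f)",
                col, skew, kurt,
            )
        rows.append({"variable": col, "skewness": skew, "excess_kurtosis": kurt, "flagged": flagged})
    return pd.DataFrame(rows)


def _align(geno: genomics.GenotypeMatrix, pheno: pd.DataFrame, subpops: pd.Series):
    """Restrict all inputs to the common accessions, in genotype order."""
    common = [
        a
        for a in geno.accession_ids
        if a in set(map(str, pheno.index)) and a in set(map(str, subpops.index))
    ]
    dropped = len(geno.accession_ids) - len(common)
    if dropped:
        logger.info("dropped %d accessions outside the common intersection", dropped)
    if len(common) < 2:
        raise ValueError("fewer than 2 accessions shared across inputs")
    keep = [i for i, a in enumerate(geno.accession_ids) if a in set(common)]
    geno2 = genomics.GenotypeMatrix(
        [geno.accession_ids[i] for i in keep], list(geno.marker_ids), geno.dosages[keep, :]
    )
    pheno.index = pheno.index.astype(str)
    subpops.index = subpops.index.astype(str)
    return geno2, pheno.loc[common], subpops.loc[common]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write the report bundle.

    Returns a dict with the in-memory stage results; the output
    directory receives: the loadings table, factor scores, convergence
    reports, genomic correlation matrix, u-hat and u*, the normality
    screen, per-algorithm arc tables plus consensus DOT/GraphML exports,
    a score report (algorithm, BIC, BGe) and a run log of seeds and
    settings.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "genotype QC"
    try:
        geno = genomics.read_genotypes(config.genotypes, config.genotype_format)
        pheno = pd.read_csv(config.phenotypes, index_col=0)
        pheno.index = pheno.index.astype(str)
        sub = pd.read_csv(config.subpops)
        subpops = pd.Series(
            sub["subpop"].astype(str).to_numpy(), index=sub["accession"].astype(str)
        )
        geno, pheno, subpops = _align(geno, pheno, subpops)
        geno = genomics.filter_maf(geno, config.maf_threshold)
        grm = genomics.cholesky_factor(genomics.compute_grm(geno))
        genomics.write_grm_csv(grm, out / "grm.csv")

        stage = "bayesian confirmatory factor analysis"
        model = load_measurement_model(config.measurement_model)
        posterior = bcfa.fit_bcfa(
            pheno, model, seed=config.seeds["cfa"], **config.cfa
        )
        posterior.loadings_table().to_csv(out / "loadings.csv", index=False)
        cfa_conv = posterior.convergence()
        cfa_conv.to_frame().to_csv(out / "cfa_convergence.csv", index=False)
        scores = bcfa.estimate_factor_scores(posterior, pheno)
        scores.to_csv(out / "factor_scores.csv")

        stage = "multivariate genomic BLUP"
        design = gblup.MtmDesign.from_subpops(scores, subpops, grm)
        mtm_post = gblup.fit_mtm(design, seed=config.seeds["mtm"], **config.mtm)
        corr = gblup.genomic_correlations(mtm_post.sigma_u_mean, list(scores.columns))
        corr.to_csv(out / "genomic_correlations.csv")
        mtm_post.u_mean.to_csv(out / "u_hat.csv")
        if config.mtm.get("chains", 1) >= 2:
            mtm_post.convergence().to_frame().to_csv(out / "mtm_convergence.csv", index=False)

        stage = "breeding-value adjustment"
        adjusted = gblup.adjust_breeding_values(mtm_post.u_mean, grm)
        adjusted.u_star.to_csv(out / "u_star.csv")
        screen = normality_screen(adjusted.u_star)
        screen.to_csv(out / "normality_screen.csv", index=False)

        stage = "bayesian network learning"
        net_cfg = config.network
        networks: dict[str, bn.AveragedNetwork] = {}
        score_rows = []
        for i, algo in enumerate(net_cfg.get("algorithms", ALGORITHMS)):
            learner = bn.make_learner(
                algo, alpha=net_cfg.get("alpha", 0.05), tabu_len=net_cfg.get("tabu_len", 10)
            )
            avg = bn.bootstrap_average(
                adjusted.u_star,
                learner,
                n_boot=net_cfg.get("n_boot", 500),
                strength_threshold=net_cfg.get("strength_threshold", 0.85),
                direction_threshold=net_cfg.get("direction_threshold", 0.5),
                seed=config.seeds["network"] + i,
            )
            networks[algo] = avg
            avg.to_frame().to_csv(out / f"arcs_{algo}.csv", index=False)
            bn.write_dot(avg.consensus, out / f"consensus_{algo}.dot", averaged=avg)
            bn.write_graphml(avg.consensus, out / f"consensus_{algo}.graphml")
            score_rows.append(
                {"algorithm": algo, "bic": avg.scores["bic"], "bge": avg.scores["bge"]}
            )
        pd.DataFrame(score_rows).to_csv(out / "network_scores.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from err

    log = {
        "n_accessions": len(pheno),
        "n_markers_post_maf": geno.n_markers,
        "maf_threshold": config.maf_threshold,
        "grm_ridge": grm.ridge,
        "cfa": {**config.cfa, "seed": config.seeds["cfa"], "converged": bool(cfa_conv.converged)},
        "mtm": {**config.mtm, "seed": config.seeds["mtm"]},
        "network": {**config.network, "seed": config.seeds["network"]},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return {
        "grm": grm,
        "posterior": posterior,
        "factor_scores": scores,
        "mtm": mtm_post,
        "genomic_correlations": corr,
        "adjusted": adjusted,
        "normality": screen,
        "networks": networks,
        "log": log,
    }
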