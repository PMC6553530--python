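#!/usr/bin/env python
"""Simulate the synthetic study panel and write it to results/panel/.

Generates a diversity-panel-shaped dataset — 374 accessions in six
subpopulations, 48 phenotypes loading on six latent factors, and a known
7-edge genetic-level DAG among the factors — and writes the dosage,
phenotype and subpopulation CSVs plus the measurement model and the
generative truth sidecar that the later stages and the final comparison
consume.
"""

from pathlib import Path

from factorbn import simdata

OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main() -> None:
    cfg = simdata.SimulationConfig.default(seed=2024, n_markers=2000)
    ds = simdata.simulate_dataset(cfg)
    paths = simdata.write_bundle(ds, OUT)
    ds.factor_scores_true.to_csv(OUT / "factor_scores_true.csv")
    ds.adjusted_genetic_true.to_csv(OUT / "adjusted_genetic_true.csv")
    print(f"wrote {len(paths)} files to {OUT}")
    print(
        f"panel: {cfg.n_accessions} accessions x {ds.genotypes.n_markers} markers "
        f"(post-QC), {cfg.n_traits} traits on {cfg.n_factors} factors, "
        f"{len(cfg.dag_edges)} true genetic edges"
    )


if __name__ == "__main__":
    main()
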