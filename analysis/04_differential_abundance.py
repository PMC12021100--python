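#!/usr/bin/env python
"""Moderated differential protein abundance between the two clusters,
adjusted for ethnicity, smoking, fruit and beef intake (model 3), followed
by over-representation and directional enrichment of the senescence sets.

Writes results/dpa/proteomics.tsv and enrichment tables.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from stratomics.dpa import (build_design, directional_enrichment, fit_moderated,
                            ora_hypergeometric)
from stratomics.layers import read_gene_sets, read_layer, read_sample_table

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240158


def main() -> None:
    out = ROOT / "dpa"
    out.mkdir(parents=True, exist_ok=True)
    prot = read_layer(ROOT / "cohort" / "proteins.tsv", "proteomics")
    samples = read_sample_table(ROOT / "cohort" / "samples.tsv")
    labels = pd.read_csv(ROOT / "stratify" / "labels.tsv", sep="\t",
                         index_col=0)["cluster"].loc[prot.sample_ids].to_numpy()
    design = build_design(samples, labels,
                          covariates=["ethnicity", "smoking", "fruit_intake",
                                      "beef_intake"])
    fit = fit_moderated(prot, design)
    table = fit.to_frame().sort_values("p")
    table.to_csv(out / "proteomics.tsv", sep="\t")
    n_sig = int((fit.fdr < 0.05).sum())
    n_up = int(((fit.fdr < 0.05) & (fit.coef > 0)).sum())
    print(f"moderated fit: d0 = {fit.d0:.3g}, s0^2 = {fit.s0_2:.3g}")
    print(f"{n_sig} proteins at FDR < 0.05 ({n_up} more abundant in cluster 2)")

    sen = read_gene_sets(ROOT / "cohort" / "senescence_sets.gmt")
    sig = set(table.index[table["fdr"] < 0.05])
    ora = ora_hypergeometric(sig, sen, prot.feature_ids)
    pd.DataFrame([vars(r) for r in ora]).to_csv(out / "ora_senescence.tsv",
                                                sep="\t", index=False)
    stats_map = dict(zip(fit.feature_ids, fit.t))
    dirn = directional_enrichment(stats_map, sen, n_perm=1000, seed=SEED)
    pd.DataFrame([vars(r) for r in dirn]).to_csv(out / "directional_senescence.tsv",
                                                 sep="\t", index=False)
    for r in dirn:
        print(f"  {r.set_name}: mean t = {r.stat:.2f}, direction = {r.direction}, "
              f"p = {r.p:.4g}, FDR = {r.fdr:.4g}")


if __name__ == "__main__":
    main()
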