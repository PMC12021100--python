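#!/usr/bin/env python
"""Consensus Gaussian Bayesian network over the selected proteins and
BIC-drop driver identification with the random-gene empirical null.

Uses 30 random restarts and 300 refinement perturbations over the 80
highest-frequency selected proteins at desk scale (the full-cohort setting
is 150 restarts / 1000 refinements over every selected protein).  Writes
results/drivers/.
"""

import json
from pathlib import Path

import pandas as pd

from stratomics import bn
from stratomics.layers import read_layer

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240158


def main() -> None:
    out = ROOT / "drivers"
    out.mkdir(parents=True, exist_ok=True)
    prot = read_layer(ROOT / "cohort" / "proteins.tsv", "proteomics")
    trace = pd.read_csv(ROOT / "select" / "trace.tsv", sep="\t", index_col=0)
    sel = trace[trace["selected"]].sort_values("frequency", ascending=False)
    selected = sel.index[:80].tolist()
    truth = json.loads((ROOT / "cohort" / "truth.json").read_text())
    in_set = len(set(truth["drivers"]) & set(selected))
    print(f"learning structure over {len(selected)} selected proteins "
          f"({in_set}/5 planted drivers survived selection; redundant "
          f"correlated features are penalized by shadow selection, so driver "
          f"recovery is assessed separately on dedicated simulations)")

    data = prot.to_frame()[selected]
    model = bn.consensus_dag(data, n_starts=30, refine_iters=300, seed=SEED)
    scores = bn.driver_scores(model, data)
    print(f"consensus DAG: {len(model.edges())} edges, score {model.score:.1f}")

    sc = bn.BicScorer(data)
    top = [s for s in scores[:5] if s.delta_bic > 0]
    for s in top:
        s.empirical_p = bn.validate_driver(s.node, model, data, n_random=5,
                                           iters=1000, seed=SEED,
                                           candidates=[t.node for t in top],
                                           scorer=sc)
    planted = set(truth["drivers"])
    print("top drivers by BIC drop:")
    for s in top:
        mark = "*planted*" if s.node in planted else ""
        print(f"  {s.rank}. {s.node}: dBIC = {s.delta_bic:.2f}, "
              f"empirical p = {s.empirical_p:.4g} {mark}")

    pd.DataFrame(model.edges(), columns=["source", "target"]).to_csv(
        out / "edges.tsv", sep="\t", index=False)
    pd.DataFrame([{"node": s.node, "delta_bic": s.delta_bic, "rank": s.rank,
                   "empirical_p": s.empirical_p} for s in scores]
                 ).to_csv(out / "drivers.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
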