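#!/usr/bin/env python
"""Call state-specific regions and gene signatures on the simulated study.

Runs the two-stage differential-region caller (NB Wald at adjP <= 0.05 and
|log2FC| >= 1, then the pooled binomial support filter) and the gene-signature
thresholds on the study written by 01_simulate_study.py, and scores both
against the planted truth.
"""

import json
from pathlib import Path

from regland import activity
from regland.activity import CountMatrix
from regland.simulate import PlantedTruth

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"
STUDY = BASE / "study"


def main():
    region_counts = CountMatrix.from_tsv(STUDY / "region_counts.tsv", STUDY / "design.tsv")
    expr_counts = CountMatrix.from_tsv(STUDY / "expr_counts.tsv", STUDY / "design_expr.tsv")
    truth = PlantedTruth.from_json(STUDY / "truth.json")

    sets = activity.differential_regions(region_counts)
    sets["results"].drop(columns="id").rename_axis("id").to_csv(
        BASE / "region_differential.tsv", sep="\t")
    expr_res = activity.nb_differential(expr_counts)
    sig_a, sig_b = activity.define_signature(expr_res, "proliferative", "invasive")
    with open(BASE / "signatures.json", "w") as fh:
        json.dump({sig_a.state: sorted(sig_a.genes),
                   sig_b.state: sorted(sig_b.genes)}, fh, indent=1)

    for state in ("proliferative", "invasive"):
        planted = truth.active_regions_by_state[state]
        called = set(sets[state])
        n_true = len(planted & called)
        print(f"{state:>14}: {len(called)} regions called, "
              f"{n_true}/{len(planted)} planted recovered "
              f"({100 * n_true / max(len(planted), 1):.1f}%)")
    print(f"gene signatures: {len(sig_a)} {sig_a.state}, {len(sig_b)} {sig_b.state}")


if __name__ == "__main__":
    main()
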