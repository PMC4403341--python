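#!/usr/bin/env python
"""Simulate the reference two-state study used by the downstream analyses.

Generates a toy genome with a 9-proliferative / 2-invasive sample panel,
planted state-specific regulatory regions, a planted master-regulator TF whose
target regions carry motif instances and are linked to nearby target genes,
and writes the study (counts, catalog, annotation, truth) under
results/analysis/study/.
"""

from pathlib import Path

from regland import io
from regland.simulate import simulate_linked_study

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis" / "study"
SEED = 20240


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    study = simulate_linked_study(seed=SEED)
    io.write_bed(study.catalog.regions, OUT / "catalog.bed")
    study.region_counts.to_tsv(OUT / "region_counts.tsv", OUT / "design.tsv")
    study.expr_counts.to_tsv(OUT / "expr_counts.tsv", OUT / "design_expr.tsv")
    io.write_tss_bed(study.annotation, OUT / "genes.bed")
    study.truth.to_json(OUT / "truth.json")
    print(f"study written to {OUT}")
    print(f"  catalog regions : {len(study.catalog)}")
    print(f"  genes           : {len(study.annotation)}")
    print(f"  planted links   : {len(study.truth.region_gene_links)}")
    print(f"  design          : {study.cfg.n_state_a} {study.cfg.state_a} vs "
          f"{study.cfg.n_state_b} {study.cfg.state_b}")


if __name__ == "__main__":
    main()
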