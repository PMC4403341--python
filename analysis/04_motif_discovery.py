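#!/usr/bin/env python
"""Master-regulator discovery by recovery-curve motif enrichment.

Plants one sharp PWM into 200 of 1,000 foreground regions of a 10,000-region
catalog, scans the planted PWM and 50 decoys over every region sequence,
ranks the catalog per motif and scores the foreground by recovery AUC at the
0.25% cutoff. The planted motif should attain the top NES by a wide margin.
"""

from pathlib import Path

import numpy as np

from regland import enrichment as en
from regland.simulate import GenomeSpec, generate_sequences_with_motifs, make_toy_catalog

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
SEED = 20242


def rand_pwm(rng, name, w, length=10):
    cons = rng.integers(0, 4, length)
    m = np.full((length, 4), (1 - w) / 3)
    m[np.arange(length), cons] = w
    return en.PWM(name, m)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    catalog = make_toy_catalog(GenomeSpec(), n_regions=10_000, region_len=500)
    ids = np.array(catalog.ids)
    planted = rand_pwm(rng, "planted_TF", 0.95)
    decoys = [rand_pwm(rng, f"decoy_{i:02d}", 0.85) for i in range(50)]
    foreground = ids[rng.choice(ids.size, 1000, replace=False)]
    targets = list(foreground[:200])
    seqs, _ = generate_sequences_with_motifs(catalog, planted, targets, seed=SEED + 1)
    encoded = en.encode_sequences(seqs)
    rankings = [en.rank_regions(en.scan_pwm(encoded, p), p.name, tie_seed=SEED + i)
                for i, p in enumerate([planted] + decoys)]
    table = en.score_features(rankings, list(foreground))
    table.to_csv(OUT / "motif_enrichment.tsv", sep="\t", index=False)
    top = table.iloc[0]
    recovered = en.leading_targets(rankings[0], list(foreground))
    print(table.head(5).to_string(index=False))
    print(f"\ntop feature: {top['feature']} (NES {top['nes']:.2f}, "
          f"Bonferroni padj {top['padj']:.2e})")
    print(f"targets inside the 0.25% cutoff: {len(recovered)} "
          f"(cutoff window T = {int(np.ceil(0.0025 * 10_000))} ranks)")


if __name__ == "__main__":
    main()
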