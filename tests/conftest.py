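import numpy as np
import pandas as pd
import pytest

from regland.simulate import (GenomeSpec, StateConfig, make_toy_catalog,
                              generate_activity_counts)


@pytest.fixture(scope="session")
def toy_spec():
    return GenomeSpec(("chr1", "chr2"), (10_000_000, 10_000_000), seed=0)


@pytest.fixture(scope="session")
def small_catalog(toy_spec):
    return make_toy_catalog(toy_spec, n_regions=1000, region_len=500)


@pytest.fixture(scope="session")
def null_counts(small_catalog):
    """1000-region null count matrix (no planted effect), 9 vs 2 design."""
    cfg = StateConfig(n_regions_active_a=0, n_regions_active_b=0)
    cm, _ = generate_activity_counts(small_catalog, cfg, seed=101)
    return cm


@pytest.fixture(scope="session")
def planted_counts(small_catalog):
    """1000-region matrix with 50 + 50 planted differential regions."""
    cfg = StateConfig(n_regions_active_a=50, n_regions_active_b=50,
                      effect_log2fc=2.0, nb_dispersion=0.1)
    return generate_activity_counts(small_catalog, cfg, seed=102)


def bp_mask(intervals: pd.DataFrame, size: int, chrom: str = "c") -> np.ndarray:
    """Brute-force per-bp boolean coverage of one chromosome."""
    mask = np.zeros(size, dtype=bool)
    sub = intervals[intervals["chrom"] == chrom] if len(intervals) else intervals
    for _, r in sub.iterrows():
        mask[int(r["start"]):int(r["end"])] = True
    return mask
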