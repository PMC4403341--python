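"""Synthetic two-state regulatory studies with planted ground truth.

Generates everything the pipeline consumes — toy genomes, regulatory feature
tracks, candidate-region catalogs, negative-binomial region-activity and
gene-expression count matrices for a two-state sample design (default 9
"proliferative" vs 2 "invasive" samples), region sequences with planted motif
instances, and region->gene links — together with a :class:`PlantedTruth`
record so every downstream stage can be scored against what was planted.

All generators are pure functions of their arguments and a seed: the same
seed yields bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .activity import CountMatrix
from .catalog import RegionCatalog, sort_intervals

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """A toy genome: chromosome names, lengths (bp) and the master seed."""

    chrom_names: tuple = ("chr1", "chr2")
    chrom_lengths: tuple = (10_000_000, 10_000_000)
    seed: int = 0

    def __post_init__(self):
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def sizes(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True)
class StateConfig:
    """Two-state sample design and planted-effect parameters.

    Defaults mirror a 9-proliferative vs 2-invasive culture panel with a
    planted mean shift of ``effect_log2fc`` on differential rows and a shared
    NB dispersion (Var = mu + dispersion * mu^2).
    """

    n_state_a: int = 9
    n_state_b: int = 2
    state_a: str = "proliferative"
    state_b: str = "invasive"
    n_regions_active_a: int = 200
    n_regions_active_b: int = 200
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0

    def __post_init__(self):
        if self.n_state_a < 1 or self.n_state_b < 1:
            raise ValueError("each state needs at least one sample")
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be non-negative")

    def sample_names(self) -> tuple[list[str], list[str]]:
        a = [f"{self.state_a[:4]}_{i+1}" for i in range(self.n_state_a)]
        b = [f"{self.state_b[:4]}_{i+1}" for i in range(self.n_state_b)]
        return a, b

    def design(self) -> pd.Series:
        a, b = self.sample_names()
        return pd.Series({**{s: self.state_a for s in a}, **{s: self.state_b for s in b}})


@dataclass
class PlantedTruth:
    """Ground truth of a simulated study.

    ``active_regions_by_state`` maps state label -> planted differential
    region IDs; ``tf_target_regions`` maps TF name -> region IDs carrying a
    planted motif instance; ``region_gene_links`` lists planted co-active
    (region_id, gene_id) pairs.
    """

    active_regions_by_state: dict = field(default_factory=dict)
    tf_target_regions: dict = field(default_factory=dict)
    region_gene_links: list = field(default_factory=list)
    motif_offsets: dict = field(default_factory=dict)

    def validate(self, region_ids, gene_ids=None) -> None:
        regions = set(region_ids)
        for state, ids in self.active_regions_by_state.items():
            missing = set(ids) - regions
            if missing:
                raise ValueError(f"truth regions not in catalog ({state}): {sorted(missing)[:3]}")
        for tf, ids in self.tf_target_regions.items():
            if not set(ids) <= regions:
                raise ValueError(f"TF {tf} targets not in catalog")
        if gene_ids is not None:
            genes = set(gene_ids)
            for r, g in self.region_gene_links:
                if r not in regions or g not in genes:
                    raise ValueError(f"dangling link {r}->{g}")

    def to_json(self, path) -> None:
        payload = {
            "active_regions_by_state": {k: sorted(v) for k, v in self.active_regions_by_state.items()},
            "tf_target_regions": {k: sorted(v) for k, v in self.tf_target_regions.items()},
            "region_gene_links": sorted(map(list, self.region_gene_links)),
            "motif_offsets": self.motif_offsets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(active_regions_by_state={k: set(v) for k, v in d["active_regions_by_state"].items()},
                   tf_target_regions={k: set(v) for k, v in d["tf_target_regions"].items()},
                   region_gene_links=[tuple(x) for x in d["region_gene_links"]],
                   motif_offsets={k: int(v) for k, v in d.get("motif_offsets", {}).items()})


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_feature_tracks(spec: GenomeSpec,
                            n_tracks: int = 3,
                            density: float = 100.0,
                            mean_len: int = 400,
                            insulator_density: float = 5.0,
                            exon_density: float = 20.0,
                            exon_len: int = 150) -> dict:
    """Random regulatory feature tracks plus insulator and exon tracks.

    Interval counts per chromosome are Poisson(density * length / 1 Mb) with
    exponential lengths (min 50 bp), clipped to chromosome bounds. Insulators
    and exons are produced the same way under their own densities and carry
    their own track names.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    rng = _rng(spec.seed)

    def one_track(dens, mlen):
        rows = []
        for chrom, length in zip(spec.chrom_names, spec.chrom_lengths):
            n = rng.poisson(dens * length / 1e6)
            starts = rng.integers(0, length, size=n)
            lens = np.maximum(rng.exponential(mlen, size=n).astype(np.int64), 50)
            ends = np.minimum(starts + lens, length)
            for s, e in zip(starts, ends):
                if e > s:
                    rows.append((chrom, int(s), int(e)))
        return sort_intervals(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    tracks = {f"track_{i+1}": one_track(density, mean_len) for i in range(n_tracks)}
    tracks["insulators"] = one_track(insulator_density, 200)
    tracks["exons"] = one_track(exon_density, exon_len)
    return tracks


def make_toy_catalog(spec: GenomeSpec,
                     n_regions: int = 10_000,
                     region_len: int = 500) -> RegionCatalog:
    """Evenly spaced disjoint regions — the fast deterministic test catalog."""
    total = sum(spec.chrom_lengths)
    rows = []
    remaining = n_regions
    for i, (chrom, length) in enumerate(zip(spec.chrom_names, spec.chrom_lengths)):
        n = round(n_regions * length / total) if i < len(spec.chrom_names) - 1 else remaining
        n = min(n, remaining)
        remaining -= n
        if n == 0:
            continue
        spacing = length // n
        if spacing <= region_len:
            raise ValueError("too many regions for the chromosome length")
        for j in range(n):
            s = j * spacing + (spacing - region_len) // 2
            rows.append((chrom, s, s + region_len))
    return RegionCatalog(pd.DataFrame(rows, columns=["chrom", "start", "end"]),
                         provenance=["toy"], build_params={"n_regions": n_regions,
                                                           "region_len": region_len})


def _nb_draws(rng, mean, dispersion, size):
    """NB with Var = mu + dispersion mu^2 via gamma-Poisson mixture."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def generate_activity_counts(catalog: RegionCatalog,
                             cfg: StateConfig,
                             seed: int = 0,
                             planted_a: list | None = None,
                             planted_b: list | None = None) -> tuple[CountMatrix, PlantedTruth]:
    """NB region-activity counts with planted state-specific regions.

    Planted regions have their mean multiplied by ``2**effect_log2fc`` in
    their active state. Row baselines are log-normal around
    ``baseline_mean``. Returns the counts and the planted truth.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    if cfg.n_regions_active_a + cfg.n_regions_active_b > len(catalog):
        raise ValueError("more planted regions than catalog regions")
    rng = _rng(seed)
    ids = np.array(catalog.ids)
    chosen = rng.choice(len(ids), size=cfg.n_regions_active_a + cfg.n_regions_active_b,
                        replace=False)
    set_a = ids[chosen[:cfg.n_regions_active_a]]
    set_b = ids[chosen[cfg.n_regions_active_a:]]
    a_names, b_names = cfg.sample_names()
    baselines = np.exp(rng.normal(np.log(cfg.baseline_mean), 0.4, size=len(ids)))
    mu = np.tile(baselines[:, None], (1, cfg.n_state_a + cfg.n_state_b))
    boost = 2.0 ** cfg.effect_log2fc
    a_idx = np.isin(ids, set_a)
    b_idx = np.isin(ids, set_b)
    mu[np.ix_(a_idx, np.arange(cfg.n_state_a))] *= boost
    mu[np.ix_(b_idx, np.arange(cfg.n_state_a, cfg.n_state_a + cfg.n_state_b))] *= boost
    counts = _nb_draws(rng, mu, cfg.nb_dispersion, mu.shape)
    cm = CountMatrix(pd.DataFrame(counts, index=ids, columns=a_names + b_names),
                     cfg.design())
    truth = PlantedTruth(active_regions_by_state={cfg.state_a: set(set_a),
                                                  cfg.state_b: set(set_b)})
    return cm, truth


def random_sequences(n: int, length: int, gc: float, rng) -> list[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=(n, length), p=p)
    return ["".join(BASES[row]) for row in draws]


def generate_sequences_with_motifs(catalog: RegionCatalog,
                                   pwm,
                                   target_ids,
                                   background_gc: float = 0.41,
                                   seed: int = 0) -> tuple[dict, dict]:
    """Background sequences with one sampled motif instance per target region.

    Every target region receives a single instance drawn column-wise from the
    PWM probabilities at a uniform random offset (recorded); all other
    regions are background-only. Returns (sequences by region ID, offsets by
    region ID).
    """
    if not 0 < background_gc < 1:
        raise ValueError("background_gc must be in (0, 1)")
    rng = _rng(seed)
    lengths = catalog.lengths()
    L = pwm.length
    if (lengths[np.isin(catalog.ids, list(target_ids))] < L).any():
        raise ValueError("PWM longer than a target region")
    seqs = {}
    offsets = {}
    targets = set(target_ids)
    unknown = targets - set(catalog.ids)
    if unknown:
        raise ValueError(f"target IDs not in catalog: {sorted(unknown)[:3]}")
    for rid, length in zip(catalog.ids, lengths):
        seq = random_sequences(1, int(length), background_gc, rng)[0]
        if rid in targets:
            off = int(rng.integers(0, length - L + 1))
            inst = "".join(BASES[rng.choice(4, p=pwm.matrix[j])] for j in range(L))
            seq = seq[:off] + inst + seq[off + L:]
            offsets[rid] = off
        seqs[rid] = seq
    return seqs, offsets


def make_gene_annotation(spec: GenomeSpec,
                         n_genes: int = 2000,
                         seed: int = 0,
                         jitter: int = 2000) -> pd.DataFrame:
    """Evenly spaced gene TSSs with uniform jitter; columns gene_id, chrom, tss, strand."""
    rng = _rng(seed)
    total = sum(spec.chrom_lengths)
    rows = []
    g = 0
    for chrom, length in zip(spec.chrom_names, spec.chrom_lengths):
        n = max(1, round(n_genes * length / total))
        spacing = length // (n + 1)
        for j in range(n):
            if g >= n_genes:
                break
            tss = (j + 1) * spacing + int(rng.integers(-jitter, jitter + 1))
            tss = int(np.clip(tss, 0, length - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene_{g+1:05d}", chrom, tss, strand))
            g += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])


def generate_expression_counts(annotation: pd.DataFrame,
                               cfg: StateConfig,
                               truth: PlantedTruth,
                               seed: int = 0,
                               region_states: dict | None = None,
                               extra_de_genes: dict | None = None) -> CountMatrix:
    """NB gene-expression counts; linked genes share their region's state effect.

    Genes appearing in ``truth.region_gene_links`` get the planted log2 fold
    change in the state where their linked region is active (so region
    activity and gene expression co-vary across samples); genes listed in
    ``extra_de_genes`` (gene -> state) are differential without any linked
    region; all other genes are independent NB noise.
    """
    rng = _rng(seed)
    gene_ids = annotation["gene_id"].tolist()
    gene_set = set(gene_ids)
    if region_states is None:
        region_states = {}
        for state, ids in truth.active_regions_by_state.items():
            for r in ids:
                region_states[r] = state
    gene_state = {}
    for r, g in truth.region_gene_links:
        if g not in gene_set:
            raise ValueError(f"link gene {g} missing from the annotation")
        if r in region_states:
            gene_state[g] = region_states[r]
    for g, state in (extra_de_genes or {}).items():
        gene_state[g] = state
    a_names, b_names = cfg.sample_names()
    n = len(gene_ids)
    baselines = np.exp(rng.normal(np.log(cfg.baseline_mean), 0.4, size=n))
    mu = np.tile(baselines[:, None], (1, cfg.n_state_a + cfg.n_state_b))
    boost = 2.0 ** cfg.effect_log2fc
    for i, g in enumerate(gene_ids):
        state = gene_state.get(g)
        if state == cfg.state_a:
            mu[i, :cfg.n_state_a] *= boost
        elif state == cfg.state_b:
            mu[i, cfg.n_state_a:] *= boost
    counts = _nb_draws(rng, mu, cfg.nb_dispersion, mu.shape)
    return CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=a_names + b_names),
                       cfg.design())


@dataclass
class LinkedStudy:
    """A full simulated study bundle with planted TF targets and gene links."""

    spec: GenomeSpec
    cfg: StateConfig
    catalog: RegionCatalog
    region_counts: CountMatrix
    expr_counts: CountMatrix
    annotation: pd.DataFrame
    truth: PlantedTruth


def simulate_linked_study(seed: int = 0,
                          n_links: int = 40,
                          chrom_mb: int = 50,
                          locus_spacing: int = 2_400_000,
                          max_gene_offset: int = 300_000,
                          n_extra_regions: int = 200,
                          n_extra_de_genes: int = 40,
                          n_null_genes: int = 400,
                          region_len: int = 1000,
                          cfg: StateConfig | None = None,
                          tf_name: str = "TF1") -> LinkedStudy:
    """Study with planted TF target regions linked to nearby target genes.

    Link loci (region + linked gene) are laid out on a grid with spacing
    larger than twice the assignment window plus the maximal gene offset, so
    that no locus' gene falls into a neighbouring locus' window; unlinked
    differential genes sit midway between loci (outside every planted
    region's 1 Mb window). Extra differential regions without linked genes
    occupy the same midpoints. This makes the planted edge set the unique
    correct answer for a 1 Mb-window assignment.
    """
    cfg = cfg or StateConfig(n_regions_active_a=0, n_regions_active_b=0)
    chrom_len = chrom_mb * 1_000_000
    spec = GenomeSpec(("chr1", "chr2"), (chrom_len, chrom_len), seed=seed)
    rng = _rng(seed)
    per_chrom = int(np.ceil(n_links / 2))
    loci = []
    for chrom in spec.chrom_names:
        for i in range(per_chrom):
            if len(loci) >= n_links:
                break
            pos = 1_000_000 + i * locus_spacing
            if pos + max_gene_offset + region_len >= chrom_len:
                raise ValueError("chromosome too short for the requested loci")
            loci.append((chrom, pos))
    regions = []
    genes = []
    links = []
    states = [cfg.state_a, cfg.state_b]
    region_states = {}
    for i, (chrom, pos) in enumerate(loci):
        rid = f"{chrom}:{pos}-{pos + region_len}"
        regions.append((chrom, pos, pos + region_len))
        offset = int(rng.integers(10_000, max_gene_offset))
        sign = 1 if rng.random() < 0.5 else -1
        gid = f"linked_{i+1:03d}"
        genes.append((gid, chrom, pos + sign * offset, "+"))
        links.append((rid, gid))
        # the planted TF drives state-B activity: all its target regions are
        # active in state B, so they form one coherent foreground set
        region_states[rid] = cfg.state_b
    # extra differential regions and unlinked differential genes at midpoints
    mid_positions = [(chrom, pos + locus_spacing // 2) for chrom, pos in loci]
    extra_regions = []
    for i in range(n_extra_regions):
        chrom, base = mid_positions[i % len(mid_positions)]
        pos = base + (i // len(mid_positions)) * (region_len + 200)
        extra_regions.append((chrom, pos, pos + region_len))
    extra_de = {}
    for i in range(n_extra_de_genes):
        chrom, base = mid_positions[i % len(mid_positions)]
        tss = base + 50_000 + (i // len(mid_positions)) * 500
        gid = f"extra_de_{i+1:03d}"
        genes.append((gid, chrom, tss, "+"))
        extra_de[gid] = states[i % 2]
    # null background regions and genes, kept out of every locus window
    null_regions = []
    for i in range(n_null_genes):
        chrom, base = mid_positions[i % len(mid_positions)]
        tss = base + 120_000 + (i // len(mid_positions)) * 700
        genes.append((f"null_{i+1:04d}", chrom, tss, "+"))
        pos = base + 200_000 + (i // len(mid_positions)) * (region_len + 300)
        null_regions.append((chrom, pos, pos + region_len))

    all_regions = pd.DataFrame(regions + extra_regions + null_regions,
                               columns=["chrom", "start", "end"])
    catalog = RegionCatalog(all_regions, provenance=["simulated"],
                            build_params={"n_links": n_links})
    annotation = pd.DataFrame(genes, columns=["gene_id", "chrom", "tss", "strand"])

    # planted activity: linked regions + extras are differential, alternating state
    extra_ids = [f"{c}:{s}-{e}" for c, s, e in extra_regions]
    for i, rid in enumerate(extra_ids):
        region_states[rid] = states[i % 2]
    active_a = {r for r, s in region_states.items() if s == cfg.state_a}
    active_b = {r for r, s in region_states.items() if s == cfg.state_b}
    truth = PlantedTruth(active_regions_by_state={cfg.state_a: active_a, cfg.state_b: active_b},
                         tf_target_regions={tf_name: {r for r, _ in links}},
                         region_gene_links=links)

    ids = np.array(catalog.ids)
    a_names, b_names = cfg.sample_names()
    baselines = np.exp(rng.normal(np.log(cfg.baseline_mean), 0.4, size=len(ids)))
    mu = np.tile(baselines[:, None], (1, cfg.n_state_a + cfg.n_state_b))
    boost = 2.0 ** cfg.effect_log2fc
    for i, rid in enumerate(ids):
        state = region_states.get(rid)
        if state == cfg.state_a:
            mu[i, :cfg.n_state_a] *= boost
        elif state == cfg.state_b:
            mu[i, cfg.n_state_a:] *= boost
    counts = _nb_draws(rng, mu, cfg.nb_dispersion, mu.shape)
    region_counts = CountMatrix(pd.DataFrame(counts, index=ids, columns=a_names + b_names),
                                cfg.design())
    expr_counts = generate_expression_counts(annotation, cfg, truth,
                                             seed=int(rng.integers(2**31)),
                                             region_states=region_states,
                                             extra_de_genes=extra_de)
    truth.validate(catalog.ids, annotation["gene_id"])
    return LinkedStudy(spec, cfg, catalog, region_counts, expr_counts, annotation, truth)
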