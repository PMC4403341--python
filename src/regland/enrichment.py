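"""Ranking-and-recovery feature discovery over the region catalog.

Every feature (a DNA-binding motif or an experimental peak track) induces one
complete ranking of all M catalog regions. A foreground region set (e.g. the
regions more active in one cell state) is then scored per feature by the area
under its cumulative recovery curve over the top 0.25% of the ranking; AUCs
are standardised across the feature collection into a normalized enrichment
score NES = (AUC - mu) / sigma, significance comes from a hypergeometric test
on the foreground count inside the cutoff (Bonferroni-corrected across
features), and the foreground regions inside the cutoff are the feature's
predicted direct targets.

Motif scoring is best-single-site log-odds (max over windows and strands);
rankings can also be built from any externally computed per-region score, so
other scorers drop in unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_CUTOFF_FRAC = 0.0025  # top 0.25% of the ranking

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
NEG_INF = float("-inf")


@dataclass
class PWM:
    """Position probability matrix over A,C,G,T with pseudo-weight smoothing."""

    name: str
    matrix: np.ndarray  # L x 4 probabilities
    pseudo: float = 1e-3

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if m.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        m = (m + self.pseudo) / (1 + 4 * self.pseudo)
        self.matrix = m

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self, background: np.ndarray | None = None) -> np.ndarray:
        """L x 5 log2-odds lookup; column 4 (N) is the background expectation."""
        q = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        lo = np.log2(self.matrix / q)
        n_col = (q * lo).sum(axis=1, keepdims=True)
        return np.hstack([lo, n_col])

    def reverse_complement(self) -> "PWM":
        rc = PWM.__new__(PWM)
        rc.name = self.name
        rc.matrix = self.matrix[::-1, ::-1].copy()
        rc.pseudo = self.pseudo
        return rc


_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
    _ENCODE_LUT[ord(_b.lower())] = _i


def encode_sequence(seq) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else -> 4 (N); passes int arrays through."""
    if isinstance(seq, np.ndarray):
        return seq
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_sequences(sequences: dict) -> dict:
    """Pre-encode a region->sequence dict for repeated scanning."""
    return {rid: encode_sequence(s) for rid, s in sequences.items()}


_SENTINEL = -1e12  # score of a window crossing a region boundary


def _strand_scores(codes: np.ndarray, starts: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Per-region max window score over one strand of concatenated sequences.

    ``codes`` concatenates all regions with ``L-1`` sentinel bases (code 5)
    appended to each, so windows never straddle two regions; ``starts`` are
    the window-start offsets of each region in the padded array.
    """
    L = lo.shape[0]
    # extend the lookup with a sentinel column so padded windows score -inf-like
    lut = np.hstack([lo, np.full((L, 1), _SENTINEL)])
    n = codes.size
    acc = np.zeros(n - L + 1)
    for j in range(L):
        acc += lut[j, codes[j:j + n - L + 1]]
    maxima = np.maximum.reduceat(acc, np.minimum(starts, acc.size - 1))
    return maxima


def scan_pwm(sequences: dict, pwm: PWM,
             background: np.ndarray | None = None) -> pd.Series:
    """Best-single-site log-odds score per region, both strands.

    ``N`` bases contribute the background expectation of the column score;
    sequences shorter than the PWM (including empty ones) score -inf.
    """
    lo_f = pwm.log_odds(background)
    lo_r = pwm.reverse_complement().log_odds(
        background if background is None else background[::-1])
    rids = list(sequences.keys())
    L = pwm.length
    pieces, starts, lengths = [], [], []
    pos = 0
    pad = np.full(L - 1, 5, dtype=np.int8)
    for rid in rids:
        seq = sequences[rid]
        codes = encode_sequence(seq)
        pieces.append(codes)
        pieces.append(pad)
        starts.append(pos)
        lengths.append(codes.size)
        pos += codes.size + L - 1
    codes_all = np.concatenate(pieces) if pieces else np.empty(0, np.int8)
    if codes_all.size < L:
        return pd.Series({rid: NEG_INF for rid in rids}, name=pwm.name)
    starts = np.asarray(starts)
    best = np.maximum(_strand_scores(codes_all, starts, lo_f),
                      _strand_scores(codes_all, starts, lo_r))
    best = np.where(np.asarray(lengths) < L, NEG_INF, best)
    best = np.where(best <= _SENTINEL / 2, NEG_INF, best)
    return pd.Series(best, index=rids, name=pwm.name)


@dataclass
class FeatureRanking:
    """One complete ordering of all M catalog regions for one feature."""

    feature_name: str
    kind: str  # "motif" | "track"
    order: list  # region IDs, rank 1 first
    scores: pd.Series | None = None
    tie_seed: int | None = None

    def __post_init__(self):
        if len(self.order) != len(set(self.order)):
            raise ValueError("ranking order must be a permutation of region IDs")

    @property
    def m(self) -> int:
        return len(self.order)

    def ranks(self) -> pd.Series:
        return pd.Series(np.arange(1, self.m + 1), index=self.order, name=self.feature_name)

    def rank_ratios(self) -> pd.Series:
        return self.ranks() / self.m


def rank_regions(scores: pd.Series, feature_name: str | None = None,
                 kind: str = "motif", tie_seed: int = 0,
                 catalog_ids=None) -> FeatureRanking:
    """Descending-score ranking with seeded uniform tie-breaking.

    ``catalog_ids``, when given, must match the score index exactly (one score
    per catalog region).
    """
    if catalog_ids is not None and set(scores.index) != set(catalog_ids):
        raise ValueError("score vector does not cover the catalog exactly")
    rng = np.random.default_rng(tie_seed)
    jitter = rng.permutation(len(scores))
    order_idx = np.lexsort((jitter, -np.nan_to_num(scores.to_numpy(dtype=float),
                                                   neginf=-1e300)))
    order = list(scores.index[order_idx])
    return FeatureRanking(feature_name or str(scores.name), kind, order,
                          scores=scores, tie_seed=tie_seed)


def track_ranking(peaks: pd.DataFrame, catalog, feature_name: str,
                  tie_seed: int = 0) -> FeatureRanking:
    """Region score = max score of overlapping peaks (0 if none), then rank.

    Any 1-bp overlap counts; ``peaks`` needs columns chrom, start, end, score.
    """
    if (peaks["score"] < 0).any():
        raise ValueError("peak scores must be non-negative")
    regions = catalog.regions
    scores = np.zeros(len(regions))
    for chrom, grp in peaks.groupby("chrom"):
        mask = regions["chrom"] == chrom
        if not mask.any():
            continue
        rs = regions.loc[mask, "start"].to_numpy()
        re_ = regions.loc[mask, "end"].to_numpy()
        ps = grp["start"].to_numpy()
        pe = grp["end"].to_numpy()
        pv = grp["score"].to_numpy(dtype=float)
        sub = np.zeros(mask.sum())
        for s, e, v in zip(ps, pe, pv):
            hit = (rs < e) & (re_ > s)
            sub[hit] = np.maximum(sub[hit], v)
        scores[np.flatnonzero(mask.to_numpy())] = sub
    series = pd.Series(scores, index=regions["id"].to_numpy(), name=feature_name)
    return rank_regions(series, feature_name, kind="track", tie_seed=tie_seed)


def combine_rankings_orderstat(rank_ratios: np.ndarray) -> np.ndarray:
    """Order-statistics Q for each row of rank ratios across N sources.

    For sorted ratios s_1 <= ... <= s_N of one region, Q = N! * V_N with
    V_0 = 1 and V_k = sum_{i=1..k} (-1)^(i-1) V_{k-i} s_{N-k+1}^i / i!  —
    the joint probability that N iid uniform order statistics fall below the
    observed ratios. Regions are re-ranked by ascending Q. Accepts a 1-D
    vector (one region) or a 2-D (regions x sources) array.
    """
    r = np.asarray(rank_ratios, dtype=float)
    squeeze = r.ndim == 1
    if squeeze:
        r = r[None, :]
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("rank ratios must lie in (0, 1]")
    s = np.sort(r, axis=1)
    n = s.shape[1]
    v = [np.ones(s.shape[0])]
    for k in range(1, n + 1):
        acc = np.zeros(s.shape[0])
        base = s[:, n - k]
        power = np.ones(s.shape[0])
        for i in range(1, k + 1):
            power = power * base
            acc += (-1) ** (i - 1) * v[k - i] * power / math.factorial(i)
        v.append(acc)
    q = math.factorial(n) * v[n]
    return q[0] if squeeze else q


@dataclass
class RecoveryResult:
    """Recovery statistics of one feature against one foreground set."""

    feature_name: str
    auc: float
    nes: float | None
    pvalue: float
    padj: float
    leading_targets: list = field(default_factory=list)


def recovery_curve(ranking: FeatureRanking, foreground, cutoff_frac: float = DEFAULT_CUTOFF_FRAC):
    """Cumulative recovery over ranks 1..T, T = ceil(cutoff_frac * M)."""
    fg = set(foreground)
    if not fg:
        raise ValueError("empty foreground")
    unknown = fg - set(ranking.order)
    if unknown:
        raise ValueError(f"foreground outside catalog: {sorted(unknown)[:3]}")
    m = ranking.m
    t = math.ceil(cutoff_frac * m)
    hits = np.zeros(t, dtype=np.int64)
    ranks = ranking.ranks()
    fg_ranks = ranks.loc[list(fg)].to_numpy()
    inside = fg_ranks[fg_ranks <= t]
    for r in inside:
        hits[r - 1:] += 1
    return hits / len(fg)


def recovery_auc(ranking: FeatureRanking, foreground,
                 cutoff_frac: float = DEFAULT_CUTOFF_FRAC) -> float:
    """Mean recovery over the top T ranks (the step-function average)."""
    curve = recovery_curve(ranking, foreground, cutoff_frac)
    return float(curve.mean())


def nes(aucs: pd.Series, population_sd: bool = True) -> pd.Series:
    """Normalized enrichment scores (AUC - mu) / sigma across the collection."""
    if len(aucs) < 3:
        raise ValueError("need at least 3 features to normalise")
    sd = aucs.std(ddof=0 if population_sd else 1)
    if sd < 1e-12:
        raise ValueError("degenerate feature collection (sigma = 0)")
    return (aucs - aucs.mean()) / sd


def hypergeom_enrichment(ranking: FeatureRanking, foreground,
                         cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
                         n_features: int = 1) -> tuple[float, float]:
    """P(X >= k) for the foreground count inside the cutoff; Bonferroni padj."""
    fg = set(foreground)
    m = ranking.m
    t = math.ceil(cutoff_frac * m)
    ranks = ranking.ranks()
    k = int((ranks.loc[list(fg)] <= t).sum())
    p = float(stats.hypergeom.sf(k - 1, m, len(fg), t))
    return p, min(1.0, p * n_features)


def leading_targets(ranking: FeatureRanking, foreground,
                    cutoff_frac: float = DEFAULT_CUTOFF_FRAC) -> list:
    """Foreground regions inside the cutoff, best rank first."""
    fg = set(foreground)
    m = ranking.m
    t = math.ceil(cutoff_frac * m)
    ranks = ranking.ranks()
    sel = ranks.loc[list(fg)]
    sel = sel[sel <= t].sort_values()
    return list(sel.index)


def score_features(rankings: list[FeatureRanking], foreground,
                   cutoff_frac: float = DEFAULT_CUTOFF_FRAC) -> pd.DataFrame:
    """Recovery AUC, NES, hypergeometric p/padj and target count per feature."""
    aucs = pd.Series({r.feature_name: recovery_auc(r, foreground, cutoff_frac)
                      for r in rankings})
    nes_vals = nes(aucs)
    rows = []
    for r in rankings:
        p, padj = hypergeom_enrichment(r, foreground, cutoff_frac, n_features=len(rankings))
        targets = leading_targets(r, foreground, cutoff_frac)
        rows.append((r.feature_name, r.kind, aucs[r.feature_name],
                     nes_vals[r.feature_name], p, padj, len(targets)))
    df = pd.DataFrame(rows, columns=["feature", "kind", "auc", "nes",
                                     "pvalue", "padj", "n_targets"])
    return df.sort_values(["nes", "feature"], ascending=[False, True]).reset_index(drop=True)


def intersect_motif_track(motif_targets, track_targets, motif_ranking: FeatureRanking | None = None):
    """Regions supported by both the motif and the track, ordered by motif rank."""
    inter = set(motif_targets) & set(track_targets)
    if motif_ranking is None:
        return sorted(inter)
    ranks = motif_ranking.ranks()
    return sorted(inter, key=lambda rid: ranks.loc[rid])
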