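"""Candidate regulatory-region catalog construction.

The catalog is the genome-wide universe of intervals over which all motif and
track rankings, recovery statistics and differential-activity calls are made.
It is built from an arbitrary set of regulatory feature tracks by a fixed
procedure: union-merge all tracks, remove or split regions against a blacklist
of insulators and coding exons, drop sub-minimal fragments, and extend short
regions toward a target length wherever the blacklist, the chromosome ends and
the neighbouring regions permit.

All coordinates are 0-based half-open (BED convention). Interval collections
are plain pandas DataFrames with columns ``chrom``, ``start``, ``end`` and
optionally ``id`` and ``score``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]

# Removal thresholds: fraction of the candidate region covered by the
# blacklist element class at or above which the whole region is discarded.
INSULATOR_REMOVE_FRAC = 0.20
EXON_REMOVE_FRAC = 0.80
MIN_REGION_LEN = 30
TARGET_REGION_LEN = 1000


class IntervalError(ValueError):
    """A malformed interval (start >= end, negative coords, out of bounds)."""


def _as_frame(intervals) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        df = intervals
    else:
        df = pd.DataFrame(list(intervals), columns=BED_COLUMNS)
    if df.empty:
        return pd.DataFrame({"chrom": pd.Series(dtype=object),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    return df


def validate_intervals(df: pd.DataFrame, chrom_sizes: Mapping[str, int] | None = None) -> None:
    """Raise :class:`IntervalError` naming the first offending interval."""
    df = _as_frame(df)
    bad = df[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        r = bad.iloc[0]
        raise IntervalError(f"malformed interval {r['chrom']}:{r['start']}-{r['end']}")
    if chrom_sizes is not None:
        for _, r in df.iterrows():
            if r["chrom"] not in chrom_sizes:
                raise IntervalError(f"unknown chromosome {r['chrom']!r}")
            if r["end"] > chrom_sizes[r["chrom"]]:
                raise IntervalError(
                    f"interval {r['chrom']}:{r['start']}-{r['end']} exceeds "
                    f"chromosome length {chrom_sizes[r['chrom']]}")


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return _as_frame(df).sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_tracks(tracks: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Union-merge interval tracks; abutting intervals (distance 0) join."""
    frames = [_as_frame(t)[BED_COLUMNS] for t in tracks]
    frames = [f for f in frames if len(f)]
    if not frames:
        return _as_frame([])
    allv = pd.concat(frames, ignore_index=True)
    validate_intervals(allv)
    allv = sort_intervals(allv)
    out_chrom, out_start, out_end = [], [], []
    for chrom, grp in allv.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or abut -> join
                cur_e = max(cur_e, e)
            else:
                out_chrom.append(chrom); out_start.append(cur_s); out_end.append(cur_e)
                cur_s, cur_e = s, e
        out_chrom.append(chrom); out_start.append(cur_s); out_end.append(cur_e)
    return pd.DataFrame({"chrom": out_chrom,
                         "start": np.asarray(out_start, dtype=np.int64),
                         "end": np.asarray(out_end, dtype=np.int64)})


def _chrom_arrays(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chrom (starts, ends, prefix-coverage) for a merged, sorted track."""
    out = {}
    for chrom, grp in sort_intervals(df).groupby("chrom"):
        s = grp["start"].to_numpy(dtype=np.int64)
        e = grp["end"].to_numpy(dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(e - s)])
        out[chrom] = (s, e, cum)
    return out


def _coverage_before(x: np.ndarray, s: np.ndarray, e: np.ndarray, cum: np.ndarray) -> np.ndarray:
    """Total bp of the merged track strictly below coordinate x (vectorised)."""
    j = np.searchsorted(s, x, side="right") - 1
    base = cum[np.maximum(j, 0) + 1] - np.where(j >= 0, e[np.maximum(j, 0)] - s[np.maximum(j, 0)], 0)
    inside = np.where(j >= 0, np.clip(np.minimum(x, e[np.maximum(j, 0)]) - s[np.maximum(j, 0)], 0, None), 0)
    return np.where(j >= 0, base + inside, 0)


def overlap_bp(regions: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """bp of each region covered by the (merged) track."""
    regions = _as_frame(regions)
    result = np.zeros(len(regions), dtype=np.int64)
    if regions.empty or _as_frame(track).empty:
        return result
    merged = merge_tracks([track])
    arrs = _chrom_arrays(merged)
    for chrom, idx in regions.groupby("chrom").groups.items():
        if chrom not in arrs:
            continue
        s, e, cum = arrs[chrom]
        rs = regions.loc[idx, "start"].to_numpy()
        re_ = regions.loc[idx, "end"].to_numpy()
        result[regions.index.get_indexer(idx)] = (
            _coverage_before(re_, s, e, cum) - _coverage_before(rs, s, e, cum))
    return result


def subtract(regions: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Cut regions at track boundaries, discarding the covered pieces."""
    regions = _as_frame(regions)
    track = merge_tracks([track]) if len(_as_frame(track)) else _as_frame(track)
    if regions.empty or track.empty:
        return regions[BED_COLUMNS].copy()
    arrs = _chrom_arrays(track)
    out = []
    for _, r in regions.iterrows():
        chrom, rs, re_ = r["chrom"], int(r["start"]), int(r["end"])
        if chrom not in arrs:
            out.append((chrom, rs, re_))
            continue
        s, e, _ = arrs[chrom]
        i0 = np.searchsorted(e, rs, side="right")
        i1 = np.searchsorted(s, re_, side="left")
        pos = rs
        for k in range(i0, i1):
            if s[k] > pos:
                out.append((chrom, pos, min(s[k], re_)))
            pos = max(pos, e[k])
        if pos < re_:
            out.append((chrom, pos, re_))
    df = pd.DataFrame(out, columns=BED_COLUMNS)
    return sort_intervals(df[df["start"] < df["end"]])


def remove_or_split_by_blacklist(
    regions: pd.DataFrame,
    insulators: pd.DataFrame,
    exons: pd.DataFrame,
    insulator_frac: float = INSULATOR_REMOVE_FRAC,
    exon_frac: float = EXON_REMOVE_FRAC,
) -> pd.DataFrame:
    """Remove regions dominated by blacklist elements, split the rest.

    A region is removed outright when insulators cover >= ``insulator_frac``
    of it or coding exons cover >= ``exon_frac`` of it (both fractions are of
    the region's own length, evaluated on the pre-split region). Surviving
    regions are cut at every blacklist boundary and the covered pieces are
    dropped, so no output interval contains any blacklist interval.
    """
    regions = sort_intervals(regions)
    if regions.empty:
        return regions
    lengths = (regions["end"] - regions["start"]).to_numpy()
    ins_cov = overlap_bp(regions, insulators)
    ex_cov = overlap_bp(regions, exons)
    keep = (ins_cov < insulator_frac * lengths) & (ex_cov < exon_frac * lengths)
    survivors = regions[keep]
    blacklist = merge_tracks([t for t in (insulators, exons) if len(_as_frame(t))])
    return subtract(survivors, blacklist)


def filter_min_length(regions: pd.DataFrame, min_len: int = MIN_REGION_LEN) -> pd.DataFrame:
    regions = _as_frame(regions)
    if regions.empty:
        return regions
    return regions[(regions["end"] - regions["start"]) >= min_len].reset_index(drop=True)


def extend_regions(
    regions: pd.DataFrame,
    blacklist: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    target_len: int = TARGET_REGION_LEN,
) -> pd.DataFrame:
    """Extend sub-target regions toward ``target_len`` where possible.

    Extension is symmetric first; any deficit blocked on one side is pushed to
    the other ("in a direction that prevents overlap"). It never crosses a
    blacklist interval, a chromosome end, or another catalog region, and never
    leaves two regions overlapping or abutting (a 1-bp gap is preserved so
    that rebuilding the catalog from its own output is the identity). Regions
    processed left to right per chromosome; an odd deficit puts the extra bp
    on the right.
    """
    regions = sort_intervals(regions)
    if regions.empty:
        return regions
    bl = _chrom_arrays(merge_tracks([blacklist])) if len(_as_frame(blacklist)) else {}
    rows = []
    for chrom, grp in regions.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy(dtype=np.int64)
        ends = grp["end"].to_numpy(dtype=np.int64)
        csize = int(chrom_sizes[chrom])
        bs, be = (bl[chrom][0], bl[chrom][1]) if chrom in bl else (np.empty(0, np.int64),) * 2
        prev_end = None
        for i in range(len(starts)):
            s, e = int(starts[i]), int(ends[i])
            deficit = target_len - (e - s)
            if deficit > 0:
                # leftmost admissible start / rightmost admissible end
                lo = 0 if prev_end is None else prev_end + 1
                j = np.searchsorted(be, s, side="right") - 1
                if j >= 0:
                    lo = max(lo, int(be[j]))
                hi = csize if i == len(starts) - 1 else int(starts[i + 1]) - 1
                k = np.searchsorted(bs, e, side="left")
                if k < len(bs):
                    hi = min(hi, int(bs[k]))
                avail_l, avail_r = s - lo, hi - e
                want_l = deficit // 2
                take_l = min(avail_l, want_l)
                take_r = min(avail_r, deficit - take_l)
                take_l = min(avail_l, deficit - take_r)  # push leftward what the right could not absorb
                s, e = s - take_l, e + take_r
            rows.append((chrom, s, e))
            prev_end = e
    return pd.DataFrame(rows, columns=BED_COLUMNS)


@dataclass
class RegionCatalog:
    """Ordered candidate-region universe with stable ``chrom:start-end`` IDs."""

    regions: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    build_params: dict = field(default_factory=dict)

    def __post_init__(self):
        df = sort_intervals(self.regions)
        if "id" not in df.columns:
            df["id"] = [f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])]
        if df["id"].duplicated().any():
            raise IntervalError("duplicate region IDs in catalog")
        self.regions = df

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def ids(self) -> list[str]:
        return self.regions["id"].tolist()

    def lengths(self) -> np.ndarray:
        return (self.regions["end"] - self.regions["start"]).to_numpy()

    def stats(self, chrom_sizes: Mapping[str, int] | None = None) -> dict:
        out = {"n_regions": len(self),
               "mean_length": float(self.lengths().mean()) if len(self) else 0.0,
               "total_bp": int(self.lengths().sum())}
        if chrom_sizes is not None:
            genome = sum(chrom_sizes.values())
            out["genome_fraction"] = out["total_bp"] / genome if genome else 0.0
        return out


def build_catalog(
    tracks: Sequence[pd.DataFrame],
    insulators: pd.DataFrame,
    exons: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    min_len: int = MIN_REGION_LEN,
    target_len: int = TARGET_REGION_LEN,
    insulator_frac: float = INSULATOR_REMOVE_FRAC,
    exon_frac: float = EXON_REMOVE_FRAC,
    provenance: Sequence[str] | None = None,
) -> RegionCatalog:
    """merge -> remove/split -> min-length filter -> extend -> ID assignment."""
    for t in tracks:
        validate_intervals(t, chrom_sizes)
    for t in (insulators, exons):
        validate_intervals(t, chrom_sizes)
    merged = merge_tracks(tracks)
    cleaned = remove_or_split_by_blacklist(merged, insulators, exons,
                                           insulator_frac=insulator_frac, exon_frac=exon_frac)
    sized = filter_min_length(cleaned, min_len=min_len)
    blacklist = merge_tracks([t for t in (insulators, exons) if len(_as_frame(t))])
    extended = extend_regions(sized, blacklist, chrom_sizes, target_len=target_len)
    params = {"min_len": min_len, "target_len": target_len,
              "insulator_frac": insulator_frac, "exon_frac": exon_frac}
    return RegionCatalog(extended, provenance=list(provenance or []), build_params=params)
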