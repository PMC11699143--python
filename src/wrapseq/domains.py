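"""Segment wrapping-index tracks into domains and compare domain sets.

A Nucleosome Wrapping Domain (NRD) is a maximal genomic run of same-sign
smoothed NRI: TiNRDs (positive, tightly wrapped) alternate with LoNRDs
(negative, loosely wrapped). The same sign-based segmentation serves for
replication-timing domains (early/late) and can be compared against
externally supplied Hi-C A/B compartments via overlap-fraction matrices
and border-centred meta-profiles.

Segmentation contract (deterministic, per chromosome):

1. smooth the track (optional, Loess over ``smooth_span`` bins);
2. assign each covered bin a sign; exact zeros take the sign of the
   nearest non-zero bin, ties broken toward the left neighbour;
3. maximal constant-sign runs become candidate domains;
4. runs shorter than ``min_size_bp`` are absorbed — shortest first,
   leftmost on ties — into the flanking run with the larger absolute
   mean signal, until all surviving runs reach the minimum size or a
   segment consists of a single run;
5. missing-bin gaps of one bin are bridged (the gap bin follows its left
   neighbour); longer gaps split segments and never host domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .wrapmetrics import SignalTrack, loess_smooth

__all__ = [
    "Domain",
    "DomainSet",
    "BorderProfile",
    "call_domains",
    "overlap_fraction",
    "list_borders",
    "border_profile",
    "region_profile",
    "read_bed4",
    "write_bed4",
]

_DOM_COLS = ["chrom", "start", "end", "label", "score"]


@dataclass(frozen=True)
class Domain:
    chrom: str
    start: int
    end: int
    label: str
    score: float = float("nan")

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"domain end <= start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DomainSet:
    """Sorted, non-overlapping labelled intervals with a two-label set."""

    frame: pd.DataFrame
    label_set: tuple[str, str]
    provenance: str = ""

    def __post_init__(self):
        df = self.frame.reset_index(drop=True)
        for col in ("chrom", "start", "end", "label"):
            if col not in df.columns:
                raise ValueError(f"domain frame lacks column {col!r}")
        if "score" not in df.columns:
            df = df.assign(score=np.nan)
        if len(df):
            if (df["end"] <= df["start"]).any():
                raise ValueError("domain with end <= start")
            bad = set(df["label"].unique()) - set(self.label_set)
            if bad:
                raise ValueError(f"labels {sorted(bad)} outside label set {self.label_set}")
            for chrom, sub in df.groupby("chrom", sort=False):
                s = sub.sort_values("start")
                if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                    raise ValueError(f"overlapping domains on {chrom}")
                # maximality: contiguous neighbours must alternate labels
                touch = s["start"].to_numpy()[1:] == s["end"].to_numpy()[:-1]
                same = s["label"].to_numpy()[1:] == s["label"].to_numpy()[:-1]
                if (touch & same).any():
                    raise ValueError(f"adjacent same-label domains on {chrom} (not maximal)")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield Domain(row.chrom, int(row.start), int(row.end), row.label,
                         float(row.score))

    def total_bp(self, label: str | None = None) -> int:
        df = self.frame
        if label is not None:
            df = df[df["label"] == label]
        return int((df["end"] - df["start"]).sum())

    def median_length(self, label: str | None = None) -> float:
        df = self.frame
        if label is not None:
            df = df[df["label"] == label]
        return float((df["end"] - df["start"]).median())


@dataclass
class BorderProfile:
    """Per-border track windows around domain borders.

    ``matrix`` rows are borders, columns run upstream to downstream across
    the border in first-label to second-label reading order; ``offsets``
    gives each column's bp offset of the column start relative to the
    border.
    """

    matrix: np.ndarray
    offsets: np.ndarray
    flank_bp: int
    bin_bp: int
    border_type: str = ""

    def mean_profile(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.matrix, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.offsets)


# -- segmentation ----------------------------------------------------------

def _assign_signs(vals: np.ndarray) -> np.ndarray:
    """Signs of a fully covered segment; zeros take nearest non-zero sign."""
    signs = np.sign(vals).astype(int)
    zeros = np.flatnonzero(signs == 0)
    if len(zeros) == 0:
        return signs
    nonzero = np.flatnonzero(signs != 0)
    if len(nonzero) == 0:
        return signs  # all-zero segment: caller drops it
    for i in zeros:
        prev = nonzero[nonzero < i]
        nxt = nonzero[nonzero > i]
        if len(prev) == 0:
            signs[i] = signs[nxt[0]]
        elif len(nxt) == 0:
            signs[i] = signs[prev[-1]]
        else:
            dl, dr = i - prev[-1], nxt[0] - i
            signs[i] = signs[prev[-1]] if dl <= dr else signs[nxt[0]]
    return signs


def _runs(signs: np.ndarray) -> list[list[int]]:
    """Maximal constant-sign runs as [start, stop, sign] (stop exclusive)."""
    runs = []
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            runs.append([start, i, int(signs[start])])
            start = i
    return runs


def segment_signs(
    signs: np.ndarray, vals: np.ndarray, min_size_bins: int
) -> list[tuple[int, int, int]]:
    """Absorb sub-minimum runs; returns final (start, stop, sign) runs.

    Deterministic: at each step the shortest (ties: leftmost) run below
    ``min_size_bins`` is merged into the flanking run with the larger
    absolute mean of ``vals`` (ties: left flank); same-sign neighbours then
    coalesce. A segment reduced to a single run is kept regardless of size.
    """
    runs = _runs(signs)
    while len(runs) > 1:
        lens = [stop - start for start, stop, _ in runs]
        short = [i for i, l in enumerate(lens) if l < min_size_bins]
        if not short:
            break
        i = min(short, key=lambda j: (lens[j], j))
        if i == 0:
            target = 1
        elif i == len(runs) - 1:
            target = i - 1
        else:
            left_mean = abs(np.nanmean(vals[runs[i - 1][0]:runs[i - 1][1]]))
            right_mean = abs(np.nanmean(vals[runs[i + 1][0]:runs[i + 1][1]]))
            target = i - 1 if left_mean >= right_mean else i + 1
        runs[i][2] = runs[target][2]
        # coalesce same-sign neighbours
        merged: list[list[int]] = []
        for run in runs:
            if merged and merged[-1][2] == run[2]:
                merged[-1][1] = run[1]
            else:
                merged.append(run)
        runs = merged
    return [(s, e, sg) for s, e, sg in runs]


def call_domains(
    track: SignalTrack,
    min_size_bp: int = 300_000,
    smooth_span: int = 10,
    labels: tuple[str, str] = ("Ti", "Lo"),
    provenance: str = "",
) -> DomainSet:
    """Call alternating sign domains on a (wrapping-index) track.

    *labels* maps (positive, negative) signs; the default Ti/Lo names
    tight and loose nucleosome wrapping domains. ``smooth_span=0`` skips
    internal smoothing for pre-smoothed input. ``min_size_bp`` is the
    absorption threshold of step 4 (default 300 kb, i.e. 3 bins at the
    100 kb default grid).
    """
    if not track.defined_mask().any():
        raise ValueError("all-missing track: nothing to segment")
    smoothed = loess_smooth(track, smooth_span) if smooth_span else track
    layout = track.layout
    bs = layout.bin_size
    min_size_bins = max(1, -(-min_size_bp // bs))
    pos_label, neg_label = labels
    rows = []
    for chrom, chrom_len in layout.chromosomes:
        sl = layout.chrom_slice(chrom)
        vals = smoothed.values[sl].copy()
        covered = ~np.isnan(vals)
        if not covered.any():
            continue
        # bridge single-bin gaps: interior missing bins flanked by covered
        # bins on both sides inherit the left neighbour's value
        gaps = np.flatnonzero(~covered)
        for g in gaps:
            if 0 < g < len(vals) - 1 and covered[g - 1] and covered[g + 1]:
                vals[g] = vals[g - 1]
                covered[g] = True
        # split into segments at remaining gaps
        boundaries = np.flatnonzero(np.diff(covered.astype(int)))
        seg_edges = np.concatenate([[0], boundaries + 1, [len(vals)]])
        for a, b in zip(seg_edges[:-1], seg_edges[1:]):
            if not covered[a]:
                continue
            seg_vals = vals[a:b]
            signs = _assign_signs(seg_vals)
            if (signs == 0).all():
                continue
            for s, e, sign in segment_signs(signs, seg_vals, min_size_bins):
                start_bp = (a + s) * bs
                end_bp = min((a + e) * bs, chrom_len)
                rows.append({
                    "chrom": chrom,
                    "start": start_bp,
                    "end": end_bp,
                    "label": pos_label if sign > 0 else neg_label,
                    "score": float(np.nanmean(seg_vals[s:e])),
                })
    return DomainSet(pd.DataFrame(rows, columns=_DOM_COLS), labels, provenance)


# -- domain comparisons ----------------------------------------------------

def _intersect_bp(a: np.ndarray, b: np.ndarray) -> int:
    """Total bp intersection of two sorted non-overlapping interval arrays."""
    total = i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def overlap_fraction(query: DomainSet, reference: DomainSet) -> pd.DataFrame:
    """Fraction of each reference label's bp overlapped by each query label.

    Entry (row r, column q) = bp of r-labelled reference domains covered
    by q-labelled query domains, divided by total bp of r. Row sums are
    <= 1 (strictly < 1 where the reference extends into genome the query
    does not cover).
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("empty DomainSet")
    mat = pd.DataFrame(
        0.0, index=list(reference.label_set), columns=list(query.label_set)
    )
    for r in reference.label_set:
        rdf = reference.frame[reference.frame["label"] == r]
        denom = float((rdf["end"] - rdf["start"]).sum())
        if denom == 0:
            mat.loc[r] = np.nan
            continue
        for q in query.label_set:
            qdf = query.frame[query.frame["label"] == q]
            inter = 0
            for chrom in rdf["chrom"].unique():
                a = rdf[rdf["chrom"] == chrom].sort_values("start")[["start", "end"]].to_numpy()
                bsub = qdf[qdf["chrom"] == chrom].sort_values("start")[["start", "end"]].to_numpy()
                if len(a) and len(bsub):
                    inter += _intersect_bp(a, bsub)
            mat.loc[r, q] = inter / denom
    mat.index.name = "reference"
    mat.columns.name = "query"
    return mat


def list_borders(ds: DomainSet, orientation: tuple[str, str]) -> pd.DataFrame:
    """Positions where a *first*-label domain abuts a *second*-label domain.

    Only shared boundaries count: junctions across assembly gaps and
    chromosome ends are not borders. Returns a frame (chrom, pos).
    """
    first, second = orientation
    rows = []
    for chrom, sub in ds.frame.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        for (_, d1), (_, d2) in zip(s.iterrows(), s.iloc[1:].iterrows()):
            if d1["end"] == d2["start"] and d1["label"] == first and d2["label"] == second:
                rows.append({"chrom": chrom, "pos": int(d1["end"])})
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def border_profile(
    track: SignalTrack,
    borders: pd.DataFrame,
    flank_bp: int,
    reverse: bool = False,
    border_type: str = "",
    exclude_partial_bins: bool = True,
) -> BorderProfile:
    """Extract track windows of ±``flank_bp`` around each border.

    Windows run ``[border - flank, border + flank)`` left to right; with
    ``reverse=True`` each row is flipped (use for the opposite border
    orientation so columns always read first-label to second-label).
    Windows exceeding the chromosome are padded with missing values;
    partial terminal bins are masked by default to avoid edge artifacts.
    """
    if len(borders) == 0:
        raise ValueError("no borders supplied")
    bs = track.layout.bin_size
    if flank_bp % bs:
        raise ValueError(f"flank_bp ({flank_bp}) must be a multiple of bin size ({bs})")
    f = flank_bp // bs
    vals = track.values.copy()
    if exclude_partial_bins:
        vals[track.layout.partial_bin_mask()] = np.nan
    mat = np.full((len(borders), 2 * f), np.nan)
    for row, (chrom, pos) in enumerate(zip(borders["chrom"], borders["pos"])):
        sl = track.layout.chrom_slice(chrom)
        nb = sl.stop - sl.start
        center = int(pos) // bs  # border lies on a bin boundary
        lo, hi = center - f, center + f
        src_lo, src_hi = max(lo, 0), min(hi, nb)
        if src_hi > src_lo:
            mat[row, src_lo - lo : src_hi - lo] = vals[sl.start + src_lo : sl.start + src_hi]
    if reverse:
        mat = mat[:, ::-1]
    offsets = (np.arange(2 * f) - f) * bs
    return BorderProfile(mat, offsets, flank_bp, bs, border_type)


def region_profile(
    track: SignalTrack,
    regions: pd.DataFrame,
    mode: str = "scaled-body",
    n_cols: int = 100,
    flank_bp: int = 2000,
    anchor: str = "start",
    scores: np.ndarray | None = None,
) -> np.ndarray:
    """Per-region track profiles (deeptools-style matrix).

    ``scaled-body`` rescales each region to *n_cols* columns, each the mean
    of the track bins overlapping its bp span. ``anchored`` centres on the
    region start (TSS) or end (TTS) with a fixed ±``flank_bp`` window at
    track resolution. Minus-strand regions are reversed so columns always
    read 5'→3'. Rows are optionally sorted by *scores* descending. Regions
    on chromosomes absent from the layout are skipped with a warning.
    """
    import warnings

    if mode not in ("scaled-body", "anchored"):
        raise ValueError(f"unknown mode {mode!r}")
    if anchor not in ("start", "end"):
        raise ValueError(f"anchor must be 'start' or 'end', got {anchor!r}")
    layout = track.layout
    bs = layout.bin_size
    strands = regions["strand"] if "strand" in regions.columns else pd.Series(
        ["+"] * len(regions), index=regions.index
    )
    if mode == "anchored":
        if flank_bp % bs:
            raise ValueError(f"flank_bp must be a multiple of bin size ({bs})")
        width = 2 * (flank_bp // bs)
    else:
        width = n_cols
    rows = []
    keep_idx = []
    for idx, (chrom, start, end, strand) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"], strands)
    ):
        if chrom not in layout.names:
            warnings.warn(f"region on unknown chromosome {chrom!r} skipped", stacklevel=2)
            continue
        sl = layout.chrom_slice(chrom)
        nb = sl.stop - sl.start
        start, end = int(start), int(end)
        if mode == "anchored":
            f = flank_bp // bs
            if (anchor == "start") == (strand != "-"):
                center = start // bs
            else:
                center = end // bs
            lo, hi = center - f, center + f
            row = np.full(width, np.nan)
            src_lo, src_hi = max(lo, 0), min(hi, nb)
            if src_hi > src_lo:
                row[src_lo - lo : src_hi - lo] = track.values[
                    sl.start + src_lo : sl.start + src_hi
                ]
        else:
            edges = start + (end - start) * np.arange(width + 1) / width
            row = np.empty(width)
            for j in range(width):
                b0 = int(edges[j]) // bs
                b1 = min(int(np.ceil(edges[j + 1])) - 1, nb * bs - 1) // bs
                chunk = track.values[sl.start + b0 : sl.start + min(b1 + 1, nb)]
                row[j] = np.nanmean(chunk) if np.isfinite(chunk).any() else np.nan
        if strand == "-":
            row = row[::-1]
        rows.append(row)
        keep_idx.append(idx)
    mat = np.array(rows) if rows else np.empty((0, width))
    if scores is not None and len(mat):
        order = np.argsort(-np.asarray(scores)[keep_idx], kind="stable")
        mat = mat[order]
    return mat


# -- BED I/O ---------------------------------------------------------------

def write_bed4(ds: DomainSet, path) -> None:
    ds.frame[["chrom", "start", "end", "label"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed4(path, label_set: tuple[str, str], provenance: str = "") -> DomainSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "label"],
                     dtype={0: str, 3: str})
    return DomainSet(df, label_set, provenance=provenance or str(path))
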