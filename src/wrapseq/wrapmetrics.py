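"""Per-bin fragment counting and the wrapping metrics NRS and NRI.

The Nucleosome Wrapping Score of a genomic bin is

    NRS(X) = (a - b) / (a + b)

where ``a`` counts fragments at least as long as the break point ``X``
(wrapped, nucleosome-protected) and ``b`` counts shorter fragments
(partially unwrapped). NRS is an absolute measure and shifts with MNase
digestion time; the Nucleosome Wrapping Index (NRI) is the genome-wide
z-score of NRS, a relative measure that is robust to both digestion
extent and the choice of break point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragio import UNGROUPED, FragmentSet, LengthGroupScheme, classify_lengths
from .layout import GenomeLayout

__all__ = [
    "BinCountMatrix",
    "SignalTrack",
    "count_fragments",
    "nrs",
    "nri",
    "loess_smooth",
    "correlate_tracks",
    "normalize_by",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class SignalTrack:
    """One float per bin of a :class:`GenomeLayout`; NaN marks missing.

    Missing values propagate through every operation — they are never
    silently zero-filled.
    """

    layout: GenomeLayout
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.layout.n_bins,):
            raise ValueError(
                f"track length {v.shape} does not match layout bin count "
                f"({self.layout.n_bins},)"
            )
        self.values = v

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.layout.chrom_slice(chrom)]

    def copy_with(self, values: np.ndarray) -> "SignalTrack":
        return SignalTrack(self.layout, np.asarray(values, dtype=float))


@dataclass
class BinCountMatrix:
    """Bins x length-group fragment counts on one layout/scheme pair."""

    layout: GenomeLayout
    scheme: LengthGroupScheme
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        expect = (self.layout.n_bins, self.scheme.n_groups)
        if c.shape != expect:
            raise ValueError(f"count matrix shape {c.shape}, expected {expect}")
        if (c < 0).any():
            raise ValueError("negative counts")
        self.counts = c.astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        df = self.layout.bins_frame()
        for j, label in enumerate(self.scheme.group_labels()):
            df[label] = self.counts[:, j]
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def count_fragments(
    frags: FragmentSet,
    layout: GenomeLayout,
    scheme: LengthGroupScheme,
    mode: str = "any-overlap",
) -> BinCountMatrix:
    """Count fragments per bin per length group.

    ``mode='any-overlap'`` (default) increments every bin a fragment
    overlaps by at least 1 bp, matching bedtools-style annotation;
    ``mode='midpoint'`` assigns each fragment to the single bin holding
    its midpoint. Fragments whose length falls outside the scheme are
    ignored.
    """
    if mode not in ("any-overlap", "midpoint"):
        raise ValueError(f"unknown counting mode {mode!r}")
    unknown = set(frags.frame["chrom"].unique()) - set(layout.names)
    if unknown:
        raise ValueError(f"fragment chromosomes absent from layout: {sorted(unknown)}")
    counts = np.zeros((layout.n_bins, scheme.n_groups), dtype=np.int64)
    if len(frags) == 0:
        return BinCountMatrix(layout, scheme, counts)
    bs = layout.bin_size
    df = frags.frame.assign(_group=classify_lengths(frags, scheme))
    df = df[df["_group"] != UNGROUPED]
    for chrom, sel in df.groupby("chrom", sort=False, observed=True):
        start = sel["start"].to_numpy()
        end = sel["end"].to_numpy()
        g = sel["_group"].to_numpy()
        off = layout.chrom_offset(chrom)
        nb = layout.n_bins_chrom(chrom)
        if mode == "midpoint":
            bins = np.minimum((start + end) // 2 // bs, nb - 1)
            np.add.at(counts, (off + bins, g), 1)
        else:
            first = start // bs
            last = np.minimum((end - 1) // bs, nb - 1)
            span = last - first + 1
            total = int(span.sum())
            # flat indices: repeat each fragment's first bin, add 0..span-1
            reps = np.repeat(first, span)
            ramp = np.arange(total) - np.repeat(np.cumsum(span) - span, span)
            np.add.at(counts, (off + reps + ramp, np.repeat(g, span)), 1)
    return BinCountMatrix(layout, scheme, counts)


def nrs(counts: BinCountMatrix, breakpoint: int = 140, min_total: int = 1) -> SignalTrack:
    """Nucleosome wrapping score per bin: (a - b)/(a + b).

    ``a`` sums the length groups at or above *breakpoint*, ``b`` the groups
    below it; the break point must be a boundary of the counting scheme.
    Bins with ``a + b < min_total`` are missing (default: only empty bins).
    """
    split = counts.scheme.group_of_breakpoint(breakpoint)
    a = counts.counts[:, split:].sum(axis=1).astype(float)
    b = counts.counts[:, :split].sum(axis=1).astype(float)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (a - b) / total
    values[total < max(min_total, 1)] = np.nan
    return SignalTrack(counts.layout, values)


def nri(nrs_track: SignalTrack, per_chromosome: bool = False) -> SignalTrack:
    """Nucleosome wrapping index: z-score of NRS over non-missing bins.

    Pooled genome-wide by default (population standard deviation,
    divisor n). Missing bins stay missing.
    """
    out = np.full_like(nrs_track.values, np.nan)

    def _z(vals: np.ndarray) -> np.ndarray:
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            raise ValueError("need >= 2 non-missing bins to z-score")
        mu = vals[ok].mean()
        sigma = vals[ok].std()  # population (ddof=0)
        if sigma == 0:
            raise ValueError("degenerate track: zero standard deviation")
        res = np.full_like(vals, np.nan)
        res[ok] = (vals[ok] - mu) / sigma
        return res

    if per_chromosome:
        for chrom in nrs_track.layout.names:
            sl = nrs_track.layout.chrom_slice(chrom)
            out[sl] = _z(nrs_track.values[sl])
    else:
        out = _z(nrs_track.values)
    return nrs_track.copy_with(out)


def _loess_1d(x: np.ndarray, y: np.ndarray, span: int) -> np.ndarray:
    """Degree-1 local regression with tricube weights, k-nearest window.

    x must be sorted and distinct (bin indices). Returns the fit at each x.
    """
    m = len(x)
    out = np.empty(m)
    lo = 0
    for i in range(m):
        # slide the contiguous window of `span` points to minimize the
        # maximum distance from x[i]
        hi = lo + span
        while hi < m and x[hi] - x[i] < x[i] - x[lo]:
            lo += 1
            hi += 1
        xw = x[lo:hi].astype(float)
        yw = y[lo:hi]
        d = np.abs(xw - x[i])
        dmax = d.max()
        if dmax == 0:
            out[i] = yw[d == 0].mean()
            continue
        w = (1 - (d / dmax) ** 3) ** 3
        sw = w.sum()
        xm = (w * xw).sum() / sw
        ym = (w * yw).sum() / sw
        sxx = (w * (xw - xm) ** 2).sum()
        if sxx <= 0:
            out[i] = ym
        else:
            beta = (w * (xw - xm) * (yw - ym)).sum() / sxx
            out[i] = ym + beta * (x[i] - xm)
    return out


def loess_smooth(track: SignalTrack, span_bins: int = 10) -> SignalTrack:
    """Loess-smooth a track per chromosome with a *span_bins*-wide window.

    Local linear regression (degree 1, tricube weights) over the
    ``span_bins`` nearest non-missing neighbours of each bin. Smoothing
    never crosses chromosome ends; missing bins stay missing. A chromosome
    with fewer non-missing bins than the span passes through unsmoothed
    (with a warning).
    """
    if span_bins < 2:
        raise ValueError(f"span_bins must be >= 2, got {span_bins}")
    out = track.values.copy()
    for chrom in track.layout.names:
        sl = track.layout.chrom_slice(chrom)
        vals = track.values[sl]
        ok = np.flatnonzero(~np.isnan(vals))
        if len(ok) == 0:
            continue
        if len(ok) < span_bins:
            warnings.warn(
                f"{chrom}: {len(ok)} non-missing bins < span {span_bins}; "
                "passed through unsmoothed",
                stacklevel=2,
            )
            continue
        out[sl.start + ok] = _loess_1d(ok, vals[ok], span_bins)
    return track.copy_with(out)


def correlate_tracks(x: SignalTrack, y: SignalTrack) -> tuple[float, int]:
    """Pearson correlation over bins non-missing in both tracks.

    Returns ``(r, n)`` where n is the number of bins used.
    """
    if x.layout != y.layout:
        raise ValueError("tracks are on different layouts")
    ok = x.defined_mask() & y.defined_mask()
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"only {n} jointly non-missing bins; need >= 3")
    xv, yv = x.values[ok], y.values[ok]
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance in one of the tracks")
    from scipy.stats import pearsonr

    r = float(pearsonr(xv, yv).statistic)
    return r, n


def normalize_by(
    track: SignalTrack, denom: SignalTrack, pseudocount: float = 0.0
) -> SignalTrack:
    """Per-bin ratio (track + pc) / (denom + pc).

    Bins where the denominator is missing, or zero with pseudocount 0,
    become missing. Used e.g. to normalize histone-modification signal by
    total histone signal to account for nucleosome-density variation.
    """
    if track.layout != denom.layout:
        raise ValueError("tracks are on different layouts")
    num = track.values + pseudocount
    den = denom.values + pseudocount
    with np.errstate(invalid="ignore", divide="ignore"):
        values = num / den
    values[den == 0] = np.nan
    values[denom.missing_mask()] = np.nan
    return track.copy_with(values)


# -- track I/O --------------------------------------------------------------

def write_bedgraph(track: SignalTrack, path) -> None:
    """Write non-missing bins as bedGraph (chrom, start, end, value)."""
    df = track.layout.bins_frame()
    df["value"] = track.values
    df[df["value"].notna()].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path, layout: GenomeLayout) -> SignalTrack:
    """Read a bedGraph onto a layout's grid.

    Each record's value is assigned to every bin it overlaps; bins not
    covered by any record are missing.
    """
    values = np.full(layout.n_bins, np.nan)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"],
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        return SignalTrack(layout, values)
    bs = layout.bin_size
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in layout._offsets:
            continue
        off = layout.chrom_offset(chrom)
        nb = layout.n_bins_chrom(chrom)
        for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
            first = int(start) // bs
            last = min((int(end) - 1) // bs, nb - 1)
            values[off + first : off + last + 1] = value
    return SignalTrack(layout, values)


def write_bigwig(track: SignalTrack, path) -> None:
    """Write non-missing bins to a bigWig file (requires pyBigWig)."""
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    bw.addHeader(list(track.layout.chromosomes))
    df = track.layout.bins_frame()
    df["value"] = track.values
    df = df[df["value"].notna()]
    for chrom, sub in df.groupby("chrom", sort=False):
        bw.addEntries(
            [chrom] * len(sub),
            sub["start"].astype(int).tolist(),
            ends=sub["end"].astype(int).tolist(),
            values=sub["value"].astype(float).tolist(),
        )
    bw.close()
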