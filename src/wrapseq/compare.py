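"""Condition and region comparisons of wrapping state.

Two analyses: fragment-length histograms (and region-restricted NRS)
inside peak/region BEDs, and parental-versus-nascent NRS differencing
per domain — the readout used to show that nascent chromatin starts out
loosely wrapped under pulse labelling and overshoots during the chase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import DomainSet
from .fragio import FragmentSet
from .wrapmetrics import SignalTrack

__all__ = ["LengthHistogram", "region_length_histogram", "nrs_difference"]


@dataclass
class LengthHistogram:
    """Fragment-length histogram for one region set.

    ``edges`` are 1 bp-wide bin edges spanning the retained length range;
    ``counts`` the per-bin tallies. ``nrs`` is the wrapping score computed
    directly from the member fragments' lengths at ``breakpoint``.
    """

    edges: np.ndarray
    counts: np.ndarray
    region_label: str
    breakpoint: int
    nrs: float

    def density(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty histogram")
        return self.counts / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"length": self.edges[:-1], "count": self.counts})


def _merge_regions(regions: pd.DataFrame) -> pd.DataFrame:
    merged = []
    for chrom, sub in regions.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        cur_start = cur_end = None
        for start, end in zip(s["start"], s["end"]):
            if cur_end is not None and start < cur_end:
                warnings.warn("overlapping regions merged", stacklevel=3)
                cur_end = max(cur_end, end)
            elif cur_end is not None and start == cur_end:
                cur_end = end
            else:
                if cur_start is not None:
                    merged.append((chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        if cur_start is not None:
            merged.append((chrom, cur_start, cur_end))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def region_length_histogram(
    frags: FragmentSet,
    regions: pd.DataFrame,
    breakpoint: int = 140,
    region_label: str = "",
) -> LengthHistogram:
    """Length histogram (1 bp bins) of fragments with midpoints in regions.

    Membership is by fragment midpoint with half-open intervals. The
    returned histogram also carries NRS(breakpoint) computed from the
    member fragments directly (a = lengths >= breakpoint, b = shorter) —
    peak regions are far below track-bin scale, so the score is built from
    fragments, not from a binned track.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    regions = _merge_regions(regions[["chrom", "start", "end"]])
    mids = frags.midpoints()
    fr = frags.frame
    member = np.zeros(len(frags), dtype=bool)
    for chrom, sub in regions.groupby("chrom", sort=False):
        sel = (fr["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        m = mids[sel]
        inside = np.searchsorted(starts, m, side="right") > np.searchsorted(
            ends, m, side="right"
        )
        member[np.flatnonzero(sel)] = inside
    lengths = frags.lengths[member]
    if len(lengths):
        lo, hi = int(lengths.min()), int(lengths.max())
    else:
        lo, hi = 0, 0
    edges = np.arange(lo, hi + 2)
    counts, _ = np.histogram(lengths, bins=edges)
    a = int((lengths >= breakpoint).sum())
    b = int((lengths < breakpoint).sum())
    score = (a - b) / (a + b) if (a + b) else np.nan
    return LengthHistogram(edges, counts, region_label, breakpoint, score)


def nrs_difference(
    parental: SignalTrack,
    nascent: SignalTrack,
    domains: DomainSet,
    mode: str = "bin-mean",
) -> pd.DataFrame:
    """Per-domain difference of nascent minus parental NRS.

    For every domain, bins missing in either track are excluded from both
    means (bin-level pairing); delta = mean(nascent) - mean(parental).
    Returns a table (chrom, start, end, label, parental_mean,
    nascent_mean, delta); a domain with no paired bin gets NaN and a
    warning. Antisymmetric under swapping the two tracks.
    """
    if mode != "bin-mean":
        raise ValueError(f"unknown mode {mode!r}")
    if parental.layout != nascent.layout:
        raise ValueError("tracks are on different layouts")
    layout = parental.layout
    bs = layout.bin_size
    rows = []
    for dom in domains:
        sl = layout.chrom_slice(dom.chrom)
        b0 = dom.start // bs
        b1 = -(-dom.end // bs)  # ceil: include partial last bin
        p = parental.values[sl.start + b0 : sl.start + min(b1, sl.stop - sl.start)]
        n = nascent.values[sl.start + b0 : sl.start + min(b1, sl.stop - sl.start)]
        ok = ~np.isnan(p) & ~np.isnan(n)
        if ok.any():
            pm, nm = float(p[ok].mean()), float(n[ok].mean())
            delta = nm - pm
        else:
            warnings.warn(
                f"domain {dom.chrom}:{dom.start}-{dom.end} has no paired bins",
                stacklevel=2,
            )
            pm = nm = delta = np.nan
        rows.append({
            "chrom": dom.chrom, "start": dom.start, "end": dom.end,
            "label": dom.label, "parental_mean": pm, "nascent_mean": nm,
            "delta": delta,
        })
    return pd.DataFrame(rows)
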