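"""Replication timing from four FACS-sorted S-phase fraction libraries.

Cells sorted into early-to-late S-phase fractions S1-S4 yield one fragment
library each; after scaling every library to 1 million fragments, the
replication timing of a bin is

    RT = log2((S1' + S2') / (S3' + S4'))

positive where the locus replicates early, negative where late. RT tracks
are typically quantile-normalized to a common target distribution before
comparing samples, and segmented into early/late domains with the same
sign-based caller used for nucleosome wrapping domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import DomainSet, call_domains
from .fragio import FragmentSet
from .layout import GenomeLayout
from .wrapmetrics import SignalTrack

__all__ = ["RTFractionCounts", "rt_score", "quantile_normalize", "rt_domains"]

FRACTIONS = ("S1", "S2", "S3", "S4")


@dataclass
class RTFractionCounts:
    """Per-bin fragment counts for the four S-phase fractions.

    ``counts`` has one column per fraction in S1..S4 order;
    ``library_totals`` are the sequencing depths used for per-million
    scaling (they may exceed the column sums when fragments fell outside
    the layout).
    """

    layout: GenomeLayout
    counts: np.ndarray
    library_totals: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (self.layout.n_bins, 4):
            raise ValueError(
                f"counts shape {c.shape}, expected ({self.layout.n_bins}, 4)"
            )
        if (c < 0).any():
            raise ValueError("negative counts")
        t = np.asarray(self.library_totals, dtype=float)
        if t.shape != (4,):
            raise ValueError("library_totals must have one entry per fraction")
        self.counts = c.astype(np.int64)
        self.library_totals = t

    @classmethod
    def from_fragment_sets(
        cls, layout: GenomeLayout, s1: FragmentSet, s2: FragmentSet,
        s3: FragmentSet, s4: FragmentSet,
    ) -> "RTFractionCounts":
        """Count fragment midpoints per bin for each fraction."""
        bs = layout.bin_size
        counts = np.zeros((layout.n_bins, 4), dtype=np.int64)
        totals = np.zeros(4)
        for j, fs in enumerate((s1, s2, s3, s4)):
            totals[j] = len(fs)
            df = fs.frame
            for chrom, sub in df.groupby("chrom", sort=False):
                off = layout.chrom_offset(chrom)
                nb = layout.n_bins_chrom(chrom)
                mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
                bins = np.minimum(mids // bs, nb - 1)
                np.add.at(counts[:, j], off + bins, 1)
        return cls(layout, counts, totals)

    @classmethod
    def from_tsv(cls, path, layout: GenomeLayout) -> "RTFractionCounts":
        """Read a per-bin count table (chrom, start, end, S1..S4)."""
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in FRACTIONS if c not in df.columns]
        if missing:
            raise ValueError(f"count table lacks columns {missing}")
        if len(df) != layout.n_bins:
            raise ValueError(
                f"count table has {len(df)} rows, layout has {layout.n_bins} bins"
            )
        counts = df[list(FRACTIONS)].to_numpy()
        return cls(layout, counts, counts.sum(axis=0).astype(float))


def rt_score(rc: RTFractionCounts) -> SignalTrack:
    """Replication timing per bin: log2 early/late ratio of scaled counts.

    Each fraction is scaled to one million fragments first; bins where the
    early (S1'+S2') or late (S3'+S4') sum is zero are missing. No
    pseudocount is applied.
    """
    if (rc.library_totals <= 0).any():
        bad = [FRACTIONS[i] for i in np.flatnonzero(rc.library_totals <= 0)]
        raise ValueError(f"fractions with zero library total: {bad}")
    scaled = rc.counts * (1e6 / rc.library_totals)
    early = scaled[:, 0] + scaled[:, 1]
    late = scaled[:, 2] + scaled[:, 3]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2(early / late)
    values[(early == 0) | (late == 0)] = np.nan
    return SignalTrack(rc.layout, values)


def quantile_normalize(track: SignalTrack, target: np.ndarray) -> SignalTrack:
    """Map non-missing values onto a target distribution by rank.

    The value of rank r among n non-missing values is replaced by the
    target's empirical quantile at probability (r - 0.5)/n, linearly
    interpolated; tied input values receive the mean of their mapped
    values, so the transform is rank-preserving (monotone). Missing bins
    stay missing.
    """
    target = np.asarray(target, dtype=float)
    if target.size == 0:
        raise ValueError("empty target")
    if (np.diff(target) < 0).any():
        raise ValueError("target must be sorted ascending")
    ok = track.defined_mask()
    n = int(ok.sum())
    if n < 2:
        raise ValueError(f"only {n} non-missing values; need >= 2")
    vals = track.values[ok]
    order = np.argsort(vals, kind="stable")
    m = len(target)
    probs = (np.arange(1, n + 1) - 0.5) / n
    tprobs = (np.arange(1, m + 1) - 0.5) / m
    mapped_sorted = np.interp(probs, tprobs, target)
    # average mapped values within groups of tied input values
    sorted_vals = vals[order]
    new_group = np.concatenate([[True], np.diff(sorted_vals) != 0])
    tie_ids = np.cumsum(new_group) - 1
    tie_means = np.bincount(tie_ids, weights=mapped_sorted) / np.bincount(tie_ids)
    mapped = np.empty(n)
    mapped[order] = tie_means[tie_ids]
    out = np.full_like(track.values, np.nan)
    out[ok] = mapped
    return track.copy_with(out)


def rt_domains(
    rt: SignalTrack, min_size_bp: int = 300_000, smooth_span: int = 10
) -> DomainSet:
    """Early/late replication-timing domains via sign segmentation."""
    return call_domains(
        rt, min_size_bp=min_size_bp, smooth_span=smooth_span,
        labels=("early", "late"), provenance="replication timing",
    )
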