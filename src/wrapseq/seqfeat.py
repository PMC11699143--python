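"""Sequence-composition diagnostics for MNase cut-site bias.

MNase prefers to cut in A/T-rich sequence, so fragment ends carry a
composition signature and fragment length can correlate with base
content. These helpers quantify that: A/T-content tracks, per-fragment
dinucleotide frequencies, base-frequency profiles around cut sites, and
composition-versus-length correlations (optionally within one domain
class). All statistics are computed on the top strand; N bases are
excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import DomainSet
from .fragio import FragmentSet
from .layout import GenomeLayout
from .wrapmetrics import SignalTrack

__all__ = [
    "BaseFrequencyMatrix",
    "at_content",
    "at_content_track",
    "dinucleotide_freq",
    "cut_site_profile",
    "length_composition_correlation",
]

_BASES = "ACGT"


def _fetch(source, chrom: str, start: int, end: int) -> str:
    """Top-strand sequence [start, end) from a FASTA handle or dict."""
    if isinstance(source, dict):
        try:
            return source[chrom][start:end].upper()
        except KeyError as exc:
            raise KeyError(f"contig {chrom!r} absent from sequence source") from exc
    try:
        record = source[chrom]
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} absent from sequence source") from exc
    return str(record[start:end]).upper()


def _contig_length(source, chrom: str) -> int:
    seq = source[chrom]
    return len(seq)


@dataclass
class BaseFrequencyMatrix:
    """Per-position base fractions around an anchor (e.g. a cut site).

    ``frequencies`` rows are relative offsets, columns A/C/G/T; at every
    position the four fractions sum to 1 after excluding N. ``n_fraction``
    reports the per-position share of N bases separately. ``n_sites`` is
    the number of anchors tallied, ``n_skipped`` those too close to a
    contig edge.
    """

    frequencies: pd.DataFrame
    n_fraction: np.ndarray
    n_sites: int
    n_skipped: int = 0

    def __post_init__(self):
        rowsum = self.frequencies[list(_BASES)].sum(axis=1).to_numpy()
        ok = np.isnan(rowsum) | (np.abs(rowsum - 1) < 1e-9)
        if not ok.all():
            raise ValueError("base fractions do not sum to 1 after N exclusion")

    def to_tsv(self, path) -> None:
        out = self.frequencies.copy()
        out["N_fraction"] = self.n_fraction
        out.index.name = "position"
        out.to_csv(path, sep="\t")


def at_content(source, intervals: pd.DataFrame | FragmentSet) -> np.ndarray:
    """A/T fraction among non-N bases per interval; all-N gives NaN."""
    df = intervals.frame if isinstance(intervals, FragmentSet) else intervals
    out = np.empty(len(df))
    for i, (chrom, start, end) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        seq = _fetch(source, chrom, int(start), int(end))
        denom = len(seq) - seq.count("N")
        out[i] = (seq.count("A") + seq.count("T")) / denom if denom else np.nan
    return out


def at_content_track(source, layout: GenomeLayout) -> SignalTrack:
    """A/T content per bin of a layout as a signal track."""
    values = at_content(source, layout.bins_frame())
    return SignalTrack(layout, values)


def dinucleotide_freq(
    source,
    frags: FragmentSet,
    dinucs: frozenset[str] | set[str] = frozenset({"AG", "TG", "CA", "CT"}),
) -> np.ndarray:
    """Per-fragment frequency of the requested dinucleotides.

    Counts matching top-strand 2-mers divided by the number of N-free
    2-mers in the fragment. Fragments shorter than 2 bp (or with no
    N-free 2-mer) give NaN.
    """
    dinucs = {d.upper() for d in dinucs}
    if any(len(d) != 2 for d in dinucs):
        raise ValueError("dinucleotides must be 2-mers")
    df = frags.frame
    out = np.empty(len(df))
    for i, (chrom, start, end) in enumerate(zip(df["chrom"], df["start"], df["end"])):
        if end - start < 2:
            out[i] = np.nan
            continue
        seq = _fetch(source, chrom, int(start), int(end))
        hits = denom = 0
        for j in range(len(seq) - 1):
            mer = seq[j : j + 2]
            if "N" in mer:
                continue
            denom += 1
            if mer in dinucs:
                hits += 1
        out[i] = hits / denom if denom else np.nan
    return out


def cut_site_profile(
    source, frags: FragmentSet, flank: int = 20
) -> tuple[BaseFrequencyMatrix, BaseFrequencyMatrix]:
    """Base-frequency profiles around fragment 5' and 3' cut sites.

    For every fragment the top-strand windows ``[start - flank,
    start + flank)`` and ``[end - flank, end + flank)`` are tallied into
    two matrices (5' ends, 3' ends). Sites closer than *flank* to a
    contig edge are skipped and counted in ``n_skipped``.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    width = 2 * flank
    base_ords = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    tallies = [np.zeros((width, 4), dtype=np.int64) for _ in range(2)]
    n_counts = [np.zeros(width, dtype=np.int64) for _ in range(2)]
    n_sites = [0, 0]
    n_skipped = [0, 0]
    df = frags.frame
    lengths: dict[str, int] = {}
    for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
        if chrom not in lengths:
            lengths[chrom] = _contig_length(source, chrom)
        clen = lengths[chrom]
        for side, site in enumerate((int(start), int(end))):
            if site - flank < 0 or site + flank > clen:
                n_skipped[side] += 1
                continue
            seq = _fetch(source, chrom, site - flank, site + flank)
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            tallies[side] += (arr[:, None] == base_ords[None, :]).astype(np.int64)
            n_counts[side] += arr == ord("N")
            n_sites[side] += 1
    out = []
    offsets = np.arange(-flank, flank)
    for side in range(2):
        if n_sites[side] == 0:
            raise ValueError("no usable cut sites (all too close to contig edges?)")
        acgt = tallies[side].astype(float)
        denom = acgt.sum(axis=1)
        with np.errstate(invalid="ignore"):
            freqs = acgt / denom[:, None]
        out.append(
            BaseFrequencyMatrix(
                frequencies=pd.DataFrame(freqs, index=offsets, columns=list(_BASES)),
                n_fraction=n_counts[side] / n_sites[side],
                n_sites=n_sites[side],
                n_skipped=n_skipped[side],
            )
        )
    return out[0], out[1]


def _midpoint_in_label(
    frags: FragmentSet, domains: DomainSet, label: str
) -> np.ndarray:
    """Mask of fragments whose midpoint falls in a *label* domain.

    Half-open membership: a midpoint exactly at a domain end is outside.
    """
    df = domains.frame[domains.frame["label"] == label]
    mask = np.zeros(len(frags), dtype=bool)
    fr = frags.frame
    mids = frags.midpoints()
    for chrom, sub in df.groupby("chrom", sort=False):
        sel = (fr["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        m = mids[sel]
        # domains are disjoint and sorted: midpoint is inside iff it has
        # entered more domains than it has left
        inside = np.searchsorted(starts, m, side="right") > np.searchsorted(
            ends, m, side="right"
        )
        mask[np.flatnonzero(sel)] = inside
    return mask


def length_composition_correlation(
    frags: FragmentSet,
    values: np.ndarray,
    domains: DomainSet | None = None,
    label: str | None = None,
) -> tuple[float, int]:
    """Pearson r between fragment length and a per-fragment statistic.

    Optionally restricted to fragments whose midpoint lies in domains of
    one label. NaN statistics are dropped. Returns ``(r, n)``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(frags),):
        raise ValueError("one value per fragment required")
    keep = ~np.isnan(values)
    if domains is not None:
        if label is None:
            raise ValueError("label required when domains are given")
        keep &= _midpoint_in_label(frags, domains, label)
    lengths = frags.lengths[keep].astype(float)
    vals = values[keep]
    if len(vals) < 3:
        raise ValueError(f"only {len(vals)} usable fragments; need >= 3")
    if lengths.std() == 0 or vals.std() == 0:
        raise ValueError("zero variance")
    from scipy.stats import pearsonr

    return float(pearsonr(lengths, vals).statistic), len(vals)
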