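"""Read, filter and length-classify paired-end fragments.

Fragments are the MNase (or histone-ChIP MNase) protection footprints: the
template interval of a properly paired read pair. Coordinates are 0-based
half-open (BED convention) throughout; BAM input is converted on read.
Strand is ignored — a footprint protects both strands.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout

__all__ = [
    "FragmentSet",
    "LengthGroupScheme",
    "TEN_GROUP_SCHEME",
    "TWO_GROUP_SCHEME",
    "UNGROUPED",
    "load_fragments",
    "classify_lengths",
    "write_bed",
]

#: Sentinel group index for lengths outside the scheme's range.
UNGROUPED = -1

_BED_COLS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class LengthGroupScheme:
    """Half-open fragment-length groups ``[b_k, b_{k+1})``.

    ``boundaries`` must be strictly increasing with at least two entries and
    a first entry >= 1. A scheme with boundaries (50, 140, 250) defines two
    groups: 50-140 bp and 140-250 bp; a 140 bp fragment falls in the upper
    group, so that "long" counts are fragments >= the break point.
    """

    boundaries: tuple[int, ...]

    def __init__(self, boundaries):
        b = tuple(int(x) for x in boundaries)
        if len(b) < 2:
            raise ValueError("scheme needs >= 2 boundaries")
        if b[0] < 1:
            raise ValueError("first boundary must be >= 1")
        if any(hi <= lo for lo, hi in zip(b, b[1:])):
            raise ValueError(f"boundaries must be strictly increasing: {b}")
        object.__setattr__(self, "boundaries", b)

    @property
    def n_groups(self) -> int:
        return len(self.boundaries) - 1

    def group_labels(self) -> list[str]:
        b = self.boundaries
        return [f"len_{lo}_{hi}" for lo, hi in zip(b, b[1:])]

    def group_of_breakpoint(self, breakpoint: int) -> int:
        """Index of the first group at or above *breakpoint*.

        Raises if the break point is not a scheme boundary: with grouped
        counts the long/short split is only exact at group boundaries.
        """
        interior = self.boundaries[1:-1]
        if breakpoint not in interior:
            raise ValueError(
                f"break point {breakpoint} is not an interior boundary of the "
                f"scheme; valid break points: {list(interior)}"
            )
        return self.boundaries.index(breakpoint)


#: The ten-group scheme used for multi-break-point analyses.
TEN_GROUP_SCHEME = LengthGroupScheme(
    (50, 80, 90, 100, 110, 120, 130, 140, 150, 160, 250)
)
#: The minimal two-group scheme for a single 140 bp break point.
TWO_GROUP_SCHEME = LengthGroupScheme((50, 140, 250))


@dataclass
class FragmentSet:
    """A collection of genomic fragments tied to one :class:`GenomeLayout`.

    ``frame`` holds one row per fragment with columns chrom/start/end/length,
    sorted is not required. ``report`` carries per-sample QC counts
    (read / kept / dropped by reason).
    """

    frame: pd.DataFrame
    layout: GenomeLayout
    provenance: str = ""
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.frame
        missing = [c for c in _BED_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"fragment frame lacks columns {missing}")
        if "length" not in df.columns:
            df = df.assign(length=df["end"] - df["start"])
            self.frame = df
        if len(df):
            if (df["end"] <= df["start"]).any():
                bad = df[df["end"] <= df["start"]].iloc[0]
                raise ValueError(f"fragment with end <= start: {tuple(bad[_BED_COLS])}")
            lengths = self.layout.lengths
            unknown = set(df["chrom"].unique()) - set(lengths)
            if unknown:
                raise ValueError(f"fragments on chromosomes absent from layout: {sorted(unknown)}")
            ends = df["chrom"].map(lengths)
            if (df["end"] > ends).any():
                bad = df[df["end"] > ends].iloc[0]
                raise ValueError(f"fragment beyond chromosome end: {tuple(bad[_BED_COLS])}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def lengths(self) -> np.ndarray:
        return self.frame["length"].to_numpy()

    def midpoints(self) -> np.ndarray:
        """Fragment midpoints, integer floor of (start+end)/2."""
        return ((self.frame["start"].to_numpy() + self.frame["end"].to_numpy()) // 2)


def _load_bed(path, layout: GenomeLayout) -> tuple[pd.DataFrame, dict]:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=_BED_COLS, dtype={0: str, 1: np.int64, 2: np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_BED_COLS).astype({"start": np.int64, "end": np.int64})
    n_read = len(df)
    known = df["chrom"].isin(layout.names)
    report = {"read": n_read, "dropped_unknown_chrom": int((~known).sum())}
    return df[known].reset_index(drop=True), report


def _load_bam(path, layout: GenomeLayout) -> tuple[pd.DataFrame, dict]:
    import pysam

    if not os.path.exists(str(path) + ".bai") and not os.path.exists(
        str(path).removesuffix(".bam") + ".bai"
    ):
        raise FileNotFoundError(
            f"BAM index not found for {path}; expected {path}.bai "
            "(run `samtools index`)"
        )
    chroms, starts, ends = [], [], []
    n_read = n_improper = n_flagged = 0
    report: dict = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam.fetch():
            n_read += 1
            if read.is_secondary or read.is_supplementary or read.is_duplicate:
                n_flagged += 1
                continue
            # one fragment per template: first-in-pair with a leftward mate
            if not read.is_proper_pair or not read.is_read1:
                n_improper += 1
                continue
            tlen = read.template_length
            if tlen > 0:
                start = read.reference_start
                end = start + tlen
            else:
                end = read.reference_end
                start = end + tlen  # tlen < 0: mate is leftmost
            chroms.append(read.reference_name)
            starts.append(start)
            ends.append(end)
    df = pd.DataFrame({"chrom": chroms,
                       "start": np.asarray(starts, dtype=np.int64),
                       "end": np.asarray(ends, dtype=np.int64)})
    known = df["chrom"].isin(layout.names) if len(df) else pd.Series([], dtype=bool)
    report.update(
        read=n_read,
        skipped_flagged=n_flagged,
        skipped_not_first_proper_pair=n_improper,
        dropped_unknown_chrom=int((~known).sum()) if len(df) else 0,
    )
    return df[known].reset_index(drop=True) if len(df) else df, report


def load_fragments(
    path,
    layout: GenomeLayout,
    min_len: int = 50,
    max_len: int = 250,
    provenance: str | None = None,
) -> FragmentSet:
    """Load fragments from BED3+ or coordinate-sorted, indexed BAM.

    Only fragments with ``min_len <= length <= max_len`` (closed interval,
    "within 50-250 bp") on chromosomes present in *layout* are retained;
    everything else is tallied in the returned set's QC report. For BAM,
    one fragment per properly paired template is emitted (first-in-pair
    only, template coordinates); secondary/supplementary/duplicate records
    are skipped.
    """
    if min_len >= max_len:
        raise ValueError(f"min_len ({min_len}) must be < max_len ({max_len})")
    spath = str(path)
    if not os.path.exists(spath):
        raise FileNotFoundError(spath)
    if spath.endswith((".bam", ".cram")):
        df, report = _load_bam(spath, layout)
    else:
        df, report = _load_bed(spath, layout)
    lengths = df["end"] - df["start"]
    keep = (lengths >= min_len) & (lengths <= max_len)
    report["dropped_length"] = int((~keep).sum())
    df = df[keep].reset_index(drop=True)
    report["kept"] = len(df)
    if len(df) == 0:
        warnings.warn(f"no fragments retained from {spath} after filtering", stacklevel=2)
    return FragmentSet(
        frame=df.assign(length=(df["end"] - df["start"]).astype(np.int64)),
        layout=layout,
        provenance=provenance if provenance is not None else os.path.basename(spath),
        report=report,
    )


def classify_lengths(frags: FragmentSet | np.ndarray, scheme: LengthGroupScheme) -> np.ndarray:
    """Assign each fragment to its length group.

    Length L maps to group k iff ``b_k <= L < b_{k+1}``; lengths outside
    ``[first, last)`` get :data:`UNGROUPED` (-1).
    """
    lengths = frags.lengths if isinstance(frags, FragmentSet) else np.asarray(frags)
    b = np.asarray(scheme.boundaries)
    idx = np.searchsorted(b, lengths, side="right") - 1
    idx[(lengths < b[0]) | (lengths >= b[-1])] = UNGROUPED
    return idx.astype(np.int64)


def write_bed(frags: FragmentSet, path) -> None:
    """Write fragments as BED3, preserving (chrom, start, end) exactly."""
    frags.frame[_BED_COLS].to_csv(path, sep="\t", header=False, index=False)


def format_report(frags: FragmentSet) -> str:
    """Per-sample QC report as plain text."""
    lines = [f"sample\t{frags.provenance}"]
    lines += [f"{k}\t{v}" for k, v in frags.report.items()]
    return "\n".join(lines) + "\n"
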