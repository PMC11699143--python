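"""Genome layout: ordered chromosomes partitioned into a fixed-width bin grid.

Every track, count matrix and domain set in the package is defined on a
:class:`GenomeLayout`. Bins are consecutive, non-overlapping, half-open
``[i*bin_size, min((i+1)*bin_size, chrom_length))``; the last bin of each
chromosome may be partial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeLayout", "read_chrom_sizes"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths plus a bin size defining the grid.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs. Names must be unique and
        lengths positive.
    bin_size
        Bin width in bp. Chromosomes shorter than one bin yield a single
        partial bin.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(self, chromosomes, bin_size: int):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        if bin_size < 1:
            raise ValueError(f"bin_size must be >= 1, got {bin_size}")
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for n, l in chroms:
            if l < 1:
                raise ValueError(f"chromosome {n!r} has non-positive length {l}")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "bin_size", int(bin_size))
        offsets, total = {}, 0
        for n, l in chroms:
            offsets[n] = total
            total += -(-l // bin_size)  # ceil division
        object.__setattr__(self, "_offsets", offsets)

    # -- basic lookups -----------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._offsets

    def chrom_length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def n_bins_chrom(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.bin_size)

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_chrom(n) for n in self.names)

    def chrom_offset(self, chrom: str) -> int:
        """Global index of the first bin of *chrom*."""
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + self.n_bins_chrom(chrom))

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index containing 0-based position *pos*."""
        if not 0 <= pos < self.lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.lengths[chrom]})")
        return self._offsets[chrom] + pos // self.bin_size

    def bins_frame(self) -> pd.DataFrame:
        """All bins as a BED-like frame (chrom, start, end) in grid order."""
        rows = []
        bs = self.bin_size
        for name, length in self.chromosomes:
            starts = np.arange(0, length, bs, dtype=np.int64)
            ends = np.minimum(starts + bs, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def partial_bin_mask(self) -> np.ndarray:
        """Boolean mask over bins that are shorter than ``bin_size``."""
        mask = np.zeros(self.n_bins, dtype=bool)
        for name, length in self.chromosomes:
            if length % self.bin_size:
                mask[self.chrom_slice(name).stop - 1] = True
        return mask

    def with_bin_size(self, bin_size: int) -> "GenomeLayout":
        return GenomeLayout(self.chromosomes, bin_size)


def read_chrom_sizes(path, bin_size: int) -> GenomeLayout:
    """Build a layout from a two-column (name, length) chrom-sizes file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, usecols=[0, 1],
                     names=["chrom", "length"], dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"empty chrom-sizes file: {path}")
    return GenomeLayout(list(zip(df["chrom"], df["length"])), bin_size)


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")
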