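"""Synthetic wrapping-seq data with known ground truth.

The generator emulates the statistical structure that the wrapping
metrics exploit: the genome is tiled by alternating domains, each bin
carries a latent tightness ``theta`` in [0, 1], and every fragment's
length is drawn from a two-component truncated-normal mixture — a "long"
nucleosome-protected component sampled with probability theta and a
"short" partially-unwrapped component otherwise. A global
``digestion_shift`` delta lowers the effective tightness uniformly,
mimicking longer MNase digestion; pulse/chase conditions offset theta
down or up to mimic immature nascent chromatin and its maturation.

Everything is deterministic given the spec seed: each (chromosome, bin,
condition) derives its own generator, so partial regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .domains import DomainSet
from .fragio import FragmentSet
from .layout import GenomeLayout

__all__ = ["SimulationSpec", "simulate_genome", "simulate_fragments", "theta_track"]

_CONDITION_CODES = {"parental": 0, "nascent": 1, "chase": 2}


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth description of a simulated wrapping-seq experiment.

    ``domain_plan`` maps each chromosome to ``(length_bp, theta)`` domains
    that tile it exactly; domain lengths must be multiples of the bin size
    so that every bin inherits a single theta. ``depth`` is the expected
    fragment count per bin (Poisson). The length mixture defaults to a
    long component at 167 +/- 15 bp (nucleosomal) and a short component at
    110 +/- 25 bp (subnucleosomal), both truncated to [50, 250] bp.
    """

    layout: GenomeLayout
    domain_plan: dict[str, tuple[tuple[int, float], ...]]
    depth: float = 200.0
    long_mean: float = 167.0
    long_sd: float = 15.0
    short_mean: float = 110.0
    short_sd: float = 25.0
    min_len: int = 50
    max_len: int = 250
    digestion_shift: float = 0.0
    pulse_delta: float = 0.2
    chase_delta: float = 0.1
    seed: int = 0

    def __post_init__(self):
        bs = self.layout.bin_size
        plan = {c: tuple((int(l), float(t)) for l, t in doms)
                for c, doms in self.domain_plan.items()}
        object.__setattr__(self, "domain_plan", plan)
        for chrom, length in self.layout.chromosomes:
            doms = plan.get(chrom)
            if not doms:
                raise ValueError(f"domain plan missing chromosome {chrom!r}")
            if sum(l for l, _ in doms) != length:
                raise ValueError(
                    f"domain plan does not tile {chrom}: lengths sum to "
                    f"{sum(l for l, _ in doms)}, chromosome is {length} bp"
                )
            for l, t in doms:
                if l % bs:
                    raise ValueError(
                        f"domain length {l} on {chrom} is not a multiple of the "
                        f"bin size {bs}"
                    )
                if not 0 <= t <= 1:
                    raise ValueError(f"theta {t} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @classmethod
    def alternating(
        cls,
        n_chroms: int = 1,
        domains_per_chrom: int = 10,
        bins_per_domain: int = 20,
        bin_size: int = 100_000,
        thetas: tuple[float, float] = (0.8, 0.2),
        **kwargs,
    ) -> "SimulationSpec":
        """Convenience builder: equal-sized domains alternating two thetas."""
        dom_len = bins_per_domain * bin_size
        chrom_len = domains_per_chrom * dom_len
        chroms = [(f"chr{i + 1}", chrom_len) for i in range(n_chroms)]
        plan = {
            name: tuple((dom_len, thetas[j % 2]) for j in range(domains_per_chrom))
            for name, _ in chroms
        }
        return cls(GenomeLayout(chroms, bin_size), plan, **kwargs)

    def with_digestion(self, delta: float) -> "SimulationSpec":
        return replace(self, digestion_shift=delta)


def theta_track(spec: SimulationSpec) -> np.ndarray:
    """Per-bin latent tightness theta, in layout bin order."""
    layout = spec.layout
    bs = layout.bin_size
    out = np.empty(layout.n_bins)
    for chrom, _ in layout.chromosomes:
        sl = layout.chrom_slice(chrom)
        pos = 0
        for length, theta in spec.domain_plan[chrom]:
            nb = length // bs
            start = sl.start + pos
            out[start : start + nb] = theta
            pos += nb
    return out


def simulate_genome(
    spec: SimulationSpec, with_fasta: bool = False
) -> tuple[GenomeLayout, DomainSet, dict[str, str] | None]:
    """Layout, ground-truth domain set, and optionally a random genome.

    Truth domains are labelled Ti where theta > 0.5 and Lo where
    theta < 0.5; theta == 0.5 stretches are indeterminate and excluded.
    Adjacent same-label domains merge. The optional FASTA is i.i.d.
    uniform over ACGT (no sequence bias) for sequence-feature tests.
    """
    rows = []
    for chrom, _ in spec.layout.chromosomes:
        pos = 0
        for length, theta in spec.domain_plan[chrom]:
            if theta != 0.5:
                label = "Ti" if theta > 0.5 else "Lo"
                if rows and rows[-1]["chrom"] == chrom and rows[-1]["end"] == pos \
                        and rows[-1]["label"] == label:
                    rows[-1]["end"] = pos + length
                else:
                    rows.append({"chrom": chrom, "start": pos, "end": pos + length,
                                 "label": label, "score": theta})
            pos += length
    truth = DomainSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"]),
        ("Ti", "Lo"), provenance="simulation ground truth",
    )
    fasta = None
    if with_fasta:
        fasta = {}
        for ci, (chrom, length) in enumerate(spec.layout.chromosomes):
            rng = np.random.default_rng([spec.seed, 7, ci])
            fasta[chrom] = "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, size=length)]
            )
    return spec.layout, truth, fasta


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Exact truncated-normal sampling via inverse-CDF."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size=n)
    return mean + sd * ndtri(u)


def simulate_fragments(
    spec: SimulationSpec, condition: str = "parental"
) -> FragmentSet:
    """Draw a fragment set for one condition.

    Per bin the fragment count is Poisson(depth); each length comes from
    the long component with probability ``clamp(theta_condition -
    digestion_shift, 0, 1)`` and the short component otherwise; start
    positions are uniform within the bin (shifted left at chromosome ends
    so fragments stay in bounds).
    """
    if condition not in _CONDITION_CODES:
        raise ValueError(
            f"unknown condition {condition!r}; choose from {sorted(_CONDITION_CODES)}"
        )
    code = _CONDITION_CODES[condition]
    offset = {"parental": 0.0, "nascent": -spec.pulse_delta,
              "chase": spec.chase_delta}[condition]
    layout = spec.layout
    bs = layout.bin_size
    theta = theta_track(spec)
    chroms, starts, ends = [], [], []
    for ci, (chrom, chrom_len) in enumerate(layout.chromosomes):
        sl = layout.chrom_slice(chrom)
        for bi in range(sl.stop - sl.start):
            rng = np.random.default_rng([spec.seed, ci, bi, code])
            n = rng.poisson(spec.depth)
            if n == 0:
                continue
            t_eff = float(np.clip(theta[sl.start + bi] + offset - spec.digestion_shift, 0, 1))
            is_long = rng.random(n) < t_eff
            lengths = np.empty(n)
            if is_long.any():
                lengths[is_long] = _truncated_normal(
                    rng, int(is_long.sum()), spec.long_mean, spec.long_sd,
                    spec.min_len, spec.max_len,
                )
            if (~is_long).any():
                lengths[~is_long] = _truncated_normal(
                    rng, int((~is_long).sum()), spec.short_mean, spec.short_sd,
                    spec.min_len, spec.max_len,
                )
            lengths = np.clip(np.rint(lengths), spec.min_len, spec.max_len).astype(np.int64)
            bin_start = bi * bs
            bin_end = min(bin_start + bs, chrom_len)
            s = rng.integers(bin_start, bin_end, size=n)
            s = np.minimum(s, chrom_len - lengths)
            chroms.extend([chrom] * n)
            starts.append(s)
            ends.append(s + lengths)
    if starts:
        frame = pd.DataFrame({
            "chrom": chroms,
            "start": np.concatenate(starts),
            "end": np.concatenate(ends),
        })
    else:
        frame = pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    frame["length"] = frame["end"] - frame["start"]
    return FragmentSet(frame, layout,
                       provenance=f"simulated:{condition}:seed{spec.seed}")
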