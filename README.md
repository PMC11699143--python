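# wrapseq

Nucleosome wrapping analytics from paired-end MNase fragment lengths.

Micrococcal nuclease (MNase) digests the linker DNA between nucleosomes and
leaves behind protected fragments whose lengths report how much DNA each
nucleosome still held on to: a fully wrapped nucleosome protects a
~147–170 bp fragment, a partially unwrapped one protects less. Paired-end
sequencing of MNase (or histone-ChIP MNase) libraries therefore carries a
genome-wide readout of nucleosome *wrapping state* in its fragment-length
distribution — "wrapping-seq". This package turns aligned paired-end
fragments into that readout, for chromatin biologists who already have
BED/BAM-level data and want quantitative, browser-ready wrapping tracks and
domain calls.

## The metrics

For a genomic bin, fragments of 50–250 bp are split at a length *break
point* X (default 140 bp) into `a` long (≥ X, wrapped) and `b` short
(< X, unwrapped) fragments. The **Nucleosome Wrapping Score** is

    NRS(X) = (a − b) / (a + b)  ∈  [−1, +1]

an absolute measure that shifts with MNase digestion time. The
**Nucleosome Wrapping Index** is its genome-wide z-score

    NRI(i) = (NRS(i) − μ) / σ

a relative measure that is robust to digestion extent and to the choice of
X. Maximal runs of same-sign NRI form **Nucleosome Wrapping Domains**:
TiNRDs (tight, positive) alternating with LoNRDs (loose, negative), which
can be compared to Hi-C A/B compartments and replication-timing domains
through overlap-fraction matrices and border meta-profiles.

Also included: replication timing `RT = log2((S1+S2)/(S3+S4))` from four
S-phase fractions with target quantile normalization, MNase sequence-bias
diagnostics (A/T content, cut-site base-frequency profiles, dinucleotide
frequencies), parental-versus-nascent NRS differencing for pulse/chase
experiments, and a simulator that generates fragment sets from a known
per-bin tightness so every stage can be validated against ground truth.

## Worked example

Simulate a 2 Mb chromosome of ten alternating 200 kb domains (tightness
0.8 vs 0.2, 200 fragments per 10 kb bin), then run the pipeline:

```python
import numpy as np
import wrapseq as ws

spec = ws.SimulationSpec.alternating(
    n_chroms=1, domains_per_chrom=10, bins_per_domain=20,
    bin_size=10_000, depth=200, seed=1)
layout, truth, _ = ws.simulate_genome(spec)
frags = ws.simulate_fragments(spec)
counts = ws.count_fragments(frags, layout, ws.TWO_GROUP_SCHEME)
nrs = ws.nrs(counts, breakpoint=140)
nri = ws.nri(nrs)
domains = ws.call_domains(nri, min_size_bp=30_000, smooth_span=10)

print(f"fragments: {len(frags)}")
print(f"mean NRS(140): {np.nanmean(nrs.values):.3f}")
print(f"domains called: {len(domains)}")
print(ws.overlap_fraction(domains, truth).round(3))
```

prints

```
fragments: 40155
mean NRS(140): 0.084
domains called: 10
query       Ti   Lo
reference
Ti         1.0  0.0
Lo         0.0  1.0
```

All ten planted domains are recovered exactly: every base of true tight
(Ti) domains lies in called Ti domains and likewise for loose (Lo). The
mean NRS near zero reflects the balanced tight/loose design; per-bin NRS
is strongly positive in tight domains and negative in loose ones.

The same pipeline is available from the shell:

```bash
wrapseq simulate --out-dir sim --seed 3 --depth 100
wrapseq nrs --frags sim/fragments_parental.bed --chrom-sizes sim/chrom.sizes \
        --bin-size 10000 --out nrs.bedgraph
wrapseq nri --nrs nrs.bedgraph --chrom-sizes sim/chrom.sizes \
        --bin-size 10000 --out nri.bedgraph
wrapseq domains --nri nri.bedgraph --chrom-sizes sim/chrom.sizes \
        --bin-size 10000 --min-size 30000 --out nrds.bed
```

`wrapseq --help` lists the remaining subcommands (fragment filtering,
overlap matrices, border profiles, replication timing, cut-site profiles,
length histograms, pulse/chase comparison).

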