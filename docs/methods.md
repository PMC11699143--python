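# Methods

## Model

A nucleosome protects the DNA wrapped around its histone core from MNase.
When wrapping is partial, protection is partial, and the library's
fragment-length distribution shifts toward sub-nucleosomal lengths. The
package quantifies this per genomic bin from paired-end fragments
(template intervals of proper pairs, 0-based half-open coordinates,
strand ignored):

* retention filter: fragment length in the closed interval [50, 250] bp
  ("within 50–250 bp" read with inclusive endpoints);
* length groups: half-open `[b_k, b_{k+1})`. The shared boundary value of
  two printed ranges (e.g. 140 in "50–140, 140–250") belongs to the upper
  group, so the long count `a` is exactly "fragments ≥ break point";
* `NRS(X) = (a − b)/(a + b)` per bin, defined only where `a + b ≥ 1`
  (`min_total` is a parameter; no coverage floor is applied by default);
* `NRI = (NRS − μ)/σ` pooled over all chromosomes, using the population
  standard deviation (divisor n). The choice of divisor is irrelevant at
  genome scale but is fixed for bit-reproducibility. μ and σ are taken
  over non-missing bins only; missing stays missing.

Defaults: break point 140 bp, bin size 100 kb. Both are parameters; the
supplied ten-group scheme (boundaries 50, 80, 90, …, 160, 250) makes any
of its interior boundaries a valid break point from one counting pass.

### Counting mode

A fragment increments every bin it overlaps by ≥ 1 bp (any-overlap),
matching bedtools-style annotation. At 100 kb bins the double-counting at
borders affects well under 1% of fragments; a midpoint-assignment mode is
available (`mode="midpoint"`) where single assignment matters, and
midpoint assignment (half-open) is always used for sub-bin-scale region
membership (peak histograms, domain filtering of fragments) and for
replication-timing counts.

### Smoothing

Loess (degree-1 local regression, tricube weights) over the `span_bins`
(default 10) nearest non-missing neighbours of each bin, computed per
chromosome and never across chromosome ends. The window is a bin count,
not a fraction of the chromosome. On a noiseless line the smoother is
exact; a chromosome with fewer non-missing bins than the span passes
through unsmoothed with a warning. The implementation agrees with
statsmodels' lowess to ~1e-15 on shared inputs, which the test suite uses
as an independent cross-check.

## Domain segmentation

TiNRDs/LoNRDs (and early/late RT domains) are maximal same-sign runs of
the smoothed track, with an explicit deterministic absorption rule in
place of any external tool's undocumented merging heuristics:

1. smooth (internal, `smooth_span=10`; pass 0 for pre-smoothed input);
2. sign per covered bin; exact zeros take the nearest non-zero sign, ties
   to the left;
3. maximal constant-sign runs are candidates;
4. runs shorter than `min_size_bp` are absorbed — shortest first,
   leftmost on ties — into the flank with larger |mean signal| (ties to
   the left), coalescing until all surviving runs reach the minimum or
   one run remains;
5. single-bin missing gaps are bridged (gap bin follows its left
   neighbour); longer gaps split segments and their junctions are never
   borders, nor are chromosome ends.

`min_size_bp` defaults to 300 kb (3 bins at the 100 kb grid), chosen so
that segmentations of mammalian-scale simulations produce domain counts
and lengths on the scale reported for mouse chromatin (~1.4 k domains of
median ~800 kb over ~2.5 Gb). Domain scores are the mean smoothed signal.
Partial terminal bins are masked in border meta-profiles to avoid edge
artifacts. Step 4's equality with exhaustive brute-force absorption is
verified for every sign string up to length 12.

## Replication timing

Each fraction S1–S4 is scaled to 1 M fragments, then
`RT = log2((S1′+S2′)/(S3′+S4′))`; bins with a zero numerator or
denominator are missing — no pseudocount, reading the formula literally.
Quantile normalization maps the value of rank r among n onto the target's
empirical quantile at probability `(r − 0.5)/n` by linear interpolation,
averaging mapped values within ties; the transform is rank-preserving and
its sorted output equals the mapped target quantiles exactly. The target
distribution is a required explicit input (the package does not presume a
pooled or reference profile). RT uses 50 kb bins by default; comparisons
against NRI resample by bin-mean onto the NRI grid.

## Sequence diagnostics

All composition statistics are top-strand with N excluded from numerator
and denominator. A/T content of an N-free sequence equals that of its
reverse complement, so it is strand-safe. Cut-site profiles tally base
frequencies in `[site − flank, site + flank)` (default flank 20 bp, a
parameter) separately for fragment 5′ and 3′ ends, skipping and counting
sites within `flank` of a contig edge. Fragment-to-domain assignment for
composition-versus-length correlations uses the fragment midpoint with
half-open intervals.

## Simulator

The generator emulates exactly the structure the metrics exploit and
nothing else. A genome is tiled by alternating domains with per-bin
latent tightness θ ∈ [0, 1]; per bin, fragment count ~ Poisson(depth) and
each length is drawn from a truncated-normal mixture: with probability θ
the "long" nucleosomal component (mean 167 bp, sd 15), otherwise the
"short" sub-nucleosomal component (mean 110 bp, sd 25), both truncated to
[50, 250] bp (exact inverse-CDF sampling). The component parameters are
modelling choices anchored to nucleosomal (~147–167 bp) versus
sub-nucleosomal fragment scales, not measured values. Perturbations:

* `digestion_shift` δ subtracts uniformly from θ — longer digestion
  strips marginal wrapping everywhere, lowering NRS genome-wide while
  preserving the ordering that NRI captures;
* conditions: `parental` uses θ, `nascent` uses θ − `pulse_delta`
  (default 0.2; newly deposited nucleosomes start loosely wrapped) and
  `chase` uses θ + `chase_delta` (default 0.1; maturation overshoot).
  The offsets are set large enough that the sign of the median per-domain
  ΔNRS is unambiguous at simulation depth, as in the pulse/chase
  experiments the design mimics.

Sampling is seeded per (chromosome, bin, condition), so any subset of the
genome regenerates identically. Default study conditions used by the
acceptance script and tests: 1,000-bin genomes (50 alternating 20-bin
domains, 10 kb bins), θ ∈ {0.8, 0.2}, depth 200 fragments/bin — sizes at
which every summary is stable across seeds yet the full pipeline runs in
seconds.

What the simulator does **not** model: MNase sequence preference (its
optional FASTA is i.i.d. uniform ACGT — composition statistics on it test
correctness, not bias), nucleosome positioning/phasing, chromatin-state
autocorrelation beyond the planted domains, mappability and copy-number
artifacts, and ChIP enrichment. Passing tests therefore demonstrate that
the estimators recover the latent wrapping structure they are defined to
measure; they do not certify biological conclusions on real libraries,
where coverage, bias and domain geometry are harsher.

## Numerical conventions and edge cases

* Missing values (NaN) propagate; nothing is silently zero-filled.
* NRS needs the break point to be a boundary of the counting scheme;
  anything else is an error naming the valid boundaries.
* z-scoring a constant track, correlating a zero-variance track,
  segmenting an all-missing track and quantile-normalizing fewer than two
  values are explicit errors, not NaN returns.
* Bins are `[i·bin, min((i+1)·bin, chrom_len))`; terminal partial bins
  are kept, flagged, and masked only in border profiles.
* BED/bedGraph writers emit plain tab-separated text; bigWig output is
  available via pyBigWig.

## Limitations

The domain caller's absorption rule is a contract of this package, not a
reimplementation of any published tool's internals; calls at domain-size
scale agree with sign segmentation generally, but exact borders may
differ from other callers by up to the smoothing span. NRS in sparse bins
is noisy (variance ~ 1/(a+b)); `min_total` exists for that but defaults
to permissive. The quantile-normalization tie rule (mean of mapped
values) matches common practice but other implementations differ in ties
at the extremes.
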