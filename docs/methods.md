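# Methods

## The processing model

The pipeline starts from aligned single-end reads (BED6 or a minimal SAM
subset: FLAG, RNAME, POS, and read length from SEQ or the CIGAR query
operations). All internal coordinates are 0-based half-open; SAM, GFF3 and
WIG conversions happen only at the format boundary.

**Fragment length.** For a single-end mononucleosomal library the insert
size is estimated by strand cross-correlation: per-base densities of
+ read 5′ starts and − read 5′ ends are built per chromosome, and the
candidate fragment length F in the search window (default 100–250 bp)
maximizing Σ p[x]·m[x+F−1] is returned, so that a + start at x paired with
a − end at x+F−1 scores exactly F — the insert size. Ties break toward the
smaller F. Because fragment-size dispersion makes the correlation peak
~2× the length SD wide, the argmax alone jitters by a few bp under
sampling noise; the estimate is refined by the vertex of a quadratic fit
over a symmetric ±8-lag window, which leaves a single-lag peak exactly in
place. A flat correlation or a single-strand library is an error.

**Dyad coverage.** Each read is reduced to its inferred dyad interval:
+ reads shift their start by floor(F/2); − reads shift their 5′ end
(rightmost base) back by floor(F/2), so both strands center symmetrically;
the center is extended 20 nt on each side, giving a half-open window of
width exactly trim = 40. floor() on odd F and the half-open window mean
the interval is centered 0.5 bp left of the dyad; this is a fixed,
tested convention (a genome mirror shifts coverage by exactly 1 bp).
Edge-running windows are clipped, flagged and counted; each unclipped read
contributes exactly 40 to the track total. RPM normalization divides by
total mapped reads and multiplies by 10⁶.

**Smoothing.** `fft_lowpass` keeps DFT coefficients with frequency index
k ≤ ceil(pc_keep·N/2) plus conjugate mirrors and zeroes the rest;
`pc_keep = 1` is the identity. Negative ringing is clamped to zero after
the inverse transform (occupancy is non-negative); linear-filter
properties (projection idempotence, Parseval, DC preservation) hold and
are tested pre-clamp. Default pc_keep = 0.02 keeps features of wavelength
≥ 100 bp at the scales used here. Chromosomes beyond a `chunking` length
(default 10⁶, so the bundled simulations are never chunked) are processed
in mirror-padded overlapping windows with central-region stitching.
Hard spectral truncation is a *global* operator whose kernel decays ~1/x,
so stitched output matches the unchunked filter only to ~1 % (max) of the
signal maximum at the default overlap; the self-consistency test asserts
that measured bound, not exactness.

**Calling.** Nucleosome dyads are local maxima of the smoothed track
(plateaus report their leftmost index) above a height floor (default
0.1 × the track's 90th percentile); maxima closer than 120 bp keep the
higher, leftmost on ties. Because truncation ringing can displace a
smoothed maximum by a few bp, the pipeline re-localizes each accepted
dyad to the coverage centroid of the *unsmoothed* RPM track within
±40 bp (detection, heights and half-height widths stay on the smoothed
signal); this brings zero-jitter recovery from ±3 bp to exact. NDRs are
maximal runs below `rel_threshold` (default 0.5) × the median occupancy
of the gene's ±2 kb window, of width ≥ 80 bp, searched strand-aware in
[TSS−1000, TSS+200]; the run overlapping (else nearest) the CRE is
reported. The relative threshold makes detection independent of library
size. The +1 nucleosome is the first called dyad at or downstream of the
TSS within 300 bp, in transcription direction; unassigned genes are
logged and dropped from anchored profiles.

**Profiles.** The anchored matrix extracts ±flank bp (default 500; 1001
columns) around each gene's anchor, reversing − strand rows so positive
positions are downstream. Clipped windows drop the gene rather than
zero-pad. Composites are log-then-average: mean over genes of
log₂(occupancy + 0.1) per position, so one deep gene cannot dominate; no
per-gene scaling is applied (exposed as a deliberate non-default).
Array spacing is the lag in 120–220 bp maximizing the per-lag Pearson
autocorrelation of the linearly detrended downstream half — detrending
because a monotone trend correlates at every lag, Pearson per lag because
per-segment normalization scores a periodic signal exactly 1 at its
period where the raw lagged sum is biased a few bp low. Significance is
the 95th percentile of the same statistic over shuffled profiles.
Phasing amplitudes A_k are peak-to-trough within
[(k−1)·s + s/2, k·s + s/2) downstream; A₄ needs flank ≥ ~4.5 spacings,
so condition comparisons use flank = 800 and adapt the number of
positions to the flank otherwise.

**Low-throughput assays.** Scanning-qPCR occupancy is
mono-nucleosomal / input quantity per replicate (input ≡ 1), summarized
as mean ± SEM (sd/√n, undefined for n < 2). Strain and transcript
comparisons are ratios of per-group means, with SEM propagated by the
delta method (relative variances add in quadrature). Quantities are
assumed linear-scale (post-Ct conversion); efficiency calibration is
upstream of this package.

## The generator

Each of `n_cells` simulated chromatin fibers places nucleosomes per gene:

- the TF is bound with probability `p_bound` (1 = fully bound barrier,
  0 = deletion-like);
- bound: the +1 dyad sits at TSS + 75 with σ = 12 bp, and no dyad may
  enter the ±75 bp exclusion zone around the CRE (150 bp NDR); unbound:
  the +1 slides 130 bp toward the promoter (dyad at CRE + 95) with
  σ = 25 bp and the exclusion is lifted;
- the downstream array follows sequentially at 147 + 18 bp steps with
  per-step Gaussian jitter accumulating along the array (σ_step = 20 bp
  bound, 45 bp unbound), steps re-drawn on hard-core (< 147 bp)
  violations;
- one upstream (−1) nucleosome mirrors the +1 across the CRE with
  σ = 30 bp (upstream nucleosomes are empirically fuzzier than the +1);
  it is sampled from the exact truncated normal honoring the NDR and the
  hard core against the +1, because plain rejection conditional on a
  far-wandering unbound +1 has unbounded failure probability;
- minus-strand genes mirror every offset.

Reads pick a (cell, gene, nucleosome) uniformly, wrap the dyad in a
fragment ~round(N(147, 10)) clamped to 100–250 bp (the gel-purification
window), and sequence 50 nt from a uniformly random end; fragments
crossing a chromosome end are re-drawn. qPCR protection of an amplicon is
the fraction of cells in which some 147 bp footprint fully covers it,
with multiplicative Gaussian noise per replicate; transcript tables give
every gene a sense and antisense quantity, with an antisense fold applied
only to barrier-dependent genes in the barrier-free condition.

The default toy genome is 50 co-oriented genes spaced 3.3 kb on one
chromosome, with the CRE 150 bp upstream of each TSS, so that each gene's
±2 kb median window is mostly nucleosome-covered by its own and its
neighbor's arrays — as in a real gene-dense genome. Strand handling is
verified by explicit mirror-image fixtures rather than by mixing strands
in the default layout. Defaults of 10⁵ reads and 300 cells keep a full
two-condition comparison under ~2 s while leaving every directional
phenotype far from its noise floor.

### Why two free-state jitters

Modeling barrier loss purely as "p_bound = 0 plus a +1 shift" reproduces
the NDR narrowing and the promoter shoulder but *cannot* lower the
phasing-decay ratio A₄/A₁: with a shared σ_step the cumulative variance
increments are identical in both conditions and cancel in the ratio
(A₄/A₁ ≈ exp(−2π²·3σ_step²/NRL²) either way). Barrier loss in the data is
an array-dephasing phenotype, so the unbound state carries its own,
larger per-step jitter (σ_step_free = 45 bp), and the larger
σ_plus_one_free broadens the +1. These values were chosen so each modeled
phenotype is resolvable at desk scale and were frozen before the
acceptance tests were written.

## What the simulations do and do not show

The generator reproduces the *geometry* of barrier-organized chromatin:
positioned dyads, exclusion zones, cumulative dephasing, mononucleosomal
fragment sampling. It omits sequence-dependent nucleosome energetics,
MNase sequence bias, PCR duplicates, mappability and inter-gene
heterogeneity. Passing tests therefore demonstrate that the pipeline
recovers planted parameters and directional condition differences under
the stated statistical model — not that it is robust to every artifact of
real MNase-seq libraries.

## Numerical choices

- Hard-core re-draws cap at 1000 attempts and then raise (degenerate
  configuration); truncation of the step distribution raises the realized
  mean spacing above footprint + linker (~172 bp at σ_step = 20), which
  the spacing estimator faithfully reports.
- All randomness flows from `numpy.random.default_rng` seeded per
  operation; pipeline sub-seeds derive deterministically from the run
  seed, so fixed-seed runs are bit-identical.
- WIG values are written with 6 significant digits (round trip ≤ 1e-6
  relative); fixedStep flavor, step = span = 1.
- Ties everywhere (peaks, plateaus, spacing lags) break leftmost/smaller
  for reproducibility.
- log₂ pseudocount 0.1 RPM bounds depleted-region composites; the
  all-zero matrix maps to log₂(pseudocount).

## Known limitations

- NDR detection needs the local ±2 kb median to be positive; on sparse
  toy genomes with long naked stretches the relative threshold collapses
  and no NDR is called (by design — occupancy there is not depleted
  *relative to its surroundings*).
- The spacing estimator assumes one dominant repeat in 120–220 bp;
  profiles mixing two repeat lengths report the stronger.
- Chunked smoothing is approximate near (and only near) chunk scale;
  at the default chunk size the bundled analyses never chunk.
- Paired-end reconstruction, duplicate removal, bigWig output and
  mappability correction are out of scope.
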