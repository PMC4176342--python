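# nucbarrier

Nucleosome-occupancy analysis of MNase-seq data under a
transcription-factor barrier model, with matched low-throughput
(qPCR-based) quantifications and a synthetic-data generator that makes the
whole pipeline testable without external sequencing data.

## The problem

At many stress-responsive promoters in fission yeast, a bZIP transcription
factor bound to its CRE motif keeps the promoter free of nucleosomes
(a nucleosome-depleted region, NDR) and acts as a *barrier* against which
the +1 nucleosome and the downstream array are statistically positioned.
Removing the factor narrows the NDR, lets the +1 nucleosome slide into the
promoter with a shoulder entering the NDR, dephases the downstream array,
and derepresses antisense transcription. `nucbarrier` implements the
computational side of testing that model:

- **dyad-centered coverage** — each aligned single-end read is shifted by
  half the estimated fragment length onto the nucleosome dyad and extended
  20 nt on each side (a 40 bp "trim" window); coverage is normalized to
  reads per million (RPM);
- **fragment-length estimation** by cross-correlating the densities of
  + read starts and − read 5′ ends;
- **FFT low-pass smoothing** — only the lowest `pc_keep` fraction of
  Fourier components is retained (default 2 %), removing per-base noise
  while keeping nucleosome-scale structure;
- **calling** — nucleosome dyads as smoothed-signal maxima (optionally
  re-localized on the unsmoothed track), promoter NDRs as runs below a
  threshold relative to the local median, and the +1 nucleosome as the
  first called dyad downstream of each TSS;
- **anchored composite profiles** — genes × positions matrices over
  ±flank bp around the CRE site or +1 dyad, averaged as mean log₂
  occupancy, with array spacing from the downstream autocorrelation and
  phasing-decay amplitudes A₁..A₄;
- **low-throughput quantification** — nucleosome-scanning qPCR occupancy
  relative to an undigested input (input ≡ 1), strain ratios with
  delta-method SEMs, and strand-specific RT-qPCR sense/antisense
  fold-changes;
- **a simulator** (`synthetic_data`) that generates chromatin fibers under
  the barrier model — Bernoulli TF binding, NDR exclusion, a jittered +1,
  a sequentially placed downstream array with cumulative jitter, a fuzzier
  upstream (−1) nucleosome — and draws mononucleosomal single-end reads,
  tiling-qPCR tables and transcript tables from them.

## Worked example

```python
import numpy as np
import nucbarrier as nb
from nucbarrier.coverage import ProcessingParams

params = ProcessingParams(flank=800)
cfg = nb.SimConfig(seed=42, p_bound=1.0)      # barrier bound in every cell
wt  = nb.run_condition(cfg, params=params)
mut = nb.run_condition(cfg.barrier_free(), params=params)

print(f"estimated fragment length: {wt.fragment_length} bp")
comp = nb.composite_log2(wt.matrix_plus_one)
sp = nb.estimate_spacing(comp)
print(f"nucleosome repeat length: {sp.spacing} bp (phased: {sp.phased})")
ndr = wt.ndrs[wt.genes[0].gene_id]
print(f"gene g000 NDR: {ndr.chrom}:{ndr.start}-{ndr.end} ({ndr.width} bp wide)")
cmp = nb.compare_conditions(wt.matrix_plus_one, mut.matrix_plus_one)
print(f"phasing decay A4/A1: barrier {cmp.decay_a['decay_ratio']:.2f}, "
      f"barrier-free {cmp.decay_b['decay_ratio']:.2f}")
occ = [np.mean([nb.occupancy_at(r.smoothed, g.chrom, g.cre_site, 50) for g in r.genes])
       for r in (wt, mut)]
print(f"CRE-site occupancy ratio (barrier-free / barrier): {occ[1]/occ[0]:.1f}")
```

prints

```
estimated fragment length: 147 bp
nucleosome repeat length: 172 bp (phased: True)
gene g000 NDR: chrI:580-924 (344 bp wide)
phasing decay A4/A1: barrier 0.43, barrier-free 0.16
CRE-site occupancy ratio (barrier-free / barrier): 4.5
```

The fragment length matches the simulated 147 bp mononucleosome insert.
The repeat length exceeds the nominal 147 + 18 bp because the hard-core
exclusion truncates the step-jitter distribution from below, pushing the
*realized* mean spacing a few bp up (on a zero-jitter simulation the
estimate is 165–166 bp). Losing the barrier collapses the NDR, raises
occupancy over the CRE ~4.5-fold, and makes the downstream array's
phasing amplitude decay much faster (A₄/A₁ 0.16 vs 0.43).

A `nucbarrier` console script exposes the same stages for shell use:
`nucbarrier simulate | coverage | smooth | call | profile | nucscan |
antisense` (see `--help` on each).

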