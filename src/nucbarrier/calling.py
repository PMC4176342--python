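"""Nucleosome dyad calling, NDR detection and +1 assignment.

Works on smoothed occupancy tracks.  Peaks in the smoothed signal mark
nucleosome dyads; promoter intervals of persistently low occupancy,
relative to the local signal level, are nucleosome-depleted regions
(NDRs); the first called dyad downstream of a gene's TSS in its direction
of transcription is its +1 nucleosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .coverage import CoverageTrack
from .io_formats import GeneModel

__all__ = [
    "NucleosomeCall",
    "NdrCall",
    "call_peaks",
    "detect_ndr",
    "assign_plus_one",
    "occupancy_at",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NucleosomeCall:
    chrom: str
    dyad: int
    height: float
    width_at_half_height: int


@dataclass(frozen=True)
class NdrCall:
    chrom: str
    start: int
    end: int
    min_value: float
    gene_id: str = ""

    @property
    def width(self) -> int:
        return self.end - self.start


def _half_height_width(x: np.ndarray, peak: int, height: float) -> int:
    """Width of the contiguous run around ``peak`` staying >= height/2."""
    half = height / 2.0
    left = peak
    while left > 0 and x[left - 1] >= half:
        left -= 1
    right = peak
    while right < x.size - 1 and x[right + 1] >= half:
        right += 1
    return right - left + 1


def default_min_height(track: CoverageTrack, fraction: float = 0.1) -> float:
    """A height floor: ``fraction`` of the track's 90th percentile."""
    allv = np.concatenate([v for v in track.data.values()])
    return fraction * float(np.percentile(allv, 90))


def call_peaks(track: CoverageTrack, min_height: float | None = None,
               min_separation: int = 120, refine_track: CoverageTrack | None = None,
               refine_halfwidth: int = 40) -> list[NucleosomeCall]:
    """Call nucleosome dyads as local maxima of the smoothed track.

    A dyad is a position strictly greater than both neighbors (plateaus
    report their leftmost index) with height >= ``min_height``.  Among
    maxima closer than ``min_separation`` only the highest survives, ties
    breaking toward the leftmost.  Calling on an unsmoothed track is
    refused: per-base dyad coverage produces one spurious maximum per read
    edge.

    Low-pass filtering rings near sharp features, which can displace a
    maximum by a few bp; passing the unsmoothed (rpm) track as
    ``refine_track`` re-localizes each accepted dyad to the coverage
    centroid within ``refine_halfwidth`` bp, while detection, heights and
    widths stay on the smoothed signal.
    """
    if track.state != "smoothed":
        raise ValueError(f"call_peaks requires a smoothed track, got state {track.state!r}")
    if refine_track is not None and refine_track.state == "smoothed":
        raise ValueError("refine_track must be an unsmoothed (raw/rpm) track")
    if min_height is None:
        min_height = default_min_height(track)
    calls: list[NucleosomeCall] = []
    for chrom, x in track.data.items():
        peaks, props = find_peaks(x, plateau_size=1)
        lefts = props["left_edges"]
        heights = x[lefts]
        keep = heights >= min_height
        lefts, heights = lefts[keep], heights[keep]
        # greedy suppression: highest first, leftmost on ties
        order = np.lexsort((lefts, -heights))
        accepted: list[int] = []
        for i in order:
            pos = lefts[i]
            if all(abs(pos - a) >= min_separation for a in accepted):
                accepted.append(pos)
        refine = refine_track.data[chrom] if refine_track is not None else None
        for pos in sorted(accepted):
            h = float(x[pos])
            dyad = int(pos)
            if refine is not None:
                lo = max(0, dyad - refine_halfwidth)
                hi = min(refine.size, dyad + refine_halfwidth + 1)
                w = refine[lo:hi]
                mass = w.sum()
                if mass > 0:
                    centroid = float(np.arange(lo, hi) @ w) / mass
                    dyad = int(np.floor(centroid + 0.5))
            calls.append(NucleosomeCall(chrom, dyad, h, _half_height_width(x, int(pos), h)))
    calls.sort(key=lambda c: (c.chrom, c.dyad))
    return calls


def detect_ndr(track: CoverageTrack, genes: Sequence[GeneModel],
               rel_threshold: float = 0.5, min_width: int = 80,
               upstream: int = 1000, downstream: int = 200,
               median_flank: int = 2000) -> dict[str, NdrCall | None]:
    """Detect the promoter NDR of each gene.

    Within the strand-aware promoter window (``upstream`` bp before to
    ``downstream`` bp after the TSS) an NDR is a maximal run of bases whose
    occupancy falls below ``rel_threshold`` times the median occupancy of
    the gene's +/- ``median_flank`` window, of width >= ``min_width``.  The
    run overlapping (or failing that, nearest to) the CRE site is reported;
    genes without an annotated CRE anchor on the TSS instead.
    """
    out: dict[str, NdrCall | None] = {}
    for gene in genes:
        x = track.data[gene.chrom]
        L = x.size
        if gene.strand == "+":
            w_lo, w_hi = gene.tss - upstream, gene.tss + downstream + 1
        else:
            w_lo, w_hi = gene.tss - downstream, gene.tss + upstream + 1
        w_lo, w_hi = max(0, w_lo), min(L, w_hi)
        m_lo, m_hi = max(0, gene.tss - median_flank), min(L, gene.tss + median_flank + 1)
        threshold = rel_threshold * float(np.median(x[m_lo:m_hi]))
        anchor = gene.cre_site if gene.cre_site is not None else gene.tss

        below = x[w_lo:w_hi] < threshold
        best: NdrCall | None = None
        best_dist = None
        i = 0
        n = below.size
        while i < n:
            if not below[i]:
                i += 1
                continue
            j = i
            while j < n and below[j]:
                j += 1
            start, end = w_lo + i, w_lo + j
            if end - start >= min_width:
                if start <= anchor < end:
                    dist = -1  # overlapping beats any non-overlapping run
                else:
                    dist = min(abs(anchor - start), abs(anchor - (end - 1)))
                if best_dist is None or dist < best_dist:
                    best = NdrCall(gene.chrom, start, end,
                                   float(x[start:end].min()), gene.gene_id)
                    best_dist = dist
            i = j
        out[gene.gene_id] = best
    return out


def assign_plus_one(calls: Sequence[NucleosomeCall], gene: GeneModel,
                    search_window: int = 300) -> NucleosomeCall | None:
    """The first called dyad at or downstream of the TSS, transcription-wise.

    Returns None when no call lies within ``search_window`` bp downstream;
    such genes are excluded from anchored profiles.
    """
    candidates = [
        c for c in calls
        if c.chrom == gene.chrom
        and 0 <= gene.direction * (c.dyad - gene.tss) <= search_window
    ]
    if not candidates:
        logger.info("gene %s: no +1 nucleosome within %d bp of TSS", gene.gene_id, search_window)
        return None
    return min(candidates, key=lambda c: gene.direction * (c.dyad - gene.tss))


def occupancy_at(track: CoverageTrack, chrom: str, position: int, halfwidth: int) -> float:
    """Mean occupancy over [position - halfwidth, position + halfwidth)."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    x = track.data[chrom]
    lo = max(0, position - halfwidth)
    hi = min(x.size, position + halfwidth)
    if hi <= lo:
        raise ValueError("window lies outside the chromosome")
    return float(x[lo:hi].mean())
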