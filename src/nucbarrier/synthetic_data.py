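"""Synthetic MNase-seq data under a transcription-factor barrier model.

The generator encodes a minimal statistical-positioning picture of a
stress-gene promoter in fission yeast.  A bZIP transcription factor bound
at its CRE site excludes nucleosomes from a window around the motif
(the nucleosome-depleted region, NDR) and acts as a barrier against which
the +1 nucleosome is positioned.  Downstream nucleosomes are placed
sequentially with cumulative Gaussian jitter, so positional variance grows
with distance from the barrier and the phased array decays.  When the
barrier is absent (the TF-deletion condition) the +1 nucleosome slides
toward the promoter, its positioning broadens, and the array downstream
loses phasing — the two phenotypes the downstream analysis must detect.

Each simulated "cell" is one chromatin fiber; sequencing draws
mononucleosomal fragments from the pooled fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import AlignedRead, GeneModel, Genome

__all__ = [
    "SimConfig",
    "NucleosomeConfiguration",
    "make_gene_models",
    "make_genome",
    "simulate_configurations",
    "simulate_reads",
    "simulate_qpcr",
    "simulate_transcripts",
]

_MAX_REJECT = 1000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the barrier-model simulation.

    Distances are bp.  ``p_bound`` is the probability that the TF occupies
    the CRE in a given cell; the deletion condition is ``p_bound = 0``.
    ``plus_one_offset`` is the distance from the TSS to the +1 dyad when the
    barrier is bound; ``fill_shift`` is how far the +1 dyad slides toward
    the NDR when it is not.  ``sigma_step`` jitter accumulates along the
    downstream array, producing phasing decay.
    """

    n_genes: int = 50
    gene_spacing: int = 3300
    first_tss: int = 900
    chrom: str = "chrI"
    cre_offset: int = 150          # TSS - cre_site distance (upstream)
    p_bound: float = 0.9
    ndr_width: int = 150
    plus_one_offset: int = 75
    linker: int = 18
    nuc_footprint: int = 147
    n_nucleosomes: int = 16        # array length, +1 .. +n
    sigma_plus_one: float = 12.0
    sigma_minus_one: float = 30.0  # upstream (-1) nucleosomes are fuzzier
    sigma_step: float = 20.0
    sigma_plus_one_free: float = 25.0
    sigma_step_free: float = 45.0  # array jitter without the barrier anchor
    fill_shift: int = 130
    n_cells: int = 300
    total_reads: int = 100_000
    frag_mean: float = 147.0
    frag_sd: float = 10.0
    frag_min: int = 100
    frag_max: int = 250
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_bound <= 1.0:
            raise ValueError("p_bound must lie in [0, 1]")
        if self.sigma_plus_one_free < self.sigma_plus_one:
            raise ValueError("sigma_plus_one_free must be >= sigma_plus_one")
        if self.sigma_step_free < self.sigma_step:
            raise ValueError("sigma_step_free must be >= sigma_step")
        if self.nuc_footprint + self.linker <= 0:
            raise ValueError("nuc_footprint + linker must be positive")
        for name in ("ndr_width", "plus_one_offset", "linker", "nuc_footprint",
                     "fill_shift", "read_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def barrier_free(self) -> "SimConfig":
        """The same conditions with the TF barrier removed (p_bound = 0)."""
        return replace(self, p_bound=0.0)


def make_gene_models(cfg: SimConfig, strand: str = "+", atf1_dependent: bool = True) -> list[GeneModel]:
    """Evenly spaced co-oriented gene models on one toy chromosome.

    Each gene carries a CRE site ``cre_offset`` bp upstream of its TSS.
    """
    genes = []
    d = 1 if strand == "+" else -1
    for i in range(cfg.n_genes):
        tss = cfg.first_tss + i * cfg.gene_spacing
        genes.append(GeneModel(
            gene_id=f"g{i:03d}", chrom=cfg.chrom, strand=strand, tss=tss,
            cre_site=tss - d * cfg.cre_offset, atf1_dependent=atf1_dependent,
        ))
    return genes


def make_genome(cfg: SimConfig) -> Genome:
    """A genome just large enough for the gene models plus flanks."""
    array_span = cfg.plus_one_offset + (cfg.n_nucleosomes - 1) * (cfg.nuc_footprint + cfg.linker)
    length = cfg.first_tss + (cfg.n_genes - 1) * cfg.gene_spacing + array_span + 1000
    return Genome({cfg.chrom: int(length)})


@dataclass
class NucleosomeConfiguration:
    """Ground-truth dyad positions per cell and gene.

    ``dyads[gene_id]`` is an integer array of shape (n_cells, n_positions)
    whose columns follow ``indices[gene_id]`` (-1 for the upstream
    nucleosome when a CRE is annotated, then 1..n for the array).
    """

    genes: list[GeneModel]
    genome: Genome
    n_cells: int
    dyads: dict[str, np.ndarray] = field(default_factory=dict)
    indices: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell, gene, index, dyad."""
        frames = []
        for g in self.genes:
            arr = self.dyads[g.gene_id]
            idx = self.indices[g.gene_id]
            n_cells, n_pos = arr.shape
            frames.append(pd.DataFrame({
                "cell": np.repeat(np.arange(n_cells), n_pos),
                "gene": g.gene_id,
                "index": np.tile(idx, n_cells),
                "dyad": arr.ravel(),
            }))
        return pd.concat(frames, ignore_index=True)

    def flat_dyads(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All dyads flattened: (chrom codes, cell ids, dyad coords).

        Chrom codes index into the genome's chromosome order.
        """
        chrom_order = {name: i for i, name in enumerate(self.genome)}
        codes, cells, coords = [], [], []
        for g in self.genes:
            arr = self.dyads[g.gene_id]
            n_cells, n_pos = arr.shape
            codes.append(np.full(arr.size, chrom_order[g.chrom], dtype=np.int64))
            cells.append(np.repeat(np.arange(n_cells), n_pos))
            coords.append(arr.ravel())
        return (np.concatenate(codes), np.concatenate(cells), np.concatenate(coords))

    def true_array_dyads(self, gene_id: str, k_max: int | None = None) -> np.ndarray:
        """Mean dyad position per array index +1..+k over cells."""
        idx = self.indices[gene_id]
        sel = idx >= 1 if k_max is None else (idx >= 1) & (idx <= k_max)
        return self.dyads[gene_id][:, sel].mean(axis=0)


def _genome_for(genes: Sequence[GeneModel], cfg: SimConfig) -> Genome:
    """Smallest genome covering every gene's nucleosomes plus 1 kb flanks."""
    array_span = cfg.plus_one_offset + (cfg.n_nucleosomes - 1) * (cfg.nuc_footprint + cfg.linker)
    lengths: dict[str, int] = {}
    for g in genes:
        far = g.tss + array_span if g.strand == "+" else g.tss + cfg.cre_offset + cfg.ndr_width
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), far + 1000)
    return Genome(lengths)


def simulate_configurations(genes: Sequence[GeneModel], cfg: SimConfig,
                            seed: int | None = None,
                            genome: Genome | None = None) -> NucleosomeConfiguration:
    """Place nucleosomes for every cell and gene under the barrier model.

    Per cell: the barrier is bound with probability ``p_bound``.  Bound
    cells position the +1 dyad at ``tss + plus_one_offset`` with jitter
    ``sigma_plus_one`` and exclude all dyads from the NDR window around the
    CRE; unbound cells shift the +1 by ``fill_shift`` toward the promoter
    with the wider ``sigma_plus_one_free`` and no exclusion.  Array
    nucleosomes follow at ``footprint + linker`` steps with per-step jitter,
    re-drawn on hard-core violations.  One upstream (-1) nucleosome mirrors
    the +1 across the CRE.  Minus-strand genes mirror every offset.
    """
    genome = genome or _genome_for(genes, cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    out = NucleosomeConfiguration(genes=list(genes), genome=genome, n_cells=cfg.n_cells)
    half_ndr = cfg.ndr_width / 2.0

    for gene in genes:
        d = gene.direction
        n = cfg.n_cells
        bound = rng.random(n) < cfg.p_bound

        nominal = np.where(
            bound,
            gene.tss + d * cfg.plus_one_offset,
            gene.tss + d * (cfg.plus_one_offset - cfg.fill_shift),
        ).astype(float)
        sigma = np.where(bound, cfg.sigma_plus_one, cfg.sigma_plus_one_free)
        plus_one = nominal + rng.normal(0.0, 1.0, n) * sigma

        def ndr_violation(pos: np.ndarray) -> np.ndarray:
            if gene.cre_site is None:
                return np.zeros(pos.shape, dtype=bool)
            inside = np.abs(pos - gene.cre_site) <= half_ndr
            return inside & bound  # exclusion only applies while the TF is bound

        plus_one = _reject_loop(
            rng, plus_one, ndr_violation,
            lambda r, m: nominal[m] + r.normal(0.0, 1.0, m.sum()) * sigma[m],
            "+1 dyad vs NDR exclusion",
        )

        # downstream array: cumulative steps with hard-core re-draws; without
        # the barrier anchor the per-step jitter itself is larger, so the
        # array dephases faster
        n_steps = cfg.n_nucleosomes - 1
        if n_steps > 0:
            step_sigma = np.where(bound, cfg.sigma_step, cfg.sigma_step_free)
            sig_mat = np.broadcast_to(step_sigma[:, None], (n, n_steps))
            steps = cfg.nuc_footprint + cfg.linker + rng.normal(0.0, 1.0, (n, n_steps)) * sig_mat
            for _ in range(_MAX_REJECT):
                bad = steps < cfg.nuc_footprint
                if not bad.any():
                    break
                steps[bad] = (cfg.nuc_footprint + cfg.linker
                              + rng.normal(0.0, 1.0, int(bad.sum())) * sig_mat[bad])
            else:
                raise RuntimeError("rejection sampling failed: linker too short for sigma_step")
            array = plus_one[:, None] + d * np.cumsum(steps, axis=1)
            dyads = np.column_stack([plus_one, array])
        else:
            dyads = plus_one[:, None]
        index = np.arange(1, cfg.n_nucleosomes + 1)

        if gene.cre_site is not None:
            # -1 nucleosome: the +1's mirror image across the CRE barrier,
            # with the (empirically fuzzier) upstream positioning jitter
            m_nominal = np.where(
                bound,
                2 * gene.cre_site - (gene.tss + d * cfg.plus_one_offset),
                2 * gene.cre_site - (gene.tss + d * cfg.plus_one_offset) + d * cfg.fill_shift,
            ).astype(float)
            m_sigma = np.where(bound, cfg.sigma_minus_one, cfg.sigma_plus_one_free)
            # the -1 must clear the +1 by a full footprint and, while the TF
            # is bound, stay out of the NDR; sample the truncated normal
            # exactly (inverse CDF) rather than reject, since the +1 can
            # wander far enough to make rejection arbitrarily inefficient
            limit = plus_one - d * cfg.nuc_footprint
            if gene.cre_site is not None:
                ndr_edge = gene.cre_site - d * (half_ndr + 1)
                limit = np.where(bound, np.minimum(d * limit, d * ndr_edge) * d, limit)
            z_lim = d * (limit - m_nominal) / np.maximum(m_sigma, 1e-12)
            tail = norm.cdf(z_lim)
            if np.any(tail < 1e-14):
                raise RuntimeError("degenerate config: no room for the -1 nucleosome")
            u = rng.random(n)
            if np.all(m_sigma == 0):
                minus_one = np.minimum(d * m_nominal, d * limit) * d
            else:
                minus_one = m_nominal + d * m_sigma * norm.ppf(u * tail)
            dyads = np.column_stack([minus_one, dyads])
            index = np.concatenate([[-1], index])

        out.dyads[gene.gene_id] = np.rint(dyads).astype(np.int64)
        out.indices[gene.gene_id] = index
    return out


def _reject_loop(rng, values, violation, redraw, what):
    for _ in range(_MAX_REJECT):
        bad = violation(values)
        if not bad.any():
            return values
        values = values.copy()
        values[bad] = redraw(rng, bad)
    raise RuntimeError(f"rejection sampling failed after {_MAX_REJECT} attempts ({what})")


def simulate_reads(config: NucleosomeConfiguration, cfg: SimConfig,
                   seed: int | None = None) -> list[AlignedRead]:
    """Draw single-end reads from mononucleosomal fragments.

    Each read picks a (cell, gene, nucleosome) uniformly, wraps the dyad in
    a fragment of length ~N(frag_mean, frag_sd) clamped to the
    gel-purification window, and sequences one end on a random strand.
    Fragments that would extend past a chromosome end are re-drawn.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    chrom_names = list(config.genome)
    chrom_lens = np.array([config.genome[c] for c in chrom_names])
    codes, _, coords = config.flat_dyads()
    n_dyads = coords.size
    if n_dyads == 0:
        return []

    total = cfg.total_reads
    idx = np.empty(total, dtype=np.int64)
    frag_len = np.empty(total, dtype=np.int64)
    pending = np.ones(total, dtype=bool)
    for _ in range(_MAX_REJECT):
        k = int(pending.sum())
        if k == 0:
            break
        idx[pending] = rng.integers(0, n_dyads, k)
        f = np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, k))
        frag_len[pending] = np.clip(f, cfg.frag_min, cfg.frag_max).astype(np.int64)
        left = coords[idx] - frag_len // 2
        right = left + frag_len
        pending = (left < 0) | (right > chrom_lens[codes[idx]])
    else:
        raise RuntimeError("fragment resampling failed: dyads too close to chromosome ends")

    left = coords[idx] - frag_len // 2
    right = left + frag_len
    read_len = np.minimum(cfg.read_length, frag_len)
    is_plus = rng.random(total) < 0.5
    start = np.where(is_plus, left, right - read_len)
    code = codes[idx]
    return [
        AlignedRead(chrom_names[code[i]], int(start[i]), int(read_len[i]),
                    "+" if is_plus[i] else "-")
        for i in range(total)
    ]


def amplicon_protection(config: NucleosomeConfiguration, center: int, halfwidth: int,
                        chrom: str | None = None) -> float:
    """Fraction of cells in which a nucleosome footprint fully covers the amplicon.

    The footprint is the 147 bp window [dyad-73, dyad+74); the amplicon
    spans [center-halfwidth, center+halfwidth] inclusive.
    """
    chrom = chrom or next(iter(config.genome))
    if not (0 <= center - halfwidth and center + halfwidth < config.genome[chrom]):
        raise ValueError(f"amplicon at {center}±{halfwidth} lies outside {chrom}")
    chrom_order = {name: i for i, name in enumerate(config.genome)}
    codes, cells, coords = config.flat_dyads()
    on_chrom = codes == chrom_order[chrom]
    covered = on_chrom & (coords <= center - halfwidth + 73) & (coords >= center + halfwidth - 73)
    protected_cells = np.unique(cells[covered])
    return protected_cells.size / config.n_cells


def simulate_qpcr(config: NucleosomeConfiguration, amplicons: Sequence[tuple[int, int]],
                  replicates: int = 3, noise_cv: float = 0.1,
                  seed: int | None = None, strain: str = "WT",
                  chrom: str | None = None, tss: int | None = None) -> pd.DataFrame:
    """Nucleosome-scanning qPCR table for a tiling-amplicon set.

    The mononucleosomal quantity of an amplicon is its true protection
    (fraction of cells fully covering it) with multiplicative Gaussian
    noise; the undigested input is 1 with the same noise model.  Positions
    are reported relative to ``tss`` when given, absolute otherwise.
    """
    rng = np.random.default_rng(seed if seed is not None else 0)
    rows = []
    for i, (center, halfwidth) in enumerate(amplicons):
        prot = amplicon_protection(config, center, halfwidth, chrom=chrom)
        pos = center - tss if tss is not None else center
        for rep in range(1, replicates + 1):
            mono = max(prot * (1.0 + rng.normal(0.0, noise_cv)), 0.0)
            inp = max(1.0 * (1.0 + rng.normal(0.0, noise_cv)), 1e-9)
            rows.append({"target": f"amp{i:02d}", "position": pos, "replicate": rep,
                         "mono_quantity": mono, "input_quantity": inp, "strain": strain})
    return pd.DataFrame(rows)


def simulate_transcripts(genes: Sequence[GeneModel], condition: str,
                         base_sense: float = 10.0, base_antisense: float = 1.0,
                         antisense_fold: float = 4.0, noise_cv: float = 0.1,
                         replicates: int = 3, seed: int | None = None) -> pd.DataFrame:
    """Strand-specific RT-qPCR quantities for one condition.

    Antisense transcription is elevated ``antisense_fold``-fold only for
    barrier-dependent genes in the ``no_barrier`` condition; sense levels
    and barrier-independent genes are untouched.
    """
    if condition not in ("barrier", "no_barrier"):
        raise ValueError(f"condition must be 'barrier' or 'no_barrier', got {condition!r}")
    rng = np.random.default_rng(seed if seed is not None else 0)
    rows = []
    for gene in genes:
        for sense_label, base in (("sense", base_sense), ("antisense", base_antisense)):
            fold = 1.0
            if (sense_label == "antisense" and gene.atf1_dependent
                    and condition == "no_barrier"):
                fold = antisense_fold
            for rep in range(1, replicates + 1):
                q = base * fold * (1.0 + rng.normal(0.0, noise_cv))
                rows.append({"gene": gene.gene_id, "strand_sense": sense_label,
                             "quantity": max(q, 1e-9), "replicate": rep,
                             "strain": condition})
    return pd.DataFrame(rows)
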