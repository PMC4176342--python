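"""End-to-end convenience pipeline: simulation through anchored composites.

Chains the individual stages with their defaults so the CLI, tests and
reproduction script share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calling import NucleosomeCall, assign_plus_one, call_peaks, detect_ndr
from .coverage import CoverageTrack, ProcessingParams, build_coverage, estimate_fragment_length, normalize_rpm
from .io_formats import AlignedRead, GeneModel
from .profiles import ProfileMatrix, build_anchor_matrix
from .smoothing import smooth_track
from .synthetic_data import NucleosomeConfiguration, SimConfig, simulate_configurations, simulate_reads

__all__ = ["ConditionRun", "run_condition", "reads_to_smoothed_track"]


@dataclass
class ConditionRun:
    """All intermediate products of one simulated condition."""

    cfg: SimConfig
    genes: list[GeneModel]
    config: NucleosomeConfiguration
    reads: list[AlignedRead]
    fragment_length: int
    raw: CoverageTrack
    rpm: CoverageTrack
    smoothed: CoverageTrack
    calls: list[NucleosomeCall]
    plus_one: dict[str, NucleosomeCall | None]
    ndrs: dict
    matrix_plus_one: ProfileMatrix
    matrix_cre: ProfileMatrix


def reads_to_smoothed_track(reads, genome, params: ProcessingParams | None = None,
                            fragment_length: int | None = None):
    """Reads -> dyad coverage -> RPM -> FFT smoothing.

    Returns (raw, rpm, smoothed, fragment_length); the fragment length is
    estimated by strand cross-correlation unless supplied.
    """
    params = params or ProcessingParams()
    if fragment_length is None:
        fragment_length = params.fragment_length or estimate_fragment_length(
            reads, params.lag_search)
    raw = build_coverage(reads, fragment_length, params, genome)
    rpm = normalize_rpm(raw)
    smoothed = smooth_track(rpm, params.pc_keep)
    return raw, rpm, smoothed, fragment_length


def run_condition(cfg: SimConfig, genes: list[GeneModel] | None = None,
                  seed: int | None = None,
                  params: ProcessingParams | None = None) -> ConditionRun:
    """Simulate one condition and run the full analysis on it."""
    from .synthetic_data import make_gene_models

    params = params or ProcessingParams()
    genes = genes if genes is not None else make_gene_models(cfg)
    base_seed = cfg.seed if seed is None else seed
    config = simulate_configurations(genes, cfg, seed=base_seed)
    reads = simulate_reads(config, cfg, seed=base_seed + 1)
    raw, rpm, smoothed, frag = reads_to_smoothed_track(reads, config.genome, params)
    calls = call_peaks(smoothed, refine_track=rpm)
    plus_one = {g.gene_id: assign_plus_one(calls, g) for g in genes}
    ndrs = detect_ndr(smoothed, genes)
    anchors_p1 = {gid: c.dyad for gid, c in plus_one.items() if c is not None}
    anchors_cre = {g.gene_id: g.cre_site for g in genes if g.cre_site is not None}
    matrix_p1 = build_anchor_matrix(smoothed, genes, anchors_p1, params.flank, "plus_one")
    matrix_cre = build_anchor_matrix(smoothed, genes, anchors_cre, params.flank, "cre")
    return ConditionRun(cfg=cfg, genes=genes, config=config, reads=reads,
                        fragment_length=frag, raw=raw, rpm=rpm, smoothed=smoothed,
                        calls=calls, plus_one=plus_one, ndrs=ndrs,
                        matrix_plus_one=matrix_p1, matrix_cre=matrix_cre)
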