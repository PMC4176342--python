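import dataclasses

import numpy as np
import pytest

from nucbarrier.io_formats import GeneModel
from nucbarrier.synthetic_data import (SimConfig, amplicon_protection, make_gene_models,
                                       simulate_configurations, simulate_qpcr, simulate_reads,
                                       simulate_transcripts)


class TestSimConfig:
    def test_invalid_p_bound_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_bound=1.5)

    def test_free_jitter_must_dominate_bound_jitter(self):
        with pytest.raises(ValueError):
            SimConfig(sigma_plus_one=20.0, sigma_plus_one_free=10.0)


class TestConfigurations:
    def test_zero_noise_dyads_sit_on_the_exact_lattice(self, zero_jitter_cfg):
        cfg = dataclasses.replace(zero_jitter_cfg, n_genes=2, n_cells=5)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        for g in genes:
            idx = config.indices[g.gene_id]
            arr = config.dyads[g.gene_id][:, idx >= 1]
            expected = g.tss + cfg.plus_one_offset + np.arange(cfg.n_nucleosomes) * 165
            assert (arr == expected).all()

    def test_same_seed_reproduces_configurations_bitwise(self, small_cfg):
        genes = make_gene_models(small_cfg)
        a = simulate_configurations(genes, small_cfg, seed=7)
        b = simulate_configurations(genes, small_cfg, seed=7)
        for gid in a.dyads:
            assert (a.dyads[gid] == b.dyads[gid]).all()

    def test_fill_shift_moves_mean_plus_one_toward_the_ndr(self):
        cfg = SimConfig(n_genes=1, n_cells=20_000, fill_shift=80,
                        sigma_plus_one=12.0, sigma_plus_one_free=12.0)
        genes = make_gene_models(cfg)
        bound = simulate_configurations(genes, dataclasses.replace(cfg, p_bound=1.0), seed=1)
        free = simulate_configurations(genes, dataclasses.replace(cfg, p_bound=0.0), seed=1)
        gid = genes[0].gene_id
        p1 = lambda c: c.dyads[gid][:, c.indices[gid] == 1].mean()
        shift = p1(bound) - p1(free)
        se = 12.0 / np.sqrt(cfg.n_cells)
        assert abs(shift - 80) <= 3 * se * np.sqrt(2)

    def test_hard_core_between_all_consecutive_dyads(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, p_bound=0.5, n_cells=2000)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        for g in genes:
            arr = np.sort(config.dyads[g.gene_id], axis=1)
            assert (np.diff(arr, axis=1) >= cfg.nuc_footprint).all()

    def test_bound_cells_keep_dyads_out_of_the_ndr(self):
        cfg = SimConfig(n_genes=2, n_cells=3000, p_bound=1.0)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        for g in genes:
            d = config.dyads[g.gene_id]
            assert (np.abs(d - g.cre_site) > cfg.ndr_width / 2).all()

    def test_positional_variance_grows_along_the_array(self, small_cfg):
        cfg = dataclasses.replace(small_cfg, n_cells=5000, p_bound=1.0)
        genes = make_gene_models(cfg)[:1]
        config = simulate_configurations(genes, cfg)
        gid = genes[0].gene_id
        idx = config.indices[gid]
        sd = config.dyads[gid].std(axis=0)
        assert sd[idx == 4] > sd[idx == 1]

    def test_minus_strand_gene_mirrors_its_plus_twin(self, zero_jitter_cfg):
        cfg = dataclasses.replace(zero_jitter_cfg, n_cells=10)
        plus = GeneModel("p", "chrI", "+", 5000, 5000 - cfg.cre_offset)
        minus = GeneModel("m", "chrI", "-", 5000, 5000 + cfg.cre_offset)
        cp = simulate_configurations([plus], cfg)
        cm = simulate_configurations([minus], cfg)
        mirrored = 2 * 5000 - cm.dyads["m"]
        assert (np.sort(cp.dyads["p"], axis=1) == np.sort(mirrored, axis=1)).all()


class TestReads:
    def test_fixed_fragment_read_ends_are_closed_form(self, zero_jitter_cfg):
        cfg = dataclasses.replace(zero_jitter_cfg, n_genes=1, n_cells=3,
                                  frag_mean=150.0, total_reads=2000)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        reads = simulate_reads(config, cfg, seed=0)
        dyads = set(config.dyads[genes[0].gene_id].ravel().tolist())
        for r in reads[:500]:
            if r.strand == "+":
                assert r.start + 75 in dyads
            else:
                assert r.end - 75 in dyads  # fragment end = dyad + 75 (F=150)

    def test_mean_plus_start_recovers_mean_dyad(self, zero_jitter_cfg):
        cfg = dataclasses.replace(zero_jitter_cfg, n_genes=1, n_nucleosomes=1,
                                  n_cells=3, frag_sd=10.0, total_reads=100_000)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        reads = simulate_reads(config, cfg, seed=0)
        starts = np.array([r.start for r in reads if r.strand == "+"])
        true_dyad = config.dyads[genes[0].gene_id].mean()
        assert abs(starts.mean() + cfg.frag_mean / 2 - true_dyad) <= 1.0

    def test_read_count_is_conserved_and_seed_deterministic(self, small_cfg):
        genes = make_gene_models(small_cfg)
        config = simulate_configurations(genes, small_cfg)
        a = simulate_reads(config, small_cfg, seed=9)
        b = simulate_reads(config, small_cfg, seed=9)
        assert len(a) == small_cfg.total_reads
        assert a == b


class TestQpcr:
    def test_amplicon_on_zero_noise_dyad_is_fully_protected(self, zero_jitter_cfg):
        cfg = dataclasses.replace(zero_jitter_cfg, n_genes=1, n_cells=10)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        dyad = int(config.dyads[genes[0].gene_id][0, 1])
        assert amplicon_protection(config, dyad, 30) == 1.0

    def test_mid_ndr_amplicon_is_unprotected_when_bound(self, zero_jitter_cfg):
        cfg = dataclasses.replace(zero_jitter_cfg, n_genes=1, n_cells=10)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        assert amplicon_protection(config, genes[0].cre_site, 30) == 0.0

    def test_amplicon_outside_genome_is_an_error(self, zero_jitter_cfg):
        cfg = dataclasses.replace(zero_jitter_cfg, n_genes=1, n_cells=5)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        with pytest.raises(ValueError, match="outside"):
            amplicon_protection(config, 10**7, 30)

    def test_zero_noise_replicates_are_identical(self, zero_jitter_cfg):
        cfg = dataclasses.replace(zero_jitter_cfg, n_genes=1, n_cells=10)
        genes = make_gene_models(cfg)
        config = simulate_configurations(genes, cfg)
        table = simulate_qpcr(config, [(genes[0].tss + 100, 30)], replicates=3,
                              noise_cv=0.0, seed=0)
        assert table["mono_quantity"].nunique() == 1
        assert (table["input_quantity"] == 1.0).all()


class TestTranscripts:
    @pytest.fixture
    def mixed_genes(self):
        return [GeneModel("dep", "chrI", "+", 1000, 800, True),
                GeneModel("indep", "chrI", "+", 9000, 8800, False)]

    def test_fold_applies_only_to_dependent_antisense(self, mixed_genes):
        kw = dict(noise_cv=0.0, antisense_fold=4.0, replicates=2, seed=0)
        barrier = simulate_transcripts(mixed_genes, "barrier", **kw)
        free = simulate_transcripts(mixed_genes, "no_barrier", **kw)
        merged = barrier.merge(free, on=["gene", "strand_sense", "replicate"],
                               suffixes=("_b", "_f"))
        ratio = merged["quantity_f"] / merged["quantity_b"]
        anti_dep = (merged["gene"] == "dep") & (merged["strand_sense"] == "antisense")
        assert (ratio[anti_dep] == 4.0).all()
        assert (ratio[~anti_dep] == 1.0).all()

    def test_fixed_seed_reproducibility(self, mixed_genes):
        a = simulate_transcripts(mixed_genes, "barrier", seed=5)
        b = simulate_transcripts(mixed_genes, "barrier", seed=5)
        assert a.equals(b)

    def test_unknown_condition_rejected(self, mixed_genes):
        with pytest.raises(ValueError, match="condition"):
            simulate_transcripts(mixed_genes, "mutant")
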