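import numpy as np
import pytest

from nucbarrier.coverage import (CoverageTrack, ProcessingParams, build_coverage, dyad_interval,
                                 estimate_fragment_length, normalize_rpm)
from nucbarrier.io_formats import AlignedRead, Genome


def _paired_reads(offset: int, n: int = 200, chrom: str = "chrI"):
    """+ starts at x and - 5' ends at x + offset, for many x."""
    reads = []
    rng = np.random.default_rng(1)
    for x in rng.integers(1000, 50_000, n):
        reads.append(AlignedRead(chrom, int(x), 50, "+"))
        reads.append(AlignedRead(chrom, int(x) + offset - 49, 50, "-"))
    return reads


class TestFragmentLength:
    def test_constructed_five_prime_offset_149_gives_insert_150(self):
        # - 5' end sits 149 bp right of the + start: insert size = 150
        assert estimate_fragment_length(_paired_reads(149)) == 150

    def test_recovery_from_simulated_library(self, wt_run):
        # frag_mean = 147, frag_sd = 10, 1e5 reads
        assert abs(wt_run.fragment_length - 147) <= 3

    def test_single_strand_input_is_an_error(self):
        reads = [AlignedRead("chrI", x, 50, "+") for x in range(1000, 1200)]
        with pytest.raises(ValueError, match="both strands"):
            estimate_fragment_length(reads)

    def test_flat_correlation_is_an_error(self):
        # one read per strand on far-apart chromosomescannot peak
        reads = [AlignedRead("chrI", 500, 50, "+"), AlignedRead("chrII", 500, 50, "-")]
        with pytest.raises(ValueError, match="no fragment-length signal"):
            estimate_fragment_length(reads)


class TestDyadInterval:
    params = ProcessingParams()

    def test_plus_read_shifts_forward_by_half_fragment(self):
        read = AlignedRead("chrI", 1000, 50, "+")
        assert dyad_interval(read, 150, self.params) == ("chrI", 1055, 1095)

    def test_minus_read_shifts_its_five_prime_end_back(self):
        read = AlignedRead("chrI", 1000, 50, "-")
        assert dyad_interval(read, 150, self.params) == ("chrI", 954, 994)

    @pytest.mark.parametrize("frag", [101, 147, 150, 250])
    @pytest.mark.parametrize("strand", "+-")
    def test_interval_width_always_equals_trim(self, frag, strand):
        read = AlignedRead("chrI", 5000, 50, strand)
        _, lo, hi = dyad_interval(read, frag, self.params)
        assert hi - lo == self.params.trim

    def test_fragment_shorter_than_trim_rejected(self):
        with pytest.raises(ValueError):
            dyad_interval(AlignedRead("chrI", 0, 50, "+"), 30, self.params)

    def test_trim_extension_consistency_enforced(self):
        with pytest.raises(ValueError, match="trim"):
            ProcessingParams(trim=40, extension=15)


class TestBuildCoverage:
    genome = Genome({"chrI": 10_000})
    params = ProcessingParams()

    def test_one_read_covers_exactly_trim_bases_at_one(self):
        track = build_coverage([AlignedRead("chrI", 1000, 50, "+")], 150, self.params, self.genome)
        x = track.data["chrI"]
        assert x.sum() == 40
        assert (x[1055:1095] == 1).all()
        assert x[1054] == 0 and x[1095] == 0

    def test_total_mass_is_reads_times_trim(self):
        rng = np.random.default_rng(2)
        reads = [AlignedRead("chrI", int(s), 50, "+-"[i % 2])
                 for i, s in enumerate(rng.integers(200, 9500, 500))]
        track = build_coverage(reads, 147, self.params, self.genome)
        assert track.clipped == 0
        assert track.total() == 500 * 40

    def test_overlapping_intervals_stack(self):
        reads = [AlignedRead("chrI", 1000, 50, "+"), AlignedRead("chrI", 1010, 50, "+")]
        track = build_coverage(reads, 150, self.params, self.genome)
        assert track.data["chrI"].max() == 2

    def test_edge_interval_is_clipped_and_counted(self):
        track = build_coverage([AlignedRead("chrI", 0, 50, "-")], 150, self.params, self.genome)
        assert track.clipped == 1
        assert track.total() < 40

    def test_mirrored_reads_give_mirrored_track(self):
        L = self.genome["chrI"]
        reads = [AlignedRead("chrI", 1000, 50, "+"), AlignedRead("chrI", 4321, 60, "-")]
        flipped = [AlignedRead("chrI", L - r.end, r.length, "-" if r.strand == "+" else "+")
                   for r in reads]
        fwd = build_coverage(reads, 146, self.params, self.genome)
        rev = build_coverage(flipped, 146, self.params, self.genome)
        # the half-open width-40 dyad window sits 0.5 bp left of the dyad,
        # so mirroring the genome shifts coverage by exactly one base
        np.testing.assert_array_equal(rev.data["chrI"][:-1], fwd.data["chrI"][::-1][1:])

    def test_dyad_coverage_peaks_on_true_dyads(self, zero_jitter_run):
        # frag_sd = 0: each nucleosome's raw-coverage plateau is centered
        # on its dyad to within 1 bp
        run = zero_jitter_run
        x = run.raw.data["chrI"]
        g = run.genes[10]
        idx = run.config.indices[g.gene_id]
        for dyad in run.config.dyads[g.gene_id][0][idx >= 1][:4]:
            window = x[dyad - 60:dyad + 60]
            plateau = np.flatnonzero(window == window.max())
            center = (plateau[0] + plateau[-1]) / 2 - 60
            assert abs(center) <= 1


class TestNormalizeRpm:
    def _track(self, values, total):
        return CoverageTrack(data={"chrI": np.asarray(values, float)},
                             state="raw", total_mapped=total)

    def test_per_million_scaling(self):
        out = normalize_rpm(self._track([5.0], 10**6))
        assert out.data["chrI"][0] == 5.0
        out = normalize_rpm(self._track([3.0], 2 * 10**6))
        assert out.data["chrI"][0] == 1.5
        assert out.state == "rpm"

    def test_linearity_of_total(self):
        rng = np.random.default_rng(3)
        values = rng.poisson(4, 1000).astype(float)
        track = self._track(values, 12345)
        out = normalize_rpm(track)
        assert abs(out.total() - track.total() * 1e6 / 12345) < 1e-9 * out.total()

    def test_zero_total_mapped_is_an_error(self):
        with pytest.raises(ValueError, match="total_mapped"):
            normalize_rpm(self._track([1.0], 0))
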