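"""Read-depth profile construction: loading, GC handling, masking."""

import numpy as np
import pysam
import pytest

from dpcnv.profile import (
    annotate_gc,
    correct_gc_bias,
    load_read_counts,
    mask_low_quality_bins,
    write_count_tsv,
)
from dpcnv.simulate import SimConfig, simulate_profile

from conftest import make_profile


def _write_bam(path, reads, ref_len=10_000):
    """reads: list of (pos, flag) on a single 10 kb contig."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr1", "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (pos, flag) in enumerate(sorted(reads)):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.query_sequence = "A" * 50
            a.query_qualities = pysam.qualitystring_to_array("I" * 50)
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = "50M"
            a.mapping_quality = 60
            a.flag = flag
            bam.write(a)
    pysam.index(str(path))


class TestLoadReadCounts:
    def test_single_read_lands_in_its_bin(self, tmp_path):
        bam = tmp_path / "one.bam"
        _write_bam(bam, [(1500, 0)])
        prof = load_read_counts(bam, bin_size=1000)
        assert prof.n_bins == 10
        assert prof.count[1] == 1
        assert prof.count.sum() == 1

    def test_filtered_flags_are_skipped(self, tmp_path):
        bam = tmp_path / "flags.bam"
        # primary, duplicate (0x400), secondary (0x100), unmapped (0x4)
        _write_bam(bam, [(100, 0), (200, 0x400), (300, 0x100), (400, 0x4)])
        prof = load_read_counts(bam, bin_size=1000)
        assert prof.count.sum() == 1
        assert prof.count[0] == 1

    def test_missing_index_is_named(self, tmp_path):
        bam = tmp_path / "noidx.bam"
        _write_bam(bam, [(100, 0)])
        (tmp_path / "noidx.bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match="noidx.bam"):
            load_read_counts(bam)

    def test_tsv_pass_through(self, tmp_path):
        p = tmp_path / "counts.tsv"
        p.write_text("#chrom\tstart\tcount\tgc\nchr1\t0\t5\t0.4\nchr1\t1000\t7\t0.5\n")
        prof = load_read_counts(p, bin_size=1000)
        assert prof.n_bins == 2
        assert list(prof.count) == [5, 7]
        assert np.allclose(prof.gc, [0.4, 0.5])

    def test_unsorted_tsv_rejected_with_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("#chrom\tstart\tcount\tgc\nchr1\t1000\t5\t\nchr1\t0\t7\t\n")
        with pytest.raises(ValueError, match="unsorted|overlapping"):
            load_read_counts(p, bin_size=1000)

    def test_bin_size_floor(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("#chrom\tstart\tcount\tgc\nchr1\t0\t5\t\n")
        with pytest.raises(ValueError, match="bin_size"):
            load_read_counts(p, bin_size=50)

    def test_simulator_tsv_round_trip(self, tmp_path):
        prof, _ = simulate_profile(SimConfig(n_bins=500, seed=3))
        out = tmp_path / "sim.tsv"
        write_count_tsv(prof, out)
        back = load_read_counts(out, bin_size=prof.width)
        assert np.array_equal(back.count, prof.count)
        assert np.array_equal(back.start, prof.start)
        assert np.allclose(back.gc, prof.gc, atol=1e-6)


class TestAnnotateGC:
    def _fasta(self, tmp_path, seq):
        p = tmp_path / "ref.fa"
        p.write_text(">chr1\n" + "\n".join(seq[i:i + 60] for i in range(0, len(seq), 60)) + "\n")
        return p

    def test_all_gc_bin(self, tmp_path):
        ref = self._fasta(tmp_path, "GGCC" * 250)  # 1000 bp, all G/C
        prof = make_profile([10], width=1000)
        out = annotate_gc(prof, ref)
        assert out.gc[0] == 1.0

    def test_fractional_gc(self, tmp_path):
        ref = self._fasta(tmp_path, "GC" * 200 + "AT" * 300)  # 400 G+C in 1000
        prof = make_profile([10], width=1000)
        out = annotate_gc(prof, ref)
        assert out.gc[0] == pytest.approx(0.4)

    def test_n_heavy_bin_masked(self, tmp_path):
        ref = self._fasta(tmp_path, "N" * 600 + "ACGT" * 100)
        prof = make_profile([10], width=1000)
        out = annotate_gc(prof, ref)
        assert out.mask[0]

    def test_missing_chromosome_named(self, tmp_path):
        ref = self._fasta(tmp_path, "ACGT" * 250)
        prof = make_profile([1, 1], chrom="chrX")
        with pytest.raises(ValueError, match="chrX"):
            annotate_gc(prof, ref)


class TestCorrectGC:
    def test_single_stratum_identity(self):
        prof = make_profile([10, 12, 14, 11, 13] * 5, gc=[0.455] * 25)
        out = correct_gc_bias(prof, min_bins_per_stratum=1)
        assert np.allclose(out.rd, out.rd_raw)

    def test_two_strata_median_ratio(self):
        # stratum A median 10, stratum B median 20, global median 15
        counts = [10] * 10 + [20] * 10
        gc = [0.30] * 10 + [0.60] * 10
        prof = make_profile(counts, gc=gc)
        out = correct_gc_bias(prof, min_bins_per_stratum=1)
        assert np.allclose(out.rd[:10], 15.0)   # x1.5
        assert np.allclose(out.rd[10:], 15.0)   # x0.75

    def test_sparse_stratum_uncorrected(self):
        counts = [10] * 30 + [100]
        gc = [0.45] * 30 + [0.72]
        prof = make_profile(counts, gc=gc)
        out = correct_gc_bias(prof, min_bins_per_stratum=20)
        assert out.rd[-1] == 100.0  # lone stratum borrows no correction

    def test_zero_median_stratum_masked(self):
        counts = [10] * 30 + [0, 0]
        gc = [0.45] * 30 + [0.70, 0.701]
        prof = make_profile(counts, gc=gc)
        out = correct_gc_bias(prof, gc_bin_width=0.01, min_bins_per_stratum=1)
        assert out.mask[-2:].all()

    def test_all_masked_errors(self):
        prof = make_profile([1, 2, 3])
        prof.mask[:] = True
        with pytest.raises(ValueError, match="masked"):
            correct_gc_bias(prof)

    def test_median_preserved_and_scale_equivariant(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(50, 2000)
        gc = rng.uniform(0.35, 0.55, 2000).round(3)
        prof = make_profile(counts, gc=gc)
        out = correct_gc_bias(prof, min_bins_per_stratum=1)
        m = np.median(prof.rd_raw)
        assert np.median(out.rd[~out.mask]) == pytest.approx(m, rel=0.02)
        # scale equivariance
        prof2 = make_profile(counts, gc=gc)
        prof2.rd_raw = prof2.rd_raw * 3.0
        out2 = correct_gc_bias(prof2, min_bins_per_stratum=1)
        assert np.allclose(out2.rd, out.rd * 3.0)

    def test_simulated_gc_bias_removed(self):
        prof, _ = simulate_profile(SimConfig(n_bins=20_000, gc_bias=0.4, seed=5))
        before = np.corrcoef(prof.rd_raw, prof.gc)[0, 1]
        out = correct_gc_bias(prof)
        ok = ~out.mask
        after = np.corrcoef(out.rd[ok], out.gc[ok])[0, 1]
        assert abs(before) > 0.5
        assert abs(after) < 0.1


class TestMaskLowQuality:
    @pytest.mark.parametrize(
        "counts,run_min,expect_masked",
        [
            ([0] * 15 + [5] * 5, 10, 15),
            ([5] * 3 + [0] * 5 + [5] * 3, 10, 0),
            ([0, 5] * 10, 2, 0),
        ],
    )
    def test_zero_runs(self, counts, run_min, expect_masked):
        prof = make_profile(counts)
        out = mask_low_quality_bins(prof, zero_run_min=run_min)
        assert out.mask.sum() == expect_masked

    def test_runs_do_not_span_chromosomes(self):
        import numpy as np
        from dpcnv.profile import BinProfile

        n = 12
        prof = BinProfile(
            chrom=np.array(["chr1"] * 6 + ["chr2"] * 6, dtype=object),
            start=np.concatenate([np.arange(6), np.arange(6)]) * 1000,
            width=1000,
            count=np.zeros(n, dtype=int),
        )
        out = mask_low_quality_bins(prof, zero_run_min=10)
        assert not out.mask.any()  # two runs of 6, neither reaches 10
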