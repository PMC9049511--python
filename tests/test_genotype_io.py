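"""PED/MAP and VCF round-trips, QC filtering, subsetting, merging."""

import numpy as np
import pytest

from haplodate.io import (MISSING, FormatError, call_rate_filter,
                          merge_datasets, read_ped_map, read_vcf,
                          subsample_group, write_ped_map, write_vcf)

from conftest import make_dataset, make_markers, make_panel


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

class TestPedMap:
    def test_roundtrip_preserves_everything(self, tmp_path):
        ds = make_dataset([[0, 1, 2], [2, MISSING, 0]], breeds=["X", "Y"])
        write_ped_map(ds, tmp_path / "a.ped", tmp_path / "a.map",
                      tmp_path / "a.tsv")
        back = read_ped_map(tmp_path / "a.ped", tmp_path / "a.map",
                            tmp_path / "a.tsv")
        assert np.array_equal(back.genotypes, ds.genotypes)
        assert back.sample_ids == ds.sample_ids
        assert list(back.markers.ids) == list(ds.markers.ids)
        assert np.array_equal(back.markers.bp, ds.markers.bp)
        # second round trip is bit-identical on disk
        write_ped_map(back, tmp_path / "b.ped", tmp_path / "b.map")
        assert (tmp_path / "a.ped").read_text() == (tmp_path / "b.ped").read_text()
        assert (tmp_path / "a.map").read_text() == (tmp_path / "b.map").read_text()

    def test_zero_zero_pair_is_missing(self, tmp_path):
        (tmp_path / "m.map").write_text("1 m0 0 100\n1 m1 0 200\n1 m2 0 300\n")
        (tmp_path / "m.ped").write_text(
            "F s1 0 0 0 -9 A A 0 0 C C\n"
            "F s2 0 0 0 -9 A C A A A C\n")
        ds = read_ped_map(tmp_path / "m.ped", tmp_path / "m.map")
        assert ds.genotypes[0, 1] == MISSING
        assert ds.genotypes[0, 0] == 0 and ds.genotypes[1, 0] == 1

    def test_three_alleles_names_marker(self, tmp_path):
        (tmp_path / "m.map").write_text("1 m0 0 100\n1 bad 0 200\n")
        (tmp_path / "m.ped").write_text(
            "F s1 0 0 0 -9 A A A C\nF s2 0 0 0 -9 A A G G\n")
        with pytest.raises(FormatError, match="bad"):
            read_ped_map(tmp_path / "m.ped", tmp_path / "m.map")

    def test_ragged_row_names_line(self, tmp_path):
        (tmp_path / "m.map").write_text("1 m0 0 100\n1 m1 0 200\n")
        (tmp_path / "m.ped").write_text(
            "F s1 0 0 0 -9 A A C C\nF s2 0 0 0 -9 A A\n")
        with pytest.raises(FormatError, match="line 2"):
            read_ped_map(tmp_path / "m.ped", tmp_path / "m.map")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER = ("##fileformat=VCFv4.2\n"
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
              "##contig=<ID=1,length=100000>\n"
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n")


class TestVcf:
    def test_phased_het_gives_haplotypes(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_HEADER + "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\n")
        panel = read_vcf(p, require_phased=True)
        assert panel.haplotypes[:, 0].tolist() == [0, 1]

    def test_unphased_het_rejected_when_phase_required(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(VCF_HEADER + "1\t100\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(FormatError, match="unphased"):
            read_vcf(p, require_phased=True)

    def test_multiallelic_skipped_with_warning(self, tmp_path):
        rows = [f"1\t{100 * (i + 1)}\t.\tA\tC\t.\tPASS\t.\tGT\t0|1\n"
                for i in range(10)]
        rows[4] = "1\t500\t.\tA\tC,G\t.\tPASS\t.\tGT\t0|1\n"
        p = tmp_path / "a.vcf"
        p.write_text(VCF_HEADER + "".join(rows))
        with pytest.warns(UserWarning, match="1 multiallelic"):
            panel = read_vcf(p, require_phased=True)
        assert panel.markers.n_markers == 9

    def test_write_read_roundtrip(self, tmp_path):
        panel = make_panel([[0, 1, 0, 1], [1, 0, MISSING, 1],
                            [0, 0, 1, 1], [1, 1, 0, 0]], breeds=["X", "Y"])
        write_vcf(panel, tmp_path / "p.vcf")
        back = read_vcf(tmp_path / "p.vcf", require_phased=True)
        # one fully missing diploid site stays missing, everything else intact
        assert np.array_equal(back.haplotypes[[0, 2, 3]],
                              panel.haplotypes[[0, 2, 3]])
        assert np.array_equal(back.markers.bp, panel.markers.bp)
        assert np.allclose(back.markers.cm, panel.markers.cm, atol=1e-4)


# ---------------------------------------------------------------------------
# call-rate filter
# ---------------------------------------------------------------------------

class TestCallRateFilter:
    def test_low_call_sample_removed(self):
        g = np.zeros((10, 10), dtype=np.int8)
        g[3, :5] = MISSING                       # 50% missing sample
        ds = make_dataset(g)
        out = call_rate_filter(ds, 0.9, 0.9)
        assert out.n_samples == 9
        assert "B_3" not in out.sample_ids

    def test_no_missing_is_identity(self):
        ds = make_dataset(np.ones((4, 6), dtype=np.int8))
        out = call_rate_filter(ds, 0.9, 0.9)
        assert np.array_equal(out.genotypes, ds.genotypes)
        assert out.sample_ids == ds.sample_ids

    def test_marker_threshold_count(self):
        # 5 markers x 10 samples; marker 2 typed in 8/10 -> dropped at 0.9.
        # Brute-force expectation: per-marker call rates [1,1,.8,1,1].
        g = np.ones((10, 5), dtype=np.int8)
        g[0, 2] = g[1, 2] = MISSING
        ds = make_dataset(g)
        rates = (ds.genotypes != MISSING).mean(axis=0)
        expected_kept = int((rates >= 0.9).sum())
        assert expected_kept == 4
        out = call_rate_filter(ds, sample_min=0.0, marker_min=0.9)
        assert out.markers.n_markers == expected_kept

    def test_idempotent(self):
        g = np.ones((10, 5), dtype=np.int8)
        g[0, 2] = g[1, 2] = MISSING
        g[3, :3] = MISSING
        once = call_rate_filter(make_dataset(g), 0.7, 0.9)
        twice = call_rate_filter(once, 0.7, 0.9)
        assert np.array_equal(once.genotypes, twice.genotypes)

    def test_all_samples_removed_is_error(self):
        g = np.full((3, 4), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="all samples"):
            call_rate_filter(make_dataset(g), 0.9, 0.9)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------

class TestSubsample:
    def _ds(self, n=20):
        return make_dataset(np.zeros((n, 5), dtype=np.int8), breeds=["DOG"] * n)

    def test_k_equals_breed_size(self):
        ds = self._ds(7)
        out = subsample_group(ds, "DOG", 7, seed=123)
        assert sorted(out.sample_ids) == sorted(ds.sample_ids)

    def test_same_seed_same_set(self):
        ds = self._ds()
        a = subsample_group(ds, "DOG", 10, seed=5)
        b = subsample_group(ds, "DOG", 10, seed=5)
        assert a.sample_ids == b.sample_ids

    def test_different_seeds_differ(self):
        # P(identical 10-of-20 subsets) = 1/C(20,10) per pair; over 5 pairs
        # a collision would be a determinism bug, not chance.
        ds = self._ds()
        diffs = [subsample_group(ds, "DOG", 10, seed=2 * s).sample_ids
                 != subsample_group(ds, "DOG", 10, seed=2 * s + 1).sample_ids
                 for s in range(5)]
        assert any(diffs)

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="fewer than"):
            subsample_group(self._ds(5), "DOG", 6, seed=0)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

class TestMerge:
    def test_intersection_size(self):
        ds = make_dataset(np.ones((2, 10), dtype=np.int8), breeds=["X", "X"])
        b = ds.subset_markers(np.arange(9))
        b = b.subset_samples([0, 1])
        b.samples["sample_id"] = ["Y_0", "Y_1"]
        merged = merge_datasets(ds, b)
        assert merged.markers.n_markers == 9
        assert merged.n_samples == 4

    def test_swapped_alleles_complemented(self):
        a = make_dataset([[0, 2], [1, 1]], breeds=["X", "X"])
        mswap = make_markers(2, alleles=("C", "A"))
        b = make_dataset([[0, 2], [2, 0]], breeds=["Y", "Y"], markers=mswap)
        merged = merge_datasets(a, b)
        assert np.array_equal(merged.genotypes[2:],
                              np.array([[2, 0], [0, 2]], dtype=np.int8))

    def test_ambiguous_at_marker_dropped(self):
        markers = make_markers(10)
        markers.allele1[3], markers.allele2[3] = "A", "T"
        a = make_dataset(np.ones((2, 10), dtype=np.int8), breeds=["X", "X"],
                         markers=markers)
        b = make_dataset(np.ones((2, 10), dtype=np.int8), breeds=["Y", "Y"],
                         markers=markers)
        with pytest.warns(UserWarning, match="1 ambiguous"):
            merged = merge_datasets(a, b)
        assert merged.markers.n_markers == 9

    def test_commutative_content(self):
        a = make_dataset([[0, 1, 2]], breeds=["X"])
        b = make_dataset([[2, 1, 0]], breeds=["Y"])
        ab = merge_datasets(a, b)
        ba = merge_datasets(b, a)
        assert set(ab.sample_ids) == set(ba.sample_ids)
        ga = {sid: ab.genotypes[i].tolist() for i, sid in enumerate(ab.sample_ids)}
        gb = {sid: ba.genotypes[i].tolist() for i, sid in enumerate(ba.sample_ids)}
        assert ga == gb

    def test_duplicate_ids_rejected(self):
        a = make_dataset([[0, 1]], breeds=["X"])
        with pytest.raises(ValueError, match="duplicate"):
            merge_datasets(a, a)
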