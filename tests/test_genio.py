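import numpy as np
import pandas as pd
import pytest

from badgers import genio
from badgers.genio import (EmptyInputError, FormatError, RegionSet,
                           read_genotypes, read_regions, read_sumstats,
                           read_weights, write_plink, write_sumstats,
                           write_weights)

from conftest import make_panel, make_variants


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadSumstats:
    def test_z_derived_from_beta_se(self, tmp_path):
        p = _write(tmp_path, "ss.tsv",
                   "SNP CHR BP A1 A2 BETA SE\n"
                   "rs1 1 100 A G 0.1 0.05\n"
                   "rs2 1 200 A G -0.2 0.1\n"
                   "rs3 1 300 A G 0.0 0.1\n")
        ss = read_sumstats(p)
        np.testing.assert_allclose(ss.df["z"], [2.0, -2.0, 0.0])
        assert ss.df["p"].between(0, 1).all()

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        p = _write(tmp_path, "ss.tsv",
                   "SNP CHR BP A1 A2 BETA SE\nrs1 1 100 A G 0.1 0.0\n"
                   "rs2 1 200 A G 0.1 0.05\n")
        ss = read_sumstats(p)
        assert ss.n_variants == 1
        assert ss.log.dropped_zero_se == 1

    def test_z_only_mode(self, tmp_path):
        p = _write(tmp_path, "ss.tsv",
                   "SNP CHR BP A1 A2 Z P\nrs1 1 100 A G 1.96 0.05\n")
        ss = read_sumstats(p)
        assert ss.df["beta"].isna().all() and ss.df["se"].isna().all()
        np.testing.assert_allclose(ss.df["z"], [1.96])

    def test_missing_required_column_names_it(self, tmp_path):
        p = _write(tmp_path, "ss.tsv", "SNP CHR A1 A2 BETA SE\nrs1 1 A G 0.1 0.05\n")
        with pytest.raises(FormatError, match="pos"):
            read_sumstats(p)

    def test_empty_table_raises(self, tmp_path):
        p = _write(tmp_path, "ss.tsv", "SNP CHR BP A1 A2 BETA SE\nrs1 1 x A G nan 0.05\n")
        with pytest.raises(EmptyInputError):
            read_sumstats(p)

    def test_inconsistent_p_recomputed_from_z(self, tmp_path):
        p = _write(tmp_path, "ss.tsv",
                   "SNP CHR BP A1 A2 Z P\nrs1 1 100 A G 2.0 0.5\n")
        ss = read_sumstats(p)
        assert ss.log.zp_inconsistent == 1
        np.testing.assert_allclose(ss.df["p"], genio.two_sided_p(np.array([2.0])))

    def test_column_map_override(self, tmp_path):
        p = _write(tmp_path, "ss.tsv",
                   "marker c b ea oa eff err\nrs1 1 100 A G 0.1 0.05\n")
        ss = read_sumstats(p, column_map={"id": "marker", "chrom": "c", "pos": "b",
                                          "a1": "ea", "a2": "oa", "beta": "eff",
                                          "se": "err"})
        assert ss.n_variants == 1

    def test_roundtrip_preserves_values(self, tmp_path):
        p = _write(tmp_path, "ss.tsv",
                   "SNP CHR BP A1 A2 BETA SE N\n"
                   "rs1 1 100 A G 0.123456789 0.05 5000\n"
                   "rs2 2 200 C T -1.5e-5 0.11 5000\n")
        ss = read_sumstats(p)
        out = tmp_path / "out.tsv"
        write_sumstats(ss, out)
        ss2 = read_sumstats(out)
        for c in ("beta", "se", "z", "p"):
            np.testing.assert_allclose(ss2.df[c], ss.df[c], rtol=1e-10)

    def test_row_order_independence(self, tmp_path):
        rows = ["rs1 1 300 A G 0.1 0.05", "rs2 1 100 C T -0.2 0.1",
                "rs3 2 200 A C 0.3 0.2"]
        head = "SNP CHR BP A1 A2 BETA SE\n"
        a = read_sumstats(_write(tmp_path, "a.tsv", head + "\n".join(rows)))
        b = read_sumstats(_write(tmp_path, "b.tsv", head + "\n".join(rows[::-1])))
        pd.testing.assert_frame_equal(a.sort_canonical().df, b.sort_canonical().df)


class TestGenotypes:
    def test_plink_bed_against_hand_packed_bytes(self, tmp_path):
        # independently hand-constructed fixture: 2 individuals x 2 variants.
        # SNP-major codes: 00=hom A1 (dosage 2), 10=het, 11=hom A2 (dosage 0).
        # variant 1: ind1 dosage 0 (11), ind2 dosage 1 (10) -> byte 0b00001011
        # variant 2: ind1 dosage 1 (10), ind2 dosage 2 (00) -> byte 0b00000010
        (tmp_path / "toy.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b00001011,
                                                  0b00000010]))
        (tmp_path / "toy.bim").write_text("1\trs1\t0\t100\tA\tG\n1\trs2\t0\t200\tC\tT\n")
        (tmp_path / "toy.fam").write_text("f1 i1 0 0 0 -9\nf2 i2 0 0 0 -9\n")
        panel = read_genotypes(tmp_path / "toy", format="plink-bed")
        np.testing.assert_array_equal(panel.dosages, [[0, 1], [1, 2]])
        assert list(panel.variants["a1"]) == ["A", "C"]

    def test_plink_missing_code(self, tmp_path):
        (tmp_path / "m.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0b00000001]))
        (tmp_path / "m.bim").write_text("1\trs1\t0\t100\tA\tG\n")
        (tmp_path / "m.fam").write_text("f1 i1 0 0 0 -9\n")
        panel = read_genotypes(tmp_path / "m", format="plink-bed")
        assert np.isnan(panel.dosages[0, 0])

    def test_plink_dimension_mismatch(self, tmp_path):
        (tmp_path / "bad.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0, 0, 0]))
        (tmp_path / "bad.bim").write_text("1\trs1\t0\t100\tA\tG\n")
        (tmp_path / "bad.fam").write_text("f1 i1 0 0 0 -9\n")
        with pytest.raises(FormatError, match="size"):
            read_genotypes(tmp_path / "bad", format="plink-bed")

    def test_plink_roundtrip(self, tmp_path):
        panel = make_panel(n=13, m=7, seed=3)
        panel.dosages[2, 4] = np.nan
        write_plink(panel, str(tmp_path / "rt"))
        back = read_genotypes(str(tmp_path / "rt"), format="plink-bed")
        np.testing.assert_array_equal(back.dosages, panel.dosages)
        pd.testing.assert_frame_equal(back.variants, panel.variants)

    def test_vcf_gt_to_dosage(self, tmp_path):
        vcf = ("##fileformat=VCFv4.2\n"
               '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
               "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
               "1\t100\trs1\tG\tA\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
               "1\t200\trs2\tG\tA,C\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        p = _write(tmp_path, "t.vcf", vcf)
        panel = read_genotypes(p, format="vcf")
        assert panel.log.skipped_multiallelic == 1  # multi-allelic site skipped
        np.testing.assert_array_equal(panel.dosages, [[0], [1], [2]])
        assert panel.variants.loc[0, "a1"] == "A"  # counted allele is ALT

    def test_matrix_tsv_non_numeric_cell_named(self, tmp_path):
        p = _write(tmp_path, "d.tsv", "rs1:1:100:A:G\trs2:1:200:C:T\n0\t1\n2\tfoo\n")
        with pytest.raises(FormatError, match="row 2"):
            read_genotypes(p, format="matrix-tsv")

    def test_matrix_tsv_parses(self, tmp_path):
        p = _write(tmp_path, "d.tsv", "rs1:1:100:A:G\trs2:1:200:C:T\n0\t1\n2\t0.5\n")
        panel = read_genotypes(p, format="matrix-tsv")
        np.testing.assert_allclose(panel.dosages, [[0, 1], [2, 0.5]])
        assert list(panel.variants["pos"]) == [100, 200]


class TestWeights:
    def test_two_by_two(self, tmp_path):
        p = _write(tmp_path, "w.tsv",
                   "SNP CHR BP A1 A2 height bmi\n"
                   "rs1 1 100 A G 0.5 0.0\nrs2 1 200 C T 0.0 -0.3\n")
        w = read_weights(p)
        np.testing.assert_allclose(w.weights, [[0.5, 0.0], [0.0, -0.3]])
        assert w.trait_ids == ["height", "bmi"]

    def test_single_trait(self, tmp_path):
        p = _write(tmp_path, "w.tsv", "SNP CHR BP A1 A2 w\nrs1 1 100 A G 1.5\n")
        w = read_weights(p)
        assert w.n_traits == 1

    def test_na_weight_zeroed_with_warning(self, tmp_path):
        p = _write(tmp_path, "w.tsv",
                   "SNP CHR BP A1 A2 w\nrs1 1 100 A G NA\nrs2 1 200 C T 1.0\n")
        w = read_weights(p)
        np.testing.assert_allclose(w.weights[:, 0], [0.0, 1.0])
        assert w.variants is not None

    def test_duplicate_variant_rejected(self, tmp_path):
        p = _write(tmp_path, "w.tsv",
                   "SNP CHR BP A1 A2 w\nrs1 1 100 A G 1.0\nrs1b 1 100 A G 2.0\n")
        with pytest.raises(FormatError, match="duplicated"):
            read_weights(p)

    def test_roundtrip(self, tmp_path, rng):
        from conftest import make_weights
        w = make_weights(rng.normal(size=(5, 3)))
        write_weights(w, tmp_path / "w.tsv")
        back = read_weights(tmp_path / "w.tsv")
        np.testing.assert_allclose(back.weights, w.weights, rtol=1e-10)


class TestRegions:
    def test_inline_string_1based(self):
        rs = read_regions("19:45147340-45594595")
        assert rs.intervals == [("19", 45147340, 45594595)]

    def test_bed_row_converts_coordinates(self, tmp_path):
        p = _write(tmp_path, "r.bed", "19\t45147339\t45594595\n")
        rs = read_regions(str(p))
        assert rs.intervals == [("19", 45147340, 45594595)]

    def test_bed_internal_bijection(self, tmp_path):
        # converting back and forth is exact on integer intervals
        for chrom, s, e in [("1", 1, 1), ("2", 5, 10), ("X", 1000, 1000)]:
            row = genio.region_to_bed_row(chrom, s, e)
            p = _write(tmp_path, "b.bed", row + "\n")
            assert read_regions(str(p)).intervals == [(chrom, s, e)]

    def test_empty_file(self, tmp_path):
        p = _write(tmp_path, "e.bed", "")
        assert read_regions(str(p)).intervals == []

    def test_end_before_start_rejected(self):
        with pytest.raises(FormatError):
            RegionSet([("1", 10, 5)])

    def test_contains_is_inclusive_and_chr_insensitive(self):
        rs = RegionSet([("19", 100, 200)])
        mask = rs.contains(["chr19", "19", "19", "1"], [100, 200, 99, 150])
        np.testing.assert_array_equal(mask, [True, True, False, False])
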