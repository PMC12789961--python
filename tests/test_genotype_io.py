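"""Format readers/writers: parsing semantics, round-trips, reader equivalence."""

import numpy as np
import pytest

from kbagen import genotype_io
from kbagen.genotype_io import ParseError

from conftest import dataset_from_calls

GENEPOP = """example file
LocA
LocB
POP
x1 , 001002 003003
x2 , 001001 000000
north , 002002 003004
POP
y1 , 001001 004004
y2 , 001002 003004
y3 , 002002 004004
south , 001001 003003
"""


@pytest.fixture
def genepop_path(tmp_path):
    p = tmp_path / "ex.gen"
    p.write_text(GENEPOP)
    return p


class TestGenepop:
    def test_heterozygote_code_splits_into_two_alleles(self, genepop_path):
        ds = genotype_io.read_genepop(genepop_path)
        i = ds.individual_ids.index("x1")
        l = [loc.name for loc in ds.loci].index("LocA")
        a = ds.loci[l].alleles
        assert ds.dosage[i, l, a.index("001")] == 1
        assert ds.dosage[i, l, a.index("002")] == 1

    def test_all_zero_code_is_missing(self, genepop_path):
        ds = genotype_io.read_genepop(genepop_path)
        i = ds.individual_ids.index("x2")
        l = [loc.name for loc in ds.loci].index("LocB")
        assert ds.missing[i, l]
        assert np.all(ds.dosage[i, l] == 0)

    def test_pop_blocks_become_areas_named_by_last_label(self, genepop_path):
        ds = genotype_io.read_genepop(genepop_path)
        table = ds.area_table()
        assert {a: len(ix) for a, ix in table.items()} == {"north": 3, "south": 4}

    def test_diploid_sum_invariant_on_read(self, genepop_path):
        ds = genotype_io.read_genepop(genepop_path)
        sums = ds.dosage.sum(axis=2)
        assert np.allclose(sums[~ds.missing], 2.0)
        assert np.all(sums[ds.missing] == 0.0)

    @pytest.mark.parametrize(
        "bad",
        [
            "t\nL1\nPOP\nx , 0010\n",        # field not 2*digits wide
            "t\nL1\nL2\nPOP\nx , 001001\n",  # fewer fields than loci
            "t\nPOP\nx , 001001\n",          # no locus names
        ],
    )
    def test_malformed_files_raise_parse_error(self, tmp_path, bad):
        p = tmp_path / "bad.gen"
        p.write_text(bad)
        with pytest.raises(ParseError):
            genotype_io.read_genepop(p)

    def test_genepop_round_trip_identity(self, tmp_path, small_mixed):
        """Dosages, areas and locus names survive write -> read exactly
        (Genepop carries no individual ids; block order is preserved)."""
        out = tmp_path / "rt.gen"
        genotype_io.write_genepop(small_mixed, out)
        back = genotype_io.read_genepop(out)
        assert [loc.name for loc in back.loci] == [loc.name for loc in small_mixed.loci]
        t0, t1 = small_mixed.area_table(), back.area_table()
        assert set(t0) == set(t1)
        for area in t0:
            assert len(t0[area]) == len(t1[area])
            for i0, i1 in zip(t0[area], t1[area]):
                for l, loc in enumerate(small_mixed.loci):
                    if small_mixed.missing[i0, l]:
                        assert back.missing[i1, l]
                        continue
                    d0 = {al: v for a, al in enumerate(loc.alleles)
                          if (v := small_mixed.dosage[i0, l, a])}
                    d1 = {al.lstrip("0") or "0": v
                          for a, al in enumerate(back.loci[l].alleles)
                          if (v := back.dosage[i1, l, a])}
                    assert d0 == d1


class TestStructure:
    def test_two_row_layout(self, tmp_path):
        p = tmp_path / "s.str"
        p.write_text("ind1 1 4 7\nind1 1 4 9\nind2 2 5 7\nind2 2 -9 7\n")
        ds = genotype_io.read_structure(p, n_loci=2)
        assert ds.area_table().keys() == {"1", "2"}
        i = ds.individual_ids.index("ind1")
        assert ds.dosage[i, 0, ds.loci[0].alleles.index("4")] == 2  # 4/4
        assert ds.dosage[i, 1, ds.loci[1].alleles.index("7")] == 1  # 7/9
        assert ds.dosage[i, 1, ds.loci[1].alleles.index("9")] == 1
        j = ds.individual_ids.index("ind2")
        assert ds.missing[j, 0]  # -9 in one row

    def test_out_of_order_pairing_raises(self, tmp_path):
        p = tmp_path / "s.str"
        p.write_text("ind1 1 4 7\nind2 1 4 9\nind2 1 5 7\nind1 1 5 7\n")
        with pytest.raises(ParseError):
            genotype_io.read_structure(p, n_loci=2)

    def test_row_width_mismatch_raises(self, tmp_path):
        p = tmp_path / "s.str"
        p.write_text("ind1 1 4\nind1 1 4\n")
        with pytest.raises(ParseError):
            genotype_io.read_structure(p, n_loci=2)


VCF = """##fileformat=VCFv4.2
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4\ts5
chr1\t100\tsnp1\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\t1/1\t./.\t0/1
chr1\t200\tsnp2\tC\tT,G\t.\t.\t.\tGT\t0/2\t1/2\t0/0\t0/1\t2/2
"""


class TestVcf:
    @pytest.fixture
    def vcf_paths(self, tmp_path):
        v = tmp_path / "x.vcf"
        v.write_text(VCF)
        pm = tmp_path / "popmap.tsv"
        pm.write_text("s1\tA\ns2\tA\ns3\tB\ns4\tB\ns5\tB\n")
        return v, pm

    def test_het_call_and_missing_semantics(self, vcf_paths):
        ds = genotype_io.read_vcf(*vcf_paths)
        i = ds.individual_ids.index("s1")
        assert list(ds.dosage[i, 0, :2]) == [1.0, 1.0]  # 0/1
        j = ds.individual_ids.index("s4")
        assert ds.missing[j, 0]  # ./.

    def test_multiallelic_site_keeps_all_alt_alleles(self, vcf_paths):
        ds = genotype_io.read_vcf(*vcf_paths)
        l = [loc.name for loc in ds.loci].index("snp2")
        assert ds.loci[l].alleles == ("C", "T", "G")
        i = ds.individual_ids.index("s2")
        assert list(ds.dosage[i, l]) == [0.0, 1.0, 1.0]  # 1/2

    def test_popmap_defines_areas(self, vcf_paths):
        ds = genotype_io.read_vcf(*vcf_paths)
        assert {a: len(ix) for a, ix in ds.area_table().items()} == {"A": 2, "B": 3}

    def test_popmap_with_unknown_sample_raises(self, tmp_path, vcf_paths):
        v, _ = vcf_paths
        pm = tmp_path / "bad.tsv"
        pm.write_text("s1\tA\nmissing_sample\tB\n")
        with pytest.raises(ValueError, match="absent from VCF"):
            genotype_io.read_vcf(v, pm)


class TestLongTable:
    def test_round_trip_identity(self, tmp_path, small_mixed):
        out = tmp_path / "t.tsv"
        genotype_io.write_table(small_mixed, out)
        back = genotype_io.read_table(out)
        assert back.equals(small_mixed)

    def test_empty_dataset_writes_header_only(self, tmp_path):
        ds = dataset_from_calls([], ["L1"])
        # 0-individual dataset: build directly
        import kbagen.datamodel as dm
        import numpy as np
        empty = dm.GenotypeDataset([], [], [dm.Locus("L1", "snp", ("1",))],
                                   np.zeros((0, 1, 1)), np.zeros((0, 1), dtype=bool))
        out = tmp_path / "e.tsv"
        genotype_io.write_table(empty, out)
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert lines == ["individual\tarea\tlocus\tallele_a\tallele_b"]

    def test_fractional_dosage_export_refused(self, tmp_path, small_mixed):
        from kbagen.preprocess import impute_mean_dosage
        imputed = impute_mean_dosage(small_mixed)
        with pytest.raises(ValueError, match="before\\s+mean imputation|integer"):
            genotype_io.write_table(imputed, tmp_path / "x.tsv")

    def test_reader_equivalence_genepop_vs_table(self, tmp_path, small_mixed):
        """Same genotypes via Genepop and via long TSV load identical
        per-area genotype sequences."""
        gp, tsv = tmp_path / "x.gen", tmp_path / "x.tsv"
        genotype_io.write_genepop(small_mixed, gp, allele_digits=2)
        genotype_io.write_table(small_mixed, tsv)
        from_gp = genotype_io.read_genepop(gp, allele_digits=2)
        from_tsv = genotype_io.read_table(tsv)
        t_gp, t_tsv = from_gp.area_table(), from_tsv.area_table()
        assert set(t_gp) == set(t_tsv)
        for area in t_tsv:
            for i0, i1 in zip(t_tsv[area], t_gp[area]):
                for l, loc in enumerate(from_tsv.loci):
                    l1 = [x.name for x in from_gp.loci].index(loc.name)
                    if from_tsv.missing[i0, l]:
                        assert from_gp.missing[i1, l1]
                        continue
                    d0 = {al: v for a, al in enumerate(loc.alleles)
                          if (v := from_tsv.dosage[i0, l, a])}
                    d1 = {al.lstrip("0") or "0": v
                          for a, al in enumerate(from_gp.loci[l1].alleles)
                          if (v := from_gp.dosage[i1, l1, a])}
                    assert d0 == d1
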