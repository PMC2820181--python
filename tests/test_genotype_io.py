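import numpy as np
import pytest

from groupgwas.genotype_io import (
    GeneGroup,
    GenotypeMatrix,
    InputError,
    SnpRecord,
    read_gene_groups,
    read_gene_regions,
    read_genotypes,
    read_phenotypes,
    write_group_results,
    write_ped_map,
    write_traw,
)
from groupgwas.groupset import GroupResult

from conftest import GPROTEIN_GENES, write_lines


def _write_ped_map(tmp_path, ped_lines, map_lines, name="toy"):
    write_lines(tmp_path / f"{name}.map", map_lines)
    write_lines(tmp_path / f"{name}.ped", ped_lines)
    return tmp_path / name


class TestPedMap:
    def test_dosage_counts_effect_allele(self, tmp_path):
        # genotypes AA / AG / GG at SNP1 -> dosages 0/1/2 for allele_b=G
        prefix = _write_ped_map(
            tmp_path,
            [
                "f1 i1 0 0 1 -9 A A C C T T",
                "f2 i2 0 0 1 -9 A G C C T T",
                "f3 i3 0 0 2 -9 G G C T T T",
            ],
            ["1 snp1 0 100", "1 snp2 0 200", "2 snp3 0 50"],
        )
        geno = read_genotypes(prefix, "ped_map")
        assert geno.individuals == ["i1", "i2", "i3"]
        j = geno.snp_index()["snp1"]
        assert geno.snps[j].allele_b == "G"
        np.testing.assert_array_equal(geno.dosage[:, j], [0, 1, 2])

    def test_missing_genotype(self, tmp_path):
        prefix = _write_ped_map(
            tmp_path,
            ["f1 i1 0 0 1 -9 0 0", "f2 i2 0 0 1 -9 A G"],
            ["1 snp1 0 100"],
        )
        geno = read_genotypes(prefix, "ped_map")
        assert np.isnan(geno.dosage[0, 0])
        assert geno.dosage[1, 0] == 1

    def test_wrong_column_count_names_line(self, tmp_path):
        prefix = _write_ped_map(
            tmp_path,
            ["f1 i1 0 0 1 -9 A A", "f2 i2 0 0 1 -9 A"],
            ["1 snp1 0 100"],
        )
        with pytest.raises(InputError, match=r"\.ped:2"):
            read_genotypes(prefix, "ped_map")

    def test_duplicate_snp_id(self, tmp_path):
        prefix = _write_ped_map(
            tmp_path,
            ["f1 i1 0 0 1 -9 A A A G"],
            ["1 snp1 0 100", "1 snp1 0 200"],
        )
        with pytest.raises(InputError, match="duplicate"):
            read_genotypes(prefix, "ped_map")

    def test_round_trip_modulo_allele_orientation(self, tmp_path, small_study):
        # ped files carry no counted-allele metadata, so re-reading may flip
        # the orientation per SNP; dosages must match exactly or as 2 - d
        geno = small_study.genotypes
        write_ped_map(geno, tmp_path / "rt")
        back = read_genotypes(tmp_path / "rt", "ped_map")
        assert back.snp_ids == geno.snp_ids
        for j, (orig, new) in enumerate(zip(geno.snps, back.snps)):
            got = back.dosage[:, j]
            want = geno.dosage[:, j]
            if new.allele_b == orig.allele_b:
                np.testing.assert_array_equal(got, want)
            else:
                np.testing.assert_array_equal(got, 2 - want)


class TestTraw:
    def test_missing_token(self, tmp_path):
        path = write_lines(
            tmp_path / "toy.traw",
            [
                "CHR\tSNP\t(C)M\tPOS\tCOUNTED\tALT\ti1\ti2",
                "1\tsnp1\t0\t100\tG\tA\tNA\t2",
            ],
        )
        geno = read_genotypes(path, "traw")
        assert np.isnan(geno.dosage[0, 0]) and geno.dosage[1, 0] == 2

    def test_bad_header(self, tmp_path):
        path = write_lines(tmp_path / "toy.traw", ["CHR\tID\tPOS\ti1", "1\tsnp1\t5\t0"])
        with pytest.raises(InputError, match="traw header"):
            read_genotypes(path, "traw")

    def test_round_trip_exact(self, tmp_path, small_study):
        geno = small_study.genotypes
        geno.dosage[0, 0] = np.nan  # make sure missing survives
        write_traw(geno, tmp_path / "rt.traw")
        back = read_genotypes(tmp_path / "rt.traw", "traw")
        assert back.individuals == geno.individuals
        assert back.snps == geno.snps
        np.testing.assert_array_equal(back.dosage, geno.dosage)

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(InputError, match="dialect"):
            read_genotypes(tmp_path / "x", "bed")


class TestGenotypeMatrix:
    def test_swap_alleles_involutive(self, small_study):
        geno = small_study.genotypes
        swapped = geno.swap_alleles()
        nonmissing = ~np.isnan(geno.dosage)
        np.testing.assert_array_equal(swapped.dosage[nonmissing], 2 - geno.dosage[nonmissing])
        back = swapped.swap_alleles()
        np.testing.assert_array_equal(back.dosage, geno.dosage)
        assert back.snps == geno.snps

    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(InputError, match="dosage"):
            GenotypeMatrix(
                snps=[SnpRecord("s1", "1", 1)],
                individuals=["i1"],
                dosage=np.array([[3.0]]),
            )

    def test_snp_record_validation(self):
        with pytest.raises(InputError):
            SnpRecord("s1", "1", 0)
        with pytest.raises(InputError):
            SnpRecord("s1", "1", 5, "A", "X")


class TestPhenotypes:
    def test_moments_reproduced(self, tmp_path, rng):
        # 627-row fixture standardized to mean 100.7, SD 15.7
        z = rng.standard_normal(627)
        trait = 100.7 + 15.7 * (z - z.mean()) / z.std(ddof=1)
        lines = ["ID\tTRAIT"] + [f"ind{i}\t{t:.10g}" for i, t in enumerate(trait)]
        table = read_phenotypes(write_lines(tmp_path / "pheno.tsv", lines))
        assert len(table) == 627
        assert table.trait.mean() == pytest.approx(100.7, abs=1e-6)
        assert table.trait.std(ddof=1) == pytest.approx(15.7, abs=1e-6)

    def test_missing_tokens_and_default_site(self, tmp_path):
        lines = ["ID\tTRAIT", "i1\t1.5", "i2\tNA", "i3\t-9"]
        table = read_phenotypes(write_lines(tmp_path / "p.tsv", lines))
        assert np.isnan(table.trait[1]) and np.isnan(table.trait[2])
        assert set(table.site) == {"all"}

    def test_site_column(self, tmp_path):
        lines = ["ID\tTRAIT\tSITE", "i1\t1\tams", "i2\t2\tlon"]
        table = read_phenotypes(write_lines(tmp_path / "p.tsv", lines))
        assert table.site == ["ams", "lon"]

    def test_non_numeric_trait(self, tmp_path):
        lines = ["ID\tTRAIT", "i1\thigh"]
        with pytest.raises(InputError, match="non-numeric"):
            read_phenotypes(write_lines(tmp_path / "p.tsv", lines))

    def test_empty_file(self, tmp_path):
        (tmp_path / "p.tsv").write_text("")
        with pytest.raises(InputError, match="empty"):
            read_phenotypes(tmp_path / "p.tsv")


class TestGeneGroups:
    def test_dedupe_within_line(self, tmp_path):
        path = write_lines(tmp_path / "g.gmt", ["Gprotein\tdesc\tGNAQ\tGNB3\tGNAQ"])
        (group,) = read_gene_groups(path)
        assert group.gene_ids == frozenset({"GNAQ", "GNB3"})

    def test_gprotein_fixture(self, tmp_path):
        path = write_lines(tmp_path / "g.gmt", ["Gprotein\tdesc\t" + "\t".join(GPROTEIN_GENES)])
        (group,) = read_gene_groups(path)
        assert len(group.gene_ids) == 27

    def test_short_line(self, tmp_path):
        path = write_lines(tmp_path / "g.gmt", ["name\tdesc"])
        with pytest.raises(InputError, match="GMT"):
            read_gene_groups(path)

    def test_empty_group_forbidden(self):
        with pytest.raises(InputError):
            GeneGroup("empty", frozenset())


class TestGeneRegions:
    def test_read(self, tmp_path):
        lines = ["GENE\tCHR\tSTART\tEND\tSTRAND", "g1\t1\t100\t200\t+", "g2\t2\t50\t60\t-"]
        genes = read_gene_regions(write_lines(tmp_path / "genes.tsv", lines))
        assert genes[1].strand == "-" and genes[0].end == 200

    def test_duplicate_gene(self, tmp_path):
        lines = ["GENE\tCHR\tSTART\tEND\tSTRAND", "g1\t1\t1\t2\t+", "g1\t1\t3\t4\t+"]
        with pytest.raises(InputError, match="duplicate"):
            read_gene_regions(write_lines(tmp_path / "genes.tsv", lines))


class TestGroupResultWriter:
    def test_table_row_format(self, tmp_path):
        results = [GroupResult("G protein relay", 25, 359, 227.0, 0.00019, 100_000, 19)]
        out = tmp_path / "res.tsv"
        write_group_results(results, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("group\tn_genes\tn_snps")
        assert lines[1].split("\t")[:5] == ["G protein relay", "25", "359", "227", "0.00019"]

    def test_empty_results(self, tmp_path):
        out = tmp_path / "res.tsv"
        write_group_results([], out)
        assert out.read_text().count("\n") == 1

    def test_ordered_by_emp_p(self, tmp_path):
        results = [
            GroupResult("b", 1, 5, 3.0, 0.5, 100, 50),
            GroupResult("a", 1, 5, 9.0, 0.01, 100, 1),
        ]
        out = tmp_path / "res.tsv"
        write_group_results(results, out)
        names = [ln.split("\t")[0] for ln in out.read_text().splitlines()[1:]]
        assert names == ["a", "b"]
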