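"""Domain types, table round-trips and genomic conventions."""

import math

import numpy as np
import pytest

from oxiscore.core_model import (
    AdmeProfile,
    BuildMismatchError,
    ConsequenceRecord,
    DrugRecord,
    GwasHit,
    PathwaySet,
    QtlRecord,
    ReadResult,
    RowError,
    SchemaError,
    Variant,
    check_builds,
    in_mhc,
    is_missense_or_worse,
    pathway_union,
    read_adme_profiles,
    read_consequences,
    read_drugs,
    read_gwas_hits,
    read_panel_tsv,
    read_panel_vcf,
    read_pathways_gmt,
    read_qtls,
    write_adme_profiles,
    write_consequences,
    write_drugs,
    write_gwas_hits,
    write_panel_tsv,
    write_panel_vcf,
    write_pathways_gmt,
    write_qtls,
)
from conftest import make_panel


def var(chrom="1", pos=1000, rsid=None):
    return Variant(chrom=chrom, pos=pos, allele_a="A", allele_b="G", rsid=rsid)


class TestTypes:
    def test_variant_invariants(self):
        with pytest.raises(ValueError):
            Variant(chrom="1", pos=0, allele_a="A", allele_b="G")
        with pytest.raises(ValueError):
            Variant(chrom="1", pos=5, allele_a="A", allele_b="A")
        with pytest.raises(ValueError):
            Variant(chrom="", pos=5, allele_a="A", allele_b="G")
        assert Variant(chrom="chr2", pos=5, allele_a="A", allele_b="G").chrom == "2"

    def test_hit_requires_risk_allele_of_variant(self):
        with pytest.raises(ValueError):
            GwasHit(variant=var(), risk_allele="T", p_value=1e-9, odds_ratio=1.2)

    def test_qtl_type_vocabulary_and_gene_case(self):
        q = QtlRecord(variant=var(), effect_allele="A", gene="keap1",
                      qtl_type="eQTL", tissue="brain", effect_sign=1)
        assert q.gene == "KEAP1"
        with pytest.raises(ValueError):
            QtlRecord(variant=var(), effect_allele="A", gene="G",
                      qtl_type="xQTL", tissue="brain", effect_sign=1)

    def test_unknown_consequence_class_rejected(self):
        with pytest.raises(ValueError, match="unknown consequence class"):
            ConsequenceRecord(variant=var(), gene="G", consequence_class="nonsense",
                              cadd_phred=10)

    @pytest.mark.parametrize(
        "term,expected",
        [("stop_gained", True), ("missense_variant", True),
         ("synonymous_variant", False), ("intron_variant", False)],
    )
    def test_severity_ordering(self, term, expected):
        assert is_missense_or_worse(term) is expected


class TestMhc:
    @pytest.mark.parametrize(
        "chrom,pos,expected",
        [
            ("6", 30_000_000, True),
            ("6", 27_000_000, True),   # closed lower bound
            ("6", 33_000_000, True),   # closed upper bound
            ("6", 26_999_999, False),
            ("6", 33_000_001, False),
            ("7", 30_000_000, False),
            ("chr6", 30_000_000, True),
        ],
    )
    def test_interval_membership(self, chrom, pos, expected):
        assert in_mhc(Variant(chrom=chrom, pos=pos, allele_a="A", allele_b="G")) is expected


GWAS_HEADER = "chrom\tpos\talleles\trisk_allele\tp_value\todds_ratio\tstudy_id\n"


class TestGwasReader:
    def test_intake_gate_drops_and_counts(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        rows = [
            ("1", 1000, "A/G", "A", "1e-9", "1.3"),   # retained
            ("1", 2000, "A/G", "G", "2e-5", "1.1"),   # dropped: above gate
            ("2", 3000, "C/T", "C", "9.9e-6", "1.2"),  # retained (just below)
            ("2", 4000, "C/T", "T", "1e-5", "1.2"),   # dropped: boundary is strict
            ("3", 5000, "A/T", "A", "5e-8", "1.4"),   # retained
        ]
        p.write_text(GWAS_HEADER + "".join(
            f"{c}\t{pos}\t{al}\t{ra}\t{pv}\t{orr}\tSTUDY1\n" for c, pos, al, ra, pv, orr in rows
        ))
        res = read_gwas_hits(p)
        assert len(res) == 3
        assert res.n_dropped == 2
        assert len(res) + res.n_dropped == len(rows)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text("chrom\tpos\talleles\trisk_allele\tp_value\tstudy_id\n")
        with pytest.raises(SchemaError, match="odds_ratio"):
            read_gwas_hits(p)

    def test_unparsable_number_reports_line(self, tmp_path):
        p = tmp_path / "gwas.tsv"
        p.write_text(
            "#build=GRCh37\n" + GWAS_HEADER
            + "1\t1000\tA/G\tA\t1e-9\t1.3\tS\n"
            + "1\t2000\tA/G\tA\tnot_a_p\t1.3\tS\n"
        )
        with pytest.raises(RowError, match="line 4"):
            read_gwas_hits(p)


class TestRoundTrips:
    """Write-then-read reproduces records exactly (floats bit-identical)."""

    def test_gwas(self, tmp_path):
        hits = [
            GwasHit(variant=var("1", 1000, "rs1"), risk_allele="A",
                    p_value=1.2345678901234e-9, odds_ratio=1.3000000000001,
                    study_id="S1"),
            GwasHit(variant=var("6", 28_000_000), risk_allele="G",
                    p_value=3.3e-8, odds_ratio=0.87, study_id="S2"),
        ]
        f = tmp_path / "g.tsv"
        write_gwas_hits(f, hits)
        back = read_gwas_hits(f)
        assert back.records == hits
        assert back.build == "GRCh37"

    def test_qtls(self, tmp_path):
        qtls = [QtlRecord(variant=var("2", 500, "rs9"), effect_allele="G",
                          gene="MAPK1", qtl_type="eQTL", tissue="brain",
                          effect_sign=-1)]
        f = tmp_path / "q.tsv"
        write_qtls(f, qtls)
        assert read_qtls(f).records == qtls

    def test_consequences(self, tmp_path):
        recs = [ConsequenceRecord(variant=var("3", 77), gene="CAPN1",
                                  consequence_class="missense_variant",
                                  cadd_phred=22.799999999999997)]
        f = tmp_path / "c.tsv"
        write_consequences(f, recs)
        assert read_consequences(f).records == recs

    def test_drugs_and_adme(self, tmp_path):
        drugs = [
            DrugRecord(name="BIIB021", target_gene="CARM1", mechanism="inhibit",
                       status="phase2", interaction_score=0.9, direct_action=True,
                       validated_transcriptional_modulator=False, source_db="DGIdb"),
            DrugRecord(name="X", target_gene="G", mechanism="other",
                       status="experimental", interaction_score=None),
        ]
        f = tmp_path / "d.tsv"
        write_drugs(f, drugs)
        assert read_drugs(f).records == drugs

        profiles = [
            AdmeProfile(compound="BIIB021", cns_activity=1, log_bb=0.2,
                        mdck_perm=600.0, caco2_perm=500.0,
                        human_oral_absorption=3, pct_human_absorption=92.0),
            AdmeProfile(compound="X"),  # all descriptors missing
        ]
        g = tmp_path / "a.tsv"
        write_adme_profiles(g, profiles)
        assert read_adme_profiles(g).records == profiles

    def test_panel_tsv_with_missing_calls(self, tmp_path):
        panel = make_panel([[0, 1, 2, -1], [2, 2, 0, 1]])
        f = tmp_path / "p.tsv"
        write_panel_tsv(f, panel)
        back = read_panel_tsv(f)[0]
        assert back.samples == panel.samples
        assert back.variants == panel.variants
        assert np.array_equal(back.genotypes, panel.genotypes)

    def test_panel_vcf(self, tmp_path):
        panel = make_panel([[0, 1, 2, -1], [2, 0, 1, 1]])
        f = tmp_path / "p.vcf"
        write_panel_vcf(f, panel)
        back = read_panel_vcf(f)[0]
        assert back.variants == panel.variants
        assert np.array_equal(back.genotypes, panel.genotypes)


class TestGmt:
    def test_parse_uppercase_dedup(self, tmp_path):
        f = tmp_path / "p.gmt"
        f.write_text("OS1\tdesc\tKEAP1\tMAPK1\nOS2\tdesc\tkeap1\tKEAP1\n")
        sets = read_pathways_gmt(f).records
        assert sets[0] == PathwaySet(name="OS1", members=frozenset({"KEAP1", "MAPK1"}))
        assert sets[1].members == frozenset({"KEAP1"})

    def test_union_of_22_single_gene_sets(self, tmp_path):
        f = tmp_path / "p.gmt"
        f.write_text("".join(f"OS{i}\td\tKEAP1\n" for i in range(22)))
        sets = read_pathways_gmt(f).records
        assert len(sets) == 22
        assert pathway_union(sets) == frozenset({"KEAP1"})

    def test_union_matches_hand_computation(self, tmp_path):
        f = tmp_path / "p.gmt"
        lines, expected = [], set()
        for i in range(22):
            members = [f"G{i}", f"G{i + 1}", "SHARED"]
            expected |= set(members)
            lines.append("\t".join([f"OS{i}", "d", *members]))
        f.write_text("\n".join(lines) + "\n")
        assert pathway_union(read_pathways_gmt(f).records) == frozenset(expected)

    def test_short_line_reports_line_number(self, tmp_path):
        f = tmp_path / "p.gmt"
        f.write_text("OS1\tdesc\tKEAP1\nOS2\tonly_two_fields\n")
        with pytest.raises(RowError, match="line 2"):
            read_pathways_gmt(f)

    def test_roundtrip(self, tmp_path):
        sets = [PathwaySet(name="OS1", members=frozenset({"A1", "B2"}))]
        f = tmp_path / "p.gmt"
        write_pathways_gmt(f, sets)
        assert read_pathways_gmt(f).records == sets


class TestBuildChecking:
    def test_mismatch_is_hard_error(self):
        a = ReadResult([], build="GRCh37", path="a.tsv")
        b = ReadResult([], build="GRCh38", path="b.tsv")
        with pytest.raises(BuildMismatchError):
            check_builds(a, b)

    def test_unlabelled_inputs_do_not_conflict(self):
        a = ReadResult([], build="GRCh37")
        b = ReadResult([], build=None)
        assert check_builds(a, b) == "GRCh37"
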