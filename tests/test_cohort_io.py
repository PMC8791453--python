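"""Cohort ingestion, TCGA-dialect filters, stratification and burden."""

from __future__ import annotations

import logging

import pytest

from stagesmg.cohort_io import (
    Cohort,
    MafFormatError,
    exclude_noncoding,
    filter_tcga_variants,
    is_nonsilent,
    read_clinical,
    read_maf,
    stratify,
    summarize_burden,
    write_maf,
)

from conftest import make_clinical, make_variant


class TestReadMaf:
    def test_roundtrip_identity(self, tmp_path):
        variants = [
            make_variant(sample_id=f"S{i}", pos=100 + i, protein_change="R10W")
            for i in range(3)
        ]
        path = write_maf(variants, tmp_path / "x.maf")
        back = read_maf(path)
        assert len(back) == 3
        assert [v.key for v in back] == [v.key for v in variants]
        assert back[0].protein_change == "R10W"
        assert back[0].callers == frozenset({"MUTECT"})

    def test_noncoding_rows_are_parsed_not_dropped(self, tmp_path):
        # Exclusion of intronic calls is a downstream filter, not a parse rule.
        variants = [make_variant(variant_classification="Intron")]
        back = read_maf(write_maf(variants, tmp_path / "x.maf"))
        assert len(back) == 1
        assert back[0].variant_classification == "Intron"

    def test_invariant_violating_row_rejected_with_diagnostic(self, tmp_path, caplog):
        path = write_maf([make_variant(pos=1), make_variant(pos=2)], tmp_path / "x.maf")
        text = path.read_text().splitlines()
        # Corrupt row 2: tumor alt count above depth.
        row = text[1].split("\t")
        cols = text[0].split("\t")
        row[cols.index("t_alt_count")] = "999"
        text[1] = "\t".join(row)
        path.write_text("\n".join(text) + "\n")
        with caplog.at_level(logging.WARNING):
            back = read_maf(path)
        assert len(back) == 1
        assert back[0].pos == 2
        assert any("row 2" in r.message for r in caplog.records)

    def test_unknown_classification_rejected(self, tmp_path):
        path = write_maf([make_variant()], tmp_path / "x.maf")
        path.write_text(path.read_text().replace("Missense_Mutation", "Weird_Class"))
        assert read_maf(path) == []

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("sample_id\tgene\nS1\tG1\n")
        with pytest.raises(MafFormatError, match="chrom"):
            read_maf(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.maf"
        path.write_text("")
        with pytest.raises(MafFormatError):
            read_maf(path)

    def test_tcga_mc3_dialect_with_starred_callers(self, tmp_path):
        header = "\t".join(
            [
                "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
                "Tumor_Seq_Allele2", "Variant_Type", "Variant_Classification",
                "Tumor_Sample_Barcode", "FILTER", "CENTERS",
            ]
        )
        row = "\t".join(
            ["PTEN", "10", "89624227", "C", "T", "SNP", "Missense_Mutation",
             "TCGA-AA-0001", "PASS", "MUTECT|MUSE*"]
        )
        path = tmp_path / "mc3.maf"
        path.write_text(header + "\n" + row + "\n")
        (v,) = read_maf(path, dialect="tcga_mc3")
        assert v.gene == "PTEN"
        assert v.callers == frozenset({"MUTECT", "MUSE"})
        assert v.t_depth is None  # depth columns absent but optional


class TestTcgaFilter:
    @pytest.mark.parametrize(
        "kwargs, retained",
        [
            (dict(filter_status="PASS", callers=frozenset({"MUTECT", "MUSE"})), True),
            (dict(filter_status="nonpreferredpair", callers=frozenset({"MUTECT"})), False),
            (dict(filter_status="WGA", callers=frozenset({"MUTECT"})), True),
            (dict(filter_status="Native_WGA_mix", callers=frozenset({"MUTECT"})), True),
            (dict(filter_status="PASS", callers=frozenset({"MUSE"})), False),
        ],
    )
    def test_snv_rules(self, kwargs, retained):
        out = filter_tcga_variants([make_variant(**kwargs)])
        assert (len(out) == 1) is retained

    @pytest.mark.parametrize(
        "callers, retained",
        [(frozenset({"VARSCANI"}), False), (frozenset({"INDELOCATOR"}), True)],
    )
    def test_indel_rules(self, callers, retained):
        v = make_variant(
            ref_allele="C",
            alt_allele="-",
            variant_type="DEL",
            variant_classification="Frame_Shift_Del",
            filter_status="WGA",
            callers=callers,
        )
        assert (len(filter_tcga_variants([v])) == 1) is retained

    def test_idempotent_and_commutes_with_noncoding_exclusion(self):
        variants = [
            make_variant(pos=1, filter_status="PASS"),
            make_variant(pos=2, filter_status="oxog"),
            make_variant(pos=3, variant_classification="Intron"),
            make_variant(pos=4, callers=frozenset({"MUSE"})),
            make_variant(pos=5, variant_classification="Silent"),
        ]
        a = exclude_noncoding(filter_tcga_variants(variants))
        b = filter_tcga_variants(exclude_noncoding(variants))
        assert a == b
        assert filter_tcga_variants(a) == a
        assert exclude_noncoding(a) == a
        assert set(v.key for v in a) <= set(v.key for v in variants)


class TestNoncodingAndNonsilent:
    def test_exclude_noncoding_keeps_coding_and_splice(self):
        classes = ["Missense_Mutation", "Intron", "5'Flank", "Splice_Site"]
        variants = [
            make_variant(pos=i + 1, variant_classification=c)
            for i, c in enumerate(classes)
        ]
        kept = {v.variant_classification for v in exclude_noncoding(variants)}
        assert kept == {"Missense_Mutation", "Splice_Site"}

    def test_all_silent_unchanged_and_empty_ok(self):
        silents = [make_variant(pos=i + 1, variant_classification="Silent") for i in range(3)]
        assert exclude_noncoding(silents) == silents
        assert exclude_noncoding([]) == []

    @pytest.mark.parametrize(
        "classification, expected",
        [
            ("Splice_Site", True),
            ("Silent", False),
            ("Frame_Shift_Del", True),
            ("Missense_Mutation", True),
            ("Nonsense_Mutation", True),
            ("In_Frame_Ins", True),
        ],
    )
    def test_is_nonsilent(self, classification, expected):
        kwargs = {"variant_classification": classification}
        if classification in ("Frame_Shift_Del",):
            kwargs.update(ref_allele="C", alt_allele="-", variant_type="DEL")
        if classification in ("In_Frame_Ins",):
            kwargs.update(ref_allele="-", alt_allele="CCC", variant_type="INS")
        assert is_nonsilent(make_variant(**kwargs)) is expected

    def test_is_nonsilent_rejects_noncoding(self):
        with pytest.raises(ValueError, match="noncoding"):
            is_nonsilent(make_variant(variant_classification="Intron"))


class TestStratify:
    def test_stage_partition(self, four_stage_cohort):
        strata = stratify(four_stage_cohort, by="stage_class")
        assert strata["early"].n_samples == 2
        assert strata["late"].n_samples == 2
        assert sum(s.n_samples for s in strata.values()) == 4

    def test_subgroup_sizes(self):
        sizes = {"MSI_hypermutated": 141, "CN_low": 140, "CN_high": 55}
        clinical = [
            make_clinical(f"S-{sub}-{i}", "I", subgroup=sub)
            for sub, n in sizes.items()
            for i in range(n)
        ]
        strata = stratify(Cohort([], clinical), by="subgroup")
        assert {k: v.n_samples for k, v in strata.items()} == sizes

    def test_unknown_routed_to_own_stratum(self):
        clinical = [make_clinical("S1", "I"), make_clinical("S2", "unknown")]
        strata = stratify(Cohort([], clinical), by="stage_class")
        assert strata["unknown"].sample_ids == ["S2"]

    def test_single_stratum_when_homogeneous(self):
        clinical = [make_clinical(f"S{i}", "III") for i in range(5)]
        assert set(stratify(Cohort([], clinical), by="stage_class")) == {"late"}


class TestBurden:
    def test_hand_computed_counts(self):
        clinical = [make_clinical(f"S{i}", "I") for i in range(3)]
        variants = [make_variant(sample_id="S1", pos=p) for p in (1, 2)]
        variants += [make_variant(sample_id="S2", pos=p) for p in (3, 4, 5, 6)]
        summary = summarize_burden(Cohort(variants, clinical))
        assert summary.mean == pytest.approx(2.0)
        assert (summary.min, summary.max) == (0, 4)
        assert summary.mean * 3 == summary.total

    def test_single_sample(self):
        summary = summarize_burden(Cohort([make_variant()], [make_clinical("S1", "I")]))
        assert summary.mean == 1.0
        assert (summary.min, summary.max) == (1, 1)

    def test_silent_not_counted_but_gene_dedup_is_not_applied_to_counts(self):
        clinical = [make_clinical("S1", "I")]
        variants = [
            make_variant(pos=1),
            make_variant(pos=2, variant_classification="Silent"),
            make_variant(pos=3),  # same gene, second non-silent hit still counts
        ]
        summary = summarize_burden(Cohort(variants, clinical))
        assert summary.total == 2
        assert summary.n_genes == 1

    def test_zero_samples_error(self):
        with pytest.raises(ValueError):
            summarize_burden(Cohort([], [], name="empty"))


class TestClinicalParsing:
    def test_aliases_normalised(self, tmp_path):
        path = tmp_path / "clin.tsv"
        path.write_text(
            "sample_id\tstage\tgrade\tsubgroup\n"
            "S1\tStage III\tG3\tMSI\n"
            "S2\tII\tgrade 1\tCN-low\n"
            "S3\t?\tG9\tmystery\n"
        )
        records = read_clinical(path)
        assert records[0].stage_class == "late"
        assert records[0].subgroup == "MSI_hypermutated"
        assert records[1].figo_stage == "II"
        assert records[1].grade == "G1"
        assert records[2].figo_stage == "unknown"
        assert records[2].subgroup == "unassigned"

    def test_duplicate_sample_ids_rejected(self):
        clinical = [make_clinical("S1", "I"), make_clinical("S1", "II")]
        with pytest.raises(ValueError, match="duplicate"):
            Cohort([], clinical)

    def test_orphan_variants_rejected(self):
        with pytest.raises(ValueError, match="missing from clinical"):
            Cohort([make_variant(sample_id="ghost")], [make_clinical("S1", "I")])
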