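"""Shared fixtures: record factories and small in-memory cohorts."""

from __future__ import annotations

import pytest

from stagesmg.cohort_io import ClinicalRecord, Cohort, VariantRecord


def make_variant(**kwargs) -> VariantRecord:
    """A valid missense SNP with every field overridable."""
    defaults = dict(
        sample_id="S1",
        gene="GENE1",
        chrom="1",
        pos=1000,
        ref_allele="A",
        alt_allele="G",
        variant_type="SNP",
        variant_classification="Missense_Mutation",
        filter_status="PASS",
        callers=frozenset({"MUTECT"}),
        t_depth=80,
        t_alt_count=20,
        n_depth=60,
        n_alt_count=0,
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


def make_deletion(**kwargs) -> VariantRecord:
    defaults = dict(
        ref_allele="C",
        alt_allele="-",
        variant_type="DEL",
        variant_classification="Frame_Shift_Del",
        callers=frozenset({"INDELOCATOR"}),
    )
    defaults.update(kwargs)
    return make_variant(**defaults)


def make_clinical(sample_id="S1", stage="III", grade="G2", subgroup="MSI_hypermutated"):
    return ClinicalRecord(
        sample_id=sample_id, figo_stage=stage, grade=grade, subgroup=subgroup
    )


@pytest.fixture
def four_stage_cohort() -> Cohort:
    """One sample per FIGO stage, each with one non-silent variant."""
    clinical = [
        make_clinical(f"S{i}", stage) for i, stage in enumerate(["I", "II", "III", "IV"])
    ]
    variants = [
        make_variant(sample_id=f"S{i}", pos=1000 + i, gene=f"G{i}") for i in range(4)
    ]
    return Cohort(variants, clinical, name="four-stage")


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def deletion_factory():
    return make_deletion
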