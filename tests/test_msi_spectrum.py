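"""Homopolymer indels, recurrence, Fisher enrichment, frequencies, consensus."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from stagesmg.cohort_io import Cohort
from stagesmg.msi_spectrum import (
    detect_homopolymer,
    fisher_2x2,
    frequency_table,
    missense_consensus,
    recurrence_table,
    subgroup_enrichment,
)

from conftest import make_clinical, make_deletion, make_variant

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


class TestDetectHomopolymer:
    def test_deletion_inside_c7_tract(self):
        # One C deleted from ATCCCCCCCGA: a (C)7 homopolymer.
        v = make_deletion(context_seq="ATCCCCCCCGA", context_offset=4)
        call = detect_homopolymer(v)
        assert (call.tract_base, call.tract_length, call.in_tract) == ("C", 7, True)

    def test_insertion_adjacent_to_run_of_four_below_threshold(self):
        v = make_variant(
            ref_allele="-",
            alt_allele="A",
            variant_type="INS",
            variant_classification="Frame_Shift_Ins",
            context_seq="GGAAAAGGGGG",
            context_offset=2,  # insertion lands inside the AAAA run
        )
        call = detect_homopolymer(v, min_tract_length=5)
        assert call.tract_length == 4
        assert not call.in_tract

    def test_dinucleotide_repeat_is_not_a_homopolymer(self):
        v = make_deletion(ref_allele="A", context_seq="ATATATAT", context_offset=2)
        call = detect_homopolymer(v)
        assert call.tract_length == 1
        assert not call.in_tract

    def test_deleted_base_must_match_run(self):
        # The run around the deleted position is long, but the deleted base
        # (G, per ref_allele) disagrees with the window: not an in-tract call.
        v = make_deletion(ref_allele="G", context_seq="TTCCCCCCCTT", context_offset=4)
        assert not detect_homopolymer(v).in_tract

    def test_snp_is_contract_violation(self):
        with pytest.raises(ValueError):
            detect_homopolymer(make_variant(context_seq="AAAA"))

    def test_missing_context_is_uncallable(self):
        call = detect_homopolymer(make_deletion(context_seq=None))
        assert call.uncallable
        assert not call.in_tract

    @pytest.mark.parametrize(
        "window, offset, ref",
        [
            ("ATCCCCCCCGA", 4, "C"),
            ("TTTTTGCAGGA", 1, "T"),
            ("ACGTACGTAAAAAAAAT", 9, "AA"),
        ],
    )
    def test_reverse_complement_invariance_for_deletions(self, window, offset, ref):
        fwd = detect_homopolymer(
            make_deletion(ref_allele=ref, context_seq=window, context_offset=offset)
        )
        rc_offset = len(window) - (offset + len(ref))
        rev = detect_homopolymer(
            make_deletion(
                ref_allele=revcomp(ref),
                context_seq=revcomp(window),
                context_offset=rc_offset,
            )
        )
        assert fwd.tract_length == rev.tract_length
        assert fwd.in_tract == rev.in_tract


class TestRecurrence:
    def test_two_samples_recurrent(self):
        variants = [
            make_variant(sample_id=s, gene="KLF3", protein_change="K106Nfs*21")
            for s in ("S1", "S2")
        ]
        df = recurrence_table(variants)
        assert df.loc[0, "n_samples"] == 2
        assert bool(df.loc[0, "recurrent"])

    def test_same_sample_twice_counts_once(self):
        variants = [
            make_variant(sample_id="S1", pos=p, protein_change="P375Hfs*7")
            for p in (1, 2)
        ]
        df = recurrence_table(variants)
        assert df.loc[0, "n_samples"] == 1
        assert not bool(df.loc[0, "recurrent"])

    def test_variants_without_protein_change_skipped(self):
        assert recurrence_table([make_variant(protein_change=None)]).empty


def fisher_oracle(a, b, c, d):
    """Two-tailed Fisher by full enumeration of the hypergeometric support."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    observed = hypergeom.pmf(a, n, row1, col1)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    return sum(
        p for x in support if (p := hypergeom.pmf(x, n, row1, col1)) <= observed * (1 + 1e-7)
    )


class TestFisher:
    def test_published_msi_enrichment_pvalue(self):
        # 11/141 MSI vs 1/195 in the combined CN subgroups: p = 0.0004.
        result = fisher_2x2(11, 130, 1, 194)
        assert round(result.p_two_tailed, 4) == 0.0004

    def test_symmetric_table_p_one(self):
        assert fisher_2x2(1, 1, 1, 1).p_two_tailed == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b + c + d == 0 or (a + b == 0 and c + d == 0):
                continue
            result = fisher_2x2(int(a), int(b), int(c), int(d))
            assert result.p_two_tailed == pytest.approx(
                fisher_oracle(int(a), int(b), int(c), int(d)), rel=1e-9
            )

    def test_transpose_invariance(self):
        p1 = fisher_2x2(3, 10, 8, 2).p_two_tailed
        p2 = fisher_2x2(3, 8, 10, 2).p_two_tailed  # transpose
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_odds_ratio_conventions(self):
        assert fisher_2x2(20, 121, 0, 195).odds_ratio == math.inf
        assert fisher_2x2(2, 4, 1, 8).odds_ratio == pytest.approx(4.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_2x2(0, 0, 0, 0)


def _subgroup_cohort():
    sizes = {"MSI_hypermutated": 141, "CN_low": 140, "CN_high": 55}
    clinical = [
        make_clinical(f"S-{sub}-{i}", "I", subgroup=sub)
        for sub, n in sizes.items()
        for i in range(n)
    ]
    variants = [
        make_variant(sample_id=f"S-MSI_hypermutated-{i}", gene="KLF3", pos=100 + i)
        for i in range(20)
    ]
    return Cohort(variants, clinical)


class TestFrequencyTable:
    def test_percent_matches_published_rounding(self):
        df = frequency_table(_subgroup_cohort(), ["KLF3"], by="subgroup")
        by_stratum = df.set_index("stratum")
        assert by_stratum.loc["MSI_hypermutated", "percent"] == 14.2
        assert by_stratum.loc["MSI_hypermutated", "n_mutated"] == 20
        assert by_stratum.loc["CN_high", "percent"] == 0.0

    def test_row_totals_match_stratum_sizes(self):
        df = frequency_table(_subgroup_cohort(), ["KLF3"], by="subgroup")
        totals = df[df.stratum != "all"].set_index("stratum")["n_total"].to_dict()
        assert totals == {"MSI_hypermutated": 141, "CN_low": 140, "CN_high": 55}

    def test_unknown_gene_gives_zero_rows(self, caplog):
        df = frequency_table(_subgroup_cohort(), ["NOPE"], by="subgroup")
        assert (df.n_mutated == 0).all()

    def test_subgroup_enrichment_wrapper(self):
        r = subgroup_enrichment(_subgroup_cohort(), "KLF3")
        assert (r.a, r.b, r.c, r.d) == (20, 121, 0, 195)
        assert r.p_two_tailed < 1e-7


class TestMissenseConsensus:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (
                {"MutationAssessor": "high", "PROVEAN": "deleterious",
                 "SIFT": "damaging", "PolyPhen2": "benign"},
                True,
            ),
            ({"MutationAssessor": "high", "PROVEAN": "deleterious"}, False),
            (
                {"MutationAssessor": "high", "PROVEAN": "deleterious",
                 "SIFT": "damaging", "PolyPhen2": "probably-damaging"},
                True,
            ),
            (
                {"MutationAssessor": "low", "PROVEAN": "neutral",
                 "SIFT": "tolerated", "PolyPhen2": "benign"},
                False,
            ),
        ],
    )
    def test_three_of_four_rule(self, labels, expected):
        assert missense_consensus(labels).impact is expected

    def test_alias_accepted(self):
        c = missense_consensus({"PolyPhen-2": "probably-damaging"})
        assert c.n_impact == 1

    def test_unknown_predictor_rejected(self):
        with pytest.raises(ValueError, match="unknown predictor"):
            missense_consensus({"CADD": "damaging"})
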