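"""MSI target-gene characterization.

Microsatellite-unstable (MSI) tumors accumulate strand-slippage indels at
homopolymer tracts; a gene recurrently hit by such indels in the
MSI-hypermutated subgroup is a candidate *MSI target gene*.  This module
provides the building blocks for that annotation:

- :func:`detect_homopolymer` — is an indel inside (or immediately adjoining)
  a mononucleotide run of a given minimum length?
- :func:`recurrence_table` — per (gene, protein change) sample counts, with
  hotspots flagged at >= 2 samples.
- :func:`fisher_2x2` — two-tailed Fisher exact test for subgroup enrichment.
- :func:`frequency_table` — mutated/total/percent per stage, subgroup or
  grade stratum.
- :func:`missense_consensus` — the >= 3-of-4 agreement rule over
  MutationAssessor / PROVEAN / SIFT / PolyPhen-2 impact labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from stagesmg.cohort_io import Cohort, NONCODING_CLASSES, VariantRecord, is_nonsilent, stratify

logger = logging.getLogger(__name__)

#: Minimum mononucleotide run length to call a tract; 5 is a conventional
#: instability floor, and the tracts of interest in EEC (e.g. (C)7) exceed it.
DEFAULT_MIN_TRACT_LENGTH = 5

#: Per-predictor label that counts as functional impact.
IMPACT_TOKENS: dict[str, str] = {
    "MutationAssessor": "high",
    "PROVEAN": "deleterious",
    "SIFT": "damaging",
    "PolyPhen2": "probably-damaging",
}
_PREDICTOR_ALIASES = {"PolyPhen-2": "PolyPhen2", "polyphen2": "PolyPhen2"}


@dataclass(frozen=True)
class HomopolymerCall:
    """Outcome of homopolymer-tract assessment for one indel."""

    variant_key: tuple
    tract_base: str | None
    tract_length: int
    in_tract: bool
    window: str | None
    uncallable: bool = False


def _run_bounds(seq: str, i: int) -> tuple[int, int]:
    """Half-open bounds of the maximal identical-base run containing index i."""
    base = seq[i]
    lo = i
    while lo > 0 and seq[lo - 1] == base:
        lo -= 1
    hi = i + 1
    while hi < len(seq) and seq[hi] == base:
        hi += 1
    return lo, hi


def detect_homopolymer(
    variant: VariantRecord, min_tract_length: int = DEFAULT_MIN_TRACT_LENGTH
) -> HomopolymerCall:
    """Assess whether an indel sits in a homopolymer tract.

    For a deletion the tract is the maximal run of identical bases containing
    the deleted base(s); the call is positive when the run reaches
    ``min_tract_length`` and every deleted base equals the run base.  For an
    insertion the inserted bases must all be one base ``b`` and the tract is
    the run of ``b`` immediately flanking the insertion point (left run +
    right run).  SNVs are a contract violation; a missing context window
    yields an ``uncallable`` result rather than an error.

    The context convention is: ``context_offset`` is the 0-based index of the
    first deleted base (deletions) or of the base 5' of the insertion point
    (insertions); it defaults to the centre of the window.
    """
    if variant.variant_type == "SNP":
        raise ValueError("detect_homopolymer expects an insertion or deletion")
    ctx = variant.context_seq
    if not ctx:
        return HomopolymerCall(
            variant_key=variant.key,
            tract_base=None,
            tract_length=0,
            in_tract=False,
            window=None,
            uncallable=True,
        )
    ctx = ctx.upper()
    offset = variant.context_offset
    if offset is None:
        offset = (len(ctx) - 1) // 2
    if variant.variant_type == "DEL":
        ref = variant.ref_allele.upper()
        span_end = offset + len(ref)
        if not 0 <= offset < span_end <= len(ctx):
            raise ValueError(
                f"deleted span [{offset}, {span_end}) outside context window "
                f"of length {len(ctx)}"
            )
        lo, hi = _run_bounds(ctx, offset)
        base = ctx[offset]
        length = hi - lo
        deleted_uniform = set(ref) == {base} and set(ctx[offset:span_end]) == {base}
        in_tract = length >= min_tract_length and deleted_uniform
    else:  # INS
        alt = variant.alt_allele.upper()
        if not 0 <= offset < len(ctx):
            raise ValueError(f"insertion point {offset} outside context window")
        bases = set(alt)
        if len(bases) != 1:
            return HomopolymerCall(
                variant_key=variant.key,
                tract_base=None,
                tract_length=0,
                in_tract=False,
                window=ctx,
            )
        base = bases.pop()
        left = 0
        i = offset
        while i >= 0 and ctx[i] == base:
            left += 1
            i -= 1
        right = 0
        i = offset + 1
        while i < len(ctx) and ctx[i] == base:
            right += 1
            i += 1
        length = left + right
        in_tract = length >= min_tract_length
    return HomopolymerCall(
        variant_key=variant.key,
        tract_base=base,
        tract_length=length,
        in_tract=in_tract,
        window=ctx,
    )


def recurrence_table(
    variants: Sequence[VariantRecord], min_count: int = 2
) -> pd.DataFrame:
    """Sample counts per (gene, protein change), flagging recurrent changes.

    One sample contributes at most once to each (gene, protein change) cell;
    variants without a protein change annotation are skipped.
    """
    samples: dict[tuple[str, str], set[str]] = {}
    for v in variants:
        if v.protein_change:
            samples.setdefault((v.gene, v.protein_change), set()).add(v.sample_id)
    rows = [
        {
            "gene": gene,
            "protein_change": change,
            "n_samples": len(ids),
            "recurrent": len(ids) >= min_count,
        }
        for (gene, change), ids in sorted(samples.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "protein_change", "n_samples", "recurrent"])


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 table with sample odds ratio and two-tailed Fisher exact p."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_tailed: float


def fisher_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-tailed Fisher exact test on [[a, b], [c, d]].

    Two-tailed p is the sum of hypergeometric point probabilities not
    exceeding that of the observed table (the dominant convention, with a
    1 + 1e-7 relative tolerance on the comparison).  The odds ratio is the
    sample odds ratio a*d / (b*c), infinite when b*c = 0 and a*d > 0.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValueError(f"negative cell count in {counts}")
    if all(x == 0 for x in counts):
        raise ValueError("all-zero 2x2 table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(a=a, b=b, c=c, d=d, odds_ratio=odds, p_two_tailed=float(p))


def subgroup_enrichment(
    cohort: Cohort, gene: str, subgroup: str = "MSI_hypermutated"
) -> ContingencyResult:
    """Fisher test of gene mutation in one subgroup vs all other assigned subgroups."""
    mutated = _mutated_samples(cohort, gene)
    in_grp = [c for c in cohort.clinical if c.subgroup == subgroup]
    out_grp = [
        c
        for c in cohort.clinical
        if c.subgroup not in (subgroup, "unassigned")
    ]
    a = sum(1 for c in in_grp if c.sample_id in mutated)
    c_ = sum(1 for c in out_grp if c.sample_id in mutated)
    return fisher_2x2(a, len(in_grp) - a, c_, len(out_grp) - c_)


def _mutated_samples(cohort: Cohort, gene: str) -> set[str]:
    out = set()
    for v in cohort.variants:
        if v.gene != gene or v.variant_classification in NONCODING_CLASSES:
            continue
        if is_nonsilent(v):
            out.add(v.sample_id)
    return out


def frequency_table(
    cohort: Cohort,
    genes: Sequence[str],
    by: str | Sequence[str] = ("stage_class", "subgroup"),
) -> pd.DataFrame:
    """Mutated count / total / percent per stratum for each gene.

    A sample counts as mutated for a gene iff it carries >= 1 non-silent
    variant in that gene.  Percentages are rounded to one decimal.  An
    unknown gene yields zero-count rows with a warning.
    """
    known = {v.gene for v in cohort.variants}
    for g in genes:
        if g not in known:
            logger.warning("frequency_table: gene %r has no variants in cohort", g)
    strata = stratify(cohort, by=by)
    rows = []
    for gene in genes:
        mutated = _mutated_samples(cohort, gene)
        rows.append(
            {
                "stratum": "all",
                "gene": gene,
                "n_mutated": len(mutated & set(cohort.sample_ids)),
                "n_total": cohort.n_samples,
            }
        )
        for label in sorted(strata):
            sub = strata[label]
            rows.append(
                {
                    "stratum": label,
                    "gene": gene,
                    "n_mutated": len(mutated & set(sub.sample_ids)),
                    "n_total": sub.n_samples,
                }
            )
    df = pd.DataFrame(rows)
    df["percent"] = (100.0 * df.n_mutated / df.n_total).round(1)
    return df


@dataclass(frozen=True)
class FunctionalConsensus:
    """Aggregated missense impact call over the four predictors."""

    labels: Mapping[str, str]
    impact: bool
    n_impact: int


def missense_consensus(labels: Mapping[str, str]) -> FunctionalConsensus:
    """Apply the >= 3-of-4 predictor agreement rule.

    ``labels`` maps predictor name (MutationAssessor, PROVEAN, SIFT,
    PolyPhen2) to that predictor's output label.  A predictor counts towards
    impact only when its label equals its impact token ("high",
    "deleterious", "damaging", "probably-damaging" respectively); missing
    predictors count as non-impact.  Unknown predictor names are an error.
    """
    normalised = {}
    for name, label in labels.items():
        canonical = _PREDICTOR_ALIASES.get(name, name)
        if canonical not in IMPACT_TOKENS:
            raise ValueError(
                f"unknown predictor {name!r}; expected one of {sorted(IMPACT_TOKENS)}"
            )
        normalised[canonical] = label
    n_impact = sum(
        1 for name, label in normalised.items() if label == IMPACT_TOKENS[name]
    )
    return FunctionalConsensus(labels=normalised, impact=n_impact >= 3, n_impact=n_impact)
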