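"""High-confidence somatic variant filtering for multi-caller exome merges.

Implements the step-wise filter used to derive high-confidence somatic
variants from a tumor/normal multi-caller merge: read-support thresholds,
germline VAF exclusion, dbSNP-based exclusion, multi-caller consensus, and
noncoding-class exclusion.  Each stage returns the retained variants plus a
:class:`FilterReport` that attributes every dropped variant to the first
failing rule, so the counts always reconcile with the input size.

Threshold semantics are literal: depth minima are inclusive (>= 14 tumor /
>= 8 normal reads), while the VAF and population-MAF exclusions are strict
(normal VAF > 3% excluded, dbSNP SNP MAF > 5% excluded; dbSNP indels are
excluded on membership alone, without MAF evaluation).  Variants missing a
field a rule needs are dropped under a separate ``missing_data`` tally
rather than raising, so real-world tables process end-to-end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from stagesmg.cohort_io import NONCODING_CLASSES, VariantRecord

logger = logging.getLogger(__name__)

#: Callers whose unanimous agreement is required for SNVs.
DEFAULT_SNV_CALLERS = frozenset({"Strelka", "Shimmer", "SomaticSniper", "MuTect"})
#: Callers of which at least one must support an indel.
DEFAULT_INDEL_CALLERS = frozenset({"Strelka", "Shimmer"})


class DbsnpLookup:
    """Population-variant membership/MAF lookup keyed by exact allele match.

    Keys are ``(chrom, pos, ref, alt)``; the value is the minor allele
    frequency in [0, 1], or ``None`` when the site is catalogued without a
    recorded frequency.  Position-only matching is deliberately not offered:
    it would over-exclude multi-allelic sites.
    """

    def __init__(self, entries: Mapping[tuple[str, int, str, str], float | None] = ()):
        self._entries: dict[tuple[str, int, str, str], float | None] = dict(entries)
        for key, maf in self._entries.items():
            if maf is not None and not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF out of [0,1] for {key}: {maf}")

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, site: tuple[str, int, str, str]) -> bool:
        return site in self._entries

    def maf(self, site: tuple[str, int, str, str]) -> float | None:
        return self._entries.get(site)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DbsnpLookup":
        """Load from a TSV with columns chrom, pos, ref, alt, maf (blank = unknown)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"chrom", "pos", "ref", "alt", "maf"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: dbSNP table missing column(s) {sorted(missing)}")
        entries = {}
        for row in df.itertuples(index=False):
            maf = None if row.maf.strip() == "" else float(row.maf)
            entries[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = maf
        return cls(entries)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        rows = [
            {"chrom": c, "pos": p, "ref": r, "alt": a, "maf": "" if m is None else m}
            for (c, p, r, a), m in sorted(self._entries.items())
        ]
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"]).to_csv(
            path, sep="\t", index=False
        )
        return path


@dataclass
class FilterReport:
    """Input/retained counts plus per-rule drop tallies (first failing rule)."""

    input_count: int = 0
    retained_count: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, rule: str) -> None:
        self.dropped[rule] = self.dropped.get(rule, 0) + 1

    @property
    def total_dropped(self) -> int:
        return sum(self.dropped.values())

    def check(self) -> None:
        if self.retained_count + self.total_dropped != self.input_count:
            raise AssertionError(
                f"filter report does not reconcile: {self.retained_count} retained + "
                f"{self.total_dropped} dropped != {self.input_count} input"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "dropped": n} for r, n in sorted(self.dropped.items())]
        rows.append({"rule": "(retained)", "dropped": self.retained_count})
        return pd.DataFrame(rows)


# Each rule returns None (pass) or the name of the tally to drop under.
RuleFn = Callable[[VariantRecord], "str | None"]


def _read_support_rule(min_tumor_depth: int, min_normal_depth: int) -> RuleFn:
    def rule(v: VariantRecord) -> str | None:
        if v.t_depth is None or v.n_depth is None:
            return "missing_data"
        if v.t_depth < min_tumor_depth or v.n_depth < min_normal_depth:
            return "read_support"
        return None

    return rule


def _germline_vaf_rule(max_normal_vaf: float) -> RuleFn:
    def rule(v: VariantRecord) -> str | None:
        if v.n_alt_count is None or v.n_depth is None or v.n_depth == 0:
            return "missing_data"
        if v.n_alt_count / v.n_depth > max_normal_vaf:
            return "germline_vaf"
        return None

    return rule


def _dbsnp_rule(lookup: DbsnpLookup, max_maf: float) -> RuleFn:
    def rule(v: VariantRecord) -> str | None:
        if v.site not in lookup:
            return None
        if v.variant_type == "SNP":
            maf = lookup.maf(v.site)
            # Catalogued without a recorded frequency: retained (conservative
            # towards keeping putative somatic calls).
            if maf is not None and maf > max_maf:
                return "dbsnp"
            return None
        return "dbsnp"  # indels excluded on membership alone

    return rule


def _caller_consensus_rule(
    snv_required: frozenset[str], indel_any_of: frozenset[str]
) -> RuleFn:
    def rule(v: VariantRecord) -> str | None:
        if not v.callers:
            return "caller_consensus"
        if v.variant_type == "SNP":
            return None if snv_required <= v.callers else "caller_consensus"
        return None if v.callers & indel_any_of else "caller_consensus"

    return rule


def _noncoding_rule(v: VariantRecord) -> str | None:
    return "noncoding" if v.variant_classification in NONCODING_CLASSES else None


def _apply(
    variants: Sequence[VariantRecord], rules: Sequence[RuleFn], label: str
) -> tuple[list[VariantRecord], FilterReport]:
    report = FilterReport(input_count=len(variants))
    retained = []
    for v in variants:
        for rule in rules:
            tally = rule(v)
            if tally is not None:
                report.drop(tally)
                break
        else:
            retained.append(v)
    report.retained_count = len(retained)
    report.check()
    logger.info(
        "%s: %d -> %d (%s)", label, report.input_count, report.retained_count,
        dict(sorted(report.dropped.items())),
    )
    return retained, report


def apply_read_support(
    variants: Sequence[VariantRecord],
    min_tumor_depth: int = 14,
    min_normal_depth: int = 8,
) -> tuple[list[VariantRecord], FilterReport]:
    """Require >= ``min_tumor_depth`` tumor and >= ``min_normal_depth`` normal reads."""
    return _apply(
        variants, [_read_support_rule(min_tumor_depth, min_normal_depth)], "read_support"
    )


def apply_germline_vaf(
    variants: Sequence[VariantRecord], max_normal_vaf: float = 0.03
) -> tuple[list[VariantRecord], FilterReport]:
    """Exclude likely germline calls with normal-sample VAF strictly above the cap."""
    return _apply(variants, [_germline_vaf_rule(max_normal_vaf)], "germline_vaf")


def apply_dbsnp(
    variants: Sequence[VariantRecord],
    lookup: DbsnpLookup,
    max_maf: float = 0.05,
) -> tuple[list[VariantRecord], FilterReport]:
    """Exclude catalogued polymorphisms.

    SNVs are dropped only when catalogued with MAF strictly above ``max_maf``;
    indels are dropped on catalogue membership alone.
    """
    return _apply(variants, [_dbsnp_rule(lookup, max_maf)], "dbsnp")


def apply_caller_consensus(
    variants: Sequence[VariantRecord],
    snv_required: frozenset[str] | set[str] = DEFAULT_SNV_CALLERS,
    indel_any_of: frozenset[str] | set[str] = DEFAULT_INDEL_CALLERS,
) -> tuple[list[VariantRecord], FilterReport]:
    """Keep SNVs called by every required caller and indels called by any listed one."""
    return _apply(
        variants,
        [_caller_consensus_rule(frozenset(snv_required), frozenset(indel_any_of))],
        "caller_consensus",
    )


def run_consensus_pipeline(
    variants: Sequence[VariantRecord],
    lookup: DbsnpLookup | None = None,
    *,
    min_tumor_depth: int = 14,
    min_normal_depth: int = 8,
    max_normal_vaf: float = 0.03,
    max_snp_maf: float = 0.05,
    snv_required: frozenset[str] | set[str] = DEFAULT_SNV_CALLERS,
    indel_any_of: frozenset[str] | set[str] = DEFAULT_INDEL_CALLERS,
) -> tuple[list[VariantRecord], FilterReport]:
    """Run the full step-wise filter.

    Rule order: read support -> germline VAF -> dbSNP -> caller consensus ->
    noncoding exclusion.  Every dropped variant is tallied under the first
    rule it fails, so ``retained + sum(dropped) == input`` exactly.  The
    dbSNP stage is skipped when no lookup is supplied.
    """
    rules: list[RuleFn] = [
        _read_support_rule(min_tumor_depth, min_normal_depth),
        _germline_vaf_rule(max_normal_vaf),
    ]
    if lookup is not None:
        rules.append(_dbsnp_rule(lookup, max_snp_maf))
    rules.append(_caller_consensus_rule(frozenset(snv_required), frozenset(indel_any_of)))
    rules.append(_noncoding_rule)
    return _apply(variants, rules, "consensus_pipeline")
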