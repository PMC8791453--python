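"""Somatic mutation cohort I/O, TCGA-dialect variant filters, and stratification.

The in-memory model is one :class:`VariantRecord` per called somatic variant
per sample, plus one :class:`ClinicalRecord` per sample carrying FIGO stage,
grade, and TCGA molecular subgroup.  A :class:`Cohort` ties the two together
and is the unit every downstream analysis consumes.

MAF dialects
------------
Mutation Annotation Format files differ mainly in column naming and in how
caller provenance is encoded.  Three dialects are built in:

``tcga_mc3``
    The MC3 pan-cancer MAF column set (``Hugo_Symbol``, ``Start_Position``,
    ``CENTERS`` with ``|``-delimited caller names, ...).
``generic``
    Plain lower-case column names matching the :class:`VariantRecord` fields;
    this is what :func:`write_maf` emits and the synthetic generator uses.
``nhgri``
    The generic column set with comma-delimited caller provenance, for
    in-house multi-caller merge tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# Controlled vocabulary of variant classifications (Oncotator/MC3 style).
NONCODING_CLASSES = frozenset(
    {"3'UTR", "5'UTR", "3'Flank", "5'Flank", "Intron", "RNA", "lincRNA", "De_novo_Start"}
)
NONSILENT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
    }
)
CODING_CLASSES = NONSILENT_CLASSES | {"Silent"}
VARIANT_CLASSIFICATIONS = CODING_CLASSES | NONCODING_CLASSES

VARIANT_TYPES = frozenset({"SNP", "INS", "DEL"})
FIGO_STAGES = frozenset({"I", "II", "III", "IV", "unknown"})
GRADES = frozenset({"G1", "G2", "G3", "unknown"})
SUBGROUPS = frozenset(
    {"MSI_hypermutated", "CN_low", "CN_high", "POLE_ultramutated", "unassigned"}
)

#: TCGA MC3 FILTER designations retained by default.
DEFAULT_KEEP_FILTERS = frozenset({"PASS", "WGA", "Native_WGA_mix"})


class MafFormatError(ValueError):
    """Raised when a mutation table cannot be interpreted under a dialect."""


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One somatic variant call in one sample.

    Coordinates follow the MAF convention: 1-based inclusive start,
    deletions use ``-`` as the alt allele, insertions ``-`` as the ref
    allele.  ``context_seq`` optionally carries the flanking sequence window
    with ``context_offset`` the 0-based index of the edited position (first
    deleted base for deletions; base immediately 5' of the insertion point
    for insertions).
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    variant_type: str
    variant_classification: str
    filter_status: str = "PASS"
    callers: frozenset[str] = frozenset()
    t_depth: int | None = None
    t_alt_count: int | None = None
    n_depth: int | None = None
    n_alt_count: int | None = None
    protein_change: str | None = None
    context_seq: str | None = None
    context_offset: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant_type {self.variant_type!r}")
        if self.variant_classification not in VARIANT_CLASSIFICATIONS:
            raise ValueError(
                f"unknown variant_classification {self.variant_classification!r}"
            )
        is_snp = (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele != "-"
            and self.alt_allele != "-"
        )
        if is_snp != (self.variant_type == "SNP"):
            raise ValueError(
                f"variant_type {self.variant_type!r} inconsistent with alleles "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        for alt, depth, label in (
            (self.t_alt_count, self.t_depth, "tumor"),
            (self.n_alt_count, self.n_depth, "normal"),
        ):
            if alt is not None and depth is not None and alt > depth:
                raise ValueError(f"{label} alt count {alt} exceeds depth {depth}")
            for v in (alt, depth):
                if v is not None and v < 0:
                    raise ValueError(f"negative read count {v}")

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """(sample, chrom, pos, ref, alt) identity of the call."""
        return (self.sample_id, self.chrom, self.pos, self.ref_allele, self.alt_allele)

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True, slots=True)
class ClinicalRecord:
    """Per-sample FIGO stage, grade, and molecular subgroup."""

    sample_id: str
    figo_stage: str = "unknown"
    grade: str = "unknown"
    subgroup: str = "unassigned"

    def __post_init__(self) -> None:
        if self.figo_stage not in FIGO_STAGES:
            raise ValueError(f"unknown FIGO stage {self.figo_stage!r}")
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")

    @property
    def stage_class(self) -> str:
        """early (I/II), late (III/IV), or unknown."""
        if self.figo_stage in ("I", "II"):
            return "early"
        if self.figo_stage in ("III", "IV"):
            return "late"
        return "unknown"


@dataclass
class Cohort:
    """A set of variants with clinical annotation for every carrying sample."""

    variants: list[VariantRecord]
    clinical: list[ClinicalRecord]
    name: str = ""

    def __post_init__(self) -> None:
        ids = [c.sample_id for c in self.clinical]
        if len(ids) != len(set(ids)):
            raise ValueError(f"cohort {self.name!r}: duplicate sample_ids in clinical")
        known = set(ids)
        orphans = {v.sample_id for v in self.variants} - known
        if orphans:
            raise ValueError(
                f"cohort {self.name!r}: variants for samples missing from clinical: "
                f"{sorted(orphans)[:5]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.clinical)

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.clinical]

    def clinical_by_id(self) -> dict[str, ClinicalRecord]:
        return {c.sample_id: c for c in self.clinical}

    def subset(self, sample_ids: Iterable[str], name: str = "") -> "Cohort":
        keep = set(sample_ids)
        return Cohort(
            variants=[v for v in self.variants if v.sample_id in keep],
            clinical=[c for c in self.clinical if c.sample_id in keep],
            name=name or self.name,
        )

    def with_variants(self, variants: Sequence[VariantRecord], name: str = "") -> "Cohort":
        return Cohort(list(variants), list(self.clinical), name or self.name)


# ---------------------------------------------------------------------------
# MAF dialects


@dataclass(frozen=True)
class MafDialect:
    name: str
    columns: Mapping[str, str]  # VariantRecord field -> file column
    caller_delimiter: str = "|"
    optional: frozenset[str] = frozenset(
        {
            "t_depth",
            "t_alt_count",
            "n_depth",
            "n_alt_count",
            "protein_change",
            "context_seq",
            "context_offset",
            "callers",
            "filter_status",
        }
    )


_GENERIC_COLUMNS = {
    "sample_id": "sample_id",
    "gene": "gene",
    "chrom": "chrom",
    "pos": "pos",
    "ref_allele": "ref_allele",
    "alt_allele": "alt_allele",
    "variant_type": "variant_type",
    "variant_classification": "variant_classification",
    "filter_status": "filter_status",
    "callers": "callers",
    "t_depth": "t_depth",
    "t_alt_count": "t_alt_count",
    "n_depth": "n_depth",
    "n_alt_count": "n_alt_count",
    "protein_change": "protein_change",
    "context_seq": "context_seq",
    "context_offset": "context_offset",
}

DIALECTS: dict[str, MafDialect] = {
    "tcga_mc3": MafDialect(
        name="tcga_mc3",
        columns={
            "sample_id": "Tumor_Sample_Barcode",
            "gene": "Hugo_Symbol",
            "chrom": "Chromosome",
            "pos": "Start_Position",
            "ref_allele": "Reference_Allele",
            "alt_allele": "Tumor_Seq_Allele2",
            "variant_type": "Variant_Type",
            "variant_classification": "Variant_Classification",
            "filter_status": "FILTER",
            "callers": "CENTERS",
            "t_depth": "t_depth",
            "t_alt_count": "t_alt_count",
            "n_depth": "n_depth",
            "n_alt_count": "n_alt_count",
            "protein_change": "HGVSp_Short",
            "context_seq": "CONTEXT",
            "context_offset": "CONTEXT_OFFSET",
        },
        caller_delimiter="|",
    ),
    "generic": MafDialect(name="generic", columns=_GENERIC_COLUMNS, caller_delimiter="|"),
    "nhgri": MafDialect(name="nhgri", columns=_GENERIC_COLUMNS, caller_delimiter=","),
}


def _parse_int(value, column: str) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if s in ("", ".", "NA", "nan"):
        return None
    try:
        return int(float(s))
    except ValueError as exc:
        raise ValueError(f"column {column!r}: cannot parse integer from {s!r}") from exc


def _parse_callers(value, delimiter: str) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    tokens = [t.strip().rstrip("*") for t in str(value).split(delimiter)]
    return frozenset(t for t in tokens if t and t != ".")


def read_maf(path: str | Path, dialect: str = "generic") -> list[VariantRecord]:
    """Read a MAF-dialect mutation table into :class:`VariantRecord` rows.

    Rows with unparseable mandatory fields, an unknown classification, or an
    invariant violation (e.g. alt count exceeding depth) are rejected with a
    row-numbered log message; the parsed/rejected counts are logged at INFO.
    Noncoding classifications are *retained* — their exclusion is a
    downstream filter (:func:`exclude_noncoding`), not a parse decision.
    """
    spec = DIALECTS.get(dialect)
    if spec is None:
        raise ValueError(f"unknown MAF dialect {dialect!r}; have {sorted(DIALECTS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise MafFormatError(f"{path}: empty MAF file") from exc
    mandatory = [
        col
        for fld, col in spec.columns.items()
        if fld not in spec.optional
    ]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise MafFormatError(f"{path}: missing mandatory column(s) {missing}")
    if df.empty:
        raise MafFormatError(f"{path}: no data rows")

    def col(row, fld, default=None):
        c = spec.columns.get(fld)
        if c is None or c not in df.columns:
            return default
        v = row[c]
        return default if v == "" else v

    records: list[VariantRecord] = []
    rejected = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        row = dict(zip(df.columns, row))
        try:
            records.append(
                VariantRecord(
                    sample_id=str(row[spec.columns["sample_id"]]),
                    gene=str(row[spec.columns["gene"]]),
                    chrom=str(row[spec.columns["chrom"]]),
                    pos=_parse_int(row[spec.columns["pos"]], "pos"),
                    ref_allele=str(row[spec.columns["ref_allele"]]),
                    alt_allele=str(row[spec.columns["alt_allele"]]),
                    variant_type=str(row[spec.columns["variant_type"]]),
                    variant_classification=str(
                        row[spec.columns["variant_classification"]]
                    ),
                    filter_status=str(col(row, "filter_status", "PASS")),
                    callers=_parse_callers(col(row, "callers"), spec.caller_delimiter),
                    t_depth=_parse_int(col(row, "t_depth"), "t_depth"),
                    t_alt_count=_parse_int(col(row, "t_alt_count"), "t_alt_count"),
                    n_depth=_parse_int(col(row, "n_depth"), "n_depth"),
                    n_alt_count=_parse_int(col(row, "n_alt_count"), "n_alt_count"),
                    protein_change=col(row, "protein_change"),
                    context_seq=col(row, "context_seq"),
                    context_offset=_parse_int(col(row, "context_offset"), "context_offset"),
                )
            )
        except (ValueError, TypeError) as exc:
            rejected += 1
            logger.warning("%s row %d rejected: %s", path.name, idx, exc)
    logger.info("%s: parsed %d variants, rejected %d rows", path.name, len(records), rejected)
    return records


def write_maf(
    variants: Sequence[VariantRecord], path: str | Path, dialect: str = "generic"
) -> Path:
    """Write variants as a tab-delimited MAF in the given dialect."""
    spec = DIALECTS[dialect]
    rows = []
    for v in variants:
        row = {}
        for fld, colname in spec.columns.items():
            val = getattr(v, fld)
            if fld == "callers":
                val = spec.caller_delimiter.join(sorted(val))
            row[colname] = "" if val is None else val
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows, columns=list(spec.columns.values())).to_csv(
        path, sep="\t", index=False
    )
    return path


_STAGE_ALIASES = {
    "i": "I", "ii": "II", "iii": "III", "iv": "IV",
    "stage i": "I", "stage ii": "II", "stage iii": "III", "stage iv": "IV",
    "1": "I", "2": "II", "3": "III", "4": "IV",
}
_SUBGROUP_ALIASES = {
    "msi": "MSI_hypermutated",
    "msi_hypermutated": "MSI_hypermutated",
    "msi-hypermutated": "MSI_hypermutated",
    "cn_low": "CN_low",
    "cn-low": "CN_low",
    "cn low": "CN_low",
    "copy-number low": "CN_low",
    "cn_high": "CN_high",
    "cn-high": "CN_high",
    "cn high": "CN_high",
    "copy-number high": "CN_high",
    "pole": "POLE_ultramutated",
    "pole_ultramutated": "POLE_ultramutated",
}


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical TSV with header sample_id, stage, grade, subgroup.

    Stage and subgroup tokens are normalised (``Stage III`` -> ``III``,
    ``MSI`` -> ``MSI_hypermutated``); unrecognised values become
    ``unknown``/``unassigned`` with a warning rather than an error so that
    partially annotated cohorts load.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "stage", "grade", "subgroup"}
    missing = required - set(df.columns)
    if missing:
        raise MafFormatError(f"{path}: clinical table missing column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        stage = str(row.stage).strip()
        stage = _STAGE_ALIASES.get(stage.lower(), stage if stage in FIGO_STAGES else "")
        if stage not in FIGO_STAGES:
            if stage:
                logger.warning("sample %s: unrecognised stage %r", row.sample_id, row.stage)
            stage = "unknown"
        grade = str(row.grade).strip().upper().replace("GRADE ", "G")
        if grade not in GRADES:
            grade = "unknown"
        sub = str(row.subgroup).strip()
        sub = _SUBGROUP_ALIASES.get(sub.lower(), sub)
        if sub not in SUBGROUPS:
            if sub:
                logger.warning(
                    "sample %s: unrecognised subgroup %r", row.sample_id, row.subgroup
                )
            sub = "unassigned"
        records.append(
            ClinicalRecord(
                sample_id=str(row.sample_id), figo_stage=stage, grade=grade, subgroup=sub
            )
        )
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "stage": c.figo_stage,
                "grade": c.grade,
                "subgroup": c.subgroup,
            }
            for c in records
        ]
    ).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Filters


def filter_tcga_variants(
    variants: Sequence[VariantRecord],
    keep_filters: frozenset[str] | set[str] = DEFAULT_KEEP_FILTERS,
    snv_caller: str = "MUTECT",
    indel_caller: str = "INDELOCATOR",
) -> list[VariantRecord]:
    """Apply the TCGA-dialect retention rule.

    A variant is retained iff its FILTER token is in ``keep_filters`` and its
    provenance names the required caller for its type (SNVs: ``snv_caller``;
    insertions/deletions: ``indel_caller``).  Order is preserved.
    """
    keep_filters = frozenset(keep_filters)
    out = []
    for v in variants:
        if v.filter_status not in keep_filters:
            continue
        required = snv_caller if v.variant_type == "SNP" else indel_caller
        if required not in v.callers:
            continue
        out.append(v)
    logger.info("filter_tcga_variants: %d -> %d", len(variants), len(out))
    return out


def exclude_noncoding(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Drop UTR/Flank/Intron/RNA/lincRNA/De-novo-start calls.

    Coding, splice-site and silent calls are retained.
    """
    out = [v for v in variants if v.variant_classification not in NONCODING_CLASSES]
    logger.info("exclude_noncoding: %d -> %d", len(variants), len(out))
    return out


def is_nonsilent(variant: VariantRecord) -> bool:
    """True for nonsynonymous and splice-junction classes, False for Silent.

    Noncoding input is a contract violation: run :func:`exclude_noncoding`
    first.
    """
    cls = variant.variant_classification
    if cls in NONCODING_CLASSES:
        raise ValueError(
            f"is_nonsilent called on noncoding classification {cls!r}; "
            "apply exclude_noncoding first"
        )
    return cls in NONSILENT_CLASSES


# ---------------------------------------------------------------------------
# Stratification & burden


def stratify(
    cohort: Cohort, by: str | Sequence[str] = "stage_class"
) -> dict[str, Cohort]:
    """Partition a cohort by stage class and/or molecular subgroup.

    ``by`` is ``"stage_class"``, ``"subgroup"`` or a sequence of both; for a
    pair the stratum label is ``"<stage>/<subgroup>"``.  Samples whose value
    is unknown/unassigned land in their own stratum, which downstream
    analyses skip.  Every sample is assigned to exactly one stratum.
    """
    keys = (by,) if isinstance(by, str) else tuple(by)
    for k in keys:
        if k not in ("stage_class", "subgroup"):
            raise ValueError(f"cannot stratify by {k!r}")

    def label(c: ClinicalRecord) -> str:
        parts = []
        for k in keys:
            parts.append(c.stage_class if k == "stage_class" else c.subgroup)
        return "/".join(parts)

    groups: dict[str, list[str]] = {}
    for c in cohort.clinical:
        groups.setdefault(label(c), []).append(c.sample_id)
    return {
        lab: cohort.subset(ids, name=f"{cohort.name}:{lab}" if cohort.name else lab)
        for lab, ids in groups.items()
    }


@dataclass(frozen=True)
class BurdenSummary:
    """Per-sample non-silent mutation burden for a cohort."""

    per_sample: Mapping[str, int]
    total: int
    mean: float
    min: int
    max: int
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.per_sample.items()), columns=["sample_id", "n_nonsilent"]
        )


def summarize_burden(cohort: Cohort) -> BurdenSummary:
    """Mean/range of per-sample non-silent counts and distinct mutated genes.

    Samples with zero non-silent variants count in the denominator.  Noncoding
    calls still present in the cohort are ignored rather than rejected.
    """
    if cohort.n_samples == 0:
        raise ValueError("summarize_burden: cohort has no samples")
    counts = {c.sample_id: 0 for c in cohort.clinical}
    genes = set()
    for v in cohort.variants:
        if v.variant_classification in NONCODING_CLASSES:
            continue
        if is_nonsilent(v):
            counts[v.sample_id] += 1
            genes.add(v.gene)
    total = sum(counts.values())
    values = list(counts.values())
    return BurdenSummary(
        per_sample=counts,
        total=total,
        mean=total / len(counts),
        min=min(values),
        max=max(values),
        n_genes=len(genes),
    )
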