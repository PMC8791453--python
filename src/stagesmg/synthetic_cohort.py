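"""Seeded synthetic somatic-mutation cohorts with known ground truth.

The generator fabricates a MAF + clinical fixture with the statistical
structure the stage-stratified SMG analysis assumes, so every pipeline stage
is testable without downloads:

- per-sample non-silent background burden driven by the same binomial model
  the analysis tests against (per-subgroup mu, per-gene factor f_g drawn so
  its 90th percentile equals the analysis constant 3.9);
- planted driver genes with stage- and subgroup-specific non-silent
  mutation frequency r;
- MSI drivers realised as 1-bp deletions inside planted homopolymer windows
  (context sequence emitted) carrying named hotspot protein changes;
- fabricated read-support, caller-provenance, FILTER and dbSNP-membership
  fields, with configurable contamination channels so each filter has true
  violations to remove.

Every run returns a *truth ledger* recording every planted driver event and
every planted filter violation, enabling closed-loop tests (each filter
removes exactly its ledger set) and end-to-end recovery tests.  All
randomness flows from one ``numpy.random.default_rng(seed)`` stream consumed
in a documented order (gene table, samples per cell in sorted order,
background matrix, driver events, violation channels, field fabrication), so
a seed pins the fixture byte-for-byte; changing the draw order is a breaking
change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from stagesmg.cohort_io import (
    ClinicalRecord,
    Cohort,
    VariantRecord,
    write_clinical,
    write_maf,
)
from stagesmg.consensus_filter import (
    DEFAULT_INDEL_CALLERS,
    DEFAULT_SNV_CALLERS,
    DbsnpLookup,
)

_BASES = ("A", "C", "G", "T")

#: Homopolymer context windows are 21 bp with the tract centred.
WINDOW_LEN = 21
TRACT_LEN = 7

#: Violation channels, in the order the categorical draw assigns them.
CHANNELS = ("filter_status", "read_support", "germline_vaf", "dbsnp", "caller_consensus", "noncoding")


@dataclass(frozen=True)
class DriverSpec:
    """A planted driver gene.

    ``r_early``/``r_late`` are the per-sample non-silent mutation
    probabilities by stage class; ``subgroups`` restricts planting to the
    listed molecular subgroups (``None`` = all).  ``homopolymer_fraction``
    of driver events are realised as 1-bp deletions inside a planted
    (tract_base)x7 homopolymer window; the rest are missense SNVs.
    ``hotspots`` are protein-change strings cycled over indel events so
    recurrence is observable.
    """

    gene: str
    r_early: float
    r_late: float
    subgroups: frozenset[str] | None = None
    homopolymer_fraction: float = 0.0
    hotspots: tuple[str, ...] = ()
    tract_base: str = "C"

    def rate(self, stage_class: str) -> float:
        return self.r_late if stage_class == "late" else self.r_early


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults mirror the TCGA EEC study strata."""

    n_samples: Mapping[tuple[str, str], int]
    mu_by_subgroup: Mapping[str, float]
    drivers: tuple[DriverSpec, ...] = ()
    n_background_genes: int = 400
    gene_length: float = 1500.0
    f_g_90th: float = 3.9
    silent_fraction: float = 0.2
    caller_style: str = "tcga"  # "tcga" or "nhgri"
    filter_violation_rate: float = 0.0
    depth_violation_rate: float = 0.0
    vaf_violation_rate: float = 0.0
    dbsnp_rate: float = 0.0
    consensus_violation_rate: float = 0.0
    noncoding_rate: float = 0.0
    benign_dbsnp_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "filter_violation_rate": self.filter_violation_rate,
            "depth_violation_rate": self.depth_violation_rate,
            "vaf_violation_rate": self.vaf_violation_rate,
            "dbsnp_rate": self.dbsnp_rate,
            "consensus_violation_rate": self.consensus_violation_rate,
            "noncoding_rate": self.noncoding_rate,
            "benign_dbsnp_rate": self.benign_dbsnp_rate,
            "silent_fraction": self.silent_fraction,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} = {r} outside [0, 1]")
        total = sum(
            rates[k]
            for k in (
                "filter_violation_rate",
                "depth_violation_rate",
                "vaf_violation_rate",
                "dbsnp_rate",
                "consensus_violation_rate",
                "noncoding_rate",
            )
        )
        if total > 1.0:
            raise ValueError(f"violation channel rates sum to {total} > 1")
        for d in self.drivers:
            for r in (d.r_early, d.r_late, d.homopolymer_fraction):
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"driver {d.gene}: rate {r} outside [0, 1]")
        for cell, n in self.n_samples.items():
            if n < 0:
                raise ValueError(f"n_samples{cell} = {n} negative")
        if self.caller_style not in ("tcga", "nhgri"):
            raise ValueError(f"unknown caller_style {self.caller_style!r}")

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "CohortConfig":
        """Study-like TCGA conditions: stratum sizes 114/119/37 early and
        27/21/18 late (MSI / CN-low / CN-high), hypermutated background for
        MSI, and two MSI-restricted homopolymer-indel drivers at the reported
        stage-specific frequencies."""
        params = dict(
            n_samples={
                ("early", "MSI_hypermutated"): 114,
                ("early", "CN_low"): 119,
                ("early", "CN_high"): 37,
                ("late", "MSI_hypermutated"): 27,
                ("late", "CN_low"): 21,
                ("late", "CN_high"): 18,
            },
            mu_by_subgroup={
                "MSI_hypermutated": 1e-5,
                "CN_low": 1e-6,
                "CN_high": 1e-6,
            },
            drivers=(
                DriverSpec(
                    gene="KLF3",
                    r_early=0.114,
                    r_late=0.259,
                    subgroups=frozenset({"MSI_hypermutated"}),
                    homopolymer_fraction=0.75,
                    hotspots=("K106Nfs*21", "P226Rfs*52", "Q227Afs*37"),
                ),
                DriverSpec(
                    gene="PAX6",
                    r_early=0.035,
                    r_late=0.259,
                    subgroups=frozenset({"MSI_hypermutated"}),
                    homopolymer_fraction=0.75,
                    hotspots=("P375Hfs*7", "H376Tfs*36"),
                ),
            ),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


def _gene_p0(mu: float, f_g: np.ndarray, L: np.ndarray) -> np.ndarray:
    return -np.expm1(0.75 * L * np.log1p(-mu * f_g))


def _make_context(rng: np.random.Generator, tract_base: str) -> tuple[str, int]:
    """A 21-bp window with a centred (tract_base)x7 run; returns (window, offset
    of a mid-tract base)."""
    flank = (WINDOW_LEN - TRACT_LEN) // 2
    other = [b for b in _BASES if b != tract_base]

    def non_tract_flank(n: int, tract_side: bool) -> str:
        # Base adjacent to the tract must differ from it so the run is exactly 7.
        chars = [str(rng.choice(_BASES)) for _ in range(n)]
        if tract_side:
            chars[-1] = str(rng.choice(other))
        return "".join(chars)

    left = non_tract_flank(flank, True)
    right = non_tract_flank(flank, True)[::-1]
    window = left + tract_base * TRACT_LEN + right
    offset = flank + TRACT_LEN // 2
    return window, offset


@dataclass
class GroundTruth:
    """Ledger of everything the generator planted."""

    seed: int
    gene_table: dict[str, tuple[float, float]]  # gene -> (f_g, L)
    driver_events: dict[str, list[str]] = field(default_factory=dict)
    violations: dict[str, list[list]] = field(default_factory=dict)
    dbsnp_contaminants: list[tuple[tuple, float]] = field(default_factory=list)
    benign_dbsnp: list[tuple[tuple, float]] = field(default_factory=list)

    def violation_keys(self, channel: str) -> set[tuple]:
        return {tuple(k) for k in self.violations.get(channel, [])}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "gene_table": {g: list(v) for g, v in self.gene_table.items()},
            "driver_events": self.driver_events,
            "violations": {c: [list(k) for k in v] for c, v in self.violations.items()},
            "dbsnp_contaminants": [[list(k), m] for k, m in self.dbsnp_contaminants],
            "benign_dbsnp": [[list(k), m] for k, m in self.benign_dbsnp],
        }


def _fabricate_depths(rng: np.random.Generator) -> tuple[int, int, int, int]:
    t_depth = 14 + int(rng.poisson(60))
    n_depth = 8 + int(rng.poisson(50))
    t_alt = max(1, int(rng.binomial(t_depth, 0.3)))
    return t_depth, t_alt, n_depth, 0


def _clean_callers(style: str, variant_type: str, rng: np.random.Generator) -> frozenset[str]:
    if style == "tcga":
        if variant_type == "SNP":
            extra = {"MUSE", "RADIA", "VARSCANS"}
            picks = {e for e in extra if rng.random() < 0.5}
            return frozenset({"MUTECT"} | picks)
        return frozenset({"INDELOCATOR"})
    if variant_type == "SNP":
        return frozenset(DEFAULT_SNV_CALLERS)
    return frozenset({str(rng.choice(sorted(DEFAULT_INDEL_CALLERS)))})


def _violated_callers(style: str, variant_type: str, rng: np.random.Generator) -> frozenset[str]:
    if style == "tcga":
        # Drop the caller the dialect filter requires.
        if variant_type == "SNP":
            return frozenset({"MUSE", "RADIA"})
        return frozenset({"VARSCANI"})
    if variant_type == "SNP":
        keep = sorted(DEFAULT_SNV_CALLERS)
        keep.remove(str(rng.choice(keep)))
        return frozenset(keep)
    return frozenset({"SomaticSniper", "MuTect"})


_NONCODING_POOL = ("Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "RNA", "lincRNA", "De_novo_Start")


def generate(config: CohortConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground-truth ledger.

    Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)

    # 1. Gene table: background genes then driver genes.  f_g ~ Exponential
    # with 90th percentile equal to the analysis constant; L fixed.
    bg_genes = [f"G{i:05d}" for i in range(config.n_background_genes)]
    scale = config.f_g_90th / math.log(10.0)
    f_draws = rng.exponential(scale, size=config.n_background_genes)
    gene_table: dict[str, tuple[float, float]] = {
        g: (float(f), config.gene_length) for g, f in zip(bg_genes, f_draws)
    }
    driver_genes = [d.gene for d in config.drivers]
    for g in driver_genes:
        gene_table[g] = (1.0, config.gene_length)
    gene_chrom = {
        g: str(1 + (i % 22)) for i, g in enumerate(bg_genes + driver_genes)
    }
    gene_base_pos = {
        g: 1_000_000 + i * 100_000 for i, g in enumerate(bg_genes + driver_genes)
    }

    # 2. Samples, cells visited in sorted order.
    clinical: list[ClinicalRecord] = []
    cells = sorted(config.n_samples.items())
    for (stage_class, subgroup), n in cells:
        stage_pool = ("III", "IV") if stage_class == "late" else ("I", "II")
        for i in range(n):
            sid = f"SYN-{stage_class}-{subgroup}-{i:04d}"
            clinical.append(
                ClinicalRecord(
                    sample_id=sid,
                    figo_stage=str(rng.choice(stage_pool)),
                    grade=str(rng.choice(("G1", "G2", "G3"))),
                    subgroup=subgroup,
                )
            )

    truth = GroundTruth(seed=config.seed, gene_table=gene_table)
    truth.violations = {c: [] for c in CHANNELS}
    variants: list[VariantRecord] = []

    f_vec = np.array([gene_table[g][0] for g in bg_genes])
    L_vec = np.array([gene_table[g][1] for g in bg_genes])

    # 3. Background mutations: one Bernoulli per (sample, gene).
    for c in clinical:
        mu = config.mu_by_subgroup.get(c.subgroup, 0.0)
        if mu <= 0 or not bg_genes:
            continue
        p0 = _gene_p0(mu, f_vec, L_vec)
        hits = np.nonzero(rng.random(len(bg_genes)) < p0)[0]
        for gi in hits:
            gene = bg_genes[int(gi)]
            silent = rng.random() < config.silent_fraction
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            variants.append(
                _make_snp(
                    c.sample_id,
                    gene,
                    gene_chrom[gene],
                    gene_base_pos[gene] + int(rng.integers(0, 5000)),
                    str(ref),
                    str(alt),
                    "Silent" if silent else "Missense_Mutation",
                )
            )

    # 4. Driver events.
    hotspot_contexts: dict[tuple[str, str], tuple[str, int, int]] = {}
    for d in config.drivers:
        truth.driver_events[d.gene] = []
        # Pre-plant one homopolymer site per hotspot so recurrence lands on
        # identical coordinates and protein changes across samples.
        for j, hs in enumerate(d.hotspots or ("fs*",)):
            window, offset = _make_context(rng, d.tract_base)
            pos = gene_base_pos[d.gene] + 10_000 + j * 100
            hotspot_contexts[(d.gene, hs)] = (window, offset, pos)
    for c in clinical:
        for d in config.drivers:
            if d.subgroups is not None and c.subgroup not in d.subgroups:
                continue
            if rng.random() >= d.rate(c.stage_class):
                continue
            truth.driver_events[d.gene].append(c.sample_id)
            if d.homopolymer_fraction > 0 and rng.random() < d.homopolymer_fraction:
                hs_list = d.hotspots or ("fs*",)
                hs = hs_list[int(rng.integers(0, len(hs_list)))]
                window, offset, pos = hotspot_contexts[(d.gene, hs)]
                variants.append(
                    VariantRecord(
                        sample_id=c.sample_id,
                        gene=d.gene,
                        chrom=gene_chrom[d.gene],
                        pos=pos,
                        ref_allele=d.tract_base,
                        alt_allele="-",
                        variant_type="DEL",
                        variant_classification="Frame_Shift_Del",
                        protein_change=hs,
                        context_seq=window,
                        context_offset=offset,
                    )
                )
            else:
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                aa = int(rng.integers(30, 400))
                variants.append(
                    _make_snp(
                        c.sample_id,
                        d.gene,
                        gene_chrom[d.gene],
                        gene_base_pos[d.gene] + 20_000 + int(rng.integers(0, 2000)),
                        str(ref),
                        str(alt),
                        "Missense_Mutation",
                        protein_change=f"X{aa}Y",
                    )
                )

    # 5. Field fabrication + violation channels, one categorical draw per variant.
    rates = np.array(
        [
            config.filter_violation_rate,
            config.depth_violation_rate,
            config.vaf_violation_rate,
            config.dbsnp_rate,
            config.consensus_violation_rate,
            config.noncoding_rate,
        ]
    )
    edges = np.cumsum(rates)
    out: list[VariantRecord] = []
    for v in variants:
        t_depth, t_alt, n_depth, n_alt = _fabricate_depths(rng)
        callers = _clean_callers(config.caller_style, v.variant_type, rng)
        filter_status = "PASS" if rng.random() < 0.8 else str(rng.choice(("WGA", "Native_WGA_mix")))
        classification = v.variant_classification
        u = rng.random()
        channel = None
        for name, edge in zip(CHANNELS, edges):
            if u < edge:
                channel = name
                break
        if channel == "filter_status":
            filter_status = str(rng.choice(("nonpreferredpair", "oxog", "StrandBias")))
        elif channel == "read_support":
            if rng.random() < 0.5:
                t_depth = int(rng.integers(0, 14))
                t_alt = min(t_alt, t_depth)
            else:
                n_depth = int(rng.integers(0, 8))
        elif channel == "germline_vaf":
            n_alt = max(int(math.floor(0.03 * n_depth)) + 1, 2)
            n_alt = min(n_alt, n_depth)
        elif channel == "dbsnp":
            if v.variant_type == "SNP":
                maf = float(rng.uniform(0.06, 0.5))
            else:
                maf = float(rng.uniform(0.001, 0.5))
            truth.dbsnp_contaminants.append((v.site, maf))
        elif channel == "caller_consensus":
            callers = _violated_callers(config.caller_style, v.variant_type, rng)
        elif channel == "noncoding":
            classification = str(rng.choice(_NONCODING_POOL))
        elif rng.random() < config.benign_dbsnp_rate and v.variant_type == "SNP":
            truth.benign_dbsnp.append((v.site, float(rng.uniform(0.001, 0.05))))
        rec = VariantRecord(
            sample_id=v.sample_id,
            gene=v.gene,
            chrom=v.chrom,
            pos=v.pos,
            ref_allele=v.ref_allele,
            alt_allele=v.alt_allele,
            variant_type=v.variant_type,
            variant_classification=classification,
            filter_status=filter_status,
            callers=callers,
            t_depth=t_depth,
            t_alt_count=t_alt,
            n_depth=n_depth,
            n_alt_count=n_alt,
            protein_change=v.protein_change,
            context_seq=v.context_seq,
            context_offset=v.context_offset,
        )
        if channel is not None:
            truth.violations[channel].append(list(rec.key))
        out.append(rec)

    cohort = Cohort(variants=out, clinical=clinical, name=f"synthetic-seed{config.seed}")
    return cohort, truth


def _make_snp(
    sample_id: str,
    gene: str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    classification: str,
    protein_change: str | None = None,
) -> VariantRecord:
    return VariantRecord(
        sample_id=sample_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        variant_type="SNP",
        variant_classification=classification,
        protein_change=protein_change,
    )


def emit_dbsnp(truth: GroundTruth, path: str | Path | None = None) -> DbsnpLookup:
    """Build the dbSNP lookup consistent with the planted contamination.

    Every ledgered germline contaminant appears with its drawn MAF (> 0.05
    for SNVs); benign entries (SNVs with MAF <= 0.05, which the filter must
    retain) are included when the config planted them.
    """
    entries: dict[tuple, float] = {}
    for site, maf in truth.dbsnp_contaminants:
        entries[tuple(site)] = maf
    for site, maf in truth.benign_dbsnp:
        entries.setdefault(tuple(site), maf)
    lookup = DbsnpLookup(entries)
    if path is not None:
        lookup.to_tsv(path)
    return lookup


def write_fixture(config: CohortConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write maf/clinical/dbsnp/truth files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate(config)
    paths = {
        "maf": write_maf(cohort.variants, out_dir / "cohort.maf", dialect="generic"),
        "clinical": write_clinical(cohort.clinical, out_dir / "clinical.tsv"),
    }
    emit_dbsnp(truth, out_dir / "dbsnp.tsv")
    paths["dbsnp"] = out_dir / "dbsnp.tsv"
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    paths["truth"] = truth_path
    return paths
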