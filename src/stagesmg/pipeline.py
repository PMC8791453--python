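"""End-to-end orchestration of the stage-stratified SMG analysis.

``run_full`` executes the step-wise flow — ingest (or simulate), variant
filtering, early/late stratification, the late-stage SMG scan, BH q-values
and SMG calling, the restricted-hypothesis early-stage re-test, the SMG
union across cohorts, MSI target-gene reports, and a power grid — and
writes plain TSV/JSON reports plus a machine-readable manifest with
per-stage record counts and per-file checksums.

An ``external_pvalues`` bypass lets the stage-specificity machinery run on
per-gene p-values produced by any SMG engine (e.g. MutSigCV output tables)
instead of the built-in binomial scan; the built-in scan is then skipped.

Configuration is a YAML-style mapping with sections ``io``, ``simulate``,
``filters``, ``model``, ``fdr``, ``msi`` and ``power``; every section is
optional and unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from stagesmg import __version__ as _version
from stagesmg.cohort_io import (
    Cohort,
    exclude_noncoding,
    filter_tcga_variants,
    read_clinical,
    read_maf,
    stratify,
    summarize_burden,
    write_maf,
)
from stagesmg.consensus_filter import DbsnpLookup, run_consensus_pipeline
from stagesmg.fdr_stage import (
    DEFAULT_Q_THRESHOLD,
    SmgSet,
    annotate_smgs,
    call_smgs,
    qq_points,
    restricted_retest,
    union_smgs,
)
from stagesmg.msi_spectrum import (
    detect_homopolymer,
    frequency_table,
    recurrence_table,
    subgroup_enrichment,
)
from stagesmg.smg_binomial import BackgroundModel, power_grid, smg_scan
from stagesmg.synthetic_cohort import CohortConfig, emit_dbsnp, generate

logger = logging.getLogger(__name__)

_SECTIONS = {"io", "simulate", "filters", "model", "fdr", "msi", "power"}


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and completed stages."""

    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {completed}: {cause}")
        self.stage = stage
        self.completed = completed
        self.cause = cause


@dataclass
class RunManifest:
    """What a run consumed and produced: inputs, seed, counts, checksums."""

    version: str
    seed: int | None
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, dict] = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def add_output(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[name] = {"path": path.name, "sha256": digest}

    def write(self, path: Path) -> None:
        doc = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "counts": self.counts,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)}")
    return cfg


def _resolve_cohort(
    cfg: Mapping[str, Any], seed: int | None, manifest: RunManifest
) -> tuple[Cohort, DbsnpLookup | None]:
    io_cfg = dict(cfg.get("io") or {})
    sim_cfg = dict(cfg.get("simulate") or {})
    if io_cfg.get("maf"):
        variants = read_maf(io_cfg["maf"], dialect=io_cfg.get("dialect", "generic"))
        clinical = read_clinical(io_cfg["clinical"])
        manifest.inputs["maf"] = str(io_cfg["maf"])
        manifest.inputs["clinical"] = str(io_cfg["clinical"])
        lookup = None
        if io_cfg.get("dbsnp"):
            lookup = DbsnpLookup.from_tsv(io_cfg["dbsnp"])
            manifest.inputs["dbsnp"] = str(io_cfg["dbsnp"])
        return Cohort(variants, clinical, name=Path(io_cfg["maf"]).stem), lookup
    sim_seed = seed if seed is not None else int(sim_cfg.pop("seed", 0))
    sim_cfg.pop("seed", None)
    config = CohortConfig.default(seed=sim_seed, **sim_cfg)
    cohort, truth = generate(config)
    manifest.inputs["simulated"] = f"seed={sim_seed}"
    return cohort, emit_dbsnp(truth)


def run_full(
    config: Mapping[str, Any] | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Run the whole analysis; returns the manifest (also written to disk).

    Any stage failure raises :class:`StageFailure` naming the stage and the
    stages already completed (their outputs remain on disk).
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=_version, seed=seed, config=_jsonable(cfg))
    completed: list[str] = []

    def stage(name: str):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                manifest.write(out_dir / "manifest.json")
                raise StageFailure(name, completed, exc) from exc
            completed.append(name)
            return result

        return deco

    filters_cfg = dict(cfg.get("filters") or {})
    model_cfg = dict(cfg.get("model") or {})
    fdr_cfg = dict(cfg.get("fdr") or {})
    msi_cfg = dict(cfg.get("msi") or {})
    power_cfg = dict(cfg.get("power") or {})
    q_threshold = float(fdr_cfg.get("q_threshold", DEFAULT_Q_THRESHOLD))

    @stage("ingest")
    def cohort_and_lookup():
        return _resolve_cohort(cfg, seed, manifest)

    cohort, lookup = cohort_and_lookup
    manifest.counts["ingested_variants"] = len(cohort.variants)
    manifest.counts["samples"] = cohort.n_samples

    @stage("filter")
    def filtered() -> Cohort:
        mode = filters_cfg.get("mode", "tcga")
        if mode == "tcga":
            variants = filter_tcga_variants(
                cohort.variants,
                keep_filters=frozenset(
                    filters_cfg.get("keep_filters", ("PASS", "WGA", "Native_WGA_mix"))
                ),
                snv_caller=filters_cfg.get("snv_caller", "MUTECT"),
                indel_caller=filters_cfg.get("indel_caller", "INDELOCATOR"),
            )
            variants = exclude_noncoding(variants)
        elif mode == "nhgri":
            variants, _report = run_consensus_pipeline(
                cohort.variants,
                lookup,
                min_tumor_depth=int(filters_cfg.get("min_tumor_depth", 14)),
                min_normal_depth=int(filters_cfg.get("min_normal_depth", 8)),
                max_normal_vaf=float(filters_cfg.get("max_normal_vaf", 0.03)),
                max_snp_maf=float(filters_cfg.get("max_snp_maf", 0.05)),
            )
        elif mode == "none":
            variants = exclude_noncoding(cohort.variants)
        else:
            raise ValueError(f"unknown filter mode {mode!r}")
        if lookup is not None and mode == "tcga":
            # TCGA-dialect inputs arrive pre-screened for population variants;
            # the dbSNP stage applies only to the in-house filter path.
            pass
        return cohort.with_variants(variants)

    manifest.counts["filtered_variants"] = len(filtered.variants)
    write_maf(filtered.variants, out_dir / "filtered.maf")
    manifest.add_output("filtered_maf", out_dir / "filtered.maf")

    @stage("burden")
    def burden():
        summary = summarize_burden(filtered)
        summary.to_frame().to_csv(out_dir / "burden.tsv", sep="\t", index=False)
        return summary

    manifest.counts["nonsilent_variants"] = burden.total
    manifest.add_output("burden", out_dir / "burden.tsv")

    @stage("stratify")
    def strata():
        return stratify(filtered, by="stage_class")

    external = fdr_cfg.get("external_pvalues")
    if external:
        import pandas as pd

        @stage("stage_specificity")
        def table():
            df = pd.read_csv(external, sep="\t")
            manifest.inputs["external_pvalues"] = str(external)
            early_p = dict(zip(df["gene"].astype(str), df["p"].astype(float)))
            genes = fdr_cfg.get("late_genes") or sorted(early_p)
            # Order the family by ascending early p for a readable table.
            genes = sorted(genes, key=lambda g: (early_p.get(g, 1.0), g))
            late = SmgSet(name="late", genes=tuple(genes))
            return restricted_retest(
                late, early_p, q_threshold=q_threshold,
                missing_p=fdr_cfg.get("missing_p"),
            )

        table.to_frame().to_csv(out_dir / "stage_specificity.tsv", sep="\t", index=False)
        manifest.add_output("stage_specificity", out_dir / "stage_specificity.tsv")
        manifest.counts["late_smgs"] = len(table.rows)
        manifest.counts["stage_specific"] = len(table.stage_specific_genes)
    else:

        @stage("smg_scan")
        def scans():
            mu = float(model_cfg.get("mu", 1e-6))
            model = BackgroundModel(
                mu=mu,
                f_g=float(model_cfg.get("f_g", 3.9)),
                L=float(model_cfg.get("L", 1500)),
                m=float(model_cfg.get("m", 0.1)),
                alpha=float(model_cfg.get("alpha", 0.1)),
                k=int(model_cfg.get("k", 14)),
            )
            late = strata.get("late")
            early = strata.get("early")
            if late is None or early is None or not late.variants or not early.variants:
                raise ValueError("need both early and late strata with variants")
            late_results = annotate_smgs(
                smg_scan(late, model), q_threshold=q_threshold
            )
            early_results = smg_scan(early, model)
            return model, late_results, early_results

        model, late_results, early_results = scans
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "gene": t.gene,
                    "n_mutated": t.n_mutated,
                    "n_tumors": t.n_tumors,
                    "frequency": round(t.frequency, 4),
                    "p_value": t.p_value,
                    "q_value": t.q_value,
                    "is_smg": t.is_smg,
                }
                for t in late_results
            ]
        ).to_csv(out_dir / "late_smgs.tsv", sep="\t", index=False)
        manifest.add_output("late_smgs", out_dir / "late_smgs.tsv")

        @stage("stage_specificity")
        def table():
            late_set = call_smgs(late_results, q_threshold=q_threshold, name="late")
            if not late_set.genes:
                return None
            early_p = {t.gene: t.p_value for t in early_results}
            return restricted_retest(
                late_set,
                early_p,
                q_threshold=q_threshold,
                late_q={t.gene: t.q_value for t in late_results},
                missing_p=1.0,
            )

        if table is not None:
            table.to_frame().to_csv(
                out_dir / "stage_specificity.tsv", sep="\t", index=False
            )
            manifest.add_output("stage_specificity", out_dir / "stage_specificity.tsv")
            manifest.counts["late_smgs"] = len(table.rows)
            manifest.counts["stage_specific"] = len(table.stage_specific_genes)
        else:
            manifest.counts["late_smgs"] = 0
            manifest.counts["stage_specific"] = 0

        @stage("qq")
        def qq():
            exp, obs = qq_points([t.p_value for t in early_results])
            pd.DataFrame({"expected_neglog10": exp, "observed_neglog10": obs}).to_csv(
                out_dir / "qq.tsv", sep="\t", index=False
            )

        manifest.add_output("qq", out_dir / "qq.tsv")

        @stage("union")
        def union():
            sets = [call_smgs(late_results, q_threshold=q_threshold, name="late")]
            u = union_smgs(sets)
            (out_dir / "union.json").write_text(json.dumps(u.to_dict(), indent=2))

        manifest.add_output("union", out_dir / "union.json")

    @stage("msi")
    def msi():
        genes = list(msi_cfg.get("genes", ("KLF3", "PAX6")))
        present = {v.gene for v in filtered.variants}
        genes = [g for g in genes if g in present]
        if not genes:
            return
        freq = frequency_table(filtered, genes, by=("stage_class", "subgroup"))
        freq.to_csv(out_dir / "msi_frequency.tsv", sep="\t", index=False)
        manifest.add_output("msi_frequency", out_dir / "msi_frequency.tsv")
        rec = recurrence_table(
            [v for v in filtered.variants if v.gene in genes]
        )
        rec.to_csv(out_dir / "msi_recurrence.tsv", sep="\t", index=False)
        manifest.add_output("msi_recurrence", out_dir / "msi_recurrence.tsv")
        import pandas as pd

        calls = []
        for v in filtered.variants:
            if v.gene in genes and v.variant_type in ("INS", "DEL"):
                h = detect_homopolymer(v, int(msi_cfg.get("min_tract_length", 5)))
                calls.append(
                    {
                        "gene": v.gene,
                        "sample_id": v.sample_id,
                        "protein_change": v.protein_change,
                        "tract_base": h.tract_base,
                        "tract_length": h.tract_length,
                        "in_tract": h.in_tract,
                        "uncallable": h.uncallable,
                    }
                )
        pd.DataFrame(
            calls,
            columns=[
                "gene", "sample_id", "protein_change",
                "tract_base", "tract_length", "in_tract", "uncallable",
            ],
        ).to_csv(out_dir / "msi_homopolymer.tsv", sep="\t", index=False)
        manifest.add_output("msi_homopolymer", out_dir / "msi_homopolymer.tsv")
        enrich = {}
        for g in genes:
            try:
                r = subgroup_enrichment(filtered, g)
                enrich[g] = {
                    "table": [r.a, r.b, r.c, r.d],
                    "odds_ratio": None if not np.isfinite(r.odds_ratio) else r.odds_ratio,
                    "p_two_tailed": r.p_two_tailed,
                }
            except ValueError:
                continue
        (out_dir / "msi_enrichment.json").write_text(json.dumps(enrich, indent=2))
        manifest.add_output("msi_enrichment", out_dir / "msi_enrichment.json")

    if power_cfg.get("enabled", True):

        @stage("power")
        def power():
            n = int(power_cfg.get("n", manifest.counts.get("samples", 270)))
            mu_min = float(power_cfg.get("mu_min", 1e-7))
            mu_max = float(power_cfg.get("mu_max", 1e-5))
            n_grid = int(power_cfg.get("grid", 25))
            r_values = [float(r) for r in power_cfg.get("r", (0.02, 0.05, 0.10, 0.20))]
            model = BackgroundModel(
                mu=mu_min,
                f_g=float(model_cfg.get("f_g", 3.9)),
                L=float(model_cfg.get("L", 1500)),
                m=float(model_cfg.get("m", 0.1)),
                alpha=float(model_cfg.get("alpha", 0.1)),
                k=int(model_cfg.get("k", 14)),
            )
            grid = power_grid(
                n, model, np.logspace(np.log10(mu_min), np.log10(mu_max), n_grid), r_values
            )
            grid.to_frame().to_csv(out_dir / "power.tsv", sep="\t", index=False)

        manifest.add_output("power", out_dir / "power.tsv")

    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
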