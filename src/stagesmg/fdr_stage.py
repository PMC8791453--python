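"""Benjamini-Hochberg FDR, SMG calling, and the restricted-hypothesis re-test.

The centrepiece is the restricted-hypothesis re-test that defines
*stage-specific* SMGs: genes called significant (q <= 0.10) in a late-stage
cohort are re-examined in the early-stage cohort using only the late-stage
SMG set as the hypothesis family — q-values are recomputed from the
early-stage p-values adjusting for k = |late-stage SMG set| tests rather
than for the whole exome.  A late-stage SMG whose early-stage q stays above
the threshold is classified stage-specific.

:func:`bh_adjust` implements the step-up procedure directly (sort ascending,
``raw_i = p_(i) * n_tests / i``, take running minima from the largest rank
down, cap at 1) because the restricted re-test needs ``n_tests`` larger than
the number of p-values supplied, which off-the-shelf implementations do not
support.  Zero p-values are accepted literally (q = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from stagesmg.smg_binomial import GeneTestResult

#: SMG definition: false discovery rate at or below this value.
DEFAULT_Q_THRESHOLD = 0.10


def bh_adjust(p_values: Sequence[float], n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    ``n_tests`` defaults to ``len(p_values)`` and may be larger (restricted-
    hypothesis correction); it may not be smaller.  Tied p-values share an
    identical q by construction of the running minimum.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if n_tests is None else int(n_tests)
    if m < p.size:
        raise ValueError(f"n_tests = {m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    raw = p[order] * m / ranks
    q_sorted = np.minimum(1.0, np.minimum.accumulate(raw[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def annotate_smgs(
    results: Sequence[GeneTestResult],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    n_tests: int | None = None,
) -> list[GeneTestResult]:
    """Fill ``q_value``/``is_smg`` on scan results via BH over all tested genes."""
    if not results:
        return []
    q = bh_adjust([t.p_value for t in results], n_tests=n_tests)
    for t, qv in zip(results, q):
        t.q_value = float(qv)
        t.is_smg = qv <= q_threshold
    return list(results)


@dataclass(frozen=True)
class SmgSet:
    """Named, ordered (ascending p) list of significant genes."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError(f"SmgSet {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    @property
    def as_set(self) -> frozenset[str]:
        return frozenset(self.genes)


def call_smgs(
    results: Sequence[GeneTestResult],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    name: str = "",
) -> SmgSet:
    """Select genes with q <= threshold (inclusive), sorted by ascending p.

    Results lacking q-values are annotated first with BH over the full list.
    """
    results = list(results)
    if any(t.q_value is None for t in results):
        annotate_smgs(results, q_threshold=q_threshold)
    sig = [t for t in results if t.q_value is not None and t.q_value <= q_threshold]
    sig.sort(key=lambda t: (t.p_value, t.gene))
    return SmgSet(name=name, genes=tuple(t.gene for t in sig))


@dataclass(frozen=True)
class StageSpecificityRow:
    gene: str
    early_p: float
    early_q: float
    stage_specific: bool
    late_q: float | None = None


@dataclass
class StageSpecificityTable:
    """Restricted-hypothesis re-test outcome for each late-stage SMG."""

    rows: list[StageSpecificityRow]
    n_tests: int
    q_threshold: float

    @property
    def stage_specific_genes(self) -> list[str]:
        return [r.gene for r in self.rows if r.stage_specific]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "late_q": r.late_q,
                    "early_p": r.early_p,
                    "early_q": r.early_q,
                    "stage_specific": r.stage_specific,
                }
                for r in self.rows
            ]
        )


def restricted_retest(
    late_smgs: SmgSet,
    early_p: Mapping[str, float],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    late_q: Mapping[str, float] | None = None,
    missing_p: float | None = None,
) -> StageSpecificityTable:
    """Re-test late-stage SMGs in the early-stage cohort, adjusting for k = |set|.

    ``early_p`` maps each late-stage SMG to its early-stage p-value.  Genes
    absent from the map raise unless ``missing_p`` supplies a fallback
    (``missing_p = 1.0`` encodes "never seen mutated early").  A gene is
    stage-specific when its recomputed early q exceeds the threshold.
    """
    genes = list(late_smgs.genes)
    if not genes:
        raise ValueError("restricted_retest: empty late-stage SMG set")
    missing = [g for g in genes if g not in early_p]
    if missing and missing_p is None:
        raise KeyError(
            f"no early-stage p-value for late-stage SMG(s) {missing}; "
            "pass missing_p to supply a fallback"
        )
    p = [early_p.get(g, missing_p) for g in genes]
    q = bh_adjust(p, n_tests=len(genes))
    rows = [
        StageSpecificityRow(
            gene=g,
            early_p=float(pv),
            early_q=float(qv),
            stage_specific=bool(qv > q_threshold),
            late_q=None if late_q is None else late_q.get(g),
        )
        for g, pv, qv in zip(genes, p, q)
    ]
    return StageSpecificityTable(rows=rows, n_tests=len(genes), q_threshold=q_threshold)


@dataclass(frozen=True)
class SmgUnion:
    """Union of SMG sets with the overlap counts needed for a Venn rendering."""

    genes: tuple[str, ...]  # sorted unique union
    set_sizes: Mapping[str, int]
    pairwise_overlap: Mapping[tuple[str, str], int]
    pairwise_shared: Mapping[tuple[str, str], tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "union": list(self.genes),
            "set_sizes": dict(self.set_sizes),
            "pairwise_overlap": {
                " & ".join(k): v for k, v in self.pairwise_overlap.items()
            },
            "pairwise_shared": {
                " & ".join(k): list(v) for k, v in self.pairwise_shared.items()
            },
        }


def union_smgs(sets: Sequence[SmgSet]) -> SmgUnion:
    """Sorted unique union of SMG sets plus pairwise overlap counts."""
    if not sets:
        raise ValueError("union_smgs: need at least one SMG set")
    union: set[str] = set()
    for s in sets:
        union |= s.as_set
    overlap = {}
    shared = {}
    for i, a in enumerate(sets):
        for b in sets[i + 1 :]:
            common = tuple(sorted(a.as_set & b.as_set))
            overlap[(a.name, b.name)] = len(common)
            shared[(a.name, b.name)] = common
    return SmgUnion(
        genes=tuple(sorted(union)),
        set_sizes={s.name: len(s) for s in sets},
        pairwise_overlap=overlap,
        pairwise_shared=shared,
    )


def qq_points(
    p_values: Sequence[float], floor: float = 1e-16
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform Q-Q coordinates on the -log10 scale.

    Returns ``(expected, observed)`` with observed p sorted ascending and
    expected quantiles ``(i - 0.5) / n``.  Zero p-values are clamped to
    ``floor`` with a warning so the log transform is defined.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("qq_points: empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p < floor):
        warnings.warn(f"{int((p < floor).sum())} p-value(s) clamped to floor {floor}")
        p = np.maximum(p, floor)
    observed = np.sort(p)
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    return -np.log10(expected), -np.log10(observed)
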