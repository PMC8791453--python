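"""Binomial background/signal model for significantly mutated gene detection.

Model
-----
Across ``n`` tumors, the number of tumors carrying at least one non-silent
mutation in a gene is modelled as Binomial(n, p).  Under the background
(passenger-only) hypothesis

    p0 = 1 - (1 - mu * f_g) ** ((3/4) * L)

where ``mu`` is the per-base per-tumor background mutation rate, ``f_g`` a
gene-specific rate factor, ``L`` the gene length in bases, and 3/4 the
approximate fraction of coding positions at which a mutation is non-silent.
The defaults ``f_g = 3.9`` and ``L = 1500`` are 90th-percentile constants, so
the null is conservative for the large majority of genes.  A driver mutated
in a fraction ``r`` of tumors, with mis-detection rate ``m``, has signal rate

    p1 = min(1, p0 + r * (1 - m)).

The per-gene test is the one-sided, inclusive upper-tail binomial exceedance
P(X >= x | n, p0): only an excess of mutated tumors is evidence of positive
selection.  Detection power at a per-test level alpha/k (family level alpha
split over k tests) is the probability under p1 of landing in the rejection
region of that test.

All tail sums use scipy's binomial survival function; nothing here is
Monte-Carlo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from stagesmg.cohort_io import Cohort, NONCODING_CLASSES, is_nonsilent


@dataclass(frozen=True)
class BackgroundModel:
    """Parameters of the binomial background/signal model.

    mu
        Background mutation rate per base per tumor.
    f_g
        Gene-specific mutation rate factor (default: 90th-percentile 3.9).
    L
        Gene length in bases (default: 90th-percentile 1500).
    m
        Mis-detection rate: probability a true driver mutation is missed.
    alpha, k
        Family significance level and number of tests; the per-test level is
        ``alpha / k``.
    """

    mu: float
    f_g: float = 3.9
    L: float = 1500.0
    m: float = 0.1
    alpha: float = 0.1
    k: int = 14

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu * self.f_g <= 1.0:
            raise ValueError(f"mu*f_g = {self.mu * self.f_g} outside [0, 1]")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m = {self.m} outside [0, 1]")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha = {self.alpha} outside (0, 1]")
        if self.k < 1:
            raise ValueError(f"k = {self.k} must be >= 1")
        if self.L <= 0:
            raise ValueError(f"L = {self.L} must be positive")

    @property
    def per_test_level(self) -> float:
        return self.alpha / self.k


def background_rate(model: BackgroundModel) -> float:
    """Per-tumor probability of >= 1 background non-silent mutation in a gene.

    Computed in log space (``-expm1(0.75 L log1p(-mu f_g))``) so that tiny
    rates do not underflow.
    """
    mf = model.mu * model.f_g
    if mf >= 1.0:
        return 1.0
    return -math.expm1(0.75 * model.L * math.log1p(-mf))


def signal_rate(p0: float, r: float, m: float) -> float:
    """Per-tumor mutation probability for a driver: p0 + r(1-m), capped at 1."""
    for name, v in (("p0", p0), ("r", r), ("m", m)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    return min(1.0, p0 + r * (1.0 - m))


def gene_pvalue(x: int, n: int, p0: float) -> float:
    """One-sided inclusive upper-tail binomial exceedance P(X >= x | n, p0)."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 = {p0} outside [0, 1]")
    if not 0 <= x <= n:
        raise ValueError(f"x = {x} outside [0, {n}]")
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, p0))


def detect_power(n: int, model: BackgroundModel, r: float) -> float:
    """Probability the test rejects at level alpha/k when the gene is a driver.

    The rejection region is {x : P(X >= x | n, p0) <= alpha/k}; power is its
    probability under Binomial(n, p1).
    """
    if n < 1:
        raise ValueError(f"n = {n} must be >= 1")
    p0 = background_rate(model)
    p1 = signal_rate(p0, r, model.m)
    x = np.arange(n + 1)
    pvals = stats.binom.sf(x - 1, n, p0)
    pvals[0] = 1.0
    reject = pvals <= model.per_test_level
    if not reject.any():
        return 0.0
    return float(stats.binom.pmf(x[reject], n, p1).sum())


@dataclass(frozen=True)
class PowerGrid:
    """Detection power over a (mu, r) grid at fixed n and model constants."""

    n: int
    model: BackgroundModel
    mu_values: tuple[float, ...]
    r_values: tuple[float, ...]
    power: np.ndarray  # shape (len(mu_values), len(r_values))

    def min(self) -> float:
        return float(self.power.min())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mu": mu, "r": r, "power": float(self.power[i, j])}
            for i, mu in enumerate(self.mu_values)
            for j, r in enumerate(self.r_values)
        ]
        return pd.DataFrame(rows)

    def plot(self, path=None):
        """Power-vs-mu curves, one per r (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        for j, r in enumerate(self.r_values):
            ax.semilogx(self.mu_values, self.power[:, j], label=f"r = {r:g}")
        ax.set_xlabel("background mutation rate mu")
        ax.set_ylabel("detection power")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        ax.set_title(f"n = {self.n}, per-test level {self.model.per_test_level:.4g}")
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def power_grid(
    n: int,
    model: BackgroundModel,
    mu_values: Sequence[float],
    r_values: Sequence[float],
) -> PowerGrid:
    """Evaluate :func:`detect_power` over the cartesian (mu, r) grid."""
    if len(mu_values) == 0 or len(r_values) == 0:
        raise ValueError("mu_values and r_values must be non-empty")
    power = np.empty((len(mu_values), len(r_values)))
    for i, mu in enumerate(mu_values):
        m = replace(model, mu=mu)
        for j, r in enumerate(r_values):
            power[i, j] = detect_power(n, m, r)
    return PowerGrid(
        n=n,
        model=model,
        mu_values=tuple(float(v) for v in mu_values),
        r_values=tuple(float(v) for v in r_values),
        power=power,
    )


@dataclass
class GeneTestResult:
    """Per-gene mutated-tumor count and significance.

    ``q_value``/``is_smg`` are filled by the FDR stage, not by the scan.
    """

    gene: str
    n_tumors: int
    n_mutated: int
    p_value: float
    q_value: float | None = None
    is_smg: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_mutated <= self.n_tumors:
            raise ValueError(
                f"{self.gene}: n_mutated {self.n_mutated} outside [0, {self.n_tumors}]"
            )

    @property
    def frequency(self) -> float:
        return self.n_mutated / self.n_tumors


def mutated_sample_counts(cohort: Cohort) -> dict[str, int]:
    """Distinct samples with >= 1 non-silent variant, per gene.

    Multiple hits in one gene in one sample count once.  Noncoding calls are
    a contract violation (filter first); Silent calls are ignored.
    """
    seen: dict[str, set[str]] = {}
    for v in cohort.variants:
        if v.variant_classification in NONCODING_CLASSES:
            raise ValueError(
                f"noncoding variant ({v.variant_classification}) in scan input; "
                "apply exclude_noncoding first"
            )
        if is_nonsilent(v):
            seen.setdefault(v.gene, set()).add(v.sample_id)
    return {g: len(s) for g, s in seen.items()}


def smg_scan(
    cohort: Cohort,
    model: BackgroundModel,
    gene_params: Mapping[str, tuple[float, float]] | None = None,
) -> list[GeneTestResult]:
    """Test every mutated gene for mutation excess over the background model.

    ``gene_params`` optionally overrides ``(f_g, L)`` per gene — e.g. from a
    gene-level background TSV — falling back to the model constants.  Results
    are sorted by ascending p-value (stable by gene symbol); q-values are left
    for the FDR stage.
    """
    if cohort.n_samples == 0:
        raise ValueError("smg_scan: cohort has no samples")
    counts = mutated_sample_counts(cohort)
    if not counts:
        raise ValueError("smg_scan: cohort has no non-silent variants")
    n = cohort.n_samples
    p0_default = background_rate(model)
    results = []
    for gene in sorted(counts):
        if gene_params is not None and gene in gene_params:
            f_g, L = gene_params[gene]
            p0 = background_rate(replace(model, f_g=f_g, L=L))
        else:
            p0 = p0_default
        x = counts[gene]
        results.append(
            GeneTestResult(gene=gene, n_tumors=n, n_mutated=x, p_value=gene_pvalue(x, n, p0))
        )
    results.sort(key=lambda t: (t.p_value, t.gene))
    return results


def load_gene_params(path) -> dict[str, tuple[float, float]]:
    """Read per-gene (f_g, L) overrides from a TSV with columns gene, f_g, L."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "f_g", "L"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene-parameter table missing {sorted(missing)}")
    return {str(r.gene): (float(r.f_g), float(r.L)) for r in df.itertuples(index=False)}
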