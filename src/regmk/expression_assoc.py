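"""Allele-specific expression of gametologs and its association with
cis-regulatory divergence.

Allele-specific expression (ASE) for a gametolog pair is
log2(mean X-allele count / mean Y-allele count) over replicates; counts
are compared only within a gene between alleles, so no cross-library
normalization is applied.  The association between ASE and the divergence
of nearby ACRs is measured with Spearman's rank correlation, with a
percentile bootstrap confidence interval over genes, a Fisher
Z-transformation test for comparing two correlations, and a randomized
down-sampling test that asks how often a smaller cohort would still
detect the association.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .selection_tests import SelectionClass


@dataclass
class ExpressionRecord:
    gene_id: str
    x_counts: tuple[float, ...]
    y_counts: tuple[float, ...]
    tissue: str = ""

    def __post_init__(self) -> None:
        if len(self.x_counts) != len(self.y_counts):
            raise ValueError(f"gene {self.gene_id}: unequal replicate counts per allele")

    @property
    def mean_x(self) -> float:
        return float(np.mean(self.x_counts))

    @property
    def mean_y(self) -> float:
        return float(np.mean(self.y_counts))

    @property
    def log2_ratio(self) -> float:
        return float(np.log2(self.mean_x / self.mean_y))


def ase_log2(
    counts: pd.DataFrame, tissue: str = "", pseudocount: float = 0.0
) -> tuple[list[ExpressionRecord], dict[str, list[str]]]:
    """Build ASE records from a long count table (gene, allele, replicate,
    count).

    Transcripts with a count of 0 in every sample are removed.  Genes
    where one allele has a zero mean have an infinite log ratio; by
    default they are excluded from ratio analyses and reported under
    ``dropped["zero_allele_mean"]``.  Passing ``pseudocount > 0`` (e.g.
    0.5) instead adds it to both allele means and retains those genes.
    """
    required = {"gene", "allele", "replicate", "count"}
    if not required <= set(counts.columns):
        raise ValueError(f"count table must have columns {sorted(required)}")
    records: list[ExpressionRecord] = []
    dropped: dict[str, list[str]] = {"all_zero": [], "zero_allele_mean": []}
    for gene, sub in counts.groupby("gene", sort=True):
        x = sub.loc[sub["allele"].str.upper() == "X"].sort_values("replicate")["count"].to_numpy(float)
        y = sub.loc[sub["allele"].str.upper() == "Y"].sort_values("replicate")["count"].to_numpy(float)
        if len(x) != len(y):
            raise ValueError(f"gene {gene}: unequal replicate counts per allele")
        if np.all(x == 0) and np.all(y == 0):
            dropped["all_zero"].append(str(gene))
            continue
        mean_x, mean_y = x.mean(), y.mean()
        if pseudocount > 0:
            x = x + pseudocount
            y = y + pseudocount
        elif mean_x == 0 or mean_y == 0:
            dropped["zero_allele_mean"].append(str(gene))
            continue
        records.append(ExpressionRecord(str(gene), tuple(x), tuple(y), tissue))
    return records, dropped


# ---------------------------------------------------------------------------
# Spearman correlation with bootstrap CI


@dataclass
class AssociationResult:
    n: int
    rho: float
    p: float
    ci_low: float
    ci_high: float
    n_boot: int


def _spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho for matched 2-D arrays (resamples x genes)."""
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def spearman_with_bootstrap(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> AssociationResult:
    """Spearman rho with two-sided p and a percentile 95% bootstrap CI.

    Bootstrap resamples gene pairs with replacement; replicates where
    either variable is constant are dropped from the percentile interval.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("paired samples required")
    if xa.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("correlation undefined for a constant variable")
    rho, p = stats.spearmanr(xa, ya)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, xa.size, size=(n_boot, xa.size))
    boots = _spearman_rows(xa[idx], ya[idx])
    boots = boots[np.isfinite(boots)]
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return AssociationResult(
        n=int(xa.size), rho=float(rho), p=float(p),
        ci_low=float(ci_low), ci_high=float(ci_high), n_boot=n_boot,
    )


def compare_correlations_fisher_z(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Compare two independent correlations via the Fisher Z-transformation.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), with a
    two-sided normal p-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both sample sizes must exceed 3")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


def downsample_significance(
    x: Sequence[float],
    y: Sequence[float],
    target_n: int,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Fraction of random subsamples of size ``target_n`` whose Spearman
    correlation stays significant at ``alpha``.

    Each permutation samples ``target_n`` pairs without replacement (a
    subsample, not a bootstrap); p-values use the t approximation for
    Spearman's rho.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if target_n < 4:
        raise ValueError("target_n must be at least 4")
    if target_n >= xa.size:
        raise ValueError("target_n must be smaller than the sample size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.empty((n_perm, target_n), dtype=int)
    for row in range(n_perm):
        idx[row] = rng.choice(xa.size, size=target_n, replace=False)
    rho = _spearman_rows(xa[idx], ya[idx])
    rho = np.clip(rho, -1 + 1e-12, 1 - 1e-12)
    t = rho * np.sqrt((target_n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), df=target_n - 2)
    return float(np.mean(p < alpha))


# ---------------------------------------------------------------------------
# Selection-class contrasts


@dataclass
class ClassContrast:
    correlations: dict[SelectionClass, AssociationResult | None]
    skipped: list[SelectionClass]
    rank_sum: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    n_omitted_dnds: int = 0


def class_contrast(
    per_gene: pd.DataFrame,
    groups: Mapping[str, Sequence[float]] | None = None,
    dnds_sentinel: float = 99.0,
    n_boot: int = 1_000,
    seed: int | np.random.Generator | None = None,
) -> ClassContrast:
    """Per-selection-class Spearman of ACR divergence against dN/dS, plus
    rank-sum contrasts between mutation-status groups.

    ``per_gene`` needs columns ``selection_class``, ``acr_divergence`` and
    ``dnds``; dN/dS entries equal to the sentinel (99, marking alignments
    too conserved to estimate a rate) are omitted before analysis.
    Classes with fewer than 4 genes are skipped with a warning.  ``groups``
    optionally maps mutation-status labels (e.g. "frameshift", "intact")
    to per-gene ACR substitution counts; all pairs are compared with
    two-sided Mann-Whitney U tests.
    """
    import warnings

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    usable = per_gene[per_gene["dnds"] != dnds_sentinel]
    n_omitted = int(len(per_gene) - len(usable))
    correlations: dict[SelectionClass, AssociationResult | None] = {}
    skipped: list[SelectionClass] = []
    for cls in SelectionClass:
        sub = usable[usable["selection_class"] == cls.value]
        if len(sub) < 4:
            correlations[cls] = None
            skipped.append(cls)
            warnings.warn(f"selection class {cls.value!r} has < 4 genes; correlation skipped")
            continue
        correlations[cls] = spearman_with_bootstrap(
            sub["acr_divergence"].to_numpy(), sub["dnds"].to_numpy(),
            n_boot=n_boot, seed=rng,
        )
    rank_sum: dict[tuple[str, str], tuple[float, float]] = {}
    if groups:
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ga = np.asarray(groups[a], dtype=float)
                gb = np.asarray(groups[b], dtype=float)
                stat, p = stats.mannwhitneyu(ga, gb, alternative="two-sided")
                rank_sum[(a, b)] = (float(stat), float(p))
    return ClassContrast(
        correlations=correlations, skipped=skipped,
        rank_sum=rank_sum, n_omitted_dnds=n_omitted,
    )
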