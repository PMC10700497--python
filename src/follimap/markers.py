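"""Group-vs-rest differential expression and thresholded marker-set construction.

Two tests are offered per gene: a Wilcoxon rank-sum test (normal
approximation with tie and continuity corrections, exact enumeration of rank
assignments when both groups have at most 8 observations) and a two-sided
t test (Welch by default; the unequal group sizes and variances of a
cluster-vs-rest design make pooled variance a poor default, though it is
available).  "Statistically higher expression" is implemented as a two-sided
p-value combined with a positive average log fold change filter.

Average log fold change is the difference of mean log-normalized expression
(natural log) between the group and the rest.  Benjamini-Hochberg adjustment
is the standard step-up procedure.  Gene sets for the intersection analysis
are built by thresholding: genes with positive logFC and p strictly below
the cutoff (raw p by default; adjusted on request).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionMatrix

__all__ = [
    "DEResult",
    "GeneSet",
    "GeneSetCollection",
    "wilcoxon_group_vs_rest",
    "ttest_group_vs_rest",
    "avg_log_fc",
    "bh_adjust",
    "build_gene_sets",
    "exact_rank_sum_p",
]

EXACT_MAX_GROUP = 8
# p-values are floored at this bound so log10 thresholds (e.g. 1e-20) stay decidable
P_FLOOR = 1e-300


@dataclass
class DEResult:
    """Per-gene differential-expression summary for one group vs the rest."""

    table: pd.DataFrame  # indexed by gene_id
    group: str
    test: str
    note: str = ""

    def significant(self, p_max: float, adjusted: bool = False, logfc_min: float = 0.0) -> list[str]:
        col = "p_adjusted" if adjusted else "p_value"
        t = self.table
        mask = (t[col] < p_max) & (t["avg_log_fc"] > logfc_min)
        return t.index[mask].tolist()


def _split(expr: ExpressionMatrix, labels: pd.Series, group: str) -> tuple[np.ndarray, np.ndarray]:
    lab = labels.reindex(expr.obs_ids)
    if lab.isna().any():
        missing = lab.index[lab.isna()][:5].tolist()
        raise ValueError(f"labels missing for observations: {missing}")
    in_group = (lab == group).to_numpy()
    if in_group.sum() == 0:
        raise ValueError(f"group {group!r} absent from labels")
    if in_group.sum() < 2 or (~in_group).sum() < 2:
        raise ValueError("both the group and the rest need at least 2 observations")
    dense = expr.dense()  # genes x obs
    return dense[:, in_group], dense[:, ~in_group]


def _base_table(
    expr: ExpressionMatrix, x: np.ndarray, y: np.ndarray, stat: np.ndarray, p: np.ndarray
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_mean": x.mean(axis=1),
            "rest_mean": y.mean(axis=1),
            "avg_log_fc": x.mean(axis=1) - y.mean(axis=1),
            "statistic": stat,
            "p_value": np.clip(p, P_FLOOR, 1.0),
            "pct_in_group": (x > 0).mean(axis=1),
            "pct_in_rest": (y > 0).mean(axis=1),
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    ).assign(p_adjusted=lambda t: bh_adjust(t["p_value"].to_numpy()))


def exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments.

    Midranks handle ties, so this is the exact permutation distribution of the
    rank-sum statistic; the two-sided p doubles the smaller tail (capped at 1).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    sums = np.array([sum(ranks[list(c)]) for c in combinations(range(n), n1)])
    eps = 1e-9
    lo = np.mean(sums <= w_obs + eps)
    hi = np.mean(sums >= w_obs - eps)
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_group_vs_rest(
    expr: ExpressionMatrix, labels: pd.Series, group: str
) -> DEResult:
    """Wilcoxon rank-sum test per gene, group vs all other observations."""
    x, y = _split(expr, labels, group)
    n1, n2 = x.shape[1], y.shape[1]
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        p = np.array([exact_rank_sum_p(x[g], y[g]) for g in range(x.shape[0])])
        # report the rank-sum statistic alongside the exact p
        stat = np.array(
            [stats.rankdata(np.concatenate([x[g], y[g]]))[:n1].sum() for g in range(x.shape[0])]
        )
        note = "exact enumeration"
    else:
        res = stats.mannwhitneyu(
            x, y, axis=1, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        stat, p = res.statistic, res.pvalue
        # fully tied genes yield zero variance -> no evidence either way
        tied = x.std(axis=1) + y.std(axis=1) == 0
        tied &= x.mean(axis=1) == y.mean(axis=1)
        p = np.where(tied, 1.0, p)
        note = "normal approximation, tie and continuity corrected"
    table = _base_table(expr, x, y, stat, p)
    return DEResult(table, group=group, test="wilcoxon", note=note)


def ttest_group_vs_rest(
    expr: ExpressionMatrix, labels: pd.Series, group: str, equal_var: bool = False
) -> DEResult:
    """Two-sided t test per gene (Welch by default), group vs rest."""
    x, y = _split(expr, labels, group)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    zero_var = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    equal_means = x.mean(axis=1) == y.mean(axis=1)
    degenerate = zero_var & equal_means
    # zero variance with equal means: no signal by convention
    stat = np.where(degenerate, 0.0, stat)
    p = np.where(degenerate, 1.0, p)
    # zero variance, different means: unbounded evidence, report the floor
    p = np.where(zero_var & ~equal_means, P_FLOOR, p)
    stat = np.nan_to_num(stat, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = np.nan_to_num(p, nan=1.0)
    table = _base_table(expr, x, y, stat, p)
    note = ("pooled" if equal_var else "welch") + (
        "; degenerate zero-variance genes flagged p=1" if degenerate.any() else ""
    )
    return DEResult(table, group=group, test="ttest", note=note)


def avg_log_fc(expr: ExpressionMatrix, labels: pd.Series, group: str) -> pd.Series:
    """Mean log-expression difference, group minus rest (natural log scale)."""
    x, y = _split(expr, labels, group)
    return pd.Series(
        x.mean(axis=1) - y.mean(axis=1), index=pd.Index(expr.gene_ids, name="gene_id")
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    modality: str  # "scRNA" | "ST"
    test: str
    threshold: float
    adjusted: bool
    logfc_min: float


@dataclass
class GeneSetCollection:
    """Named gene sets plus the tested gene universe they were drawn from."""

    sets: dict[str, GeneSet]
    universe: list[str]

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def as_dict(self) -> dict[str, list[str]]:
        return {name: gs.genes for name, gs in self.sets.items()}

    def sizes(self) -> dict[str, int]:
        return {name: len(gs.genes) for name, gs in self.sets.items()}


def build_gene_sets(
    expr: ExpressionMatrix,
    labels: pd.Series,
    test: str = "ttest",
    p_threshold: float = 1e-20,
    adjust: bool = False,
    logfc_min: float | None = None,
    modality: str = "scRNA",
    allow_empty: bool = False,
) -> GeneSetCollection:
    """One gene set per label level: positive-logFC genes with p below threshold.

    The direction filter implements "higher expression in the group": only
    genes whose mean log expression exceeds the rest-mean enter the set.
    """
    if test not in ("ttest", "wilcoxon"):
        raise ValueError("test must be 'ttest' or 'wilcoxon'")
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive; no gene can pass p < 0")
    runner = ttest_group_vs_rest if test == "ttest" else wilcoxon_group_vs_rest
    fc_min = 0.0 if logfc_min is None else logfc_min
    sets: dict[str, GeneSet] = {}
    for level in pd.unique(labels.reindex(expr.obs_ids).dropna()):
        res = runner(expr, labels, level)
        genes = res.significant(p_threshold, adjusted=adjust, logfc_min=fc_min)
        sets[str(level)] = GeneSet(
            name=str(level),
            genes=genes,
            modality=modality,
            test=test,
            threshold=p_threshold,
            adjusted=adjust,
            logfc_min=fc_min,
        )
    if not allow_empty and all(len(gs.genes) == 0 for gs in sets.values()):
        raise ValueError(
            "every gene set is empty at the requested threshold; relax it or "
            "pass allow_empty=True"
        )
    return GeneSetCollection(sets, universe=list(expr.gene_ids))
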