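"""Multimodal intersection analysis (MIA).

Each (cell-type set, region set) pair is scored by the hypergeometric
upper-tail probability of their overlap against a common gene background:
with N background genes, m in the cell-type set, n in the region set and k
shared, the enrichment p is P(X >= k) for X ~ Hypergeometric(N, m, n).
Enrichment is reported as -log10(P) and depletion as -log10(1 - P), with the
complement 1 - P obtained by direct lower-tail summation P(X <= k-1) in log
space -- computing it as 1 minus the upper tail would underflow exactly where
depletion is strongest.

The background defaults to the intersection of the two post-QC gene
universes, because the hypergeometric draw is only well-defined when both
sets are subsets of the background; genes in a set but outside the
background are dropped from that set (and counted), never added to the
background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .markers import GeneSetCollection

__all__ = [
    "MIARecord",
    "MIAMap",
    "hypergeom_upper_tail",
    "mia_pair",
    "mia_map",
]

LN10 = np.log(10.0)
DEFAULT_SCORE_CAP = 300.0


def _validate_kmnN(k: int, m: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("m", m), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if m > N or n > N:
        raise ValueError(f"set sizes m={m}, n={n} cannot exceed background N={N}")
    if k > min(m, n):
        raise ValueError(f"overlap k={k} cannot exceed min(m, n)={min(m, n)}")


def hypergeom_upper_tail(k: int, m: int, n: int, N: int) -> float:
    """P(X >= k), X ~ Hypergeometric(N, m, n) (inclusive upper tail)."""
    _validate_kmnN(k, m, n, N)
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, m, n)))


def _log10_tails(k: int, m: int, n: int, N: int) -> tuple[float, float, float]:
    """(p_enrich, log10 upper tail, log10 lower tail), tails computed separately.

    m and n are interchangeable for the hypergeometric; they are passed in
    canonical order so the computation is bitwise symmetric in the two sets.
    """
    m, n = min(m, n), max(m, n)
    log_upper = stats.hypergeom.logsf(k - 1, N, m, n)  # P(X >= k)
    log_lower = stats.hypergeom.logcdf(k - 1, N, m, n)  # P(X <= k-1), direct sum
    return float(np.exp(log_upper)), log_upper / LN10, log_lower / LN10


@dataclass
class MIARecord:
    """One cell of the MIA map."""

    set_a: str
    set_b: str
    k: int
    m: int
    n: int
    N: int
    p_enrich: float
    enrichment_score: float
    depletion_score: float
    overlap_genes: list[str]
    n_dropped_outside_background: int = 0


def mia_pair(
    set_a: Iterable[str],
    set_b: Iterable[str],
    background: Sequence[str],
    name_a: str = "A",
    name_b: str = "B",
    score_cap: float = DEFAULT_SCORE_CAP,
) -> MIARecord:
    """Hypergeometric enrichment/depletion of the overlap of two gene sets."""
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    a_all, b_all = set(set_a), set(set_b)
    a, b = a_all & bg, b_all & bg
    n_dropped = len(a_all - bg) + len(b_all - bg)
    k, m, n, N = len(a & b), len(a), len(b), len(bg)
    p_enrich, log10_upper, log10_lower = _log10_tails(k, m, n, N)
    enrichment = min(score_cap, max(0.0, -log10_upper))
    # at k=0 the lower tail P(X <= -1) is exactly 0 and -log10 diverges; the cap applies
    with np.errstate(invalid="ignore"):
        depletion = min(score_cap, max(0.0, -log10_lower))
    return MIARecord(
        set_a=name_a,
        set_b=name_b,
        k=k,
        m=m,
        n=n,
        N=N,
        p_enrich=p_enrich,
        enrichment_score=enrichment,
        depletion_score=depletion,
        overlap_genes=sorted(a & b),
        n_dropped_outside_background=n_dropped,
    )


@dataclass
class MIAMap:
    """Long-format MIA results with pivot helpers (rows: set A, columns: set B)."""

    records: list[MIARecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "type": r.set_a,
                    "region": r.set_b,
                    "k": r.k,
                    "m": r.m,
                    "n": r.n,
                    "N": r.N,
                    "p": r.p_enrich,
                    "enrichment": r.enrichment_score,
                    "depletion": r.depletion_score,
                }
                for r in self.records
            ]
        )

    def scores(self, kind: str = "enrichment") -> pd.DataFrame:
        df = self.to_frame()
        return df.pivot(index="type", columns="region", values=kind)

    def set_sizes(self) -> tuple[dict[str, int], dict[str, int]]:
        """(row set sizes, column set sizes) after background restriction."""
        rows = {r.set_a: r.m for r in self.records}
        cols = {r.set_b: r.n for r in self.records}
        return rows, cols

    def top_match(self, set_a: str) -> str:
        """Column with the row-maximum enrichment score for ``set_a``."""
        row = self.scores("enrichment").loc[set_a]
        return str(row.idxmax())


def resolve_background(
    sets_a: GeneSetCollection,
    sets_b: GeneSetCollection,
    mode: str = "intersection",
    custom: Sequence[str] | None = None,
) -> list[str]:
    if mode == "custom":
        if not custom:
            raise ValueError("custom background mode requires a gene list")
        return sorted(set(custom))
    ua, ub = set(sets_a.universe), set(sets_b.universe)
    if mode == "intersection":
        return sorted(ua & ub)
    if mode == "union":
        return sorted(ua | ub)
    raise ValueError(f"unknown background mode {mode!r}")


def mia_map(
    cell_type_sets: GeneSetCollection,
    region_sets: GeneSetCollection,
    background_mode: str = "intersection",
    custom_background: Sequence[str] | None = None,
    score_cap: float = DEFAULT_SCORE_CAP,
) -> MIAMap:
    """Full (cell type x region) MIA map over a shared gene background."""
    if not cell_type_sets.sets or not region_sets.sets:
        raise ValueError("both gene set collections must be non-empty")
    background = resolve_background(
        cell_type_sets, region_sets, background_mode, custom_background
    )
    if not background:
        raise ValueError("resolved background is empty; universes do not overlap")
    records = []
    for name_a in cell_type_sets.names():
        for name_b in region_sets.names():
            records.append(
                mia_pair(
                    cell_type_sets[name_a].genes,
                    region_sets[name_b].genes,
                    background,
                    name_a=name_a,
                    name_b=name_b,
                    score_cap=score_cap,
                )
            )
    return MIAMap(records)
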