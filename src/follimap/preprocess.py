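"""Quality control and normalization of cell and spot count matrices.

Cell filters follow the printed thresholds with strict inequalities: a cell
is dropped when its mitochondrial count fraction exceeds 10%, its UMI total
falls below 200 or exceeds 10,000, or its hemoglobin fraction exceeds the
configured cutoff (the hemoglobin rule is stated only qualitatively in the
source protocol; the 1% default is this package's documented choice).  Genes
expressed in fewer than three cells are removed.  Doublet removal is a
rank-threshold: per sample (time point), the top expected-rate fraction of
cells by doublet score is excluded, with ties broken by barcode order.

Spot filters drop low-UMI / low-gene-count spots, remove mitochondrial and
ribosomal genes, and can exclude spots by annotation label (the stand-in for
morphology-based exclusion of non-tissue areas).

Normalization: value(g, o) = ln(1 + count(g, o) / total(o) * S), where S is
the median spot total for spatial data and 10,000 for cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, ObservationTable

__all__ = [
    "QCParams",
    "QCReport",
    "ExpressionMatrix",
    "qc_cells",
    "qc_genes",
    "qc_doublets",
    "qc_spots",
    "lognormalize",
    "EmptyOutputError",
]

CELL_RULE_ORDER = ("mito", "umi_min", "umi_max", "hb")
SPOT_RULE_ORDER = ("excluded_label", "spot_umi", "spot_genes")


class EmptyOutputError(RuntimeError):
    """A filter removed every observation; parameters likely need review."""


@dataclass(frozen=True)
class QCParams:
    mito_max: float = 0.10
    umi_min: int = 200
    umi_max: int = 10_000
    hb_max: float = 0.01
    min_cells_per_gene: int = 3
    expected_doublet_rate: float = 0.06
    spot_umi_min: int = 250
    spot_gene_min: int = 100
    drop_mito_ribo_genes_in_spots: bool = True
    exclude_spot_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.umi_min >= self.umi_max:
            raise ValueError("umi_min must be below umi_max")
        for name in ("mito_max", "hb_max", "expected_doublet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-rule accounting of dropped observations (or genes).

    Each barcode is attributed to the first rule, in ``rule_order``, that
    removes it, so the per-rule counters always sum to ``n_in - n_out``.
    """

    n_in: int
    rule_order: tuple[str, ...]
    dropped: dict[str, list[str]] = field(default_factory=dict)
    kept: list[str] = field(default_factory=list)

    @property
    def n_out(self) -> int:
        return len(self.kept)

    @property
    def n_dropped_by_rule(self) -> dict[str, int]:
        return {r: len(self.dropped.get(r, [])) for r in self.rule_order}

    def check_conservation(self) -> bool:
        return self.n_in - sum(len(v) for v in self.dropped.values()) == self.n_out

    def summary(self) -> pd.DataFrame:
        rows = [{"rule": r, "n_dropped": len(self.dropped.get(r, []))} for r in self.rule_order]
        rows.append({"rule": "kept", "n_dropped": self.n_out})
        return pd.DataFrame(rows)


def _fractions(m: CountMatrix, genes: Sequence[str]) -> np.ndarray:
    totals = m.obs_totals().astype(float)
    idx = m.gene_index(genes)
    if idx.size == 0:
        return np.zeros(m.n_obs)
    part = np.asarray(m.counts[idx].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, part / totals, 0.0)
    return frac


def qc_cells(
    m: CountMatrix,
    obs: ObservationTable,
    p: QCParams,
    mito_genes: Sequence[str],
    hb_genes: Sequence[str],
) -> tuple[CountMatrix, QCReport]:
    """Drop low-quality cells; all thresholds strict, boundary values survive."""
    if set(mito_genes) & set(hb_genes):
        raise ValueError("mitochondrial and hemoglobin gene lists must be disjoint")
    if m.obs_kind != "cell":
        raise ValueError("qc_cells expects a cell matrix")
    totals = m.obs_totals()
    mito = _fractions(m, mito_genes)
    hb = _fractions(m, hb_genes)
    report = QCReport(n_in=m.n_obs, rule_order=CELL_RULE_ORDER)
    rules = {
        "mito": mito > p.mito_max,
        "umi_min": totals < p.umi_min,
        "umi_max": totals > p.umi_max,
        "hb": hb > p.hb_max,
    }
    assigned = np.zeros(m.n_obs, dtype=bool)
    for rule in CELL_RULE_ORDER:
        hit = rules[rule] & ~assigned
        report.dropped[rule] = [m.obs_ids[i] for i in np.flatnonzero(hit)]
        assigned |= rules[rule]
    report.kept = [m.obs_ids[i] for i in np.flatnonzero(~assigned)]
    if not report.kept:
        raise EmptyOutputError("all cells removed by QC; review thresholds")
    return m.subset_obs(report.kept), report


def qc_genes(m: CountMatrix, p: QCParams) -> tuple[CountMatrix, QCReport]:
    """Keep genes detected (nonzero) in at least ``min_cells_per_gene`` observations."""
    n_cells_expressing = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    keep = n_cells_expressing >= p.min_cells_per_gene
    report = QCReport(n_in=m.n_genes, rule_order=("min_cells",))
    report.dropped["min_cells"] = [g for g, k in zip(m.gene_ids, keep) if not k]
    report.kept = [g for g, k in zip(m.gene_ids, keep) if k]
    if not report.kept:
        raise EmptyOutputError("all genes removed by QC; review min_cells_per_gene")
    return m.subset_genes(keep), report


def qc_doublets(obs: ObservationTable, p: QCParams) -> tuple[list[str], QCReport]:
    """Remove the top expected-rate fraction of cells by doublet score, per sample.

    Samples are time points when a ``time_point`` column is present, the whole
    table otherwise.  The removed count per sample is round(rate * n); ties in
    score are broken by barcode lexicographic order so the cut is deterministic.
    """
    if "doublet_score" not in obs.table.columns or obs.table["doublet_score"].isna().any():
        raise ValueError(
            "doublet removal needs a complete doublet_score column; supply scores "
            "from the simulation truth or an external scoring tool"
        )
    df = obs.table
    groups = (
        df.groupby("time_point", sort=False)
        if "time_point" in df.columns
        else [("all", df)]
    )
    removed: list[str] = []
    for _, sub in groups:
        k = int(np.floor(p.expected_doublet_rate * len(sub) + 0.5))
        if k == 0:
            continue
        ranked = sub.sort_values(
            ["doublet_score", "obs_id"], ascending=[False, True], kind="stable"
        )
        removed.extend(ranked["obs_id"].head(k).tolist())
    removed_set = set(removed)
    report = QCReport(n_in=len(df), rule_order=("doublet",))
    report.dropped["doublet"] = sorted(removed)
    report.kept = [o for o in df["obs_id"] if o not in removed_set]
    if not report.kept:
        raise EmptyOutputError("all cells removed as doublets; review expected rate")
    return report.kept, report


def qc_spots(
    m: CountMatrix,
    obs: ObservationTable,
    p: QCParams,
    mito_genes: Sequence[str],
    ribo_genes: Sequence[str],
) -> tuple[CountMatrix, QCReport]:
    """Filter spots, then strip mitochondrial/ribosomal genes.

    Label exclusion (the morphology stand-in) runs before the UMI and gene
    count rules; attribution follows that order.
    """
    if m.obs_kind != "spot":
        raise ValueError("qc_spots expects a spot matrix")
    totals = m.obs_totals()
    n_genes = m.obs_n_genes()
    labels = (
        obs.column("group_label").reindex(m.obs_ids)
        if "group_label" in obs.table.columns
        else pd.Series("", index=m.obs_ids)
    )
    report = QCReport(n_in=m.n_obs, rule_order=SPOT_RULE_ORDER)
    rules = {
        "excluded_label": labels.isin(p.exclude_spot_labels).to_numpy(),
        "spot_umi": totals < p.spot_umi_min,
        "spot_genes": n_genes < p.spot_gene_min,
    }
    assigned = np.zeros(m.n_obs, dtype=bool)
    for rule in SPOT_RULE_ORDER:
        hit = rules[rule] & ~assigned
        report.dropped[rule] = [m.obs_ids[i] for i in np.flatnonzero(hit)]
        assigned |= rules[rule]
    report.kept = [m.obs_ids[i] for i in np.flatnonzero(~assigned)]
    if not report.kept:
        raise EmptyOutputError("all spots removed by QC; review thresholds")
    out = m.subset_obs(report.kept)
    if p.drop_mito_ribo_genes_in_spots:
        drop = set(mito_genes) | set(ribo_genes)
        keep_mask = np.array([g not in drop for g in out.gene_ids])
        out = out.subset_genes(keep_mask)
    return out, report


@dataclass
class ExpressionMatrix:
    """Log-normalized expression, genes x observations (sparse, natural log)."""

    gene_ids: list[str]
    obs_ids: list[str]
    values: sp.csr_matrix
    scale_factor: float
    log_base: str = "e"
    mode: str = "cells"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def gene_values(self, gene: str) -> np.ndarray:
        """Per-observation values for one gene; zeros if the gene is absent."""
        try:
            i = self.gene_ids.index(gene)
        except ValueError:
            return np.zeros(self.n_obs)
        return np.asarray(self.values[i].todense()).ravel()


def lognormalize(m: CountMatrix, mode: str = "cells") -> ExpressionMatrix:
    """ln(1 + count/total * S); S = 10,000 (cells) or median total (spots)."""
    if mode not in ("cells", "spots"):
        raise ValueError("mode must be 'cells' or 'spots'")
    totals = m.obs_totals().astype(float)
    if np.any(totals == 0):
        bad = [m.obs_ids[i] for i in np.flatnonzero(totals == 0)][:5]
        raise ValueError(f"zero-total observations must be dropped before normalization: {bad}")
    scale = float(np.median(totals)) if mode == "spots" else 10_000.0
    x = m.counts.tocsc().astype(float)
    x = x.multiply(scale / totals[None, :]).tocsr()
    x.data = np.log1p(x.data)
    return ExpressionMatrix(
        list(m.gene_ids), list(m.obs_ids), x, scale_factor=scale, log_base="e", mode=mode
    )
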