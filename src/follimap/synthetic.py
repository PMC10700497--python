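"""Synthetic scRNA-seq and spatial count data with planted, recoverable structure.

The generator emulates a postnatal mouse thyroid study design: four time
points, roughly a dozen cell types each with its own marker genes (two of
them thyroid-follicular subtypes, TFC-1 and TFC-2), a central and a
peripheral tissue region whose expression programs share a configurable
fraction of genes with the corresponding TFC subtype, mitochondrial and
hemoglobin gene classes, a planted 6% doublet rate, and ligand-receptor
channels from myeloid senders to TFC-1 whose effect decays across time
points.  Counts follow a negative-binomial model (gamma-Poisson mixture)
with a shared dispersion; every planted feature is recorded in a
:class:`SyntheticTruth` so downstream stages can be scored against ground
truth.

All randomness flows from one integer seed; submodules draw from child
streams keyed by fixed stream labels, so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import CountMatrix, LRDatabase, ObservationTable

__all__ = [
    "SimConfig",
    "RegionSpec",
    "LRChannel",
    "SyntheticTruth",
    "default_config",
    "generate_scrna",
    "generate_st",
    "generate_lr_channels",
    "write_truth",
    "read_truth",
]

# fixed offsets for child RNG streams (order is part of the determinism contract)
_STREAM_GENES = 1
_STREAM_CELLS = 2
_STREAM_DOUBLETS = 3
_STREAM_SPOTS = 4
_STREAM_SCORES = 5
_N_STREAMS = 6


def _streams(seed: int) -> list[np.random.Generator]:
    """Child generators at fixed offsets of one root sequence (single spawn)."""
    children = np.random.SeedSequence(seed).spawn(_N_STREAMS)
    return [np.random.default_rng(c) for c in children]


@dataclass(frozen=True)
class RegionSpec:
    """A spatial region program, optionally tied to a cell type.

    ``fraction`` is the share of spots assigned to the region; regions are
    laid out concentrically, first listed region innermost (central).
    """

    name: str
    cell_type: str | None
    fraction: float


@dataclass(frozen=True)
class LRChannel:
    """A planted ligand-receptor channel with a per-time-point effect schedule.

    The ligand gene is over-expressed in the sender type and the receptor gene
    in the receiver type, both scaled by ``effects[t]`` (log scale) at time
    point ``t``.  A channel with all-zero effects is a decoy: the pair exists
    in the database but nothing is planted.
    """

    pair_id: str
    ligand: str
    sender: str | None
    receptor: str
    receiver: str | None
    effects: tuple[float, ...]


def _default_cell_types() -> dict[str, float]:
    return {
        "TFC-1": 0.18,
        "TFC-2": 0.18,
        "Macrophage": 0.12,
        "Fibroblast": 0.10,
        "Neutrophil": 0.08,
        "T": 0.08,
        "Endothelial": 0.06,
        "DC": 0.06,
        "B": 0.06,
        "Stromal": 0.04,
        "C-cell": 0.04,
    }


def _default_regions() -> tuple[RegionSpec, ...]:
    return (
        RegionSpec("central", "TFC-1", 0.5),
        RegionSpec("peripheral", "TFC-2", 0.5),
    )


def _default_channels() -> tuple[LRChannel, ...]:
    on, off = 2.0, 0.0
    planted = [
        LRChannel("P01", "Tnf", "Macrophage", "Tnfrsf1a", "TFC-1", (2.0, 1.5, 1.0, 0.5)),
        LRChannel("P02", "Il1b", "Neutrophil", "Il1r1", "TFC-1", (2.0, 2.0, 1.5, 1.0)),
        LRChannel("P03", "LigA", "DC", "RecA", "TFC-1", (on, on, on, on)),
        LRChannel("P04", "LigB", "Macrophage", "RecB", "TFC-1", (on, on, on, off)),
        LRChannel("P05", "LigC", "Neutrophil", "RecC", "TFC-1", (on, on, off, off)),
        LRChannel("P06", "LigD", "DC", "RecD", "TFC-1", (on, on, off, off)),
        LRChannel("P07", "LigE", "Macrophage", "RecE", "TFC-1", (on, off, off, off)),
        LRChannel("P08", "LigF", "Neutrophil", "RecF", "TFC-1", (on, off, off, off)),
    ]
    decoys = [
        LRChannel(f"D{i:02d}", f"DLig{i}", None, f"DRec{i}", None, (0.0, 0.0, 0.0, 0.0))
        for i in range(1, 7)
    ]
    return tuple(planted + decoys)


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated study; identical configs give identical data."""

    seed: int = 0
    time_points: tuple[str, ...] = ("d5", "d10", "d20", "d30")
    n_cells_per_timepoint: int = 500
    cell_types: dict[str, float] = field(default_factory=_default_cell_types)
    n_genes: int = 1000
    n_markers_per_type: int = 20
    marker_log_effect: float = 2.0
    baseline_mean: float = 1.0
    dispersion: float = 2.0
    mito_gene_count: int = 10
    hb_gene_count: int = 5
    ribo_gene_count: int = 10
    mito_fraction_mean: float = 0.05
    hb_fraction_mean: float = 0.003
    doublet_rate: float = 0.06
    library_size_sigma: float = 0.25
    n_spots: int = 400
    spot_depth: float = 5.0
    regions: tuple[RegionSpec, ...] = field(default_factory=_default_regions)
    n_region_genes: int = 20
    region_marker_share: float = 0.6
    region_log_effect: float = 1.5
    lr_channels: tuple[LRChannel, ...] = field(default_factory=_default_channels)

    def __post_init__(self) -> None:
        freqs = np.array(list(self.cell_types.values()), dtype=float)
        if not np.isclose(freqs.sum(), 1.0):
            raise ValueError(f"cell type frequencies must sum to 1, got {freqs.sum():.4f}")
        if not 0.0 <= self.doublet_rate < 1.0:
            raise ValueError("doublet_rate must lie in [0, 1)")
        for name, val in (
            ("n_cells_per_timepoint", self.n_cells_per_timepoint),
            ("n_genes", self.n_genes),
            ("n_markers_per_type", self.n_markers_per_type),
            ("n_spots", self.n_spots),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for ch in self.lr_channels:
            if len(ch.effects) != len(self.time_points):
                raise ValueError(
                    f"channel {ch.pair_id}: {len(ch.effects)} effects for "
                    f"{len(self.time_points)} time points"
                )
            for who in (ch.sender, ch.receiver):
                if who is not None and who not in self.cell_types:
                    raise ValueError(f"channel {ch.pair_id}: unknown cell type {who!r}")
        region_frac = sum(r.fraction for r in self.regions)
        if self.regions and not np.isclose(region_frac, 1.0):
            raise ValueError("region fractions must sum to 1")


def default_config(**overrides) -> SimConfig:
    """The default study conditions, with keyword overrides."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated dataset.

    ``gene_roles``: per-gene primary role (baseline / marker / mito / hb /
    ribo / ligand / receptor / region) and its target (cell type, region, or
    channel).  ``obs``: per-observation true type or region, time point, and
    doublet flag.  ``region_genes``: full region programs including genes
    shared with cell-type marker sets.  ``channels``: the planted effect
    schedule, one row per (pair, time point).  ``region_map``: the planted
    cell type <-> region correspondence.
    """

    gene_roles: pd.DataFrame
    obs: pd.DataFrame
    channels: pd.DataFrame
    region_genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    region_map: dict[str, str] = field(default_factory=dict)

    def markers_of(self, cell_type: str) -> list[str]:
        df = self.gene_roles
        return df.loc[(df.role == "marker") & (df.target == cell_type), "gene_id"].tolist()

    def genes_of_region(self, region: str) -> list[str]:
        df = self.region_genes
        return df.loc[df.region == region, "gene_id"].tolist()

    def doublet_ids(self) -> list[str]:
        return self.obs.loc[self.obs.is_doublet, "obs_id"].tolist()


# ---------------------------------------------------------------------------
# gene panel layout


@dataclass
class _Panel:
    gene_ids: list[str]
    roles: pd.DataFrame
    mu: np.ndarray  # per-gene baseline mean
    index: dict[str, int]
    mito: list[str]
    hb: list[str]
    ribo: list[str]
    markers: dict[str, list[str]]  # cell type -> marker genes


def _build_panel(cfg: SimConfig, rng: np.random.Generator) -> _Panel:
    lr_genes: list[str] = []
    lr_role: dict[str, tuple[str, str]] = {}
    for ch in cfg.lr_channels:
        for gene, role in ((ch.ligand, "ligand"), (ch.receptor, "receptor")):
            if gene not in lr_role:
                lr_genes.append(gene)
                lr_role[gene] = (role, ch.pair_id)
    types = list(cfg.cell_types)
    n_special = (
        cfg.mito_gene_count
        + cfg.hb_gene_count
        + cfg.ribo_gene_count
        + len(lr_genes)
        + cfg.n_markers_per_type * len(types)
    )
    if n_special > cfg.n_genes:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small for {n_special} special genes "
            f"({cfg.n_markers_per_type} markers x {len(types)} types plus gene classes)"
        )
    gene_ids: list[str] = []
    rows: list[tuple[str, str, str]] = []

    def add(gid: str, role: str, target: str = "") -> None:
        gene_ids.append(gid)
        rows.append((gid, role, target))

    mito = [f"mt-Sim{i}" for i in range(1, cfg.mito_gene_count + 1)]
    hb = [f"Hba-s{i}" for i in range(1, cfg.hb_gene_count + 1)]
    ribo = [f"Rps-s{i}" for i in range(1, cfg.ribo_gene_count + 1)]
    for g in mito:
        add(g, "mito")
    for g in hb:
        add(g, "hb")
    for g in ribo:
        add(g, "ribo")
    for g in lr_genes:
        add(g, *lr_role[g])
    markers: dict[str, list[str]] = {}
    for t in types:
        mk = [f"mk-{t}-{i}" for i in range(1, cfg.n_markers_per_type + 1)]
        markers[t] = mk
        for g in mk:
            add(g, "marker", t)
    n_fill = cfg.n_genes - len(gene_ids)
    for i in range(1, n_fill + 1):
        add(f"g{i:04d}", "baseline")

    mu = rng.gamma(shape=1.5, scale=cfg.baseline_mean / 1.5, size=cfg.n_genes)
    mu = np.maximum(mu, 0.02 * cfg.baseline_mean)
    index = {g: i for i, g in enumerate(gene_ids)}
    # mito/hb classes get means pinned so their expected count fractions match cfg
    total = cfg.n_genes * cfg.baseline_mean
    mu[[index[g] for g in mito]] = cfg.mito_fraction_mean * total / cfg.mito_gene_count
    mu[[index[g] for g in hb]] = cfg.hb_fraction_mean * total / cfg.hb_gene_count
    roles = pd.DataFrame(rows, columns=["gene_id", "role", "target"])
    return _Panel(gene_ids, roles, mu, index, mito, hb, ribo, markers)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw, var = mu + mu^2/dispersion."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _apportion(n: int, fracs: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n among len(fracs) groups."""
    raw = np.asarray(fracs, dtype=float) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base.tolist()


# ---------------------------------------------------------------------------
# scRNA-seq


def generate_scrna(cfg: SimConfig) -> tuple[CountMatrix, ObservationTable, SyntheticTruth]:
    """Simulate the single-cell modality.

    Cell type counts per time point follow the configured frequencies exactly
    (largest-remainder rounding).  Doublets are planted, not sampled: per time
    point, round(doublet_rate * n) cells are replaced by the sum of their own
    counts and a random other cell's counts, flagged in truth, and given
    doublet score 1.0 (singlets get uniform scores below 0.5).
    """
    streams = _streams(cfg.seed)
    gene_rng = streams[_STREAM_GENES]
    cell_rng = streams[_STREAM_CELLS]
    dbl_rng = streams[_STREAM_DOUBLETS]
    score_rng = streams[_STREAM_SCORES]

    panel = _build_panel(cfg, gene_rng)
    types = list(cfg.cell_types)
    tps = list(cfg.time_points)
    n_types, n_tp, G = len(types), len(tps), cfg.n_genes

    # log-effect tensor: type x time x gene
    eff = np.zeros((n_types, n_tp, G))
    for ti, t in enumerate(types):
        cols = [panel.index[g] for g in panel.markers[t]]
        eff[ti, :, cols] = cfg.marker_log_effect
    for ch in cfg.lr_channels:
        if ch.sender is not None:
            eff[types.index(ch.sender), :, panel.index[ch.ligand]] += np.asarray(ch.effects)
        if ch.receiver is not None:
            eff[types.index(ch.receiver), :, panel.index[ch.receptor]] += np.asarray(ch.effects)

    per_type = _apportion(cfg.n_cells_per_timepoint, list(cfg.cell_types.values()))
    obs_ids: list[str] = []
    type_idx: list[int] = []
    tp_idx: list[int] = []
    for pi, tp in enumerate(tps):
        k = 0
        for ti, n_t in enumerate(per_type):
            for _ in range(n_t):
                k += 1
                obs_ids.append(f"{tp}_c{k:05d}")
                type_idx.append(ti)
                tp_idx.append(pi)
    n_cells = len(obs_ids)
    type_idx_a = np.array(type_idx)
    tp_idx_a = np.array(tp_idx)

    lib = np.exp(cell_rng.normal(0.0, cfg.library_size_sigma, size=n_cells))
    mean = lib[:, None] * panel.mu[None, :] * np.exp(eff[type_idx_a, tp_idx_a, :])
    counts = _nb_sample(cell_rng, mean, cfg.dispersion)  # cells x genes

    # plant doublets: per time point, round(rate*n) cells absorb a random partner
    is_doublet = np.zeros(n_cells, dtype=bool)
    for pi in range(n_tp):
        cells_here = np.flatnonzero(tp_idx_a == pi)
        n_d = int(np.floor(cfg.doublet_rate * len(cells_here) + 0.5))
        if n_d == 0:
            continue
        targets = dbl_rng.choice(cells_here, size=n_d, replace=False)
        for c in targets:
            partner = int(dbl_rng.choice(cells_here))
            while partner == c:
                partner = int(dbl_rng.choice(cells_here))
            counts[c] += counts[partner]
            is_doublet[c] = True

    score = score_rng.uniform(0.0, 0.5, size=n_cells)
    score[is_doublet] = 1.0

    mat = CountMatrix(panel.gene_ids, obs_ids, sp.csr_matrix(counts.T), "cell")
    totals = mat.obs_totals().astype(float)
    mito_idx = mat.gene_index(panel.mito)
    hb_idx = mat.gene_index(panel.hb)
    with np.errstate(invalid="ignore"):
        mito_frac = np.asarray(mat.counts[mito_idx].sum(axis=0)).ravel() / totals
        hb_frac = np.asarray(mat.counts[hb_idx].sum(axis=0)).ravel() / totals
    obs = ObservationTable(
        pd.DataFrame(
            {
                "obs_id": obs_ids,
                "group_label": [types[i] for i in type_idx],
                "time_point": [tps[i] for i in tp_idx],
                "total_umi": totals.astype(int),
                "n_genes": mat.obs_n_genes(),
                "mito_fraction": np.nan_to_num(mito_frac),
                "hb_fraction": np.nan_to_num(hb_frac),
                "doublet_score": score,
            }
        ),
        "cell",
    )
    truth = SyntheticTruth(
        gene_roles=panel.roles,
        obs=pd.DataFrame(
            {
                "obs_id": obs_ids,
                "true_type": [types[i] for i in type_idx],
                "time_point": [tps[i] for i in tp_idx],
                "is_doublet": is_doublet,
            }
        ),
        channels=_channels_frame(cfg),
        region_map={r.name: r.cell_type for r in cfg.regions if r.cell_type},
    )
    return mat, obs, truth


def _channels_frame(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for ch in cfg.lr_channels:
        for tp, e in zip(cfg.time_points, ch.effects):
            rows.append(
                {
                    "pair_id": ch.pair_id,
                    "ligand": ch.ligand,
                    "sender": ch.sender or "",
                    "receptor": ch.receptor,
                    "receiver": ch.receiver or "",
                    "time_point": tp,
                    "effect": e,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial transcriptomics


def generate_st(cfg: SimConfig) -> tuple[CountMatrix, ObservationTable, SyntheticTruth]:
    """Simulate the spatial modality.

    Spots sit on a square grid and are assigned to regions concentrically
    (first listed region innermost).  Each region's expression program shares
    ``region_marker_share`` of its genes with the linked cell type's planted
    markers, which is what makes the cell-type <-> region correspondence
    recoverable by set-overlap analysis.
    """
    if not cfg.regions:
        raise ValueError("generate_st requires at least one region")
    streams = _streams(cfg.seed)
    gene_rng = streams[_STREAM_GENES]
    spot_rng = streams[_STREAM_SPOTS]

    panel = _build_panel(cfg, gene_rng)  # same stream: identical panel as scRNA

    side = int(np.ceil(np.sqrt(cfg.n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    xs, ys = xs.ravel()[: cfg.n_spots], ys.ravel()[: cfg.n_spots]
    center = (side - 1) / 2.0
    dist = np.hypot(xs - center, ys - center)
    order = np.argsort(dist, kind="stable")
    region_of = np.empty(cfg.n_spots, dtype=int)
    sizes = _apportion(cfg.n_spots, [r.fraction for r in cfg.regions])
    start = 0
    for ri, n_r in enumerate(sizes):
        region_of[order[start : start + n_r]] = ri
        start += n_r

    # region programs: shared markers + unique baseline genes
    baseline_pool = [g for g, r in zip(panel.gene_ids, panel.roles.role) if r == "baseline"]
    n_shared = int(round(cfg.region_marker_share * cfg.n_region_genes))
    if cfg.n_region_genes * len(cfg.regions) > len(baseline_pool):
        raise ValueError("not enough baseline genes for unique region programs")
    region_rows = []
    eff = np.zeros((len(cfg.regions), cfg.n_genes))
    pool_pos = 0
    for ri, spec in enumerate(cfg.regions):
        shared_genes: list[str] = []
        if spec.cell_type is not None and n_shared > 0:
            shared_genes = panel.markers[spec.cell_type][:n_shared]
        n_uni = cfg.n_region_genes - len(shared_genes)
        unique_genes = baseline_pool[pool_pos : pool_pos + n_uni]
        pool_pos += n_uni
        for g in shared_genes + unique_genes:
            region_rows.append(
                {"region": spec.name, "gene_id": g, "shared_with_type": g in shared_genes}
            )
            eff[ri, panel.index[g]] += cfg.region_log_effect

    obs_ids = [f"spot_{i:05d}" for i in range(1, cfg.n_spots + 1)]
    lib = np.exp(spot_rng.normal(0.0, cfg.library_size_sigma, size=cfg.n_spots))
    mean = cfg.spot_depth * lib[:, None] * panel.mu[None, :] * np.exp(eff[region_of, :])
    counts = _nb_sample(spot_rng, mean, cfg.dispersion)

    mat = CountMatrix(panel.gene_ids, obs_ids, sp.csr_matrix(counts.T), "spot")
    totals = mat.obs_totals()
    obs = ObservationTable(
        pd.DataFrame(
            {
                "obs_id": obs_ids,
                "group_label": [cfg.regions[r].name for r in region_of],
                "time_point": "",
                "x": xs,
                "y": ys,
                "total_umi": totals,
                "n_genes": mat.obs_n_genes(),
            }
        ),
        "spot",
    )
    truth = SyntheticTruth(
        gene_roles=panel.roles,
        obs=pd.DataFrame(
            {
                "obs_id": obs_ids,
                "true_type": [cfg.regions[r].name for r in region_of],
                "time_point": "",
                "is_doublet": False,
            }
        ),
        channels=_channels_frame(cfg),
        region_genes=pd.DataFrame(region_rows),
        region_map={r.name: r.cell_type for r in cfg.regions if r.cell_type},
    )
    return mat, obs, truth


def generate_lr_channels(cfg: SimConfig) -> LRDatabase:
    """The ligand-receptor database implied by the configured channels (planted + decoys)."""
    rows = [
        {
            "pair_id": ch.pair_id,
            "ligand": ch.ligand,
            "receptor": ch.receptor,
            "source": "planted" if any(e != 0 for e in ch.effects) else "decoy",
        }
        for ch in cfg.lr_channels
    ]
    if not rows:
        raise ValueError("no ligand-receptor channels configured")
    return LRDatabase(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# truth round-trip


def write_truth(truth: SyntheticTruth, out_prefix: str) -> None:
    truth.gene_roles.to_csv(out_prefix + ".genes.tsv", sep="\t", index=False, lineterminator="\n")
    truth.obs.to_csv(out_prefix + ".obs.tsv", sep="\t", index=False, lineterminator="\n")
    truth.channels.to_csv(out_prefix + ".channels.tsv", sep="\t", index=False, lineterminator="\n")
    rg = truth.region_genes if not truth.region_genes.empty else pd.DataFrame(
        columns=["region", "gene_id", "shared_with_type"]
    )
    rg.to_csv(out_prefix + ".region_genes.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(
        {"region": list(truth.region_map), "cell_type": list(truth.region_map.values())}
    ).to_csv(out_prefix + ".region_map.tsv", sep="\t", index=False, lineterminator="\n")


def read_truth(out_prefix: str) -> SyntheticTruth:
    gene_roles = pd.read_csv(out_prefix + ".genes.tsv", sep="\t", keep_default_na=False)
    obs = pd.read_csv(out_prefix + ".obs.tsv", sep="\t", keep_default_na=False)
    obs["is_doublet"] = obs["is_doublet"].astype(bool)
    channels = pd.read_csv(out_prefix + ".channels.tsv", sep="\t", keep_default_na=False)
    region_genes = pd.read_csv(out_prefix + ".region_genes.tsv", sep="\t", keep_default_na=False)
    rmap_df = pd.read_csv(out_prefix + ".region_map.tsv", sep="\t", keep_default_na=False)
    return SyntheticTruth(
        gene_roles=gene_roles,
        obs=obs,
        channels=channels,
        region_genes=region_genes,
        region_map=dict(zip(rmap_df["region"], rmap_df["cell_type"])),
    )
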