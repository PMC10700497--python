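"""End-to-end orchestration: simulate/load -> QC -> normalize -> markers -> MIA -> interactions.

One YAML (or JSON) run configuration drives the whole analysis.  Each
modality comes either from input files or from the bundled simulator, never
both.  A single global seed feeds every stochastic stage (the simulator and
the permutation test draw from streams derived from it), so re-running an
identical configuration reproduces every output byte for byte; the run
manifest records a checksum per output file to make that checkable.

Stage order mirrors the analysis protocol: cell QC filters, gene filter,
doublet exclusion per sample, spot QC, log-normalization, thresholded marker
sets per modality, the MIA map, and ligand-receptor interaction scoring on
the single-cell modality.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .interactions import PermutationConfig, interaction_table
from .io_formats import (
    CountMatrix,
    ObservationTable,
    read_count_matrix,
    read_lr_database,
    read_obs_table,
    read_ortholog_map,
    write_count_matrix,
    write_gmt,
    write_lr_database,
    write_obs_table,
)
from .markers import build_gene_sets
from .mia import mia_map
from .preprocess import QCParams, lognormalize, qc_cells, qc_doublets, qc_genes, qc_spots
from .synthetic import (
    SimConfig,
    generate_lr_channels,
    generate_scrna,
    generate_st,
    write_truth,
)

__all__ = ["RunConfig", "RunManifest", "run_all", "load_config"]


class ConfigError(ValueError):
    """The run configuration is invalid; reported before any compute."""


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "follimap_run"
    scrna_source: str = "simulate"  # "simulate" | "paths"
    st_source: str = "simulate"
    scrna_paths: dict[str, str] = field(default_factory=dict)
    st_paths: dict[str, str] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    lr_path: str | None = None
    ortholog_path: str | None = None
    qc: dict[str, Any] = field(default_factory=dict)
    marker_test: str = "ttest"
    scrna_p: float = 1e-20
    st_p: float = 1e-3
    adjust: bool = False
    logfc_min: float | None = None
    mia_background: str = "intersection"
    n_permutations: int = 1000
    p_rule: str = "add_one"
    shuffle_scope: str = "joint_type_time"
    sig_threshold: float = 0.05
    senders: list[str] | None = None
    receivers: list[str] | None = None

    def sim_config(self) -> SimConfig:
        base = SimConfig(seed=self.seed)
        overrides = dict(self.simulate)
        overrides.pop("seed", None)
        valid = {f.name for f in fields(SimConfig)}
        unknown = set(overrides) - valid
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        return replace(base, **overrides)

    def qc_params(self) -> QCParams:
        valid = {f.name for f in fields(QCParams)}
        unknown = set(self.qc) - valid
        if unknown:
            raise ConfigError(f"unknown qc keys: {sorted(unknown)}")
        qc = dict(self.qc)
        if "exclude_spot_labels" in qc:
            qc["exclude_spot_labels"] = tuple(qc["exclude_spot_labels"])
        return QCParams(**qc)

    def permutation_config(self) -> PermutationConfig:
        return PermutationConfig(
            n_permutations=self.n_permutations,
            seed=self.seed,
            shuffle_scope=self.shuffle_scope,
            p_rule=self.p_rule,
        )


_PATH_KEYS = {"mtx", "genes", "barcodes", "obs"}


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    cfg = RunConfig()
    for modality, src_attr, path_attr in (
        ("scrna", "scrna_source", "scrna_paths"),
        ("st", "st_source", "st_paths"),
    ):
        block = raw.pop(modality, {"simulate": True})
        has_sim = bool(block.get("simulate"))
        has_paths = "paths" in block
        if has_sim == has_paths:
            raise ConfigError(
                f"{modality}: exactly one of 'simulate' or 'paths' must be given"
            )
        if has_paths:
            paths = block["paths"]
            missing = _PATH_KEYS - set(paths)
            if missing:
                raise ConfigError(f"{modality}.paths missing keys: {sorted(missing)}")
            for p in paths.values():
                if not Path(p).exists():
                    raise ConfigError(f"{modality}: input file not found: {p}")
            setattr(cfg, src_attr, "paths")
            setattr(cfg, path_attr, dict(paths))
        else:
            setattr(cfg, src_attr, "simulate")
    lr_block = raw.pop("lr", {})
    cfg.lr_path = lr_block.get("path")
    cfg.ortholog_path = lr_block.get("orthologs")
    for p in (cfg.lr_path, cfg.ortholog_path):
        if p and not Path(p).exists():
            raise ConfigError(f"ligand-receptor input not found: {p}")
    interactions_block = raw.pop("interactions", {})
    for key, attr in (
        ("n_permutations", "n_permutations"),
        ("p_rule", "p_rule"),
        ("shuffle_scope", "shuffle_scope"),
        ("sig_threshold", "sig_threshold"),
        ("senders", "senders"),
        ("receivers", "receivers"),
    ):
        if key in interactions_block:
            setattr(cfg, attr, interactions_block[key])
    markers_block = raw.pop("markers", {})
    for key, attr in (
        ("test", "marker_test"),
        ("scrna_p", "scrna_p"),
        ("st_p", "st_p"),
        ("adjust", "adjust"),
        ("logfc_min", "logfc_min"),
    ):
        if key in markers_block:
            setattr(cfg, attr, markers_block[key])
    mia_block = raw.pop("mia", {})
    if "background" in mia_block:
        cfg.mia_background = mia_block["background"]
    cfg.simulate = raw.pop("simulate", {})
    cfg.qc = raw.pop("qc", {})
    for key in ("seed", "outdir"):
        if key in raw:
            setattr(cfg, key, raw.pop(key))
    if raw:
        raise ConfigError(f"unknown configuration keys: {sorted(raw)}")
    if seed_override is not None:
        cfg.seed = int(seed_override)
    cfg.sim_config()
    cfg.qc_params()
    cfg.permutation_config()
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    created: str
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def checksums(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for stage in self.stages.values():
            out.update(stage.get("outputs", {}))
        return out

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(stage: str, msg: str) -> None:
    print(f"[follimap:{stage}] {msg}", file=sys.stderr)


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def _record(manifest: RunManifest, stage: str, outdir: Path, files: list[Path], **counts) -> None:
    manifest.stages[stage] = {
        "outputs": {str(f.relative_to(outdir)): _sha256(f) for f in files},
        "counts": {k: int(v) for k, v in counts.items()},
    }


def _gene_classes(m: CountMatrix) -> tuple[list[str], list[str], list[str]]:
    """Mito/hemoglobin/ribosomal gene lists by symbol prefix convention."""
    mito = [g for g in m.gene_ids if g.startswith("mt-")]
    hb = [g for g in m.gene_ids if g.startswith(("Hba", "Hbb"))]
    ribo = [g for g in m.gene_ids if g.startswith(("Rps", "Rpl"))]
    return mito, hb, ribo


def run_all(cfg: RunConfig, outdir: str | Path | None = None) -> RunManifest:
    """Execute every stage, writing all outputs and a run manifest under ``outdir``."""
    out = Path(outdir if outdir is not None else cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(cfg),
        seed=cfg.seed,
        version=__version__,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    sim = cfg.sim_config()
    qc_p = cfg.qc_params()

    # --- stage: inputs -----------------------------------------------------
    stage = "inputs"
    if cfg.scrna_source == "simulate":
        _log(stage, f"simulating scRNA modality (seed={sim.seed})")
        sc_counts, sc_obs, sc_truth = generate_scrna(sim)
        write_truth(sc_truth, str(out / "scrna_truth"))
    else:
        p = cfg.scrna_paths
        sc_counts = read_count_matrix(p["mtx"], p["genes"], p["barcodes"], "cell")
        sc_obs = read_obs_table(p["obs"], "cell")
        sc_truth = None
    if cfg.st_source == "simulate":
        _log(stage, "simulating spatial modality")
        st_counts, st_obs, st_truth = generate_st(sim)
        write_truth(st_truth, str(out / "st_truth"))
    else:
        p = cfg.st_paths
        st_counts = read_count_matrix(p["mtx"], p["genes"], p["barcodes"], "spot")
        st_obs = read_obs_table(p["obs"], "spot")
        st_truth = None
    if cfg.lr_path:
        omap = read_ortholog_map(cfg.ortholog_path) if cfg.ortholog_path else None
        lrdb = read_lr_database(cfg.lr_path, omap)
    else:
        lrdb = generate_lr_channels(sim)
    files = []
    files += [Path(p) for p in write_count_matrix(sc_counts, str(out / "scrna_raw")).values()]
    write_obs_table(sc_obs, out / "scrna_obs.tsv")
    files.append(out / "scrna_obs.tsv")
    files += [Path(p) for p in write_count_matrix(st_counts, str(out / "st_raw")).values()]
    write_obs_table(st_obs, out / "st_obs.tsv")
    files.append(out / "st_obs.tsv")
    write_lr_database(lrdb, out / "lr_pairs.csv")
    files.append(out / "lr_pairs.csv")
    _record(
        manifest, stage, out, files,
        n_cells=sc_counts.n_obs, n_spots=st_counts.n_obs,
        n_genes=sc_counts.n_genes, n_lr_pairs=len(lrdb),
    )

    # --- stage: qc ---------------------------------------------------------
    stage = "qc"
    mito, hb, ribo = _gene_classes(sc_counts)
    sc_f, cell_report = qc_cells(sc_counts, sc_obs, qc_p, mito, hb)
    obs_f = sc_obs.subset(sc_f.obs_ids)
    sc_f, gene_report = qc_genes(sc_f, qc_p)
    kept, dbl_report = qc_doublets(obs_f, qc_p)
    sc_f = sc_f.subset_obs(kept)
    obs_f = obs_f.subset(kept)
    _log(stage, f"cells {cell_report.n_in} -> {len(kept)}; genes -> {sc_f.n_genes}")
    st_mito, _, st_ribo = _gene_classes(st_counts)
    st_f, spot_report = qc_spots(st_counts, st_obs, qc_p, st_mito, st_ribo)
    st_obs_f = st_obs.subset(st_f.obs_ids)
    _log(stage, f"spots {spot_report.n_in} -> {st_f.n_obs}")
    files = []
    for name, rep in (
        ("qc_cells", cell_report), ("qc_genes", gene_report),
        ("qc_doublets", dbl_report), ("qc_spots", spot_report),
    ):
        rep.summary().to_csv(out / f"{name}_report.tsv", sep="\t", index=False)
        files.append(out / f"{name}_report.tsv")
    files += [Path(p) for p in write_count_matrix(sc_f, str(out / "scrna_qc")).values()]
    files += [Path(p) for p in write_count_matrix(st_f, str(out / "st_qc")).values()]
    write_obs_table(obs_f, out / "scrna_obs_qc.tsv")
    write_obs_table(st_obs_f, out / "st_obs_qc.tsv")
    files += [out / "scrna_obs_qc.tsv", out / "st_obs_qc.tsv"]
    _record(
        manifest, stage, out, files,
        n_cells_out=sc_f.n_obs, n_genes_out=sc_f.n_genes, n_spots_out=st_f.n_obs,
    )

    # --- stage: markers ----------------------------------------------------
    stage = "markers"
    sc_expr = lognormalize(sc_f, "cells")
    st_expr = lognormalize(st_f, "spots")
    cell_labels = obs_f.column("group_label")
    region_labels = st_obs_f.column("group_label")
    cell_sets = build_gene_sets(
        sc_expr, cell_labels, test=cfg.marker_test, p_threshold=cfg.scrna_p,
        adjust=cfg.adjust, logfc_min=cfg.logfc_min, modality="scRNA",
    )
    region_sets = build_gene_sets(
        st_expr, region_labels, test=cfg.marker_test, p_threshold=cfg.st_p,
        adjust=cfg.adjust, logfc_min=cfg.logfc_min, modality="ST",
    )
    _log(stage, f"cell-type sets: {cell_sets.sizes()}")
    _log(stage, f"region sets: {region_sets.sizes()}")
    write_gmt(cell_sets.as_dict(), out / "cell_type_sets.gmt")
    write_gmt(region_sets.as_dict(), out / "region_sets.gmt")
    files = [out / "cell_type_sets.gmt", out / "region_sets.gmt"]
    _record(
        manifest, stage, out, files,
        n_cell_type_sets=len(cell_sets.sets), n_region_sets=len(region_sets.sets),
    )

    # --- stage: mia --------------------------------------------------------
    stage = "mia"
    mia = mia_map(cell_sets, region_sets, background_mode=cfg.mia_background)
    mia.to_frame().to_csv(out / "mia.tsv", sep="\t", index=False)
    _log(stage, f"map of {len(mia.records)} pairs, background N={mia.records[0].N}")
    _record(manifest, stage, out, [out / "mia.tsv"], n_pairs=len(mia.records))

    # --- stage: interactions ----------------------------------------------
    stage = "interactions"
    itab = interaction_table(
        sc_expr, cell_labels, obs_f.column("time_point"), lrdb,
        cfg.permutation_config(), senders=cfg.senders, receivers=cfg.receivers,
        time_order=list(sim.time_points) if cfg.scrna_source == "simulate" else None,
        sig_threshold=cfg.sig_threshold,
    )
    itab.table.to_csv(out / "interactions.tsv", sep="\t", index=False)
    itab.significant_counts().to_csv(out / "interaction_counts.tsv", sep="\t", index=False)
    _log(stage, f"{len(itab.table)} records, {len(itab.skipped_strata)} strata skipped")
    _record(
        manifest, stage, out,
        [out / "interactions.tsv", out / "interaction_counts.tsv"],
        n_records=len(itab.table),
    )

    manifest.write(out / "manifest.json")
    _log("done", f"manifest at {out / 'manifest.json'}")
    return manifest
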