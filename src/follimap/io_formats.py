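"""On-disk formats for count matrices, annotation tables, and ligand-receptor databases.

All artifacts are plain text: MatrixMarket coordinate-integer matrices with
one-column TSV sidecars for gene symbols and observation barcodes (the 10x
triple convention), tab-separated annotation tables with a mandatory header,
and CSV ligand-receptor pair lists.  Indices are 1-based on disk per the
MatrixMarket standard and 0-based in memory; the conversion lives entirely in
this module.  Writers order entries row-major (gene index, then observation
index) so re-writing a file is byte-stable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "ObservationTable",
    "LRDatabase",
    "OrthologMap",
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "read_obs_table",
    "write_obs_table",
    "read_lr_database",
    "write_lr_database",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """A file violates the expected on-disk contract."""


def _check_unique(ids: Sequence[str], what: str, path: str | None = None) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()[:5]
        where = f" in {path}" if path else ""
        raise FormatError(f"duplicate {what}{where}: {dup}")


@dataclass
class CountMatrix:
    """Sparse non-negative integer UMI counts, genes x observations.

    ``obs_kind`` records whether columns are cells or spatial spots; it gates
    which QC rules apply downstream.
    """

    gene_ids: list[str]
    obs_ids: list[str]
    counts: sp.csr_matrix
    obs_kind: str  # "cell" | "spot"

    def __post_init__(self) -> None:
        if self.obs_kind not in ("cell", "spot"):
            raise ValueError(f"obs_kind must be 'cell' or 'spot', got {self.obs_kind!r}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        _check_unique(self.gene_ids, "gene identifiers")
        _check_unique(self.obs_ids, "observation barcodes")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.obs_ids)} observations"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("counts must be non-negative")
            if not np.issubdtype(data.dtype, np.integer) and np.any(data != np.floor(data)):
                raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.counts.eliminate_zeros()

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.obs_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        """Positions of ``genes`` among ``gene_ids``; unknown genes are skipped."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes if g in lookup], dtype=int)

    def subset_obs(self, keep: Sequence[str]) -> "CountMatrix":
        lookup = {o: i for i, o in enumerate(self.obs_ids)}
        idx = np.array([lookup[o] for o in keep], dtype=int)
        return CountMatrix(self.gene_ids, list(keep), self.counts[:, idx], self.obs_kind)

    def subset_genes(self, keep_mask: np.ndarray) -> "CountMatrix":
        genes = [g for g, k in zip(self.gene_ids, keep_mask) if k]
        return CountMatrix(genes, self.obs_ids, self.counts[np.asarray(keep_mask, bool)], self.obs_kind)

    def obs_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def obs_n_genes(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.obs_ids == other.obs_ids
            and self.obs_kind == other.obs_kind
            and (self.counts != other.counts).nnz == 0
        )


_OBS_COLUMNS = [
    "obs_id",
    "group_label",
    "time_point",
    "x",
    "y",
    "total_umi",
    "n_genes",
    "mito_fraction",
    "hb_fraction",
    "doublet_score",
]
_SPOT_REQUIRED = ["obs_id", "x", "y"]
_CELL_REQUIRED = ["obs_id"]


@dataclass
class ObservationTable:
    """Per-observation annotation: group label, time point, QC statistics.

    ``table`` is indexed 0..n-1 with an ``obs_id`` column; ``missing_optional``
    lists the optional columns absent from the source file.
    """

    table: pd.DataFrame
    obs_kind: str
    missing_optional: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.obs_kind not in ("cell", "spot"):
            raise ValueError(f"obs_kind must be 'cell' or 'spot', got {self.obs_kind!r}")
        required = _SPOT_REQUIRED if self.obs_kind == "spot" else _CELL_REQUIRED
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise FormatError(f"observation table missing required columns: {missing}")
        self.table = self.table.reset_index(drop=True).copy()
        self.table["obs_id"] = self.table["obs_id"].astype(str)
        _check_unique(self.table["obs_id"].tolist(), "observation barcodes")
        self.missing_optional = [c for c in _OBS_COLUMNS if c not in self.table.columns]
        for col in ("mito_fraction", "hb_fraction", "doublet_score"):
            if col in self.table.columns:
                vals = pd.to_numeric(self.table[col], errors="coerce")
                bad = vals.dropna()
                if ((bad < 0) | (bad > 1)).any():
                    raise FormatError(f"column {col} must lie in [0, 1]")
                self.table[col] = vals

    @property
    def obs_ids(self) -> list[str]:
        return self.table["obs_id"].tolist()

    def column(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"observation table has no column {name!r}")
        return self.table.set_index("obs_id")[name]

    def subset(self, keep: Sequence[str]) -> "ObservationTable":
        sub = self.table.set_index("obs_id").loc[list(keep)].reset_index()
        return ObservationTable(sub, self.obs_kind)

    def matches(self, m: CountMatrix) -> bool:
        return set(self.obs_ids) == set(m.obs_ids)


@dataclass
class LRDatabase:
    """Ligand-receptor pair list: one ligand gene and one receptor gene per pair."""

    table: pd.DataFrame  # columns: pair_id, ligand, receptor, source
    n_unmapped_dropped: int = 0

    def __post_init__(self) -> None:
        for col in ("pair_id", "ligand", "receptor"):
            if col not in self.table.columns:
                raise FormatError(f"ligand-receptor table missing column {col!r}")
        if "source" not in self.table.columns:
            self.table = self.table.assign(source="")
        self.table = self.table.reset_index(drop=True)
        _check_unique(self.table["pair_id"].tolist(), "pair identifiers")
        if (self.table["ligand"].astype(str).str.len() == 0).any() or (
            self.table["receptor"].astype(str).str.len() == 0
        ).any():
            raise FormatError("ligand and receptor genes must be non-empty")

    def __len__(self) -> int:
        return len(self.table)

    def genes(self) -> list[str]:
        out: list[str] = []
        for g in pd.concat([self.table["ligand"], self.table["receptor"]]):
            if g not in out:
                out.append(g)
        return out


@dataclass
class OrthologMap:
    """source_gene -> target_gene renaming table (e.g. human -> mouse symbols)."""

    mapping: dict[str, str]
    direction: str = "human_to_mouse"

    def get(self, gene: str) -> str | None:
        return self.mapping.get(gene)


# ---------------------------------------------------------------------------
# MatrixMarket triple


def read_count_matrix(
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    obs_kind: str,
) -> CountMatrix:
    """Read a MatrixMarket coordinate-integer matrix with gene/barcode sidecars.

    The header dimensions must match the sidecar line counts; the value field
    must be ``integer``.  Both violations are hard errors naming the file.
    """
    mtx_path = os.fspath(mtx_path)
    with open(mtx_path, "rt", encoding="utf-8") as fh:
        banner = fh.readline().split()
        if len(banner) < 4 or banner[0] != "%%MatrixMarket" or banner[1] != "matrix":
            raise FormatError(f"{mtx_path}: not a MatrixMarket file")
        if banner[2] != "coordinate" or banner[3] != "integer":
            raise FormatError(
                f"{mtx_path}: expected 'coordinate integer' format, got "
                f"'{banner[2]} {banner[3]}'"
            )
        line = fh.readline()
        while line.startswith("%"):
            line = fh.readline()
        try:
            n_rows, n_cols, nnz = (int(tok) for tok in line.split())
        except ValueError as exc:
            raise FormatError(f"{mtx_path}: malformed size line {line!r}") from exc
        rows = np.empty(nnz, dtype=np.int64)
        cols = np.empty(nnz, dtype=np.int64)
        vals = np.empty(nnz, dtype=np.int64)
        for k in range(nnz):
            parts = fh.readline().split()
            if len(parts) != 3:
                raise FormatError(f"{mtx_path}: truncated or malformed entry {k + 1}")
            try:
                r, c, v = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{mtx_path}: non-integer value in entry {k + 1}") from exc
            if not (1 <= r <= n_rows and 1 <= c <= n_cols):
                raise FormatError(f"{mtx_path}: entry {k + 1} index out of range")
            rows[k], cols[k], vals[k] = r - 1, c - 1, v
    if np.any(vals < 0):
        raise FormatError(f"{mtx_path}: negative counts")
    genes = _read_id_column(genes_path)
    barcodes = _read_id_column(barcodes_path)
    if len(genes) != n_rows:
        raise FormatError(
            f"{os.fspath(genes_path)}: {len(genes)} gene lines but header of "
            f"{mtx_path} declares {n_rows} rows"
        )
    if len(barcodes) != n_cols:
        raise FormatError(
            f"{os.fspath(barcodes_path)}: {len(barcodes)} barcode lines but header "
            f"of {mtx_path} declares {n_cols} columns"
        )
    _check_unique(genes, "gene identifiers", os.fspath(genes_path))
    _check_unique(barcodes, "observation barcodes", os.fspath(barcodes_path))
    counts = sp.coo_matrix((vals, (rows, cols)), shape=(n_rows, n_cols)).tocsr()
    return CountMatrix(genes, barcodes, counts, obs_kind)


def _read_id_column(path: str | os.PathLike) -> list[str]:
    with open(path, "rt", encoding="utf-8") as fh:
        # first tab-separated field per line (10x sidecars may carry extra columns)
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_count_matrix(m: CountMatrix, out_prefix: str | os.PathLike) -> dict[str, str]:
    """Write ``<prefix>.mtx`` plus ``<prefix>.genes.tsv`` / ``<prefix>.barcodes.tsv``.

    Entries are emitted row-major (gene index, then observation index) with
    1-based indices, so output is deterministic for a given matrix.
    """
    prefix = os.fspath(out_prefix)
    coo = m.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))
    paths = {
        "mtx": prefix + ".mtx",
        "genes": prefix + ".genes.tsv",
        "barcodes": prefix + ".barcodes.tsv",
    }
    with open(paths["mtx"], "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{m.n_genes} {m.n_obs} {coo.nnz}\n")
        for k in order:
            fh.write(f"{coo.row[k] + 1} {coo.col[k] + 1} {coo.data[k]}\n")
    for key, ids in (("genes", m.gene_ids), ("barcodes", m.obs_ids)):
        with open(paths[key], "wt", encoding="utf-8", newline="\n") as fh:
            for i in ids:
                fh.write(i + "\n")
    return paths


# ---------------------------------------------------------------------------
# Annotation tables


def read_obs_table(path: str | os.PathLike, obs_kind: str) -> ObservationTable:
    df = pd.read_csv(path, sep="\t", dtype={"obs_id": str, "group_label": str, "time_point": str})
    try:
        return ObservationTable(df, obs_kind)
    except FormatError as exc:
        raise FormatError(f"{os.fspath(path)}: {exc}") from exc


def write_obs_table(obs: ObservationTable, path: str | os.PathLike) -> None:
    cols = [c for c in _OBS_COLUMNS if c in obs.table.columns]
    extra = [c for c in obs.table.columns if c not in cols]
    obs.table[cols + extra].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Ligand-receptor database and ortholog map


def read_lr_database(
    path: str | os.PathLike, ortholog_map: OrthologMap | None = None
) -> LRDatabase:
    """Read a pair_id,ligand,receptor CSV, optionally renaming genes by orthology.

    With a map supplied, any pair whose ligand or receptor has no ortholog is
    dropped; the count of dropped pairs is recorded on the returned database.
    Genes are never invented: without a map, symbols pass through unchanged.
    """
    df = pd.read_csv(path, dtype=str).rename(columns={"source_annotation": "source"})
    n_dropped = 0
    if ortholog_map is not None:
        keep_rows = []
        for _, row in df.iterrows():
            lig = ortholog_map.get(row["ligand"])
            rec = ortholog_map.get(row["receptor"])
            if lig is None or rec is None:
                n_dropped += 1
                continue
            row = row.copy()
            row["ligand"], row["receptor"] = lig, rec
            keep_rows.append(row)
        df = pd.DataFrame(keep_rows, columns=df.columns)
    if df.empty:
        raise FormatError(
            f"{os.fspath(path)}: no ligand-receptor pairs remain"
            + (" after ortholog mapping" if ortholog_map is not None else "")
        )
    return LRDatabase(df, n_unmapped_dropped=n_dropped)


def write_lr_database(db: LRDatabase, path: str | os.PathLike) -> None:
    db.table[["pair_id", "ligand", "receptor", "source"]].to_csv(
        path, index=False, lineterminator="\n"
    )


def read_ortholog_map(path: str | os.PathLike, direction: str = "human_to_mouse") -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("source", "target"):
        if col not in df.columns:
            raise FormatError(f"{os.fspath(path)}: ortholog map missing column {col!r}")
    _check_unique(df["source"].tolist(), "source genes", os.fspath(path))
    return OrthologMap(dict(zip(df["source"], df["target"])), direction)


def write_ortholog_map(omap: OrthologMap, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"source": list(omap.mapping), "target": list(omap.mapping.values())}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "-"] + list(genes)) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            out[parts[0]] = [g for g in parts[2:] if g]
    return out
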