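"""Readers, writers and cell-level QC for the pipeline's external formats.

Count matrices follow the 10x ``filtered_feature_bc_matrix`` directory layout
(Matrix Market ``matrix.mtx`` plus ``barcodes.tsv`` and ``features.tsv`` /
``genes.tsv``, gzip tolerated).  Ortholog groups use the OrthoMCL ``groups.txt``
dialect.  Per-cell tables (cluster labels, embeddings, pseudotime) are headered
TSV/CSV with a mandatory ``cell_id`` column.  LCM bulk profiles are TSV with
genes as rows and one column per replicate, the header encoding the cell type
as ``<cell_type>_rep<k>``.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, IntegrityError

__all__ = [
    "CellMatrix",
    "OrthoGroupMap",
    "LabeledEmbedding",
    "LcmProfile",
    "read_count_matrix",
    "write_count_matrix",
    "filter_cells",
    "read_ortholog_groups",
    "read_cell_table",
    "read_embedding",
    "read_lcm_profile",
    "write_lcm_profile",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CellMatrix:
    """Sparse cells x genes UMI count matrix with identity metadata.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows, genes in columns.  Held
        sparse (CSR); densification happens only inside small-matrix
        operations.
    cell_ids, gene_ids
        Unique string identifiers aligned with the rows / columns of
        ``counts``.  Identifiers are case-sensitive and never normalized.
    species
        Species tag, supplied by configuration (never inferred from ids).
    batch
        Optional batch/replicate tag.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    species: str = ""
    batch: str | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise IntegrityError(
                f"counts shape {self.counts.shape} does not match id lists "
                f"({len(self.cell_ids)} cells, {len(self.gene_ids)} genes)"
            )
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise IntegrityError(f"duplicate {name} ids")
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise IntegrityError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise IntegrityError("non-integral counts")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class OrthoGroupMap:
    """Mapping of ortholog-group id -> set of (species, gene_id) members.

    A (species, gene_id) pair belongs to at most one group; groups are
    non-empty.  Genes absent from the map are simply unmapped.
    """

    groups: dict[str, set[tuple[str, str]]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for gid, members in self.groups.items():
            if not members:
                raise IntegrityError(f"empty ortholog group {gid!r}")
            for pair in members:
                if pair in seen:
                    raise IntegrityError(
                        f"gene {pair[1]!r} ({pair[0]}) in both {seen[pair]!r} and {gid!r}"
                    )
                seen[pair] = gid

    def __len__(self) -> int:
        return len(self.groups)

    def gene_to_group(self, species: str) -> dict[str, str]:
        """Per-species gene_id -> group_id lookup."""
        out: dict[str, str] = {}
        for gid, members in self.groups.items():
            for sp_, gene in members:
                if sp_ == species:
                    out[gene] = gid
        return out

    def n_members(self) -> int:
        return sum(len(m) for m in self.groups.values())


@dataclass
class LabeledEmbedding:
    """Per-cell coordinates (2D UMAP-like or top-PC space) with labels."""

    cell_ids: np.ndarray
    coordinates: np.ndarray  # cells x d
    species: np.ndarray      # per-cell species label
    cluster: np.ndarray      # per-cell cluster label

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2:
            raise IntegrityError("coordinates must be 2-dimensional (cells x d)")
        self.species = np.asarray(self.species, dtype=object)
        self.cluster = np.asarray(self.cluster, dtype=object)
        n = len(self.cell_ids)
        if not (self.coordinates.shape[0] == len(self.species) == len(self.cluster) == n):
            raise IntegrityError("embedding fields are not aligned 1:1 with cell_ids")
        if not np.all(np.isfinite(self.coordinates)):
            raise IntegrityError("non-finite coordinates")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def dim(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class LcmProfile:
    """LCM bulk profiles: per-cell-type replicate TPM vectors plus their mean.

    ``replicates`` maps cell type -> (genes x n_rep) array; ``mean`` is a
    genes x cell-types DataFrame of arithmetic replicate means.
    """

    gene_ids: np.ndarray
    replicates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        for ct, arr in self.replicates.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[0] != len(self.gene_ids):
                raise IntegrityError(f"replicate matrix of {ct!r} does not match gene list")
            if arr.shape[1] < 1:
                raise IntegrityError(f"cell type {ct!r} has no replicates")
            if np.any(arr < 0):
                raise IntegrityError(f"negative TPM in {ct!r}")
            self.replicates[ct] = arr

    @property
    def cell_types(self) -> list[str]:
        return list(self.replicates)

    @property
    def mean(self) -> pd.DataFrame:
        """Genes x cell-types arithmetic mean TPM."""
        return pd.DataFrame(
            {ct: arr.mean(axis=1) for ct, arr in self.replicates.items()},
            index=self.gene_ids,
        )


# ---------------------------------------------------------------------------
# count-matrix IO
# ---------------------------------------------------------------------------

def _find(directory: Path, stems: Iterable[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            p = directory / name
            if p.exists():
                return p
    raise FormatError(f"none of {list(stems)} found in {directory}")


def _read_tsv_ids(path: Path, col: int = 0) -> np.ndarray:
    opener = gzip.open if path.suffix == ".gz" else open
    rows = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split("\t"))
    if not rows:
        return np.asarray([], dtype=object)
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise FormatError(f"ragged rows in {path}")
    return np.asarray([r[col] for r in rows], dtype=object)


def read_count_matrix(
    path: str | Path, species: str = "", batch: str | None = None
) -> CellMatrix:
    """Read a 10x-style MTX directory into a :class:`CellMatrix`.

    The matrix file stores genes x cells (10x convention); the result is
    transposed to cells x genes with gene order preserved from the features
    file.  Features files with 1 or 3 columns are accepted (keyed on column 1).
    """
    directory = Path(path)
    mtx = _find(directory, ["matrix.mtx"])
    barcodes = _find(directory, ["barcodes.tsv"])
    features = _find(directory, ["features.tsv", "genes.tsv"])

    try:
        mat = scipy.io.mmread(str(mtx))
    except Exception as exc:  # scipy raises ValueError on malformed headers
        raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    mat = sp.csr_matrix(mat.T)  # cells x genes

    cell_ids = _read_tsv_ids(barcodes)
    gene_ids = _read_tsv_ids(features)
    if mat.shape[0] != len(cell_ids) or mat.shape[1] != len(gene_ids):
        raise IntegrityError(
            f"matrix is {mat.shape[0]} cells x {mat.shape[1]} genes but id files "
            f"list {len(cell_ids)} barcodes and {len(gene_ids)} features"
        )
    return CellMatrix(mat, cell_ids, gene_ids, species=species, batch=batch)


def write_count_matrix(m: CellMatrix, path: str | Path) -> None:
    """Write a :class:`CellMatrix` as an uncompressed MTX directory."""
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.coo_matrix(m.counts.T), field="integer")
    (directory / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    (directory / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in m.gene_ids)
    )


def filter_cells(m: CellMatrix, min_umi: int = 500) -> CellMatrix:
    """Keep cells with total UMI >= ``min_umi`` (inclusive threshold).

    Defaults to 500 for droplet (10x) data; plate-based assays conventionally
    use 100.  Gene set and cell order are preserved.  Removing every cell is
    a warning, not an error.
    """
    if min_umi < 1:
        raise ValueError("min_umi must be >= 1")
    keep = m.total_counts() >= min_umi
    if not keep.any():
        warnings.warn("all cells removed by UMI filter", stacklevel=2)
    return CellMatrix(
        m.counts[keep], m.cell_ids[keep], m.gene_ids, species=m.species, batch=m.batch
    )


# ---------------------------------------------------------------------------
# ortholog groups (OrthoMCL groups.txt dialect)
# ---------------------------------------------------------------------------

def read_ortholog_groups(path: str | Path) -> OrthoGroupMap:
    """Parse an OrthoMCL-style groups file: ``group_id: sp|gene sp|gene ...``."""
    groups: dict[str, set[tuple[str, str]]] = {}
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if ":" not in line:
                raise FormatError(f"{path}:{lineno}: missing 'group_id:' prefix")
            gid, _, rest = line.partition(":")
            gid = gid.strip()
            if not gid:
                raise FormatError(f"{path}:{lineno}: empty group id")
            members: set[tuple[str, str]] = set()
            tokens = rest.split()
            if not tokens:
                raise FormatError(f"{path}:{lineno}: group {gid!r} has no members")
            for tok in tokens:
                if "|" not in tok:
                    raise FormatError(f"{path}:{lineno}: token {tok!r} is not 'species|gene'")
                sp_, _, gene = tok.partition("|")
                if not sp_ or not gene:
                    raise FormatError(f"{path}:{lineno}: token {tok!r} is not 'species|gene'")
                members.add((sp_, gene))
            if gid in groups:
                raise FormatError(f"{path}:{lineno}: duplicate group id {gid!r}")
            groups[gid] = members
    return OrthoGroupMap(groups)


def write_ortholog_groups(map_: OrthoGroupMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(map_.groups):
            members = " ".join(f"{s}|{g}" for s, g in sorted(map_.groups[gid]))
            fh.write(f"{gid}: {members}\n")


# ---------------------------------------------------------------------------
# per-cell tables and LCM profiles
# ---------------------------------------------------------------------------

def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV/CSV per-cell table; requires a ``cell_id`` column."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if "cell_id" not in df.columns:
        raise FormatError(f"{path}: missing mandatory 'cell_id' column")
    if df["cell_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate cell_id values")
    return df


def read_embedding(path: str | Path) -> LabeledEmbedding:
    """Read a labeled embedding table (cell_id, x, y[, ...], species, cluster)."""
    df = read_cell_table(path)
    coord_cols = [c for c in df.columns if c not in ("cell_id", "species", "cluster")]
    for col in ("species", "cluster"):
        if col not in df.columns:
            raise FormatError(f"embedding table missing {col!r} column")
    return LabeledEmbedding(
        df["cell_id"].to_numpy(),
        df[coord_cols].to_numpy(dtype=float),
        df["species"].to_numpy(),
        df["cluster"].to_numpy(),
    )


def write_embedding(emb: LabeledEmbedding, path: str | Path) -> None:
    cols = {f"c{i}" if emb.dim > 2 else "xy"[i]: emb.coordinates[:, i] for i in range(emb.dim)}
    pd.DataFrame({"cell_id": emb.cell_ids, **cols,
                  "species": emb.species, "cluster": emb.cluster}).to_csv(
        path, sep="\t", index=False
    )


def read_lcm_profile(path: str | Path) -> LcmProfile:
    """Read an LCM TPM table: rows = genes, columns named ``<cell_type>_rep<k>``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    reps: dict[str, list[np.ndarray]] = {}
    for col in df.columns:
        ct, sep_, _ = col.rpartition("_rep")
        if not sep_ or not ct:
            raise FormatError(f"LCM column {col!r} does not match '<cell_type>_rep<k>'")
        reps.setdefault(ct, []).append(df[col].to_numpy(dtype=float))
    return LcmProfile(
        df.index.to_numpy(dtype=object),
        {ct: np.column_stack(v) for ct, v in reps.items()},
    )


def write_lcm_profile(profile: LcmProfile, path: str | Path) -> None:
    data: dict[str, np.ndarray] = {}
    for ct, arr in profile.replicates.items():
        for k in range(arr.shape[1]):
            data[f"{ct}_rep{k + 1}"] = arr[:, k]
    pd.DataFrame(data, index=profile.gene_ids).to_csv(path, sep="\t", index_label="gene_id")
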