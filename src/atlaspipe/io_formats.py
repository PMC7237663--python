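"""Readers and writers for the on-disk formats the pipeline touches.

Count matrices travel as the MatrixMarket trio (``matrix.mtx`` +
``genes.tsv`` + ``barcodes.tsv``, genes × cells on disk, the CellRanger
convention); cell annotations as a headered TSV; gene sets as GMT; run
configuration as JSON.  Every downstream module consumes the containers
defined here.  Gene identity is matched by exact, case-sensitive symbol
throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "CellAnnotations",
    "GeneSetCollection",
    "RunConfig",
    "FormatError",
    "ValidationError",
    "SMOKING_LEVELS",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
]

SMOKING_LEVELS = ("never", "light", "heavy")


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


@dataclass
class CountMatrix:
    """Sparse genes × cells UMI count matrix with symbol / barcode labels.

    Parameters
    ----------
    values
        Sparse non-negative integer matrix, genes on rows, cells on columns.
    gene_ids
        Ordered, unique gene symbols (row labels).
    cell_ids
        Ordered, unique cell barcodes (column labels).
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell barcodes")
        data = self.values.data
        if data.size:
            if (data < 0).any():
                raise ValidationError("negative UMI counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integral UMI counts")
        self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices for ``genes``; raises KeyError on a missing symbol."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from None

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.cell_ids[i] for i in idx],
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            list(self.cell_ids),
        )


@dataclass
class CellAnnotations:
    """Per-cell metadata: donor, smoking habit, population, pseudotime.

    ``smoking`` is one of ``never`` / ``light`` / ``heavy``.  ``excluded_flag``
    marks donors the smoking analyses leave out (the light-smoker /
    pediatric-donor analog).  ``population`` and ``pseudotime`` may be missing
    (NaN) per cell.
    """

    table: pd.DataFrame

    REQUIRED = ("cell_id", "donor", "smoking")
    OPTIONAL = ("population", "pseudotime", "excluded_flag")

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"annotation table missing columns {missing}")
        if df["cell_id"].duplicated().any():
            raise ValidationError("duplicated cell_id in annotations")
        bad = set(df["smoking"].dropna().unique()) - set(SMOKING_LEVELS)
        if bad:
            raise ValidationError(f"unknown smoking level(s): {sorted(bad)}")
        if "population" not in df.columns:
            df["population"] = pd.NA
        if "pseudotime" not in df.columns:
            df["pseudotime"] = np.nan
        else:
            pt = pd.to_numeric(df["pseudotime"], errors="coerce")
            finite = pt.dropna()
            if np.isinf(finite).any():
                raise ValidationError("pseudotime must be finite")
            df["pseudotime"] = pt
        if "excluded_flag" not in df.columns:
            df["excluded_flag"] = False
        df["excluded_flag"] = df["excluded_flag"].astype(bool)
        self.table = df.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table["cell_id"])

    def aligned_to(self, cell_ids: Sequence[str]) -> "CellAnnotations":
        """Reorder/subset rows to match ``cell_ids`` exactly."""
        sub = self.table.set_index("cell_id").loc[list(cell_ids)].reset_index()
        return CellAnnotations(sub)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT contents); symbols deduplicated per set."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValidationError("duplicate set names")
        clean: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            uniq = list(dict.fromkeys(members))
            if not uniq:
                raise ValidationError(f"gene set {name!r} is empty")
            clean[name] = uniq
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RunConfig:
    """All thresholds, paths and the seed a pipeline run needs.

    Thresholds mirror the module-level defaults; loading from JSON overrides
    only the keys present in the file.
    """

    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None
    # QC
    min_genes_per_cell: int = 1500
    max_mito_fraction: float = 0.40
    upper_percentile: float = 99.0
    min_cell_fraction_per_gene: float = 0.001
    scale_total: float = 10_000.0
    # DE gates
    min_logfc: float = 0.25
    min_pct: float = 0.10
    alpha_fdr: float = 0.05
    # taxonomy
    core_min: int = 5
    unique_logfc_max: float = 0.25
    unique_fdr_min: float = 0.2
    roster: list[str] = field(default_factory=list)
    # mucin
    anchor_a: str = "MUC5AC"
    anchor_b: str = "MUC5B"
    min_rho_report: float = 0.15
    program_top_n: int = 25
    # trajectory
    lineage_root: str | None = None
    lineage_end: str | None = None
    smoothing_window: int = 100
    association_q: float = 1e-10

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValidationError("seed must be a non-negative integer")
        if not 0 < self.max_mito_fraction <= 1:
            raise ValidationError("max_mito_fraction must be in (0, 1]")
        if not 50 < self.upper_percentile < 100:
            raise ValidationError("upper_percentile must be in (50, 100)")
        if not 0 < self.min_pct < 1 or not 0 < self.alpha_fdr < 1:
            raise ValidationError("min_pct and alpha_fdr must be in (0, 1)")
        if self.min_logfc < 0:
            raise ValidationError("min_logfc must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# count matrix trio


def _read_id_file(path: str | Path) -> list[str]:
    with open(path) as fh:
        # first tab-separated field of each non-empty line
        return [ln.split("\t")[0].strip() for ln in fh if ln.strip()]


def read_count_matrix(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    *,
    cells_on_rows: bool = False,
) -> CountMatrix:
    """Read a MatrixMarket trio into a :class:`CountMatrix`.

    The on-disk matrix is genes × cells by default; set ``cells_on_rows``
    for foreign files with the transposed orientation.  Row/column order is
    preserved exactly as in the id files.
    """
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if cells_on_rows:
        mat = sp.csr_matrix(mat.T)
    genes = _read_id_file(genes_path)
    cells = _read_id_file(barcodes_path)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix is {mat.shape} but id files give "
            f"{len(genes)} genes and {len(cells)} barcodes"
        )
    return CountMatrix(mat, genes, cells)


def write_count_matrix(counts: CountMatrix, out_dir: str | Path) -> None:
    """Write ``matrix.mtx``, ``genes.tsv`` and ``barcodes.tsv`` to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "matrix.mtx", counts.values.tocoo(), field="integer")
    (out / "genes.tsv").write_text("".join(f"{g}\n" for g in counts.gene_ids))
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.cell_ids))


def read_count_matrix_dir(dir_path: str | Path) -> CountMatrix:
    d = Path(dir_path)
    return read_count_matrix(d / "matrix.mtx", d / "genes.tsv", d / "barcodes.tsv")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | Path) -> CellAnnotations:
    """Read a headered annotation TSV (cell_id, donor, smoking, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "donor": str})
    return CellAnnotations(df)


def write_annotations(ann: CellAnnotations, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then member symbols, tab-separated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path} line {lineno}: GMT lines need name, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            name = fields[0]
            members = [f for f in fields[2:] if f]
            if name in sets:
                raise ValidationError(f"duplicate gene-set name {name!r}")
            if not members:
                raise FormatError(f"{path} line {lineno}: gene set {name!r} empty")
            sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.source or "na", *members]) + "\n")
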