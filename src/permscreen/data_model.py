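"""Screen data containers, on-disk I/O and dataset-level quality control.

A screen is a response-by-cell matrix of raw UMI counts together with a
gRNA-to-cell assignment table, per-gRNA metadata and a table of per-cell
technical factors.  Counts may be held dense (``numpy.ndarray``) or sparse
(``scipy.sparse.csr_matrix``); all operations accept either.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenDataset",
    "QCThresholds",
    "FormatError",
    "DimensionError",
    "CollinearityError",
    "EmptyDatasetError",
    "read_dataset",
    "write_dataset",
    "apply_dataset_qc",
    "build_covariate_matrix",
]


class FormatError(ValueError):
    """Malformed input file (bad MTX/TSV structure or invalid values)."""


class DimensionError(ValueError):
    """Tables whose shapes/keys do not line up."""


class CollinearityError(ValueError):
    """Covariate matrix is rank deficient."""


class EmptyDatasetError(ValueError):
    """QC removed every cell (or every gene)."""


@dataclass
class QCThresholds:
    """Dataset-level QC: the three uniform filters.

    Defaults are genes expressed in >= 0.005 of cells, gRNAs present in >= 10
    cells, and cells carrying exactly one gRNA.
    """

    min_gene_frac: float = 0.005
    min_cells_per_grna: int = 10
    require_single_grna: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_gene_frac <= 1.0:
            raise ValueError("min_gene_frac must be in [0, 1]")
        if self.min_cells_per_grna < 0:
            raise ValueError("min_cells_per_grna must be >= 0")


@dataclass
class ScreenDataset:
    """Full state of a screen: counts, assignments, metadata, covariates.

    Attributes
    ----------
    counts
        Response-by-cell matrix of nonnegative integer UMI counts.
    response_ids, cell_ids
        Row/column identifiers, in matrix order.
    grna_assignment
        Two-column frame (``cell_id``, ``grna_id``); before QC a cell may
        appear on several rows, after QC exactly once.
    grna_table
        Indexed by ``grna_id`` with columns ``target``, ``targeting`` (bool)
        and ``grna_group``.
    covariates
        Per-cell technical factors, indexed by ``cell_id`` and row-aligned
        with ``cell_ids``.
    filter_report
        Accumulated QC accounting (counts removed per step).
    """

    counts: np.ndarray | sp.csr_matrix
    response_ids: list[str]
    cell_ids: list[str]
    grna_assignment: pd.DataFrame
    grna_table: pd.DataFrame
    covariates: pd.DataFrame
    filter_report: dict = field(default_factory=dict)

    # -- basic geometry -------------------------------------------------
    @property
    def n_responses(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def response_row(self, response_id: str) -> np.ndarray:
        """Dense count vector for one response across all cells."""
        i = self.response_ids.index(response_id)
        row = self.counts[i]
        if sp.issparse(row):
            return np.asarray(row.todense()).ravel()
        return np.asarray(row).ravel()

    # -- assignment helpers ---------------------------------------------
    def assignment_vector(self) -> np.ndarray:
        """Per-cell gRNA id aligned with ``cell_ids``.

        Only valid once each cell carries exactly one gRNA (post-QC).
        """
        counts_per_cell = self.grna_assignment["cell_id"].value_counts()
        if (counts_per_cell > 1).any():
            raise ValueError("some cells carry more than one gRNA; run QC first")
        mapping = self.grna_assignment.set_index("cell_id")["grna_id"]
        return mapping.reindex(self.cell_ids).to_numpy()

    def grna_cells(self, grna_id: str) -> np.ndarray:
        """Sorted column indices of cells assigned the given gRNA."""
        vec = self.assignment_vector()
        return np.flatnonzero(vec == grna_id)

    def nt_grna_ids(self) -> list[str]:
        return list(self.grna_table.index[~self.grna_table["targeting"].astype(bool)])

    def library_sizes(self) -> np.ndarray:
        """Per-cell total UMI count over the current matrix."""
        if "library_size" in self.covariates.columns:
            return self.covariates["library_size"].to_numpy(dtype=float)
        if sp.issparse(self.counts):
            return np.asarray(self.counts.sum(axis=0)).ravel().astype(float)
        return self.counts.sum(axis=0).astype(float)

    def validate(self) -> None:
        if self.counts.shape != (len(self.response_ids), len(self.cell_ids)):
            raise DimensionError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.response_ids)} responses x {len(self.cell_ids)} cells"
            )
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        if data.size and data.min() < 0:
            raise FormatError("counts contain negative entries")
        cells = set(self.cell_ids)
        missing = set(self.grna_assignment["cell_id"]) - cells
        if missing:
            raise DimensionError(
                f"{len(missing)} assigned cell ids absent from counts columns"
            )
        unknown = set(self.grna_assignment["grna_id"]) - set(self.grna_table.index)
        if unknown:
            raise DimensionError(f"gRNA ids missing from metadata: {sorted(unknown)[:5]}")
        if list(self.covariates.index) != list(self.cell_ids):
            raise DimensionError("covariate rows do not align with cell_ids")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "grna_id": str}, **kw)
    except Exception as exc:  # noqa: BLE001 - rewrap with file name
        raise FormatError(f"failed to parse TSV {path}: {exc}") from exc


def _read_counts(counts_path: str) -> tuple[np.ndarray | sp.csr_matrix, list[str], list[str]]:
    if counts_path.endswith(".mtx"):
        d = os.path.dirname(counts_path)
        try:
            mat = mmread(counts_path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"malformed MatrixMarket file {counts_path}: {exc}") from exc
        mat = sp.csr_matrix(mat)
        if mat.data.size and mat.data.min() < 0:
            raise FormatError(f"{counts_path}: negative count entry")
        mat.data = mat.data.astype(np.int64)
        with open(os.path.join(d, "response_ids.txt")) as fh:
            response_ids = [line.strip() for line in fh if line.strip()]
        with open(os.path.join(d, "cell_ids.txt")) as fh:
            cell_ids = [line.strip() for line in fh if line.strip()]
        return mat, response_ids, cell_ids
    df = _read_tsv(counts_path, index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{counts_path}: non-numeric count entries")
    if arr.size and arr.min() < 0:
        raise FormatError(f"{counts_path}: negative count entry")
    return arr.astype(np.int64), [str(r) for r in df.index], [str(c) for c in df.columns]


def read_dataset(
    counts_path: str,
    grna_path: str,
    grna_meta_path: str,
    covariates_path: str | None = None,
) -> ScreenDataset:
    """Load a screen from disk (MTX + sidecars, or dense TSV) and validate it.

    Cells present in the count matrix but absent from the assignment table are
    dropped (with a logged count); the reverse is an error.
    """
    counts, response_ids, cell_ids = _read_counts(counts_path)
    assignment = _read_tsv(grna_path)
    for col in ("cell_id", "grna_id"):
        if col not in assignment.columns:
            raise FormatError(f"{grna_path}: missing required column '{col}'")
    grna_table = _read_tsv(grna_meta_path)
    if "grna_id" not in grna_table.columns:
        raise FormatError(f"{grna_meta_path}: missing required column 'grna_id'")
    grna_table = grna_table.set_index("grna_id")
    if "targeting" in grna_table.columns:
        grna_table["targeting"] = grna_table["targeting"].astype(bool)

    assigned = set(assignment["cell_id"])
    keep = [i for i, c in enumerate(cell_ids) if c in assigned]
    dropped = len(cell_ids) - len(keep)
    if dropped:
        logger.info("dropping %d cells without a gRNA assignment", dropped)
        counts = counts[:, keep]
        cell_ids = [cell_ids[i] for i in keep]

    if covariates_path is not None:
        cov = _read_tsv(covariates_path)
        if "cell_id" not in cov.columns:
            raise FormatError(f"{covariates_path}: missing required column 'cell_id'")
        cov = cov.set_index("cell_id").reindex(cell_ids)
    else:
        cov = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))

    ds = ScreenDataset(
        counts=counts,
        response_ids=response_ids,
        cell_ids=cell_ids,
        grna_assignment=assignment[["cell_id", "grna_id"]].copy(),
        grna_table=grna_table,
        covariates=cov,
        filter_report={"cells_without_assignment": dropped},
    )
    ds.validate()
    return ds


def write_dataset(ds: ScreenDataset, out_dir: str, fmt: str = "mtx") -> None:
    """Write a dataset in the same dialects :func:`read_dataset` reads."""
    os.makedirs(out_dir, exist_ok=True)
    if fmt == "mtx":
        mat = sp.coo_matrix(ds.counts)
        mmwrite(os.path.join(out_dir, "counts.mtx"), mat, field="integer")
        with open(os.path.join(out_dir, "response_ids.txt"), "w") as fh:
            fh.write("\n".join(ds.response_ids) + "\n")
        with open(os.path.join(out_dir, "cell_ids.txt"), "w") as fh:
            fh.write("\n".join(ds.cell_ids) + "\n")
    elif fmt == "tsv":
        arr = ds.counts.toarray() if sp.issparse(ds.counts) else ds.counts
        pd.DataFrame(arr, index=ds.response_ids, columns=ds.cell_ids).to_csv(
            os.path.join(out_dir, "counts.tsv"), sep="\t", index_label="response_id"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    ds.grna_assignment.to_csv(os.path.join(out_dir, "grna_assignment.tsv"), sep="\t", index=False)
    ds.grna_table.reset_index().to_csv(os.path.join(out_dir, "grna_table.tsv"), sep="\t", index=False)
    ds.covariates.reset_index().rename(columns={"index": "cell_id"}).to_csv(
        os.path.join(out_dir, "covariates.tsv"), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def _subset_cells(ds: ScreenDataset, keep_idx: np.ndarray) -> ScreenDataset:
    cell_ids = [ds.cell_ids[i] for i in keep_idx]
    kept = set(cell_ids)
    return replace(
        ds,
        counts=ds.counts[:, keep_idx],
        cell_ids=cell_ids,
        grna_assignment=ds.grna_assignment[ds.grna_assignment["cell_id"].isin(kept)].reset_index(drop=True),
        covariates=ds.covariates.loc[cell_ids],
    )


def apply_dataset_qc(ds: ScreenDataset, thr: QCThresholds | None = None) -> ScreenDataset:
    """Apply the three uniform filters (cells, then genes, then gRNAs).

    Removing a gRNA also removes its cells, which changes per-gene nonzero
    fractions, so the cells -> genes -> gRNAs pass iterates to a fixed point;
    the result satisfies all three filters simultaneously and the operation
    is idempotent.
    """
    thr = thr or QCThresholds()
    report = dict(ds.filter_report)
    report.setdefault("cells_multi_grna", 0)
    report.setdefault("genes_low_expression", 0)
    report.setdefault("grnas_low_cell_count", 0)
    report.setdefault("cells_of_removed_grnas", 0)

    while True:
        changed = False

        # cells: exactly one gRNA
        if thr.require_single_grna:
            per_cell = ds.grna_assignment["cell_id"].value_counts()
            bad = set(per_cell.index[per_cell != 1])
            keep = np.array([i for i, c in enumerate(ds.cell_ids) if c not in bad], dtype=int)
            if len(keep) < ds.n_cells:
                report["cells_multi_grna"] += ds.n_cells - len(keep)
                ds = _subset_cells(ds, keep)
                changed = True

        if ds.n_cells == 0:
            raise EmptyDatasetError("QC removed all cells")

        # genes: nonzero fraction over retained cells
        if sp.issparse(ds.counts):
            nnz = ds.counts.getnnz(axis=1)
        else:
            nnz = (ds.counts > 0).sum(axis=1)
        frac = nnz / ds.n_cells
        keep_genes = np.flatnonzero(frac >= thr.min_gene_frac)
        if len(keep_genes) < ds.n_responses:
            report["genes_low_expression"] += ds.n_responses - len(keep_genes)
            ds = replace(
                ds,
                counts=ds.counts[keep_genes, :],
                response_ids=[ds.response_ids[i] for i in keep_genes],
            )
            changed = True

        # gRNAs: minimum cell count; their cells go with them
        per_grna = ds.grna_assignment["grna_id"].value_counts()
        bad_grnas = set(per_grna.index[per_grna < thr.min_cells_per_grna])
        bad_grnas |= set(ds.grna_table.index) - set(per_grna.index)  # zero cells
        if bad_grnas:
            report["grnas_low_cell_count"] += len(bad_grnas)
            bad_cells = set(
                ds.grna_assignment.loc[
                    ds.grna_assignment["grna_id"].isin(bad_grnas), "cell_id"
                ]
            )
            keep = np.array([i for i, c in enumerate(ds.cell_ids) if c not in bad_cells], dtype=int)
            report["cells_of_removed_grnas"] += ds.n_cells - len(keep)
            ds = _subset_cells(ds, keep)
            ds = replace(ds, grna_table=ds.grna_table.drop(index=sorted(bad_grnas)))
            changed = True

        if ds.n_cells == 0:
            raise EmptyDatasetError("QC removed all cells")
        if not changed:
            break

    ds = replace(ds, filter_report=report)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Covariate matrix
# ---------------------------------------------------------------------------

_DERIVED = ("library_size",)


def build_covariate_matrix(ds: ScreenDataset, formula: list[str] | None = None) -> pd.DataFrame:
    """Expand named technical factors into a full-rank numeric design matrix.

    The first column is always an intercept of ones.  Numeric factors with all
    positive values are natural-log transformed; categorical factors are
    reference-coded (first sorted level dropped).  ``library_size`` is derived
    from the count matrix when not present in the covariate table.
    """
    if formula is None:
        formula = [c for c in ds.covariates.columns]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(ds.n_cells)}
    for name in formula:
        if name in ds.covariates.columns:
            series = ds.covariates[name]
        elif name == "library_size":
            series = pd.Series(ds.library_sizes(), index=ds.cell_ids)
        else:
            raise KeyError(f"unknown covariate {name!r}")
        if pd.api.types.is_numeric_dtype(series):
            vals = series.to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"covariate {name!r} has non-finite values")
            if np.all(vals > 0):
                vals = np.log(vals)
            if np.ptp(vals) == 0:
                raise CollinearityError(f"covariate {name!r} is constant")
            cols[name] = vals
        else:
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                raise CollinearityError(f"categorical covariate {name!r} has one level")
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (series.astype(str) == lev).astype(float).to_numpy()
    Z = pd.DataFrame(cols, index=ds.cell_ids)
    mat = Z.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise CollinearityError("covariate matrix is rank deficient")
    return Z
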