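"""Expression-matrix and gene-panel I/O.

The canonical in-memory orientation is genes x samples: rows are gene ids,
columns are sample ids. Files may be stored either way; readers transpose on
the fly. TSV/CSV files carry a header row of sample ids and a first column of
gene ids. Sparse matrices use MatrixMarket coordinate format with sidecar
``<prefix>.genes.txt`` / ``<prefix>.samples.txt`` label files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import (
    FormatError,
    NonNegativityError,
    ParameterError,
    ParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

Orientation = Literal["genes-by-samples", "samples-by-genes"]
NonNegMode = Literal["reject", "shift", "clip"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValidationError(f"duplicate {what} id: {name!r}")
        seen.add(name)


@dataclass
class ExpressionMatrix:
    """A labeled non-negative genes x samples expression matrix.

    Attributes
    ----------
    values
        Real ``(m, n)`` array, ``m`` genes by ``n`` samples. Entries must be
        finite; non-negativity is required by the factorization routines and
        enforced via :func:`enforce_nonnegativity`.
    gene_ids, sample_ids
        Unique row / column labels.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValidationError(f"expected a 2-D matrix, got ndim={self.values.ndim}")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValidationError(f"matrix must be at least 2x2, got {m}x{n}")
        if len(self.gene_ids) != m:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite entry at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GenePanel:
    """An ordered list of unique gene symbols (e.g. a pyroptosis panel)."""

    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        if not self.names:
            raise ValidationError("gene panel is empty")
        seen: set[str] = set()
        for name in self.names:
            key = name.casefold()
            if key in seen:
                raise ValidationError(f"duplicate panel gene (case-insensitive): {name!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.names)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".tsv":
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx-triplet"
    raise FormatError(f"cannot infer format from suffix {suffix!r}; pass fmt explicitly")


def _read_labeled_table(path: Path, sep: str) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path, sep=sep, index_col=0, header=0, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not read {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"{path}: no data columns found (missing labels?)")
    if frame.index.hasnans or any(str(c).startswith("Unnamed:") for c in frame.columns):
        raise FormatError(f"{path}: missing row or column labels")
    for col in frame.columns:
        if frame[col].dtype == object:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[np.flatnonzero(bad)[0]]
                raise ParseError(
                    f"{path}: non-numeric cell at row {row!r}, column {col!r}"
                )
            frame[col] = coerced
    if frame.isna().any().any():
        i, j = np.argwhere(frame.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: NaN entry at row {frame.index[i]!r}, column {frame.columns[j]!r}"
        )
    return frame


def _read_mtx_triplet(path: Path) -> pd.DataFrame:
    prefix = path.with_suffix("")
    genes_file = prefix.with_suffix(".genes.txt")
    samples_file = prefix.with_suffix(".samples.txt")
    for sidecar in (genes_file, samples_file):
        if not sidecar.exists():
            raise FormatError(f"missing sidecar label file {sidecar}")
    matrix = scipy.io.mmread(path)
    if scipy.sparse.issparse(matrix):
        matrix = matrix.toarray()
    genes = genes_file.read_text().split()
    samples = samples_file.read_text().split()
    if matrix.shape != (len(genes), len(samples)):
        raise FormatError(
            f"{path}: matrix is {matrix.shape} but sidecars list "
            f"{len(genes)} genes and {len(samples)} samples"
        )
    return pd.DataFrame(np.asarray(matrix, dtype=float), index=genes, columns=samples)


def read_expression_matrix(
    path: str | Path,
    fmt: str | None = None,
    orientation: Orientation = "genes-by-samples",
) -> ExpressionMatrix:
    """Read a labeled expression matrix from TSV, CSV or MatrixMarket triplet.

    ``orientation`` describes the file on disk; the returned matrix is always
    genes x samples.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or _infer_format(path)
    if fmt == "tsv":
        frame = _read_labeled_table(path, sep="\t")
    elif fmt == "csv":
        frame = _read_labeled_table(path, sep=",")
    elif fmt == "mtx-triplet":
        frame = _read_mtx_triplet(path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if orientation == "samples-by-genes":
        frame = frame.T
    elif orientation != "genes-by-samples":
        raise ParameterError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(
        values=frame.to_numpy(dtype=float),
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
    )


def write_expression_matrix(
    X: ExpressionMatrix, path: str | Path, fmt: str | None = None
) -> None:
    """Write genes x samples TSV/CSV at full float precision (round-trip exact)."""
    path = Path(path)
    fmt = fmt or _infer_format(path)
    if fmt not in ("tsv", "csv"):
        raise FormatError(f"write supports tsv/csv, not {fmt!r}")
    X.to_frame().to_csv(path, sep="\t" if fmt == "tsv" else ",")


def read_gene_panel(path: str | Path) -> GenePanel:
    """Read a plain-text gene panel: one symbol per line, ``#`` comments allowed."""
    names: list[str] = []
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry:
            names.append(entry)
    return GenePanel(names=names)


def enforce_nonnegativity(X: ExpressionMatrix, mode: NonNegMode = "reject") -> ExpressionMatrix:
    """Ensure all entries are >= 0.

    reject
        Raise :class:`NonNegativityError` if any entry is negative (default,
        so data are never silently altered).
    shift
        Subtract the global minimum when it is negative, i.e. add ``|min|``
        to every entry; preserves all pairwise differences.
    clip
        Set negative entries to zero.
    """
    values = X.values
    min_val = values.min()
    if min_val >= 0:
        return X
    if mode == "reject":
        i, j = np.argwhere(values == min_val)[0]
        raise NonNegativityError(
            f"negative entry {min_val} at gene {X.gene_ids[i]!r}, "
            f"sample {X.sample_ids[j]!r} (mode='reject'); use 'shift' or 'clip'"
        )
    if mode == "shift":
        logger.info("shifting matrix by %g to remove negatives", -min_val)
        shifted = values - min_val
    elif mode == "clip":
        n_neg = int((values < 0).sum())
        logger.info("clipping %d negative entries to zero", n_neg)
        shifted = np.maximum(values, 0.0)
    else:
        raise ParameterError(f"unknown non-negativity mode {mode!r}")
    return ExpressionMatrix(shifted, list(X.gene_ids), list(X.sample_ids))


def subset_genes(
    X: ExpressionMatrix, panel: GenePanel, case_sensitive: bool = False
) -> ExpressionMatrix:
    """Restrict rows to the panel genes, preserving the matrix's row order.

    Panel genes absent from the matrix are counted and logged, not fatal.
    Matching is case-insensitive by default because public microarray
    platforms mix symbol cases.
    """
    if case_sensitive:
        wanted = set(panel.names)
        keep = [i for i, g in enumerate(X.gene_ids) if g in wanted]
        found = {X.gene_ids[i] for i in keep}
        missing = [g for g in panel.names if g not in found]
    else:
        wanted = {g.casefold() for g in panel.names}
        keep = [i for i, g in enumerate(X.gene_ids) if g.casefold() in wanted]
        found = {X.gene_ids[i].casefold() for i in keep}
        missing = [g for g in panel.names if g.casefold() not in found]
    if not keep:
        raise ValidationError("no panel gene found in the matrix; nothing to factorize")
    if missing:
        logger.info("%d panel genes not found: %s", len(missing), ", ".join(missing[:10]))
    return ExpressionMatrix(
        X.values[keep, :],
        [X.gene_ids[i] for i in keep],
        list(X.sample_ids),
    )
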