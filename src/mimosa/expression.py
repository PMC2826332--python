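"""Expression-matrix I/O, validation and row normalization.

The analysis operates on a genes × samples matrix ``M[i, k]`` whose rows are
z-scored to mean 0 and variance 1 (population convention, so that a
normalized row satisfies ``sum(z**2) == N_s`` exactly).  Gene pairs are
extracted as aligned ``(x_k, y_k)`` observation vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PairData",
    "ExpressionDataError",
    "read_matrix",
    "write_matrix",
    "normalize_rows",
    "extract_pair",
]


class ExpressionDataError(ValueError):
    """Malformed or degenerate expression input."""


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix.

    Parameters
    ----------
    gene_ids
        Unique row identifiers, length ``n_genes``.
    sample_ids
        Unique column identifiers, length ``n_samples``.
    values
        Float matrix of shape ``(n_genes, n_samples)``.
    normalized
        True once every row has been z-scored (mean 0, variance 1).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    normalized: bool = False
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ExpressionDataError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExpressionDataError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ExpressionDataError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if np.isnan(self.values).any():
            raise ExpressionDataError("expression matrix contains missing values")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._index[gene_id]]
        except KeyError:
            raise ExpressionDataError(f"unknown gene id: {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PairData:
    """Aligned observation vectors ``(x_k, y_k)`` for one gene pair."""

    x: np.ndarray
    y: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ExpressionDataError("pair vectors must be 1-d and equal length")
        if len(self.x) < 3:
            raise ExpressionDataError("a gene pair needs at least 3 samples")
        if len(self.sample_ids) != len(self.x):
            raise ExpressionDataError("sample ids not aligned with pair vectors")

    @property
    def n_samples(self) -> int:
        return len(self.x)


def read_matrix(
    path, *, delimiter: str = "\t", missing: str = "error"
) -> ExpressionMatrix:
    """Read a delimited genes × samples matrix.

    The file has a header row of sample identifiers and gene identifiers in
    the first column.  ``missing`` selects the policy for rows with empty or
    NA cells: ``"error"`` (default) rejects the file, ``"drop"`` removes the
    offending gene rows with a logged warning.
    """
    if missing not in ("error", "drop"):
        raise ValueError(f"unknown missing-value policy: {missing!r}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    dup = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dup):
        raise ExpressionDataError(f"duplicate gene id: {dup[0]!r}")
    if len(sample_ids) < 3:
        raise ExpressionDataError(
            f"need at least 3 samples, found {len(sample_ids)}"
        )
    raw = df.to_numpy(dtype=object)
    was_present = pd.notna(raw)
    numeric = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = was_present & np.isnan(numeric)
    if bad.any():
        i, k = np.argwhere(bad)[0]
        raise ExpressionDataError(
            f"non-numeric value {raw[i, k]!r} for gene {gene_ids[i]!r}, "
            f"sample {sample_ids[k]!r}"
        )
    hole = np.isnan(numeric)
    if hole.any():
        rows = np.unique(np.argwhere(hole)[:, 0])
        if missing == "error":
            raise ExpressionDataError(
                f"missing value for gene {gene_ids[rows[0]]!r}"
            )
        dropped = [gene_ids[i] for i in rows]
        logger.warning("dropping %d gene(s) with missing values: %s",
                       len(dropped), ", ".join(dropped[:10]))
        keep = np.setdiff1d(np.arange(len(gene_ids)), rows)
        gene_ids = [gene_ids[i] for i in keep]
        numeric = numeric[keep]
    return ExpressionMatrix(gene_ids, sample_ids, numeric, normalized=False)


def write_matrix(m: ExpressionMatrix, path, *, delimiter: str = "\t") -> None:
    """Write the matrix back to a delimited text file (round-trippable)."""
    m.to_frame().to_csv(path, sep=delimiter, index_label="gene")


def normalize_rows(m: ExpressionMatrix, *, ddof: int = 0) -> ExpressionMatrix:
    """Z-score every row to mean 0, variance 1.

    ``ddof=0`` (default) uses the population variance convention; ``ddof=1``
    the sample convention.  Constant rows cannot be normalized and raise.
    Idempotent: re-normalizing changes nothing beyond rounding error.
    """
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=ddof, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0.0)
    if len(flat):
        raise ExpressionDataError(
            f"constant expression for gene {m.gene_ids[flat[0]]!r}; "
            "cannot be normalized"
        )
    out = replace(m, values=(m.values - mu) / sd, normalized=True)
    return out


def extract_pair(m: ExpressionMatrix, gene_a: str, gene_b: str) -> PairData:
    """Extract the aligned ``(x, y)`` vectors for a gene pair.

    ``gene_a`` plays the TF/regulator role (x), ``gene_b`` the target (y).
    The matrix must be normalized first; sample order is preserved.
    """
    if not m.normalized:
        raise ExpressionDataError("matrix must be normalized before pair extraction")
    return PairData(m.row(gene_a).copy(), m.row(gene_b).copy(), list(m.sample_ids))
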