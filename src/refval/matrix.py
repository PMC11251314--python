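"""Gene × condition TPM expression matrix.

The container every pipeline stage works on: rows are genes, columns are
biological conditions, cells are mean TPM (transcripts per million) values.
Replicates are averaged *before* this container exists — either upstream by
the user (table input) or by :func:`refval.io.read_salmon_quants`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


class ExpressionMatrix:
    """Rectangular table of mean TPM values, genes × conditions.

    Parameters
    ----------
    data : pandas.DataFrame
        Gene identifiers in the index, condition labels in the columns,
        non-negative finite TPM values in the cells.

    Raises
    ------
    ValueError
        If identifiers are blank or duplicated, fewer than two condition
        columns are present, condition labels are duplicated, or any value
        is missing, negative or non-finite.
    """

    def __init__(self, data: pd.DataFrame):
        data = data.copy()
        data.index = data.index.map(
            lambda g: "" if g is None or (isinstance(g, float) and np.isnan(g)) else str(g).strip()
        )
        data.columns = data.columns.map(str)
        data.index.name = None
        data.columns.name = None

        if (data.index == "").any():
            raise ValueError("blank gene identifier in input")
        dup = data.index[data.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene identifier(s): {sorted(set(dup))}")
        if data.shape[1] < 2:
            raise ValueError(
                f"need at least 2 condition columns, got {data.shape[1]}"
            )
        dup_c = data.columns[data.columns.duplicated()]
        if len(dup_c):
            raise ValueError(f"duplicate condition label(s): {sorted(set(dup_c))}")

        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric TPM value: {exc}") from exc
        if np.isnan(values).any():
            gene, cond = self._first_bad_cell(data, np.isnan(values))
            raise ValueError(f"missing value for gene {gene!r}, condition {cond!r}")
        if not np.isfinite(values).all():
            gene, cond = self._first_bad_cell(data, ~np.isfinite(values))
            raise ValueError(f"non-finite value for gene {gene!r}, condition {cond!r}")
        if (values < 0).any():
            gene, cond = self._first_bad_cell(data, values < 0)
            raise ValueError(f"negative TPM for gene {gene!r}, condition {cond!r}")

        self._data = pd.DataFrame(values, index=data.index, columns=data.columns)

    @staticmethod
    def _first_bad_cell(data: pd.DataFrame, mask: np.ndarray) -> tuple[str, str]:
        i, j = np.argwhere(mask)[0]
        return str(data.index[i]), str(data.columns[j])

    @classmethod
    def from_values(
        cls,
        gene_ids: Sequence[str],
        condition_labels: Sequence[str],
        values,
    ) -> "ExpressionMatrix":
        """Build a matrix from parallel arrays (genes × conditions)."""
        arr = np.asarray(values, dtype=float).reshape(len(gene_ids), len(condition_labels))
        return cls(pd.DataFrame(arr, index=list(gene_ids), columns=list(condition_labels)))

    # -- accessors ---------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        """The underlying genes × conditions DataFrame (float64)."""
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def condition_labels(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self._data.shape[0]

    @property
    def n_conditions(self) -> int:
        return self._data.shape[1]

    def to_samples_frame(self) -> pd.DataFrame:
        """Transpose to the estimator layout: conditions as rows (samples),
        genes as columns (features)."""
        return self._data.T

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_conditions} conditions)"
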