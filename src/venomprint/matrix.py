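"""The presence/absence marker matrix (individuals x markers).

Cells are strictly 0/1; missing data are not supported — the protocol
re-runs ambiguous samples instead of scoring them as unknown. Per-replicate
sub-rows are optionally retained for duplicate-based quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MatrixFormatError


def _validate_binary(df: pd.DataFrame, what: str) -> pd.DataFrame:
    values = df.to_numpy()
    if values.size and not np.isin(values, [0, 1]).all():
        bad = sorted(set(values.ravel()) - {0, 1})
        raise MatrixFormatError(f"{what} contains non-binary cells: {bad}")
    return df.astype(np.int8)


@dataclass
class BinaryMatrix:
    """Individuals x markers 0/1 table, with optional replicate bookkeeping.

    ``data`` is indexed by individual id with marker labels as columns.
    ``replicates``, when present, is indexed by (individual_id, replicate_id)
    over the same marker columns and holds the per-run rows that the
    consensus in ``data`` was derived from.
    """

    data: pd.DataFrame
    replicates: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = _validate_binary(self.data, "matrix")
        if self.data.index.has_duplicates:
            raise MatrixFormatError("duplicate individual ids")
        if self.data.columns.has_duplicates:
            raise MatrixFormatError("duplicate marker labels")
        if self.replicates is not None:
            self.replicates = _validate_binary(self.replicates, "replicate rows")
            if list(self.replicates.columns) != list(self.data.columns):
                raise MatrixFormatError("replicate rows must share the matrix's markers")

    @classmethod
    def from_rows(
        cls,
        rows: dict[str, dict[str, int]],
        marker_labels: list[str] | None = None,
    ) -> "BinaryMatrix":
        df = pd.DataFrame.from_dict(rows, orient="index")
        if marker_labels is not None:
            df = df.reindex(columns=marker_labels)
        return cls(data=df.fillna(0))

    @property
    def individual_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def marker_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    def select_markers(self, labels: list[str]) -> "BinaryMatrix":
        """Sub-matrix on `labels`, preserving order; replicates follow along."""
        reps = self.replicates[labels] if self.replicates is not None else None
        return BinaryMatrix(data=self.data[labels], replicates=reps)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinaryMatrix):
            return NotImplemented
        return self.data.equals(other.data)
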