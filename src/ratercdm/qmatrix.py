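"""Q-matrix container and CSV round-trip.

A Q-matrix is the binary item-by-attribute loading structure of a cognitive
diagnosis model: entry ``q[j, k] = 1`` declares that item ``j`` requires
attribute ``k``.  Every item must require at least one attribute and every
attribute must be required by at least one item, otherwise the latent class
structure is degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QMatrix:
    """Binary item × attribute matrix.

    Parameters
    ----------
    entries
        Array of shape ``(n_items, n_attributes)`` with entries in {0, 1}.
    attribute_names
        Optional column labels; defaults to ``A1 .. AK``.
    """

    entries: np.ndarray
    attribute_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        q = np.asarray(self.entries, dtype=int)
        if q.ndim != 2:
            raise ValueError("Q-matrix must be two-dimensional (items × attributes)")
        if not np.isin(q, (0, 1)).all():
            bad = np.argwhere(~np.isin(q, (0, 1)))
            raise ValueError(f"Q-matrix entries must be 0/1; offending cells {bad[:5].tolist()}")
        empty_rows = np.flatnonzero(q.sum(axis=1) == 0)
        if empty_rows.size:
            raise ValueError(f"items {empty_rows.tolist()} require no attribute")
        empty_cols = np.flatnonzero(q.sum(axis=0) == 0)
        if empty_cols.size:
            raise ValueError(f"attributes {empty_cols.tolist()} are required by no item")
        object.__setattr__(self, "entries", q)
        names = self.attribute_names or tuple(f"A{k + 1}" for k in range(q.shape[1]))
        if len(names) != q.shape[1]:
            raise ValueError("attribute_names length does not match the number of columns")
        object.__setattr__(self, "attribute_names", tuple(names))

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def required(self, item: int) -> tuple[int, ...]:
        """Indices of the attributes required by ``item``."""
        return tuple(np.flatnonzero(self.entries[item]))

    def row(self, item: int) -> np.ndarray:
        return self.entries[item]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=list(self.attribute_names))


def read_qmatrix(path) -> QMatrix:
    """Read a Q-matrix CSV (header of attribute names, one 0/1 row per item)."""
    frame = pd.read_csv(path)
    try:
        return QMatrix(frame.to_numpy(), tuple(str(c) for c in frame.columns))
    except ValueError as err:
        raise ValueError(f"invalid Q-matrix in {path}: {err}") from err


def write_qmatrix(qmatrix: QMatrix, path) -> None:
    qmatrix.to_frame().to_csv(path, index=False)
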