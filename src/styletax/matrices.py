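"""Square style-by-style matrices.

Rows index the target style, columns the distractor style, matching the
orientation of the published accuracy / reaction-time matrices. The diagonal
(a style against itself) is undefined and carried as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .records import StyleSet

#: Allowed statistic tags.
STATISTICS = (
    "accuracy",
    "mean_rt",
    "effective_rt",
    "similarity",
    "distance",
    "asymmetry",
)


@dataclass
class PairMatrix:
    """|S| x |S| real matrix keyed (target-row, distractor-column)."""

    styles: StyleSet
    values: np.ndarray
    statistic: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.styles)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match roster of {n} styles"
            )
        if self.statistic not in STATISTICS:
            raise ValueError(f"statistic must be one of {STATISTICS}, got {self.statistic!r}")

    def __getitem__(self, key: tuple[str, str]) -> float:
        t, d = key
        return float(self.values[self.styles.index(t), self.styles.index(d)])

    def __setitem__(self, key: tuple[str, str], value: float) -> None:
        t, d = key
        self.values[self.styles.index(t), self.styles.index(d)] = value

    @classmethod
    def empty(cls, styles: StyleSet, statistic: str) -> "PairMatrix":
        n = len(styles)
        return cls(styles=styles, values=np.full((n, n), np.nan), statistic=statistic)

    def off_diagonal(self) -> np.ndarray:
        """All off-diagonal values as a flat array."""
        n = len(self.styles)
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]

    @property
    def is_symmetric(self) -> bool:
        a = np.nan_to_num(self.values, nan=0.0, posinf=np.finfo(float).max)
        return bool(np.allclose(a, a.T, equal_nan=True))

    def missing_pairs(self) -> list[tuple[str, str]]:
        """Ordered off-diagonal pairs whose cell is NaN."""
        out = []
        labels = self.styles.labels
        for i, t in enumerate(labels):
            for j, d in enumerate(labels):
                if i != j and np.isnan(self.values[i, j]):
                    out.append((t, d))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.styles.labels, columns=self.styles.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, statistic: str) -> "PairMatrix":
        labels = tuple(str(c) for c in frame.columns)
        if tuple(str(i) for i in frame.index) != labels:
            raise ValueError("row and column labels must match")
        return cls(styles=StyleSet(labels), values=frame.to_numpy(dtype=float), statistic=statistic)


def require_same_roster(a: PairMatrix, b: PairMatrix) -> None:
    if a.styles.labels != b.styles.labels:
        raise ValueError(
            f"style rosters differ: {a.styles.labels} vs {b.styles.labels}"
        )


def condensed_upper(values: np.ndarray) -> np.ndarray:
    """Upper-triangle (excluding diagonal) of a square matrix, row-major."""
    values = np.asarray(values, dtype=float)
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]
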