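"""Shared container for per-trajectory feature matrices fed to clustering."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["DescriptionMatrix"]


@dataclass
class DescriptionMatrix:
    """N-by-d matrix of per-trajectory feature vectors.

    Rows follow the trajectory order of the originating set.  The
    ``normalization`` record documents the scheme applied (z-score or
    min-max with the constants), so that novel trajectories can be
    projected into the same space without re-fitting.
    """

    values: np.ndarray
    ids: tuple[str, ...]
    column_labels: tuple[str, ...]
    normalization: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {vals.shape}")
        if vals.shape[0] != len(self.ids):
            raise ValueError(
                f"{vals.shape[0]} rows but {len(self.ids)} trajectory ids"
            )
        if vals.shape[1] != len(self.column_labels):
            raise ValueError(
                f"{vals.shape[1]} columns but {len(self.column_labels)} labels"
            )
        if not np.isfinite(vals).all():
            raise ValueError("description matrix contains non-finite entries")
        self.values = vals
        self.ids = tuple(str(i) for i in self.ids)
        self.column_labels = tuple(str(c) for c in self.column_labels)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.ids), columns=list(self.column_labels)
        )
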