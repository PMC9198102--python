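"""Tabular container for radiomics feature vectors with sample metadata."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "META_COLUMNS"]

#: Non-feature columns, in canonical order.
META_COLUMNS = ("patient_id", "point_id", "roi", "label")


@dataclass
class FeatureTable:
    """Samples x named features, one row per (patient, point, ROI/ensemble).

    Wraps a :class:`pandas.DataFrame` whose first columns are the metadata
    columns of :data:`META_COLUMNS` followed by the feature columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing metadata columns: {missing}")
        names = list(self.feature_names)
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ValueError(f"duplicate feature names: {dupes}")
        # canonical column order: metadata first
        self.data = self.data[[*META_COLUMNS, *names]]

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def feature_matrix(self) -> np.ndarray:
        """Feature values as a float (n_samples, n_features) array."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    def binary_labels(self, positive: str = "BM") -> np.ndarray:
        """0/1 label vector with ``positive`` mapped to 1."""
        return (self.data["label"].astype(str) == positive).to_numpy(dtype=int)

    def select_rows(self, mask) -> "FeatureTable":
        return FeatureTable(self.data.loc[mask].reset_index(drop=True))
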