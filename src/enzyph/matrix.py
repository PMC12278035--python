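"""Labelled feature-matrix container with CSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import LABEL_TO_INT

_INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}


@dataclass
class FeatureMatrix:
    """Sequences x named features, with ids and integer class labels.

    Labels follow the package coding acid = 0, alkaline = 1.  Column names
    are unique and ordered deterministically (188D block first, then the
    cross-covariance block when present).
    """

    ids: list[str]
    labels: np.ndarray
    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        n, m = self.X.shape
        if len(self.ids) != n or len(self.labels) != n:
            raise ValueError("ids, labels and rows must align")
        if len(self.names) != m:
            raise ValueError("names must match the number of columns")
        if len(set(self.names)) != m:
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column(self, name_or_index) -> np.ndarray:
        i = (self.names.index(name_or_index)
             if isinstance(name_or_index, str) else int(name_or_index))
        return self.X[:, i]

    def subset(self, indices) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(self.ids, self.labels, self.X[:, indices],
                             [self.names[i] for i in indices])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "label", [_INT_TO_LABEL[v] for v in self.labels])
        df.insert(0, "id", self.ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["id", "label"]:
            raise ValueError(f"{path}: expected leading columns 'id,label'")
        labels = df["label"].map(LABEL_TO_INT)
        if labels.isna().any():
            raise ValueError(f"{path}: labels must be 'acid' or 'alkaline'")
        return cls(ids=df["id"].astype(str).tolist(),
                   labels=labels.to_numpy(),
                   X=df.iloc[:, 2:].to_numpy(dtype=float),
                   names=list(df.columns[2:]))
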