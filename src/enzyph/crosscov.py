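"""Cross-covariance (CC) features between physicochemical index profiles.

A sequence is mapped to one numeric profile per physicochemical index
(e.g. hydrophobicity, hydrophilicity); the CC value for an ordered index
pair (u1, u2) at lag ``lg`` is the mean product of the mean-centred u1
profile and the u2 profile shifted by ``lg``:

    CC(u1, u2, lg) = sum_{i=1}^{L-lg} (P_u1(R_i) - mean_u1)
                                      (P_u2(R_{i+lg}) - mean_u2) / (L - lg)

where the means are taken over the whole sequence (sequence-wise centring,
so adding a constant to an index table leaves all CC values unchanged).

The full block enumerates all ordered pairs of distinct indices and lags
1..LG, giving N(N-1)·LG features.  The default configuration (N = 2 indices,
LG = 6) yields 12 features, for a 200-dimensional combined vector together
with the 188D block.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .properties import DEFAULT_INDEX_TABLES, PropertyIndexTable, encode

DEFAULT_MAX_LAG = 6


def cc_value(sequence: str, u1: PropertyIndexTable, u2: PropertyIndexTable,
             lg: int) -> float:
    """Cross-covariance of indices ``u1`` and ``u2`` at lag ``lg``.

    Requires ``1 <= lg <= L - 1``.  The same table may be passed for both
    arguments, in which case this is the profile's autocovariance.
    """
    codes = encode(sequence)
    L = codes.size
    if not 1 <= lg <= L - 1:
        raise ValueError(f"lag must satisfy 1 <= lg <= L-1 (L={L}, lg={lg})")
    v1 = u1.as_array()[codes]
    v2 = u2.as_array()[codes]
    d1 = v1 - v1.mean()
    d2 = v2 - v2.mean()
    return float(d1[: L - lg] @ d2[lg:] / (L - lg))


def extract_cc(sequence: str,
               tables: tuple[PropertyIndexTable, ...] = DEFAULT_INDEX_TABLES,
               max_lag: int = DEFAULT_MAX_LAG) -> np.ndarray:
    """All-ordered-pair CC block: N(N-1)·max_lag values.

    Pairs are enumerated in table order (u1 outer, u2 inner, u1 != u2),
    each with lags 1..max_lag.  The sequence must be longer than max_lag.
    """
    n = len(tables)
    if n < 2:
        raise ValueError("at least 2 index tables required")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    codes = encode(sequence)
    L = codes.size
    if L <= max_lag:
        raise ValueError(f"sequence length {L} must exceed max_lag {max_lag}")
    profiles = [t.as_array()[codes] for t in tables]
    centred = [p - p.mean() for p in profiles]
    out = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            for lg in range(1, max_lag + 1):
                out.append(centred[i][: L - lg] @ centred[j][lg:] / (L - lg))
    return np.array(out)


def cc_feature_names(tables: tuple[PropertyIndexTable, ...] = DEFAULT_INDEX_TABLES,
                     max_lag: int = DEFAULT_MAX_LAG) -> list[str]:
    """Names ``<u1>x<u2>.lag<lg>`` in the same order as :func:`extract_cc`."""
    return [
        f"{tables[i].name}x{tables[j].name}.lag{lg}"
        for i in range(len(tables))
        for j in range(len(tables))
        if i != j
        for lg in range(1, max_lag + 1)
    ]


class CrossCovarianceExtractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: sequences -> cross-covariance feature matrix.

    Parameters
    ----------
    tables : tuple of PropertyIndexTable, optional
        Standardised physicochemical indices; defaults to hydrophobicity
        and hydrophilicity (N = 2).
    max_lag : int
        Maximum sequence lag LG (default 6).
    """

    def __init__(self, tables: tuple[PropertyIndexTable, ...] | None = None,
                 max_lag: int = DEFAULT_MAX_LAG):
        self.tables = tables
        self.max_lag = max_lag

    def _resolved(self) -> tuple[PropertyIndexTable, ...]:
        return DEFAULT_INDEX_TABLES if self.tables is None else tuple(self.tables)

    def fit(self, X, y=None):
        tables = self._resolved()
        if len(tables) < 2:
            raise ValueError("at least 2 index tables required")
        self.feature_names_ = cc_feature_names(tables, self.max_lag)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        tables = self._resolved()
        seqs = [getattr(x, "sequence", x) for x in X]
        return np.array([extract_cc(s, tables, self.max_lag) for s in seqs])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
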