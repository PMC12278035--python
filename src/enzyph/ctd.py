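"""The 188-dimensional physicochemical sequence descriptor.

The vector concatenates:

* 20 amino-acid composition features — the frequency ``n_i / L`` of each
  residue in fixed alphabetical order;
* for each of 8 physicochemical properties, 21 features derived from that
  property's 3-group partition of the alphabet:

  - 3 **composition** fractions (residues in each group / L);
  - 15 **distribution** values — for each group, the relative sequence
    positions (1-based position / L) of the first occurrence and of the
    25%, 50%, 75% and last occurrences of the group's residues, using the
    ``ceil(q·n)``-th occurrence for the interior quantiles;
  - 3 **bivalent frequencies** — counts of adjacent residue pairs whose
    members fall in two *different* groups (pairs {1,2}, {1,3}, {2,3},
    order within the pair ignored), each divided by ``L - 1``.

Totals: 20 + 8 x 21 = 188.  With the default property order, 1-based index
43 is the composition fraction of the medium normalized-van-der-Waals-volume
group (``NVEQIL``) — the descriptor on which acid- and alkaline-adapted
enzymes separate.

:class:`CTD188Extractor` wraps the computation as a scikit-learn
transformer over lists of sequences.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .properties import ALPHABET, DEFAULT_GROUPINGS, PropertyGrouping, encode

N_FEATURES_188 = 188

#: 1-based index of the key discriminative feature: composition of group 2
#: (medium) of the second default property, normalized van der Waals volume.
KEY_FEATURE_INDEX = 43

_QUANTILES = (0, 25, 50, 75, 100)
_GROUP_PAIRS = ((0, 1), (0, 2), (1, 2))


def aac_features(sequence: str) -> np.ndarray:
    """Amino-acid composition: frequency of each residue, alphabet order.

    Sums to 1 for any non-empty sequence.
    """
    codes = encode(sequence)
    if codes.size == 0:
        raise ValueError("empty sequence")
    return np.bincount(codes, minlength=20) / codes.size


def composition_features(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Fraction of residues in each of the grouping's 3 groups (sums to 1)."""
    codes = encode(sequence)
    if codes.size == 0:
        raise ValueError("empty sequence")
    gids = grouping.group_ids()[codes]
    return np.bincount(gids, minlength=3) / codes.size


def distribution_features(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Positional quantiles of each group's occurrences, 5 per group.

    For a group occurring at 1-based positions ``p_1 < ... < p_n`` the five
    values are ``p_1/L``, ``p_ceil(0.25 n)/L``, ``p_ceil(0.5 n)/L``,
    ``p_ceil(0.75 n)/L`` and ``p_n/L``.  A group with no occurrences
    contributes five zeros.  Output order: group 1's 5 values, then group
    2's, then group 3's.
    """
    codes = encode(sequence)
    L = codes.size
    if L == 0:
        raise ValueError("empty sequence")
    gids = grouping.group_ids()[codes]
    out = np.zeros(15)
    for g in range(3):
        pos = np.flatnonzero(gids == g) + 1  # 1-based
        n = pos.size
        if n == 0:
            continue
        idx = [0] + [math.ceil(q / 100 * n) - 1 for q in (25, 50, 75)] + [n - 1]
        out[5 * g: 5 * g + 5] = pos[idx] / L
    return out


def bivalent_frequency_features(sequence: str, grouping: PropertyGrouping) -> np.ndarray:
    """Cross-group adjacent-pair frequencies for pairs {1,2}, {1,3}, {2,3}.

    Each count of adjacent residue pairs whose two members lie in the two
    groups of the pair (in either order) is divided by ``L - 1``.  Requires
    length >= 2.
    """
    codes = encode(sequence)
    L = codes.size
    if L < 2:
        raise ValueError("bivalent frequencies need a sequence of length >= 2")
    gids = grouping.group_ids()[codes]
    a, b = gids[:-1], gids[1:]
    out = np.empty(3)
    for k, (g1, g2) in enumerate(_GROUP_PAIRS):
        out[k] = (((a == g1) & (b == g2)) | ((a == g2) & (b == g1))).sum()
    return out / (L - 1)


def extract_188d(sequence: str,
                 groupings: tuple[PropertyGrouping, ...] = DEFAULT_GROUPINGS) -> np.ndarray:
    """Compute the full 188-dimensional descriptor for one sequence.

    ``groupings`` must contain exactly 8 property partitions in the
    canonical order; the sequence must have length >= 2.
    """
    if len(groupings) != 8:
        raise ValueError(f"exactly 8 property groupings required, got {len(groupings)}")
    blocks = [aac_features(sequence)]
    for grouping in groupings:
        blocks.append(composition_features(sequence, grouping))
        blocks.append(distribution_features(sequence, grouping))
        blocks.append(bivalent_frequency_features(sequence, grouping))
    return np.concatenate(blocks)


def feature_names_188(groupings: tuple[PropertyGrouping, ...] = DEFAULT_GROUPINGS) -> list[str]:
    """Canonical names of the 188 descriptor entries, in vector order.

    Layout: the 1-based index of composition feature ``g`` of property ``k``
    is ``20 + 21(k-1) + g``; distribution and bivalent entries follow within
    each property block.
    """
    if len(groupings) != 8:
        raise ValueError(f"exactly 8 property groupings required, got {len(groupings)}")
    names = [f"aac.{aa}" for aa in ALPHABET]
    for grouping in groupings:
        p = grouping.name
        names += [f"{p}.composition.{g}" for g in (1, 2, 3)]
        names += [f"{p}.distribution.g{g}.p{q}" for g in (1, 2, 3) for q in _QUANTILES]
        names += [f"{p}.bivalent.g{g1}g{g2}" for g1, g2 in ((1, 2), (1, 3), (2, 3))]
    return names


class CTD188Extractor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: sequences -> 188D descriptor matrix.

    Parameters
    ----------
    groupings : tuple of PropertyGrouping, optional
        The 8 property partitions; defaults to the canonical set with
        normalized van der Waals volume second.

    ``transform`` accepts a list of residue strings (or objects with a
    ``sequence`` attribute) and returns an ``(n_sequences, 188)`` array.
    """

    def __init__(self, groupings: tuple[PropertyGrouping, ...] | None = None):
        self.groupings = groupings

    def _resolved(self) -> tuple[PropertyGrouping, ...]:
        return DEFAULT_GROUPINGS if self.groupings is None else tuple(self.groupings)

    def fit(self, X, y=None):
        groupings = self._resolved()
        if len(groupings) != 8:
            raise ValueError("exactly 8 property groupings required")
        self.feature_names_ = feature_names_188(groupings)
        self.n_features_out_ = N_FEATURES_188
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        groupings = self._resolved()
        seqs = [getattr(x, "sequence", x) for x in X]
        return np.array([extract_188d(s, groupings) for s in seqs])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
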