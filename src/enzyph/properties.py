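"""Physicochemical property tables for protein sequence descriptors.

Two kinds of table live here:

* :class:`PropertyGrouping` — a partition of the 20 standard amino acids
  into three ordered groups (low / medium / high) for one physicochemical
  property.  These drive the composition / distribution / bivalent-frequency
  blocks of the 188-dimensional descriptor.
* :class:`PropertyIndexTable` — a per-residue numeric index (one number per
  amino acid) used by the cross-covariance features.

The default grouping set covers the eight classic properties of the CTD
descriptor family (hydrophobicity, normalized van der Waals volume, polarity,
polarizability, charge, surface tension, secondary-structure propensity,
solvent accessibility).  The property order is fixed: normalized van der
Waals volume is always the second property, which pins the 1-based descriptor
index 43 to the composition fraction of its medium-volume group — the key
discriminative feature for pH adaptation.

Both kinds of table can be overridden from a YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: The 20 standard amino acids, in the fixed alphabetical order used for
#: every residue-indexed vector in this package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_CODE = {aa: i for i, aa in enumerate(ALPHABET)}


def encode(sequence: str) -> np.ndarray:
    """Encode a residue string as integer codes 0..19 (alphabet order).

    Raises ``ValueError`` naming the offending residue if the sequence
    contains a character outside the 20-letter alphabet.
    """
    try:
        return np.fromiter((_CODE[aa] for aa in sequence), dtype=np.int64,
                           count=len(sequence))
    except KeyError as exc:
        raise ValueError(
            f"non-standard residue {exc.args[0]!r} in sequence"
        ) from None


@dataclass(frozen=True)
class PropertyGrouping:
    """A named 3-way partition of the amino-acid alphabet.

    Group order is meaningful: group 2 is the "medium" class of the
    property (e.g. medium van der Waals volume).
    """

    name: str
    groups: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(self.groups) != 3:
            raise ValueError(f"{self.name}: exactly 3 groups required")
        residues = "".join(self.groups)
        if sorted(residues) != sorted(ALPHABET):
            raise ValueError(
                f"{self.name}: groups must partition the 20-letter alphabet, "
                f"got {''.join(sorted(residues))!r}"
            )

    def group_ids(self) -> np.ndarray:
        """Residue code -> group id (0, 1, 2), as a length-20 array."""
        ids = np.empty(20, dtype=np.int64)
        for g, members in enumerate(self.groups):
            for aa in members:
                ids[_CODE[aa]] = g
        return ids


@dataclass(frozen=True)
class PropertyIndexTable:
    """A per-residue numeric physicochemical index.

    ``values`` maps every one of the 20 standard residues to a number.
    ``normalized`` records whether the table has been standardised to zero
    mean and unit standard deviation across the 20 residues.
    """

    name: str
    values: dict = field(compare=False)
    normalized: bool = False

    def __post_init__(self) -> None:
        if sorted(self.values) != sorted(ALPHABET):
            raise ValueError(
                f"{self.name}: index table must cover exactly the 20 "
                "standard residues"
            )
        if self.normalized:
            arr = self.as_array()
            if abs(arr.mean()) > 1e-9 or abs(arr.std() - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: normalized table must have mean 0 / SD 1"
                )

    def as_array(self) -> np.ndarray:
        """Index values in alphabet order (length 20)."""
        return np.array([self.values[aa] for aa in ALPHABET], dtype=float)

    def normalize(self) -> "PropertyIndexTable":
        """Return a zero-mean, unit-SD copy (population SD over 20 residues)."""
        arr = self.as_array()
        std = arr.std()
        if std == 0:
            raise ValueError(f"{self.name}: constant index cannot be normalized")
        norm = (arr - arr.mean()) / std
        return PropertyIndexTable(
            name=self.name,
            values={aa: float(v) for aa, v in zip(ALPHABET, norm)},
            normalized=True,
        )


# The eight classic CTD property partitions.  Group order is
# low / medium / high in the property's numeric scale; the display labels
# used by some sources for hydrophobicity ("strong/moderately/weakly
# hydrophobic") are not interpreted — only membership matters.
DEFAULT_GROUPINGS: tuple[PropertyGrouping, ...] = (
    PropertyGrouping("hydrophobicity", ("RKEDQN", "GASTPHY", "CVLIMFW")),
    PropertyGrouping("normalized_vdw_volume", ("GASTPDC", "NVEQIL", "MHKFRYW")),
    PropertyGrouping("polarity", ("LIFWCMVY", "PATGS", "HQRKNED")),
    PropertyGrouping("polarizability", ("GASDT", "CPNVEQIL", "KMHFRYW")),
    PropertyGrouping("charge", ("KR", "ANCQGHILMFPSTWYV", "DE")),
    PropertyGrouping("surface_tension", ("GQDNAHR", "KTSEC", "ILMFPWYV")),
    PropertyGrouping("secondary_structure", ("EALMQKRH", "VIYCWFT", "GNPSD")),
    PropertyGrouping("solvent_accessibility", ("ALFCGIVW", "RKQEND", "MPSTHY")),
)

#: Residues of the medium normalized-van-der-Waals-volume group (group 2 of
#: the second default property).  The synthetic-data generator plants its
#: class contrast on the composition of exactly this group.
MEDIUM_VDW_RESIDUES = DEFAULT_GROUPINGS[1].groups[1]

# Kyte-Doolittle hydropathy.
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Hopp-Woods hydrophilicity.
_HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2,
    "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0,
    "M": -1.3, "F": -2.5, "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4,
    "Y": -2.3, "V": -1.5,
}

#: Default index tables for the cross-covariance block: two standardised
#: indices (N = 2), giving N(N-1)·LG = 12 cross-covariance features at the
#: default maximum lag of 6 and hence a 200-dimensional combined vector.
DEFAULT_INDEX_TABLES: tuple[PropertyIndexTable, ...] = (
    PropertyIndexTable("hydrophobicity", _KYTE_DOOLITTLE).normalize(),
    PropertyIndexTable("hydrophilicity", _HOPP_WOODS).normalize(),
)


def load_groupings(path) -> tuple[PropertyGrouping, ...]:
    """Load property groupings from a YAML file.

    Expected layout: a list of ``{name, group1, group2, group3}`` mappings
    with residues given as strings.  Each entry is validated as a partition
    of the alphabet.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return tuple(
        PropertyGrouping(e["name"], (e["group1"], e["group2"], e["group3"]))
        for e in entries
    )


def load_index_tables(path, normalize: bool = True) -> tuple[PropertyIndexTable, ...]:
    """Load cross-covariance index tables from a YAML file.

    Expected layout: a list of mappings with a ``name`` key plus one key per
    residue.  Tables are standardised to zero mean / unit SD unless
    ``normalize`` is false.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    tables = []
    for e in entries:
        values = {aa: float(e[aa]) for aa in ALPHABET}
        t = PropertyIndexTable(e["name"], values)
        tables.append(t.normalize() if normalize else t)
    return tuple(tables)
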