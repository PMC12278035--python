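"""Reading, validating, labelling and filtering protein sequences.

Sequences arrive as FASTA, with class labels assigned either from which
file a sequence was read from (two-file convention: one FASTA per class)
or from a two-column TSV label table.  Inputs are assumed pre-deduplicated;
no identity-based redundancy filtering is performed here.

Two validation modes are offered for residues outside the 20-letter standard
alphabet (B, J, O, U, X, Z, ...): ``strict`` rejects the record with an error
naming the record and residue, while ``lenient`` drops the offending residues
with a warning.  The descriptor groupings are defined only on the 20 standard
residues, so one of the two has to happen before feature extraction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .properties import ALPHABET

logger = logging.getLogger(__name__)

ACID, ALKALINE, UNLABELED = "acid", "alkaline", "unlabeled"
LABELS = (ACID, ALKALINE, UNLABELED)

#: Integer coding of class labels used throughout: acid = 0, alkaline = 1.
LABEL_TO_INT = {ACID: 0, ALKALINE: 1}

_ALPHABET_SET = frozenset(ALPHABET)


@dataclass
class ProteinRecord:
    """One labelled amino-acid sequence."""

    id: str
    sequence: str
    label: str = UNLABELED

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r} for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def _clean_sequence(rec_id: str, raw: str, strict: bool) -> str:
    seq = raw.upper()
    if not seq:
        raise ValueError(f"record {rec_id!r} has an empty sequence")
    bad = sorted(set(seq) - _ALPHABET_SET)
    if not bad:
        return seq
    if strict:
        raise ValueError(
            f"record {rec_id!r} contains non-standard residue(s) "
            f"{', '.join(repr(b) for b in bad)}"
        )
    warnings.warn(
        f"record {rec_id!r}: dropping {sum(seq.count(b) for b in bad)} "
        f"non-standard residue(s) {', '.join(repr(b) for b in bad)}",
        stacklevel=2,
    )
    kept = "".join(aa for aa in seq if aa in _ALPHABET_SET)
    if not kept:
        raise ValueError(f"record {rec_id!r} has no standard residues left")
    return kept


def read_fasta(path, label: str = UNLABELED, strict: bool = True) -> list[ProteinRecord]:
    """Read a FASTA file into labelled, uppercased, validated records.

    Parameters
    ----------
    path : file path
        FASTA file; must exist and contain at least one record.
    label : str
        Class label applied to every record in the file
        (``"acid"``, ``"alkaline"`` or ``"unlabeled"``).
    strict : bool
        If true, a record containing a residue outside the 20-letter
        alphabet raises; otherwise those residues are dropped with a
        warning.

    Record order is preserved.
    """
    records = [
        ProteinRecord(rec.id, _clean_sequence(rec.id, str(rec.seq), strict), label)
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path) -> None:
    """Write records to FASTA (sequence on a single line per record)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seqs)


def read_label_table(path) -> dict[str, str]:
    """Read a two-column TSV label table with header ``id<TAB>label``."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["id", "label"]:
            raise ValueError(f"label table {path} must start with 'id\\tlabel'")
        for line in fh:
            if not line.strip():
                continue
            rec_id, label = line.rstrip("\n").split("\t")[:2]
            if label not in LABELS:
                raise ValueError(f"unknown label {label!r} for id {rec_id!r}")
            labels[rec_id] = label
    return labels


def write_label_table(records: list[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for r in records:
            fh.write(f"{r.id}\t{r.label}\n")


def apply_labels(records: list[ProteinRecord], labels: dict[str, str]) -> list[ProteinRecord]:
    """Return records relabelled from an id -> label mapping."""
    missing = [r.id for r in records if r.id not in labels]
    if missing:
        raise ValueError(f"no label for record(s): {', '.join(missing[:5])}")
    return [ProteinRecord(r.id, r.sequence, labels[r.id]) for r in records]


def filter_min_length(records: list[ProteinRecord], min_len: int = 100) -> list[ProteinRecord]:
    """Drop sequences shorter than ``min_len`` residues (default 100).

    Relative order is preserved; the number removed is logged.  Idempotent.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    kept = [r for r in records if len(r) >= min_len]
    removed = len(records) - len(kept)
    if removed:
        logger.info("filter_min_length: removed %d of %d sequences shorter than %d",
                    removed, len(records), min_len)
    return kept
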