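"""Sequence primitives, coordinate conventions, and FASTA I/O.

All coordinates in this package are 0-based, half-open on the top (gene-sense)
strand.  A cut *junction* at index ``j`` denotes the backbone break between
positions ``j - 1`` and ``j`` of the top strand, so a deletion of the interval
``[u, v)`` spans the break iff ``u <= j - 1`` and ``v >= j``.

Sequences are plain upper-case ``str`` over the unambiguous alphabet
``{A, C, G, T}``.  Lower-case input is folded to upper case; IUPAC ambiguity
codes (including ``N``) are rejected rather than coerced, because the exact
string-matching operations downstream (microhomology search, arm validation,
dimer scanning) are undefined for ambiguous bases.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "SequenceError",
    "as_seq",
    "check_junction",
    "revcomp",
    "complement_base",
    "read_fasta",
    "write_fasta",
]

ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SequenceError(ValueError):
    """Raised for malformed sequences, coordinates, or FASTA records."""


def as_seq(text: str, *, allow_empty: bool = False) -> str:
    """Validate and normalize a nucleotide string.

    Folds case, rejects anything outside ``ACGT``.  Empty sequences are
    rejected unless the caller explicitly permits them (e.g. an edit payload
    of a pure deletion oligo).
    """
    s = str(text).upper()
    if not s:
        if allow_empty:
            return s
        raise SequenceError("empty sequence not permitted here")
    bad = set(s) - ALPHABET
    if bad:
        raise SequenceError(
            f"sequence contains non-ACGT characters: {sorted(bad)!r} "
            "(ambiguity codes are rejected, not coerced)"
        )
    return s


def check_junction(index: int, seq: str) -> int:
    """Validate a cut junction: strictly interior to ``seq``."""
    index = int(index)
    if not 0 < index < len(seq):
        raise SequenceError(
            f"junction {index} not interior to sequence of length {len(seq)}"
        )
    return index


def complement_base(base: str) -> str:
    try:
        return _COMP_BASE[base]
    except KeyError:
        raise SequenceError(f"cannot complement non-ACGT base {base!r}") from None


def revcomp(s: str) -> str:
    """Watson-Crick reverse complement of an unambiguous DNA string."""
    s = as_seq(s, allow_empty=True)
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA into ``[(name, sequence), ...]``.

    Sequences are validated/case-folded; duplicate record names are an error.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA record name {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, as_seq(str(rec.seq))))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(name, sequence)`` pairs as FASTA, wrapped at 60 columns."""
    seqrecs = [
        SeqRecord(Seq(as_seq(seq)), id=name, description="")
        for name, seq in records
    ]
    names = [r.id for r in seqrecs]
    if len(names) != len(set(names)):
        raise SequenceError("duplicate record names in FASTA output")
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seqrecs)
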