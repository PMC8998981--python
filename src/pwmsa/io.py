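"""Sequence and alignment data model plus FASTA/Clustal readers and writers.

The in-memory containers are deliberately small: a protein sequence is an
id plus a string over the 20 canonical amino-acid letters, a sequence set
adds the count ``N`` and mean length, and a multiple alignment is a
rectangular block of residue/gap characters whose rows de-gap back to the
input sequences.  File parsing and writing go through Biopython
(``Bio.SeqIO`` / ``Bio.AlignIO``); validation against the 20-letter
alphabet is done here because the downstream position weight matrices have
exactly one row per amino acid and ambiguity codes have no row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, in alphabetical order.  Row order of every
#: position weight matrix in the package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SIZE = len(ALPHABET)
_ALPHA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

GAP = "-"

#: Ambiguity / non-standard codes rejected in strict mode.
AMBIGUOUS = set("BJOUXZ*")


class FastaError(ValueError):
    """Malformed or empty sequence input."""


class DuplicateIdError(FastaError):
    """Two records share an id."""


class IllegalResidueError(FastaError):
    """A residue outside the 20-letter amino-acid alphabet (strict mode)."""


class AlignmentError(ValueError):
    """Malformed multiple-alignment input."""


def encode(residues: str) -> np.ndarray:
    """Map a residue string to int codes 0..19 (row indices of a PWM)."""
    try:
        return np.fromiter((_ALPHA_INDEX[c] for c in residues), dtype=np.int64,
                           count=len(residues))
    except KeyError as exc:  # pragma: no cover - guarded by validation
        raise IllegalResidueError(f"illegal residue {exc}") from exc


def decode(codes: Iterable[int]) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)


@dataclass(frozen=True)
class ProteinSequence:
    """One protein sequence: an id and residues over the 20-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be nonempty")
        if len(self.residues) < 1:
            raise FastaError(f"sequence {self.id!r} is empty")
        bad = [i for i, c in enumerate(self.residues) if c not in _ALPHA_INDEX]
        if bad:
            raise IllegalResidueError(
                f"record {self.id!r}: illegal residue {self.residues[bad[0]]!r} "
                f"at offset {bad[0]}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.residues)


@dataclass(frozen=True)
class SequenceSet:
    """A set of protein sequences with its count N and mean length."""

    sequences: tuple[ProteinSequence, ...]

    def __init__(self, sequences: Sequence[ProteinSequence]):
        seqs = tuple(sequences)
        if len(seqs) < 1:
            raise FastaError("sequence set is empty")
        seen: set[str] = set()
        for s in seqs:
            if s.id in seen:
                raise DuplicateIdError(f"duplicate sequence id {s.id!r}")
            seen.add(s.id)
        object.__setattr__(self, "sequences", seqs)

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def mean_length(self) -> float:
        return float(np.mean([len(s) for s in self.sequences]))

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, i: int) -> ProteinSequence:
        return self.sequences[i]

    def residue_frequencies(self) -> np.ndarray:
        """Empirical frequencies of the 20 residues pooled over the set."""
        counts = np.zeros(ALPHABET_SIZE, dtype=float)
        for s in self.sequences:
            counts += np.bincount(s.codes, minlength=ALPHABET_SIZE)
        return counts / counts.sum()


@dataclass(frozen=True)
class MultipleAlignment:
    """alpha rows of equal length K over the amino-acid alphabet plus '-'.

    Invariants enforced at construction: equal row lengths, legal
    characters, no all-gap column, no all-gap row.
    """

    row_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __init__(self, row_ids: Sequence[str], rows: Sequence[str]):
        ids = tuple(row_ids)
        rws = tuple(r.replace(".", GAP) for r in rows)
        if len(ids) != len(rws):
            raise AlignmentError("row_ids and rows differ in length")
        if not rws:
            raise AlignmentError("empty alignment")
        k = len(rws[0])
        if k == 0:
            raise AlignmentError("alignment has zero columns")
        for rid, row in zip(ids, rws):
            if len(row) != k:
                raise AlignmentError(
                    f"row {rid!r} has length {len(row)}, expected {k}"
                )
            for c in row:
                if c != GAP and c not in _ALPHA_INDEX:
                    raise AlignmentError(f"row {rid!r}: illegal character {c!r}")
            if all(c == GAP for c in row):
                raise AlignmentError(f"row {rid!r} is all gaps")
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("duplicate row ids in alignment")
        for j in range(k):
            if all(row[j] == GAP for row in rws):
                raise AlignmentError(f"column {j} consists entirely of gaps")
        object.__setattr__(self, "row_ids", ids)
        object.__setattr__(self, "rows", rws)

    @property
    def alpha(self) -> int:
        return len(self.rows)

    @property
    def k(self) -> int:
        return len(self.rows[0])

    def degap(self) -> SequenceSet:
        """Strip gaps from every row, recovering the unaligned sequences."""
        return SequenceSet(
            [ProteinSequence(rid, row.replace(GAP, ""))
             for rid, row in zip(self.row_ids, self.rows)]
        )

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def residue_count(self, j: int) -> int:
        """Number of non-gap characters in column j."""
        return sum(1 for row in self.rows if row[j] != GAP)


# ---------------------------------------------------------------------------
# file I/O


def _sanitize(residues: str, record_id: str, strict: bool,
              placeholder: str) -> str:
    out = residues.upper()
    if strict:
        for off, c in enumerate(out):
            if c not in _ALPHA_INDEX:
                raise IllegalResidueError(
                    f"record {record_id!r}: illegal residue {c!r} at offset {off}"
                )
        return out
    mapped = []
    warned = False
    for c in out:
        if c in _ALPHA_INDEX:
            mapped.append(c)
        else:
            if not warned:
                warnings.warn(
                    f"record {record_id!r}: mapping non-standard residues "
                    f"to {placeholder!r}"
                )
                warned = True
            mapped.append(placeholder)
    return "".join(mapped)


def read_fasta(path: str | Path, strict: bool = True,
               placeholder: str = "A") -> SequenceSet:
    """Read unaligned protein FASTA into a :class:`SequenceSet`.

    In strict mode (default) ambiguity codes (B/J/O/U/X/Z and '*') raise
    :class:`IllegalResidueError` naming the record and offset; in lenient
    mode they are mapped to ``placeholder`` with a warning.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    seqs = []
    for rec in records:
        seqs.append(ProteinSequence(
            rec.id, _sanitize(str(rec.seq), rec.id, strict, placeholder)
        ))
    return SequenceSet(seqs)


def write_fasta(si: SequenceSet, path: str | Path) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="")
               for s in si]
    SeqIO.write(records, str(path), "fasta")


def _looks_like_clustal(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.upper().startswith("CLUSTAL")


def read_alignment(path: str | Path, fmt: str | None = None,
                   strict: bool = True) -> MultipleAlignment:
    """Read an aligned FASTA or Clustal file.

    ``fmt`` may be ``"fasta"``, ``"clustal"`` or ``None`` (sniff: a leading
    CLUSTAL header selects Clustal).  '.' gaps are normalized to '-'.
    """
    p = Path(path)
    if fmt is None:
        fmt = "clustal" if _looks_like_clustal(p) else "fasta"
    if fmt not in ("fasta", "clustal"):
        raise AlignmentError(f"unknown alignment format {fmt!r}")
    try:
        aln = AlignIO.read(str(p), fmt)
    except ValueError as exc:
        raise AlignmentError(f"cannot parse {p} as {fmt}: {exc}") from exc
    rows = []
    ids = []
    for rec in aln:
        raw = str(rec.seq).upper().replace(".", GAP)
        cleaned = []
        for c in raw:
            if c == GAP or c in _ALPHA_INDEX:
                cleaned.append(c)
            elif strict:
                raise IllegalResidueError(
                    f"record {rec.id!r}: illegal character {c!r}"
                )
            else:
                cleaned.append("A")
        ids.append(rec.id)
        rows.append("".join(cleaned))
    return MultipleAlignment(ids, rows)


def write_alignment(ma: MultipleAlignment, path: str | Path,
                    fmt: str = "fasta") -> None:
    """Write an alignment as aligned FASTA (60-char wrap) or Clustal."""
    if fmt not in ("fasta", "clustal"):
        raise AlignmentError(f"unknown alignment format {fmt!r}")
    records = [SeqRecord(Seq(row), id=rid, description="")
               for rid, row in zip(ma.row_ids, ma.rows)]
    AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)
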