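"""Sequence I/O and the shared sequence/alignment data contracts.

All coordinates in this package are 1-based closed intervals; conversions to
0-based numpy indexing are localized to this module's helpers.  The gap symbol
is ``-``.  ``N`` is allowed in reads but never in consensus sequences, and an
``N`` never counts as a match anywhere.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
READ_ALPHABET = frozenset("ACGTN")
CONSENSUS_ALPHABET = frozenset("ACGT")

# uint8 encoding used by the alignment and consensus machinery
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}
CODE_BASE = np.array(list("ACGT-N"))
_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in BASE_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN/- string as uint8 codes (A=0,C=1,G=2,T=3,-=4,N=5)."""
    arr = _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"invalid character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(CODE_BASE[codes])


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class ReadSet:
    """A species-tagged collection of genomic reads.

    ``total_bp`` is the total searched base count; it is the denominator of
    the copies-per-3-Gbp normalization downstream.
    """

    species: str
    reads: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate read ids in ReadSet")
        for rid, s in self.reads:
            if not set(s) <= READ_ALPHABET:
                raise ValueError(f"read {rid}: alphabet outside ACGTN")

    @property
    def total_bp(self) -> int:
        return sum(len(s) for _, s in self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class CpGMask:
    """1-based consensus columns excluded from divergence (CpG dinucleotides).

    Masked columns come in adjacent (C, G) pairs of the consensus.  Masked
    columns are *excluded* from both numerator and denominator of divergence,
    they are not replaced by gap characters.
    """

    consensus_id: str
    masked_columns: frozenset[int] = frozenset()

    def as_bool(self, length: int) -> np.ndarray:
        """Boolean vector of size ``length``; True where the column is masked."""
        m = np.zeros(length, dtype=bool)
        if self.masked_columns:
            idx = np.fromiter(self.masked_columns, dtype=np.int64)
            if idx.min() < 1 or idx.max() > length:
                raise ValueError("masked column outside [1, length]")
            m[idx - 1] = True
        return m


def cpg_mask(consensus: str, consensus_id: str = "") -> CpGMask:
    """Mask exactly the column pairs (i, i+1) where consensus has C then G."""
    if not consensus:
        raise ValueError("empty consensus")
    cols: set[int] = set()
    for i in range(len(consensus) - 1):
        if consensus[i] == "C" and consensus[i + 1] == "G":
            cols.add(i + 1)
            cols.add(i + 2)
    return CpGMask(consensus_id=consensus_id, masked_columns=frozenset(cols))


@dataclass
class AnchoredAlignment:
    """Reads projected onto the column frame of one consensus.

    Row *i*, column *j* holds the read base aligned to consensus position
    ``j+1`` (1-based); columns outside a read's aligned span are gaps.  Read
    insertions relative to the consensus are dropped by construction, so every
    row has exactly ``columns`` columns.
    """

    consensus_id: str
    columns: int
    matrix: np.ndarray  # (rows, columns) uint8 codes
    row_ids: list[str]
    row_species: list[str]

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.columns:
            raise ValueError("matrix shape inconsistent with declared columns")
        if self.matrix.shape[0] != len(self.row_ids) or len(self.row_ids) != len(self.row_species):
            raise ValueError("row metadata length mismatch")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def row_strings(self) -> list[str]:
        return [decode(self.matrix[i]) for i in range(self.n_rows)]

    def subset(self, index: np.ndarray) -> "AnchoredAlignment":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AnchoredAlignment(
            consensus_id=self.consensus_id,
            columns=self.columns,
            matrix=self.matrix[idx],
            row_ids=[self.row_ids[i] for i in idx],
            row_species=[self.row_species[i] for i in idx],
        )


def _validate_fasta_text(text: str) -> None:
    in_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            in_record = True
        elif not in_record:
            raise FastaParseError("sequence data before first FASTA header", lineno)


def read_fasta(path: str | Path, species: str | None = None) -> ReadSet:
    """Read a FASTA file into a ReadSet; lowercase is uppercased.

    ``species`` defaults to the file stem.  Non-ACGTN characters are rejected.
    """
    path = Path(path)
    text = path.read_text()
    _validate_fasta_text(text)
    reads: list[tuple[str, str]] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        reads.append((rec.id, str(rec.seq).upper()))
    return ReadSet(species=species if species is not None else path.stem, reads=reads)


def write_fasta(readset: ReadSet | Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    items = readset.reads if isinstance(readset, ReadSet) else list(readset)
    with open(path, "w") as fh:
        for rid, s in items:
            fh.write(f">{rid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_aligned_fasta(aln: AnchoredAlignment, path: str | Path) -> None:
    write_fasta([(rid, row) for rid, row in zip(aln.row_ids, aln.row_strings())], path)
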