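"""FASTA input/output and numeric encoding of nucleotide sequences.

Sequences are mapped onto the ring of integers mod 4 (A=0, C=1, G=2, T=3)
so that a set of sequences becomes a real-valued matrix with one row per
sequence and one column per alignment position.  Gaps and ambiguity codes
are imputed under an explicit policy and flagged in a boolean mask, so
downstream linear algebra always sees values in {0, 1, 2, 3}.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "EncodedMatrix",
    "AlignerError",
    "read_fasta",
    "write_fasta",
    "encode_sequences",
    "decode_row",
    "align_external",
    "NUCLEOTIDE_TO_INT",
    "INT_TO_NUCLEOTIDE",
]

#: Fixed encoding of the four nucleotides onto Z4.  Any bijection is
#: equivalent up to relabeling; this one is fixed for reproducibility.
NUCLEOTIDE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3}
INT_TO_NUCLEOTIDE = {v: k for k, v in NUCLEOTIDE_TO_INT.items()}

#: Characters treated as missing data: alignment gaps and the ambiguity
#: code N.  Both are imputed by the gap policy and recorded in gap_mask.
GAP_CHARS = frozenset("-N")

_ALPHABET = frozenset("ACGTN-")


class AlignerError(RuntimeError):
    """External alignment failed or the aligner is unavailable."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N, -}.

    The sequence is stored uppercased; characters outside the alphabet
    raise ``ValueError`` at construction.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        up = self.seq.upper()
        bad = set(up) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside "
                f"{{A,C,G,T,N,-}}: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", up)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class EncodedMatrix:
    """Real matrix of Z4-encoded sequences (rows) by positions (columns).

    ``gap_mask`` is True exactly where the input had a gap, an N, or
    right-padding; those cells hold imputed values.  All entries are in
    {0, 1, 2, 3}.
    """

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("encoded matrix must be 2-d and non-empty")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.shape, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.values.shape:
            raise ValueError("gap_mask shape must match values")
        if not self.row_ids:
            self.row_ids = [f"row{i}" for i in range(self.values.shape[0])]
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("row_ids length must equal the number of rows")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Wrapped and single-line sequences are both accepted; record order is
    preserved and sequences are uppercased.  Raises ``FileNotFoundError``
    for a missing file and ``ValueError`` for an empty file or a record
    with an empty sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records to ``path`` in plain FASTA; inverse of :func:`read_fasta`."""
    if not records:
        raise ValueError("cannot write an empty record list")
    out = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")


def _impute_column(col: np.ndarray, mask: np.ndarray, policy: str) -> np.ndarray:
    """Fill masked cells of one encoded column per the gap policy."""
    if policy == "constant_zero" or mask.all():
        fill = 0
    else:
        # most frequent non-gap value; ties broken toward the smaller code
        vals = col[~mask].astype(int)
        fill = int(np.bincount(vals, minlength=4).argmax())
    out = col.copy()
    out[mask] = fill
    return out


def encode_sequences(
    records: list[SequenceRecord],
    gap_policy: str = "column_mode",
    pad_char: str = "-",
) -> EncodedMatrix:
    """Encode records as an m x M real matrix over {0,1,2,3}.

    Sequences shorter than the longest are right-padded with ``pad_char``
    before encoding, so M is the maximum input length.  Gap characters
    (``-`` and ``N``) and padding are imputed:

    - ``column_mode``: the most frequent non-gap value of the column
      (keeps entries in Z4 and avoids rank inflation from gap blocks);
    - ``constant_zero``: constant 0.

    The returned ``gap_mask`` is True exactly at imputed cells.
    """
    if not records:
        raise ValueError("no records to encode")
    if gap_policy not in ("column_mode", "constant_zero"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    M = max(len(r) for r in records)
    m = len(records)
    values = np.zeros((m, M), dtype=float)
    mask = np.zeros((m, M), dtype=bool)
    for i, rec in enumerate(records):
        padded = rec.seq.ljust(M, pad_char)
        for j, ch in enumerate(padded):
            if ch in GAP_CHARS:
                mask[i, j] = True
            else:
                values[i, j] = NUCLEOTIDE_TO_INT[ch]
    for j in range(M):
        if mask[:, j].any():
            values[:, j] = _impute_column(values[:, j], mask[:, j], gap_policy)
    return EncodedMatrix(values, [r.id for r in records], mask)


def decode_row(row: np.ndarray) -> str:
    """Inverse of the nucleotide encoding for a single Z4 row vector."""
    return "".join(INT_TO_NUCLEOTIDE[int(v) % 4] for v in np.asarray(row))


def align_external(
    records: list[SequenceRecord],
    command_template: str = "mafft --auto --quiet {input}",
) -> list[SequenceRecord]:
    """Align records by invoking an external aligner (MAFFT-style contract).

    ``command_template`` receives ``{input}`` (a temporary FASTA path) and
    must emit aligned FASTA on stdout.  The aligner is treated as a black
    box; this function only checks the contract: same ids in the same
    order, all output sequences of equal (gapped) length.

    Raises :class:`AlignerError` if the program is missing, exits
    non-zero, or violates the contract.  Equal-length simulated data
    never needs this step.
    """
    if not records:
        raise ValueError("no records to align")
    program = command_template.split()[0]
    if shutil.which(program) is None:
        raise AlignerError(
            f"external aligner {program!r} not found on PATH; install it or "
            "provide pre-aligned sequences"
        )
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "input.fasta"
        write_fasta(records, infile)
        cmd = command_template.format(input=str(infile))
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise AlignerError(
                f"aligner exited with status {proc.returncode}: "
                f"{proc.stderr.strip()[:500]}"
            )
        outfile = Path(tmp) / "aligned.fasta"
        outfile.write_text(proc.stdout)
        aligned = read_fasta(outfile)
    in_ids = [r.id for r in records]
    out_ids = [r.id for r in aligned]
    if sorted(in_ids) != sorted(out_ids):
        raise AlignerError("aligner changed the set of sequence ids")
    by_id = {r.id: r for r in aligned}
    aligned = [by_id[i] for i in in_ids]
    lengths = {len(r) for r in aligned}
    if len(lengths) != 1:
        raise AlignerError("aligned sequences do not have equal length")
    return aligned
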