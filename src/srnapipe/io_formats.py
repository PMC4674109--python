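"""Sequence and tabular IO.

FASTA/FASTQ parsing is delegated to Biopython (:mod:`Bio.SeqIO`); this module
adds the strict validation the pipeline relies on (nucleotide alphabet, quality
length, non-empty ids) and raises :class:`~srnapipe.errors.FormatError` with
the file and record position instead of silently coercing.

Tabular data are TSV with ``#``-prefixed comment lines.  Tag tables are keyed
by the tag sequence itself (tags are anonymous); miRNA tables are keyed by
miRNA name.  Library totals (total clean reads per library) travel with the
table in a ``#totals`` comment line.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ParameterError

_VALID_SEQ = re.compile(r"^[ACGTN]+$")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, optionally with Phred quality scores."""

    id: str
    seq: str
    description: str = ""
    qual: list[int] | None = None

    def __post_init__(self):
        if not self.id:
            raise ParameterError("sequence record id must be non-empty")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParameterError(
                f"quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _check_seq(seq: str, path, pos: int) -> str:
    seq = seq.upper()
    if not seq or not _VALID_SEQ.match(seq):
        raise FormatError(
            f"record {pos}: sequence contains characters outside A/C/G/T/N", path
        )
    return seq


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Raises :class:`FormatError` on empty ids or non-nucleotide residues.
    """
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise FormatError(str(exc), path) from exc
    for i, rec in enumerate(parsed, 1):
        if not rec.id:
            raise FormatError(f"record {i}: empty header", path)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, _check_seq(str(rec.seq), path, i), desc))
    return records


def write_fasta(records, path) -> None:
    bio = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_fastq(path) -> list[SequenceRecord]:
    """Read a Phred+33 FASTQ file, validating alphabet and quality length."""
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq"), 1):
            qual = rec.letter_annotations.get("phred_quality")
            seq = _check_seq(str(rec.seq), path, i)
            if qual is None or len(qual) != len(seq):
                raise FormatError(f"record {i}: quality/sequence length mismatch", path)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(SequenceRecord(rec.id, seq, desc, list(qual)))
    except FormatError:
        raise
    except FileNotFoundError:
        raise
    except ValueError as exc:
        # Biopython raises ValueError for truncated/mismatched FASTQ records
        raise FormatError(str(exc), path) from exc
    return records


def write_fastq(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.qual is None:
                raise ParameterError(f"record {r.id} has no quality scores")
            qstr = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# Count tables


@dataclass
class TagCountTable:
    """Raw counts of tags (or miRNAs) per library plus library totals.

    ``counts`` is a DataFrame indexed by tag sequence or miRNA id with one
    integer column per library.  ``totals`` holds the total number of clean
    reads per library; totals are at least the column sums of the annotated
    rows (tags not in the table still count toward the library total).
    """

    counts: pd.DataFrame
    totals: dict[str, int]
    key: str = "tag"

    def __post_init__(self):
        self.counts = self.counts.astype("int64")
        if (self.counts.to_numpy() < 0).any():
            raise ParameterError("counts must be nonnegative")
        for lib in self.counts.columns:
            if lib not in self.totals:
                raise ParameterError(f"missing library total for {lib!r}")
            if self.totals[lib] < 0:
                raise ParameterError(f"negative total for {lib!r}")

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TagCountTable)
            and self.key == other.key
            and dict(self.totals) == dict(other.totals)
            and self.counts.equals(other.counts)
        )


_INT_RE = re.compile(r"^\d+$")


def read_counts(path, key: str = "tag") -> TagCountTable:
    """Read a TSV count table written by :func:`write_counts`.

    Rejects negative or non-integer raw counts with a :class:`FormatError`
    naming the line.
    """
    totals: dict[str, int] = {}
    header: list[str] | None = None
    rows = []
    index = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#totals"):
                for part in line.split("\t")[1:]:
                    lib, _, val = part.partition("=")
                    if not _INT_RE.match(val):
                        raise FormatError(f"bad total {part!r}", path, lineno)
                    totals[lib] = int(val)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                if not header:
                    raise FormatError("header names no libraries", path, lineno)
                continue
            if len(fields) != len(header) + 1:
                raise FormatError(
                    f"expected {len(header) + 1} columns, got {len(fields)}",
                    path,
                    lineno,
                )
            for v in fields[1:]:
                if not _INT_RE.match(v):
                    raise FormatError(f"count {v!r} is not a nonnegative integer", path, lineno)
            index.append(fields[0])
            rows.append([int(v) for v in fields[1:]])
    if header is None:
        raise FormatError("missing header row", path)
    df = pd.DataFrame(rows, index=index, columns=header, dtype="int64")
    if not totals:
        totals = {lib: int(df[lib].sum()) for lib in header}
    return TagCountTable(df, totals, key=key)


def write_counts(table: TagCountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#totals\t" + "\t".join(f"{k}={v}" for k, v in table.totals.items()) + "\n")
        fh.write(table.key + "\t" + "\t".join(table.libraries) + "\n")
        for tag, row in table.counts.iterrows():
            fh.write(tag + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def format_sig(x: float, digits: int = 6) -> str:
    """Fixed 6-significant-digit formatting for normalized values."""
    if x == 0:
        return "0"
    if not math.isfinite(x):
        raise ParameterError(f"non-finite value {x!r}")
    return f"{x:.{digits}g}"


def write_table(df: pd.DataFrame, path, index_label: str, float_sig: int = 6) -> None:
    """Write a generic TSV result table with 6-sig-digit floats."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: format_sig(v, float_sig))
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index_label=index_label)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
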