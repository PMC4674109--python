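"""Raw reads -> clean, collapsed unique tags.

Cleaning removes the 3' adapter (exact leftmost match of at least
``min_adapter_overlap`` leading adapter bases), then filters inserts on
length (18-30 nt by default), ambiguous bases and mean Phred quality.
Reads with no adapter hit are dropped: without the adapter boundary the
insert length is unknown.  Collapsing produces one row per distinct insert
sequence with per-library multiplicities; the library total is the number
of clean reads, so tag counts always sum back to the clean-read count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError
from .io_formats import SequenceRecord, TagCountTable

REJECT_NO_ADAPTER = "no_adapter"
REJECT_TOO_SHORT = "too_short"
REJECT_TOO_LONG = "too_long"
REJECT_TOO_MANY_N = "too_many_n"
REJECT_LOW_QUALITY = "low_quality"

REASONS = (
    REJECT_NO_ADAPTER,
    REJECT_TOO_SHORT,
    REJECT_TOO_LONG,
    REJECT_TOO_MANY_N,
    REJECT_LOW_QUALITY,
)


@dataclass
class CleanParams:
    """Read-cleaning thresholds.

    ``min_len``/``max_len`` bound the insert length in nt; ``max_n`` caps
    ambiguous bases; ``min_mean_quality`` is a mean Phred threshold;
    ``min_adapter_overlap`` is the number of leading adapter bases that must
    match exactly for a trim.
    """

    adapter: str
    min_len: int = 18
    max_len: int = 30
    max_n: int = 0
    min_mean_quality: float = 20.0
    min_adapter_overlap: int = 6

    def __post_init__(self):
        self.adapter = self.adapter.upper()
        if not self.adapter:
            raise ParameterError("adapter must be non-empty")
        if self.min_len > self.max_len:
            raise ParameterError("min_len must be <= max_len")
        if min(self.min_len, self.max_n, self.min_adapter_overlap) < 0 or self.min_mean_quality < 0:
            raise ParameterError("thresholds must be nonnegative")


def trim_adapter(read: SequenceRecord, params: CleanParams) -> SequenceRecord | None:
    """Return the insert upstream of the leftmost adapter match, or None.

    The match probe is the first ``min_adapter_overlap`` bases of the adapter;
    a read with no occurrence is rejected (returns None).
    """
    probe = params.adapter[: params.min_adapter_overlap]
    pos = read.seq.find(probe)
    if pos < 0:
        return None
    return SequenceRecord(
        read.id,
        read.seq[:pos],
        read.description,
        read.qual[:pos] if read.qual is not None else None,
    )


def clean(
    reads: list[SequenceRecord], params: CleanParams
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Clean one library; returns surviving inserts and a rejection tally.

    Invariant: ``len(clean) + sum(tally.values()) == len(reads)``.
    """
    tally = {r: 0 for r in REASONS}
    out = []
    probe = params.adapter[: params.min_adapter_overlap]
    for read in reads:
        pos = read.seq.find(probe)
        if pos < 0:
            tally[REJECT_NO_ADAPTER] += 1
            continue
        seq = read.seq[:pos]
        if len(seq) < params.min_len:
            tally[REJECT_TOO_SHORT] += 1
            continue
        if len(seq) > params.max_len:
            tally[REJECT_TOO_LONG] += 1
            continue
        if seq.count("N") > params.max_n:
            tally[REJECT_TOO_MANY_N] += 1
            continue
        qual = read.qual[:pos] if read.qual is not None else None
        if qual and sum(qual) / len(qual) < params.min_mean_quality:
            tally[REJECT_LOW_QUALITY] += 1
            continue
        out.append(SequenceRecord(read.id, seq, read.description, qual))
    return out, tally


def collapse(libraries: dict[str, list[SequenceRecord]]) -> TagCountTable:
    """Collapse clean reads of several libraries into a unique-tag table.

    One row per distinct sequence; per-library count = read multiplicity;
    the library total is its clean-read count.
    """
    counters = {lib: Counter(r.seq for r in reads) for lib, reads in libraries.items()}
    tags = sorted(set().union(*[c.keys() for c in counters.values()]) if counters else set())
    df = pd.DataFrame(
        {lib: [counters[lib].get(t, 0) for t in tags] for lib in libraries},
        index=tags,
        dtype="int64",
    )
    totals = {lib: len(reads) for lib, reads in libraries.items()}
    return TagCountTable(df, totals, key="tag")


def size_distribution(table: TagCountTable) -> pd.DataFrame:
    """Length histogram: per length, total read count and unique tag count.

    Total mass is conserved: summing ``reads`` over lengths per library gives
    the number of clean reads represented in the table.
    """
    if len(table.counts) == 0:
        return pd.DataFrame(columns=[f"reads_{l}" for l in table.libraries] + ["tags"])
    lengths = table.counts.index.str.len()
    grouped = table.counts.groupby(lengths).sum()
    grouped.columns = [f"reads_{l}" for l in table.libraries]
    grouped["tags"] = table.counts.groupby(lengths).apply(lambda d: len(d))
    grouped.index.name = "length"
    return grouped


def modal_length(table: TagCountTable) -> int | None:
    """Most abundant insert length by total read count across libraries."""
    dist = size_distribution(table)
    if dist.empty:
        return None
    reads = dist[[c for c in dist.columns if c.startswith("reads_")]].sum(axis=1)
    return int(reads.idxmax())
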