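"""Hierarchical ncRNA annotation and conserved-miRNA identification.

Each unique tag is assigned to exactly one category by walking a priority
list (default miRNA > rRNA > tRNA > snRNA > snoRNA > mRNA > unannotated):
the first category whose reference set contains the tag -- as an exact
subsequence -- wins.  Putting miRNA first keeps known mature miRNAs from
being absorbed by overlapping rRNA/tRNA hits.

Conserved-miRNA identification is separate and more permissive: tags of
18-25 nt are matched against the mature reference by Hamming distance over
equal-length references (no indels), up to a configurable mismatch budget.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import ParameterError
from .io_formats import SequenceRecord, TagCountTable

DEFAULT_PRIORITY = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "mRNA")
UNANNOTATED = "unannotated"
UNKNOWN_FAMILY = "unknown-family"


@dataclass(frozen=True)
class MirnaMatch:
    """A tag assigned to a mature miRNA."""

    tag: str
    mirna_id: str
    family: str
    mismatches: int


def classify_tag(
    tag: str,
    references: dict[str, list[SequenceRecord]],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> str:
    """First category in priority order whose references contain the tag.

    Containment is exact-subsequence: the tag occurs verbatim inside (or
    equals) one of the category's reference sequences.
    """
    for cat in priority:
        for ref in references.get(cat, ()):
            if tag in ref.seq:
                return cat
    return UNANNOTATED


def classify_all(
    table: TagCountTable,
    references: dict[str, list[SequenceRecord]],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> pd.Series:
    return pd.Series(
        [classify_tag(t, references, priority) for t in table.counts.index],
        index=table.counts.index,
        name="category",
    )


def format_percent(count: int, denom: int) -> str:
    """Table-style percentage: half-up, 2 decimals, 3 when 2 would print
    0.00 or 0.01 (sub-0.02% values keep a significant digit)."""
    if denom <= 0:
        raise ParameterError("denominator must be positive")
    pct = Decimal(100 * count) / Decimal(denom)
    two = pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    if two in (Decimal("0.00"), Decimal("0.01")) and count != 0:
        return f"{pct.quantize(Decimal('0.001'), rounding=ROUND_HALF_UP)}%"
    if count == 0:
        return "0.000%"
    return f"{two}%"


def summarize(
    table: TagCountTable,
    classifications: pd.Series,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Category x library summary of unique tags and total reads.

    Per library the unique-tag percentages are taken over the number of
    distinct clean tags and the total percentages over the clean-read total,
    so the category rows sum back to the clean counts.
    """
    if not classifications.index.equals(table.counts.index):
        raise ParameterError("classifications must cover exactly the tags of the table")
    cats = list(priority) + [UNANNOTATED]
    rows = []
    n_unique = {lib: int((table.counts[lib] > 0).sum()) for lib in table.libraries}
    for cat in cats:
        mask = classifications == cat
        row: dict[str, object] = {"category": cat}
        for lib in table.libraries:
            col = table.counts[lib]
            uniq = int(((col > 0) & mask).sum())
            total = int(col[mask].sum())
            row[f"unique_{lib}"] = uniq
            row[f"total_{lib}"] = total
            row[f"unique_pct_{lib}"] = (
                format_percent(uniq, n_unique[lib]) if n_unique[lib] else "0.000%"
            )
            row[f"total_pct_{lib}"] = (
                format_percent(total, table.totals[lib]) if table.totals[lib] else "0.000%"
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


_MIRNA_ID = re.compile(
    r"^(?:[a-z]{2,5}-)?(?:mir|miR|MIR)-?(\d+)([a-zA-Z].*)?$"
)


def assign_family(mirna_id: str) -> str:
    """Family id from a mature-miRNA name: strip species prefix and variant
    suffix, keep the number -- ``cme-miR159a`` -> ``miR159``."""
    m = _MIRNA_ID.match(mirna_id.strip())
    if not m:
        return UNKNOWN_FAMILY
    return f"miR{m.group(1)}"


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def identify_conserved(
    table: TagCountTable,
    mature_ref: list[SequenceRecord],
    max_mismatch: int = 2,
    min_len: int = 18,
    max_len: int = 25,
) -> list[MirnaMatch]:
    """Match 18-25 nt tags to mature miRNAs by minimum Hamming distance.

    Only equal-length references are compared (no indels); ties at the
    minimum distance go to the lexicographically smallest reference id.
    """
    if max_mismatch < 0:
        raise ParameterError("max_mismatch must be >= 0")
    by_len: dict[int, list[SequenceRecord]] = {}
    for ref in mature_ref:
        by_len.setdefault(len(ref.seq), []).append(ref)
    for refs in by_len.values():
        refs.sort(key=lambda r: r.id)
    matches = []
    for tag in table.counts.index:
        if not (min_len <= len(tag) <= max_len):
            continue
        best: tuple[int, str] | None = None
        for ref in by_len.get(len(tag), ()):
            d = _hamming(tag, ref.seq)
            if d <= max_mismatch and (best is None or d < best[0]):
                best = (d, ref.id)
        if best is not None:
            matches.append(MirnaMatch(tag, best[1], assign_family(best[1]), best[0]))
    return matches


def mirna_counts(table: TagCountTable, matches: list[MirnaMatch]) -> TagCountTable:
    """Per-miRNA counts: sum of the counts of all tags assigned to it."""
    assign: dict[str, list[str]] = {}
    for m in matches:
        assign.setdefault(m.mirna_id, []).append(m.tag)
    ids = sorted(assign)
    df = pd.DataFrame(
        {lib: [int(table.counts.loc[tags, lib].sum()) for tags in (assign[i] for i in ids)]
         for lib in table.libraries},
        index=ids,
        dtype="int64",
    )
    return TagCountTable(df, dict(table.totals), key="mirna")


def membership(counts: TagCountTable) -> dict[str, set[str]]:
    """Per-library expressed sets: an entity is expressed iff raw count >= 1."""
    return {
        lib: set(counts.counts.index[counts.counts[lib] >= 1]) for lib in counts.libraries
    }
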