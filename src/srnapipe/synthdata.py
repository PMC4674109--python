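"""Synthetic data with known ground truth.

Emulates the statistical structure of a three-library plant small-RNA
study: a control library (CK), an aphid-infested library (A) and a
mock-puncture library (M) of 18-30 nt inserts sequenced as fixed-length
reads carrying a 3' adapter.  The generator produces

* a reference bundle (mature miRNAs with family-coded names, rRNA /
  tRNA / snRNA / snoRNA fragment sources, transcripts with planted
  near-complementary target sites, the adapter, and a background pool of
  unannotated siRNA-like tags with a 24-nt modal length);
* per-library FASTQ reads in which each miRNA's count is Poisson with a
  mean encoding its intended reads-per-million abundance, other
  categories fill the library according to composition weights, and a
  small fraction of junk reads fails cleaning;
* RACE clone 5'-end positions around a duplex's canonical cleavage site;
* qPCR cycle-threshold tables whose noise-free 2^-ddCT equals the intended
  fold change exactly.

All randomness flows through one numpy Generator per call; fixed seeds
give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_formats import SequenceRecord
from .qpcr import QPCRRecord
from .targets import ScoringScheme, TargetAlignment, revcomp, score_duplex

LIBRARIES = ("CK", "A", "M")

BASES = np.array(list("ACGT"))

# Default category composition of the non-miRNA part of a library,
# loosely following the proportions of total clean reads seen in leaf
# small-RNA libraries: rRNA-dominated ncRNA contamination, a sliver of
# spliceosomal/nucleolar RNAs, some mRNA breakdown, and a large
# unannotated (mostly 24-nt siRNA-like) remainder.
DEFAULT_COMPOSITION = {
    "rRNA": 0.077,
    "tRNA": 0.016,
    "snRNA": 0.0001,
    "snoRNA": 0.00005,
    "mRNA": 0.010,
    "unannotated": 0.85,
}

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# insert-length law of the unannotated background: 24-nt heterochromatic
# siRNAs dominate with a secondary 21-nt shoulder
_BG_LENGTHS = np.arange(18, 31)
_BG_WEIGHTS = np.array(
    [0.01, 0.02, 0.05, 0.12, 0.07, 0.08, 0.40, 0.10, 0.05, 0.04, 0.03, 0.02, 0.01]
)
_BG_WEIGHTS = _BG_WEIGHTS / _BG_WEIGHTS.sum()


@dataclass(frozen=True)
class PlantedSite:
    """A target site embedded in a transcript with a known intended score."""

    mirna_id: str
    transcript_id: str
    start: int  # 1-based, inclusive
    end: int
    intended_score: float


@dataclass
class ReferenceBundle:
    """All reference sequence sets one simulated study needs."""

    mature_mirnas: list[SequenceRecord]
    ncrna_sets: dict[str, list[SequenceRecord]]
    transcripts: list[SequenceRecord]
    adapter: str
    planted_sites: list[PlantedSite]
    background_pool: list[SequenceRecord]
    background_weights: np.ndarray

    def references_by_category(self) -> dict[str, list[SequenceRecord]]:
        refs = {"miRNA": self.mature_mirnas, "mRNA": self.transcripts}
        refs.update(self.ncrna_sets)
        return refs


@dataclass
class TruthTable:
    """Ground truth behind one simulated study.

    ``abundance`` holds the intended mean normalized abundance (reads per
    million) per miRNA per library; ``log2fc`` the intended fold change per
    comparison (treatment, control); ``membership`` the realized
    expressed-in-library sets (count >= 1), filled in as libraries are
    simulated; ``race_canonical`` the canonical cleavage position per
    validated target.
    """

    abundance: pd.DataFrame
    log2fc: dict[tuple[str, str], dict[str, float]]
    spiked: dict[tuple[str, str], set[str]]
    membership: dict[str, set[str]] = field(default_factory=dict)
    realized_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    race_canonical: dict[str, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def make_reference(
    seed: int,
    n_mirna: int = 60,
    n_families: int = 48,
    n_per_category: int = 20,
    n_transcripts: int = 8,
    adapter: str = DEFAULT_ADAPTER,
    background_pool_size: int = 3000,
) -> ReferenceBundle:
    """Deterministically generate a reference bundle.

    miRNA names are family-coded (``csy-miR<number><letter>``); families
    beyond the first member get letter suffixes.  At least one transcript
    carries a perfect-complement target site and one a site with a known
    nonzero penalty (3.5 under the default scheme).
    """
    if n_families < 1 or min(n_mirna, n_per_category, n_transcripts) < 1:
        raise ParameterError("all sizes must be >= 1")
    if n_families > n_mirna:
        raise ParameterError("n_families must be <= n_mirna")
    rng = np.random.default_rng(seed)

    family_numbers = sorted(rng.choice(np.arange(156, 4000), size=n_families, replace=False))
    members = [1] * n_families
    for _ in range(n_mirna - n_families):
        members[int(rng.integers(0, n_families))] += 1
    matures = []
    for num, k in zip(family_numbers, members):
        for j in range(k):
            suffix = chr(ord("a") + j) if k > 1 else ""
            length = int(rng.choice([20, 21, 21, 21, 22, 22]))
            matures.append(
                SequenceRecord(f"csy-miR{num}{suffix}", _random_seq(rng, length))
            )

    ncrna_sets = {}
    for cat, (lo, hi) in {
        "rRNA": (80, 160),
        "tRNA": (60, 90),
        "snRNA": (60, 120),
        "snoRNA": (60, 110),
    }.items():
        ncrna_sets[cat] = [
            SequenceRecord(f"{cat}_{i + 1}", _random_seq(rng, int(rng.integers(lo, hi))))
            for i in range(n_per_category)
        ]

    transcripts = [
        SequenceRecord(f"Unigene{i + 1}", _random_seq(rng, int(rng.integers(300, 600))))
        for i in range(n_transcripts)
    ]

    planted = []
    # transcript 1: perfect-complement site for the first miRNA
    planted.append(_plant_site(rng, transcripts, 0, matures[0], edits="perfect"))
    # transcript 2: site with intended penalty 3.5 for a miRNA that can
    # host both a core and a 3' G:U wobble away from the mismatch position
    for cand in matures[1:]:
        if _has_wobble(cand.seq, 2, 13, exclude={5}) and _has_wobble(
            cand.seq, 14, len(cand.seq), exclude={5}
        ):
            planted.append(_plant_site(rng, transcripts, 1, cand, edits="penalty35"))
            break
    else:
        raise ParameterError("no miRNA suitable for the penalty-3.5 planted site")

    pool = [
        SequenceRecord(
            f"bg_{i + 1}", _random_seq(rng, int(rng.choice(_BG_LENGTHS, p=_BG_WEIGHTS)))
        )
        for i in range(background_pool_size)
    ]
    weights = rng.dirichlet(np.full(background_pool_size, 0.2))

    return ReferenceBundle(
        mature_mirnas=matures,
        ncrna_sets=ncrna_sets,
        transcripts=transcripts,
        adapter=adapter.upper(),
        planted_sites=planted,
        background_pool=pool,
        background_weights=weights,
    )


def _plant_site(
    rng: np.random.Generator,
    transcripts: list[SequenceRecord],
    tx_index: int,
    mirna: SequenceRecord,
    edits: str,
) -> PlantedSite:
    """Overwrite a window of a transcript with a (possibly edited) target
    site for ``mirna`` and return the planted-site record."""
    site = list(revcomp(mirna.seq))
    L = len(site)
    score = 0.0
    if edits == "penalty35":
        # one core mismatch (2.0) + one core wobble (1.0) + one 3' wobble
        # (0.5) = 3.5 under the default scheme.  miRNA position i pairs
        # site index L - i (0-based).
        mm_pos = 5  # miRNA position, core
        base = mirna.seq[mm_pos - 1]
        non_pairing = {"A": "C", "C": "A", "G": "G", "T": "T"}[base]
        site[L - mm_pos] = non_pairing
        score += 2.0
        score += _make_wobble(
            site, mirna.seq, mirna_pos=_wobble_pos(mirna.seq, 2, 13, exclude={mm_pos}), core=True
        )
        score += _make_wobble(
            site, mirna.seq, mirna_pos=_wobble_pos(mirna.seq, 14, L, exclude={mm_pos}), core=False
        )
    tx = transcripts[tx_index]
    start0 = int(rng.integers(30, len(tx.seq) - L - 30))
    tx.seq = tx.seq[:start0] + "".join(site) + tx.seq[start0 + L :]
    return PlantedSite(mirna.id, tx.id, start0 + 1, start0 + L, score)


def _wobble_pos(mirna_seq: str, lo: int, hi: int, exclude: set[int] = frozenset()) -> int:
    """First miRNA position in [lo, hi] whose base supports a G:U wobble."""
    for i in range(lo, min(hi, len(mirna_seq)) + 1):
        if i not in exclude and mirna_seq[i - 1] in "GT":
            return i
    raise ParameterError("no wobble-capable base in the requested range")


def _has_wobble(mirna_seq: str, lo: int, hi: int, exclude: set[int] = frozenset()) -> bool:
    try:
        _wobble_pos(mirna_seq, lo, hi, exclude)
        return True
    except ParameterError:
        return False


def _make_wobble(site: list[str], mirna_seq: str, mirna_pos: int, core: bool) -> float:
    L = len(site)
    base = mirna_seq[mirna_pos - 1]
    site[L - mirna_pos] = "T" if base == "G" else "G"
    return 1.0 if core else 0.5


# ---------------------------------------------------------------------------
# Truth construction


def make_truth(
    ref: ReferenceBundle,
    seed: int,
    mirna_share: float = 0.05,
    n_spiked: int = 12,
    spike_log2fc: float = 2.0,
    absent_fraction: float = 0.15,
) -> TruthTable:
    """Intended abundances and fold changes for the three libraries.

    Baseline reads-per-million abundances are log-normal, scaled so the
    miRNA category holds ``mirna_share`` of the library.  ``n_spiked``
    miRNAs (half up, half down) get |log2FC| = ``spike_log2fc`` in A vs CK
    and an overlapping set in M vs CK; ``absent_fraction`` of miRNAs are
    silenced (abundance 0) in single libraries to create three-way Venn
    structure.
    """
    rng = np.random.default_rng(seed)
    ids = [m.id for m in ref.mature_mirnas]
    n = len(ids)
    base = rng.lognormal(mean=0.0, sigma=1.6, size=n)
    base = base / base.sum() * mirna_share * 1e6
    ab = pd.DataFrame({lib: base.copy() for lib in LIBRARIES}, index=ids)

    order = rng.permutation(n)
    spiked_a = [ids[i] for i in order[:n_spiked]]
    # M shares half of A's spikes (wounding component) plus fresh ones
    spiked_m = spiked_a[: n_spiked // 2] + [
        ids[i] for i in order[n_spiked : n_spiked + (n_spiked + 1) // 2]
    ]
    log2fc: dict[tuple[str, str], dict[str, float]] = {
        ("A", "CK"): {m: 0.0 for m in ids},
        ("M", "CK"): {m: 0.0 for m in ids},
    }
    for k, m in enumerate(spiked_a):
        fc = spike_log2fc if k % 2 == 0 else -spike_log2fc
        log2fc[("A", "CK")][m] = fc
        ab.loc[m, "A"] = ab.loc[m, "CK"] * 2.0**fc
    for k, m in enumerate(spiked_m):
        fc = spike_log2fc if k % 2 == 1 else -spike_log2fc
        log2fc[("M", "CK")][m] = fc
        ab.loc[m, "M"] = ab.loc[m, "CK"] * 2.0**fc

    # library-specific silencing of unspiked, low-abundance miRNAs
    eligible = [m for m in ids if m not in set(spiked_a) | set(spiked_m)]
    eligible = [m for m in eligible if ab.loc[m, "CK"] < np.median(base)]
    rng.shuffle(eligible)
    n_abs = int(absent_fraction * n)
    for j, m in enumerate(eligible[: 3 * n_abs // 2]):
        ab.loc[m, LIBRARIES[j % 3]] = 0.0

    return TruthTable(
        abundance=ab,
        log2fc=log2fc,
        spiked={("A", "CK"): set(spiked_a), ("M", "CK"): set(spiked_m)},
    )


# ---------------------------------------------------------------------------
# Library simulation


def simulate_counts(
    truth: TruthTable,
    library_id: str,
    depth: int,
    rng: np.random.Generator,
    overdispersion: float = 0.0,
) -> dict[str, int]:
    """Per-miRNA raw counts: Poisson with mean RPM * depth / 1e6.

    With ``overdispersion`` d > 0 the count is gamma-Poisson (negative
    binomial) with the same mean and variance mean * (1 + d * mean).
    """
    means = truth.abundance[library_id].to_numpy() * depth / 1e6
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        rates = np.where(means > 0, rng.gamma(shape, means / shape), 0.0)
    else:
        rates = means
    counts = rng.poisson(rates)
    return {m: int(c) for m, c in zip(truth.abundance.index, counts)}


def simulate_library(
    ref: ReferenceBundle,
    depth: int,
    de_spec: TruthTable,
    library_id: str,
    seed: int,
    composition: dict[str, float] | None = None,
    read_length: int = 49,
    junk_fraction: float = 0.005,
    overdispersion: float = 0.0,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Simulate one raw FASTQ library of ``depth`` reads.

    miRNA reads follow the truth table's Poisson law; the remaining depth
    is shared among the other categories according to ``composition``
    weights; ``junk_fraction`` of reads are unusable (no adapter, short
    insert, ambiguous bases, or low quality).  Returns the reads (shuffled,
    deterministic for the seed) and the truth table updated with realized
    counts and membership.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    if library_id not in LIBRARIES:
        raise ParameterError(f"library_id must be one of {LIBRARIES}")
    if not ref.mature_mirnas or not ref.background_pool:
        raise ParameterError("reference bundle is empty")
    comp = dict(DEFAULT_COMPOSITION if composition is None else composition)
    comp.pop("miRNA", None)
    weights = np.array([comp[c] for c in sorted(comp)], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ParameterError("composition weights must be nonnegative, not all zero")
    cats = sorted(comp)
    rng = np.random.default_rng(seed)

    inserts: list[str] = []

    mirna_counts = simulate_counts(de_spec, library_id, depth, rng, overdispersion)
    mirna_seq = {m.id: m.seq for m in ref.mature_mirnas}
    for mid, c in mirna_counts.items():
        inserts.extend([mirna_seq[mid]] * c)

    n_junk = int(round(depth * junk_fraction))
    n_rest = max(depth - len(inserts) - n_junk, 0)
    cat_counts = rng.multinomial(n_rest, weights / weights.sum())
    for cat, n_cat in zip(cats, cat_counts):
        if n_cat == 0:
            continue
        if cat == "unannotated":
            idx = rng.choice(len(ref.background_pool), size=n_cat, p=ref.background_weights)
            inserts.extend(ref.background_pool[i].seq for i in idx)
        else:
            sources = ref.transcripts if cat == "mRNA" else ref.ncrna_sets[cat]
            src_idx = rng.integers(0, len(sources), size=n_cat)
            lens = rng.integers(18, 31, size=n_cat)
            for si, ln in zip(src_idx, lens):
                seq = sources[si].seq
                ln = min(int(ln), len(seq))
                s0 = int(rng.integers(0, len(seq) - ln + 1))
                inserts.append(seq[s0 : s0 + ln])

    reads: list[tuple[str, list[int]]] = []
    adapter = ref.adapter
    hi_q = 38

    def assemble(insert: str, qual_val: int = hi_q, with_adapter: bool = True):
        seq = insert + (adapter if with_adapter else "")
        if len(seq) < read_length:
            seq = seq + _random_seq(rng, read_length - len(seq))
        seq = seq[:read_length]
        reads.append((seq, [qual_val] * read_length))

    for ins in inserts:
        assemble(ins)

    # junk: no-adapter, too-short insert, N-containing, low-quality
    for j in range(n_junk):
        kind = j % 4
        if kind == 0:
            assemble(_random_seq(rng, read_length), with_adapter=False)
        elif kind == 1:
            assemble(_random_seq(rng, int(rng.integers(5, 18))))
        elif kind == 2:
            ins = list(_random_seq(rng, 24))
            ins[int(rng.integers(0, 24))] = "N"
            assemble("".join(ins))
        else:
            assemble(_random_seq(rng, 24), qual_val=8)

    perm = rng.permutation(len(reads))
    records = [
        SequenceRecord(f"{library_id}_{k + 1:07d}", reads[i][0], qual=reads[i][1])
        for k, i in enumerate(perm)
    ]

    de_spec.realized_counts[library_id] = mirna_counts
    de_spec.membership[library_id] = {m for m, c in mirna_counts.items() if c >= 1}
    return records, de_spec


# ---------------------------------------------------------------------------
# RACE and qPCR simulation


def simulate_race_clones(
    duplex: TargetAlignment,
    n_clones: int,
    canonical_fraction: float,
    seed: int,
) -> list[int]:
    """Clone 5'-end positions: ``canonical_fraction`` of clones fall at the
    canonical cleavage site, the rest scatter uniformly over the rest of
    the duplex span."""
    if not 0.0 <= canonical_fraction <= 1.0:
        raise ParameterError("canonical_fraction must be in [0, 1]")
    if n_clones < 1:
        raise ParameterError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    canon = duplex.canonical_cleavage_position()
    others = [p for p in range(duplex.start, duplex.end + 1) if p != canon]
    positions = []
    for _ in range(n_clones):
        if rng.random() < canonical_fraction:
            positions.append(canon)
        else:
            positions.append(int(rng.choice(others)))
    return positions


def simulate_qpcr(
    truth: TruthTable,
    comparison: tuple[str, str] = ("A", "CK"),
    noise_sd: float = 0.0,
    seed: int = 0,
    mirnas: list[str] | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    ct_reference: float = 16.0,
    base_dct: float = 6.0,
) -> list[QPCRRecord]:
    """CT tables whose noise-free 2^-ddCT equals 2^(intended log2FC).

    The control condition sits at a fixed dCT; the treatment dCT is offset
    by -log2FC; Gaussian noise of sd ``noise_sd`` (CT units) is added to
    each well's target CT.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    fcs = truth.log2fc[comparison]
    chosen = mirnas if mirnas is not None else sorted(truth.spiked[comparison])
    records = []
    for mid in chosen:
        for condition, dct in (
            ("control", base_dct),
            ("treatment", base_dct - fcs[mid]),
        ):
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    ct_t = ct_reference + dct + (rng.normal(0, noise_sd) if noise_sd else 0.0)
                    records.append(
                        QPCRRecord(mid, condition, b, t, float(ct_t), ct_reference)
                    )
    return records
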