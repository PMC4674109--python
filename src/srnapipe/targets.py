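"""Plant miRNA target prediction by complementarity penalty scoring.

A candidate site is scored against the miRNA with position-weighted
penalties: mismatch 1.0, G:U wobble 0.5, gap 1.0, each doubled when the
position falls in the miRNA 5' core (positions 2-13, 1-based from the
miRNA 5' end).  Sites scoring at or below a cutoff (default 4.0) are
reported.  The scheme is held in a parameter object, not constants.

Cleavage mapping follows the canonical slicing rule: the guided cut falls
opposite miRNA positions 10/11, so the canonical 5' end of the 3' cleavage
fragment is the target nucleotide paired with miRNA position 10.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io_formats import SequenceRecord

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

STATE_MATCH = "|"
STATE_WOBBLE = "o"
STATE_MISMATCH = "."
STATE_GAP = "-"


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty constants for duplex scoring; all configurable."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 1.0
    core_start: int = 2  # miRNA positions with doubled penalty, inclusive
    core_end: int = 13
    max_score: float = 4.0
    max_gaps: int = 1

    def position_factor(self, mirna_pos: int) -> float:
        return 2.0 if self.core_start <= mirna_pos <= self.core_end else 1.0


def _pair_state(mirna_base: str, target_base: str) -> str:
    if _COMPLEMENT.get(mirna_base) == target_base and mirna_base != "N":
        return STATE_MATCH
    # G:U wobble on the DNA alphabet: G·T in either orientation
    if {mirna_base, target_base} == {"G", "T"}:
        return STATE_WOBBLE
    return STATE_MISMATCH


@dataclass(frozen=True)
class TargetAlignment:
    """A miRNA:target-site duplex with per-position states and total penalty.

    ``states`` is ordered by miRNA position (5'->3'); the site is the
    transcript window ``start..end`` (1-based, inclusive) read 5'->3' on the
    transcript, which pairs antiparallel to the miRNA.
    """

    mirna_id: str
    mirna_seq: str
    transcript_id: str
    start: int
    end: int
    states: str
    score: float

    @property
    def site_length(self) -> int:
        return self.end - self.start + 1

    def canonical_cleavage_position(self) -> int:
        """Transcript coordinate (1-based) of the target base paired with
        miRNA position 10.

        The site pairs antiparallel to the miRNA, so miRNA position i sits
        opposite transcript position end - i + 1; for gapped duplexes the
        single bulge shifts this by at most one base, which the rule
        tolerates (the biological cut itself is a 10/11 dinucleotide).
        """
        return self.end - 10 + 1


def score_duplex(
    mirna_seq: str,
    site_seq: str,
    scheme: ScoringScheme = ScoringScheme(),
    mirna_id: str = "mirna",
    transcript_id: str = "site",
    start: int = 1,
) -> TargetAlignment:
    """Score a miRNA against one candidate target window.

    The site is given 5'->3' in transcript orientation and pairs
    antiparallel to the miRNA: miRNA position 1 pairs the site's 3' end.
    Lengths may differ by at most ``scheme.max_gaps``; the gap placement
    minimizing the total penalty is chosen.
    """
    mirna_seq = mirna_seq.upper()
    site_seq = site_seq.upper()
    for name, s in (("mirna", mirna_seq), ("site", site_seq)):
        if not 15 <= len(s) <= 30:
            raise ParameterError(f"{name} sequence length {len(s)} outside 15-30 nt")
    diff = len(site_seq) - len(mirna_seq)
    if abs(diff) > scheme.max_gaps:
        raise ParameterError(
            f"length difference {abs(diff)} exceeds max_gaps={scheme.max_gaps}"
        )
    site_rev = site_seq[::-1]  # index i pairs miRNA position i+1

    def score_ungapped(m: str, s: str) -> tuple[float, str]:
        states = []
        total = 0.0
        for i, (mb, tb) in enumerate(zip(m, s)):
            st = _pair_state(mb, tb)
            if st == STATE_MISMATCH:
                total += scheme.mismatch * scheme.position_factor(i + 1)
            elif st == STATE_WOBBLE:
                total += scheme.wobble * scheme.position_factor(i + 1)
            states.append(st)
        return total, "".join(states)

    if diff == 0:
        total, states = score_ungapped(mirna_seq, site_rev)
    else:
        # place one gap in the shorter strand at every position, keep the best
        best: tuple[float, str] | None = None
        longer, shorter = (
            (site_rev, mirna_seq) if diff > 0 else (mirna_seq, site_rev)
        )
        for gap_at in range(len(shorter) + 1):
            states = []
            total = 0.0
            si = 0
            for pos in range(len(longer)):
                if pos == gap_at:
                    # penalty position: the miRNA coordinate the gap sits at
                    mirna_pos = si + 1 if diff > 0 else pos + 1
                    total += scheme.gap * scheme.position_factor(mirna_pos)
                    states.append(STATE_GAP)
                    continue
                a = longer[pos]
                b = shorter[si]
                mb, tb = (b, a) if diff > 0 else (a, b)
                mirna_pos = (si + 1) if diff > 0 else (pos + 1)
                st = _pair_state(mb, tb)
                if st == STATE_MISMATCH:
                    total += scheme.mismatch * scheme.position_factor(mirna_pos)
                elif st == STATE_WOBBLE:
                    total += scheme.wobble * scheme.position_factor(mirna_pos)
                states.append(st)
                si += 1
            if best is None or total < best[0]:
                best = (total, "".join(states))
        total, states = best
    return TargetAlignment(
        mirna_id=mirna_id,
        mirna_seq=mirna_seq,
        transcript_id=transcript_id,
        start=start,
        end=start + len(site_seq) - 1,
        states=states,
        score=total,
    )


def _ungapped_window_scores(mirna_seq: str, tx_seq: str, scheme: ScoringScheme):
    """Vectorized ungapped penalties of every miRNA-length window.

    Returns an array of total penalties indexed by window start (0-based).
    """
    L = len(mirna_seq)
    tx = np.frombuffer(tx_seq.encode(), dtype="S1")
    if len(tx) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(tx, L)[:, ::-1]
    mir = np.frombuffer(mirna_seq.encode(), dtype="S1")
    comp = np.frombuffer(revcomp(mirna_seq)[::-1].encode(), dtype="S1")
    match = windows == comp[None, :]
    wobble = ((mir == b"G")[None, :] & (windows == b"T")) | (
        (mir == b"T")[None, :] & (windows == b"G")
    )
    penalty = np.where(match, 0.0, np.where(wobble, scheme.wobble, scheme.mismatch))
    factor = np.array([scheme.position_factor(i + 1) for i in range(L)])
    return (penalty * factor[None, :]).sum(axis=1)


def scan(
    mirnas: list[SequenceRecord],
    transcripts: list[SequenceRecord],
    scheme: ScoringScheme = ScoringScheme(),
) -> list[TargetAlignment]:
    """Slide every miRNA over every transcript; report sites scoring
    <= scheme.max_score, sorted by score then transcript position.

    Every miRNA-length window is scored ungapped (vectorized); around
    near-threshold windows, single-gap variants one base longer or shorter
    are additionally tried and the best placement kept.  Overlapping
    placements collapse to the local best.
    """
    if not transcripts:
        raise ParameterError("transcripts must be non-empty")
    hits: list[TargetAlignment] = []
    gap_slack = 2.0 * scheme.gap * 2.0  # widest possible gain from re-gapping
    for mir in mirnas:
        L = len(mir.seq)
        for tx in transcripts:
            scores = _ungapped_window_scores(mir.seq, tx.seq, scheme)
            candidates = [
                int(s) for s in range(len(scores))
                if scores[s] <= scheme.max_score + gap_slack
            ]
            best_at: dict[int, TargetAlignment] = {}
            for s0 in candidates:
                variants = [(s0, L)]
                if scheme.max_gaps >= 1:
                    variants += [(s0, L - 1), (s0, L + 1), (s0 - 1, L + 1)]
                for vs, wlen in variants:
                    if vs < 0 or wlen < 15 or wlen > 30 or vs + wlen > len(tx.seq):
                        continue
                    aln = score_duplex(
                        mir.seq, tx.seq[vs : vs + wlen], scheme, mir.id, tx.id, start=vs + 1
                    )
                    if aln.score <= scheme.max_score:
                        prev = best_at.get(vs)
                        if prev is None or aln.score < prev.score:
                            best_at[vs] = aln
            kept: list[TargetAlignment] = []
            for s0 in sorted(best_at):
                aln = best_at[s0]
                if kept and abs(kept[-1].start - aln.start) <= 1:
                    if aln.score < kept[-1].score:
                        kept[-1] = aln
                    continue
                kept.append(aln)
            hits.extend(kept)
    hits.sort(key=lambda a: (a.score, a.transcript_id, a.start, a.mirna_id))
    return hits


@dataclass(frozen=True)
class CleavageProfile:
    """RACE clone 5'-end tallies over a target transcript."""

    transcript_id: str
    tallies: dict[int, int]
    canonical_position: int

    @property
    def n_clones(self) -> int:
        return sum(self.tallies.values())

    @property
    def canonical_count(self) -> int:
        return self.tallies.get(self.canonical_position, 0)

    @property
    def canonical_fraction(self) -> float:
        n = self.n_clones
        return self.canonical_count / n if n else 0.0

    @property
    def label(self) -> str:
        return f"{self.canonical_count}/{self.n_clones}"


def map_cleavage(
    clones: list[int],
    alignment: TargetAlignment,
    transcript_length: int | None = None,
) -> CleavageProfile:
    """Tally RACE clone 5'-end positions against a predicted duplex.

    The canonical site is the transcript base paired with miRNA position 10.
    Positions are 1-based on the transcript; any clone outside the
    transcript bounds is a parameter error.
    """
    if transcript_length is not None:
        for p in clones:
            if not 1 <= p <= transcript_length:
                raise ParameterError(
                    f"clone position {p} outside transcript 1..{transcript_length}"
                )
    return CleavageProfile(
        transcript_id=alignment.transcript_id,
        tallies=dict(Counter(clones)),
        canonical_position=alignment.canonical_cleavage_position(),
    )
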