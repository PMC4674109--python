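"""Normalization, the Audic–Claverie tag-count test, and Venn overlaps.

Normalized expression is reads-per-million of clean reads,
``10^6 * count / total``, with a zero-count adjustment: a miRNA unobserved
in a library gets the sentinel value 0.01 so that log2 fold changes stay
finite.  Genes whose normalized expression is below 1 in both libraries of
a comparison are excluded from differential-expression calling as too
lowly expressed to test.

The test itself treats each library as Poisson sampling of tags.  Given a
gene with x tags out of N1 in one library and y out of N2 in the other, the
probability of y conditional on x is

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

which is the negative-binomial pmf with size x+1 and success probability
N1/(N1+N2).  It is evaluated in log space via log-gamma; the two-sided
p-value doubles the smaller tail (the observed point counted in both
tails) and clips at 1.  Significance requires p < alpha (default 0.05)
and |log2 fold change| >= 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ParameterError
from .io_formats import TagCountTable

ZERO_ADJUST = 0.01


def normalize(
    counts: TagCountTable, zero_adjust: float = ZERO_ADJUST
) -> pd.DataFrame:
    """Reads-per-million normalization with the zero-count adjustment.

    Returns a float DataFrame shaped like the count matrix; cells with raw
    count 0 hold exactly ``zero_adjust`` (default 0.01).
    """
    for lib, tot in counts.totals.items():
        if tot <= 0:
            raise ParameterError(f"library total for {lib!r} must be > 0")
    norm = counts.counts.astype(float)
    for lib in counts.libraries:
        norm[lib] = norm[lib] * 1e6 / counts.totals[lib]
    norm[counts.counts == 0] = zero_adjust
    return norm


def exclusion_rule(
    norm_treatment: float, norm_control: float, mode: str = "both"
) -> bool:
    """Low-expression exclusion: True when the gene is dropped.

    ``mode="both"`` (default): excluded iff both normalized values are < 1.
    ``mode="either"``: excluded as soon as one value is < 1.
    """
    if mode == "both":
        return norm_treatment < 1 and norm_control < 1
    if mode == "either":
        return norm_treatment < 1 or norm_control < 1
    raise ParameterError(f"unknown exclusion mode {mode!r}")


def _check_counts(x: int, y: int, n1: float, n2: float) -> None:
    if x < 0 or y < 0 or x != int(x) or y != int(y):
        raise ParameterError("tag counts must be nonnegative integers")
    if n1 <= 0 or n2 <= 0:
        raise ParameterError("library totals must be positive")


def ac_log_density(x: int, y: int, n1: float, n2: float) -> float:
    """log p(y | x) for the Poisson tag-sampling model (see module docs)."""
    _check_counts(x, y, n1, n2)
    r = n2 / n1
    return (
        y * math.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(r)
    )


def ac_density(x: int, y: int, n1: float, n2: float) -> float:
    """p(y | x): probability of y tags in library 2 given x in library 1."""
    return math.exp(ac_log_density(x, y, n1, n2))


def _log_lower_tail(x: int, y: int, n1: float, n2: float) -> float:
    """log P(Y <= y | x), by log-sum-exp over the densities 0..y."""
    ys = np.arange(y + 1)
    r = n2 / n1
    logs = (
        ys * math.log(r)
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * math.log1p(r)
    )
    return float(logsumexp(logs))


def _log_upper_tail(x: int, y: int, n1: float, n2: float) -> float:
    """log P(Y >= y | x), summed upward from y until terms are negligible.

    Direct summation from the smaller side avoids the catastrophic
    cancellation of 1 - CDF(y-1) when the upper tail is tiny.
    """
    r = n2 / n1
    q = r / (1 + r)  # density ratio factor, < 1
    log_t = ac_log_density(x, y, n1, n2)
    total = log_t
    yy = y
    while True:
        # d(y+1)/d(y) = q * (x+y+1)/(y+1)
        ratio = q * (x + yy + 1) / (yy + 1)
        log_t += math.log(ratio)
        new_total = np.logaddexp(total, log_t)
        yy += 1
        if ratio < 1 and log_t < total - 40:
            return float(new_total)
        total = new_total


def ac_pvalue(
    x: int, y: int, n1: float, n2: float, alternative: str = "two-sided"
) -> float:
    """Tag-count test p-value.

    Two-sided (default): twice the smaller of the two deviation tails
    P(Y >= y | x) and P(X >= x | y) (library roles and totals swapped),
    observed point included, clipped at 1.  This symmetrized form treats
    the two libraries exchangeably: swapping (x, N1) with (y, N2) leaves
    the p-value unchanged.  One-sided alternatives condition on x and use
    the single matching tail of Y.  Always > 0.
    """
    _check_counts(x, y, n1, n2)
    if alternative == "two-sided":
        tail_fwd = _log_upper_tail(x, y, n1, n2)
        tail_rev = _log_upper_tail(y, x, n2, n1)
        log_p = math.log(2) + min(tail_fwd, tail_rev)
    elif alternative == "greater":
        log_p = _log_upper_tail(x, y, n1, n2)
    elif alternative == "less":
        log_p = _log_lower_tail(x, y, n1, n2)
    else:
        raise ParameterError(f"unknown alternative {alternative!r}")
    return min(1.0, math.exp(min(log_p, 0.0)))


@dataclass
class DERecord:
    """One miRNA in one pairwise comparison."""

    mirna_id: str
    comparison: str
    x: int  # raw count, control
    y: int  # raw count, treatment
    n1: int  # control library total
    n2: int  # treatment library total
    norm_control: float
    norm_treatment: float
    log2fc: float
    pvalue: float
    excluded: bool
    significant: bool

    @property
    def direction(self) -> str:
        if not self.significant:
            return "-"
        return "up" if self.log2fc > 0 else "down"


def call_de(
    counts: TagCountTable,
    comparisons: list[tuple[str, str]],
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    zero_adjust: float = ZERO_ADJUST,
    exclusion_mode: str = "both",
    alternative: str = "two-sided",
) -> list[DERecord]:
    """Differential-expression calls for (treatment, control) library pairs.

    Fold change is log2(treatment/control) on zero-adjusted normalized
    values; a record is significant iff it is not excluded, p < alpha and
    |log2fc| >= min_abs_log2fc.
    """
    for trt, ctl in comparisons:
        for lib in (trt, ctl):
            if lib not in counts.libraries:
                raise ParameterError(f"unknown library {lib!r}")
    norm = normalize(counts, zero_adjust)
    records = []
    for trt, ctl in comparisons:
        label = f"{ctl}-VS-{trt}"
        n1, n2 = counts.totals[ctl], counts.totals[trt]
        for mid in counts.counts.index:
            x = int(counts.counts.at[mid, ctl])
            y = int(counts.counts.at[mid, trt])
            nc, nt = float(norm.at[mid, ctl]), float(norm.at[mid, trt])
            excluded = exclusion_rule(nt, nc, exclusion_mode)
            log2fc = math.log2(nt / nc)
            p = ac_pvalue(x, y, n1, n2, alternative)
            sig = (not excluded) and p < alpha and abs(log2fc) >= min_abs_log2fc
            records.append(
                DERecord(mid, label, x, y, n1, n2, nc, nt, log2fc, p, excluded, sig)
            )
    return records


def de_table(records: list[DERecord]) -> pd.DataFrame:
    rows = [
        {
            "mirna": r.mirna_id,
            "comparison": r.comparison,
            "x": r.x,
            "y": r.y,
            "N1": r.n1,
            "N2": r.n2,
            "norm_control": r.norm_control,
            "norm_treatment": r.norm_treatment,
            "log2fc": r.log2fc,
            "pvalue": r.pvalue,
            "excluded": r.excluded,
            "significant": r.significant,
            "direction": r.direction,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Venn / overlap structure


@dataclass(frozen=True)
class VennRegions:
    """Three-set overlap structure (names a, b, c in fixed order).

    ``pairwise`` counts are intersection totals (the triple region is part
    of each pairwise count), matching how co-expression between two
    libraries is usually reported.
    """

    names: tuple[str, str, str]
    exclusive: tuple[int, int, int]
    pairwise: tuple[int, int, int]  # |a∩b|, |b∩c|, |a∩c|
    triple: int

    def __post_init__(self):
        ab, bc, ac = self.pairwise
        if min(self.exclusive) < 0 or self.triple < 0:
            raise ParameterError("region counts must be nonnegative")
        if min(ab - self.triple, bc - self.triple, ac - self.triple) < 0:
            raise ParameterError("pairwise totals cannot be below the triple count")

    @property
    def pairwise_only(self) -> tuple[int, int, int]:
        ab, bc, ac = self.pairwise
        t = self.triple
        return (ab - t, bc - t, ac - t)

    @property
    def set_sizes(self) -> dict[str, int]:
        a, b, c = self.exclusive
        ab, bc, ac = self.pairwise_only
        t = self.triple
        return {
            self.names[0]: a + ab + ac + t,
            self.names[1]: b + ab + bc + t,
            self.names[2]: c + bc + ac + t,
        }

    @property
    def union(self) -> int:
        return sum(self.exclusive) + sum(self.pairwise_only) + self.triple

    @classmethod
    def from_sets(cls, sets: dict[str, set]) -> "VennRegions":
        if len(sets) != 3:
            raise ParameterError("exactly three named sets required")
        (na, sa), (nb, sb), (nc, sc) = sets.items()
        t = len(sa & sb & sc)
        return cls(
            names=(na, nb, nc),
            exclusive=(len(sa - sb - sc), len(sb - sa - sc), len(sc - sa - sb)),
            pairwise=(len(sa & sb), len(sb & sc), len(sa & sc)),
            triple=t,
        )


def venn(sets: dict[str, set]) -> VennRegions:
    """All seven regions plus union for three named membership sets."""
    return VennRegions.from_sets(sets)


def de_overlap(records: list[DERecord]) -> VennRegions:
    """Venn over the significant miRNA ids of three comparisons."""
    by_cmp: dict[str, set] = {}
    for r in records:
        by_cmp.setdefault(r.comparison, set())
        if r.significant:
            by_cmp[r.comparison].add(r.mirna_id)
    if len(by_cmp) != 3:
        raise ParameterError(f"need exactly three comparisons, got {sorted(by_cmp)}")
    return venn(by_cmp)
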