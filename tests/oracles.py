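"""Independent exact-arithmetic oracles used only by the tests.

The tag-count test statistic is recomputed here with stdlib rationals
(fractions.Fraction) straight from its closed form, with no shared code
with the log-space implementation under test.
"""

from fractions import Fraction
from math import comb


def density_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    r = Fraction(n2, n1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


def pvalue_exact(x: int, y: int, n1: int, n2: int) -> Fraction:
    # doubled smaller deviation tail, roles exchangeable
    fwd = 1 - sum(density_exact(x, yy, n1, n2) for yy in range(y))
    rev = 1 - sum(density_exact(y, xx, n2, n1) for xx in range(x))
    return min(Fraction(1), 2 * min(fwd, rev))


def ols_r_squared(xs, ys):
    """Closed-form squared Pearson correlation, hand-computed."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    return sxy * sxy / (sxx * syy)
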