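"""Stem-loop qRT-PCR relative expression (2^-ddCT) and concordance with
sequencing-derived fold changes.

CT values are cycle thresholds; the target miRNA is normalized against a
reference gene (dCT = CT_target - CT_reference), treatment against control
(ddCT = mean dCT_treatment - mean dCT_control), and relative expression is
2^-ddCT.  Technical replicates are averaged into their biological
replicate before any cross-replicate statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError


@dataclass(frozen=True)
class QPCRRecord:
    """One well: CTs for target miRNA and reference gene."""

    mirna_id: str
    condition: str  # "treatment" or "control"
    bio_rep: int
    tech_rep: int
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_reference)):
            raise ParameterError("CT values must be finite")


def _mean_dct(records: list[QPCRRecord]) -> float:
    """Average technical replicates per biological replicate, then average
    the per-biological-replicate dCTs."""
    by_bio: dict[int, list[QPCRRecord]] = {}
    for r in records:
        by_bio.setdefault(r.bio_rep, []).append(r)
    dcts = []
    for reps in by_bio.values():
        ct_t = sum(r.ct_target for r in reps) / len(reps)
        ct_r = sum(r.ct_reference for r in reps) / len(reps)
        dcts.append(ct_t - ct_r)
    return sum(dcts) / len(dcts)


def ddct(records: list[QPCRRecord]) -> float:
    """Relative expression 2^-ddCT of treatment over control for one miRNA."""
    trt = [r for r in records if r.condition == "treatment"]
    ctl = [r for r in records if r.condition == "control"]
    if not trt or not ctl:
        raise ParameterError("both treatment and control records required")
    ddct_value = _mean_dct(trt) - _mean_dct(ctl)
    return 2.0 ** (-ddct_value)


def ddct_table(records: list[QPCRRecord]) -> pd.DataFrame:
    """Per-miRNA relative expression and its log2."""
    by_mirna: dict[str, list[QPCRRecord]] = {}
    for r in records:
        by_mirna.setdefault(r.mirna_id, []).append(r)
    rows = []
    for mid in sorted(by_mirna):
        rel = ddct(by_mirna[mid])
        rows.append({"mirna": mid, "relative_expression": rel, "log2fc_qpcr": math.log2(rel)})
    return pd.DataFrame(rows).set_index("mirna")


@dataclass(frozen=True)
class ConcordanceResult:
    """Sequencing vs qPCR fold-change agreement."""

    pairs: pd.DataFrame  # columns log2fc_seq, log2fc_qpcr, indexed by miRNA
    slope: float
    intercept: float
    r_squared: float


def concordance(
    seq_log2fc: dict[str, float], qpcr_relative: dict[str, float]
) -> ConcordanceResult:
    """Least-squares fit of qPCR log2 fold change on sequencing log2 fold
    change over the shared miRNAs; R^2 is the squared Pearson correlation.
    """
    shared = sorted(set(seq_log2fc) & set(qpcr_relative))
    if len(shared) < 3:
        raise ParameterError(f"need >= 3 paired miRNAs, got {len(shared)}")
    x = np.array([seq_log2fc[m] for m in shared], dtype=float)
    y = np.array([math.log2(qpcr_relative[m]) for m in shared], dtype=float)
    fit = stats.linregress(x, y)
    pairs = pd.DataFrame({"log2fc_seq": x, "log2fc_qpcr": y}, index=shared)
    return ConcordanceResult(
        pairs=pairs,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
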