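"""Multi-condition study summaries: replicate statistics, HDR-vs-NHEJ
testing, outcome-tier classification, and HDR/NHEJ correlation.

An editing "condition" is a combination of locus, nuclease platform, guide
set, donor strand and cell type; each condition yields per-replicate HDR and
NHEJ allele frequencies (%), typically n = 6 biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["ConditionReplicates", "ConditionSummary", "summarize", "tier_classify",
           "correlation_r2", "TIER_DESCRIPTIONS"]

#: Tier 1 (best) to tier 5 (worst), ranking conditions by how strongly they
#: favor precise HDR edits over NHEJ indels.
TIER_DESCRIPTIONS = {
    1: ">0.1% HDR and HDR >= NHEJ",
    2: "<=0.1% HDR and HDR >= NHEJ",
    3: "2x HDR >= NHEJ > 1x HDR",
    4: ">0.1% HDR and NHEJ > 2x HDR",
    5: "<=0.1% HDR and NHEJ > 2x HDR",
}


@dataclass(frozen=True)
class ConditionReplicates:
    """Per-replicate HDR and NHEJ frequencies (%) for one editing condition."""

    hdr_freqs: tuple[float, ...]
    nhej_freqs: tuple[float, ...]
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hdr_freqs", tuple(float(x) for x in self.hdr_freqs))
        object.__setattr__(self, "nhej_freqs", tuple(float(x) for x in self.nhej_freqs))
        if len(self.hdr_freqs) != len(self.nhej_freqs):
            raise ValueError("HDR and NHEJ replicate counts must match")
        if len(self.hdr_freqs) == 0:
            raise ValueError("need at least one replicate")
        if any(x < 0 for x in self.hdr_freqs + self.nhej_freqs):
            raise ValueError("frequencies must be >= 0")

    @property
    def n(self) -> int:
        return len(self.hdr_freqs)


@dataclass(frozen=True)
class ConditionSummary:
    mean_hdr: float
    sem_hdr: float
    mean_nhej: float
    sem_nhej: float
    n: int
    p_value: float | None  # two-tailed HDR-vs-NHEJ t-test; None when n < 2
    ratio: float  # HDR:NHEJ mean ratio (inf when NHEJ mean is 0)
    tier: int
    condition: dict = field(default_factory=dict)


def _sem(x: np.ndarray) -> float:
    # SEM = sample SD / sqrt(n); 0 for a single replicate
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def summarize(reps: ConditionReplicates) -> ConditionSummary:
    """Mean +/- SEM per class and a two-tailed Student's t-test HDR vs NHEJ.

    The test is the classical two-sample equal-variance t-test between the
    HDR and NHEJ replicate sets.  When both sets are identical (zero
    pooled variance, equal means) the difference is exactly zero and the
    p-value is reported as 1.0; with n < 2 no test is performed.
    """
    hdr = np.asarray(reps.hdr_freqs)
    nhej = np.asarray(reps.nhej_freqs)
    mean_hdr, mean_nhej = float(hdr.mean()), float(nhej.mean())

    p_value: float | None = None
    if reps.n >= 2:
        if np.ptp(hdr) == 0 and np.ptp(nhej) == 0:  # zero variance in both
            p_value = 1.0 if mean_hdr == mean_nhej else 0.0
        else:
            _, p = stats.ttest_ind(hdr, nhej, equal_var=True)
            p_value = float(p)

    if mean_nhej > 0:
        ratio = mean_hdr / mean_nhej
    else:
        ratio = float("inf") if mean_hdr > 0 else float("nan")

    return ConditionSummary(
        mean_hdr=mean_hdr,
        sem_hdr=_sem(hdr),
        mean_nhej=mean_nhej,
        sem_nhej=_sem(nhej),
        n=reps.n,
        p_value=p_value,
        ratio=ratio,
        tier=tier_classify(mean_hdr, mean_nhej),
        condition=dict(reps.condition),
    )


def tier_classify(mean_hdr: float, mean_nhej: float) -> int:
    """Classify a condition into the five HDR-favorability tiers.

    Tier 1 (best): >0.1% HDR and at least as much HDR as NHEJ.
    Tier 2: <=0.1% HDR but still at least as much HDR as NHEJ.
    Tier 3: NHEJ exceeds HDR but by at most 2-fold (no HDR threshold).
    Tier 4: >0.1% HDR with NHEJ more than 2-fold above HDR.
    Tier 5 (worst): <=0.1% HDR with NHEJ more than 2-fold above HDR.
    Boundary ties go to the better tier.
    """
    if mean_hdr < 0 or mean_nhej < 0:
        raise ValueError("frequencies must be >= 0")
    if mean_hdr >= mean_nhej:
        return 1 if mean_hdr > 0.1 else 2
    if 2 * mean_hdr >= mean_nhej:
        return 3
    return 4 if mean_hdr > 0.1 else 5


def correlation_r2(hdr_values, nhej_values) -> tuple[float, bool]:
    """Squared Pearson correlation between HDR and NHEJ frequencies.

    Zero-valued points are ordinary observations and must be included.
    Returns (R^2, degenerate): a constant input list makes the correlation
    undefined; R^2 is reported as 0 with the degenerate flag set.
    """
    x = np.asarray(list(hdr_values), dtype=float)
    y = np.asarray(list(nhej_values), dtype=float)
    if x.size != y.size:
        raise ValueError("lists must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, True
    r, _ = stats.pearsonr(x, y)
    return float(r * r), False
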