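"""Subset-based Poisson quantification of WT / HDR / NHEJ allele classes.

The standard digital-PCR estimator, lambda = -ln(N_neg / N_total), needs a
set of partitions in which the species of interest is absent (N_neg) and a
reference total (N_total).  In the drop-off/gain-probe assay some droplet
populations are inseparable — WT and NHEJ+WT droplets share one cluster, as
do HDR and HDR+WT — so each class uses the droplet subset in which its
presence/absence is unambiguous:

* NHEJ:  N_neg = empty,                 N_total = empty + NHEJ
* HDR:   N_neg = empty + NHEJ + WT+,    N_total = all four clusters
* WT:    N_neg = empty + NHEJ,          N_total = empty + NHEJ + WT+

Under independent Poisson loading each subset estimator is consistent for
its class rate, because conditioning on "no copies of the other classes"
leaves the class's own occupancy distribution untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gating import ClusterCounts
from .simulate import DEFAULT_DROPLET_VOLUME_NL

__all__ = [
    "PoissonRate",
    "ClassEstimate",
    "QuantEstimate",
    "poisson_lambda",
    "quantify_classes",
    "frequencies_from_copies",
    "merge_wells",
    "subtract_background",
]

_Z95 = float(stats.norm.ppf(0.975))


class SaturatedWellError(ValueError):
    """No negative droplets: the Poisson rate is unbounded."""


@dataclass(frozen=True)
class PoissonRate:
    """A rate estimate (copies per droplet) with its 95% CI and inputs."""

    lam: float
    ci_low: float
    ci_high: float
    se: float
    n_neg: int
    n_total: int


@dataclass(frozen=True)
class ClassEstimate:
    """Quantities for one allele class derived from its PoissonRate."""

    rate: PoissonRate
    copies: float
    concentration: float  # copies/ul
    frequency: float  # % of total template copies (NaN if undefined)


@dataclass(frozen=True)
class QuantEstimate:
    """Per-class estimates plus the droplet totals they were computed from."""

    wt: ClassEstimate
    hdr: ClassEstimate
    nhej: ClassEstimate
    counts: ClusterCounts
    droplet_volume_nl: float

    @property
    def frequencies(self) -> tuple[float, float, float]:
        return (self.wt.frequency, self.hdr.frequency, self.nhej.frequency)


def poisson_lambda(n_neg: int, n_total: int) -> PoissonRate:
    """Estimate copies-per-droplet from negative/total partition counts.

    lambda = -ln(n_neg / n_total).  The 95% CI is a normal interval from the
    delta-method standard error on the log negative fraction,
    SE = sqrt((n_total - n_neg) / (n_total * n_neg)), truncated at zero.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_neg > n_total:
        raise ValueError("n_neg cannot exceed n_total")
    if n_neg == 0:
        raise SaturatedWellError(
            "no negative droplets: rate unbounded (saturated well)"
        )
    lam = -np.log(n_neg / n_total)
    se = np.sqrt((n_total - n_neg) / (n_total * float(n_neg)))
    return PoissonRate(
        lam=float(lam),
        ci_low=float(max(0.0, lam - _Z95 * se)),
        ci_high=float(lam + _Z95 * se),
        se=float(se),
        n_neg=int(n_neg),
        n_total=int(n_total),
    )


def _class_estimate(
    rate: PoissonRate, n_droplets: int, lam_sum: float, droplet_volume_nl: float
) -> ClassEstimate:
    copies = rate.lam * n_droplets
    concentration = rate.lam * 1000.0 / droplet_volume_nl
    frequency = 100.0 * rate.lam / lam_sum if lam_sum > 0 else float("nan")
    return ClassEstimate(rate, float(copies), float(concentration), float(frequency))


def quantify_classes(
    counts: ClusterCounts,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
) -> QuantEstimate:
    """Apply the three subset estimators to gated cluster counts.

    Copies are reported as lambda x (all analyzed droplets), i.e. each class
    rate scaled to the full accepted-droplet set; concentrations assume the
    configured droplet volume.  Frequencies are each class rate as a percent
    of the summed rates and are NaN for an all-empty well.
    """
    if counts.n_empty == 0:
        raise SaturatedWellError("n_empty = 0: all estimators saturated")
    e, n, w, h = counts.n_empty, counts.n_nhej, counts.n_wt_plus, counts.n_hdr_plus
    rate_nhej = poisson_lambda(e, e + n)
    rate_hdr = poisson_lambda(e + n + w, e + n + w + h)
    rate_wt = poisson_lambda(e + n, e + n + w)

    lam_sum = rate_wt.lam + rate_hdr.lam + rate_nhej.lam
    total = counts.n_total
    return QuantEstimate(
        wt=_class_estimate(rate_wt, total, lam_sum, droplet_volume_nl),
        hdr=_class_estimate(rate_hdr, total, lam_sum, droplet_volume_nl),
        nhej=_class_estimate(rate_nhej, total, lam_sum, droplet_volume_nl),
        counts=counts,
        droplet_volume_nl=droplet_volume_nl,
    )


def frequencies_from_copies(
    copies_hdr: float, copies_nhej: float, copies_wt: float
) -> tuple[float, float, float]:
    """Allelic frequencies (%) of (HDR, NHEJ, WT) from per-class copy counts."""
    if min(copies_hdr, copies_nhej, copies_wt) < 0:
        raise ValueError("copy counts must be >= 0")
    total = copies_hdr + copies_nhej + copies_wt
    if total <= 0:
        raise ValueError("at least one copy count must be positive")
    return (
        100.0 * copies_hdr / total,
        100.0 * copies_nhej / total,
        100.0 * copies_wt / total,
    )


def merge_wells(counts_list) -> ClusterCounts:
    """Pool replicate wells by element-wise summation of cluster counts.

    Merging is the digital-PCR way to gain sensitivity: rates estimated from
    pooled counts are unchanged in expectation while their standard errors
    shrink roughly as 1/sqrt(number of wells).
    """
    counts_list = list(counts_list)
    if not counts_list:
        raise ValueError("need at least one well to merge")
    merged = counts_list[0]
    for c in counts_list[1:]:
        merged = merged + c
    return merged


def subtract_background(edited: float, control: float) -> float:
    """Background-corrected frequency: max(0, edited - control).

    Signal measured in an unedited control reflects assay background (e.g.
    template damage or misgated droplets) and is subtracted from the edited
    sample's frequency; negative corrected values are clamped to zero and
    read as "undetectable".
    """
    if edited < 0 or control < 0:
        raise ValueError("frequencies must be >= 0")
    return max(0.0, edited - control)
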