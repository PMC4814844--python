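"""Rectangular gating of two-channel droplet amplitudes into four clusters.

Cluster definitions follow the drop-off/gain-probe assay geometry: droplets
with any HDR allele gain extra FAM and sit at FAM++ (``hdr+``); droplets
containing only NHEJ alleles lose the HEX drop-off signal (FAM+ HEX−,
``nhej``); every other template-positive droplet is FAM+ HEX+ (``wt+``);
double-negatives are ``empty``.  FAM− HEX+ droplets match no cluster
definition and are counted as anomalous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import WellData

__all__ = ["GateConfig", "ClusterCounts", "CLUSTER_LABELS", "assign_clusters",
           "fit_gates_from_controls", "truth_clusters"]

logger = logging.getLogger(__name__)

#: Integer label -> cluster name, in the order counts are reported.
CLUSTER_LABELS = ("empty", "nhej", "wt+", "hdr+", "anomalous")


@dataclass(frozen=True)
class GateConfig:
    """Axis-aligned amplitude thresholds.

    ``fam_low`` separates FAM− from FAM+, ``fam_high`` separates FAM+ from
    FAM++ (the HDR gain-probe level), ``hex_low`` separates HEX− from HEX+.
    """

    fam_low: float = 3000.0
    fam_high: float = 7000.0
    hex_low: float = 3000.0

    def __post_init__(self) -> None:
        vals = (self.fam_low, self.fam_high, self.hex_low)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("gate thresholds must be finite")
        if not self.fam_low < self.fam_high:
            raise ValueError("require fam_low < fam_high")


@dataclass(frozen=True)
class ClusterCounts:
    """Droplet counts per cluster; the sufficient statistic for quantification."""

    n_empty: int
    n_nhej: int
    n_wt_plus: int
    n_hdr_plus: int
    n_anomalous: int = 0

    def __post_init__(self) -> None:
        for name in ("n_empty", "n_nhej", "n_wt_plus", "n_hdr_plus", "n_anomalous"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_total(self) -> int:
        """Droplets in the four assay clusters (anomalous excluded)."""
        return self.n_empty + self.n_nhej + self.n_wt_plus + self.n_hdr_plus

    def __add__(self, other: "ClusterCounts") -> "ClusterCounts":
        return ClusterCounts(
            self.n_empty + other.n_empty,
            self.n_nhej + other.n_nhej,
            self.n_wt_plus + other.n_wt_plus,
            self.n_hdr_plus + other.n_hdr_plus,
            self.n_anomalous + other.n_anomalous,
        )


def _label_amplitudes(ch1: np.ndarray, ch2: np.ndarray, gates: GateConfig) -> np.ndarray:
    fam_pos = ch1 >= gates.fam_low
    fam_hi = ch1 >= gates.fam_high
    hex_pos = ch2 >= gates.hex_low

    labels = np.full(ch1.shape, 4, dtype=np.int8)  # anomalous unless matched
    labels[~fam_pos & ~hex_pos] = 0  # empty
    labels[fam_pos & ~hex_pos] = 1  # nhej
    labels[fam_pos & hex_pos] = 2  # wt+
    labels[fam_hi] = 3  # hdr+ overrides, regardless of HEX
    return labels


def assign_clusters(
    well: WellData, gates: GateConfig | None = None
) -> tuple[ClusterCounts, np.ndarray]:
    """Assign every droplet to one cluster; return counts and per-droplet labels.

    Label precedence follows the assay definition: FAM >= ``fam_high`` is
    HDR+ whatever the HEX amplitude; below that, FAM+ droplets split on HEX
    into NHEJ (HEX−) and WT+ (HEX+); FAM− droplets are empty (HEX−) or
    anomalous (HEX+, excluded from downstream totals with a warning).
    """
    gates = gates or GateConfig()
    labels = _label_amplitudes(well.ch1, well.ch2, gates)
    n = np.bincount(labels, minlength=5)
    counts = ClusterCounts(int(n[0]), int(n[1]), int(n[2]), int(n[3]), int(n[4]))
    if counts.n_anomalous:
        logger.warning(
            "well %s: %d FAM-/HEX+ droplets matched no cluster definition; "
            "excluded from quantification totals",
            well.well_id,
            counts.n_anomalous,
        )
    return counts, labels


def truth_clusters(well: WellData, model=None) -> np.ndarray:
    """Cluster labels implied by simulation truth occupancy (the oracle).

    In multi-probe mode partial HEX retention is amplitude-level randomness,
    so truth labels here reflect occupancy only: any HDR copy -> hdr+, else
    any WT copy -> wt+, else any NHEJ copy -> nhej, else empty.
    """
    if well.truth is None:
        raise ValueError("well carries no truth occupancy")
    wt, hdr, nhej = well.truth[:, 0], well.truth[:, 1], well.truth[:, 2]
    labels = np.zeros(well.n_droplets, dtype=np.int8)
    labels[nhej > 0] = 1
    labels[wt > 0] = 2
    labels[hdr > 0] = 3
    return labels


def _best_two_group_split(values: np.ndarray) -> tuple[float, float, float]:
    """Exact 1-D two-group partition minimizing within-group variance.

    Returns (low-group mean, high-group mean, threshold at the midpoint).
    Equivalent to 1-D 2-means on sorted data, solved by scanning all split
    points with prefix sums.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 2 or x[0] == x[-1]:
        raise ValueError("degenerate input: single cluster; supply manual gates")
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(1, n)  # low group sizes
    sse_lo = csq[:-1] - csum[:-1] ** 2 / k
    sse_hi = (csq[-1] - csq[:-1]) - (csum[-1] - csum[:-1]) ** 2 / (n - k)
    best = int(np.argmin(sse_lo + sse_hi))
    mean_lo = csum[best] / (best + 1)
    mean_hi = (csum[-1] - csum[best]) / (n - best - 1)
    return mean_lo, mean_hi, 0.5 * (mean_lo + mean_hi)


def _check_separation(values: np.ndarray, mean_lo: float, mean_hi: float,
                      threshold: float, what: str) -> None:
    lo = values[values < threshold]
    hi = values[values >= threshold]
    if lo.size < 2 or hi.size < 2:
        raise ValueError(f"degenerate {what}: one group nearly empty; supply manual gates")
    spread = max(lo.std(), hi.std())
    if spread > 0 and (mean_hi - mean_lo) < 4 * spread:
        raise ValueError(f"degenerate {what}: groups not separated; supply manual gates")


def fit_gates_from_controls(negative_well: WellData, positive_well: WellData) -> GateConfig:
    """Fit thresholds from an unedited negative and an edited positive control.

    The negative control carries empty and WT+ droplets and fixes ``fam_low``
    (Ch1 baseline vs FAM+) and ``hex_low`` (Ch2 baseline vs HEX+).  The
    positive control additionally contains HDR FAM++ droplets; ``fam_high``
    is fit on its FAM-positive droplets (FAM+ vs FAM++ groups).  Thresholds
    are midpoints between adjacent group means.  Degenerate (single-cluster)
    channels raise ``ValueError``; gates from configuration always override
    this helper.
    """
    lo, hi, fam_low = _best_two_group_split(negative_well.ch1)
    _check_separation(negative_well.ch1, lo, hi, fam_low, "negative-control FAM")
    lo, hi, hex_low = _best_two_group_split(negative_well.ch2)
    _check_separation(negative_well.ch2, lo, hi, hex_low, "negative-control HEX")

    fam_pos = positive_well.ch1[positive_well.ch1 >= fam_low]
    if fam_pos.size < 2:
        raise ValueError("degenerate positive control: no FAM-positive droplets")
    lo, hi, fam_high = _best_two_group_split(fam_pos)
    _check_separation(fam_pos, lo, hi, fam_high, "positive-control FAM+/FAM++")
    return GateConfig(fam_low=fam_low, fam_high=fam_high, hex_low=hex_low)
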