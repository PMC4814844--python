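"""Serial-dilution sensitivity analysis and limit of detection.

Reproduces the spike-in validation design: synthetic HDR/NHEJ control
alleles are serially diluted 2-fold into a constant WT genomic background,
several wells per dilution point are simulated, gated, merged and
quantified, and the limit of detection (LoD) for each class is the smallest
spike fraction whose 95% confidence interval on the class rate does not
overlap the interval measured from WT-only background wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gating import GateConfig, assign_clusters
from .quantify import QuantEstimate, merge_wells, quantify_classes
from .simulate import AmplitudeModel, TemplateMix, simulate_well, spike_in_mix

__all__ = ["DilutionPoint", "LodResult", "run_dilution_series", "lod_by_ci_nonoverlap",
           "default_twofold_fractions"]


@dataclass(frozen=True)
class DilutionPoint:
    """One dilution point: true spike fraction (%) and its merged estimate."""

    spike_fraction: float
    estimate: QuantEstimate
    wells_merged: int


@dataclass(frozen=True)
class LodResult:
    """CI-non-overlap LoD for one allele class.

    ``lod_fraction`` is the smallest tested fraction that is detected with
    every larger fraction also detected; ``at_floor`` means the smallest
    tested fraction was detected, so the true LoD is at or below it.
    """

    allele_class: str
    lod_fraction: float | None
    at_floor: bool
    background_ci_high: float
    fractions: tuple[float, ...]
    detected: tuple[bool, ...]

    def __str__(self) -> str:
        if self.lod_fraction is None:
            return f"{self.allele_class}: not detected at any tested fraction"
        rel = "<=" if self.at_floor else "="
        return f"{self.allele_class}: LoD {rel} {self.lod_fraction:g}%"


def default_twofold_fractions(start: float = 5.0, floor: float = 0.02) -> list[float]:
    """2-fold dilution ladder in percent, from ``start`` down to >= ``floor``."""
    fractions = []
    f = start
    while f >= floor:
        fractions.append(f)
        f /= 2.0
    return fractions


def _simulate_point(
    fraction_pct: float,
    background_copies: float,
    n_wells: int,
    n_droplets: int,
    model: AmplitudeModel,
    gates: GateConfig,
    rng_seeds,
    spike: tuple[str, ...],
    droplet_volume_nl: float,
) -> QuantEstimate:
    frac = fraction_pct / 100.0
    mix = spike_in_mix(
        background_copies,
        frac if "hdr" in spike else 0.0,
        frac if "nhej" in spike else 0.0,
        n_droplets,
    )
    counts = []
    for w in range(n_wells):
        well = simulate_well(mix, n_droplets, model, seed=next(rng_seeds))
        counts.append(assign_clusters(well, gates)[0])
    return quantify_classes(merge_wells(counts), droplet_volume_nl)


def run_dilution_series(
    fractions,
    background_copies: float = 30_000,
    wells_per_point: int = 2,
    wt_only_wells: int = 4,
    model: AmplitudeModel | None = None,
    seed: int | None = None,
    n_droplets: int = 15_000,
    gates: GateConfig | None = None,
    spike: tuple[str, ...] = ("hdr", "nhej"),
    droplet_volume_nl: float = 0.85,
) -> tuple[list[DilutionPoint], QuantEstimate]:
    """Simulate, gate, merge and quantify a spike-in dilution ladder.

    ``fractions`` are spike percentages of total copies, strictly decreasing;
    each point spikes the classes in ``spike`` at that fraction into a
    ``background_copies`` WT background per well.  WT-only background wells
    (fraction 0) are merged separately.  Returns the per-point estimates and
    the background estimate.
    """
    fractions = [float(f) for f in fractions]
    if not fractions:
        raise ValueError("need at least one dilution fraction")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be >= 0")
    if any(nxt >= prev for prev, nxt in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly decreasing")
    if not set(spike) <= {"hdr", "nhej"}:
        raise ValueError("spike classes must be among {'hdr', 'nhej'}")
    model = model or AmplitudeModel()
    gates = gates or GateConfig()

    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(fractions) * wells_per_point + wt_only_wells))

    points = [
        DilutionPoint(
            spike_fraction=f,
            estimate=_simulate_point(
                f, background_copies, wells_per_point, n_droplets,
                model, gates, seeds, spike, droplet_volume_nl,
            ),
            wells_merged=wells_per_point,
        )
        for f in fractions
    ]

    wt_counts = []
    wt_mix = TemplateMix(lambda_wt=background_copies / n_droplets)
    for _ in range(wt_only_wells):
        well = simulate_well(wt_mix, n_droplets, model, seed=next(seeds))
        wt_counts.append(assign_clusters(well, gates)[0])
    background = quantify_classes(merge_wells(wt_counts), droplet_volume_nl)
    return points, background


def lod_by_ci_nonoverlap(
    points: list[DilutionPoint],
    background: QuantEstimate,
    allele_class: str = "nhej",
) -> LodResult:
    """LoD as the lowest fraction whose 95% CI clears the background CI.

    A point is detected when its class-rate CI lower bound exceeds the
    background class-rate CI upper bound.  The LoD is the smallest tested
    fraction that is detected with all larger fractions also detected
    (consecutive-detection rule, so an isolated low-fraction false positive
    cannot define the LoD).  Points must be sorted by descending fraction.
    """
    if allele_class not in ("hdr", "nhej", "wt"):
        raise ValueError("allele_class must be 'hdr', 'nhej' or 'wt'")
    fracs = [p.spike_fraction for p in points]
    if any(nxt >= prev for prev, nxt in zip(fracs, fracs[1:])):
        raise ValueError("points must be sorted by strictly descending fraction")

    bg_high = getattr(background, allele_class).rate.ci_high
    detected = tuple(
        getattr(p.estimate, allele_class).rate.ci_low > bg_high for p in points
    )

    lod = None
    for frac, det in zip(fracs, detected):
        if det:
            lod = frac
        else:
            break
    at_floor = bool(detected) and all(detected)
    return LodResult(
        allele_class=allele_class,
        lod_fraction=lod,
        at_floor=at_floor,
        background_ci_high=float(bg_high),
        fractions=tuple(fracs),
        detected=detected,
    )
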