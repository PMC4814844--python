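"""Synthetic two-channel droplet data with known ground truth.

Emulates a duplex drop-off/gain-probe ddPCR assay for genome editing: a FAM
reference probe counts every template, a FAM gain probe raises HDR-edited
templates to a second, higher FAM level (FAM++), and a HEX drop-off probe over
the cut site loses its binding site on NHEJ alleles.  Templates partition into
droplets by independent Poisson loading per allele class; droplet fluorescence
is a deterministic function of occupancy plus Gaussian noise and optional
"rain" (droplets displaced toward baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TemplateMix",
    "AmplitudeModel",
    "DropletRecord",
    "WellData",
    "simulate_well",
    "spike_in_mix",
    "make_synthetic_allele",
]

#: Droplet volume in nanolitres used to convert rates to concentrations.
#: Allele frequencies are volume-invariant; copies/ul are not.
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Haploid genome copies per nanogram of human genomic DNA (~3.3 pg/genome,
#: i.e. ~300 copies/ng), used to convert DNA mass to template copies.
GENOME_COPIES_PER_NG = 300.0


@dataclass(frozen=True)
class TemplateMix:
    """Mean template copies per droplet for each allele class.

    The per-class rate ``lambda`` is the Poisson mean governing how many
    copies of that allele land in a single droplet.
    """

    lambda_wt: float = 0.0
    lambda_hdr: float = 0.0
    lambda_nhej: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lambda_wt", "lambda_hdr", "lambda_nhej"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def total(self) -> float:
        return self.lambda_wt + self.lambda_hdr + self.lambda_nhej

    def concentrations(self, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL):
        """Per-class concentration in copies/ul given the droplet volume."""
        if droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")
        f = 1000.0 / droplet_volume_nl  # copies/droplet -> copies/ul
        return (self.lambda_wt * f, self.lambda_hdr * f, self.lambda_nhej * f)

    @classmethod
    def from_concentrations(
        cls,
        wt: float,
        hdr: float,
        nhej: float,
        droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    ) -> "TemplateMix":
        f = droplet_volume_nl / 1000.0
        return cls(wt * f, hdr * f, nhej * f)


@dataclass(frozen=True)
class AmplitudeModel:
    """Cluster amplitude geometry and noise of the two-channel readout.

    Levels are in arbitrary fluorescence units.  ``n_nhej_probes`` > 1 turns
    on multi-probe mode, where an NHEJ allele may retain a secondary drop-off
    probe site (probability ``p_partial_retention``) so that NHEJ-only
    droplets sit at ``hex_partial_level`` instead of HEX baseline — the NHEJ
    cluster then does not entirely lose HEX fluorescence.
    """

    baseline_fam: float = 1000.0
    fam_ref_level: float = 5000.0
    fam_hdr_level: float = 9000.0
    baseline_hex: float = 1000.0
    hex_wt_level: float = 5000.0
    hex_partial_level: float = 3000.0
    noise_sd_fam: float = 300.0
    noise_sd_hex: float = 300.0
    rain_fraction: float = 0.0
    n_nhej_probes: int = 1
    p_partial_retention: float = 0.0

    def __post_init__(self) -> None:
        if not (self.fam_hdr_level > self.fam_ref_level > self.baseline_fam):
            raise ValueError("require fam_hdr_level > fam_ref_level > baseline_fam")
        if not (self.hex_wt_level > self.hex_partial_level >= self.baseline_hex):
            raise ValueError("require hex_wt_level > hex_partial_level >= baseline_hex")
        if not 0 <= self.rain_fraction <= 1:
            raise ValueError("rain_fraction must be in [0, 1]")
        if not 0 <= self.p_partial_retention <= 1:
            raise ValueError("p_partial_retention must be in [0, 1]")
        if self.noise_sd_fam < 0 or self.noise_sd_hex < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.n_nhej_probes < 1:
            raise ValueError("n_nhej_probes must be >= 1")

    def noise_free(self) -> "AmplitudeModel":
        """Copy of this model with noise and rain switched off."""
        return replace(self, noise_sd_fam=0.0, noise_sd_hex=0.0, rain_fraction=0.0)


@dataclass(frozen=True)
class DropletRecord:
    """One droplet: FAM (Ch1) and HEX (Ch2) amplitudes, optional truth."""

    ch1_amplitude: float
    ch2_amplitude: float
    truth_occupancy: tuple[int, int, int] | None = None  # (wt, hdr, nhej)


@dataclass
class WellData:
    """Per-well droplet amplitudes, vectorized.

    ``ch1``/``ch2`` are parallel float arrays (FAM, HEX); ``truth`` is an
    optional ``(n, 3)`` integer array of per-droplet (WT, HDR, NHEJ) template
    copies carried through from simulation.
    """

    well_id: str
    ch1: np.ndarray
    ch2: np.ndarray
    sample_id: str = ""
    truth: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape or self.ch1.ndim != 1:
            raise ValueError("ch1 and ch2 must be 1-D arrays of equal length")
        if self.ch1.size == 0:
            raise ValueError("a well must contain at least one droplet")
        if not (np.isfinite(self.ch1).all() and np.isfinite(self.ch2).all()):
            raise ValueError("amplitudes must be finite")
        if self.truth is not None:
            self.truth = np.asarray(self.truth, dtype=int)
            if self.truth.shape != (self.ch1.size, 3):
                raise ValueError("truth must have shape (n_droplets, 3)")
            if (self.truth < 0).any():
                raise ValueError("truth occupancies must be >= 0")

    @property
    def n_droplets(self) -> int:
        return int(self.ch1.size)

    @property
    def droplets(self) -> list[DropletRecord]:
        occ = self.truth
        return [
            DropletRecord(
                float(self.ch1[i]),
                float(self.ch2[i]),
                tuple(int(x) for x in occ[i]) if occ is not None else None,
            )
            for i in range(self.n_droplets)
        ]


def simulate_well(
    mix: TemplateMix,
    n_droplets: int,
    model: AmplitudeModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
    well_id: str = "A01",
    sample_id: str = "",
    metadata: dict | None = None,
) -> WellData:
    """Simulate one well of droplets under independent Poisson loading.

    Each droplet draws independent Poisson occupancies (WT, HDR, NHEJ) with
    the rates in ``mix``.  Endpoint PCR saturates, so co-occupied droplets
    take the class maximum per channel, not the sum: any HDR copy puts FAM at
    ``fam_hdr_level`` (FAM++); otherwise any WT or NHEJ copy puts FAM at
    ``fam_ref_level``; otherwise FAM baseline.  HEX is at ``hex_wt_level`` if
    any WT copy is present, at ``hex_partial_level`` if (in multi-probe mode)
    an NHEJ copy retains a secondary probe site, else HEX baseline.  Rain and
    Gaussian noise are applied after level assignment.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    model = model or AmplitudeModel()
    rng = np.random.default_rng(seed)

    # fixed draw order (WT, HDR, NHEJ) so seeds are reproducible
    occ_wt = rng.poisson(mix.lambda_wt, n_droplets)
    occ_hdr = rng.poisson(mix.lambda_hdr, n_droplets)
    occ_nhej = rng.poisson(mix.lambda_nhej, n_droplets)

    any_wt = occ_wt > 0
    any_hdr = occ_hdr > 0
    any_nhej = occ_nhej > 0

    fam = np.full(n_droplets, model.baseline_fam)
    fam[any_wt | any_nhej] = model.fam_ref_level
    fam[any_hdr] = model.fam_hdr_level

    hex_ = np.full(n_droplets, model.baseline_hex)
    if model.n_nhej_probes > 1 and model.p_partial_retention > 0:
        # at least one of the droplet's NHEJ copies keeps a secondary site
        retains = rng.random(n_droplets) < (
            1.0 - (1.0 - model.p_partial_retention) ** np.maximum(occ_nhej, 1)
        )
        hex_[any_nhej & retains] = model.hex_partial_level
    hex_[any_wt] = model.hex_wt_level

    if model.rain_fraction > 0:
        rainy = rng.random(n_droplets) < model.rain_fraction
        u = rng.random(n_droplets)  # same displacement on both channels
        fam = np.where(rainy, model.baseline_fam + u * (fam - model.baseline_fam), fam)
        hex_ = np.where(rainy, model.baseline_hex + u * (hex_ - model.baseline_hex), hex_)

    if model.noise_sd_fam > 0:
        fam = fam + rng.normal(0.0, model.noise_sd_fam, n_droplets)
    if model.noise_sd_hex > 0:
        hex_ = hex_ + rng.normal(0.0, model.noise_sd_hex, n_droplets)

    truth = np.column_stack([occ_wt, occ_hdr, occ_nhej])
    return WellData(
        well_id=well_id,
        ch1=fam,
        ch2=hex_,
        sample_id=sample_id,
        truth=truth,
        metadata=dict(metadata or {}),
    )


def spike_in_mix(
    wt_copies: float,
    hdr_fraction: float,
    nhej_fraction: float,
    n_droplets: int,
) -> TemplateMix:
    """Per-droplet rates for a WT background spiked with synthetic alleles.

    ``hdr_fraction`` and ``nhej_fraction`` are fractions of *total* template
    copies (not of WT), mirroring a spike-in of synthetic HDR/NHEJ control
    alleles into a fixed mass of WT genomic DNA: total copies are
    ``wt_copies / (1 - hdr_fraction - nhej_fraction)``.
    """
    if wt_copies < 0:
        raise ValueError("wt_copies must be >= 0")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    for name, f in (("hdr_fraction", hdr_fraction), ("nhej_fraction", nhej_fraction)):
        if not 0 <= f < 1:
            raise ValueError(f"{name} must be in [0, 1)")
    if hdr_fraction + nhej_fraction >= 1:
        raise ValueError("spike fractions must sum to < 1")
    total = wt_copies / (1.0 - hdr_fraction - nhej_fraction)
    return TemplateMix(
        lambda_wt=wt_copies / n_droplets,
        lambda_hdr=total * hdr_fraction / n_droplets,
        lambda_nhej=total * nhej_fraction / n_droplets,
    )


_BASES = set("ACGT")


def make_synthetic_allele(wt_amplicon: str, edit: dict) -> str:
    """Build a synthetic control-allele sequence from the WT amplicon.

    ``edit`` is a dict: ``{"op": "substitute", "position": i, "base": "A"}``
    replaces the base at 0-based position ``i`` (HDR point-mutation control);
    ``{"op": "delete", "position": i, "length": k}`` removes ``k`` bases
    starting at ``i`` (the canonical NHEJ control is a 1-bp deletion at the
    predicted cut site); ``{"op": "insert", "position": i, "sequence": s}``
    inserts ``s`` at inter-base position ``i`` (1-bp and 4-bp insertion
    controls behave equivalently to the deletion control).
    """
    seq = wt_amplicon.upper()
    if not set(seq) <= _BASES:
        raise ValueError("amplicon must be over {A,C,G,T}")
    op = edit.get("op")
    pos = int(edit["position"])
    n = len(seq)
    if op == "substitute":
        base = edit["base"].upper()
        if base not in _BASES:
            raise ValueError(f"invalid base {base!r}")
        if not 0 <= pos < n:
            raise ValueError("substitution position outside amplicon")
        return seq[:pos] + base + seq[pos + 1 :]
    if op == "delete":
        length = int(edit.get("length", 1))
        if length < 1:
            raise ValueError("deletion length must be >= 1")
        if not (0 <= pos and pos + length <= n):
            raise ValueError("deletion outside amplicon")
        return seq[:pos] + seq[pos + length :]
    if op == "insert":
        ins = edit["sequence"].upper()
        if not set(ins) <= _BASES:
            raise ValueError("insertion must be over {A,C,G,T}")
        if not 0 <= pos <= n:
            raise ValueError("insertion position outside amplicon")
        return seq[:pos] + ins + seq[pos:]
    raise ValueError(f"unknown edit op {op!r}")
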