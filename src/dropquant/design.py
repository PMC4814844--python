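"""Assay design rules for drop-off/gain-probe editing assays.

Encodes the placement rules that make the quantification valid: the
predicted nuclease cut site sits mid-amplicon with 75-125 bp of flank to
each primer, at least one primer lies outside the donor so that unintegrated
donor molecules are not counted as edits, the reference probe keeps away
from the cut site (the nexus of NHEJ-generated sequence loss) and the donor
span, every NHEJ drop-off probe covers a cut site, and the HDR gain probe
covers the intended edit.  Also provides nearest-neighbor melting
temperatures under the thermodynamic settings used for assay design (50 mM
monovalent, 3.0 mM divalent, 0 mM dNTPs, SantaLucia-1998 parameters) and a
rule for when a dark (non-extendible) blocking oligo is advisable.

All coordinates are 0-based half-open intervals on the reference strand;
cut sites are inter-base indices (position k lies between bases k-1 and k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Interval",
    "Guide",
    "NucleasePair",
    "NucleaseSpec",
    "AssayLayout",
    "RuleReport",
    "predict_cut_sites",
    "validate_layout",
    "melting_temperature",
    "dark_probe_recommended",
]


@dataclass(frozen=True)
class Interval:
    """0-based half-open [start, end) on the reference strand."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def within(self, other: "Interval") -> bool:
        return other.start <= self.start and self.end <= other.end


@dataclass(frozen=True)
class Guide:
    """A CRISPR guide: protospacer interval, strand, and PAM side.

    On the plus strand the PAM is 3' of the protospacer (reference
    coordinates just past ``protospacer.end``); on the minus strand the PAM
    lies at reference coordinates just before ``protospacer.start``.
    """

    protospacer: Interval
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if len(self.protospacer) < 17:
            raise ValueError("protospacer implausibly short")


@dataclass(frozen=True)
class NucleasePair:
    """Left/right DNA-binding intervals of a TALEN or FokI-dCas9 pair."""

    left: Interval
    right: Interval

    def __post_init__(self) -> None:
        if self.left.overlaps(self.right):
            raise ValueError("binding arms must not overlap")
        if self.right.start < self.left.end:
            raise ValueError("right arm must lie 3' of left arm")


@dataclass(frozen=True)
class NucleaseSpec:
    """A nuclease configuration: CRISPR guides and/or dimeric binding pairs.

    ``kind`` is one of 'crispr' (single or dual guides), 'talen', or
    'foki-dcas9'.  Dimeric kinds carry exactly one binding pair; CRISPR
    carries one or two guides.
    """

    kind: str
    guides: tuple[Guide, ...] = ()
    pair: NucleasePair | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("crispr", "talen", "foki-dcas9"):
            raise ValueError(f"unknown nuclease kind {self.kind!r}")
        if self.kind == "crispr":
            if not 1 <= len(self.guides) <= 2 or self.pair is not None:
                raise ValueError("CRISPR spec needs 1 or 2 guides and no binding pair")
        else:
            if self.pair is None or self.guides:
                raise ValueError(f"{self.kind} spec needs a binding pair and no guides")


def predict_cut_sites(spec: NucleaseSpec) -> list[int]:
    """Predicted cut positions: 3 bp upstream of the PAM for CRISPR guides,
    the midpoint of the spacer between binding domains for TALEN/FokI-dCas9.

    Cut positions are inter-base indices.  For a plus-strand guide with
    protospacer [s, e) the blunt cut falls between positions e-4 and e-3,
    i.e. index e-3; the minus-strand convention mirrors it (index s+3).
    Odd TALEN spacers floor the midpoint.  Dual systems return one site per
    guide, sorted.
    """
    sites: list[int] = []
    if spec.kind == "crispr":
        for g in spec.guides:
            if g.strand == "+":
                sites.append(g.protospacer.end - 3)
            else:
                sites.append(g.protospacer.start + 3)
    else:
        spacer = Interval(spec.pair.left.end, spec.pair.right.start)
        sites.append((spacer.start + spacer.end) // 2)
    return sorted(sites)


@dataclass(frozen=True)
class AssayLayout:
    """Interval model of one assay: amplicon, primers, probes, cut sites,
    donor span and edit position."""

    amplicon: Interval
    fwd_primer: Interval
    rev_primer: Interval
    ref_probe: Interval
    hdr_probe: Interval
    nhej_probes: tuple[Interval, ...]
    cut_sites: tuple[int, ...]
    donor_span: Interval
    edit_position: int
    dark_probe: Interval | None = None

    def __post_init__(self) -> None:
        probes = (self.ref_probe, self.hdr_probe, *self.nhej_probes)
        for p in probes:
            if len(p) == 0:
                raise ValueError("probe intervals must be non-degenerate")
        for iv in (self.fwd_primer, self.rev_primer, *probes):
            if not iv.within(self.amplicon):
                raise ValueError("all intervals must lie within the amplicon")
        if not self.nhej_probes:
            raise ValueError("need at least one NHEJ probe")
        if not self.cut_sites:
            raise ValueError("need at least one predicted cut site")
        if self.fwd_primer.start != self.amplicon.start:
            raise ValueError("forward primer must start the amplicon")
        if self.rev_primer.end != self.amplicon.end:
            raise ValueError("reverse primer must end the amplicon")


@dataclass(frozen=True)
class RuleCheck:
    rule: str
    passed: bool
    message: str


@dataclass(frozen=True)
class RuleReport:
    checks: tuple[RuleCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def as_records(self) -> list[dict]:
        return [vars(c) for c in self.checks]


#: Required flank between a cut site and each inner primer boundary (bp).
FLANK_MIN, FLANK_MAX = 75, 125
#: Default half-width of the exclusion window around each cut site inside
#: which the reference probe must not bind (bp).
DEFAULT_CUT_EXCLUSION_BP = 30


def validate_layout(
    layout: AssayLayout, cut_exclusion_bp: int = DEFAULT_CUT_EXCLUSION_BP
) -> RuleReport:
    """Check an assay layout against the placement rules.

    Rules: (a) each cut site keeps 75-125 bp of flank to each inner primer
    boundary; (b) at least one primer is disjoint from the donor span;
    (c) the reference probe avoids a ``cut_exclusion_bp`` window around each
    cut site and the donor span; (d) every NHEJ probe interval overlaps a cut
    site; (e) the HDR probe contains the edit position.  Report-style
    output: nothing raises, each rule carries a pass flag and message.
    """
    checks: list[RuleCheck] = []

    inner_left = layout.fwd_primer.end
    inner_right = layout.rev_primer.start
    flank_ok, parts = True, []
    for cut in layout.cut_sites:
        left, right = cut - inner_left, inner_right - cut
        ok = FLANK_MIN <= left <= FLANK_MAX and FLANK_MIN <= right <= FLANK_MAX
        flank_ok &= ok
        parts.append(f"cut {cut}: flanks {left}/{right} bp")
    checks.append(RuleCheck(
        "cut_site_flanks", flank_ok,
        "; ".join(parts) + f" (required {FLANK_MIN}-{FLANK_MAX})",
    ))

    fwd_out = not layout.fwd_primer.overlaps(layout.donor_span)
    rev_out = not layout.rev_primer.overlaps(layout.donor_span)
    checks.append(RuleCheck(
        "primer_outside_donor", fwd_out or rev_out,
        f"forward {'outside' if fwd_out else 'inside'} donor span, "
        f"reverse {'outside' if rev_out else 'inside'} donor span",
    ))

    ref_clear = not layout.ref_probe.overlaps(layout.donor_span)
    for cut in layout.cut_sites:
        window = Interval(cut - cut_exclusion_bp, cut + cut_exclusion_bp)
        ref_clear &= not layout.ref_probe.overlaps(window)
    checks.append(RuleCheck(
        "ref_probe_distant", ref_clear,
        f"reference probe vs donor span and +/-{cut_exclusion_bp} bp cut windows",
    ))

    # a drop-off probe destroys its signal only if the break falls inside it
    nhej_ok = all(
        any(p.start < cut < p.end for cut in layout.cut_sites)
        for p in layout.nhej_probes
    )
    checks.append(RuleCheck(
        "nhej_probe_covers_cut", nhej_ok,
        "every NHEJ drop-off probe must span a predicted cut site",
    ))

    checks.append(RuleCheck(
        "hdr_probe_covers_edit", layout.hdr_probe.contains(layout.edit_position),
        f"HDR probe {layout.hdr_probe.start}-{layout.hdr_probe.end} vs edit at "
        f"{layout.edit_position}",
    ))
    return RuleReport(tuple(checks))


# --- nearest-neighbor melting temperature (SantaLucia 1998 unified set) ---

# dH kcal/mol, dS cal/(mol K); key is the 5'->3' dimer on the probe strand.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# Duplex initiation with a terminal G.C vs terminal A.T pair.
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}

_R = 1.987  # gas constant, cal/(mol K)


def _effective_monovalent_mM(monovalent_mM: float, divalent_mM: float,
                             dntp_mM: float) -> float:
    # von Ahsen conversion: divalent cations beyond those chelated by dNTPs
    # act like 120*sqrt(c) mM of monovalent salt.
    free_div = max(divalent_mM - dntp_mM, 0.0)
    return monovalent_mM + 120.0 * math.sqrt(free_div)


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if not set(seq) <= set("ACGT"):
        raise ValueError("sequence must be over {A,C,G,T} (no ambiguity codes)")
    return seq


def _tm_from_thermo(dh_kcal: float, ds_cal: float, n_stacks: int,
                    monovalent_mM: float, divalent_mM: float, dntp_mM: float,
                    oligo_conc_nM: float) -> float:
    na_eff = _effective_monovalent_mM(monovalent_mM, divalent_mM, dntp_mM) / 1000.0
    ds_cal = ds_cal + 0.368 * n_stacks * math.log(na_eff)
    ct = oligo_conc_nM * 1e-9
    # oligo in excess over target: effective concentration CT/4
    return dh_kcal * 1000.0 / (ds_cal + _R * math.log(ct / 4.0)) - 273.15


def melting_temperature(
    seq: str,
    monovalent_mM: float = 50.0,
    divalent_mM: float = 3.0,
    dntp_mM: float = 0.0,
    oligo_conc_nM: float = 50.0,
) -> float:
    """Duplex melting temperature (degC) of an oligo against its perfect
    complement, by SantaLucia-1998 nearest-neighbor thermodynamics.

    Stack and initiation dH/dS are summed over the sequence, the entropic
    salt correction 0.368 * N_stacks * ln[Na+] is applied with divalent
    cations folded into an effective monovalent concentration
    (120*sqrt(divalent - dNTP) mM), and Tm = dH / (dS + R ln(CT/4)).
    """
    seq = _check_seq(seq)
    if len(seq) < 8:
        raise ValueError("sequence must be at least 8 nt")
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        h, s = _INIT[term]
        dh += h
        ds += s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    return _tm_from_thermo(dh, ds, len(seq) - 1, monovalent_mM, divalent_mM,
                           dntp_mM, oligo_conc_nM)


def _tm_against_template(probe: str, template: str, monovalent_mM: float,
                         divalent_mM: float, dntp_mM: float,
                         oligo_conc_nM: float) -> float:
    """Approximate Tm of ``probe`` hybridized to a near-identical
    ``template``: nearest-neighbor stacks touching a mismatched position are
    dropped (contribute no stability); initiation terms kept for matched
    termini only."""
    dh, ds, n_stacks = 0.0, 0.0, 0
    if probe[0] == template[0]:
        h, s = _INIT[probe[0]]
        dh, ds = dh + h, ds + s
    if probe[-1] == template[-1]:
        h, s = _INIT[probe[-1]]
        dh, ds = dh + h, ds + s
    for i in range(len(probe) - 1):
        if probe[i] == template[i] and probe[i + 1] == template[i + 1]:
            h, s = _NN[probe[i : i + 2]]
            dh, ds = dh + h, ds + s
            n_stacks += 1
    if n_stacks == 0:
        return float("-inf")
    return _tm_from_thermo(dh, ds, n_stacks, monovalent_mM, divalent_mM,
                           dntp_mM, oligo_conc_nM)


def dark_probe_recommended(
    hdr_probe_seq: str,
    wt_local_seq: str,
    tm_margin_c: float = 8.0,
    monovalent_mM: float = 50.0,
    divalent_mM: float = 3.0,
    dntp_mM: float = 0.0,
    oligo_conc_nM: float = 50.0,
) -> tuple[bool, str]:
    """Decide whether a dark (3'-blocked) oligo is needed to stop the HDR
    gain probe cross-hybridizing to the WT sequence.

    Recommended when the probe differs from WT at no more than one base AND
    its approximate Tm against WT is within ``tm_margin_c`` (inclusive) of
    its matched Tm — i.e. the single mismatch does not destabilize binding
    enough to keep the probe off unedited templates.
    """
    probe = _check_seq(hdr_probe_seq)
    wt = _check_seq(wt_local_seq)
    if len(probe) != len(wt):
        raise ValueError("probe and WT sequences must be aligned (equal length)")
    if len(probe) < 8:
        raise ValueError("probe must be at least 8 nt")
    mismatches = sum(a != b for a, b in zip(probe, wt))
    if mismatches == 0:
        return True, "probe identical to WT: always cross-reactive"
    if mismatches > 1:
        return False, f"{mismatches} mismatches vs WT: cross-hybridization unlikely"
    tm_matched = melting_temperature(probe, monovalent_mM, divalent_mM, dntp_mM,
                                     oligo_conc_nM)
    tm_wt = _tm_against_template(probe, wt, monovalent_mM, divalent_mM, dntp_mM,
                                 oligo_conc_nM)
    delta = tm_matched - tm_wt
    if delta <= tm_margin_c:
        return True, (f"single mismatch, Tm penalty {delta:.1f} degC <= "
                      f"{tm_margin_c:g} degC margin: dark probe recommended")
    return False, (f"single mismatch but Tm penalty {delta:.1f} degC exceeds "
                   f"{tm_margin_c:g} degC margin")
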