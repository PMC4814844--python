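# Methods

## Droplet model

The simulator emulates an endpoint duplex ddPCR readout of a
drop-off/gain-probe editing assay. A well is a set of monodisperse droplets;
each droplet receives independent Poisson numbers of WT, HDR and NHEJ
template copies with per-class means (λ_wt, λ_hdr, λ_nhej). Independence
across classes and droplets is the standard dilute-template partitioning
assumption; it is also what makes the subset estimators below consistent.

Fluorescence is a deterministic function of occupancy, plus noise. Endpoint
PCR saturates, so a co-occupied droplet takes the class *maximum* per
channel, not the sum: any HDR copy → FAM at the FAM++ level; otherwise any
template → FAM+ ; any WT copy → HEX+. In multi-probe assays (two NHEJ
drop-off probes, used when dual nucleases cut at two sites) an NHEJ allele
may retain the secondary probe's binding site, so NHEJ-only droplets sit at
a partial HEX level rather than HEX baseline; this is controlled by
`n_nhej_probes` and `p_partial_retention` (per-copy retention probability;
a droplet shows partial HEX if any of its NHEJ copies retains a site).

Default amplitude geometry (arbitrary units): baselines (1000, 1000), FAM+
5000, FAM++ 9000, HEX+ 5000, partial HEX 3000, Gaussian noise SD 300 per
channel. These were chosen so the default rectangular gates (fam_low 3000,
fam_high 7000, hex_low 3000) sit many noise SDs from every level —
cluster separation, not gate placement, is what the simulator is meant to
probe. "Rain" (droplets of intermediate amplitude, from partial
amplification) is modeled as a configurable fraction of droplets displaced
uniformly toward baseline with one displacement factor shared by both
channels; the default is 0 because rain magnitude is instrument- and
assay-specific.

Conversions: droplet volume defaults to 0.85 nL (configurable; frequencies
are volume-invariant, concentrations are not) and human genomic DNA is
taken as 300 haploid copies/ng, so the conventional 100 ng input is
~30,000 copies per well. Default droplet count is 15,000/well, a typical
accepted-droplet count for this instrument class. One seeded generator
drives each well, with draws in a fixed order (WT, HDR, NHEJ occupancies,
then retention, rain, noise), so a seed fully determines a well.

## Gating

Gates are axis-aligned thresholds: FAM ≥ fam_high → HDR+ regardless of HEX
(HDR+WT droplets are HEX+ but still belong to the HDR class); below that,
FAM+ droplets split on hex_low into NHEJ (HEX−) and WT+ (HEX+); FAM−/HEX−
is empty. FAM−/HEX+ matches no cluster definition; such droplets are
counted as anomalous, excluded from downstream totals, and logged. The
threshold form was chosen over free polygons because the clusters are
axis-aligned and manual polygon gating is not reproducible.

`fit_gates_from_controls` is an optional aid: per channel it solves the
exact 1-D two-group minimum-within-variance partition (prefix-sum scan,
equivalent to 1-D 2-means) on a negative control (baseline vs positive
groups on each channel) and on the positive control's FAM-positive droplets
(FAM+ vs FAM++), placing each threshold at the midpoint of the two group
means. Inputs whose groups are nearly empty or separated by less than four
within-group SDs are rejected as degenerate rather than silently fit;
configured gates always override fitted ones. For multi-probe assays
`hex_low` must be placed between the partial and full HEX levels — there
is no principled automatic rule, so this is left to configuration.

## Quantification

λ = −ln(N_neg/N_total) per class over the subsets listed in the README.
The 95% CI is a normal interval with the delta-method SE of the log
negative fraction, SE = √((N_total−N_neg)/(N_total·N_neg)), truncated at
zero; with every droplet negative the estimate is exactly 0 with a
degenerate CI. A well with no empty droplets is rejected as saturated
(rate unbounded), matching the practice of loading 2,000–40,000 copies per
reaction so wells stay unsaturated.

Copies are reported as λ × (all analyzed droplets) — the class rate scaled
to the full accepted-droplet set; whether an instrument reports copies per
analyzed volume or per accepted droplets varies, and frequencies are
unaffected by this choice. Frequencies are λ_class/Σλ × 100 and sum to
100% whenever defined (an all-empty well has no defined frequencies and is
flagged). Wells are merged by summing cluster counts before estimation,
which leaves rates unchanged in expectation and shrinks SEs ≈ 1/√wells.
Background subtraction (edited − unedited control, per class) clamps at
zero: a negative corrected frequency has no physical meaning and reads as
"undetectable". Percentages are kept at full precision and rounded to one
decimal only for display.

## Limit of detection

A dilution series spikes synthetic HDR/NHEJ control alleles at 2-fold
decreasing fractions of total copies into a constant WT background
(default: 5% → ~0.02%, 30,000 copies per 15,000-droplet well, two merged
wells per point, four merged WT-only wells). A point is *detected* when its
class-rate CI lower bound exceeds the WT-only background's CI upper bound;
the LoD is the smallest detected fraction with all larger fractions also
detected (the consecutive-detection rule keeps an isolated low-fraction
fluctuation from defining the LoD). Detection is decided on the rate (λ)
scale, where the CI is computed, rather than the derived frequency scale.
If the lowest tested fraction is detected the result is reported as
"≤ lowest tested". The simulated background contains no false-positive
droplets by default; a misgating rate can be emulated by raising the
amplitude noise or rain. No probit/LoD95 modeling is attempted — only the
CI non-overlap rule.

## Study summaries

Conditions (locus × nuclease × guides × donor strand × cell type) carry
per-replicate HDR and NHEJ frequencies, typically n = 6. `summarize`
reports mean ± SEM (sd/√n) and a classical two-sample, equal-variance,
two-tailed Student's t-test between the HDR and NHEJ replicate sets (the
paired/pooled structure of replicates across transfections is not modeled);
identical zero-variance sets give p = 1. Conditions rank into five tiers,
best to worst: (1) >0.1% HDR with HDR ≥ NHEJ, (2) ≤0.1% HDR with
HDR ≥ NHEJ, (3) NHEJ above HDR but within 2-fold (no HDR threshold),
(4) >0.1% HDR with NHEJ > 2×HDR, (5) otherwise. Boundary ties (HDR = NHEJ,
HDR = 0.1%, NHEJ = 2×HDR) are assigned to the better tier. HDR/NHEJ
correlation is the squared Pearson r of the per-condition frequency pairs,
with zero-valued points included; constant inputs are flagged degenerate
with R² reported as 0.

## Assay design rules

Coordinates are 0-based half-open on the reference strand; cut sites are
inter-base indices (k is between bases k−1 and k). Predicted cuts: CRISPR
blunt cut 3 bp 5′ of the PAM (plus-strand protospacer [s,e) → index e−3;
minus strand mirrored → s+3 — the paper-equivalent convention for minus
strands is taken as the mirror image); TALEN/FokI-dCas9 cut at the floor
midpoint of the spacer between binding arms. Layout validation checks:
75–125 bp between each cut site and each inner primer boundary (cut
mid-amplicon); at least one primer outside the donor span (so unintegrated
donor is never amplified and counted); the reference probe clear of the
donor span and of a ±30 bp window around every cut site ("distant from the
cut" is not a number anywhere, so 30 bp is a configurable default); every
NHEJ probe spanning a cut site; the HDR probe containing the edit position.

Melting temperatures use SantaLucia-1998 unified nearest-neighbor
parameters with the entropic salt correction 0.368·N_stacks·ln[Na⁺] and
divalent cations folded into an effective monovalent concentration as
120·√(divalent − dNTP) mM, at the design-tool conditions 50 mM
monovalent, 3 mM divalent, 0 mM dNTPs, 50 nM oligo (CT/4 excess
approximation). A dark (3′-blocked) competitor oligo is recommended when
the HDR probe differs from WT by ≤1 base and its Tm against the WT
sequence is within 8 °C (inclusive, configurable) of its matched Tm. The
cross-hybridization Tm is approximated by dropping nearest-neighbor stacks
that touch the mismatch rather than using full mismatch tables — a
deliberate, documented overestimate of the penalty that errs toward
recommending the dark probe.

## Problem sizes and what the tests show

Property tests verify: Poisson void-fraction and estimator consistency at
10⁶ droplets (3 SE), exhaustive agreement of the subset estimators with
direct formula evaluation for every cluster-count composition up to 50
droplets, exact truth recovery of gating at zero noise, frequency
normalization, tier-partition totality, and Tm agreement with an
independent nearest-neighbor implementation within 0.5 °C. Validation runs
use one 15,000-droplet well for spike-in recovery and 8-point ladders with
two 15,000-droplet wells per point for LoD.

The simulator reproduces partition statistics and cluster geometry, not
chemistry: no droplet-volume variability, no probe cross-talk or
competition kinetics, no systematic rain structure, and background false
positives only if configured. Passing tests therefore demonstrate the
correctness of the estimators and rules given the assay's statistical
model — not that any particular wet-lab assay achieves these LoDs.
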