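# Methods

## Model

One qPCR reaction receives template molecules by Poisson partitioning: if
the extract loaded into the reaction carries a mean of λ copies, the
realized copy number is `k ~ Poisson(λ)` and the reaction is positive with
probability `p = 1 − e^(−λ)`. A positive reaction crosses the fluorescence
threshold at

    Ct = intercept + slope · log10(copies per reaction),

the log-linear calibration with `slope < 0` in cycles per decade. The
amplification efficiency is `E = 10^(−1/slope) − 1`; a slope of −3.3219
cycles/decade is perfect per-cycle doubling (100%). Inverting the curve
gives `copies = 10^((Ct − intercept)/slope)`, and copies per reaction
convert to copies per litre of filtered water by

    C_L = C_r · (V_e / V_r) / V_w

with `V_e` the extract elution volume (µL), `V_r` the template volume per
reaction (µL) and `V_w` the filtered water volume (L). This assumes
complete capture on the filter and complete recovery into the eluate, so
`C_L` is an *effective* concentration, comparable across samples processed
the same way rather than an absolute census of molecules in the lake.

## Single-molecule (MPN) copy estimation

Near the detection limit, absolute copy numbers are estimated from
positive/negative replicate ratios rather than from instrument
fluorescence: with `k` positives of `n` replicates, the maximum-likelihood
estimate is `λ̂ = −ln((n−k)/n)` (undefined when all replicates are
positive — the remedy is more replicates at that dilution, and
`SaturatedOutcomeError` says so). A mean load of ~1 copy/reaction yields
a 7:3 positive:negative ratio. The estimate anchors one dilution of a
serial standard series; more concentrated standards receive
`λ̂ · fold^(steps)`. An optional Clopper–Pearson interval on the positive
fraction is transformed through `−ln(1−p)`; the single-dilution closed
form is used rather than multi-dilution maximum likelihood because the
workflow anchors on the one standard nearest 70% detection.

## LOD and LOQ

Two conventions are implemented side by side:

- **Replicate scheme** (`lod_loq_danish`): LOD is the lowest standard
  concentration with at least one positive replicate, LOQ the lowest at
  which *all* replicates amplify. Three replicates per tenfold dilution is
  the conventional design; the rule generalises to any replicate count.
  The two limits coincide whenever the same dilution first satisfies both.
- **Statistical scheme** (`lod_statistical`, `loq_norwegian`): LOD is the
  smallest λ with false-negative probability `e^(−λ) ≤ α`
  (`λ* = ln 20 ≈ 3.0` copies/reaction at α = 5%; 5 copies/reaction gives
  a 0.67% false-negative rate). LOQ is the lowest fully-detected
  concentration whose replicate Ct standard deviation is below ±0.5 cycles.

A replicate counts as positive only when its Ct is below the cut-off
(41 cycles by default): later signals are characteristic of carry-over
contamination and are censored to non-detect, with the original Ct kept in
an audit field.

## Inhibition and the decision rules

Humic substances co-extracted from environmental water inhibit
polymerase, delaying or suppressing amplification in undiluted extract. The
dilution-pair design (2 undiluted + 2 ten-fold-diluted replicates) measures
this directly: ΔCt = mean(diluted) − mean(undiluted) is 3.32 cycles
(= log2 10) for a clean 10× dilution at ~100% efficiency. The accepted
window is 3.32 ± 0.5 (2.82–3.82, boundaries inclusive — the exception
branches are defined by strict inequalities, which forces inclusivity):

- within the window → quantify from all replicates, diluted estimates
  multiplied by 10 back to the extract scale;
- ΔCt < 2.82 (inhibition) → quantify from the diluted replicates only;
- ΔCt > 3.82 (dilution out of range) → quantify from the undiluted
  replicates only.

In both decision schemes a sample is *detected* only with ≥ 2 positive
replicates of 4; it is *quantified* only when ≥ 2 of the branch-relevant
replicates sit at or above the LOQ (the LOQ is compared against what the
reaction itself contained), otherwise it is reported `<LOQ>`. In the
single-dilution scheme, non-detect replicates enter the per-filter mean as
zero copies once the sample qualifies for quantification. A single
positive replicate is reported as `0` — under Poisson statistics a lone
late positive is equally consistent with trace contamination. Reported SDs
are across replicate-level copies/L estimates within a filter. Site
summaries average quantified filters (with not-detected filters as zero)
and flag below-LOQ filters explicitly rather than imputing LOQ/2.

## Specificity screening

Cross-reactivity risk of a primer/probe set against non-target species is
scored as the minimum Hamming mismatch count of each oligo over all
windows of the candidate CO1 sequence (reverse primers are
reverse-complemented and scanned on the forward strand; gaps from
pre-aligned input are removed first; ties break to the leftmost window).
IUPAC ambiguity codes match when the base sets intersect — conservative
for a specificity claim. Best-window placement is a deliberate choice over
fixed alignment columns: it can only under-count mismatches, never
over-count, so a "≥ 6 mismatches" verdict is robust to alignment
uncertainty. No thermodynamic modelling (Tm, ΔG) is attempted; the score
is a sequence-distance screen, not a hybridisation prediction.

## Synthetic data generator

`simulate` draws each well's copy number from Poisson(λ) with
λ = extract concentration × template volume / dilution factor, then
generates Ct from the *realized* copy count plus Gaussian noise
(default SD 0.3 cycles) — realized-copy generation is what produces the
stochastic partial detection and inflated variance below the LOQ that the
analysis rules exist to handle. Zero realized copies, or a Ct beyond the
50-cycle budget, is a non-detect. Inhibition is modelled as an additive Ct
shift on undiluted wells only, fully removed by 10× dilution — the minimal
model consistent with the ΔCt remedy. Surveys assume complete
filter-to-eluate recovery; blanks and no-template controls are clean
unless a contamination rate is set, in which case contaminated blanks show
late signals (Ct ≥ 41). All randomness flows through a single numpy
generator keyed by the config seed.

Defaults: curve slope −3.32 cycles/decade and intercept 40 cycles
(a well-optimised TaqMan assay), Ct noise SD 0.3 cycles — chosen so that
replicate repeatability crosses the SD ±0.5 quantification bound near
10 copies/reaction, matching how the repeatability-based LOQ behaves in
practice; both are configurable.

What the generator does *not* model: eDNA transport, degradation and
spatial heterogeneity in the water body; extraction efficiency below
100%; sequence-level amplification bias; fluorescence-curve shape.
Passing recovery tests therefore validate the statistical decision
machinery under the stated sampling model, not field performance.

## Numerical and testing choices

- Curve fitting excludes non-detect replicates (no imputation at Ct 50)
  and drops concentrations with no detections, warning; fits need ≥ 2
  usable concentrations. Recovery tests fit series spanning the
  quantifiable range, 10–10⁶ copies/reaction at 3 replicates × 6 tenfold
  dilutions, where slope is recovered within ±0.15 and intercept within
  ±0.5 cycles in ≥ 95% of seeds.
- Parameter-recovery checks run 100 seeds of small surveys (three truth
  levels 10³–10⁵ copies/L plus a zero site, four replicates each, 18
  standard wells), recovering truth within ±25% median relative error and
  never quantifying the zero site; MPN recovery uses 1000 reactions per
  seed at λ ∈ {0.5, 1.2, 2.4} within ±10% in ≥ 95% of seeds.
- Efficiency is reported to 0.1% by default; log base is 10 throughout.
- Degenerate inputs raise typed errors rather than returning sentinels:
  saturated MPN, unassessable ΔCt, undefined LOD, curve fits with < 2
  concentrations, non-detects passed to the Ct inverter.
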