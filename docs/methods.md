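# Methods

`l1census` re-implements, as a tested pipeline, the quantitative analyses of
a census of neocortical layer-1 (L1) interneurons: electrophysiological
firing-pattern classification, morphometric feature extraction with
supervised cluster validation, and paired-recording synaptic and
gap-junction analysis.  No raw recordings are distributed with the package;
every analysis path is exercised end to end on synthetic data whose
generating parameters are known, so each extractor and classifier can be
tested as a parameter-recovery problem.

## Firing-pattern (e-type) classification

A cell's response to a suprathreshold current step is reduced to its
inter-spike-interval (ISI) sequence, ISIs are regressed against AP sequence
order (ordinary least squares, index 1..n), and the decision tree is:

1. residual RMS > 30 ms: the train is poorly described by a line.  If any
   ISI exceeds 100 ms (a "silent period") the cell stutters (cSTUT);
   otherwise it fires irregularly (cIR).
2. residual RMS ≤ 30 ms: an initial burst marks bNAC — either four rapid
   onset spikes (mean of the first three ISIs strictly below 25 ms,
   subtype `burst4`) or an initial spike pair (first ISI ≤ 25 ms, subtype
   `doublet`), with `burst4` taking precedence.  Otherwise a slope ≥ 1 ms
   per AP index marks accommodation (cAC) and a flatter train cNAC.

The burst test precedes the slope test because burst ISIs would otherwise
corrupt the accommodation fit; the regression is nevertheless computed on
all ISIs, including any burst.  "RMS" is the root mean square of the
residuals of a single representative sweep.  All thresholds
(`rms_threshold=30`, `slope_threshold=1`, `gap_threshold=100`) are keyword
arguments of `classify_etype`.

Spike detection (which the classification convention leaves open) uses a
dV/dt threshold of 20 mV/ms, a minimum peak of −10 mV and a 2 ms
refractory merge — standard practice for current-clamp data.  AP amplitude
is measured threshold-to-peak, where threshold is the voltage at the last
upward dV/dt crossing before the peak; rise/fall times use the 20–80%
amplitude crossings on each flank (the same kinetic convention used for
postsynaptic potentials); "duration" is full width at the threshold level;
the steady-state window of a step response is its last 20%.

## Morphometry

Reconstructions are standard 7-column SWC trees (1 = soma, 2 = axon,
3 = basal dendrite), in μm, with y increasing toward the pia and z the
slice depth.  Histological shrinkage is undone by rescaling z by
original/measured slice thickness (default original 300 μm); in-plane
shrinkage (0–10%) is left uncorrected.

The battery emits 44 named features per cell: soma cross-section; per
neurite type (dendritic, axonal) the trunk count/diameter, segment count,
maximal branch order, maximal path and radial distance, tip count
("degree"), total length/surface/volume, mean inter-branch-point segment
length, horizontal and vertical ranges, length-weighted spatial moments,
arbor density, mean segment tortuosity, and the horizontal-to-vertical
extent ratio.  Conventions for quantities whose original definitions are
proprietary and unpublished (they were produced by commercial
reconstruction software) are fixed as follows and are not claims of
bit-compatibility with that software:

- **Branch order** is centrifugal with the trunk at order 1; each
  bifurcation increments both daughters.
- **Segments** run between consecutive branch points (or branch point and
  tip); the soma-to-trunk edge is not neurite cable, so segment path
  lengths sum exactly to total neurite length.
- **Tortuosity** is segment path length over its end-to-end chord.
- **Moments** are exact line integrals over the arbor: each edge
  contributes its length-weighted midpoint (first moment) plus the
  uniform-segment within-edge variance, span²/12 per axis (second moment),
  measured relative to the soma centroid.
- **Density** is total neurite length divided by the convex-hull volume of
  the arbor's points; degenerate (coplanar) arbors fall back to a planar
  hull with an area-based density and are flagged.
- **Bifurcation angles**: *local* between the first daughter points,
  *maximum* between daughter chords to the next branch point or tip,
  *planar* between those chords projected onto the plane normal to the
  incoming parent direction, *local spline* between 5-point
  moving-average-smoothed daughter directions.  Trifurcations take the
  pairwise maximum.  Angles are averaged per cell before any cross-cell
  statistics.
- **Soma cross-section** is the convex area of the soma contour's x–y
  projection; a single-point soma uses the equivalent circle of its
  radius.

## Objective class validation

Feature tables are z-normalized per feature (sample SD), after dropping a
configurable high-coefficient-of-variation list that defaults to the two
tortuosity features.  Cells with any |z| > 2 on the remaining features are
reported as outliers with their worst feature and z magnitude.  Feature
power reports, per feature, the pooled within-class variance of the
z-scored values and the between-class over total variance ratio; features
rank by the latter.

Class structure is probed two ways: PCA (unsupervised) and LDA against the
hypothesized class labels, validated by ten rounds of stratified ten-fold
cross-validation compared with the same procedure run on label-shuffled
replicates.  The comparison is a t-test, but fold scores within one label
assignment are positively correlated through the shared data, so pooling
them as independent observations is anticonservative (measured ~23% type-I
error at α = 0.05 on unstructured data).  The implemented test therefore
compares the actual mean cross-validated score against the distribution of
per-shuffle mean scores: a one-sample Student test with K − 1 degrees of
freedom and a 1 + 1/K variance correction for the single actual draw
(measured type-I ≈ 5.5% on pure noise, K = 10 shuffles by default).  Both
raw score vectors remain in the report.  When features outnumber
cells − classes, the within-class scatter is singular and Ledoit–Wolf
shrinkage LDA is used (noted in the result).  The three-scenario study
(all six classes; dropping a maximally distinct class; merging the two
neurogliaform classes) reruns the same validation per scenario.

## Synaptic physiology

IPSPs are hyperpolarizing; all measurements are taken on the
baseline-subtracted sweep average.  Amplitude is peak-to-peak (baseline to
trough); rise time runs 20→80% of amplitude on the onset flank, decay
80→20% on the recovery flank; onset is the first 5% crossing after
stimulus start and latency is measured from the last presynaptic AP peak
preceding onset (robust under noise; the underlying experimental
convention is unstated, so this is a documented package convention).
Trial-to-trial variability is the sample (n−1) SD of single-sweep
amplitudes over their mean.  Detection requires the trough to exceed the
larger of a stated floor (0.05 mV) and 5 σ of the averaged baseline noise,
because the minimum over thousands of samples of pure noise sits several σ
below zero; a non-detection is an explicit below-detection result, never a
zero.

Receptor classification mirrors the physiology of the two GABA receptor
classes.  Ionotropic (GABA_A) responses follow single APs with rise times
under 60 ms.  Metabotropic (GABA_B) responses require presynaptic trains
at a minimum instantaneous rate (40 Hz) and rise slowly.  For compound
train responses, summation makes even purely fast responses rise over tens
of milliseconds, so the fast-vs-mixed decision rests on the *late charge
fraction*: the share of the IPSP time-integral falling more than 120 ms
after the last presynaptic spike, where fast kinetics (decay ≈ 40 ms) have
decayed below 5%.  Measured on the generator, this fraction is ≤ 0.013 for
pure GABA_A, ≥ 0.046 for mixed, and ≥ 0.19 for pure GABA_B connections;
the threshold is 0.025 (configurable).  A connection with a fast single-AP
response and a slow train tail is GABA_A+B; a train-only response with
slow rise or a slow tail is GABA_B.

The rise-time distribution across a population of connections is fitted
with a two-component Gaussian mixture (EM, five seeded restarts,
components reported in ascending mean order, with a likelihood-ratio
comparison against one component).  Amplitude rundown over repeated
stimulation is fitted as a geometric decay on log amplitudes; the reported
`rundown_rate` is the per-repetition fractional loss.  Gap junctions are
quantified by the coupling coefficient — follower over injected cell
steady-state deflection under a hyperpolarizing step — with a paired
t-test across sweeps for directional symmetry.  The pharmacology ledger
decomposes the IPSP into a fast (GABA_A blocker-sensitive) component,
a slow (GABA_B blocker-sensitive) component, a residual, and a washout
recovery fraction, by epoch differences.

Reversal potentials come from the Nernst equation at 34 °C with the
solution recipes: pipette K⁺ 120 mM (110 K-gluconate + 10 KCl) against
bath 2.5 mM gives E_K ≈ −102 mV; pipette Cl⁻ 10 mM against bath 133.5 mM
(counting two Cl⁻ per divalent chloride salt) gives E_Cl ≈ −69 mV.

## Circuit statistics

Connection probabilities are empirical fractions with Clopper–Pearson 95%
intervals.  Directed (chemical) probabilities count each ordered direction
of a probed pair as one test — the convention under which 248 connections
over 2 × 1568 ordered tests reproduces the reported 7.9% — while
undirected (gap-junction) probabilities count pairs once (82/1568 = 5.2%);
both modes are available.  Putative synaptic contacts are presynaptic axon
points within 3 μm lateral distance of postsynaptic soma/dendrite points
with |Δz| ≤ 1 μm ("same focal plane"), deduplicated within 2 μm; the
thresholds are configurable since the experimental criterion is
qualitative.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
the biophysics that produced it.

**Voltage traces.** 2 s sweeps at 5–10 kHz (default 10 kHz), square step
from 200 ms, spikes as a difference-of-exponentials template (τ 0.25/0.8
ms, amplitude 60 mV threshold-to-peak, fast AHP 14 mV) riding on a
subthreshold plateau — not a conductance model, since the classifier
consumes only spike times and waveform shape.  Per e-type ISI programs:
cAC base 32 ms with slope 3 ms/index; cNAC flat 30 ms (1.5 ms jitter);
bNAC variants prepend a 9 ms four-spike burst or a ≤ 24 ms doublet;
cSTUT mixes 35 ms spiking ISIs with two ~190 ms silent periods; cIR
alternates short (~6 ms) and long (~85 ms) log-normal ISI components,
capped below 95 ms.  The cIR program is deliberately bimodal: with every
ISI capped below the 100 ms gap rule, a unimodal log-normal cannot push
the regression RMS above the 30 ms threshold (measured 15–22 ms), whereas
the alternating mixture yields RMS ≈ 34–42 ms — consistent with irregular
firing as short runs separated by sub-gap pauses.  All defaults sit well
clear of every decision margin, which is what makes the ≥ 95% round-trip
contract meaningful.

**Morphologies.** Six class parameter sets (axonal and dendritic extents,
segment lengths, tortuosity, trunk counts, branch-order caps, total cable
budgets) taken from the reported class means.  Growth: four extent-setting
trunks (±x, ±y) reach 90% of the target half-extents inside a reflecting
bounding box, plus filler trunks; every interior trunk segment end
bifurcates into the continuation and a side branch, and side branches
continue through further bifurcations with probability `branch_prob`,
capped by branch order and the per-neurite cable budget.  Segments are
zig-zag chains of four substeps at a fixed angle arccos(1/t) to the
segment axis, which imposes the target tortuosity t exactly per segment;
axes are redirected inward at segment start when the projected endpoint
would leave the box, so boundary reflections rarely distort a segment
mid-course.  The descending-axon class allocates 80% of its vertical
extent to a downward trunk, guaranteeing a collateral crossing 100 μm
below the soma.  Measured recovery over 12 seeds per class: extents within
7%, mean segment lengths within 11%, tortuosity within 1.5% of target.

**Synapses.** The fast component is a per-AP biexponential kernel (τ 8/40
ms).  The slow component is a minimal cooperative G-protein cascade:
spikes whose preceding ISI meets the minimum drive rate (40 Hz) release
into a transmitter pool (τ 100 ms) read out through a 4-site Hill gate and
a 60 ms effector relaxation — producing the sigmoidal rise, 10–20 ms onset
delay, slow multi-exponential decay, and strict train gating (a single AP
or a 20 Hz train produces exactly zero slow response).  Whole-cell
repetitions are scaled by (1 − rundown_rate)^k, emulating cytoplasmic
dilution; perforated-patch simulations set the rate to 0.  Gaussian
recording noise is seeded per sweep.

**Pair populations.** Each ordered direction of a pair connects
independently with the directed synaptic probability; each unordered pair
carries a gap junction with its own probability.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: electrode/access-resistance artifacts,
temperature and liquid-junction effects, bursty non-stationarity within a
sweep, correlated (non-white) noise, reconstruction errors (broken
branches, z-compression beyond the global shrinkage factor), receptor
kinetics beyond the two-component model, and any covariance between a
cell's e-type and its m-type.  Classifier accuracies measured here are
upper bounds for real data.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately moderate sizes chosen to give
stable statistics: 200 cells for the e-type round trip, 12–50 seeds per
morphological class, 200 seeded populations of 1568 pairs for interval
coverage, 100 noise trials for the validation-test level check, and
100 + 100 draws for the mixture recovery.  Exponential fits use
`scipy.optimize.curve_fit` with data-scaled initial values and explicit
failure (carrying the residual norm) on non-convergence.  Crossing times
are linearly interpolated between samples.  Ties and degenerate cases are
explicit: zero vertical extent yields a flagged infinite ratio, coincident
segment endpoints a flagged NaN tortuosity, an all-identical mixture input
a flagged degenerate fit, and a truncated AP flags its unavailable
features rather than fabricating them.

## Known limitations

- The expected e-type composition of L1 (40% cNAC etc.) is an empirical
  property of real tissue; the pipeline reports raw counts and exact
  ratios and makes no attempt to reproduce population tables measured on
  undeposited recordings.
- The printed morphometric class means come from expert reconstructions;
  the generator targets a subset of them (extents, segment lengths,
  tortuosity, cable totals) and treats the rest as free.
- `detect_appositions` works on reconstruction points, not bouton
  annotations; with bouton markers supplied it could be restricted to
  marked positions, which is left to the caller.
- The validation t-test's level correction assumes the shuffle replicates
  are exchangeable with the actual labels under the null; structured
  confounders (e.g., batch effects correlated with labels) violate this
  for real data just as they do for the original procedure.
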