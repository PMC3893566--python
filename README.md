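# l1census

A quantitative census pipeline for neocortical **layer-1 (L1) interneurons**,
for cellular electrophysiologists and neuroinformaticians who need the three
classification workflows of an L1 microcircuit study as tested, scriptable
code:

1. **Firing-pattern (e-type) classification** from current-clamp step
   responses — cAC, cNAC, bNAC (burst/doublet), cSTUT, cIR;
2. **Morphometrics and m-type validation** from SWC reconstructions — a
   44-feature battery, feature power, PCA, and LDA with a
   label-randomization cross-validation test;
3. **Paired-recording synaptic analysis** — IPSP kinetics, GABA_A / GABA_B /
   GABA_A+B receptor classification, rise-time mixture fitting, amplitude
   rundown, gap-junction coupling coefficients, pharmacological block
   accounting, and circuit-level connection statistics.

Because no raw recordings accompany the original census, the package ships a
first-class synthetic-data module (`l1census.synthetic_data`) that generates
every input with known ground truth — voltage traces per firing type,
stochastic branching morphologies per m-type, IPSP trains per receptor
class, and probed pair populations — so the whole pipeline is testable as a
parameter-recovery problem.

## The core statistics

**E-types.** For a spike train with peak times $t_1 < \dots < t_n$, the
ISIs $d_i = t_{i+1} - t_i$ are regressed on AP order $i$:
$d_i = \alpha + \beta i + \varepsilon_i$. With residual RMS
$\sqrt{\tfrac1n\sum\hat\varepsilon_i^2} \le 30$ ms the train is "regular":
an onset burst (mean of first three ISIs < 25 ms, or first ISI ≤ 25 ms)
gives bNAC, else $\beta \ge 1$ ms/index gives cAC and $\beta < 1$ cNAC.
Above 30 ms RMS, a silent period (any ISI > 100 ms) gives cSTUT, else cIR.

**M-types.** Each reconstruction maps to a 44-feature vector (extents,
branching, length-weighted moments $m_1 = \tfrac{1}{L}\int (x - x_{soma})\,
d\ell$, $m_2^2 = \tfrac{1}{L}\int (x - m_1)^2\, d\ell$, hull density,
tortuosity, H/V ratios). Features are z-scored, outliers (|z| > 2) flagged,
and the hypothesized classes tested by 10×10-fold LDA cross-validation
against label-shuffled replicates (level-corrected Student t-test).

**Synapses.** IPSP amplitude is peak-to-peak on the sweep mean, kinetics at
20–80% of amplitude, $CV = s_A/\bar A$ over sweeps. A single-AP response
with rise < 60 ms is GABA_A-like; a train-only response (≥ 40 Hz drive)
with slow rise is GABA_B-like; a fast response plus a slow late-charge tail
is mixed. The gap-junction coupling coefficient is
$cc = \Delta V_{post}/\Delta V_{pre}$ at steady state. Reversal potentials
follow Nernst, $E = \tfrac{RT}{zF}\ln\tfrac{[C]_o}{[C]_i}$.

## Worked example

Generate one accommodating cell, detect its spikes, and classify it:

```python
from l1census import synthetic_data as sd, ephys_features as ef, etype_classifier as ec
from l1census import circuit_stats as cs

spec = sd.EphysGenSpec.for_etype("cAC", seed=42)
trace = sd.generate_spike_response(spec)     # 2 s sweep, 10 kHz, 50 pA step
spikes = ef.detect_spikes(trace)             # 14 APs
label = ec.classify_etype(spikes)
print(label.label, label.evidence["slope"], label.evidence["rms_error"])

ap = ef.extract_ap_features(trace, spikes, 0)
print(ap.amplitude, ap.half_width)

print(cs.nernst(-1, 10.0, 133.5, 34.0))      # chloride reversal
```

prints (rounded):

```
cAC 3.06 1.29
60.2 1.18
-68.6
```

meaning: the ISI regression has slope 3.06 ms per AP index with residual
RMS 1.29 ms — well fit and accommodating, hence cAC; the first AP is
60.2 mV tall (threshold-to-peak) with a 1.18 ms half-width; and 10 mM
pipette against 133.5 mM bath chloride at 34 °C gives
E_Cl ≈ −69 mV, the driving-force anchor for the IPSP protocols.

The same flow works from the shell:

```sh
l1census synth --seed 3 --out traces/         # synthetic cohort + manifest
l1census etype traces/ --out etypes.tsv       # firing-pattern table
l1census morph reconstructions/ --shrinkage 200 --out morpho.tsv
l1census stats nernst --ion K --c-in 120 --c-out 2.5 --temp 34
l1census demo --seed 7 --out report.json      # full synthetic pipeline
```

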