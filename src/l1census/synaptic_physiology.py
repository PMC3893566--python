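"""Paired-recording analysis: IPSP kinetics, receptor class, gap junctions.

A paired recording holds the presynaptic spike times and the repeated
postsynaptic sweeps of one tested connection.  IPSPs are hyperpolarizing
deflections; amplitudes are measured peak-to-peak (baseline to trough) on
the sweep average, kinetics at 20-80% of the amplitude, and trial-to-trial
variability as the coefficient of variation of single-sweep amplitudes.

Receptor classification follows the physiology of the two GABA receptor
classes: ionotropic GABA_A responses follow single presynaptic APs with fast
rise times (< 60 ms by default), while metabotropic GABA_B responses require
presynaptic trains at a minimum instantaneous rate (40 Hz by default) and
rise slowly through a G-protein cascade.  Mixed (GABA_A+B) connections show
a fast single-AP response plus a disproportionate slow component in the
train response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ephys_features import VoltageTrace

__all__ = [
    "PairedRecording",
    "IpspFeatures",
    "ReceptorClass",
    "GapJunctionMeasurement",
    "PharmacologyLedger",
    "BelowDetection",
    "average_sweeps",
    "extract_ipsp",
    "classify_receptor",
    "fit_rise_time_mixture",
    "measure_rundown",
    "coupling_coefficient",
    "gj_analyze",
    "pharmacology_account",
]


@dataclass
class PairedRecording:
    """Presynaptic spike times plus repeated postsynaptic sweeps."""

    pre_spike_times: np.ndarray          # ms
    post_sweeps: list                    # list of VoltageTrace, equal length
    holding_potential: float = -57.0     # mV
    stim_frequency: float = np.nan       # Hz (nominal train rate)
    inter_stimulus_interval: float = 60.0  # s between repetitions
    patch_mode: str = "whole_cell"       # whole_cell | perforated
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre_spike_times = np.asarray(self.pre_spike_times, dtype=float)
        if len(self.post_sweeps) < 1:
            raise ValueError("need >= 1 postsynaptic sweep")
        n = len(self.post_sweeps[0])
        if any(len(s) != n for s in self.post_sweeps):
            raise ValueError("sweeps must have equal length")


@dataclass
class IpspFeatures:
    """Kinetic and amplitude measurements of one connection's IPSP."""

    amplitude: float            # mV, baseline-to-trough on the mean trace
    rise_time_2080: float       # ms
    decay_time_2080: float      # ms (80 -> 20% on the recovery flank)
    latency: float              # ms, presynaptic AP peak to IPSP onset
    halfwidth: float            # ms
    cv: float                   # SD of single-sweep amplitudes / mean
    sweep_amplitudes: np.ndarray
    onset_time: float = np.nan  # ms (5% crossing)
    late_charge_fraction: float = np.nan  # share of IPSP integral in the
    # slow window; the GABA_B discriminator


class BelowDetection(RuntimeError):
    """No deflection above the noise floor - a result, not a zero."""


@dataclass
class ReceptorClass:
    label: str                 # GABA_A | GABA_B | GABA_AB | unclassified
    evidence: dict = field(default_factory=dict)


@dataclass
class GapJunctionMeasurement:
    cc_12: float
    cc_21: float
    symmetric: bool
    p_value: float = np.nan


@dataclass
class PharmacologyLedger:
    """IPSP amplitudes (mV) across pharmacological epochs, in order."""

    baseline: float
    gabazine: float
    gabazine_plus_cgp: float
    washout: float | None = None


# ---------------------------------------------------------------------------


def average_sweeps(rec: PairedRecording, baseline_window: float = 50.0) -> VoltageTrace:
    """Pointwise mean of the repetition sweeps, baseline-subtracted.

    The baseline is the mean over ``baseline_window`` ms preceding the first
    presynaptic spike (or the start of the sweep when no spike precedes it).
    """
    template = rec.post_sweeps[0]
    stacked = np.vstack([s.voltage for s in rec.post_sweeps])
    mean_v = stacked.mean(axis=0)
    t = template.time
    t_ref = rec.pre_spike_times[0] if len(rec.pre_spike_times) else t[0]
    base_mask = (t >= t_ref - baseline_window) & (t < t_ref)
    if not base_mask.any():
        base_mask = t < t[0] + baseline_window
    baseline = float(mean_v[base_mask].mean())
    return VoltageTrace(
        t, mean_v - baseline, template.stimulus,
        {**template.metadata, "baseline_mv": baseline, "n_sweeps": len(rec.post_sweeps)},
    )


def _crossing_time(t: np.ndarray, v: np.ndarray, level: float, rising: bool) -> float:
    """Linear-interpolated first time |v| crosses `level` (deflections < 0)."""
    cond = v <= level if rising else v >= level
    idx = np.nonzero(cond)[0]
    if len(idx) == 0:
        return np.nan
    j = idx[0]
    if j == 0:
        return float(t[0])
    v0, v1 = v[j - 1], v[j]
    if v1 == v0:
        return float(t[j])
    return float(t[j - 1] + (level - v0) / (v1 - v0) * (t[j] - t[j - 1]))


def extract_ipsp(
    rec: PairedRecording,
    noise_floor: float = 0.05,
    onset_fraction: float = 0.05,
    late_window_start: float = 120.0,
    baseline_window: float = 50.0,
) -> IpspFeatures:
    """Measure the compound IPSP of a paired recording.

    The amplitude is baseline-to-trough (peak-to-peak) on the sweep mean;
    rise time runs from the 20% to the 80% crossing on the onset flank and
    decay from 80% back to 20% on the recovery flank.  IPSP onset is the
    first crossing of ``onset_fraction`` of the peak after stimulus start
    and latency is measured from the last presynaptic AP peak preceding
    onset (the first AP when onset precedes every later AP).

    ``late_charge_fraction`` is the share of the IPSP time-integral that
    falls more than ``late_window_start`` ms after the last presynaptic
    spike - near zero for purely fast (GABA_A-like) kinetics.

    Raises :class:`BelowDetection` when no deflection exceeds the noise floor.
    """
    mean_trace = average_sweeps(rec, baseline_window)
    t, v = mean_trace.time, mean_trace.voltage
    if len(rec.pre_spike_times) == 0:
        raise ValueError("recording has no presynaptic spikes")
    t0 = rec.pre_spike_times[0]
    post = t >= t0
    tp, vp = t[post], v[post]
    trough_idx = int(np.argmin(vp))
    amplitude = -float(vp[trough_idx])
    # detection floor: the stated floor or 5 sigma of the averaged baseline,
    # whichever is larger (the trace minimum over thousands of samples sits
    # several sigma below zero on pure noise)
    base_mask0 = (t >= t0 - baseline_window) & (t < t0)
    if not base_mask0.any():
        base_mask0 = t < t[0] + baseline_window
    sigma = float(np.std(v[base_mask0]))
    floor = max(noise_floor, 5.0 * sigma)
    if amplitude <= floor:
        raise BelowDetection(
            f"peak deflection {amplitude:.3f} mV <= detection floor {floor:.3f} mV"
        )
    peak = vp[trough_idx]  # negative
    lv20, lv50, lv80 = 0.2 * peak, 0.5 * peak, 0.8 * peak
    onset_level = onset_fraction * peak

    rise_t, rise_v = tp[: trough_idx + 1], vp[: trough_idx + 1]
    fall_t, fall_v = tp[trough_idx:], vp[trough_idx:]

    r20 = _crossing_time(rise_t, rise_v, lv20, rising=True)
    r80 = _crossing_time(rise_t, rise_v, lv80, rising=True)
    f80 = _crossing_time(fall_t, fall_v, lv80, rising=False)
    f20 = _crossing_time(fall_t, fall_v, lv20, rising=False)
    r50 = _crossing_time(rise_t, rise_v, lv50, rising=True)
    f50 = _crossing_time(fall_t, fall_v, lv50, rising=False)

    onset = _crossing_time(rise_t, rise_v, onset_level, rising=True)
    prior = rec.pre_spike_times[rec.pre_spike_times <= onset]
    ref_spike = prior[-1] if len(prior) else rec.pre_spike_times[0]
    latency = onset - ref_spike

    # per-sweep amplitudes at trough neighbourhood of each baseline-corrected sweep
    sweep_amps = []
    t_ref = rec.pre_spike_times[0]
    base_mask = (t >= t_ref - baseline_window) & (t < t_ref)
    if not base_mask.any():
        base_mask = t < t[0] + baseline_window
    for sweep in rec.post_sweeps:
        sv = sweep.voltage - sweep.voltage[base_mask].mean()
        sweep_amps.append(-float(sv[post].min()))
    sweep_amps_arr = np.array(sweep_amps)
    mean_amp = sweep_amps_arr.mean()
    cv = float(sweep_amps_arr.std(ddof=1) / mean_amp) if len(sweep_amps_arr) > 1 and mean_amp != 0 else 0.0

    # charge partition for the slow-component test
    dt = mean_trace.dt
    defl = np.clip(-vp, 0.0, None)
    total_q = float(defl.sum() * dt)
    t_last = rec.pre_spike_times[-1]
    late = tp >= t_last + late_window_start
    late_q = float(defl[late].sum() * dt)
    late_fraction = late_q / total_q if total_q > 0 else np.nan

    return IpspFeatures(
        amplitude=amplitude,
        rise_time_2080=r80 - r20,
        decay_time_2080=f20 - f80,
        latency=float(latency),
        halfwidth=float(f50 - r50),
        cv=cv,
        sweep_amplitudes=sweep_amps_arr,
        onset_time=float(onset),
        late_charge_fraction=late_fraction,
    )


def classify_receptor(
    features_single_ap: IpspFeatures | None,
    features_train: IpspFeatures | None,
    rise_cutoff: float = 60.0,
    train_freq_min: float = 40.0,
    slow_charge_fraction: float = 0.025,
) -> ReceptorClass:
    """Assign GABA_A / GABA_B / GABA_AB from single-AP and train responses.

    * GABA_A: a single-AP response with rise time below ``rise_cutoff`` and
      no disproportionate slow component in the train response.
    * GABA_B: no single-AP response; a train response (driven at or above
      ``train_freq_min`` Hz) with slow rise or a persistent slow tail.
    * GABA_AB: a fast single-AP response plus a train response whose late
      tail (after the fast kinetics have decayed) carries at least
      ``slow_charge_fraction`` of the IPSP integral.

    Because summation makes even purely fast compound train responses rise
    slowly, the fast-vs-mixed decision rests on the late charge fraction of
    the train response, not its rise time; the rise-time cutoff applies to
    the single-AP response and to train-only responses.

    ``features_single_ap`` / ``features_train`` are None when the respective
    protocol produced no detectable response.
    """
    evidence = {
        "single_ap_response": features_single_ap is not None,
        "train_response": features_train is not None,
        "min_effective_freq": train_freq_min,
    }
    if features_single_ap is None and features_train is None:
        evidence["reason"] = "no detectable response in either protocol"
        return ReceptorClass("unclassified", evidence)

    slow_tail = False
    if features_train is not None:
        evidence["train_rise_time"] = features_train.rise_time_2080
        evidence["train_late_charge_fraction"] = features_train.late_charge_fraction
        slow_tail = (
            np.isfinite(features_train.late_charge_fraction)
            and features_train.late_charge_fraction >= slow_charge_fraction
        )

    if features_single_ap is not None:
        evidence["rise_time"] = features_single_ap.rise_time_2080
        evidence["latency"] = features_single_ap.latency
        fast = features_single_ap.rise_time_2080 < rise_cutoff
        if fast and slow_tail:
            return ReceptorClass("GABA_AB", evidence)
        if fast:
            return ReceptorClass("GABA_A", evidence)
        evidence["reason"] = "single-AP response with slow rise"
        return ReceptorClass("unclassified", evidence)

    # train-only response
    evidence["rise_time"] = features_train.rise_time_2080
    evidence["latency"] = features_train.latency
    if features_train.rise_time_2080 >= rise_cutoff or slow_tail:
        return ReceptorClass("GABA_B", evidence)
    evidence["reason"] = "train-only response without slow kinetics"
    return ReceptorClass("unclassified", evidence)


def fit_rise_time_mixture(rise_times, n_components: int = 2, seed: int = 0) -> dict:
    """Two-component Gaussian mixture of the rise-time distribution.

    Returns means, SDs and weights in ascending mean order plus the
    log-likelihood and a likelihood-ratio comparison against a single
    component.  All-identical inputs are flagged degenerate.
    """
    x = np.asarray(rise_times, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError(f"need >= 10 values, got {len(x)}")
    if np.ptp(x) == 0:
        return {
            "means": np.array([float(x[0, 0])] * n_components),
            "sds": np.zeros(n_components),
            "weights": np.full(n_components, 1.0 / n_components),
            "degenerate": True,
        }
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(
        n_components=n_components, random_state=seed, n_init=5, max_iter=500
    ).fit(x)
    if not gm.converged_:
        raise RuntimeError(f"mixture fit did not converge: {gm.lower_bound_}")
    order = np.argsort(gm.means_.ravel())
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(x)
    ll2 = float(gm.score(x) * len(x))
    ll1 = float(gm1.score(x) * len(x))
    return {
        "means": gm.means_.ravel()[order],
        "sds": np.sqrt(gm.covariances_.ravel()[order]),
        "weights": gm.weights_[order],
        "log_likelihood": ll2,
        "lrt_statistic": 2.0 * (ll2 - ll1),
        "degenerate": False,
    }


def measure_rundown(per_repetition_amplitudes, isi_s: float | None = None) -> dict:
    """Geometric amplitude decay over stimulation repetitions.

    Fits amp_k = a0 * ratio**k by least squares on log amplitudes.  The
    returned ``ratio`` is the per-repetition retention (1.0 = no decay);
    ``rundown_rate`` = 1 - ratio is the fraction lost per repetition.
    """
    amps = np.asarray(per_repetition_amplitudes, dtype=float)
    if len(amps) < 3:
        raise ValueError("need >= 3 repetitions")
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive for a geometric fit")
    k = np.arange(len(amps), dtype=float)
    slope, intercept = np.polyfit(k, np.log(amps), 1)
    ratio = float(np.exp(slope))
    resid = np.log(amps) - (slope * k + intercept)
    n = len(amps)
    se_slope = float(
        np.sqrt(np.sum(resid**2) / max(n - 2, 1) / np.sum((k - k.mean()) ** 2))
    )
    return {
        "ratio": ratio,
        "rundown_rate": 1.0 - ratio,
        "a0": float(np.exp(intercept)),
        "ratio_se": ratio * se_slope,  # delta method on log scale
        "isi_s": isi_s,
    }


def coupling_coefficient(pre_deflection: float, post_deflection: float) -> float:
    """Gap-junction coupling coefficient: post / pre steady-state deflection."""
    if abs(pre_deflection) < 1e-9:
        raise ValueError("presynaptic deflection is zero")
    return float(post_deflection / pre_deflection)


def _sweep_deflections(rec: PairedRecording, baseline_window: float = 50.0):
    """Per-sweep steady-state deflections of a hyperpolarizing-step recording.

    Uses the last 20% of the step window in the stimulus channel of the
    injected cell; for the follower cell the same window is applied.
    """
    template = rec.post_sweeps[0]
    stim = template.stimulus
    on = np.nonzero(stim != 0)[0]
    if len(on) == 0:
        raise ValueError("no step in stimulus channel")
    i0, i1 = on[0], on[-1] + 1
    n_ss = max(1, int(round(0.2 * (i1 - i0))))
    deflections = []
    for sweep in rec.post_sweeps:
        v = sweep.voltage
        baseline = float(v[: max(1, i0)].mean())
        deflections.append(float(v[i1 - n_ss:i1].mean()) - baseline)
    return np.array(deflections)


def gj_analyze(
    rec_pre_12: PairedRecording, rec_post_12: PairedRecording,
    rec_pre_21: PairedRecording, rec_post_21: PairedRecording,
    alpha: float = 0.05,
) -> GapJunctionMeasurement:
    """Bidirectional coupling coefficients and a symmetry test.

    Direction 1->2 is measured from the injected cell's sweeps
    (``rec_pre_12``) and the follower's sweeps (``rec_post_12``); likewise
    2->1.  Per-sweep coefficient pairs feed a paired t-test; the connection
    is flagged symmetric when the two directions do not differ significantly.
    """
    pre12 = _sweep_deflections(rec_pre_12)
    post12 = _sweep_deflections(rec_post_12)
    pre21 = _sweep_deflections(rec_pre_21)
    post21 = _sweep_deflections(rec_post_21)
    cc12_sweeps = post12 / pre12
    cc21_sweeps = post21 / pre21
    cc12 = float(np.mean(cc12_sweeps))
    cc21 = float(np.mean(cc21_sweeps))
    n = min(len(cc12_sweeps), len(cc21_sweeps))
    if n >= 2:
        diff = cc12_sweeps[:n] - cc21_sweeps[:n]
        if np.allclose(diff, 0):
            p = 1.0
        else:
            _, p = stats.ttest_rel(cc12_sweeps[:n], cc21_sweeps[:n])
            p = float(p)
    else:
        p = np.nan
    symmetric = bool(np.isnan(p) or p >= alpha)
    return GapJunctionMeasurement(cc12, cc21, symmetric, p)


def pharmacology_account(ledger: PharmacologyLedger) -> dict:
    """Decompose the IPSP into receptor components from blocker epochs.

    The GABA_A-mediated (fast) component is the amplitude abolished by the
    GABA_A blocker; the GABA_B-mediated (slow) component is the amplitude
    further abolished by the GABA_B blocker; the remainder is residual.
    Recovery is the washout amplitude as a fraction of baseline (NaN with a
    flag when washout is missing).
    """
    flags = []
    fast = ledger.baseline - ledger.gabazine
    slow = ledger.gabazine - ledger.gabazine_plus_cgp
    residual = ledger.gabazine_plus_cgp
    if ledger.washout is None:
        recovery = np.nan
        flags.append("washout missing")
    else:
        recovery = ledger.washout / ledger.baseline
    return {
        "fast_component": float(fast),
        "slow_component": float(slow),
        "residual": float(residual),
        "recovery_fraction": float(recovery),
        "flags": flags,
    }
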