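"""Single-cell electrophysiology: trace I/O, spike detection, AP feature battery.

Traces are current-clamp sweeps (membrane potential in mV against time in ms,
with the injected current in pA as a third channel).  The feature battery
covers the per-AP waveform parameters (amplitude, half-width, 20-80% rise and
fall times, fast AHP) and the passive parameters (input resistance at peak and
steady state, membrane time constant from a delta pulse, rheobase).

Conventions (configurable where noted):

* AP amplitude is measured threshold-to-peak, where the threshold is the
  voltage at the first crossing of a dV/dt criterion (default 20 mV/ms).
* Rise and fall times are measured between the 20% and 80% crossings of the
  amplitude on each flank, mirroring the kinetic convention used for
  postsynaptic potentials.
* "Duration" is the full width of the spike at the threshold voltage level.
* The steady-state window of a step response is the last 20% of the step.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "VoltageTrace",
    "SpikeTrain",
    "APFeatures",
    "PassiveFeatures",
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "detect_spikes",
    "extract_ap_features",
    "extract_passive",
    "calibrate_rheobase",
]


class TraceFormatError(ValueError):
    """Raised when a columnar trace file cannot be parsed or is inconsistent."""


@dataclass
class VoltageTrace:
    """A uniformly sampled current-clamp sweep.

    Attributes
    ----------
    time : ndarray
        Sample times in ms, uniformly spaced and strictly increasing.
    voltage : ndarray
        Membrane potential in mV.
    stimulus : ndarray
        Injected current in pA, aligned sample-for-sample with ``voltage``.
    metadata : dict
        Free-form sweep metadata; ``cell_id``, ``sweep_id`` and
        ``sampling_rate_khz`` are required by the on-disk format.
    """

    time: np.ndarray
    voltage: np.ndarray
    stimulus: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        if not (len(self.time) == len(self.voltage) == len(self.stimulus)):
            raise ValueError("time, voltage and stimulus must have equal length")
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        """Sample period in ms."""
        return float(self.time[1] - self.time[0])

    @property
    def sampling_rate_khz(self) -> float:
        return 1.0 / self.dt

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class SpikeTrain:
    """Detected action potentials of one sweep."""

    peak_times: np.ndarray        # ms
    threshold_times: np.ndarray   # ms, one per spike, precedes the peak
    peak_indices: np.ndarray      # sample indices into the source trace
    threshold_indices: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.threshold_times = np.asarray(self.threshold_times, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.threshold_indices = np.asarray(self.threshold_indices, dtype=int)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if np.any(self.threshold_times >= self.peak_times):
            raise ValueError("each threshold time must precede its peak")

    @property
    def n_spikes(self) -> int:
        return len(self.peak_times)

    def __len__(self) -> int:
        return self.n_spikes


@dataclass
class APFeatures:
    """Waveform parameters of a single action potential.

    Any feature that cannot be measured (e.g. a spike truncated at the end
    of the sweep, or no post-spike minimum before the next AP) is NaN and
    listed in ``unavailable``.
    """

    amplitude: float      # mV, threshold to peak
    duration: float       # ms, full width at threshold level
    half_width: float     # ms, full width at 50% amplitude
    rise_time: float      # ms, 20-80% of amplitude on the rising flank
    fall_time: float      # ms, 80-20% on the falling flank
    ahp_time: float       # ms, peak to post-spike minimum
    rise_rate: float      # mV/ms over the 20-80% rise
    fall_rate: float      # mV/ms over the 80-20% fall
    fast_ahp: float       # mV, threshold voltage minus post-spike minimum
    unavailable: tuple = ()


@dataclass
class PassiveFeatures:
    """Passive/subthreshold parameters extracted from step and delta sweeps."""

    r_in_peak: float       # MOhm, peak deflection / step current
    r_in_ss: float         # MOhm, steady-state deflection / step current
    tau_delta: float       # ms, single-exponential decay constant
    ap_threshold: float    # mV (NaN when no AP available)
    sahp_max: float        # mV (NaN when unavailable)
    i_min_threshold: float  # pA, rheobase (NaN when not calibrated)


# ---------------------------------------------------------------------------
# Columnar trace format
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("cell_id", "sweep_id", "sampling_rate_khz")


def write_trace(trace: VoltageTrace, path) -> None:
    """Write a sweep to the columnar text format.

    UTF-8 text; ``#``-prefixed ``key: value`` header lines, then
    tab-separated ``time_ms  voltage_mv  stimulus_pa``.
    """
    meta = dict(trace.metadata)
    meta.setdefault("sampling_rate_khz", trace.sampling_rate_khz)
    buf = io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}: {value}\n")
    buf.write("# columns: time_ms\tvoltage_mv\tstimulus_pa\n")
    for t, v, s in zip(trace.time, trace.voltage, trace.stimulus):
        buf.write(f"{t:.6f}\t{v:.6f}\t{s:.6f}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_trace(path) -> VoltageTrace:
    """Read a sweep from the columnar text format (see :func:`write_trace`)."""
    meta: dict = {}
    rows = []
    for lineno, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        parts = line.split()
        if len(parts) != 3:
            raise TraceFormatError(
                f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
            )
        try:
            rows.append([float(x) for x in parts])
        except ValueError as exc:
            raise TraceFormatError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise TraceFormatError(f"{path}: no data rows")
    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise TraceFormatError(f"{path}: missing header keys {missing}")
    data = np.array(rows)
    if np.any(np.diff(data[:, 0]) <= 0):
        raise TraceFormatError(f"{path}: non-monotone time column")
    meta["sampling_rate_khz"] = float(meta["sampling_rate_khz"])
    return VoltageTrace(data[:, 0], data[:, 1], data[:, 2], meta)


# ---------------------------------------------------------------------------
# Spike detection and AP features
# ---------------------------------------------------------------------------

def detect_spikes(
    trace: VoltageTrace,
    dvdt_threshold: float = 20.0,
    min_peak: float = -10.0,
    refractory: float = 2.0,
) -> SpikeTrain:
    """Detect action potentials in a current-clamp sweep.

    A spike is a local maximum above ``min_peak`` (mV) preceded by an upward
    crossing of ``dvdt_threshold`` (mV/ms).  Peaks closer than ``refractory``
    (ms) are merged, keeping the larger.  Returns an empty train when the
    sweep is subthreshold.
    """
    v = trace.voltage
    dt = trace.dt
    distance = max(1, int(round(refractory / dt)))
    peak_idx, _ = find_peaks(v, height=min_peak, distance=distance)

    dvdt = np.gradient(v, dt)
    peaks, thresholds = [], []
    for p in peak_idx:
        # walk back from the peak to the last upward dV/dt crossing
        i = p
        while i > 0 and dvdt[i - 1] >= dvdt_threshold:
            i -= 1
        if i == p:  # no suprathreshold dV/dt run ends at this peak
            run = np.nonzero(dvdt[:p] >= dvdt_threshold)[0]
            if len(run) == 0:
                continue
            i = run[-1]
            while i > 0 and dvdt[i - 1] >= dvdt_threshold:
                i -= 1
        peaks.append(p)
        thresholds.append(i)
    peaks_arr = np.array(peaks, dtype=int)
    thr_arr = np.array(thresholds, dtype=int)
    return SpikeTrain(
        peak_times=trace.time[peaks_arr] if len(peaks_arr) else np.array([]),
        threshold_times=trace.time[thr_arr] if len(thr_arr) else np.array([]),
        peak_indices=peaks_arr,
        threshold_indices=thr_arr,
    )


def _interp_crossing(t: np.ndarray, v: np.ndarray, level: float) -> float:
    """First time v crosses `level`, linearly interpolated; NaN if never."""
    above = v >= level if v[0] < level else v <= level
    idx = np.nonzero(above)[0]
    if len(idx) == 0:
        return np.nan
    j = idx[0]
    if j == 0:
        return float(t[0])
    v0, v1 = v[j - 1], v[j]
    if v1 == v0:
        return float(t[j])
    frac = (level - v0) / (v1 - v0)
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def extract_ap_features(
    trace: VoltageTrace,
    spikes: SpikeTrain,
    index: int,
    ahp_window: float = 20.0,
) -> APFeatures:
    """Extract the waveform parameters of the AP with ordinal ``index``.

    ``ahp_window`` bounds the search for the post-spike minimum (ms); the
    search never extends past the next spike's threshold.
    """
    if index >= spikes.n_spikes:
        raise IndexError(f"spike index {index} out of range ({spikes.n_spikes} spikes)")
    unavailable: list[str] = []
    p = spikes.peak_indices[index]
    th = spikes.threshold_indices[index]
    t, v = trace.time, trace.voltage
    v_thr = v[th]
    v_peak = v[p]
    amplitude = v_peak - v_thr

    # falling flank search window: to next spike threshold or ahp_window
    if index + 1 < spikes.n_spikes:
        end = spikes.threshold_indices[index + 1]
    else:
        end = min(len(v), p + int(round(ahp_window / trace.dt)) + 1)
    rising_t, rising_v = t[th : p + 1], v[th : p + 1]
    falling_t, falling_v = t[p:end], v[p:end]

    lv20 = v_thr + 0.2 * amplitude
    lv50 = v_thr + 0.5 * amplitude
    lv80 = v_thr + 0.8 * amplitude

    r20 = _interp_crossing(rising_t, rising_v, lv20)
    r80 = _interp_crossing(rising_t, rising_v, lv80)
    rise_time = r80 - r20

    f80 = _interp_crossing(falling_t, falling_v, lv80)
    f20 = _interp_crossing(falling_t, falling_v, lv20)
    fall_time = f20 - f80

    r50 = _interp_crossing(rising_t, rising_v, lv50)
    f50 = _interp_crossing(falling_t, falling_v, lv50)
    half_width = f50 - r50

    f_thr = _interp_crossing(falling_t, falling_v, v_thr)
    duration = f_thr - t[th]

    truncated = index + 1 >= spikes.n_spikes and end == len(v)
    for name, val in [
        ("fall_time", fall_time),
        ("half_width", half_width),
        ("duration", duration),
    ]:
        if not np.isfinite(val):
            unavailable.append(name)
    if truncated and not np.isfinite(f20):
        unavailable.append("truncated_at_sweep_end")

    # post-spike minimum (fast AHP)
    if end - p >= 3:
        seg = v[p:end]
        mins, _ = find_peaks(-seg)
        if len(mins) > 0:
            m = p + mins[0]
            ahp_time = t[m] - t[p]
            fast_ahp = v_thr - v[m]
        elif index + 1 >= spikes.n_spikes and np.argmin(seg) not in (0, len(seg) - 1):
            m = p + int(np.argmin(seg))
            ahp_time = t[m] - t[p]
            fast_ahp = v_thr - v[m]
        else:
            ahp_time = fast_ahp = np.nan
            unavailable.append("ahp_time")
    else:
        ahp_time = fast_ahp = np.nan
        unavailable.append("ahp_time")

    rise_rate = 0.6 * amplitude / rise_time if rise_time and np.isfinite(rise_time) else np.nan
    fall_rate = 0.6 * amplitude / fall_time if fall_time and np.isfinite(fall_time) else np.nan

    return APFeatures(
        amplitude=float(amplitude),
        duration=float(duration),
        half_width=float(half_width),
        rise_time=float(rise_time),
        fall_time=float(fall_time),
        ahp_time=float(ahp_time),
        rise_rate=float(rise_rate),
        fall_rate=float(fall_rate),
        fast_ahp=float(fast_ahp),
        unavailable=tuple(unavailable),
    )


# ---------------------------------------------------------------------------
# Passive properties
# ---------------------------------------------------------------------------

class FitError(RuntimeError):
    """Exponential fit did not converge; carries the residual norm."""

    def __init__(self, message: str, residual_norm: float = np.nan):
        super().__init__(message)
        self.residual_norm = residual_norm


def _step_window(trace: VoltageTrace):
    """Indices of the (nonzero) step in the stimulus channel."""
    stim = trace.stimulus
    on = np.nonzero(stim != 0)[0]
    if len(on) == 0:
        raise ValueError("stimulus channel carries no step")
    return on[0], on[-1] + 1, float(stim[on[0]])


def extract_passive(
    trace_hyperpol: VoltageTrace,
    trace_delta: VoltageTrace | None = None,
    ss_fraction: float = 0.2,
) -> PassiveFeatures:
    """Input resistances from a hyperpolarizing step; tau from a delta pulse.

    ``r_in_peak`` uses the maximal deflection from the pre-step baseline,
    ``r_in_ss`` the mean over the last ``ss_fraction`` of the step.
    ``tau_delta`` is the time constant of a single exponential fitted to the
    post-pulse relaxation of the delta-pulse sweep (NaN when no delta sweep
    is supplied).
    """
    i0, i1, amp = _step_window(trace_hyperpol)
    if amp == 0:
        raise ValueError("zero-current stimulus")
    v = trace_hyperpol.voltage
    baseline = float(np.mean(v[: max(1, i0)])) if i0 > 0 else float(v[0])
    seg = v[i0:i1] - baseline
    if amp < 0:
        peak_defl = float(seg.min())
    else:
        peak_defl = float(seg.max())
    n_ss = max(1, int(round(ss_fraction * (i1 - i0))))
    ss_defl = float(np.mean(seg[-n_ss:]))
    # MOhm = mV / nA = mV / (pA / 1000)
    r_in_peak = abs(peak_defl / amp) * 1e3
    r_in_ss = abs(ss_defl / amp) * 1e3

    tau = np.nan
    if trace_delta is not None:
        j0, j1, _ = _step_window(trace_delta)
        vd = trace_delta.voltage
        base_d = float(np.mean(vd[: max(1, j0)])) if j0 > 0 else float(vd[0])
        t_rel = trace_delta.time[j1:] - trace_delta.time[j1]
        y = vd[j1:] - base_d
        if len(y) < 4:
            raise FitError("delta-pulse relaxation too short to fit")
        a0 = y[0] if y[0] != 0 else 1.0
        try:
            popt, _ = curve_fit(
                lambda tt, a, ta: a * np.exp(-tt / ta),
                t_rel,
                y,
                p0=(a0, max(t_rel[-1] / 5.0, trace_delta.dt)),
                maxfev=5000,
            )
        except RuntimeError as exc:
            raise FitError(f"exponential fit failed: {exc}") from exc
        resid = y - popt[0] * np.exp(-t_rel / popt[1])
        rnorm = float(np.linalg.norm(resid))
        if not np.isfinite(popt[1]) or popt[1] <= 0:
            raise FitError("non-physical time constant", rnorm)
        tau = float(popt[1])

    return PassiveFeatures(
        r_in_peak=r_in_peak,
        r_in_ss=r_in_ss,
        tau_delta=tau,
        ap_threshold=np.nan,
        sahp_max=np.nan,
        i_min_threshold=np.nan,
    )


class RheobaseNotFound(RuntimeError):
    """No sweep in the family elicited an action potential."""


def calibrate_rheobase(sweep_family: list[VoltageTrace], **detect_kwargs) -> float:
    """Smallest step amplitude (pA) that elicits at least one AP.

    ``sweep_family`` is a set of step sweeps at increasing amplitudes; the
    step amplitude is read from each sweep's stimulus channel.
    """
    firing_amps = []
    for sweep in sweep_family:
        _, _, amp = _step_window(sweep)
        if detect_spikes(sweep, **detect_kwargs).n_spikes >= 1:
            firing_amps.append(abs(amp))
    if not firing_amps:
        raise RheobaseNotFound("no sweep in the family elicited an AP")
    return float(min(firing_amps))
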