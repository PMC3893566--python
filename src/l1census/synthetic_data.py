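"""Synthetic study inputs with known ground truth.

Every input the census pipeline consumes can be generated here with a seeded
random stream: step-response voltage traces for the five firing types,
stochastic branching morphologies for the six morphological classes,
paired-recording IPSP trains for the three GABA receptor classes (with
amplitude rundown in whole-cell mode), and bidirectionally probed cell-pair
populations with known connection probabilities.  The generators are the
inverse of the analysis modules: their parameters are the quantities the
extractors and classifiers are expected to recover.

The action potential is a difference-of-exponentials template riding on a
threshold level, not a conductance model - the downstream classifier only
consumes spike times and waveform shape.  The GABA_B response is produced by
a cooperative G-protein cascade: presynaptic spikes arriving at or above the
minimum drive rate feed a slow transmitter pool that is read out through a
Hill-type gate (4 binding sites by default), yielding the sigmoidal rise,
onset delay and slow multi-exponential decay characteristic of metabotropic
inhibition, and no response at all to single APs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ephys_features import VoltageTrace
from .morphology import AXON, DENDRITE, SOMA, Morphology
from .synaptic_physiology import PairedRecording

__all__ = [
    "EphysGenSpec",
    "MorphGenSpec",
    "SynapseGenSpec",
    "generate_spike_response",
    "generate_rheobase_family",
    "generate_passive_sweeps",
    "generate_morphology",
    "generate_paired_recording",
    "generate_gj_recording",
    "generate_pair_population",
    "write_manifest",
    "read_manifest",
    "ETYPE_DEFAULTS",
    "MTYPE_DEFAULTS",
    "RECEPTOR_DEFAULTS",
]


# ---------------------------------------------------------------------------
# Electrophysiology generator
# ---------------------------------------------------------------------------

@dataclass
class EphysGenSpec:
    """Generative parameters of one firing-type voltage response.

    ``etype`` selects the ISI program; ``base_isi``/``isi_slope``/
    ``isi_noise_sd`` parameterize it (ms, ms per AP index, ms).  cSTUT
    trains interleave ``silent_period`` gaps; cIR alternates short and long
    log-normal ISI components (``isi_cv`` scales the within-component
    jitter), every interval kept below the silent-period rule.
    """

    etype: str = "cNAC"
    base_isi: float = 30.0
    isi_slope: float = 0.0
    isi_noise_sd: float = 1.0
    n_spikes: int = 12
    silent_period: float = 0.0        # ms, cSTUT only (> 100)
    isi_cv: float = 0.8               # cIR only
    burst_isi: float = 9.0            # ms, bNAC burst/doublet onset interval
    ap_amplitude: float = 60.0        # mV threshold-to-peak
    ap_threshold: float = -40.0       # mV
    ap_ahp_depth: float = 14.0        # mV below threshold
    ap_tau_rise: float = 0.25         # ms
    ap_tau_fall: float = 0.8          # ms
    sampling_rate: float = 10.0       # kHz
    sweep_duration: float = 2000.0    # ms
    stim_onset: float = 200.0         # ms
    stim_amplitude: float = 50.0      # pA square step
    v_rest: float = -65.0             # mV
    seed: int = 0

    _ETYPES = ("cAC", "cNAC", "bNAC_burst", "bNAC_doublet", "cSTUT", "cIR")

    def __post_init__(self) -> None:
        if self.etype not in self._ETYPES:
            raise ValueError(f"unknown etype {self.etype!r}")
        if self.base_isi <= 0:
            raise ValueError("base_isi must be > 0")
        if self.n_spikes < 2:
            raise ValueError("n_spikes must be >= 2")
        if not (5.0 <= self.sampling_rate <= 10.0):
            raise ValueError("sampling_rate must be in [5, 10] kHz")
        if self.etype == "cSTUT" and not self.silent_period > 100.0:
            raise ValueError("cSTUT specs need silent_period > 100 ms")
        if self.etype != "cSTUT" and self.silent_period > 100.0:
            raise ValueError("silent_period > 100 ms is reserved for cSTUT")

    @classmethod
    def for_etype(cls, etype: str, seed: int = 0, **overrides) -> "EphysGenSpec":
        """A spec with class-typical defaults for one of the five e-types.

        Defaults place every spec well clear of the classifier decision
        margins (slope 1 ms/index, residual RMS 30 ms, gap 100 ms).
        """
        base = dict(ETYPE_DEFAULTS[etype])
        base.update(overrides)
        return cls(etype=etype, seed=seed, **base)


#: Class-typical generator parameters for each firing type.  Chosen so the
#: realized ISI statistics sit far from every classifier threshold: cAC
#: accommodates at 3 ms/index (threshold 1), cNAC is flat with 1.5 ms jitter,
#: cSTUT mixes 35 ms spiking ISIs with ~190 ms silent periods, and cIR draws
#: broad log-normal ISIs capped below the 100 ms gap rule.
ETYPE_DEFAULTS: dict[str, dict] = {
    "cAC": dict(base_isi=32.0, isi_slope=3.0, isi_noise_sd=1.5, n_spikes=14),
    "cNAC": dict(base_isi=30.0, isi_slope=0.0, isi_noise_sd=1.5, n_spikes=14),
    "bNAC_burst": dict(base_isi=45.0, isi_slope=0.0, isi_noise_sd=1.5,
                       n_spikes=14, burst_isi=9.0),
    "bNAC_doublet": dict(base_isi=55.0, isi_slope=0.0, isi_noise_sd=1.5,
                         n_spikes=12, burst_isi=15.0),
    "cSTUT": dict(base_isi=35.0, isi_slope=0.0, isi_noise_sd=3.0,
                  n_spikes=14, silent_period=190.0),
    "cIR": dict(base_isi=55.0, isi_slope=0.0, isi_noise_sd=0.0,
                n_spikes=16, isi_cv=0.8),
}


def _draw_isis(spec: EphysGenSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_spikes - 1
    noise = rng.normal(0.0, spec.isi_noise_sd, size=n) if spec.isi_noise_sd > 0 else np.zeros(n)
    if spec.etype in ("cAC", "cNAC"):
        isis = spec.base_isi + spec.isi_slope * np.arange(n) + noise
    elif spec.etype == "bNAC_burst":
        isis = spec.base_isi + noise
        isis[:3] = spec.burst_isi + 0.2 * noise[:3]
    elif spec.etype == "bNAC_doublet":
        isis = spec.base_isi + noise
        isis[0] = min(spec.burst_isi + 0.2 * noise[0], 24.0)
    elif spec.etype == "cSTUT":
        isis = spec.base_isi + noise
        # two silent periods at interior positions, apart from each other
        n_gaps = 2 if n >= 6 else 1
        positions = rng.choice(np.arange(1, n - 1), size=n_gaps, replace=False)
        isis[positions] = spec.silent_period * (1.0 + 0.1 * rng.standard_normal(n_gaps))
    elif spec.etype == "cIR":
        # irregular firing alternates brief spike runs with long (but
        # sub-silent-period) pauses: a balanced two-component log-normal
        # mixture keeps every ISI below the 100 ms gap rule while the
        # short/long alternation drives the regression residuals well
        # above the goodness-of-fit threshold
        jitter = spec.isi_cv / 0.8
        phase = int(rng.integers(2))
        comp = (np.arange(n) + phase) % 2 == 0  # alternating short/long runs
        short = rng.lognormal(math.log(6.0), 0.3 * jitter, size=n)
        long_ = rng.lognormal(math.log(85.0), 0.12 * jitter, size=n)
        isis = np.where(comp, short, long_)
        isis = np.clip(isis, 2.0, 94.0)
    else:  # pragma: no cover
        raise AssertionError(spec.etype)
    return np.maximum(isis, 2.0)


def _ap_kernel(spec: EphysGenSpec, dt: float) -> tuple[np.ndarray, int]:
    """Difference-of-exponentials AP waveform sampled at dt, plus the index
    of its peak.  The kernel is the spike's voltage excursion relative to
    the threshold level: it starts at 0, peaks at ``ap_amplitude``, dips to
    ``-ap_ahp_depth`` (the fast AHP) and relaxes back to 0."""
    tr, tf = spec.ap_tau_rise, spec.ap_tau_fall
    t_peak = tr * tf / (tf - tr) * math.log(tf / tr)
    t = np.arange(0.0, 12.0 * tf, dt)
    shape = np.exp(-t / tf) - np.exp(-t / tr)
    shape /= shape.max()
    spike = spec.ap_amplitude * shape
    # AHP: slower difference of exponentials, peak depth ahp_depth
    ta_r, ta_f = 1.5, 6.0
    t2 = np.arange(0.0, 40.0, dt)
    ahp = np.exp(-t2 / ta_f) - np.exp(-t2 / ta_r)
    ahp /= ahp.max()
    ahp = -spec.ap_ahp_depth * ahp
    kernel = np.zeros(len(spike) + len(ahp))
    kernel[: len(spike)] += spike
    # AHP starts once the spike has mostly repolarized
    start = int(round((t_peak + 3.0 * tf) / dt))
    kernel[start : start + len(ahp)] += ahp[: len(kernel) - start]
    return kernel, int(np.argmax(kernel))


def generate_spike_response(spec: EphysGenSpec) -> VoltageTrace:
    """Simulate the step response of one cell of the requested firing type.

    The trace holds exactly ``spec.n_spikes`` template APs whose peak-time
    differences realize the e-type's ISI program; the stimulus channel holds
    the square current step.  Ground truth (e-type, ISI draw) is stored in
    the trace metadata.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    isis = _draw_isis(spec, rng)
    first = spec.stim_onset + 10.0
    peaks = first + np.concatenate([[0.0], np.cumsum(isis)])
    dt = 1.0 / spec.sampling_rate
    if peaks[-1] > spec.sweep_duration - 60.0:
        raise ValueError(
            f"spike train ({peaks[-1]:.0f} ms) does not fit the "
            f"{spec.sweep_duration:.0f} ms sweep"
        )
    n = int(round(spec.sweep_duration / dt))
    t = np.arange(n) * dt
    v = np.full(n, spec.v_rest)
    stim_off = spec.sweep_duration - 200.0
    stim = np.where((t >= spec.stim_onset) & (t < stim_off), spec.stim_amplitude, 0.0)
    # subthreshold depolarization toward threshold during the step
    plateau = spec.ap_threshold - 8.0
    on = (t >= spec.stim_onset) & (t < stim_off)
    v[on] = plateau - (plateau - spec.v_rest) * np.exp(
        -(t[on] - spec.stim_onset) / 15.0
    )
    off = t >= stim_off
    v[off] = spec.v_rest + (plateau - spec.v_rest) * np.exp(-(t[off] - stim_off) / 15.0)

    kernel, k_peak = _ap_kernel(spec, dt)
    # spike contribution added on the subthreshold curve: a 1 ms pre-ramp
    # lifts the membrane from the plateau to threshold, the kernel rides on
    # top, and a taper returns the contribution to zero at the window end
    lift = spec.ap_threshold - plateau
    n_ramp = max(1, int(round(1.0 / dt)))
    contrib = np.concatenate([
        np.linspace(0.0, lift, n_ramp, endpoint=False),
        lift + kernel,
    ])
    n_taper = max(1, int(round(10.0 / dt)))
    contrib[-n_taper:] *= np.linspace(1.0, 0.0, n_taper)
    c_peak = n_ramp + k_peak
    for pk in peaks:
        i0 = int(round(pk / dt)) - c_peak
        i1 = min(n, i0 + len(contrib))
        v[max(0, i0) : i1] += contrib[max(0, -i0) : i1 - i0]
    meta = {
        "cell_id": f"synth-{spec.etype}-{spec.seed}",
        "sweep_id": 0,
        "sampling_rate_khz": spec.sampling_rate,
        "etype_true": spec.etype,
        "isis_true": isis,
        "peak_times_true": peaks,
    }
    return VoltageTrace(t, v, stim, meta)


def generate_rheobase_family(
    rheobase_pa: float,
    amplitudes,
    etype: str = "cNAC",
    seed: int = 0,
) -> list[VoltageTrace]:
    """A ladder of step sweeps that first fires at ``rheobase_pa``.

    Sweeps with step amplitude below the built-in rheobase are subthreshold
    (no APs); sweeps at or above it contain a spike train.
    """
    sweeps = []
    for amp in amplitudes:
        if amp >= rheobase_pa:
            spec = EphysGenSpec.for_etype(etype, seed=seed, stim_amplitude=float(amp))
            sweeps.append(generate_spike_response(spec))
        else:
            spec = EphysGenSpec.for_etype(etype, seed=seed, stim_amplitude=float(amp))
            dt = 1.0 / spec.sampling_rate
            n = int(round(spec.sweep_duration / dt))
            t = np.arange(n) * dt
            stim_off = spec.sweep_duration - 200.0
            stim = np.where(
                (t >= spec.stim_onset) & (t < stim_off), float(amp), 0.0
            )
            v = np.full(n, spec.v_rest)
            on = (t >= spec.stim_onset) & (t < stim_off)
            depol = 8.0 * amp / max(rheobase_pa, 1.0)
            v[on] += depol * (1.0 - np.exp(-(t[on] - spec.stim_onset) / 15.0))
            sweeps.append(
                VoltageTrace(t, v, stim, {
                    "cell_id": f"synth-rheo-{seed}", "sweep_id": len(sweeps),
                    "sampling_rate_khz": spec.sampling_rate,
                })
            )
    return sweeps


def generate_passive_sweeps(
    r_in_mohm: float = 150.0,
    tau_ms: float = 18.0,
    step_pa: float = -100.0,
    delta_pa: float = -300.0,
    sampling_rate: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VoltageTrace, VoltageTrace]:
    """RC step and delta-pulse sweeps with known resistance and time constant."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, 800.0, dt)
    v_rest = -65.0
    # step sweep: 100-500 ms
    stim = np.where((t >= 100.0) & (t < 500.0), step_pa, 0.0)
    v_inf = r_in_mohm * step_pa * 1e-3  # mV
    v = np.full_like(t, v_rest)
    on = (t >= 100.0) & (t < 500.0)
    v[on] += v_inf * (1.0 - np.exp(-(t[on] - 100.0) / tau_ms))
    off = t >= 500.0
    v_at_off = v_inf * (1.0 - math.exp(-400.0 / tau_ms))
    v[off] += v_at_off * np.exp(-(t[off] - 500.0) / tau_ms)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, len(v))
    step_trace = VoltageTrace(t, v, stim, {
        "cell_id": "synth-passive", "sweep_id": 0, "sampling_rate_khz": sampling_rate,
    })
    # delta sweep: 2 ms pulse at 100 ms, then pure exponential relaxation
    stim_d = np.where((t >= 100.0) & (t < 102.0), delta_pa, 0.0)
    vd = np.full_like(t, v_rest)
    pulse_defl = r_in_mohm * delta_pa * 1e-3 * (2.0 / tau_ms)  # small-pulse charge
    on_d = (t >= 100.0) & (t < 102.0)
    vd[on_d] += pulse_defl * (t[on_d] - 100.0) / 2.0
    off_d = t >= 102.0
    vd[off_d] += pulse_defl * np.exp(-(t[off_d] - 102.0) / tau_ms)
    if noise_sd > 0:
        vd = vd + rng.normal(0.0, noise_sd, len(vd))
    delta_trace = VoltageTrace(t, vd, stim_d, {
        "cell_id": "synth-passive", "sweep_id": 1, "sampling_rate_khz": sampling_rate,
    })
    return step_trace, delta_trace


# ---------------------------------------------------------------------------
# Morphology generator
# ---------------------------------------------------------------------------

@dataclass
class MorphGenSpec:
    """Generative parameters of one morphological class.

    Extents are axonal targets (um); ``dend_*`` fields their dendritic
    counterparts.  ``mean_segment_length`` applies to dendritic segments and
    ``axon_segment_length`` to axonal ones.  Tortuosity is imposed exactly
    per segment by zig-zag substeps at a fixed angle to the segment axis.
    """

    mtype: str = "NGC-DA"
    target_h_extent: float = 481.0
    target_v_extent: float = 263.0
    dend_h_extent: float = 122.0
    dend_v_extent: float = 133.0
    mean_segment_length: float = 26.0   # um, dendrite
    axon_segment_length: float = 42.0   # um
    branch_prob: float = 0.45
    max_order: int | None = 16
    tortuosity_target: float = 1.30
    n_dendrites: int = 5
    descending_collateral: bool = False
    axon_length_budget: float = 9000.0   # um total axonal cable
    dend_length_budget: float = 1800.0   # um total dendritic cable
    z_half_depth: float = 60.0
    seed: int = 0

    _MTYPES = ("NGC-DA", "NGC-SA", "HAC", "DAC", "LAC", "SAC")

    def __post_init__(self) -> None:
        for name in ("target_h_extent", "target_v_extent", "dend_h_extent",
                     "dend_v_extent", "mean_segment_length", "axon_segment_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tortuosity_target < 1.0:
            raise ValueError("tortuosity_target must be >= 1")
        if self.mtype not in self._MTYPES:
            raise ValueError(f"unknown mtype {self.mtype!r}")
        if self.branch_prob >= 1.0 and self.max_order is None:
            raise ValueError("branch_prob >= 1 with unbounded order: tree diverges")

    @classmethod
    def for_mtype(cls, mtype: str, seed: int = 0, **overrides) -> "MorphGenSpec":
        base = dict(MTYPE_DEFAULTS[mtype])
        base.update(overrides)
        return cls(mtype=mtype, seed=seed, **base)


#: Class means of the morphological battery (axonal and dendritic extents in
#: um, segment lengths in um, tortuosity) used as generator defaults.
MTYPE_DEFAULTS: dict[str, dict] = {
    "NGC-DA": dict(target_h_extent=481.0, target_v_extent=263.0,
                   dend_h_extent=122.0, dend_v_extent=133.0,
                   mean_segment_length=26.0, axon_segment_length=42.0,
                   tortuosity_target=1.30, n_dendrites=5, max_order=16,
                   axon_length_budget=11000.0, dend_length_budget=1500.0,
                   branch_prob=0.55),
    "NGC-SA": dict(target_h_extent=513.0, target_v_extent=163.0,
                   dend_h_extent=191.0, dend_v_extent=150.0,
                   mean_segment_length=33.0, axon_segment_length=45.0,
                   tortuosity_target=1.29, n_dendrites=6, max_order=15,
                   axon_length_budget=6100.0, dend_length_budget=1800.0,
                branch_prob=0.45),
    "HAC": dict(target_h_extent=826.0, target_v_extent=202.0,
                dend_h_extent=227.0, dend_v_extent=170.0,
                mean_segment_length=45.0, axon_segment_length=67.0,
                tortuosity_target=1.27, n_dendrites=5, max_order=14,
                axon_length_budget=9700.0, dend_length_budget=1800.0,
                branch_prob=0.40),
    "DAC": dict(target_h_extent=1035.0, target_v_extent=602.0,
                dend_h_extent=305.0, dend_v_extent=209.0,
                mean_segment_length=50.0, axon_segment_length=60.0,
                tortuosity_target=1.24, n_dendrites=6, max_order=20,
                axon_length_budget=14600.0, dend_length_budget=2500.0,
                branch_prob=0.45, descending_collateral=True),
    "LAC": dict(target_h_extent=879.0, target_v_extent=316.0,
                dend_h_extent=211.0, dend_v_extent=187.0,
                mean_segment_length=34.0, axon_segment_length=44.0,
                tortuosity_target=1.31, n_dendrites=6, max_order=21,
                axon_length_budget=15000.0, dend_length_budget=2000.0,
                branch_prob=0.50),
    "SAC": dict(target_h_extent=411.0, target_v_extent=251.0,
                dend_h_extent=218.0, dend_v_extent=194.0,
                mean_segment_length=38.0, axon_segment_length=45.0,
                tortuosity_target=1.22, n_dendrites=5, max_order=12,
                axon_length_budget=3300.0, dend_length_budget=1600.0,
                branch_prob=0.40),
}


def _perp_basis(axis: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to ``axis``."""
    while True:
        v = rng.standard_normal(3)
        v -= np.dot(v, axis) * axis
        norm = np.linalg.norm(v)
        if norm > 1e-6:
            return v / norm


class _TreeBuilder:
    def __init__(self, spec: MorphGenSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.ids: list[int] = []
        self.parents: list[int] = []
        self.structs: list[int] = []
        self.xyz: list[np.ndarray] = []
        self.radius: list[float] = []
        self._budgets = {
            AXON: spec.axon_length_budget,
            DENDRITE: spec.dend_length_budget,
        }

    def add(self, structure: int, pos: np.ndarray, radius: float, parent: int) -> int:
        nid = len(self.ids) + 1
        self.ids.append(nid)
        self.parents.append(parent)
        self.structs.append(structure)
        self.xyz.append(np.asarray(pos, float))
        self.radius.append(radius)
        return nid

    def soma(self, radius: float = 7.4) -> int:
        center = self.add(SOMA, np.zeros(3), radius, -1)
        for ang in np.linspace(0, 2 * math.pi, 8, endpoint=False):
            self.add(SOMA, [radius * math.cos(ang), radius * math.sin(ang), 0.0],
                     1.0, center)
        return center

    def segment_points(self, start: np.ndarray, axis: np.ndarray,
                       length: float, box: tuple,
                       n_sub: int = 4) -> tuple[list[np.ndarray], np.ndarray]:
        """Zig-zag chain realizing the tortuosity target exactly: substeps
        alternate +/- theta from the segment axis, theta = arccos(1 / t).
        Substeps that would leave the bounding box reflect the axis, so
        overshoot never exceeds one substep.  Returns (points, final axis).
        """
        theta = math.acos(1.0 / self.spec.tortuosity_target)
        axis = axis / np.linalg.norm(axis)
        bounds = box
        # redirect the axis inward when the projected endpoint would leave
        # the box, so the segment keeps a straight axis (exact tortuosity)
        endpoint = start + length * math.cos(theta) * axis
        for d, (lo, hi) in enumerate(bounds):
            if endpoint[d] < lo or endpoint[d] > hi:
                axis[d] = -axis[d]
        perp = _perp_basis(axis, self.rng)
        step = length / n_sub
        pts = []
        pos = start.copy()
        for i in range(n_sub):
            sgn = 1.0 if i % 2 == 0 else -1.0
            direction = math.cos(theta) * axis + sgn * math.sin(theta) * perp
            pos = pos + step * direction
            # mirror backstop for the rare zig-zag poke through a wall
            for d, (lo, hi) in enumerate(bounds):
                if pos[d] < lo:
                    pos[d] = 2 * lo - pos[d]
                    axis[d] = -axis[d]
                    perp[d] = -perp[d]
                elif pos[d] > hi:
                    pos[d] = 2 * hi - pos[d]
                    axis[d] = -axis[d]
                    perp[d] = -perp[d]
            pts.append(pos.copy())
        return pts, axis

    def budget_left(self, structure: int) -> float:
        return self._budgets.get(structure, math.inf)

    def spend(self, structure: int, length: float) -> None:
        if structure in self._budgets:
            self._budgets[structure] -= length

    def grow_trunk(self, parent: int, structure: int, axis: np.ndarray,
                   reach: float, seg_len_mean: float, radius: float,
                   box: tuple) -> None:
        """A trunk advances until its axial path meets ``reach``; when
        branching is on, every interior segment end bifurcates into the
        trunk continuation plus a side branch, so generator segments
        coincide with inter-branch-point segments."""
        spec = self.spec
        rng = self.rng
        axis = np.asarray(axis, float)
        axis /= np.linalg.norm(axis)
        pos = self.xyz[0].copy()
        node = parent
        advance = 0.0
        order = 1
        while advance < reach:
            length = max(5.0, rng.gamma(16.0, seg_len_mean / 16.0))
            pts, axis = self.segment_points(pos, axis, length, box)
            for pt in pts:
                node = self.add(structure, pt, radius, node)
                pos = pt
            self.spend(structure, length)
            advance += length / spec.tortuosity_target
            if advance >= reach:
                break
            if (spec.branch_prob > 0.0
                    and (spec.max_order is None or order < spec.max_order)
                    and self.budget_left(structure) > 0):
                self._grow_side(node, pos, axis, structure, seg_len_mean,
                                radius, order + 1, box)
                order += 1

    def _grow_side(self, parent: int, start: np.ndarray, trunk_axis: np.ndarray,
                   structure: int, seg_len_mean: float, radius: float,
                   order: int, box: tuple) -> None:
        """A side branch: one segment, then with branch_prob a bifurcation
        into two further side branches (subject to order and length budget)."""
        spec = self.spec
        rng = self.rng
        perp = _perp_basis(trunk_axis, rng)
        ang = math.radians(rng.uniform(45.0, 75.0))
        axis = math.cos(ang) * trunk_axis + math.sin(ang) * perp
        axis /= np.linalg.norm(axis)
        pos = start.copy()
        node = parent
        length = max(5.0, rng.gamma(16.0, seg_len_mean / 16.0))
        pts, axis = self.segment_points(pos, axis, length, box)
        for pt in pts:
            node = self.add(structure, pt, radius, node)
            pos = pt
        self.spend(structure, length)
        if (rng.random() < spec.branch_prob
                and (spec.max_order is None or order < spec.max_order)
                and self.budget_left(structure) > 0):
            for _ in range(2):
                self._grow_side(node, pos, axis, structure, seg_len_mean,
                                radius, order + 1, box)

    def build(self) -> Morphology:
        return Morphology(
            np.array(self.ids), np.array(self.parents), np.array(self.structs),
            np.array(self.xyz), np.array(self.radius),
        )


def generate_morphology(spec: MorphGenSpec) -> Morphology:
    """Grow one stochastic reconstruction of the requested class.

    Four extent-setting axonal trunks (left/right horizontal, up/down
    vertical) pin the arbor's horizontal and vertical extents near their
    targets; additional random trunks and stochastic side branching fill the
    arbor in.  DAC specs allocate most of the vertical extent to a downward
    trunk - the descending collateral - which crosses 100 um below the soma.
    Seed-deterministic.
    """
    rng = np.random.default_rng(spec.seed)
    b = _TreeBuilder(spec, rng)
    center = b.soma()

    hx = spec.target_h_extent / 2.0
    if spec.descending_collateral:
        v_down, v_up = 0.8 * spec.target_v_extent, 0.2 * spec.target_v_extent
    else:
        v_down = v_up = spec.target_v_extent / 2.0
    axon_box = ((-hx, hx), (-v_down, v_up),
                (-spec.z_half_depth, spec.z_half_depth))
    seg_a = spec.axon_segment_length
    trunk_reach = 0.9  # trunks stop just shy; reflections cap the rest
    for axis, reach in [
        ((1.0, 0.1, 0.05), hx * trunk_reach),
        ((-1.0, -0.1, -0.05), hx * trunk_reach),
        ((0.15, 1.0, 0.05), v_up * trunk_reach),
        ((-0.15, -1.0, -0.05), v_down * trunk_reach),
    ]:
        ax = np.array(axis) / np.linalg.norm(axis)
        b.grow_trunk(center, AXON, ax, reach, seg_a, 0.3, axon_box)
    # filler trunks at random azimuths
    for _ in range(2):
        ang = rng.uniform(0, 2 * math.pi)
        ax = np.array([math.cos(ang), math.sin(ang), rng.uniform(-0.2, 0.2)])
        ax /= np.linalg.norm(ax)
        b.grow_trunk(center, AXON, ax, 0.35 * min(hx, (v_up + v_down) / 2),
                     seg_a, 0.3, axon_box)

    dhx, dvy = spec.dend_h_extent / 2.0, spec.dend_v_extent / 2.0
    dend_box = ((-dhx, dhx), (-dvy, dvy),
                (-spec.z_half_depth, spec.z_half_depth))
    dend_axes = [(1.0, 0.1, 0.0), (-1.0, -0.1, 0.0),
                 (0.1, 1.0, 0.0), (-0.1, -1.0, 0.0)]
    dend_reaches = [dhx * trunk_reach, dhx * trunk_reach,
                    dvy * trunk_reach, dvy * trunk_reach]
    while len(dend_axes) < spec.n_dendrites:
        ang = rng.uniform(0, 2 * math.pi)
        dend_axes.append((math.cos(ang), math.sin(ang), rng.uniform(-0.1, 0.1)))
        dend_reaches.append(0.5 * min(dhx, dvy))
    for axis, reach in zip(dend_axes[: spec.n_dendrites],
                           dend_reaches[: spec.n_dendrites]):
        ax = np.array(axis) / np.linalg.norm(axis)
        b.grow_trunk(center, DENDRITE, ax, reach, spec.mean_segment_length,
                     0.6, dend_box)
    morph = b.build()
    morph.metadata.update({
        "mtype_true": spec.mtype, "seed": spec.seed,
        "target_h_extent": spec.target_h_extent,
        "target_v_extent": spec.target_v_extent,
    })
    return morph


# ---------------------------------------------------------------------------
# Synapse generator
# ---------------------------------------------------------------------------

@dataclass
class SynapseGenSpec:
    """Generative parameters of one synaptic connection.

    The fast component is a per-AP biexponential IPSP (GABA_A-like); the
    slow component is driven by a cooperative G-protein cascade that only
    transmitter released at instantaneous rates >= ``min_drive_freq``
    reaches (GABA_B-like).  ``rundown_rate`` scales repetition k by
    (1 - rundown_rate)**k, emulating cytoplasmic dilution in whole-cell
    mode; perforated-patch simulations use 0.
    """

    receptor: str = "GABA_AB"
    gA_amp: float = 2.0             # mV
    tau_rise_A: float = 8.0         # ms
    tau_decay_A: float = 40.0       # ms
    gB_amp: float = 1.5             # mV
    gB_onset_delay: float = 15.0    # ms
    n_binding_sites: int = 4
    min_drive_freq: float = 40.0    # Hz
    tau_pool: float = 100.0         # ms, transmitter pool decay
    tau_effector: float = 60.0      # ms, K-conductance relaxation
    pool_half: float = 2.0          # pool level at half gate activation
    rundown_rate: float = 0.0
    noise_sd: float = 0.0           # mV
    n_repetitions: int = 5
    sampling_rate: float = 10.0     # kHz
    post_window: float = 500.0      # ms recorded after the last spike
    v_hold: float = -57.0
    patch_mode: str = "whole_cell"
    seed: int = 0

    _RECEPTORS = ("GABA_A", "GABA_B", "GABA_AB")

    def __post_init__(self) -> None:
        if self.receptor not in self._RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")
        if not self.tau_rise_A < self.tau_decay_A:
            raise ValueError("tau_rise_A must be < tau_decay_A")
        if not (0.0 <= self.rundown_rate < 1.0):
            raise ValueError("rundown_rate must be in [0, 1)")

    @classmethod
    def for_receptor(cls, receptor: str, seed: int = 0, **overrides) -> "SynapseGenSpec":
        base = dict(RECEPTOR_DEFAULTS[receptor])
        base.update(overrides)
        return cls(receptor=receptor, seed=seed, **base)


RECEPTOR_DEFAULTS: dict[str, dict] = {
    "GABA_A": dict(gA_amp=2.5, gB_amp=0.0),
    "GABA_B": dict(gA_amp=0.0, gB_amp=1.8),
    "GABA_AB": dict(gA_amp=2.0, gB_amp=1.5),
}


def _gaba_a_kernel(spec: SynapseGenSpec, dt: float) -> np.ndarray:
    t = np.arange(0.0, 8.0 * spec.tau_decay_A, dt)
    shape = np.exp(-t / spec.tau_decay_A) - np.exp(-t / spec.tau_rise_A)
    return -spec.gA_amp * shape / shape.max()


def _gaba_b_response(spec: SynapseGenSpec, t: np.ndarray,
                     spikes: np.ndarray) -> np.ndarray:
    """Cooperative cascade: qualifying spikes feed a slow transmitter pool
    G; a Hill gate with ``n_binding_sites`` reads it out; the gated signal
    relaxes through the effector conductance time constant."""
    if spec.gB_amp == 0.0 or len(spikes) == 0:
        return np.zeros_like(t)
    dt = t[1] - t[0]
    max_isi = 1000.0 / spec.min_drive_freq
    qualifying = [
        s for i, s in enumerate(spikes)
        if i > 0 and (s - spikes[i - 1]) <= max_isi + 1e-9
    ]
    if not qualifying:
        return np.zeros_like(t)
    G = np.zeros_like(t)
    impulse = np.zeros_like(t)
    for s in qualifying:
        idx = int(round((s + spec.gB_onset_delay) / dt))
        if 0 <= idx < len(impulse):
            impulse[idx] += 1.0
    decay = math.exp(-dt / spec.tau_pool)
    g = 0.0
    for i in range(len(t)):
        g = g * decay + impulse[i]
        G[i] = g
    n = spec.n_binding_sites
    gate = G**n / (spec.pool_half**n + G**n)
    # effector relaxation (first-order low-pass)
    alpha = dt / (spec.tau_effector + dt)
    B = np.zeros_like(t)
    b = 0.0
    for i in range(len(t)):
        b += alpha * (gate[i] - b)
        B[i] = b
    return -spec.gB_amp * B


def generate_paired_recording(spec: SynapseGenSpec, pre_spikes) -> PairedRecording:
    """Simulate the postsynaptic sweeps evoked by a presynaptic spike train.

    The GABA_A component answers every AP with a biexponential IPSP; the
    GABA_B component answers only spike runs at or above ``min_drive_freq``
    through the cascade, with sigmoidal rise and slow decay.  Repetition k
    is scaled by (1 - rundown_rate)**k; noise is seeded per sweep.
    """
    pre = np.asarray(pre_spikes, dtype=float)
    if len(pre) == 0:
        raise ValueError("presynaptic spike list is empty")
    if np.any(np.diff(pre) < 0):
        raise ValueError("presynaptic spikes must be sorted")
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sampling_rate
    t_end = pre[-1] + spec.post_window
    t = np.arange(0.0, t_end, dt)
    clean = np.zeros_like(t)
    if spec.gA_amp > 0:
        kern = _gaba_a_kernel(spec, dt)
        for s in pre:
            i0 = int(round(s / dt))
            i1 = min(len(t), i0 + len(kern))
            if i0 < len(t):
                clean[i0:i1] += kern[: i1 - i0]
    clean += _gaba_b_response(spec, t, pre)

    sweeps = []
    for k in range(spec.n_repetitions):
        scale = (1.0 - spec.rundown_rate) ** k
        v = spec.v_hold + scale * clean
        if spec.noise_sd > 0:
            v = v + rng.normal(0.0, spec.noise_sd, len(v))
        sweeps.append(VoltageTrace(t, v, np.zeros_like(t), {
            "cell_id": f"synth-{spec.receptor}-{spec.seed}", "sweep_id": k,
            "sampling_rate_khz": spec.sampling_rate,
        }))
    return PairedRecording(
        pre_spike_times=pre,
        post_sweeps=sweeps,
        holding_potential=spec.v_hold,
        stim_frequency=(
            1000.0 / float(np.median(np.diff(pre))) if len(pre) > 1 else np.nan
        ),
        patch_mode=spec.patch_mode,
        metadata={"receptor_true": spec.receptor, "seed": spec.seed,
                  "rundown_rate_true": spec.rundown_rate},
    )


def generate_gj_recording(
    cc: float,
    r_in_mohm: float = 150.0,
    step_pa: float = -80.0,
    tau_ms: float = 15.0,
    n_sweeps: int = 10,
    noise_sd: float = 0.05,
    sampling_rate: float = 10.0,
    seed: int = 0,
) -> tuple[PairedRecording, PairedRecording]:
    """Gap-junction probe: hyperpolarizing step in one cell, attenuated
    steady-state deflection (coupling coefficient ``cc``) in the other.

    Returns (injected-cell recording, follower-cell recording); both hold
    the step in their stimulus channel for windowing.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / sampling_rate
    t = np.arange(0.0, 600.0, dt)
    stim = np.where((t >= 100.0) & (t < 500.0), step_pa, 0.0)
    v_rest = -65.0
    defl = r_in_mohm * step_pa * 1e-3
    base = np.full_like(t, v_rest)
    on = (t >= 100.0) & (t < 500.0)
    base[on] += defl * (1.0 - np.exp(-(t[on] - 100.0) / tau_ms))
    off = t >= 500.0
    base[off] += defl * (1.0 - math.exp(-400.0 / tau_ms)) * np.exp(
        -(t[off] - 500.0) / tau_ms
    )
    follower = v_rest + cc * (base - v_rest)

    def sweeps(center: np.ndarray) -> list[VoltageTrace]:
        out = []
        for k in range(n_sweeps):
            v = center + rng.normal(0.0, noise_sd, len(center))
            out.append(VoltageTrace(t, v, stim, {
                "cell_id": "synth-gj", "sweep_id": k,
                "sampling_rate_khz": sampling_rate,
            }))
        return out

    meta = {"cc_true": cc, "seed": seed}
    rec_pre = PairedRecording(np.array([100.0]), sweeps(base), metadata=meta)
    rec_post = PairedRecording(np.array([100.0]), sweeps(follower), metadata=meta)
    return rec_pre, rec_post


# ---------------------------------------------------------------------------
# Pair populations
# ---------------------------------------------------------------------------

def generate_pair_population(
    n_pairs: int,
    p_syn_directed: float,
    p_gj: float,
    seed: int = 0,
):
    """A probed population of cell pairs with ground-truth connectivity.

    Each ordered direction of a pair is synaptically connected independently
    with ``p_syn_directed``; each unordered pair carries a gap junction with
    ``p_gj``.  Returns a DataFrame with one row per pair and boolean columns
    ``syn_12``, ``syn_21``, ``gj``.
    """
    import pandas as pd

    for name, p in (("p_syn_directed", p_syn_directed), ("p_gj", p_gj)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "pair_id": np.arange(n_pairs),
        "syn_12": rng.random(n_pairs) < p_syn_directed,
        "syn_21": rng.random(n_pairs) < p_syn_directed,
        "gj": rng.random(n_pairs) < p_gj,
    })


# ---------------------------------------------------------------------------
# Ground-truth manifests
# ---------------------------------------------------------------------------

def write_manifest(entries: dict, path) -> None:
    """Key-value text manifest (one ``key: value`` per line)."""
    from pathlib import Path

    lines = [f"{k}: {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_manifest(path) -> dict:
    from pathlib import Path

    out = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out
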