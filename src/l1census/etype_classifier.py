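"""Firing-pattern (e-type) classification from inter-spike-interval structure.

Layer-1 interneurons are assigned one of five Petilla-style firing types from
the response to a suprathreshold step:

* cAC  - classical accommodating: ISIs lengthen through the train.
* cNAC - classical non-accommodating: roughly constant ISIs.
* bNAC - bursting non-accommodating: a four-spike burst (mean of the first
  three ISIs < 25 ms) or an initial doublet (first ISI <= 25 ms).
* cSTUT - stuttering: a poorly fit ISI regression with at least one silent
  period (an ISI > 100 ms).
* cIR  - irregular: a poorly fit regression without silent periods.

The decision tree regresses ISI against AP sequence order; the RMS of the
regression residuals separates the regular group (RMS <= 30 ms) from the
stuttering/irregular group, and within the regular group a slope >= 1 ms per
AP index marks accommodation.  The burst test precedes the slope test because
burst ISIs would otherwise corrupt the accommodation fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ephys_features import SpikeTrain

__all__ = [
    "IsiRegression",
    "EtypeLabel",
    "InsufficientSpikes",
    "isi_sequence",
    "fit_isi_regression",
    "detect_silent_periods",
    "detect_burst_subtype",
    "classify_etype",
]

ETYPES = ("cAC", "cNAC", "bNAC", "cSTUT", "cIR")


class InsufficientSpikes(ValueError):
    """Fewer spikes than the classifier requires (minimum 3)."""


@dataclass
class IsiRegression:
    """OLS fit of ISI (ms) against AP sequence index 1..n."""

    slope: float       # ms per AP index
    intercept: float   # ms
    rms_error: float   # root mean square of residuals, ms
    r: float           # Pearson correlation of ISI with index
    n_isi: int


@dataclass
class EtypeLabel:
    label: str                 # cAC | cNAC | bNAC | cSTUT | cIR | unclassified
    subtype: str = "none"      # burst4 | doublet | none (bNAC only)
    evidence: dict | None = None

    def __post_init__(self) -> None:
        if self.subtype != "none" and self.label != "bNAC":
            raise ValueError("subtype applies only to bNAC labels")


def isi_sequence(spikes: SpikeTrain | np.ndarray) -> np.ndarray:
    """Inter-spike intervals (ms) in AP sequence order.

    Accepts a :class:`SpikeTrain` or a sorted array of peak times; requires
    at least 3 spikes.
    """
    peaks = spikes.peak_times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if len(peaks) < 3:
        raise InsufficientSpikes(f"need >= 3 spikes, got {len(peaks)}")
    return np.diff(peaks)


def fit_isi_regression(isis: np.ndarray) -> IsiRegression:
    """Ordinary least squares of ISI against AP sequence index (1..n)."""
    isis = np.asarray(isis, dtype=float)
    n = len(isis)
    if n < 2:
        raise ValueError("need >= 2 ISIs for a regression")
    x = np.arange(1, n + 1, dtype=float)
    slope, intercept = np.polyfit(x, isis, 1)
    resid = isis - (slope * x + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))
    sd_y = np.std(isis)
    r = float(np.corrcoef(x, isis)[0, 1]) if sd_y > 0 else 0.0
    return IsiRegression(float(slope), float(intercept), rms, r, n)


def detect_silent_periods(isis: np.ndarray, gap_threshold: float = 100.0) -> np.ndarray:
    """All ISIs strictly greater than ``gap_threshold`` ms (silent periods)."""
    isis = np.asarray(isis, dtype=float)
    return isis[isis > gap_threshold]


def detect_burst_subtype(isis: np.ndarray) -> str:
    """Initial-burst test: 'burst4', 'doublet' or 'none'.

    burst4: four rapid onset spikes, i.e. the mean of the first three ISIs is
    strictly below 25 ms.  Otherwise doublet: first ISI at most 25 ms.
    burst4 takes precedence.
    """
    isis = np.asarray(isis, dtype=float)
    if len(isis) == 0:
        raise ValueError("need >= 1 ISI")
    if len(isis) >= 3 and np.mean(isis[:3]) < 25.0:
        return "burst4"
    if isis[0] <= 25.0:
        return "doublet"
    return "none"


def classify_etype(
    spikes: SpikeTrain | np.ndarray,
    rms_threshold: float = 30.0,
    slope_threshold: float = 1.0,
    gap_threshold: float = 100.0,
) -> EtypeLabel:
    """Assign an e-type label from a spike train.

    Decision tree: a regression RMS above ``rms_threshold`` puts the cell in
    the stuttering/irregular group (cSTUT when any silent period exceeds
    ``gap_threshold``, else cIR).  Within the well-fit group an initial burst
    gives bNAC; otherwise slope >= ``slope_threshold`` gives cAC and a
    flatter train cNAC.
    """
    try:
        isis = isi_sequence(spikes)
    except InsufficientSpikes as exc:
        return EtypeLabel("unclassified", evidence={"reason": str(exc)})
    reg = fit_isi_regression(isis)
    gaps = detect_silent_periods(isis, gap_threshold)
    burst = detect_burst_subtype(isis)
    evidence = {
        "slope": reg.slope,
        "intercept": reg.intercept,
        "rms_error": reg.rms_error,
        "r": reg.r,
        "max_silent_gap": float(gaps.max()) if len(gaps) else 0.0,
        "burst_isis": list(isis[:3]),
        "n_isi": reg.n_isi,
    }
    if reg.rms_error > rms_threshold:
        label = "cSTUT" if len(gaps) > 0 else "cIR"
        return EtypeLabel(label, evidence=evidence)
    if burst != "none":
        return EtypeLabel("bNAC", subtype=burst, evidence=evidence)
    if reg.slope >= slope_threshold:
        return EtypeLabel("cAC", evidence=evidence)
    return EtypeLabel("cNAC", evidence=evidence)
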