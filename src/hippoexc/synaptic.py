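"""Spontaneous synaptic event detection and excitation--inhibition summary.

Events (sEPSCs recorded at -70 mV, sIPSCs at 0 mV) are detected with the
classical sliding optimally-scaled template scheme: at every offset a
double-exponential template is least-squares fitted (scale + offset) to the
trace and an event is declared where the detection criterion -- the fitted
scale divided by its standard error -- exceeds a threshold (default 3.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VoltageClampTrace",
    "SynapticEvent",
    "EIResult",
    "double_exp_kernel",
    "detect_events",
    "summarize_events",
    "compute_ei_ratio",
]


@dataclass
class VoltageClampTrace:
    """Whole-cell voltage-clamp current trace (pA)."""

    current: np.ndarray
    dt: float  # s
    holding_mv: float  # -70 (sEPSC) or 0 (sIPSC)
    truth_events: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration_s(self) -> float:
        return self.current.size * self.dt

    @property
    def polarity(self) -> int:
        """Deflection sign: inward (negative) at -70 mV, outward at 0 mV."""
        return -1 if self.holding_mv < -35 else +1


@dataclass(frozen=True)
class SynapticEvent:
    onset_s: float
    amplitude_pa: float  # magnitude
    rise_ms: float
    decay_ms: float
    detection_score: float


@dataclass(frozen=True)
class EIResult:
    """Excitation-inhibition summary.

    ``ei_ratio`` follows the normalized convention
    f_E*A_E / (f_E*A_E + f_I*A_I) in [0, 1] by default; the pure-ratio
    convention f_E*A_E / (f_I*A_I) is available via ``compute_ei_ratio``.
    The normalized convention is an assumption of this implementation.
    """

    f_e_hz: float
    a_e_pa: float | None
    f_i_hz: float
    a_i_pa: float | None
    ei_ratio: float | None
    convention: str = "normalized"


def double_exp_kernel(rise_ms: float, decay_ms: float, dt: float,
                      support_factor: float = 6.0) -> np.ndarray:
    """Unit-peak double-exponential kernel exp(-t/τd) - exp(-t/τr)."""
    if not (decay_ms > rise_ms > 0):
        raise ValueError("need decay > rise > 0")
    tr, td = rise_ms * 1e-3, decay_ms * 1e-3
    n = int(round(support_factor * td / dt))
    t = np.arange(n) * dt
    k = np.exp(-t / td) - np.exp(-t / tr)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def _sliding_template_criterion(data: np.ndarray, w: np.ndarray):
    """Vectorised optimally-scaled sliding template fit.

    For each window of length N, fit data ≈ s*w + c by least squares and
    return (scale s, detection criterion s / SE(s)) per offset.
    """
    n = w.size
    sw = w.sum()
    sww = (w * w).sum()
    ones = np.ones(n)
    sd = np.convolve(data, ones[::-1], mode="valid")
    swd = np.convolve(data, w[::-1], mode="valid")
    sdd = np.convolve(data * data, ones[::-1], mode="valid")
    denom = sww - sw * sw / n
    s = (swd - sw * sd / n) / denom
    c = (sd - s * sw) / n
    sse = (sdd + s * s * sww + n * c * c
           - 2.0 * (s * swd + c * sd - s * c * sw))
    sse = np.maximum(sse, 0.0)
    noise_sd = np.sqrt(sse / max(n - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = np.where(noise_sd > 0, s / noise_sd, 0.0)
    return s, crit


def detect_events(
    trace: VoltageClampTrace,
    rise_ms: float = 1.0,
    decay_ms: float = 6.0,
    criterion_threshold: float = 3.5,
    template: np.ndarray | None = None,
) -> list[SynapticEvent]:
    """Sliding-template synaptic event detection.

    The template polarity follows the holding potential (inward/negative at
    -70 mV).  Overlapping detections are resolved to local maxima of the
    criterion, with a minimum inter-event separation equal to the template
    rise time to avoid double-counting single events.  Amplitudes are
    reported as magnitudes.
    """
    if template is None:
        template = double_exp_kernel(rise_ms, decay_ms, trace.dt)
    template = np.asarray(template, dtype=float)
    if np.ptp(template) == 0:
        raise ValueError("degenerate (constant) template")
    if template.size >= trace.current.size:
        raise ValueError("template support must be much shorter than the trace")
    w = template * trace.polarity

    s, crit = _sliding_template_criterion(trace.current, w)
    above = crit > criterion_threshold
    if not above.any():
        return []

    refractory = max(1, int(round(rise_ms * 1e-3 / trace.dt)))
    # all local maxima of the criterion above threshold, separated by at
    # least the template rise time
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(crit, height=criterion_threshold, distance=refractory)
    amps = np.abs(s[peaks] * template.max())
    # suppress tail artifacts: a small detection inside the decaying support
    # of a much larger preceding event is its tail, not a new event
    support = template.size
    order = np.argsort(crit[peaks])[::-1]
    accepted: list[int] = []
    for idx in order:
        i = peaks[idx]
        tail = any(0 < i - peaks[j] <= support and amps[idx] < 0.25 * amps[j]
                   for j in accepted)
        if not tail:
            accepted.append(idx)
    accepted.sort(key=lambda idx: peaks[idx])
    return [
        SynapticEvent(
            onset_s=peaks[idx] * trace.dt,
            amplitude_pa=float(amps[idx]),
            rise_ms=rise_ms,
            decay_ms=decay_ms,
            detection_score=float(crit[peaks[idx]]),
        )
        for idx in accepted
    ]


def summarize_events(events, duration_s: float) -> tuple[float, float | None]:
    """(frequency Hz, mean amplitude pA).  Amplitude is None for no events."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    f = len(events) / duration_s
    if not events:
        return f, None
    return f, float(np.mean([abs(e.amplitude_pa) for e in events]))


def compute_ei_ratio(
    f_e: float, a_e: float | None, f_i: float, a_i: float | None,
    convention: str = "normalized",
) -> float | None:
    """Scalar excitation-inhibition ratio from event frequencies and amplitudes.

    ``normalized``: E/(E+I) with E = f_E*A_E, I = f_I*A_I (bounded [0,1]);
    ``pure``: E/I.  Returns None (undefined) when both drives are zero.
    The normalized default is this package's assumption, labelled in outputs.
    """
    e = f_e * (a_e or 0.0)
    i = f_i * (a_i or 0.0)
    if e < 0 or i < 0:
        raise ValueError("drives must be nonnegative")
    if e == 0 and i == 0:
        return None
    if convention == "normalized":
        return e / (e + i)
    if convention == "pure":
        return float(np.inf) if i == 0 else e / i
    raise ValueError("convention must be 'normalized' or 'pure'")


def ei_summary(epsc_events, epsc_duration_s, ipsc_events, ipsc_duration_s,
               convention: str = "normalized") -> EIResult:
    """Full E-I summary from detected sEPSC and sIPSC event lists."""
    f_e, a_e = summarize_events(epsc_events, epsc_duration_s)
    f_i, a_i = summarize_events(ipsc_events, ipsc_duration_s)
    return EIResult(f_e, a_e, f_i, a_i,
                    compute_ei_ratio(f_e, a_e, f_i, a_i, convention), convention)
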