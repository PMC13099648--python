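"""Morpho-electric feature extraction from current-clamp sweeps.

Per-neuron intrinsic-excitability parameters: rheobase (minimum 1-s
depolarizing step current eliciting an action potential), output gain (linear
slope of the rising portion of the I--F curve), spike latency under a 1-s
800-pA ramp, passive properties (input resistance R_in, membrane capacitance
C_m, resting membrane potential) from a hyperpolarizing step, secondary
parameters (maximal firing rate, spike accommodation), the inactivation
threshold marking depolarization block, dentate-granule-cell Type I/II
classification from the inactivation-threshold distribution, and soma-volume
prediction from C_m assuming a constant specific membrane capacitance.

Units: current pA, voltage mV, resistance MΩ, capacitance pF, time s unless
a name says otherwise.  Missing values propagate as None / NaN, never 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import gaussian_kde

__all__ = [
    "StepProtocol",
    "RampProtocol",
    "Sweep",
    "SweepSet",
    "Spike",
    "NeuronFeatures",
    "detect_spikes",
    "build_if_curve",
    "compute_gain",
    "compute_rheobase",
    "compute_spike_latency",
    "compute_passive",
    "compute_secondary",
    "compute_inactivation_threshold",
    "classify_dgc_type",
    "predict_soma_volume",
    "percent_of_control",
    "extract_features",
]


@dataclass(frozen=True)
class StepProtocol:
    """Family of square current steps (1-s epochs by convention)."""

    start_pa: float
    increment_pa: float
    n_steps: int
    duration_s: float = 1.0
    pre_s: float = 0.1
    post_s: float = 0.1

    @property
    def currents(self) -> np.ndarray:
        return self.start_pa + self.increment_pa * np.arange(self.n_steps)


@dataclass(frozen=True)
class RampProtocol:
    """Linear current ramp from 0 to ``peak_pa`` over ``duration_s``."""

    peak_pa: float = 800.0
    duration_s: float = 1.0
    pre_s: float = 0.1
    post_s: float = 0.1


@dataclass
class Sweep:
    voltage: np.ndarray  # mV
    current: np.ndarray  # pA (injected command)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.shape != self.current.shape:
            raise ValueError("voltage and current arrays must be aligned")


@dataclass
class SweepSet:
    sweeps: list[Sweep]
    dt: float  # s
    protocol: StepProtocol | RampProtocol | None = None
    meta: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)  # simulator ground truth

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


@dataclass(frozen=True)
class Spike:
    """One action potential and its waveform metrics."""

    t_s: float
    threshold_mv: float
    peak_mv: float
    amplitude_mv: float
    half_width_ms: float
    rise_time_ms: float
    fahp_mv: float
    sahp_mv: float | None = None  # train-level; filled by compute_sahp


@dataclass
class NeuronFeatures:
    rheobase_pa: float | None = None
    gain: float | None = None  # spikes s^-1 pA^-1
    spike_latency_ms: float | None = None
    r_in_mohm: float | None = None
    c_m_pf: float | None = None
    rmp_mv: float | None = None
    max_rate_hz: float | None = None
    accommodation: float | None = None
    inactivation_threshold_pa: float | None = None
    dgc_type: str = "n/a"  # "I", "II" or "n/a"
    soma_volume_um3: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# spike detection and waveform metrics

def detect_spikes(
    sweep: Sweep,
    dt: float,
    dvdt_threshold: float = 20.0,  # mV/ms
    peak_window_ms: float = 5.0,
    fahp_window_ms: float = 5.0,
    min_amplitude_mv: float = 20.0,
) -> list[Spike]:
    """Detect action potentials by a dV/dt threshold crossing.

    Spike onset is the first sample where dV/dt exceeds ``dvdt_threshold``
    after having been below it; threshold voltage is the voltage at onset.
    Candidates whose threshold-to-peak excursion is below
    ``min_amplitude_mv`` are discarded (recording noise can exceed the
    slope criterion but never produces a full-height action potential).
    Amplitude = peak - threshold; half-width at half-amplitude; rise time
    10--90% of the threshold-to-peak excursion; fAHP = threshold voltage
    minus the minimum within ``fahp_window_ms`` after the peak.
    """
    v = sweep.voltage
    if v.size < 3:
        return []
    dvdt = np.gradient(v) / (dt * 1e3)  # mV/ms
    above = dvdt >= dvdt_threshold
    onsets = np.flatnonzero(above & ~np.r_[False, above[:-1]])

    peak_w = max(1, int(round(peak_window_ms * 1e-3 / dt)))
    fahp_w = max(1, int(round(fahp_window_ms * 1e-3 / dt)))

    spikes: list[Spike] = []
    last_peak = -1
    for i in onsets:
        if i <= last_peak:  # still inside the previous AP
            continue
        seg = v[i : i + peak_w]
        pk_rel = int(np.argmax(seg))
        pk = i + pk_rel
        thr_v = v[i]
        peak_v = v[pk]
        if peak_v <= thr_v:
            continue
        amp = peak_v - thr_v
        if amp < min_amplitude_mv:
            continue
        half = thr_v + amp / 2.0
        # half-width: crossings of the half-amplitude level around the peak
        up = _cross_time(v, i, pk, half, dt, rising=True)
        down = _cross_time(v, pk, min(pk + peak_w, v.size - 1), half, dt, rising=False)
        half_width_ms = (down - up) * 1e3 if (up is not None and down is not None) else np.nan
        t10 = _cross_time(v, i, pk, thr_v + 0.1 * amp, dt, rising=True)
        t90 = _cross_time(v, i, pk, thr_v + 0.9 * amp, dt, rising=True)
        rise_ms = (t90 - t10) * 1e3 if (t10 is not None and t90 is not None) else np.nan
        trough = float(np.min(v[pk : pk + fahp_w])) if pk + 1 < v.size else thr_v
        spikes.append(
            Spike(
                t_s=i * dt,
                threshold_mv=float(thr_v),
                peak_mv=float(peak_v),
                amplitude_mv=float(amp),
                half_width_ms=float(half_width_ms),
                rise_time_ms=float(rise_ms),
                fahp_mv=float(thr_v - trough),
            )
        )
        last_peak = pk + fahp_w
    return spikes


def _cross_time(v, i0, i1, level, dt, rising=True):
    """Linear-interpolated time (s) where v crosses level in [i0, i1]."""
    if i1 <= i0:
        return None
    seg = v[i0 : i1 + 1]
    if rising:
        idx = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        idx = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if idx.size == 0:
        return None
    j = idx[0]
    frac = (level - seg[j]) / (seg[j + 1] - seg[j]) if seg[j + 1] != seg[j] else 0.0
    return (i0 + j + frac) * dt


def compute_sahp(sweep: Sweep, dt: float, train_end_s: float, rmp_mv: float,
                 window_ms: tuple[float, float] = (200.0, 500.0)) -> float | None:
    """Slow AHP: baseline minus mean voltage 200--500 ms after train end."""
    i0 = int((train_end_s + window_ms[0] * 1e-3) / dt)
    i1 = int((train_end_s + window_ms[1] * 1e-3) / dt)
    if i1 > sweep.voltage.size or i1 <= i0:
        return None
    return float(rmp_mv - np.mean(sweep.voltage[i0:i1]))


# ---------------------------------------------------------------------------
# I-F curve and derived excitability parameters

def _step_current(sweep: Sweep, dt: float, proto: StepProtocol) -> float:
    i0 = int(proto.pre_s / dt)
    i1 = int((proto.pre_s + proto.duration_s) / dt)
    pre = sweep.current[: i0] if i0 > 0 else np.array([0.0])
    return float(np.mean(sweep.current[i0:i1]) - np.mean(pre))


def build_if_curve(sweep_set: SweepSet, dvdt_threshold: float = 20.0) -> list[tuple[float, int]]:
    """One (step current pA, spike count during the 1-s step) point per sweep.

    Counts spikes within the step window only; points ordered by current.
    """
    proto = sweep_set.protocol
    if not isinstance(proto, StepProtocol):
        raise ValueError("build_if_curve requires a step-family protocol")
    pts = []
    for sw in sweep_set.sweeps:
        cur = _step_current(sw, sweep_set.dt, proto)
        spikes = detect_spikes(sw, sweep_set.dt, dvdt_threshold)
        t0, t1 = proto.pre_s, proto.pre_s + proto.duration_s
        n = sum(1 for s in spikes if t0 <= s.t_s < t1)
        pts.append((cur, n))
    pts.sort(key=lambda p: p[0])
    currents = [round(c, 6) for c, _ in pts]
    if len(set(currents)) != len(currents):
        raise ValueError("duplicate step currents in sweep set")
    return pts


def compute_rheobase(if_curve: Sequence[tuple[float, int]]) -> float | None:
    """Smallest depolarizing step current with >= 1 spike; None if none."""
    for cur, n in sorted(if_curve):
        if cur > 0 and n >= 1:
            return float(cur)
    return None


def compute_gain(if_curve: Sequence[tuple[float, int]]) -> float | None:
    """OLS slope (spikes s^-1 pA^-1) of the rising portion of the I-F curve.

    Fit range: first suprathreshold point through the maximum-rate point
    (inclusive), excluding the descending limb caused by depolarization
    block.  None (missing) with fewer than 3 points in range.
    """
    pts = sorted(if_curve)
    counts = [n for _, n in pts]
    first = next((i for i, n in enumerate(counts) if n >= 1), None)
    if first is None:
        return None
    cmax = max(counts)
    imax = max(i for i, n in enumerate(counts) if n == cmax)  # end of the plateau
    if imax < first:
        return None
    sel = pts[first : imax + 1]
    if len(sel) < 3:
        return None
    x = np.array([c for c, _ in sel])
    y = np.array([n for _, n in sel], dtype=float)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def compute_spike_latency(ramp_set: SweepSet, dvdt_threshold: float = 20.0) -> float | None:
    """Delay (ms) from ramp onset to the first AP; None if no spike."""
    proto = ramp_set.protocol
    if not isinstance(proto, RampProtocol):
        raise ValueError("compute_spike_latency requires a ramp protocol")
    sw = ramp_set.sweeps[0]
    spikes = detect_spikes(sw, ramp_set.dt, dvdt_threshold)
    for s in spikes:
        if s.t_s >= proto.pre_s:
            return float((s.t_s - proto.pre_s) * 1e3)
    return None


# ---------------------------------------------------------------------------
# passive properties

def compute_passive(sweep_set: SweepSet, dvdt_threshold: float = 20.0
                    ) -> tuple[float, float, float]:
    """(R_in MΩ, C_m pF, RMP mV) from a subthreshold hyperpolarizing step.

    RMP = mean pre-step voltage; R_in = steady-state ΔV / I; τ from a
    single-exponential fit to the onset transient; C_m = τ / R_in.
    """
    proto = sweep_set.protocol
    if not isinstance(proto, StepProtocol):
        raise ValueError("compute_passive requires a step protocol")
    dt = sweep_set.dt
    sw = sweep_set.sweeps[0]
    if detect_spikes(sw, dt, dvdt_threshold):
        raise ValueError("passive step evoked spikes; use a smaller amplitude")
    i_step = _step_current(sw, dt, proto)
    i0 = int(proto.pre_s / dt)
    i1 = int((proto.pre_s + proto.duration_s) / dt)
    rmp = float(np.mean(sw.voltage[:i0])) if i0 > 0 else float(sw.voltage[0])
    if i_step == 0:  # no stimulus: only the resting potential is defined
        return math.nan, math.nan, rmp
    # steady state from the last 20% of the step
    ss = float(np.mean(sw.voltage[i1 - (i1 - i0) // 5 : i1]))
    dv = ss - rmp
    r_in = dv / i_step * 1e3  # mV/pA = GΩ -> MΩ
    if r_in <= 0:
        raise ValueError("non-positive input resistance estimate")

    t = (np.arange(i0, i1) - i0) * dt
    v = sw.voltage[i0:i1]

    def expdecay(t, tau):
        return ss + (rmp - ss) * np.exp(-t / tau)

    tau0 = max(dt * 5, 0.02)
    (tau,), _ = curve_fit(expdecay, t, v, p0=[tau0], maxfev=5000)
    c_m = tau * 1e3 / r_in * 1e3  # ms / MΩ = nF -> pF
    return float(r_in), float(c_m), rmp


# ---------------------------------------------------------------------------
# secondary parameters, inactivation, subtype classification

def compute_secondary(
    if_curve: Sequence[tuple[float, int]],
    sweep_set: SweepSet | None = None,
    min_spikes_for_accommodation: int = 5,
    dvdt_threshold: float = 20.0,
) -> tuple[float | None, float | None]:
    """(max firing rate Hz, accommodation ratio).

    Max rate = maximum spike count over the 1-s steps.  Accommodation =
    last ISI / first ISI at the first step with at least
    ``min_spikes_for_accommodation`` spikes; None if no such train.
    """
    counts = [n for _, n in sorted(if_curve)]
    max_rate = float(max(counts)) if counts else None
    accommodation = None
    if sweep_set is not None and isinstance(sweep_set.protocol, StepProtocol):
        proto = sweep_set.protocol
        by_cur = {}
        for sw in sweep_set.sweeps:
            by_cur[round(_step_current(sw, sweep_set.dt, proto), 6)] = sw
        for cur, n in sorted(if_curve):
            if n >= min_spikes_for_accommodation and round(cur, 6) in by_cur:
                sw = by_cur[round(cur, 6)]
                spikes = [s for s in detect_spikes(sw, sweep_set.dt, dvdt_threshold)
                          if proto.pre_s <= s.t_s < proto.pre_s + proto.duration_s]
                if len(spikes) >= 2:
                    isis = np.diff([s.t_s for s in spikes])
                    if isis[0] > 0:
                        accommodation = float(isis[-1] / isis[0])
                break
    return max_rate, accommodation


def compute_inactivation_threshold(
    if_curve: Sequence[tuple[float, int]],
    sweep_set: SweepSet | None = None,
    drop_frac: float = 0.5,
    cease_frac: float = 0.8,
    dvdt_threshold: float = 20.0,
) -> float | None:
    """Current (pA) at which the neuron enters depolarization block.

    The smallest step current at which (a) the spike count falls below
    ``drop_frac`` of the neuron's maximum and (b) spiking ceases before
    ``cease_frac`` of the step duration.  None when never satisfied
    (a Type II-like neuron that sustains firing).
    """
    pts = sorted(if_curve)
    counts = [n for _, n in pts]
    if not counts or max(counts) == 0:
        return None
    cmax = max(counts)
    imax = int(np.argmax(counts))
    last_spike_by_cur: dict[float, float] = {}
    if sweep_set is not None and isinstance(sweep_set.protocol, StepProtocol):
        proto = sweep_set.protocol
        for sw in sweep_set.sweeps:
            cur = round(_step_current(sw, sweep_set.dt, proto), 6)
            spikes = [s for s in detect_spikes(sw, sweep_set.dt, dvdt_threshold)
                      if proto.pre_s <= s.t_s < proto.pre_s + proto.duration_s]
            if spikes:
                last_spike_by_cur[cur] = (spikes[-1].t_s - proto.pre_s) / proto.duration_s
    for i, (cur, n) in enumerate(pts):
        if i <= imax:
            continue
        if n >= drop_frac * cmax:
            continue
        if sweep_set is not None:
            last = last_spike_by_cur.get(round(cur, 6))
            if n > 0 and last is not None and last >= cease_frac:
                continue
        return float(cur)
    return None


def classify_dgc_type(
    thresholds: Sequence[float | None],
    cutoff: float | str = "auto",
) -> tuple[list[str], float | None]:
    """Label dentate granule cells Type I / Type II from inactivation thresholds.

    Type I cells inactivate at low currents (finite threshold <= cutoff);
    cells that never inactivate (None) are Type II.  With ``cutoff="auto"``
    the cutoff is placed at the minimum-density valley between the two modes
    of the finite-threshold histogram (Gaussian KDE); a unimodal distribution
    triggers a warning and all finite thresholds are labelled Type I.

    Returns (labels, cutoff_used).
    """
    finite = np.array([t for t in thresholds if t is not None], dtype=float)
    if cutoff == "auto":
        cut = _valley_cutoff(finite)
        if cut is None:
            warnings.warn("inactivation-threshold distribution looks unimodal; "
                          "labelling all finite thresholds Type I")
            cut = float(np.inf)
    else:
        cut = float(cutoff)
    labels = ["II" if t is None else ("I" if t <= cut else "II") for t in thresholds]
    return labels, (None if not np.isfinite(cut) else float(cut))


def _valley_cutoff(x: np.ndarray) -> float | None:
    if x.size < 4 or np.ptp(x) == 0:
        return None
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    d = kde(grid)
    # interior local maxima
    is_max = np.r_[False, (d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:]), False]
    peaks = np.flatnonzero(is_max)
    if peaks.size < 2:
        return None
    top2 = sorted(peaks[np.argsort(d[peaks])[-2:]])
    valley = top2[0] + int(np.argmin(d[top2[0] : top2[1] + 1]))
    return float(grid[valley])


# ---------------------------------------------------------------------------
# soma volume and normalization

def predict_soma_volume(c_m_pf: float, specific_cm_uf_cm2: float = 0.9) -> float:
    """Equivalent-sphere soma volume (µm³) from membrane capacitance.

    Membrane area A = C_m / c_spec with the specific membrane capacitance
    constant across neuron types (0.9 µF/cm²); the soma is modelled as a
    sphere of the same surface area: V = (4/3)π r³, r = sqrt(A / 4π).
    """
    if c_m_pf <= 0:
        raise ValueError("C_m must be positive")
    area_cm2 = c_m_pf * 1e-12 / (specific_cm_uf_cm2 * 1e-6)  # F / (F/cm²)
    area_um2 = area_cm2 * 1e8
    r = math.sqrt(area_um2 / (4 * math.pi))
    return (4.0 / 3.0) * math.pi * r**3


def percent_of_control(values, control_values) -> np.ndarray:
    """Express values as a percentage of the mean of within-mouse controls."""
    control_values = np.asarray(control_values, dtype=float)
    m = control_values.mean()
    if m == 0:
        raise ValueError("control mean is zero")
    return 100.0 * np.asarray(values, dtype=float) / m


# ---------------------------------------------------------------------------
# orchestration

def extract_features(
    step_set: SweepSet,
    ramp_set: SweepSet | None = None,
    passive_set: SweepSet | None = None,
    dvdt_threshold: float = 20.0,
) -> NeuronFeatures:
    """Full morpho-electric parameter vector for one neuron."""
    feats = NeuronFeatures()
    curve = build_if_curve(step_set, dvdt_threshold)
    feats.rheobase_pa = compute_rheobase(curve)
    feats.gain = compute_gain(curve)
    feats.max_rate_hz, feats.accommodation = compute_secondary(
        curve, step_set, dvdt_threshold=dvdt_threshold)
    feats.inactivation_threshold_pa = compute_inactivation_threshold(
        curve, step_set, dvdt_threshold=dvdt_threshold)
    if ramp_set is not None:
        feats.spike_latency_ms = compute_spike_latency(ramp_set, dvdt_threshold)
    if passive_set is not None:
        feats.r_in_mohm, feats.c_m_pf, feats.rmp_mv = compute_passive(
            passive_set, dvdt_threshold)
        feats.soma_volume_um3 = predict_soma_volume(feats.c_m_pf)
    return feats
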