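"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here so each downstream
stage is testable without recordings or sequencing data:

* LFP traces: Gaussian noise plus injected half-sine transients of known
  width and amplitude (amplitude given in multiples of the noise s.d.).
* Current-clamp sweeps: a leaky integrate-and-fire neuron with known R_in,
  C_m, resting/threshold/reset potentials, driven by step families, ramps
  or hyperpolarizing steps; a stereotyped 2-ms action-potential waveform is
  stamped at spike times so waveform metrics are computable while the
  underlying dynamics stay analytic.
* Voltage-clamp traces: Poisson synaptic event trains convolved with a
  double-exponential kernel plus noise.
* snRNA-seq counts: negative-binomial (gamma-Poisson) UMI matrices with
  log-normal library-size variation, planted per-group log-fold-changes,
  and a planted APOE-expression-high subpopulation.

All randomness derives from the config seed via the package seed-splitting
scheme (see :mod:`hippoexc._rng`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import stream
from .ephys import RampProtocol, StepProtocol, Sweep, SweepSet
from .genes import CountMatrix
from .lfp import LfpRecording
from .synaptic import VoltageClampTrace, double_exp_kernel

__all__ = [
    "LfpSimConfig",
    "NeuronModelParams",
    "SynapticSimConfig",
    "SynthCountConfig",
    "PlantedPattern",
    "candidate_group_lfcs",
    "simulate_lfp",
    "simulate_current_clamp",
    "simulate_synaptic_trace",
    "simulate_counts",
    "lif_first_spike_time",
    "lif_spike_count",
]

GENOTYPES = ("E3", "E4", "fE4_Syn1Cre")
AGES = (5, 10, 15, 20)


# ---------------------------------------------------------------------------
# LFP

@dataclass
class LfpSimConfig:
    """Synthetic LFP: Gaussian noise + half-sine transients.

    ``events`` entries are (onset_s, amplitude_sd, width_ms, polarity) with
    amplitude expressed in multiples of the baseline noise s.d.  When
    ``noise_sd`` is 0 (noise-free construction), a reference s.d. of 1 µV
    is used to scale event amplitudes.
    """

    duration_s: float = 60.0
    fs_hz: float = 5000.0
    noise_sd: float = 10.0  # µV
    events: list = field(default_factory=list)  # (onset_s, amp_sd, width_ms, polarity)
    activity_mask: list = field(default_factory=list)  # (start_s, end_s); empty = all active
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValueError("fs_hz and duration_s must be positive")
        for ev in self.events:
            onset, amp, width, pol = ev
            if width <= 0:
                raise ValueError("event widths must be positive")
            if not (0 <= onset and onset + width * 1e-3 <= self.duration_s):
                raise ValueError(f"event at {onset}s outside [0, {self.duration_s}]s")
            if pol not in (+1, -1):
                raise ValueError("polarity must be +1 or -1")


def simulate_lfp(config: LfpSimConfig) -> LfpRecording:
    """Generate a single-channel LFP trace with a ground-truth event table."""
    # reject overlapping events up front, listing the collisions
    spans = sorted((on, on + w * 1e-3, i) for i, (on, _, w, _) in enumerate(config.events))
    collisions = [
        (spans[i][2], spans[i + 1][2])
        for i in range(len(spans) - 1)
        if spans[i + 1][0] < spans[i][1]
    ]
    if collisions:
        raise ValueError(f"overlapping events (index pairs): {collisions}")

    rng = stream(config.seed, "lfp")
    n = int(round(config.duration_s * config.fs_hz))
    x = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)

    ref_sd = config.noise_sd if config.noise_sd > 0 else 1.0
    rows = []
    for onset, amp_sd, width_ms, pol in config.events:
        w = int(round(width_ms * 1e-3 * config.fs_hz))
        i0 = int(round(onset * config.fs_hz))
        t = np.arange(w) / max(w - 1, 1)
        x[i0 : i0 + w] += pol * amp_sd * ref_sd * np.sin(np.pi * t)
        rows.append({"onset_s": onset, "width_ms": width_ms,
                     "amplitude_sd": amp_sd, "polarity": pol})

    if config.activity_mask:
        mask = np.zeros(n, dtype=bool)
        for a, b in config.activity_mask:
            mask[int(a * config.fs_hz) : int(b * config.fs_hz)] = True
    else:
        mask = np.ones(n, dtype=bool)

    truth = pd.DataFrame(rows, columns=["onset_s", "width_ms", "amplitude_sd", "polarity"])
    return LfpRecording(
        samples=x[None, :],
        fs_hz=config.fs_hz,
        channel_meta=[{"region": "CA3", "layer": "pyr"}],
        activity_mask=mask,
        truth_events=truth,
    )


# ---------------------------------------------------------------------------
# leaky integrate-and-fire current clamp

@dataclass
class NeuronModelParams:
    """Ground-truth passive and threshold parameters of the LIF neuron."""

    r_in_mohm: float = 150.0
    c_m_pf: float = 120.0
    v_rest_mv: float = -70.0
    v_thresh_mv: float = -50.0
    v_reset_mv: float = -60.0
    refractory_ms: float = 2.0
    noise_sd_mv: float = 0.0  # additive observation noise on the recorded voltage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_in_mohm <= 0 or self.c_m_pf <= 0:
            raise ValueError("R_in and C_m must be positive")
        if self.v_thresh_mv <= self.v_rest_mv:
            raise ValueError("V_thresh must exceed V_rest")

    @property
    def tau_s(self) -> float:
        return self.r_in_mohm * self.c_m_pf * 1e-6  # MΩ·pF = µs

    @property
    def rheobase_pa(self) -> float:
        """Analytic long-step rheobase (V_thresh - V_rest) / R_in."""
        return (self.v_thresh_mv - self.v_rest_mv) / self.r_in_mohm * 1e3


def _ap_template(dt: float, v_thresh: float, v_reset: float,
                 peak_mv: float = 40.0, dur_ms: float = 2.0) -> np.ndarray:
    """Stereotyped AP waveform: fast rise, repolarization with fAHP undershoot."""
    knots_ms = np.array([0.0, 0.35, 0.9, 1.4, dur_ms])
    knots_v = np.array([v_thresh, peak_mv, v_reset - 4.0, v_reset - 1.5, v_reset])
    t = np.arange(int(round(dur_ms * 1e-3 / dt))) * dt * 1e3
    return np.interp(t, knots_ms, knots_v)


def simulate_current_clamp(
    params: NeuronModelParams,
    protocol: StepProtocol | RampProtocol,
    dt: float = 1e-4,
) -> SweepSet:
    """Integrate the LIF model dV/dt = (-(V - V_rest) + I R_in) / τ.

    Spikes are emitted when V reaches V_thresh; the membrane is then reset
    and held for the refractory period, over which the stereotyped AP
    template is stamped into the recorded trace.  Spike times per sweep are
    attached as ground truth.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    tau = params.tau_s
    rng = stream(params.seed, "current_clamp")
    template = _ap_template(dt, params.v_thresh_mv, params.v_reset_mv)

    if isinstance(protocol, StepProtocol):
        currents = protocol.currents
        n = int(round((protocol.pre_s + protocol.duration_s + protocol.post_s) / dt))
        i0, i1 = int(protocol.pre_s / dt), int((protocol.pre_s + protocol.duration_s) / dt)
        drive = []
        for amp in currents:
            i_t = np.zeros(n)
            i_t[i0:i1] = amp
            drive.append(i_t)
    elif isinstance(protocol, RampProtocol):
        n = int(round((protocol.pre_s + protocol.duration_s + protocol.post_s) / dt))
        i0, i1 = int(protocol.pre_s / dt), int((protocol.pre_s + protocol.duration_s) / dt)
        i_t = np.zeros(n)
        i_t[i0:i1] = protocol.peak_pa * np.arange(i1 - i0) / (i1 - i0)
        drive = [i_t]
    else:
        raise TypeError("protocol must be StepProtocol or RampProtocol")

    decay = np.exp(-dt / tau)
    refr_n = max(1, int(round(params.refractory_ms * 1e-3 / dt)))
    sweeps, truth_spikes = [], []
    for i_t in drive:
        v = np.empty(n)
        v_dyn = params.v_rest_mv
        hold = 0
        stamped_until = -1
        spike_times = []
        for j in range(n):
            if hold > 0:
                hold -= 1
                if j >= stamped_until:  # beyond the stamped AP waveform
                    v[j] = v_dyn
            else:
                v_inf = params.v_rest_mv + i_t[j] * params.r_in_mohm * 1e-3  # pA·MΩ=µV->mV
                v_dyn = v_inf + (v_dyn - v_inf) * decay
                if v_dyn >= params.v_thresh_mv:
                    spike_times.append(j * dt)
                    seg = template[: min(template.size, n - j)]
                    v[j : j + seg.size] = seg
                    stamped_until = j + seg.size
                    v_dyn = params.v_reset_mv
                    hold = max(refr_n, seg.size) - 1
                    continue
                v[j] = v_dyn
        if params.noise_sd_mv > 0:
            v = v + rng.normal(0.0, params.noise_sd_mv, size=n)
        sweeps.append(Sweep(voltage=v, current=i_t))
        truth_spikes.append(spike_times)

    return SweepSet(
        sweeps=sweeps,
        dt=dt,
        protocol=protocol,
        meta={"model": "lif"},
        truth={"params": params, "spike_times": truth_spikes},
    )


def lif_first_spike_time(params: NeuronModelParams, i_pa: float) -> float | None:
    """Closed-form time to first threshold crossing under a constant step."""
    dv = params.v_thresh_mv - params.v_rest_mv
    drive = i_pa * params.r_in_mohm * 1e-3  # mV
    if drive <= dv:
        return None
    return params.tau_s * np.log(drive / (drive - dv))


def lif_spike_count(params: NeuronModelParams, i_pa: float, duration_s: float) -> int:
    """Closed-form LIF spike count for a constant step of given duration."""
    t1 = lif_first_spike_time(params, i_pa)
    if t1 is None or t1 > duration_s:
        return 0
    drive = i_pa * params.r_in_mohm * 1e-3
    dv_reset = params.v_thresh_mv - params.v_reset_mv
    isi = (params.refractory_ms * 1e-3
           + params.tau_s * np.log((drive - (params.v_reset_mv - params.v_rest_mv))
                                   / (drive - (params.v_thresh_mv - params.v_rest_mv))))
    assert dv_reset > 0
    return 1 + int((duration_s - t1) / isi)


# ---------------------------------------------------------------------------
# voltage-clamp synaptic traces

@dataclass
class SynapticSimConfig:
    """Poisson synaptic event train convolved with a double-exponential kernel."""

    rate_hz: float = 2.0
    amp_mean_pa: float = 20.0
    amp_sd_pa: float = 4.0
    rise_ms: float = 1.0
    decay_ms: float = 6.0
    noise_sd_pa: float = 1.0
    duration_s: float = 60.0
    holding_mv: float = -70.0
    dt: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate must be nonnegative")
        if not (self.decay_ms > self.rise_ms > 0):
            raise ValueError("need decay > rise > 0")
        if self.duration_s <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be positive")


def simulate_synaptic_trace(config: SynapticSimConfig) -> VoltageClampTrace:
    """Noise + Poisson-timed kernel events, with ground-truth onset table."""
    rng = stream(config.seed, "synaptic")
    n = int(round(config.duration_s / config.dt))
    x = rng.normal(0.0, config.noise_sd_pa, n) if config.noise_sd_pa > 0 else np.zeros(n)

    kernel = double_exp_kernel(config.rise_ms, config.decay_ms, config.dt)
    polarity = -1 if config.holding_mv < -35 else +1

    onsets, amps = [], []
    if config.rate_hz > 0:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / config.rate_hz)
            if t >= config.duration_s:
                break
            onsets.append(t)
            amps.append(max(rng.normal(config.amp_mean_pa, config.amp_sd_pa), 0.1))

    for t, a in zip(onsets, amps):
        i = int(round(t / config.dt))
        seg = kernel[: n - i]
        x[i : i + seg.size] += polarity * a * seg

    truth = pd.DataFrame({"onset_s": onsets, "amplitude_pa": amps})
    return VoltageClampTrace(current=x, dt=config.dt, holding_mv=config.holding_mv,
                             truth_events=truth)


# ---------------------------------------------------------------------------
# negative-binomial snRNA-seq counts

@dataclass
class PlantedPattern:
    """Planted multiplicative expression shift for one gene.

    ``group_lfc`` maps (genotype, age_months) to a natural-log fold change
    applied to the gene's mean in that group.  ``exclude_apoe_high``
    restricts the shift to non-APOE-high cells; ``apoe_high_only`` restricts
    it to APOE-high cells.  ``apoe_high_extra`` maps groups to an additional
    log fold change applied only to that group's APOE-high cells, on top of
    ``group_lfc`` (e.g. to plant an opposite-direction effect in high cells).
    """

    group_lfc: dict
    exclude_apoe_high: bool = False
    apoe_high_only: bool = False
    apoe_high_extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for (gt, age) in list(self.group_lfc) + list(self.apoe_high_extra):
            if gt not in GENOTYPES or age not in AGES:
                raise ValueError(f"unknown group {(gt, age)}; genotypes {GENOTYPES}, "
                                 f"ages {AGES}")


def candidate_group_lfcs(lfc: float) -> dict:
    """Group pattern realizing all six candidate criteria.

    Shifted in E4 at 5 and 10 months (criteria 1-3), unshifted in
    fE4/Syn1-Cre+ (criterion 4), and shifted equally in E3 and E4 at 20
    months (criterion 5 null, criterion 6 same-direction aging effect).
    """
    return {("E4", 5): lfc, ("E4", 10): lfc, ("E3", 20): lfc, ("E4", 20): lfc}


def standard_planted_patterns(lfc: float = 1.0) -> tuple[dict, list]:
    """Planted genes realizing pass/fail patterns of the six filter criteria.

    Returns ``(planted_genes, true_candidates)``: two full candidates (one
    up-, one down-regulated) plus one gene failing each criterion --
    failing c1 (no 5-month effect), c3 (opposite direction in APOE-high
    cells), c4 (normalization absent: still shifted after neuronal APOE4
    deletion), c5 (effect persists at 20 months), and c6 (no aging effect
    in E3).  All fail patterns are planted effects, so they fail their
    criterion deterministically rather than by absence of significance.
    """
    cand = candidate_group_lfcs
    planted = {
        "cand_up": PlantedPattern(cand(lfc)),
        "cand_down": PlantedPattern(cand(-lfc)),
        "fail_c1_late_onset": PlantedPattern({("E4", 10): lfc}),
        "fail_c3_apoehigh_flip": PlantedPattern(
            cand(lfc), apoe_high_extra={("E4", 10): -3.0 * lfc}),
        "fail_c4_no_normalization": PlantedPattern(
            {**cand(lfc), ("fE4_Syn1Cre", 5): lfc, ("fE4_Syn1Cre", 10): lfc}),
        "fail_c5_persists_aged": PlantedPattern(
            {("E4", 5): lfc, ("E4", 10): lfc, ("E4", 20): lfc}),
        "fail_c6_no_aging": PlantedPattern({("E4", 5): lfc, ("E4", 10): lfc}),
    }
    return planted, ["cand_up", "cand_down"]


@dataclass
class SynthCountConfig:
    """Negative-binomial UMI counts with planted DE patterns.

    Group sizes are cells per (genotype, age) combination; the fE4/Syn1-Cre+
    genotype exists at 5 and 10 months only, matching the study design of
    4 mice per genotype and age.
    """

    n_genes: int = 300
    cells_per_group: dict | int = 200
    base_mean_range: tuple = (0.2, 5.0)  # per-gene baseline mean UMI (log-uniform)
    n_housekeeping: int = 10       # abundant invariant genes dominating the library,
    housekeeping_mean: float = 100.0  # as in real cells; damps compositional shifts
    dispersion: float = 0.3        # asymptotic NB dispersion at high expression
    dispersion_scale: float = 0.4  # mean-dispersion trend: phi_i = dispersion + scale/mean_i
    libsize_sigma: float = 0.15  # log-normal library-size variation
    planted_genes: dict = field(default_factory=dict)  # gene -> PlantedPattern
    planted_base_mean: float = 2.0
    apoe_gene: str = "Apoe"
    apoe_base_mean: float = 20.0  # Apoe is among the most abundant transcripts
    apoe_high_frac: float = 0.05
    apoe_high_lfc: float = 3.5
    mito_fraction_mean: float = 0.001
    n_samples_per_group: int = 4  # mice
    cluster_ids: tuple = ("c1",)
    gene_names: tuple = ()  # optional explicit names for the first genes
    seed: int = 0

    def groups(self) -> list[tuple[str, int]]:
        gs = [("E3", a) for a in AGES if a in (5, 10, 20)]
        gs += [("E4", a) for a in AGES if a in (5, 10, 20)]
        gs += [("fE4_Syn1Cre", a) for a in (5, 10)]
        return gs

    def group_size(self, group) -> int:
        if isinstance(self.cells_per_group, dict):
            return int(self.cells_per_group.get(group, 0))
        return int(self.cells_per_group)


def simulate_counts(config: SynthCountConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Gamma-Poisson UMI counts with planted group shifts and metadata.

    Returns (CountMatrix genes x cells, CellMeta) with metadata columns:
    barcode, genotype, age_months, cluster_id, sample_id, apoe_high_true,
    mito_fraction, n_genes_detected, n_umi.
    """
    rng = stream(config.seed, "counts")
    named = list(config.gene_names)
    if len(named) > config.n_genes:
        raise ValueError("more gene_names than n_genes")
    generic = (f"gene{i:04d}" for i in range(2 * config.n_genes))
    fill = [g for g in generic if g not in named][: config.n_genes - len(named)]
    genes = named + fill
    genes += [f"hk{i:02d}" for i in range(config.n_housekeeping)]
    if config.apoe_gene not in genes:
        genes[-1] = config.apoe_gene
    gidx = {g: i for i, g in enumerate(genes)}

    for g, pat in config.planted_genes.items():
        if g not in gidx:
            raise ValueError(f"planted gene {g!r} not in gene list")
        pat.validate()

    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(genes)))
    base[config.n_genes :] = config.housekeeping_mean
    base[gidx[config.apoe_gene]] = config.apoe_base_mean
    for g in config.planted_genes:
        base[gidx[g]] = config.planted_base_mean

    blocks, meta_rows = [], []
    for gt, age in config.groups():
        n_cells = config.group_size((gt, age))
        if n_cells == 0:
            continue
        apoe_high = rng.random(n_cells) < config.apoe_high_frac
        lib = np.exp(rng.normal(0.0, config.libsize_sigma, n_cells))
        mu = np.repeat(base[:, None], n_cells, axis=1)
        for g, pat in config.planted_genes.items():
            lfc = pat.group_lfc.get((gt, age))
            if lfc is not None:
                cellmask = np.ones(n_cells, dtype=bool)
                if pat.exclude_apoe_high:
                    cellmask &= ~apoe_high
                if pat.apoe_high_only:
                    cellmask &= apoe_high
                mu[gidx[g], cellmask] *= np.exp(lfc)
            extra = pat.apoe_high_extra.get((gt, age))
            if extra is not None:
                mu[gidx[g], apoe_high] *= np.exp(extra)
        mu[gidx[config.apoe_gene], apoe_high] *= np.exp(config.apoe_high_lfc)
        mu = mu * lib[None, :]
        # gene-wise dispersion follows the standard decreasing mean-dispersion
        # trend; abundant genes are less overdispersed
        phi = config.dispersion + config.dispersion_scale / base
        shape = (1.0 / phi)[:, None]
        lam = rng.gamma(shape, scale=mu / shape)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))
        samples = rng.integers(0, config.n_samples_per_group, n_cells)
        clusters = np.asarray(config.cluster_ids)[
            rng.integers(0, len(config.cluster_ids), n_cells)]
        mito = np.clip(rng.normal(config.mito_fraction_mean,
                                  config.mito_fraction_mean / 2, n_cells), 0, 1)
        for j in range(n_cells):
            meta_rows.append({
                "genotype": gt, "age_months": age, "cluster_id": clusters[j],
                "sample_id": f"{gt}_{age}m_m{samples[j]}",
                "apoe_high_true": bool(apoe_high[j]),
                "mito_fraction": float(mito[j]),
            })

    X = sp.hstack(blocks).tocsr()
    meta = pd.DataFrame(meta_rows)
    meta.insert(0, "barcode", [f"cell{i:05d}" for i in range(len(meta))])
    meta["n_umi"] = np.asarray(X.sum(axis=0)).ravel().astype(int)
    meta["n_genes_detected"] = np.asarray((X > 0).sum(axis=0)).ravel().astype(int)
    cm = CountMatrix(X, genes, list(meta["barcode"]))
    return cm, meta
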