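# Methods

This note documents the models and procedures implemented in `hippoexc`,
the defaults and their rationale, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter for reproducibility.

## LFP conditioning and interictal-spike detection

Conditioning follows the standard chain for chronic hippocampal recordings:
polyphase anti-aliased decimation to the analysis rate (5 kHz by default),
a 2nd-order Butterworth high-pass at 0.1 Hz applied forward–backward for
zero phase, Gaussian smoothing with kernel σ = 2 ms, and optional
sample-wise subtraction of a reference channel (e.g. corpus callosum) to
remove movement artifacts. Two numerical points:

- At sub-Hz cutoffs the filter time constant (~10 s) dwarfs the default
  `filtfilt` padding, leaving multi-second edge transients large enough to
  trigger the event detector; the high-pass therefore removes the mean and
  uses Gustafsson initial conditions, which bound the edge error below
  0.1 µV on 60-s traces.
- The 2-ms smoother belongs to conditioning *raw high-rate* recordings. It
  is skipped when data are already at the analysis rate, because convolving
  a 5-ms transient with a 2-ms Gaussian widens it past the 10-ms duration
  gate by construction.

The baseline amplitude scale is the robust s.d., 1.4826 × median absolute
deviation over active samples — deliberately insensitive to the sparse
high-amplitude events being detected, unlike the plain standard deviation
(a 1 % contamination with 10× events inflates the plain s.d. by > 10 % but
moves the MAD estimate by < 2 %).

An interictal spike is a deflection exceeding 5 baseline s.d. (absolute
value by default; one-sided modes are available because depth electrodes may
see either polarity) whose **duration** lies in 10–100 ms. Duration is
measured as the full event extent: the above-threshold run extended outward
to where the deflection returns to the noise floor (1 baseline s.d.). For a
half-sine transient this tracks the injected width (0.92 × width at 8 s.d.),
whereas the literal between-threshold-crossings duration would be only
0.57 × width, misclassifying long events whose crossing happens to fall
inside the gate; the crossing rule remains available as
`duration_mode="crossing"`. Extents separated by less than 5 ms are merged:
in noise, brief dips below threshold fragment a single long event, and
without merging a rejected 150-ms transient can leave an in-gate fragment.
Rates are events per minute of *active* time; an event counts iff its onset
lies inside the externally supplied activity mask (the package does not
infer movement state).

## Leaky integrate-and-fire simulator

Current-clamp sweeps are generated from dV/dt = (−(V−V_rest) + I·R_in)/τ
with τ = R_in·C_m, spike emission at V_thresh, reset to V_reset and an
absolute refractory period (2 ms default). Integration is exponential-Euler
at dt = 0.1 ms, which is exact for piecewise-constant input. A stereotyped
2-ms action-potential waveform (rise to +40 mV in 0.35 ms, repolarization
with a 4-mV fast-afterhyperpolarization undershoot) is stamped into the
recorded trace at spike times: waveform metrics (amplitude, half-width,
rise time, fAHP) are computable while spike *timing* stays analytic, so
rheobase, I–F counts and ramp latency have closed-form oracles. `noise_sd`
is additive observation noise on the recorded voltage; the dynamics remain
deterministic. Protocols mirror the experimental ones: 1-s incremental
steps (50 pA for pyramidal cells, 20 pA for dentate granule cells), a 1-s
0→800 pA ramp, and a hyperpolarizing step (−50 pA) for passive properties.

## Feature extraction

Spikes are detected at the first dV/dt ≥ 20 mV/ms crossing, with a 20-mV
minimum threshold-to-peak excursion (recording noise can exceed the slope
criterion at 0.1-ms sampling but never produces a full-height AP).
Rheobase is the smallest depolarizing step current with ≥ 1 spike. Gain is
the ordinary-least-squares slope of the I–F curve from the first
suprathreshold step through the end of the maximum-rate plateau, excluding
the descending limb caused by depolarization block; fewer than three points
in range yields an explicit missing value, never zero. Passive properties
come from the hyperpolarizing step: RMP = pre-step mean, R_in =
steady-state ΔV/I, τ from a single-exponential fit of the onset transient,
C_m = τ/R_in. The inactivation threshold is the smallest step at which the
count falls below 50 % of the neuron's maximum and spiking ceases before
80 % of the step; granule cells with a finite threshold at or below the
minimum-density valley between the two histogram modes (Gaussian KDE;
manual override available) are Type I, the rest Type II. Soma volume is
predicted from C_m assuming 0.9 µF/cm² specific membrane capacitance and a
spherical soma of equal surface area: C_m = 90 pF ⇒ area 10⁴ µm²,
volume 9.40 × 10⁴ µm³.

A family-level property used in validation: output gain grows with R_in
*at fixed membrane time constant* (the hyperexcitable archetype is a
smaller cell — higher R_in, lower C_m, similar τ — and at fixed τ the I–F
curve compresses along the current axis, steepening the fit). At fixed C_m
the trend reverses, because high-R_in neurons are pushed into the
refractory-saturated region of the I–F curve where the fitted slope
flattens. The same fixed-τ family reproduces the C_m–R_in inverse relation.

## Synaptic event detection and E–I ratio

The classical sliding optimally-scaled template scheme: at every offset a
unit-peak double-exponential kernel (default rise 1 ms, decay 6 ms) is
least-squares fitted (scale + offset) and the detection criterion is the
fitted scale divided by the residual noise s.d.; events are local criterion
maxima above threshold (default 3.5) separated by at least the template
rise time. A low-amplitude detection (< 25 % of a preceding event's
amplitude) inside that event's template support is treated as its decay
tail, not a new event — without this, noise-free events yield a spurious
secondary detection on the tail where both the fitted scale and the
residual are small. Amplitudes are reported as magnitudes; polarity follows
the holding potential (inward at −70 mV, outward at 0 mV).

The excitation–inhibition ratio defaults to the normalized convention
f_E·A_E / (f_E·A_E + f_I·A_I) ∈ [0, 1]; the pure ratio f_E·A_E / (f_I·A_I)
is selectable. The normalized form is an assumption of this package and is
labelled as such in outputs.

## Excitability clustering

Features (default: gain, rheobase, spike latency, C_m, R_in) are z-scored
with the sample (n−1) standard deviation — the denominator is fixed so
exact tests are possible — and clustered with k-means (k = 2, k-means++
initialisation, 10 restarts, best inertia kept; deterministic given the
seed). The hyperexcitable centroid is identified by majority vote over the
expected loading signs (gain +, R_in +, rheobase −, latency −, C_m −); a
tie raises an error demanding a manual label.

Stability: 1,000 iterations each fit k-means on a random 80 % subsample
(the literal reading of the published procedure; a strict 5-fold mode is a
trivial variant of the same machinery), assign all cells to the nearest
iteration centroid, match iteration clusters to the full-data clusters by
minimum-total-distance optimal pairing, and record retention. The
"unstable" flag fires when mean retention drops below 0.97, calibrated on
synthetic data: separated clusters retain essentially every cell, while a
single isotropic Gaussian forced to k = 2 retains only 0.73–0.93 on average
(sample anisotropy anchors the split direction, so null retention sits well
above the 50 % chance level — a threshold near 0.9 would not separate the
regimes).

Membership strength is the residual: distances to the two centroids are
z-scored across cells and the residual is (z(d_normal) − z(d_hyper))/√2,
the signed perpendicular offset from the unity line; positive = more
hyperexcitable. Residuals are compared across genotype × age with a
type-II two-way ANOVA (interaction included) and Tukey HSD over the
genotype×age cells.

## Statistical framework

- **LRT**: Gaussian linear model, full = intercept + age + genotype (main
  effects; categorical), null = intercept only; statistic
  2(ℓ_full − ℓ_null) = n·ln(RSS₀/RSS₁) with df = number of added
  parameters. The p-value uses the exact finite-sample null distribution —
  the statistic is a monotone function of the nested F statistic, so
  P(F(k, n−p) > (e^{LR/n}−1)(n−p)/k) is exact under Gaussian errors. The
  asymptotic χ² reference (size ≈ 0.059 at n = 60, measured at 2×10⁵
  replicates) is available as `reference="chisq"`. The Gaussian family is
  itself an assumption; mouse-level nesting is annotated but not modelled
  (analysis is at the cell level), a documented limitation.
- **FDR**: Benjamini–Hochberg step-up.
- **Post hoc routing**: Shapiro–Wilk at α = 0.05 on each group; both normal
  → unpaired two-tailed t; otherwise Mann–Whitney U (exact for tie-free
  n ≤ 20, tie-corrected normal approximation otherwise). The test identity
  is always reported.
- **CMH**: Mantel–Haenszel χ² without continuity correction (so an exactly
  balanced stratum gives χ² = 0) and the MH common odds ratio;
  zero-margin strata are dropped with a warning.
- **Cluster proportions**: per-cluster unpaired t on per-sample
  proportions, BH across clusters, enrichment flags on raw and adjusted p.

## snRNA-seq candidate-gene filter

QC keeps cells with 200–2,400 detected genes and 500–4,500 UMIs
(inclusive) and mitochondrial fraction strictly below 0.25 %.
Normalization is ln(1 + 10⁴·x/cell_total). Differential expression is a
tie-corrected Wilcoxon rank-sum on normalized values, testing only genes
detected in ≥ 10 % of either population with
|log FC| ≥ 0.05, where log FC = ln(mean(expm1(A))+1) − ln(mean(expm1(B))+1)
(natural log; log2 selectable — cluster markers use log2 with the 0.25
threshold and positive direction). Raw p < 0.05 is the significance gate by
design — the filter's purpose is to prioritize candidates for functional
validation, not to control error rates — and BH-adjusted p is reported
alongside. "Not DE" is the symmetric negation: fails any of the gates or
p ≥ 0.05.

APOE-expression-high cells are those whose normalized APOE level strictly
exceeds the cell-type median + 2 sample s.d., computed within cell type;
types with < 3 cells get no high cells (warning). Note the rule is only
informative when high expressors are a rare tail: a large high fraction
inflates the within-type s.d. and pushes the cut beyond its own
subpopulation.

The six criteria, evaluated per gene within a target cluster, with effect
direction required to agree across all positive criteria:

1. DE, E4-KI vs E3-KI at 5 months;
2. DE, E4-KI vs E3-KI at 10 months, same direction;
3. DE, APOE-high E4-KI vs E3-KI cells at 10 months, same direction;
4. not DE, fE4-KI/Syn1-Cre⁺ vs E3-KI at 5 **and** 10 months (jointly);
5. not DE, E4-KI vs E3-KI at 20 months;
6. DE, 20-month vs 5-month E3-KI, same direction.

The report carries per-criterion flags and the successive pass counts in
filter order (necessarily non-increasing). Cluster alignment across
independently processed datasets uses the Jaccard similarity index over
marker-gene sets with greedy matching: repeatedly take the globally highest
remaining similarity, ties broken by the smaller relative cluster-size
difference, then lexically.

## Synthetic count generator

Counts are gamma-Poisson (negative binomial) with per-gene baseline means
log-uniform on [0.2, 5] UMI, log-normal library-size variation (σ = 0.15),
and a decreasing mean–dispersion trend φᵢ = 0.3 + 0.4/meanᵢ — the standard
empirical structure of UMI data, where abundant genes are less
overdispersed. Ten housekeeping genes at mean 100 dominate the library, as
in real cells; without them, planting a handful of strong effects in a
~150-gene universe shifts library totals by several percent and every
unplanted gene acquires a spurious compositional log FC exceeding the 0.05
gate. The APOE-like gene has baseline mean 20 (it is among the most
abundant hippocampal transcripts) and a planted high subpopulation of 5 %
of cells elevated by 3.5 natural-log units — a rare, strongly separated
tail, which is the regime where the median + 2 s.d. rule is meaningful
(classification precision ≈ 1.0, recall ≈ 0.95 at these settings).

Planted patterns map (genotype, age) groups to multiplicative fold changes;
`standard_planted_patterns` provides two full candidates (up and down) and
one gene failing each criterion. All fail patterns are *planted effects* —
e.g. the criterion-3 failure is an opposite-direction effect confined to
APOE-high cells — so each fails its criterion deterministically rather
than through absence of statistical significance, which at desk scale would
flip by chance at the few-percent level per run.

The generator emulates genotype/age group structure, library-size and
overdispersion noise, a planted APOE-high subpopulation and mitochondrial
fractions. It does not emulate batch effects, ambient RNA, doublets,
cell-type mixtures within a cluster, or gene–gene correlation beyond the
library size; passing tests therefore demonstrate correctness of the
filter logic and its statistical gates, not robustness to those artifacts.

## Validation study conditions

The experiments in `hippoexc.validation` (run by `scripts/acceptance.py`
and the acceptance tests) use these problem sizes, chosen as the package's
reference conditions:

- IIS: 200 traces × 60 s at 5 kHz, one event each of width 5/20/50/150 ms
  at 8 s.d., detection on the traces directly (no smoothing stage — see
  above).
- LIF recovery: 25 noise-free + 25 noisy (0.5 mV) neurons, R_in ∈
  [100, 260] MΩ, C_m ∈ [70, 220] pF, 20-pA steps; gain monotonicity on a
  fixed-τ (20 ms) family of 8 neurons.
- Clustering: 2 × 50 cells, blob separation 10 s.d., 1,000 bootstrap
  iterations; enrichment power with 70/30 vs 30/70 archetype mixing at
  n = 25 per genotype×age cell, 30 replicates.
- Statistics: 1,000 null LRT replicates (2×2 design, n = 15/cell); 2,000
  null Pearson replicates at n = 10.
- Candidate filter: 150 variable genes + housekeeping, 8,000 cells per
  (genotype, age) group, planted |log FC| = 1. Group size matters here:
  the "not DE" criteria use raw p, so a planted candidate can be rejected
  by a chance p < 0.05 in a null contrast unless arms are large enough
  that the |log FC| ≥ 0.05 gate binds first (null log FC s.d. ≈ 0.012 at
  n = 8000 vs ≈ 0.05 at n = 250, where the α ≈ 5 % channel is fully open).

## Known limitations

- The LIF neuron has no adaptation, sag, or dendrites; accommodation on
  its regular trains is 1 by construction, and waveform metrics reflect
  the stamped template, not membrane dynamics.
- Bootstrap retention is an optimistic stability measure for small n
  (subsamples overlap heavily); the one-blob calibration above quantifies
  this.
- The E–I ratio formula is an assumption (see above); both conventions are
  implemented and the output labels the one used.
- The candidate filter inherits the raw-p design choice: its false-positive
  behaviour is governed by the joint significance + effect-size gate, not
  by any FDR guarantee.
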