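# Methods

This note documents the models implemented in `bcmotion`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish.

## Scope and coordinate conventions

All stimuli and receptive fields (RFs) live on one spatial axis.  Retinal
motion analyses of small objects reduce to the motion axis, and the bar
heights used experimentally never enter any computation, so the second
spatial dimension is dropped throughout.  Space bin `i` is centered at
`origin_um + (i + 0.5) * dx`; time bin `j` covers the half-open interval
`[j*dt, (j+1)*dt)`.  Rasterization is by center sampling — a bin is lit when
its center lies under the object, with no anti-aliasing — which keeps
frame-by-frame oracles exact.  RFs carry a lag axis running from 0 (most
recent stimulus frame) to 0.5 s into the past.

## Stimuli

Four classes of space–time contrast fields, all in [−1, +1] with 0 the mean
luminance:

* **Moving bar** — a +1 bar of width *w* whose leading edge is at
  `start + direction * speed * t`.  Default geometry: 20 µm bar, 500 µm/s,
  100 µm travel.
* **1-D binary noise** — 20 adjacent 20 µm bars, each independently black or
  white (±1) redrawn at 20 Hz, seeded.
* **Looming / receding spot** — a bright spot expanding from 10 to 600 µm.
  The stated expansion rate (800 µm/s) is applied to the *diameter* by
  default (each edge moves at half that speed); an `edge` convention is
  selectable, since either reading is defensible.  Receding is the exact
  time reverse of looming.
* **Bar sequences** — 7 bars at 20 µm pitch flashed one per dwell period
  (33.3 ms, giving a 600 µm/s apparent velocity).  The **motion-coherence
  index** of an ordering is
  `k = (Σ|x_j − x_i| − s_max) / (s_min − s_max)`, where the sum runs over
  temporally adjacent bar positions and `s_min`/`s_max` are the extreme
  adjacent-distance sums over all orderings of those positions, found by
  exhaustive search (supported up to 9 bars; 7 bars give 5040 orderings).
  A perfect spatial sweep has k = 1, the worst ordering k = 0.

## Synthetic receptive fields

The generator produces ground-truth center–surround space-time RFs

    W(x, τ) = pol · A · [ G(x; c, σ_c) · k_c(τ) − a_s · G(x; c, σ_s) · k_s(τ) ]

with Gaussian spatial profiles, a biphasic center kernel (difference of two
alpha functions, peak normalized), and a delayed monophasic surround lobe
(a Gaussian bump in time of s.d. `surround_tau_s`, default 40 ms, peaking
`surround_latency_s` after the center peak).  The RF is space–time separable
iff the surround is absent; a delayed surround makes it rank 2 and confers
radial direction selectivity under the convolution model.

**Parameters are defined on the measurement scale.**  Because center and
surround overlap in space and time, naive kernel amplitudes would not
reproduce the values that the feature extractor reads off the summed RF.
`make_rf` therefore solves a small fixed point — a monotone bisection on the
internal surround amplitude nested with updates of the surround peak time
and internal center width — until `extract_features` (default regions)
reports exactly the planted surround strength, latency, and center FWHM.
The round trip is exact to ~1% over the documented envelope (strength
0.1–1.2, latency 0.02–0.08 s at the default 25 ms lag resolution); very
strong surrounds combined with very short latencies (< 20 ms) are outside
the feasible envelope because the surround then swamps the center peak.

Default shape parameters: center σ = 12 µm (FWHM 28 µm, a small bipolar-cell
center), surround σ = 5 × center σ.  The wide surround matters: with
narrower surrounds (2–3 × center), matching the *measured* flank-band
surround strength forces internal surround amplitudes several times the
center's, i.e. RFs whose spatial integral is surround-dominated.  Such RFs
produce large stimulus-offset rebounds that saturate every preference index;
they do not resemble measured bipolar-cell RFs.

**Noise model** — additive Gaussian on the trace (fluorescence indicators
are analog; there is no spike-count process to motivate Poisson noise), with
optional rectification at zero.  All randomness flows through explicit
seeds; there is no global random state.

**Populations** — type-level parameters are spaced evenly across their
ranges (well-separated types), each ROI adds ~5% multiplicative jitter, a
center-position offset (±10 µm), and an IPL depth drawn from a narrow
type-specific band (s.d. 0.02).  Ground-truth labels are returned so every
downstream stage can be scored against the plant.

**What the generator does not emulate:** imaging point-spread functions,
photobleaching, movie-level pixel noise, ROI segmentation, or the empirical
distribution of surround strengths across real types (exposed as ranges
instead).  Passing recovery tests therefore demonstrate correctness of the
estimators under the stated statistical assumptions, not performance on raw
imaging data.

## Trace processing and d′

Traces are high-pass filtered (Butterworth, 0.2 Hz, order 5, applied
zero-phase) and z-normalized.  Per stimulus condition, trials are smoothed
by exact Gaussian-process regression with an RBF kernel (variance 1.1,
lengthscale 0.05 s on the trial clock), yielding a posterior mean and
pointwise s.d. on a 50 Hz grid, refined to 125 Hz inside a warp window
covering the moving-bar epoch.  Data sizes here are small, so the exact GP
is used rather than a sparse approximation; the observation-noise variance
is a parameter (default 0.1 in z-units).  A ROI is flagged non-responsive
(discarded) when the s.d. over time of its posterior mean is below 0.1 in
every condition.

The motion-preference statistic between two conditions is

    d′ = (μ₁ − μ₂) / sqrt(0.5 (σ₁² + σ₂²))

where μ is the (signed) peak of the posterior mean inside the analysis
window and σ the posterior s.d. of the mean at that peak (the alternative —
predictive s.d. of a new observation — is available through the noise
parameter).  d′ is antisymmetric and invariant to common rescaling.

## RF estimation and features

`estimate_rf` solves a penalized least-squares problem on the stimulus
history matrix: a second-difference roughness penalty over space and lag
(plus a small ridge folded into the penalty so the high-penalty limit is
zero and rank-deficient designs stay well posed), with the penalty weight
chosen by generalized cross-validation over a log-spaced grid by default.
This is a regularized spike-triggered average; no basis dimension needs to
be chosen and recovery tests define adequacy (noise-free recovery r > 0.95,
median r ≥ 0.8 at SNR 3).

Features are computed on polarity-corrected kernels:

* the **center temporal kernel** is the spatial average over the center
  region (default: within one FWHM of a Gaussian fit to the spatial profile
  during the center response, capped at 30% of the spatial extent so flanks
  always remain);
* the **surround temporal kernel** averages two flank bands between 1.5 and
  2.5 FWHM from the center (a finite band, not the whole remaining grid —
  the far grid would dilute the surround arbitrarily with extent);
* **latency** = surround-peak time − center-peak time (parabolic
  interpolation for sub-bin precision); **surround strength** = ratio of
  those peak magnitudes; **biphasic index** = |max/min| of the center
  kernel; **FWHM** from the Gaussian fit.

All four are ratios, times or widths and hence invariant to RF scaling.

`rf_trajectory` finds the space–time peak within an early and a late lag
window and reports the displacement `x₂ − x₁` and slope
`(x₂ − x₁)/(t₂ − t₁)` — the preferred motion distance and velocity of
motion-tuned RFs.

## Clustering

RFs within a field are pre-clustered hierarchically (correlation distance,
average linkage, fixed distance criterion 0.05 — the criterion is stated,
the metric/linkage are package choices and configurable); each pre-cluster's
mean RF defines a common center (its extremum; minimum for Off), and members
are shifted onto it.  One spatial half of each aligned RF (center to edge,
cropped to the width available for all ROIs) is flattened and reduced by
sparse PCA (4 components); the component weights, optionally with IPL depth,
are jointly standardized so no feature dominates, and Gaussian mixtures are
fitted for each candidate cluster count (default 3–19, full covariance,
k-means++ with restarts, seeded).  The count minimizing BIC is selected.

Sample-size note: a full-covariance mixture in 5 features has ~21 free
parameters per component, so reliable BIC selection of k = 4 needs on the
order of 80+ samples; recovery studies use 20 ROIs per planted type.

Cluster stratification profiles are Gaussian KDEs of member IPL depths on a
common [0, 1] grid; Pearson correlation against reference (anatomical)
profiles gives the match matrix, with a 0.7 threshold for assignment by
default.

## Linear motion model

Responses are predicted by per-location temporal convolution summed over
space, with no output nonlinearity (rectification exists only in the SAC
input pathway).  The stimulus is zero before onset and after offset, and the
prediction runs one lag span past the stimulus end so responses still
developing at offset (a bar arriving at the center) are not truncated.

The preference index between two stimuli is
`(peak₁ − peak₂)/(peak₁ + peak₂)`, peaks taken as the maximum of the
polarity-corrected trace and floored at zero (a fully suppressed modeled
response counts as no response, keeping the index in [−1, 1]).

Velocity-tuning stimulus pairs are anchored to the RF center: 'originates'
starts with the bar body centered on the RF center and moves outward over
100 µm (the experimental travel distance); 'terminates' is its exact
space–time mirror; pass-through pairs span surround–center–surround; looming
pairs expand about the center.  The exact anchoring (bar body centered at
onset) is a package choice — it makes the originate/terminate pair an exact
mirror over a common footprint, so a separable RF scores ≈ 0.

`scale_surround` multiplies all values of polarity opposite to the center
(negative for On, positive for Off) by the given factor, following the
polarity-based selection used for the published manipulation; center-polarity
values are untouched.  `decompose_center_surround` instead partitions
*space* (center region vs. its complement) so the two traces sum exactly to
the full prediction by linearity.

## SAC dendrite model

A ball-and-stick model: an iso-potential spherical soma (7 µm) coupled to a
150 µm dendrite (first 10 µm at 0.4 µm diameter, rest 0.2 µm), discretized
into 1 µm compartments (the count is a package choice; halving dt and the
compartment length changes peak responses by < 1%).  Passive properties
R_i = 150 Ω·cm, R_m = 21 700 Ω·cm², C_m = 1 µF/cm², E_L = −54.4 mV.  The
distal third of the dendrite carries a voltage-gated Ca²⁺ conductance
ḡ = 0.013 mS/mm², I_Ca = ḡ m² (V − E_Ca) with E_Ca = 120 mV.

**Gating kinetics are package defaults, not measurements**: m∞ is a
Boltzmann with half-activation −15 mV and slope 10 mV, first-order gating
with τ = 1 ms.  These values were chosen so the distal compartment responds
*gradedly* through the calibration target: with steeper/lower-threshold
gating (e.g. half −30 mV, slope 6 mV) the distal compartment is regenerative
— its peak jumps all-or-none from about −41 mV to about +94 mV — and no
input scale can place the peak at −35 mV.  No reported quantity depends on
the exact gating numbers; they are config entries.

Ca²⁺ per compartment follows d[Ca]/dt = −γ_Ca I_Ca − ([Ca] − Ca₀)/τ_Ca with
γ_Ca = 20 M/nC applied directly to the compartment membrane current (the
per-volume normalization is left implicit in that unit), Ca₀ = 50 nM,
τ_Ca = 5 ms, clipped at zero.  Integration: backward Euler on the cable
voltage (tridiagonal solve per 0.1 ms step, the Ca conductance entering the
implicit step at the current gating value), exponential updates for gating
and Ca²⁺.  A voltage-clamp mode substitutes a prescribed V(t), used to
verify the Ca²⁺ relaxation in isolation.  Correctness anchors: the passive
steady-state profile matches the closed-form sealed-end cable solution
(cosh attenuation) within 1%; the iso-potential step response recovers
τ_m = R_m C_m = 21.7 ms within 2%; clamped Ca²⁺ decay recovers τ_Ca
within 5%.

**Synaptic input.**  Synapses are placed from a per-10 µm density profile
and assigned BC types by a dendritic-interval layout (default: one
'proximal' type below 50 µm, one 'distal' type beyond).  The default bundle
ships a *distally declining* density (4,4,3,3,3,2,2,2,1,…,1; 30 synapses),
consistent with connectomic input maps in which glutamatergic drive to SAC
dendrites is strongest proximally.  This profile is load-bearing: with a
uniform profile the tip voltage is dominated by tip-local inputs and the
surround manipulation reverses sign, whereas the declining profile makes the
readout reflect the proximally-weighted aggregate input RF, reproducing the
surround-dominated direction selectivity (see below).  Each synapse injects
`scale · n_syn · max(0, baseline + prediction)` as current — spontaneous
baseline release (default 10% of the strongest single-synapse modulation)
that center/surround stimulation pushes up/down, rectified at zero.  Whether
the drive should be a current or a conductance is underdetermined; it is
implemented as a current, with units absorbed by the calibration.  The
input scale is calibrated per configuration (bracket + bisection, monotone
in the scale) so the slowest centrifugal sweep peaks at −35 ± 0.5 mV in the
most distal compartment.  The soma is a sealed end (no load from unmodelled
dendrites).

**Wiring manipulations** relabel identities with positions and counts fixed:
`all_proximal` / `all_distal` assign one type everywhere; `swapped`
exchanges the proximal and distal labels (an involution).  **Path variants**:
`single_dendrite` (bar sweeps 0–150 µm), `cell_diameter` (extends 150 µm to
the soma side), `cell_surround` (extends 100 µm past the tip).  Centrifugal
(CF) and centripetal (CP) stimuli are exact mirrors over the path.

**DSI** is computed per distal-third compartment from the peak
depolarization above the pre-stimulus rest (a time-integral variant is
selectable), DSI = (CF − CP)/(CF + CP), and reported as the mean over those
compartments.  A 200 ms settle period with baseline drive precedes each
stimulus so "rest" is the baseline-driven steady state.

**Default BC types** (On model): a sustained proximal type (center τ 70 ms,
surround strength 0.5, latency 60 ms) and a more transient distal type
(center τ 40 ms, surround strength 0.2, latency 30 ms); the Off model is
analogous with inverted polarity.  Cluster-derived RFs are conditioned for
model use by SVD denoising (top 3 components), 20× spatial and 1.6× temporal
linear interpolation of the singular vectors, reconstruction (conserving the
kernel integral), and mirroring of the wider half into a fully symmetric
spatial RF.

With these defaults the On model prefers CF motion at 500–1000 µm/s
(DSI ≈ +0.4/+0.6), scaling the surrounds to 1% substantially weakens the
DSI, the wiring manipulations order as original > either single-type
wiring > 0 > swapped, and the `cell_diameter` path at high velocity
yields negative DSI (proximal inputs are stimulated symmetrically while
distal inputs favor CP).

## Reported problem sizes

Recovery and sign-level studies run at desk scale: populations of 2–4 types
× 20 ROIs for clustering (20 seeded runs), 8 ROIs at SNR 3 for estimation
recovery, 200 random sequences for the coherence scan, and two velocities
per SAC configuration.  These sizes were chosen as the smallest at which the
statistical claims are stable across seeds.

## Known limitations

* One spatial dimension; no 2-D RFs or chromatic stimuli.
* The linear model fits no output nonlinearity; saturation and adaptation
  are absent.
* The SAC model omits inhibitory inputs, gap junctions, and all intrinsic
  channels beyond the single Ca²⁺ conductance; it is one dendrite, not the
  radial cell.
* The generator's type parameters are stylized; absolute DSI magnitudes
  depend on the assumed density profile and baseline fraction, and only
  sign-level and ordering claims are treated as conclusions.
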