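# bcmotion

Models of motion sensing in retinal bipolar cells (BCs) and its inheritance
by starburst amacrine cells (SACs).

Bipolar cells relay photoreceptor signals into the inner retina through an
antagonistic center–surround receptive field (RF): an excitatory Gaussian
center and a wider, delayed, opposite-polarity surround.  Because the
surround acts late, a small object moving *out of* the RF center drives the
center before the delayed inhibition arrives, while an object moving *into*
the center drags its own surround signal along with it — a Barlow–Levick
arrangement that makes many BCs *radially direction selective* (rDS):
stronger glutamate release for motion originating in the center than for
motion arriving from the surround.  This package implements, end to end, the
computational pipeline for studying that phenomenon and its consequences for
the direction selectivity of SAC dendrites, with a synthetic-data generator
standing in for two-photon glutamate imaging.

## What is inside

| module | contents |
| --- | --- |
| `bcmotion.stimuli` | 1-D space–time contrast fields: moving bar, binary 20 Hz noise, looming/receding spot, bar sequences; the motion-coherence index *k* = (Σ\|x_j − x_i\| − s_max)/(s_min − s_max) with exhaustive normalization |
| `bcmotion.synth` | ground-truth center–surround space-time RFs W(x,τ) = G_c k_c − a_s G_s k_s, labeled populations, noisy response traces |
| `bcmotion.responses` | Butterworth high-pass + z-normalization; Gaussian-process trace smoothing (RBF kernel, variance 1.1, lengthscale 0.05 s, 50 Hz grid with a 125 Hz warp window); the discriminability statistic d′ = (μ₁ − μ₂)/√(0.5(σ₁² + σ₂²)) |
| `bcmotion.rf` | penalized least-squares spike-triggered averaging over a 0.5 s lag span; RF features (center–surround latency, surround strength, biphasic index, center FWHM); RF-trajectory displacement and velocity |
| `bcmotion.cluster` | center alignment by hierarchical pre-clustering (distance criterion 0.05), half-RF cropping, sparse PCA (4 components) + Gaussian-mixture clustering with BIC model selection, IPL-stratification correlation |
| `bcmotion.motion` | linear convolution response prediction r(t) = Σ_x Σ_τ W[x,τ] S[x,t−τ]; preference index (peak₁ − peak₂)/(peak₁ + peak₂); velocity tuning; surround scaling; center/surround decomposition; coherence scans |
| `bcmotion.sac` | biophysical ball-and-stick SAC dendrite (Table-style constants: R_i = 150 Ω·cm, R_m = 21 700 Ω·cm², C_m = 1 µF/cm², E_L = −54.4 mV, E_Ca = 120 mV, ḡ_Ca = 0.013 mS/mm², τ_Ca = 5 ms, γ_Ca = 20 M/nC, dt = 0.1 ms), synapse maps and wiring manipulations, RF-driven rectified current injection, DSI = (CF − CP)/(CF + CP) |
| `bcmotion.io`, `bcmotion.pipeline` | NPZ/HDF5 array schema with validation, CSV tables, and a seeded end-to-end pipeline with a checksummed manifest |

## Worked example

```python
from bcmotion import motion, rf, synth

params = synth.SyntheticRFParams(surround_strength=0.5, surround_latency_s=0.05)
cell = synth.make_rf(params)

feats = rf.extract_features(cell)
print(feats.surround_strength, feats.latency_s)   # 0.500  0.0501

tuning = motion.rds_tuning(cell, [100, 250, 500, 1000, 2000])
print(tuning.preference)
# [0.035 0.172 0.668 0.990 0.727]
```

The feature extractor reads back the planted surround strength (0.5) and
center–surround latency (50 ms) from the summed RF.  The tuning curve is the
preference index for a bar moving out of the center versus into it: positive
at every velocity (the cell prefers originating motion), strongest near
1000 µm/s, and it vanishes for a surround-free RF (≈ 0.01) — the surround is
what carries the radial direction selectivity.

For the downstream circuit, `examples/06_sac_dsi.py` drives the SAC dendrite
model with these BC inputs; with the default wiring it prints DSI ≈ +0.37 at
500 µm/s and ≈ +0.57 at 1000 µm/s (preference for soma→tip motion), dropping
to ≈ +0.18 when the BC surrounds are scaled to 1%.

Each script in `examples/` is a short, self-contained demonstration of one
capability (stimuli and coherence, RF synthesis, RF estimation, clustering,
motion preference, SAC direction selectivity).

## Documentation

`docs/methods.md` describes the model assumptions, parameter choices, the
synthetic-data generator's scope, and numerical details.
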