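"""Predict motion responses by convolution and score radial preferences.

An RF with a delayed antagonistic surround responds more strongly to a bar
moving out of its center ('originates') than to one arriving from the
surround ('terminates'); a surround-free RF does not.  The same model links
response amplitude to the motion coherence of random bar sequences.
"""

import numpy as np
from scipy.stats import spearmanr

from bcmotion import motion as mo, synth

rds = synth.make_rf(synth.SyntheticRFParams())           # delayed surround
flat = synth.make_rf(synth.SyntheticRFParams(surround_strength=0.0))

velocities = [100, 250, 500, 1000, 2000]
tun = mo.rds_tuning(rds, velocities)
print("originate-vs-terminate preference (delayed surround RF):")
for v, p in zip(tun.velocities_um_s, tun.preference):
    print(f"  {v:6.0f} um/s : {p:+.3f}")
flat_tun = mo.rds_tuning(flat, [500])
print(f"surround-free RF at 500 um/s: {flat_tun.preference[0]:+.3f} "
      "(no radial preference)")

loom = mo.rds_tuning(rds, [800], pairing="loom_vs_recede")
print(f"loom-vs-recede preference at 800 um/s: {loom.preference[0]:+.3f}")

scan = mo.coherence_scan(rds, n_orders=200, seed=0)
rand = scan[~scan.ordered]
rho = spearmanr(rand.k, rand.peak).statistic
print(f"Spearman rho between coherence k and predicted amplitude over "
      f"200 random 7-bar sequences: {rho:+.3f}")
print(f"ordered-sequence amplitude {scan[scan.ordered].peak.iloc[0]:.2f} vs "
      f"random median {rand.peak.median():.2f}")
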