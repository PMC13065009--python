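"""Task-relevance comparison of tracked features vs. band log-power.

Simulates eight subjects whose 10 Hz rhythm amplitude follows a block
task (10 s on/off), tracks each with the EKF, and contrasts four
features — tracked frequency, tracked magnitude, covariance Frobenius
norm, band log-power — by each subject's maximum absolute correlation
with the task labels (Wilcoxon signed-rank, BH-corrected).
"""

import numpy as np

from oscitrack import (
    BandpassSpec, EKFHyperParams, TaskReference, bandpass,
    feature_comparison, log_power_feature, track_signal,
)

fs, dur = 120.0, 240.0
n = int(dur * fs)
t = np.arange(n) / fs
blocks = (np.floor(t / 10) % 2).astype(float)
spec = BandpassSpec(8, 12, order=5, fs=fs)
hp = EKFHyperParams(q_osc=1e-2, q_freq=1e-5, q_damp=1e-6, r_meas=1e-1,
                    f_init=10.0, rho_init=0.97, p0_scale=1.0)

features = {k: [] for k in ("ekf_freq", "ekf_mag", "cov_frob", "log_power")}
refs = []
for s in range(8):
    rng = np.random.default_rng(s)
    y = ((1.0 + 0.8 * blocks) * np.cos(2 * np.pi * 10 * t + rng.uniform(0, 6))
         + 0.8 * rng.standard_normal(n))
    yf = bandpass(y, spec)
    res = track_signal(yf, fs, hp)
    features["ekf_freq"].append(res.freq[None, :])
    features["ekf_mag"].append(res.mag[None, :])
    features["cov_frob"].append(res.cov_frob[None, :])
    features["log_power"].append(log_power_feature(yf)[None, :])
    refs.append(TaskReference(blocks, "binary"))

per_subject, contrasts = feature_comparison(features, refs)
print("median max-|r| per feature:")
print(per_subject.median().round(3).to_string())
print("\npairwise Wilcoxon contrasts (BH-corrected):")
print(contrasts[["feature_a", "feature_b", "median_diff", "p_adj",
                 "significant"]].round(4).to_string(index=False))
print("\nHigher max-|r| means the feature follows the task blocks more "
      "closely; the contrasts test feature pairs across subjects.")
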