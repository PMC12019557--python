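"""Compute HBI and RV nuisance regressors from simulated physiology.

A 1000 Hz pulse wave and respiration trace are conditioned (40 Hz,
zero-phase low-pass), beats are detected, and the two regressors are
derived: sliding-window median heartbeat interval convolved with the
negated cardiac response function, and sliding-window respiratory
variance convolved with the respiratory response function.
"""

import numpy as np

import affectconsensus as ac

cardiac_raw, beat_times = ac.simulate_physio_trace(
    "cardiac", duration_s=120, period_s=0.9, jitter_sd_s=0.05, noise_sd=0.05, seed=2
)
resp_raw, _ = ac.simulate_physio_trace(
    "respiration", duration_s=120, period_s=4.0, jitter_sd_s=0.3, noise_sd=0.05, seed=3
)

cardiac = ac.condition_trace(cardiac_raw)
resp = ac.condition_trace(resp_raw)
peaks = ac.detect_peaks(cardiac)
matched = sum(float(np.abs(peaks.times - t).min()) <= 0.05 for t in beat_times)

hbi = ac.compute_hbi(peaks, duration_s=120)
rv = ac.compute_rv(resp)

print(f"beats detected: {peaks.times.size} "
      f"({100 * matched / beat_times.size:.1f}% of true beats within 50 ms)")
print(f"mean inter-beat interval: {np.mean(peaks.intervals):.3f} s")
print(f"HBI regressor: {hbi.values.size} samples at {hbi.output_rate} Hz, "
      f"SD {hbi.values.std():.3f}")
print(f"RV regressor:  {rv.values.size} samples at {rv.output_rate} Hz, "
      f"SD {rv.values.std():.3f}")

# Both regressors are on the 1 Hz annotation grid, ready to be resampled to
# the scanner TR and entered as nuisance covariates in an fMRI model.
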