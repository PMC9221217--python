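"""Estimate the Hurst exponent of simulated BOLD-like series with R/S.

Generates fractional Gaussian noise at several known persistence levels and
recovers each with the rescaled-range estimator, showing the estimator's
small positive bias near h = 0.5 and its recovery of persistent dynamics.
"""

import numpy as np

from atlasfusion import rs_hurst, rs_hurst_batch, simulate_fgn

print("single series, N = 1024:")
for h_true in (0.5, 0.7, 0.9):
    series = simulate_fgn(h_true, 1024, seed=42)
    est = rs_hurst(series)
    print(
        f"  true h = {h_true:.1f} -> estimate {est.h:.3f} "
        f"(log-log fit R^2 = {est.fit_r2:.3f}, windows {est.window_sizes.tolist()})"
    )

print("\nMonte-Carlo means, 50 replicates each, N = 1024:")
for h_true in (0.5, 0.6, 0.7, 0.8):
    series = np.vstack([simulate_fgn(h_true, 1024, seed=s) for s in range(50)])
    h_est, _, _ = rs_hurst_batch(series)
    print(f"  true h = {h_true:.1f} -> mean estimate {h_est.mean():.3f} (sd {h_est.std():.3f})")

print(
    "\nA voxel with h > 0.5 has a persistent (positively autocorrelated) BOLD"
    "\nseries; the R/S estimator recovers the ordering with a known upward"
    "\nbias at h = 0.5 that shrinks with series length."
)
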