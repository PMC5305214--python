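"""Disassembly-rate inference from censored complex lifetimes.

Feeds the summary counts of a 22-minute helicase tracking experiment
(296 complexes observed to disassemble with mean lifetime 10.4 min,
31 persisting to the end of the window, shortest observable lifetime
4 min) into the censored-exponential maximum-likelihood estimator, and
converts the rate into conflicts per 40-minute replication cycle.
"""

import numpy as np

from replicount import LifetimeDataset, estimate_rate, rate_error

data = LifetimeDataset.from_counts(
    n_observed=296, n_censored=31, tau_bar=10.4, window_T=22.0, tau_min=4.0
)
est = estimate_rate(data, cycle_length=40.0)
est.k_error = rate_error(est, data, n_sim=50_000, seed=0, frame_interval=2.0)

print(f"disassembly rate k = {est.k_hat:.4f} /min  (bootstrap std {est.k_error:.4f})")
print(f"mean complex lifetime 1/k = {est.tau_calc:.1f} min")
print(f"expected disassembly events per 40-min replication cycle: {est.n_conflicts:.1f}")
print(f"fraction persisting the full window (model): "
      f"{np.exp(-est.k_hat * (data.window_T - data.tau_min)):.3f}")

survival_10 = np.exp(-est.k_hat * (10.0 - data.tau_min))
print(f"model survival at 10 min: {survival_10:.2f} -- the probability a "
      "complex observable at 4 min is still intact at 10 min")
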