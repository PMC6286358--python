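"""Fit the saturating-exponential maturation model and test it against a
temporal-order null.

Subject values are binned by integer years, bin means are fit with
f(t) = f0 + (f_inf - f0)(1 - exp(-t/T)) weighted by 1/SEM^2, and the fit is
compared with 1000 surrogates in which the time labels were shuffled.
"""

import numpy as np

import wordgraphs as wg

# 200 simulated subjects on a known curve: f0=4, f_inf=18, T=6 years
true = dict(f0=4.0, f_inf=18.0, T=6.0)
series = wg.generate_binned_series(**true, bins=20, per_bin=10,
                                   noise_sd=0.2, seed=1)
fit = wg.fit_exponential(series, "N")
print(f"true      f0={true['f0']:.2f}  f_inf={true['f_inf']:.2f}  "
      f"T={true['T']:.2f}")
print(f"recovered f0={fit.f0:.2f}  f_inf={fit.f_inf:.2f}  T={fit.T:.2f}  "
      f"(R^2={fit.r_squared:.4f}, RMSE={fit.rmse:.3f}, "
      f"|f_inf-f0|={fit.delta:.2f})")

# rebuild subject-level data for the permutation null
rng = np.random.default_rng(2)
times = np.repeat(np.arange(20.0), 10)
values = wg.model_f(times, **true) + rng.normal(0, 0.2, times.size)
null = wg.permute_time(values, times, "N", n_perm=1000, seed=3)
print(f"observed rho = {null.observed_rho:.3f}, "
      f"permutation p = {null.p_rho:.4f}")
print(f"observed R^2 = {null.observed_r2:.3f} vs null 97.5th pct = "
      f"{np.percentile(null.null_r2, 97.5):.3f}")
print()
print("Shuffling the time axis destroys the fit: the observed statistics "
      "sit far outside their surrogate distributions, so the maturation "
      "trend is temporal structure, not noise.")
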