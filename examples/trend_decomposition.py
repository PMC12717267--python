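"""Structural state-space decomposition of a seasonal weekly series.

Simulates a series with seasonality and a slow trend, fits local-linear-trend
models with and without the trigonometric seasonal block, and compares them
by leave-future-out expected log predictive density (ELPD).
"""

import numpy as np
import pandas as pd

from aerodiv.trends import SSMSpec, compare_models, fit_ssm, seasonal_regressors, ssm_diagnostics

rng = np.random.default_rng(0)
n = 156  # three years of weeks
t = np.arange(n)
y = pd.Series(
    1.0 * np.sin(2 * np.pi * t / 52.0) + 0.01 * t + rng.normal(0, 0.4, n)
)
X = seasonal_regressors(t, n_harmonics=3, period=52.0)

seasonal = SSMSpec(trend="llt", regressors=X, n_iter=600, burn=200, seed=0)
bare = SSMSpec(trend="llt", n_iter=600, burn=200, seed=0)

fit = fit_ssm(y, seasonal)
lo, hi = fit.slope_interval()
print(f"posterior mean slope interval: [{lo:.4f}, {hi:.4f}] (truth 0.01/week)")

diag = ssm_diagnostics(fit)
print(f"residual checks: F variance ratio {diag['f_variance_ratio']:.2f}, "
      f"KS d {diag['ks_d']:.3f}, {diag['n_significant_acf']} significant ACF lags "
      f"(expect ~{diag['acf_expected_false_positives']:.1f} false positives)")

ranked = compare_models(y, [seasonal, bare], refit_stride=10, n_draws_eval=10)
print(ranked[["spec_index", "elpd", "n_parameters", "rank"]].to_string(index=False))
# the seasonal model (spec_index 0) should rank first: its one-step-ahead
# predictions on held-out future weeks are sharper
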