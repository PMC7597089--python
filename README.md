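# convodiff

Statistical inference for **convolutionally observed diffusion processes** —
diffusions seen only through a backward moving average of their path.

Some high-frequency biomedical signals (EEG is the canonical case) behave in
a way ordinary microstructure-noise models cannot explain: their realised
volatility *decreases* as the sampling frequency increases, i.e. the record
is *smoother* than a diffusion, not rougher.  A latent diffusion

    dX_t = b(X_t, β) dt + a(X_t, α) dw_t

observed through a rectangular kernel of width ρ sampling steps,

    X̄_{ih} = (ρh)⁻¹ ∫_{ih−ρh}^{ih} X_s ds       (ρ = 0: direct observation),

reproduces exactly this signature.  The package provides, per axis:

* **ρ̂** — the smoothing-parameter estimator.  The full quadratic variation
  `(nh)⁻¹ Σ (ΔX̄_k)²` and the reduced one (two-step increments at even
  indices) converge to known multiples of the same invariant-measure
  integral; their ratio R(ρ) is strictly decreasing and is inverted
  analytically (with clamping at the parameter-box boundary).
* **T** — a test of H0: ρ = 0 against H1: ρ > 0,
  `T = sqrt(3 / (2 Σ(ΔX̄_k)⁴)) · (Σ(ΔX̄_k)² − Σ_{even}(two-step)²)`,
  asymptotically N(0,1) under H0 and diverging to −∞ under smoothing;
  rejection region `T < Φ⁻¹(α_sig)`.
* **α̂, β̂** — least-square quasi-likelihood fits corrected for the
  convolution: the diffusion contrast matches `(ΔX̄)(ΔX̄)ᵀ/h` to
  `G(x, α|ρ) = a aᵀ ∘ fG(ρ_i, ρ_j)`, where fG is the closed-form deflation
  factor of the increment covariance; the drift contrast lags the drift one
  full window behind the increment.  A naive local-Gaussian-approximation
  (LGA) baseline, which ignores the convolution and is badly biased under
  smoothing, is included for comparison.
* an **Euler–Maruyama + convolution-by-summation simulator** and a
  deterministic replication engine for the reference Monte-Carlo studies.

Everything is exposed both as scikit-learn-style estimators
(`SmoothingEstimator`, `SmoothnessTest`, `ConvolutionLeastSquares`,
`LGAEstimator` — `fit`, fitted attributes with trailing underscores,
`get_params`/`set_params`) and as plain functions (`estimate_rho`,
`smoothness_test`, `fit`, `lga_fit`), plus a `convodiff` command-line tool.

## Worked example

Simulate the 1-D Ornstein–Uhlenbeck design `dX = (−2X + 1)dt + 3 dw` at
`n = 10⁵`, `h = 10^{−10/3}`, observed through a window of ρ = 1 sampling
step, then recover everything from the data alone:

```python
import numpy as np
from convodiff import (SimulationConfig, ou_preset_1d, simulate_convobs,
                       SmoothingEstimator, SmoothnessTest,
                       ConvolutionLeastSquares, LGAEstimator)

h = 10.0 ** (-10.0 / 3.0)
model = ou_preset_1d()
series = simulate_convobs(model, [3.0], [-2.0, 1.0], [1.0],
                          SimulationConfig(n=100_000, h=h, m=2, seed=1))

rho = SmoothingEstimator(rho_bar=100.0).fit(series)
print("rho_hat:", np.round(rho.rho_hat_, 4), " QV ratio:", np.round(rho.ratio_, 4))

test = SmoothnessTest(alpha_sig=0.05).fit(series)
print("T:", np.round(test.statistic_, 2), " reject:", test.reject_)

fitted = ConvolutionLeastSquares(model=model, rho_bar=100.0).fit(series)
print("corrected: alpha", np.round(fitted.alpha_hat_, 3),
      "beta", np.round(fitted.beta_hat_, 3))

naive = LGAEstimator(model=model).fit(series)
print("naive LGA: alpha", np.round(naive.alpha_hat_, 3),
      "beta", np.round(naive.beta_hat_, 3))
```

Output:

```
rho_hat: [0.9806]  QV ratio: [0.8046]
T: [-54.06]  reject: [ True]
corrected: alpha [2.984] beta [-2.939  2.846]
naive LGA: alpha [2.448] beta [-1.979  1.924]
```

The sample QV ratio 0.8046 sits at the population value R(1) = 4/5, so the
inversion returns ρ̂ ≈ 0.98; the test statistic −54 rejects direct
observation at any conventional level.  The corrected diffusion estimate
2.984 recovers the true α = 3, while the naive fit collapses to
`3·sqrt(fG(1,1)) = 3·sqrt(2/3) ≈ 2.449` — the systematic deflation that
motivates the correction.  (Drift estimates are intrinsically noisy at this
time horizon; their spread across replicates is an order of magnitude larger
than the diffusion estimate's.)

The same workflow from the shell:

```sh
convodiff simulate --model ou1d --alpha 3 --beta -2,1 --rho 1 \
    --n 100000 --h 4.6416e-4 --seed 1 --out series.csv
convodiff estimate-rho --input series.csv --h 4.6416e-4
convodiff test-smoothness --input series.csv --h 4.6416e-4
convodiff fit --input series.csv --h 4.6416e-4 --model ou1d
convodiff rv-profile --input series.csv --h 4.6416e-4 --kmax 100
```

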