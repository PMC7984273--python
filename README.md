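# autonom

**Automatic nonstationary oscillatory modelling**: Bayesian segmentation and
line-spectrum estimation for time series whose periodic behaviour changes
abruptly — breathing traces that alternate between sniffing, normal breathing
and apnea; wrist- or chest-worn temperature recordings whose circadian and
ultradian rhythms switch between day activity and night rest; any evenly
sampled signal with sharp spectral peaks whose locations and strengths shift
at unknown times.

## Model

The series `y_1..y_n` is approximated by a piecewise sinusoidal regression:
an unknown number `k` of change-points `s_1 < … < s_k` splits the index range
into segments, and within segment `j`

    y_t = α_j + μ_j t + Σ_{l=1}^{m_j} [ β_{j,l}^{(1)} cos(2π ω_{j,l} t)
                                      + β_{j,l}^{(2)} sin(2π ω_{j,l} t) ] + ε_t,
    ε_t ~ N(0, σ_j²),

with the number of sinusoids `m_j`, the frequencies `ω_{j,l} ∈ (0, 0.5)`
(cycles per sample), the coefficients and the variances all unknown.  Priors
are truncated Poisson on `k` and `m_j`, an even-order-statistics density on
the locations, uniform frequencies, a diffuse Gaussian on the coefficients
and a vague Inverse-Gamma on the variances.

Inference is by reversible-jump MCMC: each sweep updates every segment's
sinusoids (periodogram-informed Metropolis–Hastings on frequencies, exact
Gibbs on coefficients and variances, birth/death moves on `m_j`) and then the
change-point configuration (relocation, segment splits and merges with all
proposal densities carried in the acceptance ratios).  The posterior sample
yields model probabilities `π(k|y)`, conditional change-point and frequency
posteriors, per-sinusoid power `I(ω) = (β^{(1)})² + (β^{(2)})²` and phase,
a fitted signal with a 95% credible band, and a time-varying spectral peak
track.  `docs/methods.md` has the full account.

## Worked example

```python
import numpy as np
from autonom import AutoNOM, simulate_piecewise_sinusoid, illustrative_spec

# three oscillatory regimes, breaks at t = 300 and 650, unit noise
data, truth = simulate_piecewise_sinusoid(illustrative_spec(), rng=11)

model = AutoNOM(n_iter=6000, burn_in=1500, random_state=0).fit(data.values)
print("modal k:", model.k_mode_)
print("modal m:", model.m_mode_)
print("change-points:", np.round(model.changepoints_, 1))
for j, freqs in enumerate(model.frequencies_):
    print(f"segment {j + 1} frequencies:", np.round(freqs, 4))
```

Output from the run above:

```
modal k: 2
modal m: (3, 1, 2)
change-points: [300.2 648.1]
segment 1 frequencies: [0.0422 0.0671 0.1429]
segment 2 frequencies: [0.0829]
segment 3 frequencies: [0.046  0.0668]
```

The sampler identifies the two change-points (truth: 300 and 650), the right
number of sinusoids per regime (3, 1, 2) and every generating frequency
(truth: 0.042/0.067/0.143, 0.083, 0.046/0.067) to within a few ten-thousandths
of a cycle per sample.  `model.predict()` returns the posterior-mean signal
and `model.credible_band()` its pointwise 95% band.

The same functionality is available from the shell:

```sh
autonom simulate --model illustrative --seed 11 --out y.csv
autonom fit --input y.csv --iters 6000 --burnin 1500 --seed 0 --outdir run/
autonom summarize --trace run/trace.csv --input y.csv --out summary.json
```

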