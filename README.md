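# laminarpa

**Laminar population analysis (LPA)** for extracellular recordings: a joint
decomposition of multi-unit activity (MUA) and local field potential /
current source density (LFP/CSD) from laminar probes into physiologically
interpretable per-population contributions.

## The problem

A laminar probe inserted through cortex records, at each contact, a mixture
of signals generated by many neural populations: the spiking of nearby
cells (the high-frequency MUA band) and the synaptic currents they evoke
throughout the column (the low-frequency LFP band and its depth derivative,
the CSD). Blind decompositions such as PCA or ICA split these matrices into
components with no built-in physiological meaning. LPA instead constrains
the factorization with a forward model of how firing generates fields, so
each component *is* a population: a cortical layer, or an external input
structure such as the thalamus or cortical feedback.

## The model

Signals are channels-by-time matrices `phi(z_i, t_j)`. The method runs in
four steps:

1. **MUA decomposition.** `phi_M ≈ Σ_n M_n(z_i) r_n(t_j)`, where each
   spatial profile `M_n` is a unit-height trapezoid (position `z`, plateau
   width `a`, ramp width `b`) and trapezoids of different populations do
   not overlap. Given candidate trapezoids the rates are the least-squares
   optimum `r = pinv(Mᵀ) phi_M`; the trapezoid parameters are optimized by
   seeded differential evolution to minimize the relative MSE
   `e_M = Σ(phi_M − phi_est)² / Σ phi_M²`.
2. **Postsynaptic kernels.** Each population's rate is convolved with a
   causal exponential kernel `h(t) = (1/τ) e^{−(t−Δ)/τ} Θ(t−Δ)` (unit
   mass, per-population `τ` and `Δ`), giving the time course `R = h ⊛ r`
   of the field that firing in that population generates. Firing rates of
   **external structures** are simply appended as extra rows of `r`.
3. **Field decomposition.** Spatial field profiles follow by least
   squares, `L = phi_C pinv(R)`; the kernel parameters are globally
   optimized against `e_C = relMSE + λ · dev(C_est)`, where `dev` is the
   time-averaged absolute channel sum of the estimated CSD normalized to
   its peak — a penalty on violations of charge balance (Kirchhoff's
   current law), needed because the delta inverse-CSD estimator does not
   enforce a zero channel sum.
4. **Contributions.** Population `n`'s contribution to the field is the
   outer product `L[:, n] R[n, :]`; contributions sum to the total
   reconstruction exactly.

CSD is estimated from the LFP by the **delta iCSD** method (planar current
discs of radius `R` at each contact, `phi = F c` with
`F_ji = (1/2σ)(√(R² + h²) − h)`, `h = |z_j − z_i|`), or by the traditional
second-spatial-derivative estimator. A forward-model synthetic generator
(`laminarpa.synthetic`) plants known populations, kernels, and
charge-balanced field profiles so the whole pipeline is validated by
parameter recovery, and PCA/ICA baselines are included for comparison.

## Worked example

```python
import laminarpa as lp
from laminarpa.synthetic import SyntheticConfig, make_ground_truth, make_recordings

truth = make_ground_truth(SyntheticConfig(), seed=1)   # 26 channels, 5 layers,
rec = make_recordings(truth, seed=1)                   # 750 ms trials, 1 ms bins

cfg = lp.AnalysisConfig(n_populations=5, rng_seed=1)
mua_fit = lp.fit_mua(rec.mua, truth.geometry, cfg)

predicted = lp.classify_channels(mua_fit.model, truth.geometry)
observed = lp.true_channel_layers(truth.geometry)
cm = lp.confusion_matrix(predicted, observed, layers=truth.geometry.layer_names)
print("layer F1:", {l: round(lp.f1(cm, l), 2) for l in truth.geometry.layer_names})

result = lp.fit_csd(rec.csd, truth.rates_all, cfg)
print(f"CSD fit: e_C = {result.error:.3g}, correlation = {result.correlation:.4f}")
```

On the default noise-free fixture this prints

```
layer F1: {'L1': 1.0, 'L2/3': 1.0, 'L4': 1.0, 'L5': 1.0, 'L6': 1.0}
CSD fit: e_C = 8.47e-10, correlation = 1.0000
```

i.e. every probe channel is assigned its true layer (the MUA fit reaches
`e_M ≈ 3e-32`), and the kernel fit reproduces the planted CSD essentially
exactly — the recovered time constants land within 0.2 % of the planted
values (e.g. thalamus `τ = 5.00 ms, Δ = 3.0 ms`) and every per-population
contribution correlates with its ground truth at `r = 1.000`.

A command-line interface mirrors the library
(`laminarpa synth | fit-mua | fit-csd | csd | baselines | report`); run
`laminarpa --help`.

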