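# Methods

This note documents the model implemented by `laminarpa`, its assumptions,
the numerical choices made where the design was genuinely open, what the
synthetic generator does and does not emulate, and the known limitations.

## Signal model

A laminar probe records channels-by-time matrices on a common
stimulus-aligned time base (bin width `dt` in ms, first-bin time `t0`
relative to stimulus onset). Depths are in micrometres, increasing from
the cortical surface downward; channel 0 is the most superficial contact.

The raw extracellular potential is split at a cutoff frequency (default
300 Hz) with a 5th-order Butterworth filter applied forward-backward, so
both bands are zero-phase: the low band is the LFP, the high band carries
multi-unit activity. The decomposition needs a non-negative, slowly
varying MUA signal, so the high band is rectified (absolute value) and
smoothed with a 2-ms-sd Gaussian (reflect padding at trial edges) before
trial averaging. The rectify-and-smooth envelope is this package's
documented choice for turning the broadband high-pass signal into the
quantity the factor model is fitted to; band power over sliding windows
would be an alternative with coarser time resolution.

Population firing rates from spike events are per-population spike-count
histograms at 1-ms bins, Gaussian-smoothed with a 2-bin standard
deviation, averaged over trials, and scaled to spikes/s per cell when
cell counts are known. Smoothing conserves total spike count up to edge
effects.

## The decomposition

**Step 1 — MUA.** The trial-averaged MUA envelope is modelled as
`phi_M(z_i, t_j) = sum_n M_n(z_i) r_n(t_j)` with each `M_n` a unit-height
trapezoid (centre `z`, plateau `a`, ramp `b`) and pairwise non-overlapping
supports. Rates given trapezoids are the least-squares optimum
`r = pinv(M^T) phi_M`, so the global search runs only over the spatial
parameters with the relative MSE as cost. The unit height pins the
spatial scale: rescaling the data rescales the rates and leaves the
profiles unchanged.

Non-overlap is enforced by construction rather than rejection: the
optimizer works in a unit cube whose coordinates are per-population gap
weights, plateau fractions, and ramp fractions; widths are mapped into
their micrometre bounds, scaled down only if they jointly exceed the
probe span, and the leftover span is distributed over the gaps
proportionally to the gap weights. Every decoded candidate is feasible
and ordered by depth, so the stochastic search wastes no evaluations on
constraint violations. The probe span is extended by half a contact
spacing at each end so populations may cover the outermost channels.
Candidates leaving some population with no channel support get a large
constant cost plus the number of empty rows, steering the search back to
identifiable configurations.

**Step 2 — kernels.** Each presynaptic rate (laminar populations, plus
any appended external structures) is convolved with a causal exponential
kernel `h(t) = (1/tau) exp(-(t - delta)/tau)` for `t >= delta`, sampled
on the bin grid and scaled by `dt` so that a steady rate `c` maps to a
steady postsynaptic profile `c` (the Riemann mass of the sampled kernel
approaches 1 from above with bias ~`dt/2tau`). Convolutions are computed
by FFT with the rate transforms precomputed once per fit.

**Step 3 — field.** Given the postsynaptic temporal profiles `R`, the
spatial field profiles are the least-squares optimum `L = phi pinv(R)`.
The kernel parameters `(tau_n, delta_n)` are optimized globally against

    e_C = sum (C - C_est)^2 / sum C^2  +  lambda * dev(C_est)

where `dev` is the time-averaged absolute CSD channel sum normalized to
the peak |CSD| — the charge-balance diagnostic. At `lambda = 0` the cost
is exactly the relative MSE.

**Step 4 — contributions.** Population `n`'s contribution is the outer
product of column `n` of `L` with row `n` of `R`; the total
reconstruction is computed as the sum of the stored contributions, so the
self-consistency identity holds bit-exactly.

## CSD estimation

The delta inverse-CSD method models sources as infinitely thin discs of
radius `R` (default 400 um) at each contact in a homogeneous medium of
conductivity `sigma` (default 0.3 S/m, the conventional cortical value;
configurable). The forward matrix `F_ji = (1/2 sigma)(sqrt(R^2 + h^2) - h)`
with `h = |z_j - z_i|` is inverted per time bin; `delta_icsd` and
`forward_lfp_from_csd` are exact mutual inverses, and an ill-conditioned
`F` (condition number above 1e12) raises rather than returning noise
amplification silently. Output units are planar source density per disc;
the decomposition uses CSD only up to a consistent scale. The traditional
estimator multiplies the discrete second spatial depth-derivative of the
LFP by `-sigma`; it requires uniform spacing, returns interior channels
only, and enforces a zero channel sum by construction (its interior sum
telescopes to the boundary slopes). Sign convention: sinks negative,
sources positive.

The zero-sum penalty uses the *absolute* per-bin channel sum, normalized
to the peak CSD magnitude. A signed, unnormalized sum would reward
cancellation of imbalances of opposite sign across time and change
meaning with the data scale, so the absolute normalized form is the
implemented definition of both the diagnostic and the penalty.

## Numerical choices

* Every pseudoinverse uses an SVD with relative singular-value cutoff
  1e-10.
* The global optimizer for both fits is seeded differential evolution
  (population-size multiplier 15, iteration cap 400, relative tolerance
  1e-6, plus an absolute tolerance 1e-8 because the noise-free optimum
  has cost ~0 where a purely relative criterion never triggers), followed
  by a local polish. Identical seeds give bit-identical results; budget
  exhaustion returns the best-so-far parameters with a warning and
  `converged=False`.
* Kernel-fit bounds default to `tau` in [1, 100] ms and `delta` in
  [0, 50] ms; both are configuration and are recorded in result bundles.
* On the bin grid the delay of a point-sampled exponential kernel is
  identifiable only up to its containing bin: moving `delta` within
  `((k-1) dt, k dt]` rescales the sampled kernel by a constant that the
  least-squares spatial step absorbs, so the cost is exactly flat there.
  The fit reports the grid-aligned supremum of the equivalence class as
  the canonical delay.
* Near-collinear postsynaptic profiles (condition number above 1e6)
  trigger a warning naming the most correlated population pair — the
  synchrony failure mode; the spatial profiles of such populations are
  poorly determined.
* Channel-layer classification: each channel belongs to the unique
  population with positive trapezoid weight there (non-overlap guarantees
  uniqueness); uncovered channels are assigned to the nearest support and
  logged. A population is labelled with the layer its support overlaps
  most, in micrometres; exact ties go to the shallower layer and are
  logged. Per-layer precision, recall, and F1 follow from the
  predicted-by-true confusion matrix (rows normalized by row sums);
  zero-denominator scores are defined as 0 with a warning. Scores are
  displayed at 2 decimal places; full precision is retained in bundles.
* `lambda` selection, when wanted, is a grid search choosing the value
  that minimizes the channel-sum deviation of the resulting estimate.
* MUA-derived internal rates and spike-derived external rates live on
  different amplitude scales; how to reconcile them is genuinely
  unresolved, so the package appends external rows as given and leaves
  any per-row standardization to the caller.

## The synthetic generator

The default fixture emulates a stimulus-evoked laminar recording at desk
scale: 26 channels at 40 um spacing spanning ~1 mm, five named layers
whose boundaries fall between contacts (a contact exactly on a boundary
would have an ill-defined true layer), one trapezoid population tiling
each layer, 750-ms trials (100 ms pre-stimulus, 250-ms stimulus) at 1-ms
bins, 10 trials, and three external structures (thalamic input, cortical
feedback, background). Rates are a baseline plus alpha-function
transients peaking ~50 ms after stimulus onset and offset with
population-specific latencies and amplitudes, plus smoothed private
variability; a synchrony parameter `rho` mixes every laminar rate with
one shared course, so pairwise rate correlation rises monotonically with
`rho` and the condition number of the true postsynaptic profile matrix
rises with it — the mechanism behind the synchrony failure mode. Field
profiles are dipoles built from two unit-mass Gaussians, so each
contribution's channel sum is exactly zero; an imbalance fraction adds
back a scaled sink lobe for penalty experiments. MUA is the exact
profile-rate product, the LFP is the disc-forward image of the total CSD,
and spikes are inhomogeneous Poisson draws of the laminar rates. All
randomness flows from one integer seed.

Measurement noise defaults to zero: recovery is assessed under noise-free
forward data, which is what makes the exactness and 10 %-recovery checks
meaningful. What passing these tests shows is that the implementation
inverts its own forward model correctly and that the failure modes
(synchrony, charge imbalance) behave as expected; it does not show that
the trapezoid/exponential-kernel model is adequate for any particular
real cortical recording, where profiles are not trapezoids, kernels are
not single exponentials, excitatory and inhibitory contributions
superimpose with opposite signs, and noise is structured.

Problem sizes in the test suite and the acceptance script (the default
26 x 750 fixture; reduced optimizer budgets of 60-150 iterations for the
synchrony, penalty, and comparison experiments) were chosen as desk-scale
study conditions that resolve every planted parameter.

## Baselines

PCA is the rank-k SVD of the per-channel-centred CSD (orthogonal spatial
maps, non-increasing explained variance; all components plus the channel
means restore the input exactly). ICA is FastICA over temporal sources
with a fixed seed; component order and sign are not meaningful, so
comparisons use optimal assignment on absolute correlation. These are
comparison points, not part of the method, and are delegated to standard
implementations. On rate-synchronous data both baselines share the same
identifiability limit as the population decomposition.

## Known limitations

* One temporal profile per population: excitatory and inhibitory
  contributions within a layer are not separated.
* Exponential kernels only; other kernel families would require extending
  the kernel bank.
* Delta-variant inverse CSD only (no spline or kernel CSD, no
  Vaknin-electrode handling); traditional CSD drops the boundary
  channels.
* The trapezoid boundaries are identifiable only where channels sample
  them; between contacts they are constrained only by the ramp geometry.
* No power-law correction relating MUA amplitude to firing rate; MUA-
  derived rates are in arbitrary units.
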