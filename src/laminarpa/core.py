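"""Laminar population analysis: the decomposition proper.

The method factorizes laminar recordings into per-population spatial and
temporal profiles in four steps:

1. **MUA decomposition.** The MUA envelope ``phi_M`` (N_ch x B) is modelled
   as ``phi_M(z_i, t_j) = sum_n M_n(z_i) r_n(t_j)`` where each spatial
   profile ``M_n`` is a trapezoid of unit height (position z, plateau width
   a, ramp width b) and the trapezoids of different populations do not
   overlap. Given candidate trapezoids, the rates are the least-squares
   optimum ``r = pinv(M^T) phi_M``; the trapezoid parameters are optimized
   globally (seeded differential evolution) to minimize the relative MSE.
2. **Postsynaptic kernels.** Each population's rate is convolved with a
   causal exponential kernel ``h(t) = (1/tau) exp(-(t - delta)/tau)`` for
   ``t >= delta`` (unit mass), giving the time course ``R`` of the
   postsynaptic field that firing in that (presynaptic) population evokes.
3. **Field decomposition.** The spatial profiles of the per-population
   field follow by least squares, ``L = phi_C pinv(R)``, and the kernel
   parameters (tau, delta per population) are globally optimized to
   minimize the relative MSE of ``L R`` against the recorded field, plus an
   optional penalty ``lambda * dev(C_est)`` on the deviation of the
   estimated CSD's channel sum from zero.
4. **Contributions.** The outer product of column n of L with row n of R is
   the per-population contribution; contributions sum to the total
   reconstruction exactly.

Firing rates of structures outside the probed area (e.g. thalamic input or
cortical feedback) can be appended to the rate matrix before step 2; they
participate in the field decomposition but not in the spatial MUA model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy.optimize import OptimizeResult, differential_evolution

from .config import AnalysisConfig
from .containers import ProbeGeometry, RateMatrix, RecordingMatrix
from .csd import channel_sum_deviation

logger = logging.getLogger("laminarpa")

__all__ = [
    "TrapezoidProfile",
    "PopulationModel",
    "KernelParams",
    "MuaFit",
    "DecompositionResult",
    "trapezoid_eval",
    "build_spatial_matrix",
    "infer_rates",
    "reconstruct",
    "relative_mse",
    "fit_mua",
    "exp_kernel",
    "postsynaptic_profiles",
    "infer_spatial_field",
    "csd_cost",
    "fit_csd",
    "append_external_rates",
    "merge_populations",
    "population_layer_labels",
    "classify_channels",
    "true_channel_layers",
]

#: relative singular-value cutoff for every pseudoinverse in the method
PINV_RCOND = 1e-10

#: condition number of R above which near-collinear rates are reported
COLLINEARITY_THRESHOLD = 1e6

_OVERLAP_TOL = 1e-9

#: absolute convergence tolerance for the global search; the noise-free
#: optimum has cost ~0, where a purely relative criterion never triggers
DE_ATOL = 1e-8


# ---------------------------------------------------------------------------
# spatial model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrapezoidProfile:
    """Unit-height trapezoid: plateau of width ``a`` centred at depth ``z``
    with linear ramps of width ``b`` on each side (all in um)."""

    z: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"plateau width a must be >= 0, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"ramp width b must be > 0, got {self.b}")

    @property
    def support(self) -> tuple[float, float]:
        half = self.a / 2.0 + self.b
        return self.z - half, self.z + half


def trapezoid_eval(profile: TrapezoidProfile, depth_um) -> np.ndarray | float:
    """Trapezoid weight in [0, 1] at the given depth(s)."""
    d = np.abs(np.asarray(depth_um, dtype=float) - profile.z)
    w = np.clip((profile.a / 2.0 + profile.b - d) / profile.b, 0.0, 1.0)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class PopulationModel:
    """Ordered, non-overlapping trapezoid profiles with labels."""

    profiles: tuple[TrapezoidProfile, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        profiles = tuple(self.profiles)
        if not profiles:
            raise ValueError("need at least one population")
        labels = tuple(self.labels) if self.labels else tuple(
            f"pop_{i}" for i in range(len(profiles))
        )
        if len(labels) != len(profiles):
            raise ValueError("label count must match profile count")
        zs = [p.z for p in profiles]
        if any(z2 < z1 for z1, z2 in zip(zs, zs[1:])):
            raise ValueError("populations must be ordered by depth")
        for i, (p1, p2) in enumerate(zip(profiles, profiles[1:])):
            if p1.support[1] > p2.support[0] + _OVERLAP_TOL:
                raise ValueError(
                    f"trapezoid supports of populations {i} and {i + 1} overlap: "
                    f"{p1.support} vs {p2.support}"
                )
        object.__setattr__(self, "profiles", profiles)
        object.__setattr__(self, "labels", labels)

    @property
    def n_populations(self) -> int:
        return len(self.profiles)


def build_spatial_matrix(pops: PopulationModel, geom: ProbeGeometry) -> np.ndarray:
    """Spatial-profile matrix M (N_pop x N_ch): M[n, i] = weight of
    population n at channel depth z_i.

    Non-overlap of the trapezoids guarantees that each channel has positive
    weight for at most one population. Populations whose support covers no
    channel produce an all-zero row and are reported in a warning.
    """
    m = np.vstack([trapezoid_eval(p, geom.depths_um) for p in pops.profiles])
    zero = ~m.any(axis=1)
    if zero.any():
        names = [pops.labels[i] for i in np.flatnonzero(zero)]
        warnings.warn(
            f"populations {names} cover no channel (all-zero spatial rows)",
            stacklevel=2,
        )
    return m


def infer_rates(m: np.ndarray, phi_m: RecordingMatrix) -> RateMatrix:
    """Least-squares rates given spatial profiles: ``r = pinv(M^T) phi_M``.

    Optimal in the least-squares sense for the factor model given M; exact
    when ``phi_M`` lies in the row space of M.
    """
    m = np.atleast_2d(np.asarray(m, float))
    if m.shape[1] != phi_m.n_channels:
        raise ValueError(
            f"spatial matrix has {m.shape[1]} channels, signal has {phi_m.n_channels}"
        )
    if np.linalg.matrix_rank(m, tol=None) < m.shape[0]:
        zero_rows = np.flatnonzero(~m.any(axis=1)).tolist()
        raise ValueError(
            "spatial matrix is rank deficient"
            + (f" (populations with zero support: {zero_rows})" if zero_rows else "")
        )
    rates = np.linalg.pinv(m.T, rcond=PINV_RCOND) @ phi_m.values
    return RateMatrix(rates, dt=phi_m.dt, t0=phi_m.t0)


def reconstruct(spatial: np.ndarray, temporal: np.ndarray) -> np.ndarray:
    """Channels x bins reconstruction from spatial and temporal factors.

    Accepts either orientation of the spatial factor: an N_pop x N_ch MUA
    profile matrix (result ``spatial.T @ temporal``) or an N_ch x N_pop
    field profile matrix (result ``spatial @ temporal``).
    """
    spatial = np.atleast_2d(np.asarray(spatial, float))
    temporal = np.atleast_2d(np.asarray(temporal, float))
    n_pop = temporal.shape[0]
    if spatial.shape[1] == n_pop:
        return spatial @ temporal
    if spatial.shape[0] == n_pop:
        return spatial.T @ temporal
    raise ValueError(
        f"cannot align spatial factor {spatial.shape} with temporal factor {temporal.shape}"
    )


def relative_mse(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Relative mean square error: sum((truth - est)^2) / sum(truth^2)."""
    truth = np.asarray(truth, float)
    estimate = np.asarray(estimate, float)
    if truth.shape != estimate.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {estimate.shape}")
    denom = np.sum(truth**2)
    if denom == 0.0:
        raise ValueError("relative MSE undefined for an all-zero reference")
    return float(np.sum((truth - estimate) ** 2) / denom)


# ---------------------------------------------------------------------------
# MUA fit (step 1)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuaFit:
    """Result of the MUA decomposition."""

    model: PopulationModel
    spatial: np.ndarray          # M, N_pop x N_ch
    rates: RateMatrix            # r, N_pop x B (MUA-scaled a.u.)
    error: float                 # relative MSE e_M
    converged: bool


def _decode_trapezoids(
    x: np.ndarray, n_pop: int, span: tuple[float, float], a_bounds, b_bounds
) -> PopulationModel:
    """Map a unit-cube optimizer vector to a feasible non-overlapping model.

    Layout of ``x`` (length 3 n_pop + 1): one gap weight before each
    population plus a trailing gap weight, and per population a plateau
    fraction and a ramp fraction mapped into their um bounds. If the widths
    alone exceed the probe span they are scaled down to fit; any leftover
    span is distributed over the gaps proportionally to the gap weights.
    Every decoded candidate is feasible, so the global search never wastes
    evaluations on constraint violations.
    """
    top, bottom = span
    length = bottom - top
    gaps_w = np.asarray([x[3 * i] for i in range(n_pop)] + [x[-1]], float)
    a_lo, a_hi = a_bounds
    b_lo, b_hi = b_bounds
    a = a_lo + np.asarray([x[3 * i + 1] for i in range(n_pop)], float) * (a_hi - a_lo)
    b = b_lo + np.asarray([x[3 * i + 2] for i in range(n_pop)], float) * (b_hi - b_lo)
    widths = a + 2.0 * b
    total_width = widths.sum()
    if total_width > length:
        shrink = length / total_width
        a *= shrink
        b *= shrink
        widths = a + 2.0 * b
    leftover = length - widths.sum()
    gsum = gaps_w.sum()
    gaps = gaps_w / gsum * leftover if gsum > 0 else np.full(n_pop + 1, leftover / (n_pop + 1))
    profiles = []
    cursor = top
    for i in range(n_pop):
        cursor += gaps[i]
        profiles.append(TrapezoidProfile(z=cursor + widths[i] / 2.0, a=a[i], b=max(b[i], 1e-9)))
        cursor += widths[i]
    return PopulationModel(tuple(profiles))


def fit_mua(
    phi_m: RecordingMatrix, geom: ProbeGeometry, config: AnalysisConfig
) -> MuaFit:
    """Step 1: fit non-overlapping trapezoid profiles (and their rates) to
    the MUA envelope by seeded global optimization.

    At each candidate the rates are the least-squares optimum given the
    trapezoids, so the search runs only over the 3 N_pop spatial parameters
    (plus gap weights); the cost is the relative MSE of the reconstruction.
    Populations in the returned model are ordered by depth.
    """
    n_pop = config.n_populations
    if phi_m.n_channels != geom.n_channels:
        raise ValueError(
            f"MUA has {phi_m.n_channels} channels, geometry has {geom.n_channels}"
        )
    if n_pop > geom.n_channels:
        raise ValueError(
            f"cannot place {n_pop} populations with positive channel support "
            f"on a {geom.n_channels}-channel probe"
        )
    span = geom.span_um
    length = span[1] - span[0]
    b_lo = config.trapezoid_b_bounds_um[0]
    if n_pop * 2 * b_lo > length:
        raise ValueError(
            f"cannot place {n_pop} non-overlapping trapezoids with ramp width "
            f">= {b_lo} um within the {length:.0f} um probe span"
        )
    a_hi = config.trapezoid_a_bounds_um[1]
    a_bounds = (config.trapezoid_a_bounds_um[0], length if a_hi is None else a_hi)
    b_hi = config.trapezoid_b_bounds_um[1]
    b_bounds = (b_lo, length / 2.0 if b_hi is None else b_hi)
    phi = phi_m.values
    denom = np.sum(phi**2)
    if denom == 0.0:
        raise ValueError("MUA envelope is identically zero")

    def cost(x: np.ndarray) -> float:
        model = _decode_trapezoids(x, n_pop, span, a_bounds, b_bounds)
        m = np.vstack([trapezoid_eval(p, geom.depths_um) for p in model.profiles])
        covered = m.any(axis=1)
        if not covered.all():
            # infeasible for rate inference; steer the search away
            return 100.0 + float((~covered).sum())
        rates = np.linalg.pinv(m.T, rcond=PINV_RCOND) @ phi
        resid = phi - m.T @ rates
        return float(np.sum(resid**2) / denom)

    result: OptimizeResult = differential_evolution(
        cost,
        bounds=[(0.0, 1.0)] * (3 * n_pop + 1),
        seed=config.rng_seed,
        popsize=config.de_popsize,
        maxiter=config.de_maxiter,
        tol=config.de_tol,
        atol=DE_ATOL,
        polish=True,
    )
    if not result.success:
        warnings.warn(
            f"MUA fit did not converge within the optimizer budget "
            f"({result.message}); returning best-so-far parameters",
            stacklevel=2,
        )
    model = _decode_trapezoids(result.x, n_pop, span, a_bounds, b_bounds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero rows excluded by the cost already
        m = build_spatial_matrix(model, geom)
    rates = infer_rates(m, phi_m)
    return MuaFit(
        model=model,
        spatial=m,
        rates=rates,
        error=float(result.fun),
        converged=bool(result.success),
    )


# ---------------------------------------------------------------------------
# kernels and field decomposition (steps 2-4)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelParams:
    """Per-population exponential-kernel parameters (ms)."""

    tau_ms: np.ndarray
    delay_ms: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tau = np.atleast_1d(np.asarray(self.tau_ms, float))
        delay = np.atleast_1d(np.asarray(self.delay_ms, float))
        if tau.shape != delay.shape:
            raise ValueError("tau and delay arrays must have the same length")
        if np.any(tau <= 0):
            raise ValueError("time constants tau must be positive")
        if np.any(delay < 0):
            raise ValueError("delays must be >= 0 (causality)")
        labels = tuple(self.labels) if self.labels else tuple(
            f"pop_{i}" for i in range(tau.size)
        )
        if len(labels) != tau.size:
            raise ValueError("label count must match kernel count")
        object.__setattr__(self, "tau_ms", tau)
        object.__setattr__(self, "delay_ms", delay)
        object.__setattr__(self, "labels", labels)

    @property
    def n_populations(self) -> int:
        return self.tau_ms.size


def exp_kernel(tau_ms: float, delay_ms: float, dt: float, n_bins: int) -> np.ndarray:
    """Causal exponential kernel sampled at the bin grid.

    ``h(t) = (1/tau) exp(-(t - delta)/tau)`` for ``t >= delta`` and 0
    before; with the dt scaling used in :func:`postsynaptic_profiles` the
    kernel mass approaches 1 once the window is long compared to tau.
    """
    if tau_ms <= 0:
        raise ValueError(f"tau must be positive, got {tau_ms}")
    if delay_ms < 0:
        raise ValueError(f"delay must be >= 0, got {delay_ms}")
    t = dt * np.arange(n_bins)
    h = np.where(t >= delay_ms, np.exp(-(t - delay_ms) / tau_ms) / tau_ms, 0.0)
    return h


def _kernel_bank(kernels: KernelParams, dt: float, n_bins: int) -> np.ndarray:
    return np.vstack(
        [exp_kernel(t, d, dt, n_bins) for t, d in zip(kernels.tau_ms, kernels.delay_ms)]
    )


def postsynaptic_profiles(rates: RateMatrix, kernels: KernelParams) -> np.ndarray:
    """Step 2: per-population postsynaptic temporal profiles ``R = h (*) r``.

    Row-wise causal convolution of each population's rate with its own
    kernel, truncated to the recording length and scaled by dt so that a
    unit-mass kernel maps a steady rate c to a steady profile c.
    """
    if kernels.n_populations != rates.n_populations:
        raise ValueError(
            f"{kernels.n_populations} kernels for {rates.n_populations} populations"
        )
    b = rates.n_bins
    h = _kernel_bank(kernels, rates.dt, b)
    nfft = sp_fft.next_fast_len(2 * b - 1)
    prod = sp_fft.rfft(rates.values, nfft, axis=1) * sp_fft.rfft(h, nfft, axis=1)
    return sp_fft.irfft(prod, nfft, axis=1)[:, :b] * rates.dt


def infer_spatial_field(field: RecordingMatrix, r_est: np.ndarray,
                        labels: tuple[str, ...] | None = None) -> np.ndarray:
    """Step 3: least-squares spatial field profiles ``L = phi pinv(R)``.

    Warns (naming the most correlated population pair) when the temporal
    profiles are near-collinear — the failure mode of the method under high
    inter-population rate synchrony.
    """
    r_est = np.atleast_2d(np.asarray(r_est, float))
    if r_est.shape[1] != field.n_bins:
        raise ValueError(
            f"temporal profiles have {r_est.shape[1]} bins, field has {field.n_bins}"
        )
    sv = np.linalg.svd(r_est, compute_uv=False)
    cond = np.inf if sv[-1] == 0 else sv[0] / sv[-1]
    if cond > COLLINEARITY_THRESHOLD:
        names = labels or tuple(f"pop_{i}" for i in range(r_est.shape[0]))
        corr = np.corrcoef(r_est)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        warnings.warn(
            f"postsynaptic temporal profiles are near-collinear "
            f"(condition number {cond:.3g}); most correlated pair: "
            f"{names[i]} / {names[j]} (r={corr[i, j]:.3f}). The spatial "
            "profiles of these populations are poorly determined.",
            stacklevel=2,
        )
    return field.values @ np.linalg.pinv(r_est, rcond=PINV_RCOND)


def csd_cost(c: np.ndarray, c_est: np.ndarray, lambda_penalty: float) -> float:
    """Total CSD cost: relative MSE plus the zero-sum penalty.

    The penalty is ``lambda`` times the time-averaged absolute channel sum
    of the estimate, normalized by its peak magnitude (the deviation-from-
    zero diagnostic); at lambda = 0 the cost reduces exactly to the plain
    relative MSE.
    """
    if lambda_penalty < 0:
        raise ValueError("lambda must be >= 0")
    cost = relative_mse(c, c_est)
    if lambda_penalty > 0:
        cost += lambda_penalty * channel_sum_deviation(c_est)
    return cost


@dataclass(frozen=True)
class DecompositionResult:
    """Full output of the field (LFP/CSD) decomposition.

    ``contributions[n]`` is the N_ch x B field generated by population n;
    their sum equals ``reconstruction`` exactly.
    """

    labels: tuple[str, ...]
    kernels: KernelParams
    rates: RateMatrix                      # presynaptic rates used (input)
    postsynaptic_temporal: np.ndarray      # R, N_pop x B
    spatial_field: np.ndarray              # L, N_ch x N_pop
    contributions: np.ndarray              # N_pop x N_ch x B
    reconstruction: np.ndarray             # N_ch x B
    error: float                           # total cost e_C at the optimum
    mse: float                             # relative-MSE part
    correlation: float                     # Pearson r, estimate vs recording
    channel_sum_dev: float                 # deviation diagnostic of the estimate
    lambda_penalty: float
    converged: bool
    spatial_mua: np.ndarray | None = None  # M from step 1, when available
    mua_error: float | None = None         # e_M from step 1


def fit_csd(
    c: RecordingMatrix, rates: RateMatrix, config: AnalysisConfig
) -> DecompositionResult:
    """Steps 2-4: optimize per-population kernel parameters against the
    recorded field (CSD or LFP).

    A seeded differential-evolution search runs over (tau_n, delta_n) for
    every presynaptic population (laminar and external alike); at each
    candidate the spatial profiles are the least-squares optimum, and the
    cost is the relative MSE plus the lambda-weighted zero-sum penalty.
    If the optimizer budget is exhausted the best-so-far parameters are
    returned with ``converged=False`` and a warning.
    """
    if rates.n_bins != c.n_bins:
        raise ValueError(f"rates have {rates.n_bins} bins, field has {c.n_bins}")
    n_pop = rates.n_populations
    b = c.n_bins
    lam = config.lambda_penalty
    phi = c.values
    denom = np.sum(phi**2)
    if denom == 0.0:
        raise ValueError("field recording is identically zero")
    nfft = sp_fft.next_fast_len(2 * b - 1)
    rate_f = sp_fft.rfft(rates.values, nfft, axis=1)
    dt = rates.dt
    t_grid = dt * np.arange(b)

    def temporal(x: np.ndarray) -> np.ndarray:
        tau = x[0::2][:, None]
        delay = x[1::2][:, None]
        h = np.where(t_grid >= delay, np.exp(-(t_grid - delay) / tau) / tau, 0.0)
        prod = rate_f * sp_fft.rfft(h, nfft, axis=1)
        return sp_fft.irfft(prod, nfft, axis=1)[:, :b] * dt

    def cost(x: np.ndarray) -> float:
        r_est = temporal(x)
        l_est = phi @ np.linalg.pinv(r_est, rcond=PINV_RCOND)
        c_est = l_est @ r_est
        value = float(np.sum((phi - c_est) ** 2) / denom)
        if lam > 0:
            value += lam * channel_sum_deviation(c_est)
        return value

    bounds = [config.tau_bounds_ms, config.delta_bounds_ms] * n_pop
    result: OptimizeResult = differential_evolution(
        cost,
        bounds=bounds,
        seed=config.rng_seed,
        popsize=config.de_popsize,
        maxiter=config.de_maxiter,
        tol=config.de_tol,
        atol=DE_ATOL,
        polish=True,
    )
    if not result.success:
        warnings.warn(
            f"kernel fit did not converge within the optimizer budget "
            f"({result.message}); returning best-so-far parameters",
            stacklevel=2,
        )
    # On the bin grid the delay is identifiable only up to its containing
    # bin: moving delta within (k-1, k]*dt rescales the sampled exponential
    # by a constant, which the least-squares spatial profiles absorb, so the
    # cost is exactly flat there. Report the grid-aligned supremum of each
    # delay's cost-equivalence class as its canonical representative.
    delays = np.ceil(result.x[1::2] / dt - 1e-9) * dt
    delays = np.clip(delays, config.delta_bounds_ms[0], config.delta_bounds_ms[1])
    kernels = KernelParams(result.x[0::2], delays, labels=rates.labels)
    r_est = postsynaptic_profiles(rates, kernels)
    l_est = infer_spatial_field(c, r_est, labels=rates.labels)
    contributions = l_est.T[:, :, None] * r_est[:, None, :]
    reconstruction = contributions.sum(axis=0)
    mse = relative_mse(phi, reconstruction)
    corr = float(np.corrcoef(phi.ravel(), reconstruction.ravel())[0, 1])
    dev = channel_sum_deviation(reconstruction)
    return DecompositionResult(
        labels=rates.labels,
        kernels=kernels,
        rates=rates,
        postsynaptic_temporal=r_est,
        spatial_field=l_est,
        contributions=contributions,
        reconstruction=reconstruction,
        error=float(result.fun),
        mse=mse,
        correlation=corr,
        channel_sum_dev=dev,
        lambda_penalty=lam,
        converged=bool(result.success),
    )


# ---------------------------------------------------------------------------
# external structures and population grouping
# ---------------------------------------------------------------------------

def append_external_rates(internal: RateMatrix, external: RateMatrix) -> RateMatrix:
    """Row-stack external-structure rates under the laminar rates.

    External rows keep their labels and are flagged so that downstream
    steps exempt them from the spatial MUA model. Time bases must match.
    """
    if external.n_populations == 0:
        return internal
    if not internal.same_timebase(external):
        raise ValueError(
            "internal and external rates differ in time base "
            f"(dt {internal.dt} vs {external.dt}, t0 {internal.t0} vs {external.t0}, "
            f"B {internal.n_bins} vs {external.n_bins})"
        )
    return RateMatrix(
        np.vstack([internal.values, external.values]),
        dt=internal.dt,
        t0=internal.t0,
        labels=internal.labels + external.labels,
        external=internal.external + (True,) * external.n_populations,
    )


def merge_populations(
    rates: RateMatrix,
    grouping: dict[str, tuple[str, ...]],
    cell_counts: dict[str, float] | None = None,
) -> RateMatrix:
    """Merge internal populations according to ``grouping``.

    ``grouping`` maps each merged label to the internal labels it absorbs
    and must partition the internal populations exactly. Grouped rows are
    summed, or cell-count-weighted averaged when ``cell_counts`` is given.
    External rows pass through unchanged after the merged internal rows.
    """
    internal_labels = [l for l, ext in zip(rates.labels, rates.external) if not ext]
    grouped = [label for members in grouping.values() for label in members]
    if sorted(grouped) != sorted(internal_labels):
        raise ValueError(
            f"grouping {sorted(grouped)} is not a partition of the internal "
            f"populations {sorted(internal_labels)}"
        )
    index = {label: i for i, label in enumerate(rates.labels)}
    rows, labels = [], []
    for new_label, members in grouping.items():
        block = rates.values[[index[m] for m in members]]
        if cell_counts is None:
            rows.append(block.sum(axis=0))
        else:
            w = np.asarray([cell_counts[m] for m in members], float)
            rows.append(w @ block / w.sum())
        labels.append(new_label)
    ext_flags = [False] * len(labels)
    for label, ext in zip(rates.labels, rates.external):
        if ext:
            rows.append(rates.values[index[label]])
            labels.append(label)
            ext_flags.append(True)
    return RateMatrix(
        np.vstack(rows), dt=rates.dt, t0=rates.t0,
        labels=tuple(labels), external=tuple(ext_flags),
    )


# ---------------------------------------------------------------------------
# channel-layer classification
# ---------------------------------------------------------------------------

def population_layer_labels(model: PopulationModel, geom: ProbeGeometry) -> tuple[str, ...]:
    """Label each population with the layer its support overlaps the most,
    measured in um against the geometry's layer boundaries. Exact overlap
    ties go to the shallower layer (and are logged)."""
    if geom.layer_boundaries_um is None:
        raise ValueError("geometry has no layer boundaries")
    layers = list(geom.layer_boundaries_um.items())
    out = []
    for pop_label, profile in zip(model.labels, model.profiles):
        lo, hi = profile.support
        overlaps = np.array(
            [max(0.0, min(hi, bottom) - max(lo, top)) for _, (top, bottom) in layers]
        )
        best = int(np.argmax(overlaps))  # argmax takes the first (shallower) on ties
        if np.sum(np.isclose(overlaps, overlaps[best])) > 1:
            logger.info(
                "population %s overlaps several layers equally (%s um); "
                "assigning the shallower layer %s",
                pop_label, overlaps[best], layers[best][0],
            )
        out.append(layers[best][0])
    return tuple(out)


def classify_channels(model: PopulationModel, geom: ProbeGeometry) -> tuple[str, ...]:
    """Predicted layer for each channel.

    Each channel belongs to the unique population with positive trapezoid
    weight there (non-overlap guarantees uniqueness); channels covered by
    no population are assigned to the population with the nearest support
    (logged). The population's layer label is then the channel's predicted
    layer.
    """
    pop_layers = population_layer_labels(model, geom)
    weights = np.vstack([trapezoid_eval(p, geom.depths_um) for p in model.profiles])
    assignment = weights.argmax(axis=0)
    uncovered = ~weights.any(axis=0)
    if uncovered.any():
        for ch in np.flatnonzero(uncovered):
            depth = geom.depths_um[ch]
            dist = [
                min(abs(depth - p.support[0]), abs(depth - p.support[1]))
                for p in model.profiles
            ]
            assignment[ch] = int(np.argmin(dist))
        logger.info(
            "channels %s lie outside every population support; assigned by proximity",
            np.flatnonzero(uncovered).tolist(),
        )
    return tuple(pop_layers[i] for i in assignment)


def true_channel_layers(geom: ProbeGeometry) -> tuple[str, ...]:
    """Ground-truth layer of each channel from the geometry's boundaries."""
    return tuple(geom.layer_of_depth(d) for d in geom.depths_um)
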