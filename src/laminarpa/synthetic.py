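"""Forward-model ground-truth generator.

The generator emulates a stimulus-evoked laminar recording with known
populations so that the decomposition can be validated by parameter
recovery:

* a 26-channel laminar probe at 40 um spacing spanning ~1 mm of cortex
  with five named layers;
* one population per layer with a non-overlapping trapezoid depth profile;
* per-population firing rates built from a baseline plus alpha-function
  transients peaking ~50 ms after stimulus onset and offset, with private
  temporal variability; a synchrony parameter rho in [0, 1] mixes every
  laminar rate with one shared time course (rho = 0: independent evoked
  responses; rho = 1: identical rates);
* external structures (thalamic input, cortical feedback, background) with
  their own rates, exempt from the laminar spatial model;
* per-population CSD contributions formed by convolving each rate with its
  planted exponential kernel and multiplying with a charge-balanced
  (zero-channel-sum) dipolar depth profile; an imbalance control injects a
  nonzero channel sum to exercise the zero-sum penalty;
* MUA as the trapezoid-profile/rate product, LFP from the total CSD via
  the disc forward model, and spikes as inhomogeneous Poisson realizations
  of the laminar rates.

All stochasticity flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import ProbeGeometry, RateMatrix, RecordingMatrix, SignalKind
from .core import (
    KernelParams,
    PopulationModel,
    TrapezoidProfile,
    append_external_rates,
    build_spatial_matrix,
    postsynaptic_profiles,
)
from .csd import forward_lfp_from_csd

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "SyntheticRecordings",
    "default_geometry",
    "default_populations",
    "make_rates",
    "make_balanced_profiles",
    "make_ground_truth",
    "make_recordings",
]

# boundaries fall between channel depths (20 + 40 i um) so that no contact
# sits exactly on a layer border, which would make its layer ill-defined
_DEFAULT_LAYERS: dict[str, tuple[float, float]] = {
    "L1": (0.0, 120.0),
    "L2/3": (120.0, 280.0),
    "L4": (280.0, 440.0),
    "L5": (440.0, 720.0),
    "L6": (720.0, 1040.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic fixture.

    Defaults emulate the geometry and protocol of a large-scale cortical
    column simulation probed with a laminar electrode: 26 channels at 40 um
    spacing, five layers, 750 ms trials (100 ms pre-stimulus baseline,
    250 ms stimulus), 1 ms bins, 10 trials, and evoked transients peaking
    ~50 ms after stimulus onset and offset. Measurement noise defaults to
    zero (recovery is assessed under noise-free forward data); the rates
    themselves always carry private smoothed temporal variability so that
    populations are temporally distinguishable at low synchrony.
    """

    n_channels: int = 26
    spacing_um: float = 40.0
    first_depth_um: float = 20.0
    conductivity_s_per_m: float = 0.3
    disc_radius_um: float = 400.0
    ramp_um: float = 20.0  # trapezoid ramp width on each side

    dt_ms: float = 1.0
    t0_ms: float = -100.0
    n_bins: int = 750
    stimulus_onset_ms: float = 0.0
    stimulus_offset_ms: float = 250.0
    transient_latency_ms: float = 50.0
    alpha_width_ms: float = 15.0
    n_trials: int = 10
    cells_per_population: int = 20

    # per-layer rate shape (spikes/s); order follows the layer map
    baselines_hz: tuple[float, ...] = (3.0, 5.0, 8.0, 6.0, 4.0)
    onset_amps_hz: tuple[float, ...] = (15.0, 30.0, 45.0, 35.0, 25.0)
    latencies_ms: tuple[float, ...] = (55.0, 48.0, 45.0, 50.0, 60.0)
    offset_amp_fraction: float = 0.6
    rate_noise_sd_hz: float = 1.5
    rate_noise_smooth_bins: float = 5.0

    # inter-population rate synchrony (0 = independent, 1 = identical)
    synchrony: float = 0.0

    # external structures: label -> (baseline, onset amp, latency ms)
    external_structures: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "thalamus": (10.0, 60.0, 40.0),
            "feedback": (6.0, 25.0, 75.0),
            "background": (12.0, 0.0, 50.0),
        }
    )

    # planted exponential kernels, laminar populations then externals
    kernel_tau_ms: tuple[float, ...] = (8.0, 14.0, 6.0, 18.0, 11.0, 5.0, 20.0, 30.0)
    kernel_delay_ms: tuple[float, ...] = (4.0, 6.0, 3.0, 7.0, 9.0, 3.0, 10.0, 12.0)

    # CSD spatial-profile construction (see make_balanced_profiles)
    field_amps: tuple[float, ...] = (0.8, 1.2, 1.5, 1.3, 1.0, 1.5, 1.2, 0.3)
    field_width_um: float = 80.0
    dipole_separation_um: float = 120.0
    # per-population fractional channel-sum imbalance (0 = charge balanced)
    imbalance: tuple[float, ...] = (0.0,) * 8

    # measurement noise (sd, same units as the signals)
    mua_noise_sd: float = 0.0
    csd_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.synchrony <= 1.0:
            raise ValueError("synchrony must lie in [0, 1]")
        n_pop = len(self.baselines_hz)
        n_total = n_pop + len(self.external_structures)
        for name in ("onset_amps_hz", "latencies_ms"):
            if len(getattr(self, name)) != n_pop:
                raise ValueError(f"{name} must have {n_pop} entries")
        for name in ("kernel_tau_ms", "kernel_delay_ms", "field_amps", "imbalance"):
            if len(getattr(self, name)) != n_total:
                raise ValueError(f"{name} must have {n_total} entries (laminar + external)")

    @property
    def n_laminar(self) -> int:
        return len(self.baselines_hz)

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + self.dt_ms * np.arange(self.n_bins)


def default_geometry(config: SyntheticConfig | None = None) -> ProbeGeometry:
    """Probe geometry of the fixture, with named layer boundaries."""
    config = config or SyntheticConfig()
    depths = config.first_depth_um + config.spacing_um * np.arange(config.n_channels)
    span_bottom = depths[-1] + config.spacing_um / 2.0
    layers = dict(_DEFAULT_LAYERS)
    if config.n_laminar != len(layers):
        # equal-thickness layers for non-default population counts
        edges = np.linspace(0.0, span_bottom, config.n_laminar + 1)
        layers = {
            f"pop_{i}": (float(edges[i]), float(edges[i + 1]))
            for i in range(config.n_laminar)
        }
    else:
        # stretch the deepest boundary to the probe span bottom
        names = list(layers)
        top, _ = layers[names[-1]]
        layers[names[-1]] = (top, float(max(span_bottom, top + config.spacing_um)))
    return ProbeGeometry(
        depths_um=depths,
        conductivity_s_per_m=config.conductivity_s_per_m,
        disc_radius_um=config.disc_radius_um,
        layer_boundaries_um=layers,
    )


def default_populations(geom: ProbeGeometry, ramp_um: float = 20.0) -> PopulationModel:
    """One trapezoid per layer, supports tiling the layer intervals."""
    profiles, labels = [], []
    for name, (top, bottom) in geom.layer_boundaries_um.items():
        width = bottom - top
        b = min(ramp_um, width / 4.0)
        profiles.append(TrapezoidProfile(z=(top + bottom) / 2.0, a=width - 2 * b, b=b))
        labels.append(name)
    return PopulationModel(tuple(profiles), tuple(labels))


def _alpha(t_ms: np.ndarray, width_ms: float) -> np.ndarray:
    """Alpha function normalized to unit peak at t = width."""
    x = np.clip(t_ms / width_ms, 0.0, None)
    return x * np.exp(1.0 - x)


def _smooth_noise(rng: np.random.Generator, n_bins: int, sd: float, smooth_bins: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n_bins)
    raw = rng.standard_normal(n_bins)
    sm = ndimage.gaussian_filter1d(raw, sigma=smooth_bins, mode="reflect")
    # restore the requested sd after smoothing
    sm *= sd / max(sm.std(), 1e-12)
    return sm


def _rate_template(
    config: SyntheticConfig, baseline: float, amp: float, latency: float
) -> np.ndarray:
    t = config.times_ms
    onset = config.stimulus_onset_ms + latency
    offset = config.stimulus_offset_ms + latency
    return (
        baseline
        + amp * _alpha(t - onset, config.alpha_width_ms)
        + config.offset_amp_fraction * amp * _alpha(t - offset, config.alpha_width_ms)
    )


def make_rates(
    config: SyntheticConfig, seed: int = 0
) -> tuple[RateMatrix, RateMatrix]:
    """Generate laminar and external firing rates.

    Each laminar rate is ``(1 - rho) * private + rho * shared`` where both
    the private and the shared course are a baseline plus evoked alpha
    transients plus smoothed Gaussian variability; pairwise rate
    correlation therefore increases monotonically with rho, reaching
    identical rates at rho = 1. External rates are never mixed.
    """
    rng = np.random.default_rng(seed)
    rho = config.synchrony
    noise = lambda sd=config.rate_noise_sd_hz: _smooth_noise(
        rng, config.n_bins, sd, config.rate_noise_smooth_bins
    )
    shared = _rate_template(
        config,
        baseline=float(np.mean(config.baselines_hz)),
        amp=float(np.mean(config.onset_amps_hz)),
        latency=config.transient_latency_ms,
    ) + noise()
    laminar = []
    for base, amp, lat in zip(config.baselines_hz, config.onset_amps_hz, config.latencies_ms):
        private = _rate_template(config, base, amp, lat) + noise()
        laminar.append((1.0 - rho) * private + rho * shared)
    laminar = np.clip(np.vstack(laminar), 0.0, None)
    geom_layers = tuple(_DEFAULT_LAYERS) if config.n_laminar == len(_DEFAULT_LAYERS) else tuple(
        f"pop_{i}" for i in range(config.n_laminar)
    )
    internal = RateMatrix(
        laminar, dt=config.dt_ms, t0=config.t0_ms, labels=geom_layers
    )
    ext_rows, ext_labels = [], []
    for label, (base, amp, lat) in config.external_structures.items():
        sd = config.rate_noise_sd_hz * (2.0 if amp == 0.0 else 1.0)
        ext_rows.append(np.clip(_rate_template(config, base, amp, lat) + noise(sd), 0.0, None))
        ext_labels.append(label)
    external = RateMatrix(
        np.vstack(ext_rows) if ext_rows else np.zeros((0, config.n_bins)),
        dt=config.dt_ms,
        t0=config.t0_ms,
        labels=tuple(ext_labels),
        external=(True,) * len(ext_labels),
    )
    return internal, external


def make_balanced_profiles(
    config: SyntheticConfig, geom: ProbeGeometry, populations: PopulationModel
) -> np.ndarray:
    """Per-population CSD depth profiles L_true (N_ch x N_pop_total).

    Each profile is a dipole: a sink Gaussian and a source Gaussian, each
    normalized to unit mass on the channel grid, so their difference sums
    to exactly zero across channels. The per-population ``imbalance``
    fraction adds back a scaled sink lobe, giving a controlled nonzero
    channel sum for penalty experiments. Laminar dipoles are centred on
    their trapezoids; external structures target fixed depths (thalamic
    input to mid-depth granular territory, feedback to the upper layers,
    background diffusely at mid-depth).
    """
    z = geom.depths_um
    span_top, span_bottom = geom.span_um
    centres = [p.z for p in populations.profiles]
    for i, _ in enumerate(config.external_structures):
        frac = (0.38, 0.15, 0.55)[i % 3]
        centres.append(span_top + frac * (span_bottom - span_top))
    w = config.field_width_um
    sep = config.dipole_separation_um
    cols = []
    for mu, amp, imb in zip(centres, config.field_amps, config.imbalance):
        sink = np.exp(-0.5 * ((z - (mu - sep / 2.0)) / w) ** 2)
        source = np.exp(-0.5 * ((z - (mu + sep / 2.0)) / w) ** 2)
        sink /= sink.sum()
        source /= source.sum()
        profile = amp * (source - sink)  # superficial sink, deeper source
        profile += imb * amp * sink
        cols.append(profile)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Everything the generator planted, for recovery scoring."""

    config: SyntheticConfig
    geometry: ProbeGeometry
    populations: PopulationModel
    rates_internal: RateMatrix
    rates_external: RateMatrix
    rates_all: RateMatrix
    kernels: KernelParams
    spatial_field: np.ndarray        # L_true, N_ch x N_pop_total
    postsynaptic_temporal: np.ndarray  # R_true, N_pop_total x B
    contributions: np.ndarray        # N_pop_total x N_ch x B
    csd_total: np.ndarray            # noise-free sum of contributions
    mua_total: np.ndarray            # noise-free M^T r

    @property
    def labels(self) -> tuple[str, ...]:
        return self.rates_all.labels


def make_ground_truth(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticGroundTruth:
    """Build the full planted ground truth for the given study conditions."""
    config = config or SyntheticConfig()
    geom = default_geometry(config)
    populations = default_populations(geom, config.ramp_um)
    internal, external = make_rates(config, seed)
    rates_all = append_external_rates(internal, external)
    kernels = KernelParams(
        np.asarray(config.kernel_tau_ms),
        np.asarray(config.kernel_delay_ms),
        labels=rates_all.labels,
    )
    l_true = make_balanced_profiles(config, geom, populations)
    r_true = postsynaptic_profiles(rates_all, kernels)
    contributions = l_true.T[:, :, None] * r_true[:, None, :]
    csd_total = contributions.sum(axis=0)
    m = build_spatial_matrix(populations, geom)
    mua_total = m.T @ internal.values
    return SyntheticGroundTruth(
        config=config,
        geometry=geom,
        populations=populations,
        rates_internal=internal,
        rates_external=external,
        rates_all=rates_all,
        kernels=kernels,
        spatial_field=l_true,
        postsynaptic_temporal=r_true,
        contributions=contributions,
        csd_total=csd_total,
        mua_total=mua_total,
    )


@dataclass(frozen=True)
class SyntheticRecordings:
    """Observable signals generated from a ground truth."""

    truth: SyntheticGroundTruth
    mua: RecordingMatrix            # trial-averaged MUA envelope (a.u.)
    mua_trials: np.ndarray          # trials x channels x bins
    csd: RecordingMatrix            # total CSD including measurement noise
    lfp: RecordingMatrix            # disc-forward LFP of the stored CSD
    spikes: pd.DataFrame            # columns population_id, trial, time_ms


def make_recordings(truth: SyntheticGroundTruth, seed: int = 0) -> SyntheticRecordings:
    """Draw observable recordings (and Poisson spikes) from a ground truth.

    With zero measurement noise the stored CSD equals the planted total
    exactly and the stored LFP is its disc-forward image, so inverse-CSD
    recovery is exact by construction.
    """
    config = truth.config
    rng = np.random.default_rng(seed)
    shape = truth.mua_total.shape
    mua_trials = truth.mua_total[None] + config.mua_noise_sd * rng.standard_normal(
        (config.n_trials, *shape)
    )
    mua = RecordingMatrix(
        mua_trials.mean(axis=0), dt=config.dt_ms, t0=config.t0_ms, kind=SignalKind.MUA
    )
    csd_values = truth.csd_total + config.csd_noise_sd * rng.standard_normal(shape)
    csd = RecordingMatrix(csd_values, dt=config.dt_ms, t0=config.t0_ms, kind=SignalKind.CSD)
    lfp = forward_lfp_from_csd(csd, truth.geometry)
    records: list[tuple[str, int, float]] = []
    dt_s = config.dt_ms / 1000.0
    times = truth.rates_internal.times
    for label, rate in zip(truth.rates_internal.labels, truth.rates_internal.values):
        lam = rate * dt_s * config.cells_per_population
        for trial in range(config.n_trials):
            counts = rng.poisson(lam)
            for b in np.flatnonzero(counts):
                for t_spike in times[b] + config.dt_ms * rng.random(counts[b]):
                    records.append((label, trial, float(t_spike)))
    spikes = pd.DataFrame(records, columns=["population_id", "trial", "time_ms"])
    return SyntheticRecordings(
        truth=truth, mua=mua, mua_trials=mua_trials, csd=csd, lfp=lfp, spikes=spikes
    )
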