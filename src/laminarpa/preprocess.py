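"""Band splitting, MUA envelope, trial averaging, and spike-derived rates.

The extracellular potential (ECP) is split at a cutoff frequency (default
300 Hz) with a zero-phase Butterworth filter: the low band is the local
field potential (LFP), the high band reflects multi-unit activity (MUA).
The MUA is rectified and smoothed into a non-negative envelope suitable for
the spatiotemporal factor model, and population firing rates are estimated
from spike event lists as smoothed per-cell spike-count histograms.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .containers import RateMatrix, RecordingMatrix, SignalKind, trial_stack

__all__ = [
    "split_bands",
    "mua_envelope",
    "trial_average",
    "firing_rate_from_spikes",
]


def _butter_sos(cutoff_hz: float, fs_hz: float, order: int, btype: str) -> np.ndarray:
    nyq = fs_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is at or above Nyquist ({nyq} Hz); "
            "increase the sampling rate or lower the cutoff"
        )
    return signal.butter(order, cutoff_hz, btype=btype, fs=fs_hz, output="sos")


def split_bands(
    ecp: RecordingMatrix, cutoff_hz: float = 300.0, order: int = 5
) -> tuple[RecordingMatrix, RecordingMatrix]:
    """Split the ECP into LFP (low-pass) and raw MUA (high-pass) bands.

    Both filters are order-``order`` Butterworth designs applied
    forward-backward (zero phase), so band outputs are not delayed with
    respect to the input.

    Returns
    -------
    (lfp, mua_raw)
        ``lfp`` carries kind LFP; ``mua_raw`` carries kind MUA and is the
        signed high-pass signal (see :func:`mua_envelope`).
    """
    if ecp.kind is not SignalKind.ECP:
        raise ValueError(f"expected an ECP matrix, got kind={ecp.kind.value}")
    fs = ecp.fs_hz
    low = signal.sosfiltfilt(_butter_sos(cutoff_hz, fs, order, "lowpass"), ecp.values, axis=1)
    high = signal.sosfiltfilt(_butter_sos(cutoff_hz, fs, order, "highpass"), ecp.values, axis=1)
    return (
        ecp.with_values(low, kind=SignalKind.LFP),
        ecp.with_values(high, kind=SignalKind.MUA),
    )


def mua_envelope(mua_raw: RecordingMatrix, smooth_ms: float = 2.0) -> RecordingMatrix:
    """Non-negative MUA envelope: |high-pass signal| smoothed by a Gaussian.

    The high-pass band is rectified (absolute value) and low-pass smoothed
    with a Gaussian of standard deviation ``smooth_ms`` (reflect padding at
    the trial edges), yielding the slowly varying, non-negative signal the
    population factor model is fitted to.
    """
    if mua_raw.kind is not SignalKind.MUA:
        raise ValueError(f"expected a MUA matrix, got kind={mua_raw.kind.value}")
    if smooth_ms <= 0:
        raise ValueError(f"smooth_ms must be positive, got {smooth_ms}")
    sigma_bins = smooth_ms / mua_raw.dt
    env = ndimage.gaussian_filter1d(
        np.abs(mua_raw.values), sigma=sigma_bins, axis=1, mode="reflect"
    )
    return mua_raw.with_values(env, kind=SignalKind.MUA)


def trial_average(trials: Sequence[RecordingMatrix]) -> RecordingMatrix:
    """Element-wise mean across trials (all trials must share shape/dt/t0)."""
    stacked = trial_stack(trials)
    return trials[0].with_values(stacked.mean(axis=0))


def firing_rate_from_spikes(
    events: pd.DataFrame,
    populations: Sequence[str],
    t0_ms: float,
    n_bins: int,
    bin_ms: float = 1.0,
    gauss_sigma_bins: float = 2.0,
    n_trials: int | None = None,
    cells_per_population: Mapping[str, int] | None = None,
) -> RateMatrix:
    """Population firing rates from spike events.

    Spike counts are histogrammed per population at ``bin_ms`` resolution,
    Gaussian-smoothed along time with ``gauss_sigma_bins`` bins standard
    deviation, averaged over trials, and scaled to spikes/s per cell when
    ``cells_per_population`` is given (otherwise per-population total
    spikes/s).

    Parameters
    ----------
    events
        DataFrame with columns ``population_id``, ``trial``, ``time_ms``.
    populations
        Ordered population labels defining the row order of the output.
    t0_ms, n_bins, bin_ms
        Time base of the output rate matrix.
    n_trials
        Number of trials to average over; inferred from the events when
        omitted (max trial index + 1).
    """
    required = {"population_id", "trial", "time_ms"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events missing columns: {sorted(missing)}")
    known = set(populations)
    unknown = set(events["population_id"].unique()) - known
    if unknown:
        raise ValueError(f"unknown population labels in events: {sorted(unknown)}")
    if n_trials is None:
        n_trials = int(events["trial"].max()) + 1 if len(events) else 1
    edges = t0_ms + bin_ms * np.arange(n_bins + 1)
    tmin, tmax = edges[0], edges[-1]
    out = np.zeros((len(populations), n_bins))
    for row, pop in enumerate(populations):
        times = events.loc[events["population_id"] == pop, "time_ms"].to_numpy(float)
        if times.size and (times.min() < tmin or times.max() > tmax):
            raise ValueError(
                f"population {pop!r} has spikes outside the recording window "
                f"[{tmin}, {tmax}] ms"
            )
        counts, _ = np.histogram(times, bins=edges)
        out[row] = counts
    out = ndimage.gaussian_filter1d(out, sigma=gauss_sigma_bins, axis=1, mode="reflect")
    # counts/bin -> spikes/s, averaged over trials (and cells when known)
    out *= 1000.0 / bin_ms / n_trials
    if cells_per_population is not None:
        for row, pop in enumerate(populations):
            out[row] /= cells_per_population[pop]
    return RateMatrix(out, dt=bin_ms, t0=t0_ms, labels=tuple(populations))
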