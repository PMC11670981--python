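"""File formats, result bundles, and pipeline orchestration.

On-disk conventions (all language-portable):

* **Recordings** — HDF5 with one dataset per signal kind (``ecp``, ``mua``,
  ``lfp``, ``csd``), each either trials x channels x bins or channels x
  bins, plus ``depths_um`` and root attributes ``dt_ms`` / ``t0_ms``. A
  CSV matrix (channels x bins) is accepted for single-trial data.
* **Geometry** — YAML mirroring :class:`ProbeGeometry` (depths, sigma, disc
  radius, optional layer boundaries).
* **Spike events** — tab-delimited text with columns ``population_id``,
  ``trial``, ``time_ms``.
* **Result bundle** — HDF5 with groups ``/spatial`` (trapezoid parameters
  and profile matrices), ``/temporal`` (rates, kernels, postsynaptic
  profiles), ``/contributions``, ``/metrics``.

Depths are um from the cortical surface downward; channel index 0 is the
most superficial contact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .config import AnalysisConfig, CsdMethod
from .containers import ProbeGeometry, RateMatrix, RecordingMatrix, SignalKind
from .core import (
    DecompositionResult,
    KernelParams,
    MuaFit,
    PopulationModel,
    TrapezoidProfile,
    append_external_rates,
    fit_csd,
    fit_mua,
)
from .csd import delta_icsd, traditional_csd
from .preprocess import mua_envelope, split_bands, trial_average

__all__ = [
    "TrialEnsemble",
    "load_geometry",
    "save_geometry",
    "load_recording",
    "save_recording",
    "load_spikes",
    "save_spikes",
    "save_bundle",
    "load_bundle",
    "preprocess_ecp",
    "estimate_csd",
    "run_pipeline",
]

_SIGNAL_KEYS = {"ecp": SignalKind.ECP, "mua": SignalKind.MUA,
                "lfp": SignalKind.LFP, "csd": SignalKind.CSD}


@dataclass(frozen=True)
class TrialEnsemble:
    """Stimulus-aligned trials of one signal kind plus the probe geometry."""

    trials: tuple[RecordingMatrix, ...]
    geometry: ProbeGeometry

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def kind(self) -> SignalKind:
        return self.trials[0].kind


# ---------------------------------------------------------------------------
# geometry and spikes
# ---------------------------------------------------------------------------

def save_geometry(geom: ProbeGeometry, path: str | Path) -> None:
    data: dict = {
        "depths_um": [float(d) for d in geom.depths_um],
        "conductivity_s_per_m": float(geom.conductivity_s_per_m),
        "disc_radius_um": float(geom.disc_radius_um),
    }
    if geom.layer_boundaries_um is not None:
        data["layer_boundaries_um"] = {
            name: [float(top), float(bottom)]
            for name, (top, bottom) in geom.layer_boundaries_um.items()
        }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_geometry(path: str | Path) -> ProbeGeometry:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "depths_um" not in data:
        raise ValueError(f"geometry file {path} must define 'depths_um'")
    layers = data.get("layer_boundaries_um")
    return ProbeGeometry(
        depths_um=np.asarray(data["depths_um"], float),
        conductivity_s_per_m=float(data.get("conductivity_s_per_m", 0.3)),
        disc_radius_um=float(data.get("disc_radius_um", 400.0)),
        layer_boundaries_um={k: (float(v[0]), float(v[1])) for k, v in layers.items()}
        if layers
        else None,
    )


def save_spikes(events: pd.DataFrame, path: str | Path) -> None:
    events[["population_id", "trial", "time_ms"]].to_csv(path, sep="\t", index=False)


def load_spikes(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = {"population_id", "trial", "time_ms"} - set(events.columns)
    if missing:
        raise ValueError(f"spike file {path} missing columns: {sorted(missing)}")
    return events


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def save_recording(
    path: str | Path,
    signals: dict[str, np.ndarray],
    geometry: ProbeGeometry,
    dt_ms: float,
    t0_ms: float = 0.0,
) -> None:
    """Write signal arrays (trials x channels x bins, or channels x bins)
    keyed by kind name ('ecp', 'mua', 'lfp', 'csd') into one HDF5 file."""
    unknown = set(signals) - set(_SIGNAL_KEYS)
    if unknown:
        raise ValueError(f"unknown signal keys: {sorted(unknown)}")
    with h5py.File(path, "w") as f:
        for key, values in signals.items():
            values = np.asarray(values, float)
            if values.ndim not in (2, 3):
                raise ValueError(f"signal {key!r} must be 2-D or 3-D")
            f.create_dataset(key, data=values)
        f.create_dataset("depths_um", data=geometry.depths_um)
        f.attrs["dt_ms"] = float(dt_ms)
        f.attrs["t0_ms"] = float(t0_ms)


def load_recording(
    path: str | Path,
    geometry_path: str | Path,
    kind: str = "ecp",
    dt_ms: float | None = None,
    t0_ms: float = 0.0,
) -> TrialEnsemble:
    """Load a trial ensemble of one signal kind.

    HDF5 files carry their own time base and may hold several trials; a
    CSV file is read as a single channels x bins matrix of the requested
    kind and requires ``dt_ms``. The matrix row count must equal the
    geometry's channel count.
    """
    path = Path(path)
    geom = load_geometry(geometry_path)
    if kind not in _SIGNAL_KEYS:
        raise ValueError(f"unknown signal kind {kind!r}")
    sig_kind = _SIGNAL_KEYS[kind]
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if kind not in f:
                raise ValueError(f"{path} has no dataset {kind!r}")
            values = np.asarray(f[kind], float)
            dt = float(f.attrs["dt_ms"])
            t0 = float(f.attrs["t0_ms"])
            if "depths_um" in f and not np.allclose(f["depths_um"], geom.depths_um):
                raise ValueError(f"{path}: stored depths differ from the geometry file")
    else:
        if dt_ms is None:
            raise ValueError("dt_ms is required when loading a CSV matrix")
        values = pd.read_csv(path, header=None).to_numpy(float)
        dt, t0 = dt_ms, t0_ms
    if values.ndim == 2:
        values = values[None]
    if values.shape[1] != geom.n_channels:
        raise ValueError(
            f"recording has {values.shape[1]} channels but the geometry "
            f"defines {geom.n_channels}"
        )
    trials = tuple(
        RecordingMatrix(v, dt=dt, t0=t0, kind=sig_kind) for v in values
    )
    return TrialEnsemble(trials=trials, geometry=geom)


# ---------------------------------------------------------------------------
# result bundle
# ---------------------------------------------------------------------------

def save_bundle(
    path: str | Path,
    result: DecompositionResult | None = None,
    mua_fit: MuaFit | None = None,
    config: AnalysisConfig | None = None,
) -> None:
    """Write fit results into the standard HDF5 bundle layout."""
    with h5py.File(path, "w") as f:
        spatial = f.create_group("spatial")
        temporal = f.create_group("temporal")
        metrics = f.create_group("metrics")
        if config is not None:
            f.attrs["config_json"] = json.dumps(config.to_dict())
        if mua_fit is not None:
            spatial.create_dataset("mua_profiles", data=mua_fit.spatial)
            spatial.create_dataset(
                "trapezoids",
                data=np.array([[p.z, p.a, p.b] for p in mua_fit.model.profiles]),
            )
            spatial["trapezoids"].attrs["columns"] = ["z_um", "a_um", "b_um"]
            temporal.create_dataset("rates", data=mua_fit.rates.values)
            temporal["rates"].attrs["labels"] = list(mua_fit.rates.labels)
            temporal["rates"].attrs["dt_ms"] = mua_fit.rates.dt
            temporal["rates"].attrs["t0_ms"] = mua_fit.rates.t0
            metrics.attrs["e_M"] = mua_fit.error
            metrics.attrs["mua_converged"] = mua_fit.converged
        if result is not None:
            spatial.create_dataset("field_profiles", data=result.spatial_field)
            temporal.create_dataset("postsynaptic", data=result.postsynaptic_temporal)
            temporal.create_dataset("presynaptic_rates", data=result.rates.values)
            temporal["presynaptic_rates"].attrs["labels"] = list(result.rates.labels)
            temporal["presynaptic_rates"].attrs["external"] = [
                bool(e) for e in result.rates.external
            ]
            temporal.create_dataset("kernel_tau_ms", data=result.kernels.tau_ms)
            temporal.create_dataset("kernel_delay_ms", data=result.kernels.delay_ms)
            contrib = f.create_group("contributions")
            contrib.create_dataset("data", data=result.contributions)
            contrib.attrs["labels"] = list(result.labels)
            f.create_dataset("reconstruction", data=result.reconstruction)
            metrics.attrs["e_C"] = result.error
            metrics.attrs["mse"] = result.mse
            metrics.attrs["correlation"] = result.correlation
            metrics.attrs["channel_sum_dev"] = result.channel_sum_dev
            metrics.attrs["lambda"] = result.lambda_penalty
            metrics.attrs["csd_converged"] = result.converged


def load_bundle(path: str | Path) -> dict:
    """Read a result bundle back into plain arrays and metadata."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "config_json" in f.attrs:
            out["config"] = AnalysisConfig.from_dict(json.loads(f.attrs["config_json"]))
        for group in ("spatial", "temporal", "contributions"):
            if group in f:
                out[group] = {k: np.asarray(v) for k, v in f[group].items()}
                out[group].update(
                    {f"{k}:{a}": v for k in f[group]
                     for a, v in f[group][k].attrs.items()}
                )
        if "reconstruction" in f:
            out["reconstruction"] = np.asarray(f["reconstruction"])
        if "metrics" in f:
            out["metrics"] = dict(f["metrics"].attrs)
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def preprocess_ecp(
    ensemble: TrialEnsemble, config: AnalysisConfig
) -> tuple[RecordingMatrix, RecordingMatrix]:
    """Raw ECP trials -> (trial-averaged MUA envelope, trial-averaged LFP)."""
    mua_trials, lfp_trials = [], []
    for trial in ensemble.trials:
        lfp, mua_raw = split_bands(trial, config.cutoff_hz, config.filter_order)
        mua_trials.append(mua_envelope(mua_raw, config.mua_smooth_ms))
        lfp_trials.append(lfp)
    return trial_average(mua_trials), trial_average(lfp_trials)


def estimate_csd(
    lfp: RecordingMatrix, geom: ProbeGeometry, config: AnalysisConfig
) -> RecordingMatrix:
    """LFP -> CSD with the configured estimator (config may override the
    geometry's disc radius / conductivity)."""
    geom = ProbeGeometry(
        depths_um=geom.depths_um,
        conductivity_s_per_m=config.conductivity_s_per_m,
        disc_radius_um=config.disc_radius_um,
        layer_boundaries_um=geom.layer_boundaries_um,
    )
    if config.csd_method is CsdMethod.DELTA_ICSD:
        return delta_icsd(lfp, geom)
    return traditional_csd(lfp, geom)


@dataclass(frozen=True)
class PipelineResult:
    mua_fit: MuaFit
    decomposition: DecompositionResult


def run_pipeline(
    config: AnalysisConfig,
    geom: ProbeGeometry,
    mua: RecordingMatrix,
    field: RecordingMatrix,
    external_rates: RateMatrix | None = None,
) -> PipelineResult:
    """Run the full decomposition on preprocessed, trial-averaged inputs.

    Steps: trapezoid/rate fit on the MUA envelope; optional appending of
    external-structure rates; kernel fit and contribution reconstruction
    on the field (an LFP input is first converted to CSD with the
    configured estimator). Deterministic for a fixed ``rng_seed``.
    """
    if field.kind is SignalKind.LFP:
        field = estimate_csd(field, geom, config)
    mua_fit = fit_mua(mua, geom, config)
    rates = mua_fit.rates
    if geom.layer_boundaries_um is not None:
        from .core import population_layer_labels

        labels = population_layer_labels(mua_fit.model, geom)
        rates = RateMatrix(rates.values, dt=rates.dt, t0=rates.t0, labels=labels)
    if external_rates is not None:
        rates = append_external_rates(rates, external_rates)
    decomposition = fit_csd(field, rates, config)
    result = PipelineResult(mua_fit=mua_fit, decomposition=decomposition)
    return result
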