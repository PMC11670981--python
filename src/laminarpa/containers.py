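"""Core in-memory containers for laminar recordings.

The package operates on channels-by-time matrices sampled along a laminar
probe. Three containers anchor everything else:

``RecordingMatrix``
    A single N_ch x B signal matrix (extracellular potential, MUA envelope,
    LFP, or CSD) with its time base (bin width ``dt`` in ms, first-bin time
    ``t0`` relative to stimulus onset).
``RateMatrix``
    Per-population firing-rate time courses (N_pop x B), with labels and an
    internal/external flag per row.
``ProbeGeometry``
    Channel depths, tissue conductivity, disc radius for the inverse-CSD
    forward model, and optional named layer boundaries.

Depths are in micrometres, increasing from the cortical surface downward;
channel index 0 is the most superficial contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np


class SignalKind(str, Enum):
    """What a RecordingMatrix holds."""

    ECP = "ECP"
    MUA = "MUA"
    LFP = "LFP"
    CSD = "CSD"


@dataclass(frozen=True)
class RecordingMatrix:
    """A channels x time-bins signal with a stimulus-aligned time axis.

    Parameters
    ----------
    values
        Real matrix of shape (N_ch, B). Units are uV for ECP/LFP/MUA and
        planar current-source density (a.u.) for CSD.
    dt
        Bin width in ms (> 0).
    t0
        Time of the first bin relative to stimulus onset, in ms.
    kind
        One of :class:`SignalKind`.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    kind: SignalKind = SignalKind.ECP

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D (channels x bins), got ndim={v.ndim}")
        if v.shape[1] < 2:
            raise ValueError(f"need at least 2 time bins, got {v.shape[1]}")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite entries")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "kind", SignalKind(self.kind))

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Bin times in ms relative to stimulus onset."""
        return self.t0 + self.dt * np.arange(self.n_bins)

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz implied by the bin width."""
        return 1000.0 / self.dt

    def with_values(self, values: np.ndarray, kind: SignalKind | None = None) -> "RecordingMatrix":
        return replace(self, values=values, kind=self.kind if kind is None else kind)


@dataclass(frozen=True)
class RateMatrix:
    """Per-population firing-rate time courses (N_pop x B).

    Rates are in spikes/s when derived from spike trains, or MUA-scaled
    arbitrary units when inferred from the MUA decomposition. ``external``
    flags rows that come from structures outside the recorded area and are
    therefore exempt from the spatial (trapezoid) model.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    labels: tuple[str, ...] = ()
    external: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(v)):
            raise ValueError("rates contain non-finite entries")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        labels = tuple(self.labels) if self.labels else tuple(f"pop_{i}" for i in range(v.shape[0]))
        external = tuple(self.external) if self.external else (False,) * v.shape[0]
        if len(labels) != v.shape[0]:
            raise ValueError(f"{len(labels)} labels for {v.shape[0]} rate rows")
        if len(external) != v.shape[0]:
            raise ValueError("external flags must match row count")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "external", external)

    @property
    def n_populations(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_bins)

    def same_timebase(self, other: "RateMatrix | RecordingMatrix") -> bool:
        return (
            np.isclose(self.dt, other.dt)
            and np.isclose(self.t0, other.t0)
            and self.n_bins == other.values.shape[1]
        )


@dataclass(frozen=True)
class ProbeGeometry:
    """Laminar probe geometry and volume-conductor parameters.

    Parameters
    ----------
    depths_um
        Strictly increasing channel depths in um (surface -> deep).
    conductivity_s_per_m
        Extracellular conductivity sigma in S/m (cortical grey matter is
        conventionally ~0.3 S/m).
    disc_radius_um
        Radius R of the constant-CSD discs assumed by the delta inverse-CSD
        forward model.
    layer_boundaries_um
        Optional ordered mapping layer name -> (top, bottom) in um; intervals
        must be non-overlapping and ordered by depth. Used for channel-layer
        classification metrics.
    """

    depths_um: np.ndarray
    conductivity_s_per_m: float = 0.3
    disc_radius_um: float = 400.0
    layer_boundaries_um: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_um, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("depths_um must be a 1-D array of >= 2 depths")
        if not np.all(np.diff(d) > 0):
            raise ValueError("channel depths must be strictly increasing (surface to deep)")
        if self.conductivity_s_per_m <= 0:
            raise ValueError("conductivity must be positive")
        if self.disc_radius_um <= 0:
            raise ValueError("disc radius must be positive")
        if self.layer_boundaries_um is not None:
            lb = dict(self.layer_boundaries_um)
            prev_bottom = -np.inf
            for name, (top, bottom) in lb.items():
                if not top < bottom:
                    raise ValueError(f"layer {name!r}: top must be above bottom")
                if top < prev_bottom:
                    raise ValueError(f"layer {name!r} overlaps the previous layer")
                prev_bottom = bottom
            object.__setattr__(self, "layer_boundaries_um", lb)
        object.__setattr__(self, "depths_um", d)

    @property
    def n_channels(self) -> int:
        return self.depths_um.size

    @property
    def spacing_um(self) -> float:
        """Inter-channel spacing; raises for non-uniform probes."""
        diffs = np.diff(self.depths_um)
        if not np.allclose(diffs, diffs[0]):
            raise ValueError("probe has non-uniform channel spacing")
        return float(diffs[0])

    @property
    def span_um(self) -> tuple[float, float]:
        """Probe span (top, bottom) in um, extended by half a spacing on
        each end so that populations may cover the outermost contacts."""
        d = self.depths_um
        half_top = (d[1] - d[0]) / 2.0
        half_bot = (d[-1] - d[-2]) / 2.0
        return float(d[0] - half_top), float(d[-1] + half_bot)

    @property
    def layer_names(self) -> tuple[str, ...]:
        if self.layer_boundaries_um is None:
            raise ValueError("geometry has no layer boundaries")
        return tuple(self.layer_boundaries_um)

    def layer_of_depth(self, depth_um: float) -> str:
        """Layer containing ``depth_um`` ([top, bottom); last layer closed)."""
        if self.layer_boundaries_um is None:
            raise ValueError("geometry has no layer boundaries")
        items = list(self.layer_boundaries_um.items())
        for i, (name, (top, bottom)) in enumerate(items):
            closed_right = i == len(items) - 1
            if top <= depth_um < bottom or (closed_right and np.isclose(depth_um, bottom)):
                return name
        raise ValueError(f"depth {depth_um} um lies outside all layer boundaries")


def trial_stack(trials: Sequence[RecordingMatrix]) -> np.ndarray:
    """Stack a list of equally-shaped trials into trials x channels x bins."""
    if len(trials) == 0:
        raise ValueError("empty trial list")
    first = trials[0]
    for t in trials[1:]:
        if t.values.shape != first.values.shape:
            raise ValueError("trials differ in shape")
        if not (np.isclose(t.dt, first.dt) and np.isclose(t.t0, first.t0)):
            raise ValueError("trials differ in time base")
    return np.stack([t.values for t in trials], axis=0)
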