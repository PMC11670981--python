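"""Current source density estimation along a laminar probe.

Two estimators are provided. The delta inverse-CSD method models the CSD as
a set of infinitely thin current discs of radius R centred at each channel
depth; the LFP generated by those discs is a linear map ``phi = F c`` with

    F[j, i] = 1 / (2 sigma) * (sqrt(R^2 + (z_j - z_i)^2) - |z_j - z_i|)

and the CSD estimate is the inverse map applied to the LFP per time bin.
The traditional estimator multiplies the discrete second spatial derivative
of the LFP with the negative conductivity and is only defined on interior
channels of a uniformly spaced probe.

Sign convention: current sinks are negative, sources positive.
"""

from __future__ import annotations

import numpy as np

from .containers import ProbeGeometry, RecordingMatrix, SignalKind

__all__ = [
    "forward_matrix",
    "delta_icsd",
    "forward_lfp_from_csd",
    "traditional_csd",
    "channel_sum_deviation",
]

_UM_PER_M = 1e6

#: delta-iCSD forward matrices with condition number above this raise.
MAX_CONDITION_NUMBER = 1e12


def forward_matrix(geom: ProbeGeometry) -> np.ndarray:
    """Disc-source forward matrix F (N_ch x N_ch), in V per (A/m^2).

    Entry (j, i) is the potential at channel j produced by a disc of unit
    planar current density at channel i's depth.
    """
    z = geom.depths_um / _UM_PER_M
    r = geom.disc_radius_um / _UM_PER_M
    h = np.abs(z[:, None] - z[None, :])
    return (np.sqrt(r**2 + h**2) - h) / (2.0 * geom.conductivity_s_per_m)


def delta_icsd(lfp: RecordingMatrix, geom: ProbeGeometry) -> RecordingMatrix:
    """Delta inverse-CSD estimate: solve ``F c = phi`` per time bin.

    Output units are planar current-source density (current per area per
    disc); the decomposition uses CSD only up to a consistent scale.
    """
    if lfp.kind is not SignalKind.LFP:
        raise ValueError(f"expected an LFP matrix, got kind={lfp.kind.value}")
    if lfp.n_channels != geom.n_channels:
        raise ValueError(
            f"LFP has {lfp.n_channels} channels but geometry has {geom.n_channels}"
        )
    if geom.n_channels < 2:
        raise ValueError("delta iCSD needs at least 2 channels")
    f = forward_matrix(geom)
    cond = np.linalg.cond(f)
    if cond > MAX_CONDITION_NUMBER:
        raise np.linalg.LinAlgError(
            f"delta-iCSD forward matrix is ill-conditioned (cond={cond:.3g}); "
            "check disc radius and channel spacing"
        )
    csd = np.linalg.solve(f, lfp.values)
    return lfp.with_values(csd, kind=SignalKind.CSD)


def forward_lfp_from_csd(csd: RecordingMatrix, geom: ProbeGeometry) -> RecordingMatrix:
    """LFP generated by a disc-CSD profile: ``phi = F c`` (inverse of
    :func:`delta_icsd` on the same geometry)."""
    if csd.kind is not SignalKind.CSD:
        raise ValueError(f"expected a CSD matrix, got kind={csd.kind.value}")
    if csd.n_channels != geom.n_channels:
        raise ValueError(
            f"CSD has {csd.n_channels} channels but geometry has {geom.n_channels}"
        )
    return csd.with_values(forward_matrix(geom) @ csd.values, kind=SignalKind.LFP)


def traditional_csd(lfp: RecordingMatrix, geom: ProbeGeometry) -> RecordingMatrix:
    """Traditional CSD: negative conductivity times the discrete second
    spatial derivative of the LFP.

    Only interior channels are estimated; the output has N_ch - 2 rows
    corresponding to ``geom.depths_um[1:-1]``. Requires uniform spacing.
    """
    if lfp.kind is not SignalKind.LFP:
        raise ValueError(f"expected an LFP matrix, got kind={lfp.kind.value}")
    if lfp.n_channels != geom.n_channels:
        raise ValueError(
            f"LFP has {lfp.n_channels} channels but geometry has {geom.n_channels}"
        )
    if geom.n_channels < 3:
        raise ValueError("traditional CSD needs at least 3 channels")
    try:
        dz = geom.spacing_um / _UM_PER_M
    except ValueError as err:
        raise ValueError(
            "traditional CSD requires uniform channel spacing; "
            "use delta_icsd for non-uniform probes"
        ) from err
    phi = lfp.values
    d2 = (phi[2:] - 2.0 * phi[1:-1] + phi[:-2]) / dz**2
    return lfp.with_values(-geom.conductivity_s_per_m * d2, kind=SignalKind.CSD)


def channel_sum_deviation(csd: RecordingMatrix | np.ndarray) -> float:
    """Deviation from zero of the CSD summed across channels.

    Kirchhoff's current law requires transmembrane currents to balance, so a
    physical CSD should sum to ~0 across depth at every instant. The
    diagnostic is the time-averaged absolute channel sum,

        (1/B) * sum_j | sum_i C(z_i, t_j) |,

    normalized to the maximum absolute CSD value. Zero for a perfectly
    balanced CSD; defined as 0 for an identically zero CSD.
    """
    values = csd.values if isinstance(csd, RecordingMatrix) else np.asarray(csd, float)
    if isinstance(csd, RecordingMatrix) and csd.kind is not SignalKind.CSD:
        raise ValueError(f"expected a CSD matrix, got kind={csd.kind.value}")
    peak = np.max(np.abs(values))
    if peak == 0.0:
        return 0.0
    return float(np.mean(np.abs(values.sum(axis=0))) / peak)
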