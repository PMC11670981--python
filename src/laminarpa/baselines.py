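"""PCA and ICA baselines for blind spatiotemporal CSD decomposition.

Both operate on the channels x time CSD matrix with the time-mean removed
per channel. PCA returns the rank-k singular-value decomposition (spatial
maps orthogonal, explained variance non-increasing); ICA extracts k
maximally independent temporal sources with their spatial mixing maps
(component order and sign carry no meaning). Each component's CSD is the
outer product of its spatial map and temporal course, so summing all
min-dimension PCA components (plus the channel means) restores the input
exactly. These are comparison points for the population decomposition,
not part of the method itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .containers import RecordingMatrix

__all__ = ["ComponentSet", "decompose_pca", "decompose_ica"]


@dataclass(frozen=True)
class ComponentSet:
    """k spatial maps with their temporal courses and component CSDs."""

    method: str
    spatial: np.ndarray            # N_ch x k
    temporal: np.ndarray           # k x B
    channel_means: np.ndarray      # N_ch (removed before decomposition)
    explained_variance: np.ndarray | None = None  # PCA only, fractions
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.spatial.shape[1]

    @property
    def component_csd(self) -> np.ndarray:
        """Per-component CSD matrices, shape (k, N_ch, B)."""
        return self.spatial.T[:, :, None] * self.temporal[:, None, :]

    def reconstruction(self, include_mean: bool = True) -> np.ndarray:
        rec = self.component_csd.sum(axis=0)
        return rec + self.channel_means[:, None] if include_mean else rec


def _centred(c: RecordingMatrix) -> tuple[np.ndarray, np.ndarray]:
    means = c.values.mean(axis=1)
    return c.values - means[:, None], means


def decompose_pca(c: RecordingMatrix, k: int) -> ComponentSet:
    """Rank-k SVD of the per-channel-centred CSD.

    Spatial maps are the left singular vectors; temporal courses carry the
    singular values. Explained-variance fractions are reported per
    component.
    """
    if not 1 <= k <= min(c.n_channels, c.n_bins):
        raise ValueError(
            f"k must be in [1, {min(c.n_channels, c.n_bins)}], got {k}"
        )
    x, means = _centred(c)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    ev = s**2 / np.sum(s**2) if np.any(s) else np.zeros_like(s)
    return ComponentSet(
        method="pca",
        spatial=u[:, :k],
        temporal=s[:k, None] * vt[:k],
        channel_means=means,
        explained_variance=ev[:k],
    )


def decompose_ica(
    c: RecordingMatrix, k: int, seed: int = 0, max_iter: int = 1000, tol: float = 1e-6
) -> ComponentSet:
    """FastICA of the per-channel-centred CSD: k independent temporal
    sources (rows) with spatial mixing maps (columns).

    Deterministic for a fixed seed. Non-convergence within ``max_iter``
    fixed-point iterations produces a warning and a result flagged
    ``converged=False``.
    """
    if not 1 <= k <= c.n_channels:
        raise ValueError(f"k must be in [1, {c.n_channels}], got {k}")
    x, means = _centred(c)
    ica = FastICA(n_components=k, random_state=seed, max_iter=max_iter, tol=tol)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(x.T).T  # samples = time bins
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
            warnings.warn(
                f"ICA did not converge in {max_iter} iterations; "
                "returning the partial result",
                stacklevel=2,
            )
    return ComponentSet(
        method="ica",
        spatial=ica.mixing_,
        temporal=sources,
        channel_means=means,
        converged=converged,
    )
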