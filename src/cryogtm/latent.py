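"""Latent grid and nonlinear basis expansion.

The generative topographic mapping places K nodes on a regular grid in a
low-dimensional (1-3D) latent space and maps them through a basis expansion

    A(s; W) = Phi(s) W

into the Fourier data space.  Phi holds M_NL Gaussian bumps

    phi_m(s_k) = exp(-||s_k - mu_m||^2 / (2 sigma^2))

plus one constant basis function (the bias), so M = M_NL + 1.  Adjacent
latent nodes share basis support, which is what makes the mapped manifold
smooth and the clustering topographic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError

__all__ = ["LatentGrid", "BasisMatrix", "build_latent_grid", "build_basis"]

#: hard cap on the number of latent nodes accepted by :func:`build_latent_grid`
MAX_NODES_DEFAULT = 100_000


@dataclass(frozen=True)
class LatentGrid:
    """Regular grid of latent nodes with a uniform delta-sum prior.

    Nodes have unit spacing along every axis and are enumerated in row-major
    (raster) order over the axes in declaration order, so node k maps stably
    to class index k.
    """

    shape: tuple[int, ...]
    nodes: np.ndarray = field(repr=False)  # (K, L) float64

    @property
    def dims(self) -> int:
        return len(self.shape)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def prior_weight(self) -> float:
        """Uniform prior mass per node, 1/K."""
        return 1.0 / self.n_nodes


@dataclass(frozen=True)
class BasisMatrix:
    """Evaluated basis expansion Phi, shape (K, M_NL + 1).

    The last column is the constant basis (all ones); the first ``n_gaussian``
    columns are Gaussian bumps of common width ``width`` centred at
    ``centers``.
    """

    centers: np.ndarray = field(repr=False)  # (M_NL, L)
    width: float
    values: np.ndarray = field(repr=False)  # (K, M)

    @property
    def n_gaussian(self) -> int:
        return self.centers.shape[0]

    @property
    def n_total(self) -> int:
        return self.values.shape[1]


def build_latent_grid(shape, max_nodes: int = MAX_NODES_DEFAULT) -> LatentGrid:
    """Build a regular latent grid with unit node spacing.

    Parameters
    ----------
    shape
        Per-dimension node counts; between 1 and 3 dimensions, every count
        >= 1, product (the class number K) at most ``max_nodes``.
    """
    shape = tuple(int(c) for c in shape)
    if not 1 <= len(shape) <= 3:
        raise ConfigurationError(
            f"latent grid must have 1-3 dimensions, got shape {shape!r}"
        )
    if any(c < 1 for c in shape):
        raise ConfigurationError(f"every node count must be >= 1, got {shape!r}")
    k = int(np.prod(shape))
    if k > max_nodes:
        raise ConfigurationError(f"{k} latent nodes exceeds cap {max_nodes}")
    axes = [np.arange(c, dtype=float) for c in shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([m.ravel(order="C") for m in mesh], axis=1)
    return LatentGrid(shape=shape, nodes=nodes)


def _center_counts(shape: tuple[int, ...], n_gaussian: int) -> list[int]:
    """Per-axis Gaussian-center counts, proportional to the latent shape.

    Counts are rounded; if the Cartesian product overshoots ``n_gaussian``
    the last axis is trimmed deterministically (never below 1).
    """
    ndim = len(shape)
    if ndim == 1:
        return [n_gaussian]
    scale = (n_gaussian / float(np.prod(shape))) ** (1.0 / ndim)
    counts = [max(1, round(c * scale)) for c in shape]
    # trim from the last axis until the product fits
    for axis in range(ndim - 1, -1, -1):
        while int(np.prod(counts)) > n_gaussian and counts[axis] > 1:
            counts[axis] -= 1
    return counts


def build_basis(grid: LatentGrid, n_gaussian=None, width="auto") -> BasisMatrix:
    """Evaluate the basis expansion Phi on the latent grid.

    Parameters
    ----------
    grid
        Latent grid the basis is evaluated on.
    n_gaussian
        Number of Gaussian basis functions M_NL.  ``None`` or the string
        ``"auto0.8"`` selects the default round(0.8 K).  In more than one
        dimension the centers form a Cartesian product of per-axis even
        spacings, so the realised count may be slightly below the request.
    width
        Gaussian width sigma; ``"auto"`` ties it to the spacing between
        adjacent centers (the largest per-axis spacing).
    """
    k = grid.n_nodes
    if n_gaussian is None or n_gaussian == "auto0.8":
        n_gaussian = max(1, round(0.8 * k))
    n_gaussian = int(n_gaussian)
    if n_gaussian < 1:
        raise ConfigurationError("n_gaussian must be >= 1")
    if n_gaussian > k:
        warnings.warn(
            f"n_gaussian={n_gaussian} exceeds K={k}: over-complete basis",
            stacklevel=2,
        )

    counts = _center_counts(grid.shape, n_gaussian)
    per_axis = []
    spacings = []
    for count, extent in zip(counts, grid.shape):
        hi = float(extent - 1)
        if count == 1:
            per_axis.append(np.array([hi / 2.0]))
            spacings.append(max(hi, 1.0))
        else:
            per_axis.append(np.linspace(0.0, hi, count))
            spacings.append(hi / (count - 1) if hi > 0 else 1.0)
    mesh = np.meshgrid(*per_axis, indexing="ij")
    centers = np.stack([m.ravel(order="C") for m in mesh], axis=1)

    if width == "auto":
        sigma = float(max(spacings))
    else:
        sigma = float(width)
        if sigma <= 0:
            raise ConfigurationError(f"basis width must be positive, got {sigma}")

    # squared distances node-to-center, (K, M_NL)
    diff = grid.nodes[:, None, :] - centers[None, :, :]
    d2 = np.einsum("kml,kml->km", diff, diff)
    values = np.empty((k, centers.shape[0] + 1))
    values[:, :-1] = np.exp(-d2 / (2.0 * sigma * sigma))
    values[:, -1] = 1.0
    return BasisMatrix(centers=centers, width=sigma, values=values)
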