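"""End-to-end classification pipeline over a ParticleSet.

Thin orchestration: apply any supplied in-plane alignment, transform to the
packed Fourier data space, evaluate per-image CTFs on the same packing, fit
the mapping by EM and produce hard assignments plus Wiener-filtered class
averages.  Everything the CLI and the hierarchy module do goes through
:func:`run_classification`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine
from .ctf import CtfStack, ctf_for_stack
from .engine import FitHistory, GtmModel
from .fourier import FourierStack, apply_alignment, normalize_stack, to_fourier
from .latent import BasisMatrix, LatentGrid, build_basis, build_latent_grid
from .particles import ParticleSet

__all__ = ["ClassificationResult", "run_classification"]


@dataclass
class ClassificationResult:
    """Everything one clustering run produces."""

    labels: np.ndarray  # (N,) hard assignments
    responsibilities: np.ndarray = field(repr=False)  # (K, N)
    model: GtmModel
    history: FitHistory
    averages: np.ndarray = field(repr=False)  # (K, box, box)
    fourier_averages: np.ndarray = field(repr=False)  # (K, J)
    blank: np.ndarray  # (K,) blank-class flags
    grid: LatentGrid
    basis: BasisMatrix
    stack: FourierStack = field(repr=False)
    ctf: CtfStack = field(repr=False)

    @property
    def n_classes(self) -> int:
        return self.grid.n_nodes

    @property
    def max_responsibility(self) -> np.ndarray:
        return self.responsibilities.max(axis=0)

    @property
    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


def run_classification(
    particles: ParticleSet,
    latent_shape,
    n_gaussian="auto0.8",
    basis_width="auto",
    alpha: float = 0.01,
    max_iter: int = 30,
    tol: float = 0.001,
    patience: int = 6,
    seed: int = 0,
    init_radius: float = 0.25,
    beta0="auto",
    lowpass: float | None = None,
    use_alignment: bool = True,
    normalize: bool = False,
    stop_on_convergence: bool = True,
) -> ClassificationResult:
    """Cluster a particle set into prod(latent_shape) classes.

    ``lowpass`` (Angstroms) truncates the Fourier data space for speed;
    ``normalize`` standardises each image by its background noise before
    the transform (off by default).
    """
    images = particles.images
    if use_alignment and particles.alignment is not None:
        images = apply_alignment(images, particles.alignment)
    if normalize:
        images = normalize_stack(images)
    stack = to_fourier(images, particles.pixel_size, resolution_cutoff=lowpass)
    ctf = ctf_for_stack(
        particles.ctf_params,
        particles.pixel_size,
        particles.box,
        stack.components,
        n_images=particles.n_images,
    )
    grid = build_latent_grid(latent_shape)
    basis = build_basis(grid, n_gaussian=n_gaussian, width=basis_width)
    model, resp, history = engine.fit(
        stack,
        ctf,
        grid,
        basis,
        max_iter=max_iter,
        tol=tol,
        patience=patience,
        seed=seed,
        init_radius=init_radius,
        beta0=beta0,
        alpha=alpha,
        stop_on_convergence=stop_on_convergence,
    )
    labels = engine.assign(resp)
    averages, fourier_averages, blank = engine.class_averages(stack, ctf, resp, model)
    return ClassificationResult(
        labels=labels,
        responsibilities=resp,
        model=model,
        history=history,
        averages=averages,
        fourier_averages=fourier_averages,
        blank=blank,
        grid=grid,
        basis=basis,
        stack=stack,
        ctf=ctf,
    )
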