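"""Shared construction helpers for the test suite."""

import numpy as np

from cryogtm.ctf import CtfStack
from cryogtm.engine import GtmModel
from cryogtm.fourier import FourierStack, build_component_map
from cryogtm.latent import build_basis, build_latent_grid

_SHARED_COMPONENTS = build_component_map(8, 1.0)


def make_tiny_instance(seed):
    """Random small EM instance (K,M <= 5, N <= 10, J <= 8) for oracle tests.

    Returns (stack, ctf_stack, responsibilities, model); the stack's
    component map is a placeholder (the engine math never touches it).
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 6))
    m_nl = int(rng.integers(1, min(k, 4) + 1))
    n = int(rng.integers(2, 11))
    j = int(rng.integers(2, 9))
    grid = build_latent_grid((k,))
    basis = build_basis(grid, n_gaussian=m_nl, width=float(rng.uniform(0.5, 2.0)))
    t = rng.normal(size=(n, j))
    ctf = rng.uniform(-1.0, 1.0, size=(n, j))
    r = rng.dirichlet(np.ones(k), size=n).T
    w = rng.normal(size=(basis.n_total, j))
    model = GtmModel(
        W=w,
        beta_bar=float(rng.uniform(0.3, 3.0)),
        alpha=float(rng.uniform(0.001, 0.5)),
        basis=basis,
        grid=grid,
    )
    stack = FourierStack(data=t, components=_SHARED_COMPONENTS)
    return stack, CtfStack(values=ctf), r, model


def merge_datasets(datasets, pixel_size):
    """Concatenate simulated datasets into one ParticleSet + variant ids."""
    from cryogtm.fourier import AlignmentParams
    from cryogtm.particles import ParticleSet

    images = np.concatenate([d.images for d in datasets]).astype(float)
    ctf = [p for d in datasets for p in d.ctf_params]
    align = AlignmentParams(
        theta=np.concatenate([d.alignment.theta for d in datasets]),
        shift_x=np.concatenate([d.alignment.shift_x for d in datasets]),
        shift_y=np.concatenate([d.alignment.shift_y for d in datasets]),
    )
    pset = ParticleSet(
        images=images, pixel_size=pixel_size, ctf_params=ctf, alignment=align
    )
    variant = np.concatenate(
        [np.full(d.images.shape[0], i) for i, d in enumerate(datasets)]
    )
    return pset, variant
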