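"""Hierarchical unsupervised clustering: re-cluster one class's members.

A first clustering pass may leave classes that mix distinct underlying
structures (different conformations, or different particles that project
similarly).  Selecting the members of such a class and running a fresh
clustering on them - with a new, smaller latent grid - splits the mixture
without any re-alignment: members keep the alignment state and CTF metadata
they carried in the parent run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import DataError
from .particles import ParticleSet
from .pipeline import ClassificationResult, run_classification

__all__ = ["SubClassification", "select_class_members", "subclassify", "child_seed"]


@dataclass
class SubClassification:
    """Result of re-clustering one parent class."""

    parent_class: int
    index_map: np.ndarray  # original image indices of the sub-stack
    result: ClassificationResult

    @property
    def labels(self) -> np.ndarray:
        """Sub-class labels, aligned with ``index_map``."""
        return self.result.labels


def select_class_members(
    particles: ParticleSet, labels, class_ids
) -> tuple[ParticleSet, np.ndarray]:
    """Extract the members of one or more classes.

    Returns the sub-stack (alignment and CTF metadata preserved) and the
    index map back into the parent stack.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != particles.n_images:
        raise DataError("label count does not match particle count")
    if np.isscalar(class_ids):
        class_ids = [class_ids]
    mask = np.isin(labels, np.asarray(class_ids))
    index_map = np.flatnonzero(mask)
    if index_map.size == 0:
        raise DataError(f"no images assigned to class(es) {class_ids!r}")
    return particles.select(index_map), index_map


def child_seed(master_seed: int, class_id: int) -> int:
    """Deterministic per-class seed below 2**31 derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, class_id]).generate_state(1)[0] % 2**31)


def subclassify(
    particles: ParticleSet,
    labels,
    class_id: int,
    sub_k: int,
    seed: int = 0,
    latent_shape=None,
    **fit_options,
) -> SubClassification:
    """Re-cluster the members of ``class_id`` into ``sub_k`` sub-classes.

    A fresh 1D latent grid of ``sub_k`` nodes is used unless a
    ``latent_shape`` is given; the sub-run's seed is derived from the
    master seed and the class id, so parallel sub-runs over different
    classes are independent yet reproducible.  Remaining keyword options
    are forwarded to :func:`cryogtm.pipeline.run_classification`.
    """
    import warnings

    sub_particles, index_map = select_class_members(particles, labels, class_id)
    if sub_particles.n_images < sub_k:
        warnings.warn(
            f"class {class_id} has {sub_particles.n_images} members for "
            f"{sub_k} sub-classes",
            stacklevel=2,
        )
    if latent_shape is None:
        latent_shape = (sub_k,)
    try:
        result = run_classification(
            sub_particles,
            latent_shape,
            seed=child_seed(seed, class_id),
            **fit_options,
        )
    except Exception as exc:
        raise RuntimeError(f"sub-classification of class {class_id} failed") from exc
    return SubClassification(parent_class=class_id, index_map=index_map, result=result)
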