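"""In-memory particle set: real-space images plus per-image metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import DataError
from .ctf import CtfParams
from .fourier import AlignmentParams

__all__ = ["ParticleSet"]


@dataclass
class ParticleSet:
    """A boxed particle stack with CTF parameters and optional alignment."""

    images: np.ndarray = field(repr=False)  # (N, box, box)
    pixel_size: float
    ctf_params: list[CtfParams]
    alignment: AlignmentParams | None = None

    def __post_init__(self):
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise DataError(f"expected square image stack, got {self.images.shape}")
        if len(self.ctf_params) != self.images.shape[0]:
            raise DataError(
                f"{len(self.ctf_params)} CTF parameter sets for "
                f"{self.images.shape[0]} images"
            )
        if self.alignment is not None and self.alignment.n_images != self.images.shape[0]:
            raise DataError("alignment parameter count does not match image count")

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    @property
    def box(self) -> int:
        return self.images.shape[1]

    def select(self, indices) -> "ParticleSet":
        """Sub-set by image index, preserving CTF and alignment state."""
        idx = np.asarray(indices)
        return ParticleSet(
            images=self.images[idx],
            pixel_size=self.pixel_size,
            ctf_params=[self.ctf_params[i] for i in idx],
            alignment=None if self.alignment is None else self.alignment.select(idx),
        )
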