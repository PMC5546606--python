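"""Real-space particle stacks <-> the packed real Fourier data space.

The per-component Gaussian likelihood of the model is written over *real*
scalars, so each image's 2D FFT is packed into a real vector: one unique
(non-Hermitian-redundant) coefficient contributes its real part and, unless
it is self-conjugate (where the imaginary part is identically zero), its
imaginary part as a separate component.  ``ComponentMap`` records, for every
packed component j, its frequency indices on the rfft2 grid, which part it
is, and the Hermitian multiplicity needed for Parseval-type sums.

In-plane alignment applies the operator T_{-tau}: rotate by -theta about the
geometric box centre (pixel box/2, box/2, 0-based), then translate by
(-r_x, -r_y), with bilinear interpolation; out-of-field samples take the
image mean.  Rotation angles are counter-clockwise in the (x=column, y=row)
index plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._errors import ConfigurationError, DataError

__all__ = [
    "ComponentMap",
    "FourierStack",
    "AlignmentParams",
    "build_component_map",
    "to_fourier",
    "unpack_component_row",
    "apply_alignment",
    "normalize_stack",
]


@dataclass(frozen=True)
class ComponentMap:
    """Deterministic packing order of real Fourier components.

    For each component j: ``(ky[j], kx[j])`` index the rfft2 grid of shape
    (box, box//2 + 1), ``part[j]`` is 0 for the real and 1 for the imaginary
    part, and ``mult[j]`` is the Hermitian multiplicity (2 for coefficients
    whose conjugate partner was dropped, 1 for self-conjugate ones).
    Components are enumerated raster-wise over (ky, kx) with the real part
    immediately followed by the imaginary part of the same coefficient.
    """

    box: int
    pixel_size: float
    ky: np.ndarray = field(repr=False)
    kx: np.ndarray = field(repr=False)
    part: np.ndarray = field(repr=False)
    mult: np.ndarray = field(repr=False)
    resolution_cutoff: float | None = None

    @property
    def n_components(self) -> int:
        return self.ky.size


@dataclass(frozen=True)
class FourierStack:
    """Packed Fourier coefficients of N images, shape (N, J) real."""

    data: np.ndarray = field(repr=False)
    components: ComponentMap

    @property
    def n_images(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    @property
    def box(self) -> int:
        return self.components.box

    @property
    def pixel_size(self) -> float:
        return self.components.pixel_size

    def select(self, indices) -> "FourierStack":
        return FourierStack(data=self.data[np.asarray(indices)], components=self.components)


@dataclass(frozen=True)
class AlignmentParams:
    """Per-image in-plane pose tau = (theta, r_x, r_y).

    theta in degrees counter-clockwise, translations in pixels; theta is
    reduced to [0, 360) on construction.
    """

    theta: np.ndarray = field(repr=False)
    shift_x: np.ndarray = field(repr=False)
    shift_y: np.ndarray = field(repr=False)

    def __post_init__(self):
        for name in ("theta", "shift_x", "shift_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise DataError(f"non-finite alignment parameter in {name}")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "theta", np.mod(self.theta, 360.0))

    @property
    def n_images(self) -> int:
        return self.theta.size

    @classmethod
    def identity(cls, n: int) -> "AlignmentParams":
        z = np.zeros(n)
        return cls(theta=z.copy(), shift_x=z.copy(), shift_y=z.copy())

    def select(self, indices) -> "AlignmentParams":
        idx = np.asarray(indices)
        return AlignmentParams(
            theta=self.theta[idx], shift_x=self.shift_x[idx], shift_y=self.shift_y[idx]
        )


def build_component_map(
    box: int, pixel_size: float, resolution_cutoff: float | None = None
) -> ComponentMap:
    """Enumerate the unique real components of a box x box transform.

    ``resolution_cutoff`` (Angstroms) drops coefficients beyond that
    resolution; ``None`` keeps everything up to Nyquist, in which case
    J == box**2 exactly.
    """
    if box % 2 != 0 or box < 2:
        raise ConfigurationError(f"box must be even and >= 2, got {box}")
    half = box // 2
    freqs = np.fft.fftfreq(box, d=pixel_size)
    rfreqs = np.fft.rfftfreq(box, d=pixel_size)
    fmax = np.inf if resolution_cutoff is None else 1.0 / resolution_cutoff

    ky_list, kx_list, part_list, mult_list = [], [], [], []
    for ky in range(box):
        for kx in range(half + 1):
            if kx in (0, half) and ky > half:
                continue  # conjugate partner of (box - ky, kx)
            f2 = freqs[ky] ** 2 + rfreqs[kx] ** 2
            if f2 > fmax * fmax * (1 + 1e-12):
                continue
            self_conj = ky in (0, half) and kx in (0, half)
            mult = 1 if self_conj else 2
            ky_list.append(ky)
            kx_list.append(kx)
            part_list.append(0)
            mult_list.append(mult)
            if not self_conj:
                ky_list.append(ky)
                kx_list.append(kx)
                part_list.append(1)
                mult_list.append(mult)
    return ComponentMap(
        box=box,
        pixel_size=pixel_size,
        ky=np.array(ky_list, dtype=np.intp),
        kx=np.array(kx_list, dtype=np.intp),
        part=np.array(part_list, dtype=np.int8),
        mult=np.array(mult_list, dtype=np.int8),
        resolution_cutoff=resolution_cutoff,
    )


def to_fourier(
    images: np.ndarray,
    pixel_size: float,
    resolution_cutoff: float | None = None,
    components: ComponentMap | None = None,
) -> FourierStack:
    """Forward-FFT a stack of square images into the packed data space.

    The FFT is unnormalised (numpy forward convention), so a constant image
    c maps to a single zero-frequency component of value c * box**2.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    if images.ndim != 3 or images.shape[1] != images.shape[2]:
        raise DataError(f"expected square image stack, got shape {images.shape}")
    box = images.shape[1]
    if components is None:
        components = build_component_map(box, pixel_size, resolution_cutoff)
    elif components.box != box:
        raise DataError("component map box does not match image box")
    f = np.fft.rfft2(images)
    coeff = f[:, components.ky, components.kx]
    data = np.where(components.part == 0, coeff.real, coeff.imag)
    return FourierStack(data=np.ascontiguousarray(data), components=components)


def unpack_component_row(row: np.ndarray, components: ComponentMap) -> np.ndarray:
    """Inverse of the packing: one component row -> real-space image."""
    box = components.box
    half = box // 2
    f = np.zeros((box, half + 1), dtype=complex)
    re = components.part == 0
    f[components.ky[re], components.kx[re]] += row[re]
    im = ~re
    f[components.ky[im], components.kx[im]] += 1j * row[im]
    # restore conjugate-symmetric entries in the kx = 0 and kx = half columns
    for kx in (0, half):
        for ky in range(half + 1, box):
            f[ky, kx] = np.conj(f[box - ky, kx])
    return np.fft.irfft2(f, s=(box, box))


def _warp(image: np.ndarray, theta_deg: float, rx: float, ry: float) -> np.ndarray:
    """Rotate content by -theta about the box centre, then shift by (-rx,-ry)."""
    box = image.shape[0]
    c = box / 2.0
    phi = np.deg2rad(theta_deg)
    cos, sin = np.cos(phi), np.sin(phi)
    # output (x, y) -> input (x, y): p_in = Rot(theta) (p_out - c - T) + c,
    # with T = (-rx, -ry); Rot acts counter-clockwise on (x=col, y=row).
    rows, cols = np.indices(image.shape)
    x = cols - c + rx
    y = rows - c + ry
    x_in = cos * x - sin * y + c
    y_in = sin * x + cos * y + c
    return ndimage.map_coordinates(
        image, [y_in, x_in], order=1, mode="constant", cval=float(image.mean())
    )


def apply_alignment(images: np.ndarray, params: AlignmentParams) -> np.ndarray:
    """Apply T_{-tau} per image: rotate by -theta, translate by (-r_x, -r_y)."""
    images = np.asarray(images, dtype=float)
    if images.shape[0] != params.n_images:
        raise DataError(
            f"{params.n_images} alignment triples for {images.shape[0]} images"
        )
    out = np.empty_like(images)
    for i in range(images.shape[0]):
        out[i] = _warp(images[i], params.theta[i], params.shift_x[i], params.shift_y[i])
    return out


def normalize_stack(images: np.ndarray, background_radius: float = 0.45) -> np.ndarray:
    """Subtract the mean and divide by the background standard deviation.

    Background pixels are those farther than ``background_radius * box``
    from the box centre (ring and corners), which at typical particle sizes
    contain noise only.
    """
    images = np.asarray(images, dtype=float)
    box = images.shape[-1]
    c = box / 2.0
    rows, cols = np.indices((box, box))
    bg = np.hypot(rows - c, cols - c) > background_radius * box
    if not bg.any():
        bg = np.ones((box, box), dtype=bool)
    out = np.empty_like(images)
    for i in range(images.shape[0]):
        mu = images[i].mean()
        sd = images[i][bg].std()
        out[i] = (images[i] - mu) / (sd if sd > 0 else 1.0)
    return out
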