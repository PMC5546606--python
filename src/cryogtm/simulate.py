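"""Synthetic single-particle benchmark generator.

Emulates the statistical structure of a projection-image benchmark: a 3D
density is projected along view directions drawn around quasi-uniform
orientation centres on the upper hemisphere, shifted by a sub-box amount,
CTF-modulated in the Fourier domain and contaminated with white Gaussian
noise at a chosen SNR.  The built-in phantom is an asymmetric arrangement
of 3D Gaussian blobs; any external volume can be substituted.

Ground truth (centre ids, view vectors, in-plane angles, shifts, defocus)
is recorded per image, so the recorded pose can stand in for an external
alignment step: feeding it to :func:`cryogtm.fourier.apply_alignment`
exactly undoes the simulated in-plane rotation and shift.

Conventions
-----------
* Volumes are indexed ``[z, y, x]`` (MRC section order); images ``[y, x]``.
* ``spread_deg`` is the standard deviation of the angular distance between
  a member view and its centre (the deviation magnitude is Rayleigh).
* SNR is the variance ratio of the CTF-modulated, shifted signal to the
  added noise (configurable to the pre-CTF signal variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._errors import ConfigurationError
from .ctf import CtfParams, evaluate_ctf
from .fourier import AlignmentParams

__all__ = [
    "Phantom",
    "SimConfig",
    "SimulatedDataset",
    "make_phantom",
    "stretch_phantom",
    "sample_orientations",
    "project",
    "corrupt",
    "simulate_dataset",
]

#: Rayleigh scale -> standard deviation of the magnitude
_RAYLEIGH_STD = np.sqrt(2.0 - np.pi / 2.0)


@dataclass(frozen=True)
class Phantom:
    """Asymmetric Gaussian-blob density on a cubic voxel grid."""

    density: np.ndarray = field(repr=False)  # (S, S, S), [z, y, x]
    pixel_size: float
    seed: int
    positions: np.ndarray = field(repr=False)  # (B, 3) in (z, y, x) voxels
    amplitudes: np.ndarray = field(repr=False)
    widths: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.density.shape[0]


def make_phantom(
    size: int = 48,
    n_blobs: int = 8,
    seed: int = 0,
    pixel_size: float = 3.0,
    width_scale: float = 1.0,
) -> Phantom:
    """Seeded random blob arrangement within a sphere of radius 0.4 * size.

    Blob amplitudes are uniform in [0.5, 1.5] and widths uniform in
    [0.03, 0.06] * size voxels; random placement makes the density
    asymmetric (no point-group symmetry) almost surely.  ``width_scale``
    inflates every blob's extent, producing a structural variant of the
    same arrangement (e.g. for mixture/demixing experiments).
    """
    if size < 32:
        raise ConfigurationError(f"phantom size must be >= 32, got {size}")
    rng = np.random.default_rng(seed)
    c = size / 2.0
    # uniform in the ball: direction times radius^(1/3) scaling
    dirs = rng.normal(size=(n_blobs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = 0.4 * size * rng.uniform(size=n_blobs) ** (1.0 / 3.0)
    positions = c + dirs * radii[:, None]
    amplitudes = rng.uniform(0.5, 1.5, size=n_blobs)
    widths = rng.uniform(0.03, 0.06, size=n_blobs) * size * width_scale

    zz, yy, xx = np.ogrid[:size, :size, :size]
    density = np.zeros((size, size, size))
    for p, a, w in zip(positions, amplitudes, widths):
        d2 = (zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2
        density += a * np.exp(-d2 / (2.0 * w * w))
    return Phantom(
        density=density,
        pixel_size=pixel_size,
        seed=seed,
        positions=positions,
        amplitudes=amplitudes,
        widths=widths,
    )


def stretch_phantom(phantom: Phantom, factor: float, axis: int = 0) -> Phantom:
    """Structural variant: stretch the blob arrangement along one axis.

    Blob positions move away from the box centre by ``factor`` along the
    chosen axis (0 = z) and the density is re-evaluated, giving a particle
    of different extent (length) but identical composition - the kind of
    variant a mixture-demixing experiment needs.
    """
    size = phantom.size
    c = size / 2.0
    positions = phantom.positions.copy()
    positions[:, axis] = c + (positions[:, axis] - c) * factor
    zz, yy, xx = np.ogrid[:size, :size, :size]
    density = np.zeros((size, size, size))
    for p, a, w in zip(positions, phantom.amplitudes, phantom.widths):
        d2 = (zz - p[0]) ** 2 + (yy - p[1]) ** 2 + (xx - p[2]) ** 2
        density += a * np.exp(-d2 / (2.0 * w * w))
    return Phantom(
        density=density,
        pixel_size=phantom.pixel_size,
        seed=phantom.seed,
        positions=positions,
        amplitudes=phantom.amplitudes,
        widths=phantom.widths,
    )


def _hemisphere_centers(n: int) -> np.ndarray:
    """Quasi-uniform points on the z >= 0 hemisphere (Fibonacci spiral)."""
    i = np.arange(n)
    z = (i + 0.5) / n  # uniform in (0, 1]
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(1.0 - z * z)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def _tangent_basis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    return e1, e2


def sample_orientations(
    n_centers: int, per_center: int, spread_deg: float = 2.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw view vectors clustered around hemisphere centres.

    Returns ``(views, center_ids, psi)``: unit view vectors (N, 3), the
    generating centre of each view, and uniform in-plane angles in degrees.
    The angular deviation from the centre has magnitude Rayleigh-distributed
    with standard deviation ``spread_deg`` and uniform azimuth.
    """
    if n_centers < 1 or per_center < 1 or spread_deg < 0:
        raise ConfigurationError("invalid orientation sampling configuration")
    rng = np.random.default_rng(seed)
    centers = _hemisphere_centers(n_centers)
    n = n_centers * per_center
    views = np.empty((n, 3))
    center_ids = np.repeat(np.arange(n_centers), per_center)
    sigma = spread_deg / _RAYLEIGH_STD if spread_deg > 0 else 0.0
    for ci, c in enumerate(centers):
        e1, e2 = _tangent_basis(c)
        rho = np.deg2rad(sigma * np.sqrt(rng.standard_exponential(per_center) * 2.0))
        azim = rng.uniform(0.0, 2.0 * np.pi, per_center)
        tang = np.cos(azim)[:, None] * e1 + np.sin(azim)[:, None] * e2
        block = np.cos(rho)[:, None] * c + np.sin(rho)[:, None] * tang
        views[ci * per_center : (ci + 1) * per_center] = block
    views /= np.linalg.norm(views, axis=1, keepdims=True)
    psi = rng.uniform(0.0, 360.0, n)
    return views, center_ids, psi


def _rotation_for(view: np.ndarray, psi_deg: float) -> np.ndarray:
    """Rotation (x, y, z convention) mapping the ray z-axis to ``view``.

    R = Rz(phi) Ry(theta) Rz(psi) with (theta, phi) the polar angles of the
    view vector; the sampling ray direction R @ z equals ``view``.
    """
    vx, vy, vz = view
    theta = np.arccos(np.clip(vz, -1.0, 1.0))
    phi = np.arctan2(vy, vx)
    psi = np.deg2rad(psi_deg)

    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(phi) @ ry(theta) @ rz(psi)


def project(phantom: Phantom, view, psi_deg: float = 0.0) -> np.ndarray:
    """Line-integral projection of the phantom along a view direction.

    The volume is resampled with trilinear interpolation on rays parallel
    to the rotated z-axis and summed, giving an image indexed [y, x].
    """
    view = np.asarray(view, dtype=float)
    view = view / np.linalg.norm(view)
    r_xyz = _rotation_for(view, psi_deg)
    # permute (x, y, z) matrix into (z, y, x) index order
    r_idx = r_xyz[::-1, ::-1]
    size = phantom.size
    c = np.full(3, size / 2.0)
    offset = c - r_idx @ c
    rotated = ndimage.affine_transform(
        phantom.density, r_idx, offset=offset, order=1, mode="constant", cval=0.0
    )
    return rotated.sum(axis=0)  # sum over z -> image [y, x]


def corrupt(
    image: np.ndarray,
    shift=(0.0, 0.0),
    ctf: CtfParams | None = None,
    snr: float = np.inf,
    seed: int = 0,
    pixel_size: float = 1.0,
    snr_reference: str = "post_ctf",
) -> np.ndarray:
    """Shift, CTF-modulate and add white Gaussian noise to one projection.

    The shift ``(dx, dy)`` moves content by +dx columns and +dy rows via a
    Fourier phase ramp; the CTF multiplies in the Fourier domain; noise
    variance is var(signal) / snr, where the signal is the post-CTF image
    (``snr_reference="pre_ctf"`` uses the clean projection instead).
    """
    if snr <= 0:
        raise ConfigurationError("snr must be positive")
    image = np.asarray(image, dtype=float)
    box = image.shape[0]
    f = np.fft.rfft2(image)
    dy, dx = float(shift[1]), float(shift[0])
    fy = np.fft.fftfreq(box)[:, None]
    fx = np.fft.rfftfreq(box)[None, :]
    f = f * np.exp(-2j * np.pi * (fy * dy + fx * dx))
    if ctf is not None:
        full = evaluate_ctf(ctf, pixel_size, box)
        f = f * full[:, : box // 2 + 1]
    signal = np.fft.irfft2(f, s=(box, box))
    if not np.isfinite(snr):
        return signal
    ref_var = image.var() if snr_reference == "pre_ctf" else signal.var()
    noise_sd = np.sqrt(ref_var / snr)
    rng = np.random.default_rng(seed)
    return signal + rng.normal(0.0, noise_sd, size=signal.shape)


@dataclass(frozen=True)
class SimConfig:
    """Benchmark dataset conditions.

    Defaults mirror the reference benchmark protocol: shifts uniform in
    +-2 px, defocus uniform in [-3.5, -1.0] um (underfocus negative), and
    a 2 degree angular spread around each orientation centre.
    """

    n_centers: int = 500
    per_center: int = 100
    spread_deg: float = 2.0
    box: int = 48
    pixel_size: float = 3.0
    shift_range: float = 2.0
    defocus_range: tuple[float, float] = (-3.5, -1.0)
    voltage: float = 300.0
    cs: float = 2.0
    amplitude_contrast: float = 0.1
    snr: float = 1.0 / 100.0
    apply_shifts: bool = True
    n_blobs: int = 8
    seed: int = 0


@dataclass
class SimulatedDataset:
    """Images plus per-image metadata and ground truth."""

    images: np.ndarray  # (N, box, box) float32
    ctf_params: list[CtfParams]
    alignment: AlignmentParams  # pose that apply_alignment() must undo
    ground_truth: pd.DataFrame
    config: SimConfig
    phantom: Phantom


def simulate_dataset(config: SimConfig, phantom: Phantom | None = None) -> SimulatedDataset:
    """Generate the full benchmark dataset from a config (fully seeded).

    The ground-truth table records, per image, the centre id, view vector,
    in-plane angle psi, applied shift, defocus and SNR.  The alignment
    entry stores the (theta, r_x, r_y) triple that exactly undoes the
    simulated in-plane pose when passed to ``apply_alignment`` (rotation is
    applied before translation there, so the recorded shift is the applied
    shift rotated into the aligned frame).
    """
    cfg = config
    if phantom is None:
        phantom = make_phantom(cfg.box, cfg.n_blobs, seed=cfg.seed, pixel_size=cfg.pixel_size)
    root = np.random.SeedSequence([cfg.seed, 2**16])
    seq_orient, seq_shift, seq_defocus, seq_noise = root.spawn(4)
    orient_seed = int(seq_orient.generate_state(1)[0] % 2**31)
    views, center_ids, psi = sample_orientations(
        cfg.n_centers, cfg.per_center, cfg.spread_deg, seed=orient_seed
    )
    n = views.shape[0]
    rng_shift = np.random.default_rng(seq_shift)
    rng_defocus = np.random.default_rng(seq_defocus)
    shifts = (
        rng_shift.uniform(-cfg.shift_range, cfg.shift_range, size=(n, 2))
        if cfg.apply_shifts
        else np.zeros((n, 2))
    )
    lo, hi = min(cfg.defocus_range), max(cfg.defocus_range)
    defocus = rng_defocus.uniform(lo, hi, size=n)
    noise_seeds = np.random.default_rng(seq_noise).integers(0, 2**31, size=n)

    images = np.empty((n, cfg.box, cfg.box), dtype=np.float32)
    ctf_params = []
    for i in range(n):
        p = CtfParams(
            defocus_u=defocus[i],
            defocus_v=defocus[i],
            voltage=cfg.voltage,
            cs=cfg.cs,
            amplitude_contrast=cfg.amplitude_contrast,
        )
        ctf_params.append(p)
        proj = project(phantom, views[i], psi_deg=psi[i])
        images[i] = corrupt(
            proj,
            shift=shifts[i],
            ctf=p,
            snr=cfg.snr,
            seed=int(noise_seeds[i]),
            pixel_size=cfg.pixel_size,
        )

    # alignment that undoes the pose: rotate content by -theta first, then
    # translate.  Projecting with in-plane angle psi rotates image content
    # by -psi, so theta = -psi undoes it; the translation is the applied
    # shift rotated into the aligned frame.
    theta = (-psi) % 360.0
    phi_r = np.deg2rad(-theta)
    rx = np.cos(phi_r) * shifts[:, 0] - np.sin(phi_r) * shifts[:, 1]
    ry = np.sin(phi_r) * shifts[:, 0] + np.cos(phi_r) * shifts[:, 1]
    alignment = AlignmentParams(theta=theta, shift_x=rx, shift_y=ry)

    ground_truth = pd.DataFrame(
        {
            "image": np.arange(n),
            "center_id": center_ids,
            "view_x": views[:, 0],
            "view_y": views[:, 1],
            "view_z": views[:, 2],
            "psi": psi,
            "shift_x": shifts[:, 0],
            "shift_y": shifts[:, 1],
            "align_theta": alignment.theta,
            "align_rx": alignment.shift_x,
            "align_ry": alignment.shift_y,
            "defocus_u": defocus,
            "defocus_v": defocus,
            "snr": np.full(n, cfg.snr),
        }
    )
    return SimulatedDataset(
        images=images,
        ctf_params=ctf_params,
        alignment=alignment,
        ground_truth=ground_truth,
        config=cfg,
        phantom=phantom,
    )
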