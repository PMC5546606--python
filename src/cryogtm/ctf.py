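"""Contrast transfer function evaluation on the Fourier grid.

The observation model couples each Fourier component of an image to the
mapped manifold through the microscope's CTF,

    t_ij = CTF_ij * A_j(s_k; W) + n_ij,

so the CTF has to be evaluated per image on exactly the component packing
used by the data space.  The weak-phase CTF is

    CTF(k, theta) = -sqrt(1 - A^2) sin(chi) - A cos(chi)
    chi(k, theta) = pi lam dz(theta) k^2 - (pi/2) Cs lam^3 k^4 + phase_shift

with lam the relativistic electron wavelength, dz(theta) the astigmatic
defocus (positive for underfocus inside chi) and A the amplitude-contrast
fraction.  No envelope decay is applied by default, and the data are never
phase-flipped: CTF correction lives inside the E-M kernel itself.

Defocus convention: parameters are stored in micrometres with underfocus
*negative* (the convention of typical acquisition logs); the sign is flipped
internally so underfocus gives positive dz in chi.  RELION STAR files store
positive-underfocus Angstroms; the conversion happens at the STAR boundary
(see :mod:`cryogtm.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ConfigurationError, DataError

__all__ = [
    "CtfParams",
    "CtfStack",
    "electron_wavelength",
    "evaluate_ctf",
    "ctf_for_stack",
]


@dataclass(frozen=True)
class CtfParams:
    """Per-image CTF parameters.

    defocus_u / defocus_v are in micrometres, negative for underfocus;
    astig_angle in degrees gives the azimuth of the defocus_u axis.
    """

    defocus_u: float
    defocus_v: float
    astig_angle: float = 0.0
    voltage: float = 300.0  # kV
    cs: float = 2.0  # mm
    amplitude_contrast: float = 0.1
    phase_shift: float = 0.0  # radians

    def __post_init__(self):
        if self.voltage <= 0:
            raise ConfigurationError("voltage must be positive")
        if self.cs < 0:
            raise ConfigurationError("spherical aberration must be >= 0")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ConfigurationError("amplitude_contrast must lie in [0, 1]")


@dataclass(frozen=True)
class CtfStack:
    """CTF_ij values (N, J) aligned index-for-index with a FourierStack."""

    values: np.ndarray = field(repr=False)

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstroms for a voltage in kV."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v * v)


def evaluate_ctf(params: CtfParams, pixel_size: float, box: int) -> np.ndarray:
    """Evaluate the CTF on the full (box, box) Fourier grid.

    The grid follows ``np.fft.fftfreq`` ordering along both axes, in units
    of inverse Angstroms, so row/column indices match FFT output indices.
    """
    if pixel_size <= 0:
        raise ConfigurationError("pixel_size must be positive")
    if box < 8 or box % 2 != 0:
        raise ConfigurationError(f"box must be even and >= 8, got {box}")

    lam = electron_wavelength(params.voltage)
    freqs = np.fft.fftfreq(box, d=pixel_size)
    fy = freqs[:, None]
    fx = freqs[None, :]
    k2 = fx * fx + fy * fy
    theta = np.arctan2(fy, fx)

    # micrometres (underfocus negative) -> Angstroms (underfocus positive)
    dz_u = -params.defocus_u * 1e4
    dz_v = -params.defocus_v * 1e4
    ast = np.deg2rad(params.astig_angle)
    dz = 0.5 * (dz_u + dz_v) + 0.5 * (dz_u - dz_v) * np.cos(2.0 * (theta - ast))

    cs_a = params.cs * 1e7  # mm -> Angstroms
    chi = (
        np.pi * lam * dz * k2
        - 0.5 * np.pi * cs_a * lam**3 * k2 * k2
        + params.phase_shift
    )
    a = params.amplitude_contrast
    return -np.sqrt(1.0 - a * a) * np.sin(chi) - a * np.cos(chi)


def ctf_for_stack(
    params_list, pixel_size: float, box: int, component_map, n_images: int | None = None
) -> CtfStack:
    """Evaluate the CTF per image on the packed Fourier components.

    ``component_map`` is the :class:`cryogtm.fourier.ComponentMap` of the
    FourierStack the CTF will multiply; the real and imaginary parts of one
    coefficient share the same CTF value.  The CTF image is computed once
    per distinct parameter set and broadcast.
    """
    params_list = list(params_list)
    n = len(params_list)
    if n == 0:
        raise DataError("empty CTF parameter list")
    if n_images is not None and n != n_images:
        raise DataError(f"{n} CTF parameter sets for {n_images} images")
    ky = component_map.ky
    kx = component_map.kx
    values = np.empty((n, ky.size))
    cache: dict[CtfParams, np.ndarray] = {}
    for i, p in enumerate(params_list):
        row = cache.get(p)
        if row is None:
            full = evaluate_ctf(p, pixel_size, box)
            row = full[ky, kx]
            cache[p] = row
        values[i] = row
    return CtfStack(values=values)
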