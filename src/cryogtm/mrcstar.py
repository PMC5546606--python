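"""Minimal MRC2014 stack and RELION-dialect STAR file I/O.

Covers exactly what the pipeline needs: mode-2 (float32) image stacks with
a correct 1024-byte header, and STAR files consisting of named loop blocks
read into / written from pandas DataFrames.  Not a general-purpose
implementation of either format.
"""

from __future__ import annotations

import io as _io
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import DataError

__all__ = ["read_mrcs", "write_mrcs", "read_star", "write_star"]

_HEADER_SIZE = 1024
_MODE_FLOAT32 = 2


def write_mrcs(path, images: np.ndarray, pixel_size: float = 1.0) -> None:
    """Write an image stack as an MRC2014 mode-2 file (.mrcs convention)."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    nz, ny, nx = images.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)  # NX NY NZ
    struct.pack_into("<i", header, 12, _MODE_FLOAT32)  # MODE
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    struct.pack_into(
        "<3f", header, 40, nx * pixel_size, ny * pixel_size, nz * pixel_size
    )  # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(images.min()), float(images.max()), float(images.mean())
    )
    struct.pack_into("<i", header, 88, 0)  # ISPG (stack)
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(images.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(images.tobytes())


def read_mrcs(path) -> tuple[np.ndarray, float]:
    """Read a mode-2 MRC stack; returns (images (N, ny, nx), pixel size)."""
    raw = Path(path).read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise DataError(f"{path}: truncated MRC header")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    (mode,) = struct.unpack_from("<i", raw, 12)
    if mode != _MODE_FLOAT32:
        raise DataError(f"{path}: unsupported MRC mode {mode} (expected 2)")
    (mx,) = struct.unpack_from("<i", raw, 28)
    (cella_x,) = struct.unpack_from("<f", raw, 40)
    pixel_size = cella_x / mx if mx > 0 else 1.0
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    offset = _HEADER_SIZE + nsymbt
    expected = nx * ny * nz * 4
    data = raw[offset : offset + expected]
    if len(data) < expected:
        raise DataError(
            f"{path}: stack holds {len(data) // (nx * ny * 4)} of {nz} declared images"
        )
    images = np.frombuffer(data, dtype="<f4").reshape(nz, ny, nx)
    return images.astype(np.float32), float(pixel_size)


def write_star(path, df: pd.DataFrame, block_name: str = "particles") -> None:
    """Write one DataFrame as a STAR loop block; columns are the tags."""
    lines = [f"data_{block_name}", "", "loop_"]
    for i, col in enumerate(df.columns, start=1):
        lines.append(f"_{col} #{i}")
    for _, row in df.iterrows():
        fields = []
        for v in row:
            if isinstance(v, (float, np.floating)):
                fields.append(f"{v:.6f}")
            else:
                fields.append(str(v))
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_star(path) -> pd.DataFrame:
    """Read the first loop block of a STAR file into a DataFrame.

    Column tags lose their leading underscore; numeric columns are
    converted automatically.
    """
    text = Path(path).read_text()
    columns: list[str] = []
    rows: list[str] = []
    in_loop = False
    collecting = False
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            if collecting and rows:
                break  # end of the first loop block
            continue
        if stripped.startswith("data_"):
            if collecting and rows:
                break
            in_loop = False
            collecting = False
            continue
        if stripped == "loop_":
            in_loop = True
            columns = []
            continue
        if in_loop and stripped.startswith("_"):
            columns.append(stripped.split()[0].lstrip("_"))
            collecting = True
            continue
        if collecting:
            rows.append(stripped)
    if not columns:
        raise DataError(f"{path}: no loop block found")
    df = pd.read_csv(
        _io.StringIO("\n".join(rows)), sep=r"\s+", names=columns, engine="python"
    )
    return df
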