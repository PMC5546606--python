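"""Dataset readers/writers and run manifests.

The STAR dialect follows RELION particle metadata: defocus in Angstroms
with underfocus positive (converted here to the internal negative-microns
convention), rlnAnglePsi / rlnOriginX / rlnOriginY as the in-plane pose,
and 1-based rlnClassNumber on output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._errors import DataError
from .ctf import CtfParams
from .fourier import AlignmentParams
from .mrcstar import read_mrcs, read_star, write_mrcs, write_star
from .particles import ParticleSet
from .pipeline import ClassificationResult
from .simulate import SimulatedDataset

__all__ = ["read_particles", "write_results", "write_dataset", "load_manifest"]

logger = logging.getLogger(__name__)

_REQUIRED_CTF = ("rlnDefocusU", "rlnDefocusV")
_CTF_DEFAULTS = {
    "rlnDefocusAngle": 0.0,
    "rlnVoltage": 300.0,
    "rlnSphericalAberration": 2.0,
    "rlnAmplitudeContrast": 0.1,
}


def read_particles(stack_path, star_path) -> ParticleSet:
    """Load an MRCS stack with its STAR metadata into a ParticleSet.

    Defocus is converted Angstroms (underfocus positive) to micrometres
    (underfocus negative).  Missing alignment columns fall back to the
    identity alignment with a logged notice.
    """
    images, pixel_size = read_mrcs(stack_path)
    meta = read_star(star_path)
    if len(meta) != images.shape[0]:
        raise DataError(
            f"STAR lists {len(meta)} particles but stack holds {images.shape[0]}"
        )
    for col in _REQUIRED_CTF:
        if col not in meta.columns:
            raise DataError(f"missing required CTF column {col}")
    for col, default in _CTF_DEFAULTS.items():
        if col not in meta.columns:
            logger.info("STAR missing %s; using default %s", col, default)
            meta[col] = default

    ctf_params = [
        CtfParams(
            defocus_u=-row.rlnDefocusU * 1e-4,
            defocus_v=-row.rlnDefocusV * 1e-4,
            astig_angle=float(row.rlnDefocusAngle),
            voltage=float(row.rlnVoltage),
            cs=float(row.rlnSphericalAberration),
            amplitude_contrast=float(row.rlnAmplitudeContrast),
        )
        for row in meta.itertuples()
    ]

    n = images.shape[0]
    theta = np.zeros(n)
    sx = np.zeros(n)
    sy = np.zeros(n)
    if "rlnAnglePsi" in meta.columns:
        theta = meta["rlnAnglePsi"].to_numpy(dtype=float)
    else:
        logger.info("STAR missing rlnAnglePsi; assuming zero rotation")
    if "rlnOriginX" in meta.columns and "rlnOriginY" in meta.columns:
        sx = meta["rlnOriginX"].to_numpy(dtype=float)
        sy = meta["rlnOriginY"].to_numpy(dtype=float)
    else:
        logger.info("STAR missing rlnOriginX/Y; assuming zero shifts")
    alignment = AlignmentParams(theta=theta, shift_x=sx, shift_y=sy)
    return ParticleSet(
        images=images.astype(float),
        pixel_size=pixel_size,
        ctf_params=ctf_params,
        alignment=alignment,
    )


def write_dataset(dataset: SimulatedDataset, outdir) -> dict:
    """Write a simulated dataset as MRCS + STAR + ground-truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    write_mrcs(outdir / "particles.mrcs", dataset.images, pixel_size=cfg.pixel_size)
    star = pd.DataFrame(
        {
            "rlnImageName": [
                f"{i + 1:06d}@particles.mrcs" for i in range(dataset.images.shape[0])
            ],
            "rlnDefocusU": [-p.defocus_u * 1e4 for p in dataset.ctf_params],
            "rlnDefocusV": [-p.defocus_v * 1e4 for p in dataset.ctf_params],
            "rlnDefocusAngle": [p.astig_angle for p in dataset.ctf_params],
            "rlnVoltage": [p.voltage for p in dataset.ctf_params],
            "rlnSphericalAberration": [p.cs for p in dataset.ctf_params],
            "rlnAmplitudeContrast": [p.amplitude_contrast for p in dataset.ctf_params],
            "rlnAnglePsi": dataset.alignment.theta,
            "rlnOriginX": dataset.alignment.shift_x,
            "rlnOriginY": dataset.alignment.shift_y,
        }
    )
    write_star(outdir / "particles.star", star)
    dataset.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
    manifest = {
        "kind": "simulated_dataset",
        "version": __version__,
        "config": asdict(cfg),
        "files": {
            "stack": "particles.mrcs",
            "star": "particles.star",
            "ground_truth": "ground_truth.csv",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def write_results(
    outdir, result: ClassificationResult, config: dict, seed: int
) -> dict:
    """Write a classification run: averages, assignments, history, manifest.

    Class averages go out in descending size order; the manifest records
    the permutation (original class index per written slice) and the blank
    classes.  Rerunning with the same seed reproduces identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = result.class_sizes
    order = np.argsort(-sizes, kind="stable")
    write_mrcs(
        outdir / "class_averages.mrcs",
        result.averages[order],
        pixel_size=config.get("pixel_size", 1.0),
    )
    assignments = pd.DataFrame(
        {
            "rlnClassNumber": result.labels + 1,
            "smlMaxResponsibility": result.max_responsibility,
        }
    )
    write_star(outdir / "assignments.star", assignments)
    pd.DataFrame(
        {"image": np.arange(result.labels.size), "class": result.labels,
         "max_responsibility": result.max_responsibility}
    ).to_csv(outdir / "assignments.csv", index=False)
    pd.DataFrame({"class": np.arange(sizes.size), "size": sizes}).to_csv(
        outdir / "class_sizes.csv", index=False
    )
    hist = result.history
    pd.DataFrame(
        {
            "iteration": np.arange(1, hist.n_iterations + 1),
            "loss": hist.loss,
            "beta_bar": hist.beta_bar,
        }
    ).to_csv(outdir / "history.csv", index=False)
    manifest = {
        "kind": "classification_run",
        "version": __version__,
        "seed": int(seed),
        "config": config,
        "n_classes": int(result.n_classes),
        "average_order": [int(k) for k in order],
        "blank_classes": [int(k) for k in np.flatnonzero(result.blank)],
        "converged": bool(hist.converged),
        "converged_at": hist.converged_at,
        "files": {
            "averages": "class_averages.mrcs",
            "assignments_star": "assignments.star",
            "assignments_csv": "assignments.csv",
            "class_sizes": "class_sizes.csv",
            "history": "history.csv",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def load_manifest(run_dir) -> dict:
    path = Path(run_dir) / "manifest.json"
    if not path.exists():
        raise DataError(f"no manifest.json under {run_dir}")
    return json.loads(path.read_text())
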