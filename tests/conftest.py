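import numpy as np
import pytest

from cryogtm.particles import ParticleSet
from cryogtm.pipeline import run_classification
from cryogtm.simulate import SimConfig, simulate_dataset

#: conditions of the scaled-down recovery benchmark: 20 view centres with
#: 100 projections each, box 48, SNR 1/50, shifts +-2 px, defocus -1..-3.5 um
BENCH_CONFIG = SimConfig(n_centers=20, per_center=100, box=48, snr=1 / 50, seed=11)


@pytest.fixture(scope="session")
def bench_dataset():
    """The simulated benchmark stack shared by the recovery experiments."""
    return simulate_dataset(BENCH_CONFIG)


@pytest.fixture(scope="session")
def bench_particles(bench_dataset):
    ds = bench_dataset
    return ParticleSet(
        images=ds.images.astype(float),
        pixel_size=ds.config.pixel_size,
        ctf_params=ds.ctf_params,
        alignment=ds.alignment,
    )


@pytest.fixture(scope="session")
def bench_fit(bench_particles):
    """Full 30-iteration fit (K = 20) with ground-truth alignment applied."""
    return run_classification(
        bench_particles,
        (20,),
        seed=3,
        normalize=True,
        stop_on_convergence=False,
    )
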