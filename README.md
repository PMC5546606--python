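# cryogtm

Unsupervised 2D classification of single-particle cryo-EM images by
CTF-aware generative topographic mapping (GTM).

Cryo-EM datasets contain tens of thousands of noisy projection images of a
molecule in unknown orientations and conformations. Sorting them into
homogeneous 2D classes — without any reference structure — is the first step
in assessing structural heterogeneity and in building *ab initio* 3D models.
`cryogtm` implements a statistical-manifold-learning approach to this
problem: a low-dimensional latent grid is mapped through a nonlinear basis
expansion into the Fourier data space, with the microscope's contrast
transfer function (CTF) built directly into the observation model, so
classification is never biased by per-image defocus variation and class
averages come out CTF-corrected.

## Model

Each image's Fourier components t_ij are modelled as

    t_ij = CTF_ij · A_j(s_k; W) + n_ij,      A(s; W) = Φ(s) W

where s_k are K latent nodes on a regular 1–3D grid (uniform delta-sum
prior), Φ holds M_NL Gaussian basis functions plus a constant bias, and
n_ij is Gaussian noise with precision β_ij. Fitting is by
expectation-maximization:

* **E-step** — responsibilities R_ki ∝ exp(−½ Σ_j β̄ (t_ij − CTF_ij A_kj)²),
  computed in the log domain.
* **M-step** — per Fourier component j an independent ridge system
  C_j w_j = b_j updates W; the noise precisions are re-estimated from the
  responsibility-weighted residuals and pooled to a scalar mean β̄.
* Convergence is monitored through the weighted loss
  L = Σ_ijk R_ki (t_ij − CTF_ij A_kj)²; the rule triggers when L changes by
  < 0.1 % for six consecutive iterations.

After fitting, class averages are formed by the Wiener-type filter

    A_kj = Σ_i R_ki β̄ CTF_ij t_ij / (Σ_i R_ki β̄ CTF_ij² + α),

and each image is hard-assigned to its maximum-responsibility node. Classes
that mix distinct structures can be re-clustered hierarchically
(`cryogtm.hierarchy.subclassify`).

The package also ships a full simulation benchmark: an asymmetric
Gaussian-blob phantom is projected along views clustered around
quasi-uniform orientation centres on the upper hemisphere, shifted,
CTF-modulated and corrupted with white Gaussian noise at a chosen SNR, with
complete ground truth (views, in-plane angles, shifts, defocus) recorded.
Clustering quality is evaluated through within-class pairwise angular
distance histograms, ranked class sizes, effective class counts and
majority-vote purity.

## Worked example

```python
import numpy as np
from cryogtm import SimConfig, simulate_dataset, ParticleSet, run_classification
from cryogtm.metrics import purity, effective_class_count

cfg = SimConfig(n_centers=20, per_center=100, box=48, snr=1/50, seed=11)
ds = simulate_dataset(cfg)                       # 2,000 simulated particles
particles = ParticleSet(
    images=ds.images.astype(float), pixel_size=cfg.pixel_size,
    ctf_params=ds.ctf_params, alignment=ds.alignment,
)
res = run_classification(particles, (20,), seed=3, normalize=True,
                         stop_on_convergence=False)
print("converged at iteration", res.history.converged_at)
print("effective classes", effective_class_count(res.labels))
print("purity", purity(res.labels, ds.ground_truth["center_id"].to_numpy()))
```

prints

```
converged at iteration 12
effective classes 20
purity 0.753
```

meaning the loss-plateau rule triggered after 12 of 30 EM iterations, all
20 classes received particles, and 75 % of images landed in a class whose
majority shares their true orientation centre (chance level here is ~5 %;
k-means on the same images scores 0.52).

The same pipeline is available from the shell:

```bash
cryogtm simulate --config sim.yaml --seed 11 --out sim/
cryogtm classify --stack sim/particles.mrcs --star sim/particles.star \
    --k 20 --normalize --seed 3 --out run/
cryogtm subclassify --run run/ --class-id 4 --sub-k 10 --seed 3
cryogtm eval --labels run/ --ground-truth sim/ground_truth.csv --out report/
```

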