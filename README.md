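# lpsmri

Low-rank plus sparse (L+S / robust-PCA) decomposition and reconstruction
of dynamic MRI series, with discrete shearlets as the sparsifying
transform.

Dynamic MR series — contrast-enhanced (DCE) abdominal imaging, cine
small-bowel motility imaging — are temporally redundant: a static or
quasi-periodically breathing background carries most of the energy,
while the signal of interest (enhancement, peristalsis) is rapid, local
and aperiodic. Writing the series as a Casorati matrix M ((Nx·Ny) × Nt,
one vectorized frame per column), the package solves

    min_{L,S}  ½‖Fu(L+S) − y‖₂² + λ_L‖L‖_* + λ_S‖Φ(S)‖₁

by alternating singular-value thresholding of L, magnitude shrinkage of
Φ(S), and a data-consistency step, where Fu is the (optionally
undersampled) Fourier operator and Φ a pluggable sparsifying transform:
identity, temporal Fourier (`tf`), orthogonal wavelets (`wt`), or a
Parseval cone-adapted discrete shearlet frame (`ds`). With Fu = I the
same iteration is a pure image decomposition, splitting background and
periodic motion (L) from enhancement or bowel motility (S).

Around the solver the package provides the full evaluation pipeline:

* seeded synthetic phantoms with ground truth — a DCE abdomen (extended
  Tofts kinetics, Ct = Ktrans·(Cp ⊛ e^{−kep t}) + vp·Cp, driven by a
  Parker-type population AIF and converted through the spoiled
  gradient-echo signal equation) and a small-bowel series (breath-hold +
  free-breathing segments, one sinusoidal respiratory mode, sparse
  local motility events);
* variable-density Cartesian undersampling with Monte-Carlo
  minimum-peak-interference mask selection, and noisy (k,t)-space
  simulation;
* a k-t FOCUSS baseline (iteratively reweighted x-f reconstruction);
* optical-flow registration with an intensity-change field and
  bending-energy regularization, Jacobian-determinant motility maps
  σ_J and ROI motility scores μ(σ_J);
* metrics (relative reconstruction error re = ‖y−ye‖₂²/‖y‖₂², L0
  sparsity counts, exact Mann-Whitney U test) and experiment drivers.

It is aimed at MR-reconstruction researchers who want a compact,
fully-tested reference implementation of the shearlet-regularized L+S
pipeline that runs end-to-end on synthetic data.

## Worked example

Decompose the bundled small-bowel phantom (50 free-breathing frames,
one respiratory mode plus sparse motility) with the shearlet transform
and the motility-separation weights:

```python
import lpsmri as lp

bowel, truth = lp.generate_bowel_phantom(
    lp.BowelPhantomConfig(n_bh=0, n_fb=50), seed=1
)
ds = lp.get_transform("ds", 64, 64)
res = lp.lps_decompose(
    bowel.data,
    lp.LPSConfig(lambda_l=0.0025, lambda_s=0.00125, transform=ds),
)
print(res.rank_l, res.rank_s, res.iterations)
```

prints

```
2 50 50
```

the rank of the low-rank component is 2 (the static anatomy plus the
single periodic respiratory mode), while the sparse component is full
rank over the 50 frames (it holds the aperiodic motility events and the
noise) — the separation the decomposition is designed to produce. The
same run on the DCE phantom with λ_L = λ_S = 0.01 gives rank(L) = 1:
static anatomy only, with all enhancement in S.

The experiment drivers reproduce the higher-level comparisons, e.g.

```python
from lpsmri.experiments import run_reconstruction_benchmark
rep = run_reconstruction_benchmark(n_seeds=5, master_seed=0)
print(rep["summary"])
```

benchmarks k-t FOCUSS against L+S with identity/TF/DS transforms at 4-
and 8-fold undersampling (median + IQR of re over seeds, with
Mann-Whitney comparisons); at 4× the shearlet variant attains the
lowest median re.

A thin CLI mirrors the library:

```sh
lps-shear phantom --kind bowel --nt 50 --seed 1 --out bowel.h5
lps-shear decompose --input bowel.h5 --transform ds \
    --lambda-l 0.0025 --lambda-s 0.00125 --out dec.h5
lps-shear motility --input dec.h5 --component S
```

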