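# annealtomo

Discrete tomographic reconstruction by quadratic binary optimization, with
annealing-style samplers and classical baselines, on self-contained toy
problems.

## The problem

Emission tomography (SPECT/PET) reconstructs an activity distribution `x`
from line-integral measurements `y = M x`, where the system matrix `M`
stacks one row per detector bin per view.  Quantum annealers and their
hybrid extensions minimize quadratic functions of binary variables — so
*discrete* tomography, where pixels take binary or small-integer values,
maps naturally onto that hardware.  This package is for researchers who
want to study that mapping without hardware access: it generates the whole
toy problem (phantom, parallel-beam geometry, explicit system matrix,
sinogram), performs the optimization-based reconstruction with classical
samplers that honor the annealer's interface, and benchmarks against the
standard classical inverters.

## The method

The least-squares objective

```
H(x) = ||M x − y||²  =  xᵀ(MᵀM)x − 2(Mᵀy)ᵀx + yᵀy
```

becomes, for binary pixels (using `x_i² = x_i`), the QUBO with

```
linear_i   = (MᵀM)_ii − 2(Mᵀy)_i
coupler_ij = 2(MᵀM)_ij        (i < j)
offset     = yᵀy
```

so the energy of *every* binary assignment equals its squared residual
exactly, and reported energies read directly as data misfit.  Gray-level
images use a bounded-integer quadratic model lowered to a QUBO through an
R-bit positional encoding (`N²·R` binary variables for an N×N image).
Models are solved by exhaustive enumeration (small problems; a ground-truth
oracle) or seeded single-spin-flip simulated annealing (the classical
stand-in for the quantum/hybrid solver).  The lowest-energy sample is the
reconstruction; the occurrence-weighted pixel variance of all samples gives
an uncertainty map.  Baselines: ramp-filtered backprojection (FBP), SART
and its discrete extension DART, and the (truncated) Moore–Penrose
pseudoinverse — each followed by a shared discretization step.

## Worked example

```python
import numpy as np
from annealtomo import (Geometry, AnnealingReconstructor, make_phantom,
                        project, reconstruct_dart, rmse)

phantom = make_phantom("foam", 16, levels=2, seed=1)   # 16x16 binary image
geom = Geometry(image_size=16, n_views=16)             # V = B = N: fully determined
sino = project(phantom, geom)                          # 16x16 sinogram

qa = AnnealingReconstructor(levels=2, sampler="sa",
                            reads=20, sweeps=2000, seed=0).fit(geom)
recon = qa.reconstruct(sino)

print("best-sample energy:", qa.sample_set_.first.energy)
print("QA   RMSE:", rmse(recon, phantom))
print("DART RMSE:", rmse(reconstruct_dart(sino, levels=2), phantom))
```

prints

```
best-sample energy: 3.637978807091713e-12
QA   RMSE: 0.0
DART RMSE: 0.0
```

the energy is the squared residual `‖Mx̂ − y‖²` of the returned image —
zero up to floating-point round-off, meaning the sampler found an image
whose projections match the data exactly; RMSE `0.0` means that image is
the ground-truth phantom, for the annealing arm and the DART baseline alike
(on fully determined noiseless problems both should recover the phantom).

The reconstructors are scikit-learn estimators: `fit(geometry)` precomputes
the system matrix, `transform` maps stacked sinogram vectors to stacked
image vectors, and `get_params`/`clone` work as usual.  A thin CLI covers
the same ground:

```
annealtomo simulate --kind foam --size 16 --seed 1 --out toy
annealtomo reconstruct --sinogram toy_sinogram.csv --method qa --out recon.csv
annealtomo evaluate --recon recon.csv --truth toy_phantom.csv --levels 2
annealtomo experiment --name size_sweep --out results/size_sweep
```

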