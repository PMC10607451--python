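# Methods

## Forward model

The projector is the parallel-beam "rotate then sum" convention of emission
tomography toy problems.  A view at angle `a` rotates the image
counter-clockwise by `a` about the pixel-center `( (N−1)/2, (N−1)/2 )` with
bilinear interpolation and zero padding, then sums along the vertical axis
into `B = N` detector bins: the 0° view is the image's column sums ("viewed
from the top"), and increasing angles scan clockwise over `[0°, 180°)` in
equal steps `180·k/V`.  Rotation + summation is linear, so each view is a
sparse matrix acting on the row-major vectorized image; the explicit system
matrix `M` (shape `V·B × N²`) is those per-view operators stacked.  For
`N ≤ 64`, `project` and `build_system_matrix` read from one cached dense
array, making `M·vec(x) ≡ vec(project(x))` *bitwise* exact, not just close;
finer grids (used only for acquisition) stay matrix-free and sparse.

Rotate-then-sum with bilinear weights was chosen over exact ray tracing
because it keeps the operator linear and column-constructible, at the cost
of ~1% per-view mass non-conservation near gray-level discontinuities
(measured: < 1% relative spread of per-view totals at N = 32 for images
inside the inscribed circle; worse at N ≤ 16, where pixels are coarse
relative to the interpolation kernel).

### Count-noise surrogate

Low-count emission noise is imitated by perturbing the *image*, not the
sinogram, independently for each view: offsets are drawn uniformly from
{−1, 0, +1} at active pixels and {0, +1} at empty ones, so the perturbed
image stays non-negative and the noise is signal-dependent like Poisson
counts, while remaining trivially re-derivable in tests.  One seeded stream
drives all views of one acquisition.

### Inverse-crime avoidance

Testing an inverter with the same discrete operator that generated the data
("inverse crime") flatters it.  The rebinned-acquisition path simulates on a
4× finer grid (nearest-neighbour upsampled phantom, 128 bins at N = 32) and
averages groups of 4 adjacent bins, scaled by 1/4 to convert fine-grid line
integrals into coarse-pixel units.  The mismatch against the direct coarse
projection is small but nonzero — mean absolute deviation ≈ 0.1–1% of the
coarse sinogram's maximum, bounded in tests at 5% — which is exactly the
regime wanted: the reconstruction model is *almost* right.

## Quadratic models

For binary pixels the squared residual `‖Mx − y‖²` is a QUBO with
`linear_i = (MᵀM)_ii − 2(Mᵀy)_i`, `coupler_ij = 2(MᵀM)_ij` (`i < j`), and
offset `yᵀy`.  Two bookkeeping conventions are forced by requiring
`energy(x) = ‖Mx − y‖²` for *all* assignments (the module's governing
contract, enumeration-tested): the diagonal of `MᵀM` folds into the linear
bias because `x_i² = x_i`, and the symmetric cross terms double the stored
upper-triangular coupler.  The constant offset is kept inside the model so
energies read as squared residuals; couplers with magnitude below 1e−12 are
dropped.  Ising form is the exact substitution `x = (s+1)/2`.

Integer images keep an explicit diagonal quadratic term (`x_i² ≠ x_i`) in a
bounded-integer model, lowered to a QUBO by the positional encoding
`x_p = Σ_b 2^b z_{p,b}`.  The encoder refuses bit widths whose cap
`2^R − 1` cannot reach the upper bound; when the cap exceeds the bound the
encoded model relaxes the box to the cap (standard practice — the energy
identity holds on the whole encoded domain).  "4-bit" gray range is
`levels = 16` (values 0–15); digit-like images use `levels = 17`
(values 0–16, needing 5 bits) — the two conventions coexist, so `levels`
is always explicit.

## Samplers

`solve_exact` enumerates all `2^n` assignments in integer order with bit 0
as the most significant position, which makes integer order coincide with
lexicographic order on bit-tuples; ties within 1e−9 of the minimum are all
returned, then up to 100 next-best states.  It is the oracle every other
sampler is audited against (no sampler may return a lower energy).

`solve_simulated_annealing` is the classical stand-in for the
quantum/hybrid hardware: independent reads, each a single-spin-flip
Metropolis walk over a geometric inverse-temperature ladder from
`β = 1/ΔE_max` to `1000/ΔE_max` (`ΔE_max` = largest possible single-flip
energy change), one proposed flip per variable per sweep in fixed order,
finished by a zero-temperature greedy descent to a single-flip local
minimum.  Local fields are maintained incrementally (O(1) per proposal,
O(n) per acceptance; numba-compiled), and all randomness comes from one
seeded generator, so runs are bitwise reproducible.  Identical assignments
aggregate into occurrence counts; records sort by (energy, lexicographic
bits).  Default strength scales with the variable count (e.g. 16 reads ×
6000 sweeps at n = 1024), sized so a 32×32 binary reconstruction takes tens
of seconds on one core.  `time_limit` is accepted for interface parity with
hybrid solvers and logged, nothing more; the remote-QPU backend is a stub
that refuses to run, so nothing here ever needs network access.

The *uncertainty map* is the occurrence-weighted population variance of the
decoded pixel values over all returned samples, energies ignored.

## Baselines

All baselines invert the identical sinogram.  FBP is matrix-free: ramp
(Ram-Lak) filtering in the frequency domain (zero-padded to ≥ 4× the bin
count), backprojection by rotating the smeared filtered view with the
projector's own convention, scaled by `π/(2V)` — implementing it in-house
keeps it aligned with the forward geometry to the pixel, where a foreign
radon convention would introduce a half-bin shift.  SART does per-view
additive updates `x += λ·M_vᵀ((y_v − M_v x)/rowsum)/colsum` with λ = 0.5
and zero-sum rows/columns skipped.  DART (2 iterations by default)
alternates discretization with a SART re-solve restricted to "free" pixels
(those with a 4-neighbour at a different level), after subtracting the
fixed pixels' forward projection from the data; the canonical random free
fraction is omitted so runs are deterministic — a documented deviation that
in rare configurations can fix a wrongly-segmented interior pixel DART then
cannot revisit.  The pseudoinverse reconstructor truncates the SVD at
`cutoff · σ_max` (relative convention), floored at the numerical-rank
threshold `σ_max · max(m,n) · ε` so `cutoff = 0` means "untruncated" in the
standard library sense; the system matrices here are rank-deficient (null
space of dimension 3–12 at N = 4–16), but the minimum-norm solution lies
close enough to the binary ground truth that discretization recovers it
exactly on noiseless fully determined problems.

Discretization — clip to `[0, levels−1]`, round half up — is the shared
final step for continuous methods, and ties at `x.5` go up (midpoint rule;
the least surprising choice given no stated convention).

## Metrics

RMSE is per-pixel.  SSIM uses uniform (not Gaussian) windows, 7×7 by
default and 3×3 when the image cannot host 7×7 (N = 4), stabilizers
`c1 = (0.01·L)²`, `c2 = (0.03·L)²` with data range `L = levels − 1`,
unbiased local covariance normalization, and averaging over windows fully
inside the image — verified against an independent reference implementation
to 1e−6.

## Synthetic phantoms

The four binary families are procedural stand-ins with deliberately
different frequency content: `foam` thresholds smoothed Gaussian noise at
its median; `tree` draws recursive branching strokes; `snowflake` mirrors
random radial rays six-fold; `molecule` packs disjoint filled disks.  They
emulate the *variance in image content* the benchmark needs, not any
specific pixel pattern; degenerate draws at very small sizes are repaired
deterministically so both classes are always present.  `shepp_logan`
quantizes the standard head phantom (bilinear resize, scale to
`[0, levels−1]`, round half up); `digit` sums a few anisotropic Gaussian
bumps and quantizes, emulating small handwritten-digit rasters.  What these
phantoms do **not** model: anatomical structure, attenuation, scatter,
detector blur, or continuous activity values — so passing benchmarks here
demonstrates correctness of the optimization mapping and solver plumbing,
not clinical readiness.

## Problem sizes and known limitations

Experiments default to N ≤ 32 (binary, 1024 variables) and N ≤ 16
(integer), with the exact solver reserved for n ≤ 22 variables; these sizes
make every benchmark reproducible in minutes on one core, and mirror the
regime where dense `MᵀM` couplings are tractable.  Known limitations:

* Plain simulated annealing is weaker than commercial hybrid solvers on
  binary-encoded *integer* problems — the positional weights (1, 2, 4, 8)
  create steep barriers between codes — so gray-level reconstructions trail
  the pseudoinverse/DART baselines at N ≥ 8.  Binary problems do not suffer
  from this and reach energy 0 reliably up to N = 32.
* On fully determined noiseless binary problems the global minimum is
  occasionally *degenerate*: the rank-deficient system matrix admits
  another binary image with identical projections, and the energy-0 sample
  returned may then differ from ground truth in a few pixels.
* Underdetermined (2–4 view) problems have massively degenerate energy-0
  sets; which solution is returned depends on the seed, so quantitative
  few-view results have high variance by nature.
* The per-view mass-conservation error of the bilinear projector grows as
  N shrinks; at N = 4 it is a few percent.
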