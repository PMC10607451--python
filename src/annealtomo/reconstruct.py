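"""Reconstruction methods as scikit-learn style estimators.

Every reconstructor is calibrated to a projection geometry with ``fit`` (which
precomputes whatever the method needs — the system matrix, its pseudoinverse —
as trailing-underscore attributes) and then maps sinograms to images with
``transform`` (rows of vectorized sinograms in, rows of vectorized images out,
so the estimators compose with sklearn pipelines and model selection) or with
the convenience method ``reconstruct`` (one Sinogram in, one N x N image out).

Continuous methods (FBP, SART, pseudoinverse) return continuous images —
discretize explicitly with :func:`annealtomo.baselines.discretize`.  The
discrete methods (DART, annealing) return gray-level images directly.
"""

from __future__ import annotations

import math

import numpy as np
from skimage.transform import rotate as _sk_rotate
from sklearn.base import BaseEstimator, TransformerMixin

from .forward import Geometry, Sinogram, SystemMatrix, build_system_matrix
from .qubo import build_binary_qubo, build_integer_model, encode_integer_as_binary
from .samplers import (
    best_sample,
    solve_exact,
    solve_qpu_stub,
    solve_simulated_annealing,
    uncertainty_map,
)


def _as_geometry(X) -> Geometry:
    if isinstance(X, Geometry):
        return X
    if isinstance(X, Sinogram):
        return X.geometry
    raise TypeError("fit expects a Geometry (or a Sinogram carrying one)")


def _discretize(image: np.ndarray, levels: int) -> np.ndarray:
    clipped = np.clip(np.asarray(image, dtype=float), 0, levels - 1)
    return np.floor(clipped + 0.5).astype(np.int64)


class _BaseReconstructor(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing; subclasses implement _reconstruct_vector."""

    def fit(self, X, y=None):
        self.geometry_ = _as_geometry(X)
        self._prepare()
        return self

    def _prepare(self) -> None:  # pragma: no cover - overridden where needed
        pass

    def _check_fitted(self):
        if not hasattr(self, "geometry_"):
            raise RuntimeError("reconstructor is not fitted; call fit(geometry) first")

    def _sino_rows(self, Y) -> np.ndarray:
        g = self.geometry_
        if isinstance(Y, Sinogram):
            if Y.geometry != g:
                raise ValueError("sinogram geometry differs from the fitted geometry")
            return Y.vector()[None, :]
        arr = np.asarray(Y, dtype=float)
        if arr.ndim == 2 and arr.shape == (g.n_views, g.n_bins):
            return arr.reshape(1, -1)
        if arr.ndim == 1 and arr.size == g.n_measurements:
            return arr[None, :]
        if arr.ndim == 2 and arr.shape[1] == g.n_measurements:
            return arr
        raise ValueError(
            f"cannot interpret input of shape {arr.shape} as sinograms for geometry {g}"
        )

    def transform(self, Y) -> np.ndarray:
        self._check_fitted()
        rows = self._sino_rows(Y)
        out = np.stack([self._reconstruct_vector(r) for r in rows])
        return out

    def reconstruct(self, sino) -> np.ndarray:
        self._check_fitted()
        n = self.geometry_.image_size
        return self.transform(sino)[0].reshape(n, n)

    def _reconstruct_vector(self, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class FBPReconstructor(_BaseReconstructor):
    """Filtered backprojection with a ramp (Ram-Lak) filter.

    Matrix-free: each view is filtered in the frequency domain and smeared
    back by rotating with the projector's own angle convention, so the
    reconstruction is aligned with the forward model to the pixel.
    """

    def __init__(self, pad_factor: int = 4):
        self.pad_factor = pad_factor

    def _reconstruct_vector(self, y: np.ndarray) -> np.ndarray:
        g = self.geometry_
        if g.n_views < 1:
            raise ValueError("FBP needs at least one view")
        sino = y.reshape(g.n_views, g.n_bins)
        n, b = g.image_size, g.n_bins
        size = max(64, int(2 ** math.ceil(math.log2(self.pad_factor * b))))
        ramp = 2.0 * np.abs(np.fft.rfftfreq(size))
        rec = np.zeros((n, n))
        for k, angle in enumerate(g.angles):
            padded = np.zeros(size)
            padded[:b] = sino[k]
            filtered = np.fft.irfft(np.fft.rfft(padded) * ramp, n=size)[:b]
            smear = np.tile(filtered, (n, 1))
            rec += _sk_rotate(smear, -float(angle), order=1, preserve_range=True)
        return (rec * np.pi / (2.0 * g.n_views)).ravel()


def _sart_sweeps(
    M: np.ndarray,
    y: np.ndarray,
    geometry: Geometry,
    x0: np.ndarray,
    iterations: int,
    relaxation: float,
    column_mask: np.ndarray | None = None,
) -> np.ndarray:
    """SART: per-view additive updates x += lam * M_v^T((y_v - M_v x)/rowsum)/colsum,
    sweeping views in angle order; one iteration = one full sweep.  Zero-sum
    rows/columns are skipped.  ``column_mask`` restricts updates to a pixel
    subset (used by DART's free-pixel solves)."""
    eps = 1e-12
    b = geometry.n_bins
    x = x0.astype(float).copy()
    mask = np.ones(M.shape[1], dtype=bool) if column_mask is None else column_mask
    blocks = []
    for v in range(geometry.n_views):
        Mv = M[v * b : (v + 1) * b, :][:, mask]
        row_sums = Mv.sum(axis=1)
        col_sums = Mv.sum(axis=0)
        blocks.append((Mv, row_sums, col_sums, y[v * b : (v + 1) * b]))
    for _ in range(iterations):
        for Mv, row_sums, col_sums, yv in blocks:
            resid = yv - Mv @ x[mask]
            resid = np.where(row_sums > eps, resid / np.maximum(row_sums, eps), 0.0)
            corr = Mv.T @ resid
            corr = np.where(col_sums > eps, corr / np.maximum(col_sums, eps), 0.0)
            x[mask] += relaxation * corr
    return x


class SARTReconstructor(_BaseReconstructor):
    """Simultaneous algebraic reconstruction (additive per-view updates)."""

    def __init__(self, iterations: int = 10, relaxation: float = 0.5):
        self.iterations = iterations
        self.relaxation = relaxation

    def _prepare(self) -> None:
        self.system_matrix_ = build_system_matrix(self.geometry_)

    def _reconstruct_vector(self, y: np.ndarray) -> np.ndarray:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        n2 = self.geometry_.image_size ** 2
        return _sart_sweeps(
            self.system_matrix_.values,
            y,
            self.geometry_,
            np.zeros(n2),
            self.iterations,
            self.relaxation,
        )


def _free_pixel_mask(discrete: np.ndarray) -> np.ndarray:
    """Pixels with at least one 4-neighbour at a different gray level."""
    d = discrete
    free = np.zeros_like(d, dtype=bool)
    free[:-1, :] |= d[:-1, :] != d[1:, :]
    free[1:, :] |= d[1:, :] != d[:-1, :]
    free[:, :-1] |= d[:, :-1] != d[:, 1:]
    free[:, 1:] |= d[:, 1:] != d[:, :-1]
    return free


class DARTReconstructor(_BaseReconstructor):
    """Discrete algebraic reconstruction (DART).

    Alternates a continuous SART solve with segmentation: pixels in the
    interior of a homogeneous region are fixed at their discrete level, their
    forward projection is subtracted from the data, and SART re-solves only
    the boundary ("free") pixels.  Deterministic variant: the free set is
    exactly the 4-neighbour boundary, with no random free fraction and no
    smoothing, which keeps runs bitwise reproducible.
    """

    def __init__(
        self,
        levels: int = 2,
        dart_iterations: int = 2,
        sart_iterations: int = 10,
        sart_subiterations: int = 1,
        relaxation: float = 0.5,
    ):
        self.levels = levels
        self.dart_iterations = dart_iterations
        self.sart_iterations = sart_iterations
        self.sart_subiterations = sart_subiterations
        self.relaxation = relaxation

    def _prepare(self) -> None:
        self.system_matrix_ = build_system_matrix(self.geometry_)

    def _reconstruct_vector(self, y: np.ndarray) -> np.ndarray:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        g = self.geometry_
        n = g.image_size
        M = self.system_matrix_.values
        x = _sart_sweeps(M, y, g, np.zeros(n * n), self.sart_iterations, self.relaxation)
        for _ in range(self.dart_iterations):
            d = _discretize(x.reshape(n, n), self.levels)
            free = _free_pixel_mask(d).ravel()
            if not free.any():
                return d.ravel().astype(float)
            fixed_image = np.where(~free, d.ravel(), 0).astype(float)
            y_res = y - M @ fixed_image
            x = _sart_sweeps(
                M, y_res, g, x, self.sart_subiterations, self.relaxation, column_mask=free
            )
            x = np.where(free, x, d.ravel().astype(float))
        return _discretize(x.reshape(n, n), self.levels).ravel().astype(float)


class PseudoinverseReconstructor(_BaseReconstructor):
    """Moore-Penrose pseudoinverse reconstruction x = M^+ y.

    ``cutoff`` truncates the SVD: singular values below cutoff * sigma_max are
    treated as zero (relative convention), which regularizes noisy and
    rank-deficient problems.
    """

    def __init__(self, cutoff: float = 0.0):
        self.cutoff = cutoff

    def _prepare(self) -> None:
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        self.system_matrix_ = build_system_matrix(self.geometry_)
        M = self.system_matrix_.values
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        smax = s[0] if s.size else 0.0
        # relative truncation, floored at the numerical-rank threshold so a
        # zero cutoff means "untruncated" in the standard library sense
        floor = smax * max(M.shape) * np.finfo(float).eps
        keep = s >= max(self.cutoff * smax, floor)
        inv = np.zeros_like(s)
        inv[keep] = 1.0 / s[keep]
        self.singular_values_ = s
        self.pinv_ = (Vt.T * inv) @ U.T

    def _reconstruct_vector(self, y: np.ndarray) -> np.ndarray:
        return self.pinv_ @ y


class AnnealingReconstructor(_BaseReconstructor):
    """Discrete reconstruction by quadratic binary optimization.

    Builds the QUBO (binary) or bounded-integer quadratic model (gray-level,
    lowered through an R-bit positional encoding) whose energy is the squared
    residual ||M x - y||^2, and samples it with the selected backend:

    * ``'exact'``  — exhaustive enumeration (ground-truth oracle, small n);
    * ``'sa'``     — seeded simulated annealing (default hardware stand-in);
    * ``'auto'``   — exact when the variable count allows it, else annealing;
    * ``'qpu-stub'`` — interface placeholder that refuses to run.

    After each reconstruction the full sample set and the pixel-wise
    uncertainty map (occurrence-weighted variance of the returned samples)
    are available as ``sample_set_`` and ``uncertainty_map_``.
    """

    def __init__(
        self,
        levels: int = 2,
        sampler: str = "auto",
        reads: int = 50,
        sweeps: int = 1000,
        seed: int | None = None,
        bits: int | None = None,
        max_exact_vars: int = 16,
    ):
        self.levels = levels
        self.sampler = sampler
        self.reads = reads
        self.sweeps = sweeps
        self.seed = seed
        self.bits = bits
        self.max_exact_vars = max_exact_vars

    def _prepare(self) -> None:
        self.system_matrix_ = build_system_matrix(self.geometry_)

    def _build_model(self, y: np.ndarray):
        if self.levels == 2:
            return build_binary_qubo(self.system_matrix_, y), None
        bits = self.bits if self.bits is not None else max(1, math.ceil(math.log2(self.levels)))
        integer = build_integer_model(self.system_matrix_, y, upper_bound=self.levels - 1)
        return encode_integer_as_binary(integer, bits)

    def _solve(self, model):
        choice = self.sampler
        if choice == "auto":
            choice = "exact" if model.n_vars <= self.max_exact_vars else "sa"
        if choice == "exact":
            return solve_exact(model, max_vars=max(self.max_exact_vars, 22))
        if choice == "sa":
            return solve_simulated_annealing(
                model, reads=self.reads, sweeps=self.sweeps, seed=self.seed
            )
        if choice == "qpu-stub":
            return solve_qpu_stub(model)
        raise ValueError(f"unknown sampler {self.sampler!r}")

    def _reconstruct_vector(self, y: np.ndarray) -> np.ndarray:
        model, encoding = self._build_model(y)
        samples = self._solve(model)
        n = self.geometry_.image_size
        image = best_sample(samples, encoding, n)
        self.sample_set_ = samples
        self.encoding_ = encoding
        self.uncertainty_map_ = uncertainty_map(samples, encoding, n)
        return image.ravel()
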