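"""Parallel-beam forward model: geometry, projection, system matrix, noise.

The projector follows the emission-tomography toy-problem convention: the view
at 0 degrees is taken from the top of the image (its line integrals are column
sums) and successive views rotate clockwise, with angles equally spaced on
[0, 180).  A view is computed by rotating the image about its center
((N-1)/2, (N-1)/2) with bilinear interpolation and zero padding, then summing
along the vertical axis.  Because rotation + summation is linear, each view is
a sparse matrix applied to the vectorized (row-major) image, and the explicit
system matrix M is those per-view matrices stacked — so M @ vec(x) equals
vec(project(x)) to machine precision by construction.

The count-noise surrogate perturbs the *image* independently per view with
integer offsets in {-1, 0, +1} ({0, +1} where the image is zero, keeping the
perturbed image non-negative), imitating signal-dependent Poisson noise in
low-count acquisitions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import sparse


@dataclass(frozen=True)
class Geometry:
    """Projection geometry: N x N image, V views, B detector bins per view.

    Angles are fixed to the equally-spaced ladder 180*k/V degrees,
    k = 0..V-1 (180 itself excluded).  B defaults to N.
    """

    image_size: int
    n_views: int
    n_bins: int = 0  # 0 -> defaults to image_size

    def __post_init__(self):
        if self.image_size < 2:
            raise ValueError("image_size must be >= 2")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.n_bins == 0:
            object.__setattr__(self, "n_bins", self.image_size)
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def angles(self) -> np.ndarray:
        """View angles in degrees: 180*k/V, strictly increasing, 180 excluded."""
        return 180.0 * np.arange(self.n_views) / self.n_views

    @property
    def n_measurements(self) -> int:
        return self.n_views * self.n_bins

    def to_dict(self) -> dict:
        return {
            "image_size": self.image_size,
            "n_views": self.n_views,
            "n_bins": self.n_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(d["image_size"], d["n_views"], d.get("n_bins", 0))


@dataclass
class Sinogram:
    """V x B matrix of line-integral measurements plus its geometry.

    Vectorized order of y: views in angle order, bins left-to-right within a
    view (row-major on V x B).
    """

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_views, self.geometry.n_bins)
        if self.values.shape != expected:
            raise ValueError(f"sinogram shape {self.values.shape} != geometry {expected}")

    def vector(self) -> np.ndarray:
        return self.values.ravel()


@dataclass
class SystemMatrix:
    """Dense m x n system matrix (m = V*B, n = N^2) with its geometry."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        g = self.geometry
        if self.values.shape != (g.n_measurements, g.image_size**2):
            raise ValueError("system matrix shape inconsistent with geometry")

    @property
    def shape(self):
        return self.values.shape


@lru_cache(maxsize=512)
def _view_operator(size: int, angle: float) -> sparse.csr_matrix:
    """Sparse (B=N, N^2) operator: rotate CCW by `angle` (bilinear, zero pad,
    center (N-1)/2) then sum along the vertical axis.

    Rotating the image counter-clockwise by the view angle realizes the
    "viewed from the top, then clockwise" acquisition convention.
    """
    n = size
    th = np.deg2rad(angle)
    c = (n - 1) / 2.0
    co, si = np.cos(th), np.sin(th)
    rows_d, cols_d = np.mgrid[0:n, 0:n]
    dr = rows_d.ravel() - c
    dc = cols_d.ravel() - c
    # inverse mapping: source coordinates sampled for each destination pixel
    sr = co * dr + si * dc + c
    sc = -si * dr + co * dc + c
    r0 = np.floor(sr).astype(int)
    c0 = np.floor(sc).astype(int)
    fr = sr - r0
    fc = sc - c0
    bins = cols_d.ravel()  # destination column = detector bin
    data, row_idx, col_idx = [], [], []
    for ri, wi in ((r0, 1.0 - fr), (r0 + 1, fr)):
        for ci, wj in ((c0, 1.0 - fc), (c0 + 1, fc)):
            w = wi * wj
            keep = (ri >= 0) & (ri < n) & (ci >= 0) & (ci < n) & (w != 0)
            data.append(w[keep])
            row_idx.append(bins[keep])
            col_idx.append((ri * n + ci)[keep])
    mat = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(row_idx), np.concatenate(col_idx))),
        shape=(n, n * n),
    )
    return mat.tocsr()


_DENSE_LIMIT = 64  # dense stacked operator cached up to this image size


@lru_cache(maxsize=8)
def _stacked_operator(size: int, n_views: int) -> np.ndarray:
    """Dense (V*B, N^2) stack of the per-view operators.

    `project` and `build_system_matrix` both read from this one array for
    N <= 64, which makes the matrix/operator consistency invariant bitwise
    exact rather than merely close.
    """
    angles = 180.0 * np.arange(n_views) / n_views
    return sparse.vstack([_view_operator(size, float(a)) for a in angles]).toarray()


def _check_image(image: np.ndarray, geometry: Geometry) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.shape != (geometry.image_size, geometry.image_size):
        raise ValueError(
            f"image shape {image.shape} does not match geometry size {geometry.image_size}"
        )
    if geometry.n_bins != geometry.image_size:
        raise ValueError("project requires n_bins == image_size; use rebin_sinogram for coarser bins")
    return image


def project(image: np.ndarray, geometry: Geometry) -> Sinogram:
    """Forward-project an image into a sinogram (one row per view)."""
    image = _check_image(image, geometry)
    x = image.ravel()
    g = geometry
    if g.image_size <= _DENSE_LIMIT:
        out = (_stacked_operator(g.image_size, g.n_views) @ x).reshape(g.n_views, g.n_bins)
    else:
        out = np.empty((g.n_views, g.n_bins))
        for k, a in enumerate(g.angles):
            out[k] = _view_operator(g.image_size, float(a)) @ x
    return Sinogram(out, geometry)


def build_system_matrix(geometry: Geometry) -> SystemMatrix:
    """Assemble the dense m x n system matrix for a geometry.

    Column j is the vectorized sinogram of the unit image with a single 1 at
    pixel j; equivalently the per-view operators stacked, so that
    M @ vec(x) == vec(project(x, geometry)) holds exactly.
    """
    if geometry.n_bins != geometry.image_size:
        raise ValueError("system matrix requires n_bins == image_size")
    if geometry.image_size > _DENSE_LIMIT:
        raise ValueError(
            f"dense system matrix refused for N > {_DENSE_LIMIT} "
            "(use the matrix-free projector on fine grids)"
        )
    return SystemMatrix(
        _stacked_operator(geometry.image_size, geometry.n_views).copy(), geometry
    )


def rebin_sinogram(sino: Sinogram, factor: int, scale: float | None = None) -> Sinogram:
    """Average groups of ``factor`` adjacent bins and rescale to coarse-pixel units.

    The default ``scale = 1/factor`` converts line integrals measured on a
    fine grid into the units of a grid coarsened by the same factor (a ray
    through the fine grid accumulates about ``factor`` times more samples).
    The view count and angles are unchanged; the attached geometry refers to
    the coarse grid.
    """
    if factor < 1 or sino.geometry.n_bins % factor != 0:
        raise ValueError(f"factor {factor} must divide n_bins {sino.geometry.n_bins}")
    if scale is None:
        scale = 1.0 / factor
    v, b = sino.values.shape
    coarse = sino.values.reshape(v, b // factor, factor).mean(axis=2) * scale
    g = sino.geometry
    new_geom = Geometry(
        image_size=g.image_size // factor if g.image_size % factor == 0 else g.image_size,
        n_views=g.n_views,
        n_bins=b // factor,
    )
    return Sinogram(coarse, new_geom)


def sample_noise_field(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one integer noise field for one view.

    Offsets are uniform over {-1, 0, +1} where the image is positive and over
    {0, +1} where it is zero, so image + noise stays non-negative.
    """
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.integer):
        if not np.allclose(image, np.round(image)):
            raise ValueError("noise model requires an integer-valued image")
        image = np.round(image).astype(np.int64)
    if image.min() < 0:
        raise ValueError("noise model requires a non-negative image")
    three = rng.integers(-1, 2, size=image.shape)
    two = rng.integers(0, 2, size=image.shape)
    return np.where(image != 0, three, two)


def project_with_noise(image: np.ndarray, geometry: Geometry, seed: int) -> Sinogram:
    """Project with an independent noise realization of the image per view.

    Each view v draws its own noise field n_v from a single seeded stream and
    measures project(image + n_v) at that view's angle, imitating independent
    low-count acquisitions.
    """
    img = np.asarray(image)
    if not np.issubdtype(img.dtype, np.integer) and not np.allclose(img, np.round(img)):
        raise ValueError("noise model requires an integer-valued image")
    img = np.round(np.asarray(img, dtype=float)).astype(np.int64)
    _check_image(img, geometry)
    rng = np.random.default_rng(seed)
    g = geometry
    out = np.empty((g.n_views, g.n_bins))
    dense = _stacked_operator(g.image_size, g.n_views) if g.image_size <= _DENSE_LIMIT else None
    for k, a in enumerate(g.angles):
        noisy = (img + sample_noise_field(img, rng)).ravel().astype(float)
        if dense is not None:
            out[k] = dense[k * g.n_bins : (k + 1) * g.n_bins] @ noisy
        else:
            out[k] = _view_operator(g.image_size, float(a)) @ noisy
    return Sinogram(out, geometry)


# ---------------------------------------------------------------------------
# plain-text I/O

def save_sinogram_csv(sino: Sinogram, path) -> None:
    """CSV (one row per view) plus a JSON sidecar `<path>.json` with the geometry."""
    np.savetxt(path, sino.values, delimiter=",")
    with open(str(path) + ".json", "w") as fh:
        json.dump(sino.geometry.to_dict(), fh)


def load_sinogram_csv(path) -> Sinogram:
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    with open(str(path) + ".json") as fh:
        geom = Geometry.from_dict(json.load(fh))
    return Sinogram(values, geom)


def save_system_matrix_csv(matrix: SystemMatrix, path, force: bool = False) -> None:
    """CSV export; refuses image_size > 64 unless ``force`` (the dense matrix
    grows as N^4 and the text form becomes unwieldy)."""
    if matrix.geometry.image_size > 64 and not force:
        raise ValueError("refusing to write system matrix for N > 64; pass force=True to override")
    np.savetxt(path, matrix.values, delimiter=",")
    with open(str(path) + ".json", "w") as fh:
        json.dump(matrix.geometry.to_dict(), fh)


def load_system_matrix_csv(path) -> SystemMatrix:
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    with open(str(path) + ".json") as fh:
        geom = Geometry.from_dict(json.load(fh))
    return SystemMatrix(values, geom)
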