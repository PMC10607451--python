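"""Procedural ground-truth phantoms for discrete tomography experiments.

Six phantom families are provided.  Four are binary toy images with
deliberately different frequency content — ``foam`` (thresholded smoothed
noise blobs), ``tree`` (recursive branching strokes), ``snowflake`` (six-fold
mirrored random rays) and ``molecule`` (a cluster of disjoint filled disks).
The remaining two are gray-level: ``shepp_logan`` (the standard head phantom
quantized to a requested number of levels) and ``digit`` (smooth 8x8-style
blob images with small-integer values, emulating handwritten-digit rasters
with intensities in [0, levels-1]).

All phantoms are square integer arrays with values in {0, ..., levels-1},
vectorized row-major (top-left origin) wherever they appear as a vector.
Generation is deterministic per (kind, size, levels, seed).
"""

from __future__ import annotations

import csv

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.data import shepp_logan_phantom
from skimage.draw import disk as draw_disk, line as draw_line
from skimage.transform import resize

PHANTOM_KINDS = ("foam", "tree", "snowflake", "molecule", "shepp_logan", "digit")
BINARY_KINDS = ("foam", "tree", "snowflake", "molecule")


def _validate_size(size: int, minimum: int = 2) -> None:
    if int(size) != size or size < minimum:
        raise ValueError(f"phantom size must be an integer >= {minimum}, got {size!r}")


def _ensure_both_classes(img: np.ndarray) -> np.ndarray:
    """Guarantee the binary-phantom contract (both classes present).

    Degenerate draws are possible only at the very smallest sizes; they are
    repaired deterministically so the (kind, size, seed) -> image map stays
    a pure function.
    """
    if img.max() == 0:
        img[img.shape[0] // 2, img.shape[1] // 2] = 1
    if img.min() == 1:
        img[0, 0] = 0
    return img


def _foam(size: int, rng: np.random.Generator) -> np.ndarray:
    # Smoothed white noise thresholded at its median: blob-like regions whose
    # characteristic scale grows with the image.
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=max(1.0, size / 10.0), mode="reflect")
    img = (smooth > np.median(smooth)).astype(np.int64)
    return _ensure_both_classes(img)


def _tree(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros((size, size), dtype=np.int64)

    def branch(r: int, c: int, direction: float, length: int, depth: int) -> None:
        if length < 1 or depth > 4:
            return
        r2 = int(round(r - length * np.cos(direction)))
        c2 = int(round(c + length * np.sin(direction)))
        r2 = int(np.clip(r2, 0, size - 1))
        c2 = int(np.clip(c2, 0, size - 1))
        rr, cc = draw_line(r, c, r2, c2)
        img[rr, cc] = 1
        n_child = 2 if depth < 3 else int(rng.integers(1, 3))
        for _ in range(n_child):
            spread = rng.uniform(0.3, 0.9) * (1 if rng.random() < 0.5 else -1)
            branch(r2, c2, direction + spread, int(length * rng.uniform(0.5, 0.75)), depth + 1)

    trunk = max(1, size // 3)
    branch(size - 1, size // 2, 0.0, trunk, 0)
    branch(size - 1 - trunk, size // 2, rng.uniform(-0.4, 0.4), max(1, size // 4), 1)
    return _ensure_both_classes(img)


def _snowflake(size: int, rng: np.random.Generator) -> np.ndarray:
    # Random radial rays in one wedge, replicated with 6-fold rotational
    # symmetry and mirrored, drawn on a fine polar raster.
    img = np.zeros((size, size), dtype=np.int64)
    center = (size - 1) / 2.0
    max_r = center
    n_rays = int(rng.integers(2, 5))
    base_angles = rng.uniform(0.0, np.pi / 6.0, n_rays)
    lengths = rng.uniform(0.45, 1.0, n_rays) * max_r
    for theta0, length in zip(base_angles, lengths):
        for k in range(6):
            for sign in (+1, -1):
                theta = sign * theta0 + k * np.pi / 3.0
                radii = np.linspace(0.0, length, 4 * size)
                rr = np.round(center - radii * np.cos(theta)).astype(int)
                cc = np.round(center + radii * np.sin(theta)).astype(int)
                keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
                img[rr[keep], cc[keep]] = 1
    return _ensure_both_classes(img)


def _molecule(size: int, rng: np.random.Generator) -> np.ndarray:
    # Disjoint filled disks ("atoms"); rejection-sampled centers keep the
    # disks from merging where the grid allows it.
    img = np.zeros((size, size), dtype=np.int64)
    n_disks = int(rng.integers(3, 7))
    radius = max(1.0, size / 8.0)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_disks and attempts < 200:
        attempts += 1
        r = rng.uniform(radius, size - 1 - radius) if size > 2 * radius + 1 else rng.uniform(0, size - 1)
        c = rng.uniform(radius, size - 1 - radius) if size > 2 * radius + 1 else rng.uniform(0, size - 1)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= (2 * radius) ** 2 for r0, c0 in centers):
            centers.append((r, c))
    for r, c in centers:
        rr, cc = draw_disk((r, c), radius + 0.5, shape=img.shape)
        img[rr, cc] = 1
    return _ensure_both_classes(img)


def _shepp_logan(size: int, levels: int) -> np.ndarray:
    cont = resize(
        shepp_logan_phantom(), (size, size), order=1, anti_aliasing=True, mode="reflect"
    )
    cont = np.clip(cont, 0.0, None)
    if cont.max() > 0:
        cont = cont / cont.max()
    return np.floor(cont * (levels - 1) + 0.5).astype(np.int64)


def _digit(size: int, levels: int, rng: np.random.Generator) -> np.ndarray:
    # Sum of a few anisotropic Gaussian bumps along a random short stroke:
    # smooth, connected, digit-like intensity blobs.
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    img = np.zeros((size, size))
    n_blobs = int(rng.integers(2, 5))
    for _ in range(n_blobs):
        r0 = rng.uniform(0.2 * size, 0.8 * size)
        c0 = rng.uniform(0.2 * size, 0.8 * size)
        sr = rng.uniform(0.08, 0.3) * size
        sc = rng.uniform(0.08, 0.3) * size
        amp = rng.uniform(0.5, 1.0)
        img += amp * np.exp(-(((rows - r0) / sr) ** 2 + ((cols - c0) / sc) ** 2))
    img -= img.min()
    if img.max() > 0:
        img = img / img.max()
    return np.floor(img * (levels - 1) + 0.5).astype(np.int64)


def make_phantom(kind: str, size: int, levels: int = 2, seed: int = 0) -> np.ndarray:
    """Generate a deterministic square phantom.

    Parameters
    ----------
    kind : {'foam', 'tree', 'snowflake', 'molecule', 'shepp_logan', 'digit'}
        Phantom family.  The first four are binary and require ``levels=2``.
    size : int
        Image side length N (the image is N x N).
    levels : int
        Number of allowed gray levels L; values lie in {0, ..., L-1}.
    seed : int
        Seed for the pseudo-random construction.  The same
        (kind, size, levels, seed) always yields a bitwise-identical image.

    Returns
    -------
    numpy.ndarray of shape (size, size), dtype int64
    """
    if kind not in PHANTOM_KINDS:
        raise ValueError(f"unknown phantom kind {kind!r}; choose from {PHANTOM_KINDS}")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if kind in BINARY_KINDS:
        if levels != 2:
            raise ValueError(f"binary phantom kind {kind!r} requires levels=2")
        _validate_size(size, minimum=2)
    else:
        _validate_size(size, minimum=4 if kind == "shepp_logan" else 2)
    rng = np.random.default_rng(seed)
    if kind == "foam":
        return _foam(size, rng)
    if kind == "tree":
        return _tree(size, rng)
    if kind == "snowflake":
        return _snowflake(size, rng)
    if kind == "molecule":
        return _molecule(size, rng)
    if kind == "shepp_logan":
        return _shepp_logan(size, levels)
    return _digit(size, levels, rng)


def downsample_local_mean(image: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by taking local means of ``factor`` x ``factor`` blocks.

    The output is continuous (floating point); re-discretize explicitly with
    :func:`annealtomo.baselines.discretize` when a gray-level image is needed.
    The global mean of the image is preserved exactly.
    """
    image = np.asarray(image, dtype=float)
    n = image.shape[0]
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    if factor < 1 or n % factor != 0:
        raise ValueError(f"factor {factor} must divide image size {n}")
    m = n // factor
    return image.reshape(m, factor, m, factor).mean(axis=(1, 3))


def upsample_nearest(image: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour upsampling (each pixel becomes a factor x factor block).

    Exact right-inverse of :func:`downsample_local_mean`:
    ``downsample_local_mean(upsample_nearest(x, f), f) == x``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return np.kron(np.asarray(image), np.ones((factor, factor), dtype=np.asarray(image).dtype))


def save_phantom_csv(image: np.ndarray, path) -> None:
    """Write exact integer pixel values as CSV (the lossless interchange format)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for row in np.asarray(image):
            writer.writerow([int(v) if float(v).is_integer() else float(v) for v in row])


def load_phantom_csv(path) -> np.ndarray:
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    if np.allclose(arr, np.round(arr)):
        return arr.astype(np.int64)
    return arr


def save_phantom_png(image: np.ndarray, path, levels: int | None = None) -> None:
    """Write an 8-bit PNG with gray levels scaled to the full 0-255 range."""
    img = np.asarray(image, dtype=float)
    top = (levels - 1) if levels is not None else max(img.max(), 1)
    scaled = np.clip(img / top * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(scaled, mode="L").save(path)


def load_phantom_png(path, levels: int | None = None) -> np.ndarray:
    """Read an 8-bit gray PNG, optionally rescaling back to ``levels`` values."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    if levels is None:
        return arr
    return np.floor(arr / 255.0 * (levels - 1) + 0.5).astype(np.int64)
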