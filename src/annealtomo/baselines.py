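"""Functional front-end for the classical baseline reconstructions.

Thin wrappers over the estimator classes in :mod:`annealtomo.reconstruct`,
for scripts that want one-shot calls rather than fitted objects.  All
baselines consume the identical Sinogram/Geometry as the annealing path —
one forward model, many inverters.
"""

from __future__ import annotations

import numpy as np

from .forward import Sinogram, SystemMatrix
from .reconstruct import (
    DARTReconstructor,
    FBPReconstructor,
    PseudoinverseReconstructor,
    SARTReconstructor,
)


def discretize(image: np.ndarray, levels: int) -> np.ndarray:
    """Clip to [0, levels-1] then round to the nearest integer level (half up).

    The shared post-processing step that turns continuous reconstructions into
    gray-level images comparable with discrete ground truth; idempotent on
    already-discrete input.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    clipped = np.clip(np.asarray(image, dtype=float), 0, levels - 1)
    return np.floor(clipped + 0.5).astype(np.int64)


def reconstruct_fbp(sino: Sinogram) -> np.ndarray:
    """Ramp-filtered backprojection; continuous N x N image."""
    return FBPReconstructor().fit(sino.geometry).reconstruct(sino)


def reconstruct_sart(
    sino: Sinogram, iterations: int = 10, relaxation: float = 0.5
) -> np.ndarray:
    """SART; continuous N x N image."""
    est = SARTReconstructor(iterations=iterations, relaxation=relaxation)
    return est.fit(sino.geometry).reconstruct(sino)


def reconstruct_dart(
    sino: Sinogram,
    levels: int = 2,
    dart_iterations: int = 2,
    sart_iterations: int = 10,
    relaxation: float = 0.5,
) -> np.ndarray:
    """DART; discrete N x N image with values in {0, ..., levels-1}."""
    est = DARTReconstructor(
        levels=levels,
        dart_iterations=dart_iterations,
        sart_iterations=sart_iterations,
        relaxation=relaxation,
    )
    return est.fit(sino.geometry).reconstruct(sino).astype(np.int64)


def reconstruct_pinv(M: SystemMatrix, y, cutoff: float = 0.0) -> np.ndarray:
    """Truncated-pseudoinverse least squares; continuous N x N image."""
    est = PseudoinverseReconstructor(cutoff=cutoff)
    est.fit(M.geometry)
    yv = y.vector() if isinstance(y, Sinogram) else np.asarray(y, dtype=float).ravel()
    n = M.geometry.image_size
    return (est.pinv_ @ yv).reshape(n, n)
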