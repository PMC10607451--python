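"""Quadratic-model formulations of the least-squares reconstruction objective.

For a system matrix M and measurement vector y the reconstruction objective is

    H(x) = ||M x - y||^2 = x^T (M^T M) x - 2 (M^T y)^T x + y^T y.

For binary pixels x_i in {0, 1} the identity x_i^2 = x_i folds the diagonal of
M^T M into the linear bias, giving the QUBO

    linear_i   = (M^T M)_ii - 2 (M^T y)_i
    coupler_ij = 2 (M^T M)_ij            (stored once per unordered pair i<j)
    offset     = y^T y

so that the QUBO energy of every binary assignment equals the squared residual
exactly — the load-bearing identity every model in this module satisfies.  The
constant offset does not change the argmin but is kept inside the model so
reported energies read directly as squared residuals.

Gray-level problems use a bounded-integer quadratic model (the hybrid-solver
formulation), which can be lowered to a QUBO through a positional binary
encoding of each pixel (R bits per pixel -> N^2 * R binary variables).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .forward import Sinogram, SystemMatrix

_COUPLER_EPS = 1e-12


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, SystemMatrix):
        return M.values
    return np.asarray(M, dtype=float)


def _as_vector(y) -> np.ndarray:
    if isinstance(y, Sinogram):
        return y.vector()
    return np.asarray(y, dtype=float).ravel()


@dataclass
class QuboModel:
    """Quadratic unconstrained binary optimization model.

    energy(x) = sum_i linear_i x_i + sum_{i<j} coupler_ij x_i x_j + offset
    for x in {0,1}^n.  Couplers are keyed (i, j) with i < j only.
    """

    linear: np.ndarray
    couplers: dict = field(default_factory=dict)
    offset: float = 0.0

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).ravel()
        for (i, j) in self.couplers:
            if not (0 <= i < j < self.n_vars):
                raise ValueError(f"coupler key {(i, j)} must satisfy 0 <= i < j < n_vars")

    @property
    def n_vars(self) -> int:
        return self.linear.size

    def coupling_matrix(self) -> np.ndarray:
        """Dense symmetric matrix A with A_ij = A_ji = coupler_ij (zero diagonal).

        The pair term of the energy is x^T A x / 2; the local field at i is
        linear_i + (A @ x)_i, which drives single-flip samplers.
        """
        cached = getattr(self, "_dense_couplings", None)
        if cached is not None:
            return cached
        A = np.zeros((self.n_vars, self.n_vars))
        for (i, j), v in self.couplers.items():
            A[i, j] = A[j, i] = v
        self._dense_couplings = A
        return A

    def energy(self, x) -> float:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.n_vars:
            raise ValueError("assignment length mismatch")
        if not np.all((x == 0) | (x == 1)):
            raise ValueError("QUBO assignment must be binary")
        e = float(self.linear @ x) + self.offset
        for (i, j), v in self.couplers.items():
            e += v * x[i] * x[j]
        return e

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_vars": self.n_vars,
                "linear": self.linear.tolist(),
                "couplers": [[int(i), int(j), v] for (i, j), v in sorted(self.couplers.items())],
                "offset": self.offset,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "QuboModel":
        d = json.loads(text)
        return cls(
            linear=np.asarray(d["linear"], dtype=float),
            couplers={(int(i), int(j)): float(v) for i, j, v in d["couplers"]},
            offset=float(d["offset"]),
        )


@dataclass
class IsingModel:
    """Spin formulation: energy(s) = sum h_i s_i + sum_{i<j} J_ij s_i s_j + offset,
    s_i in {-1, +1}; equals the source QUBO's energy under s = 2x - 1."""

    h: np.ndarray
    J: dict = field(default_factory=dict)
    offset: float = 0.0

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float).ravel()

    @property
    def n_vars(self) -> int:
        return self.h.size

    def energy(self, s) -> float:
        s = np.asarray(s, dtype=float).ravel()
        if not np.all(np.abs(s) == 1):
            raise ValueError("Ising assignment must be +/-1 spins")
        e = float(self.h @ s) + self.offset
        for (i, j), v in self.J.items():
            e += v * s[i] * s[j]
        return e


@dataclass
class IntegerModel:
    """Bounded-integer quadratic model (the constrained-quadratic formulation).

    objective(x) = sum_i linear_i x_i + sum_i quad_diag_i x_i^2
                   + sum_{i<j} quadratic_ij x_i x_j + constant
    over integer x_i in [0, upper_bound].  For integer variables x_i^2 != x_i,
    so the diagonal quadratic term is stored explicitly; built from (M, y) the
    objective equals ||M x - y||^2 on the whole feasible box.
    """

    linear: np.ndarray
    quad_diag: np.ndarray
    quadratic: dict = field(default_factory=dict)
    constant: float = 0.0
    upper_bound: int = 1

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).ravel()
        self.quad_diag = np.asarray(self.quad_diag, dtype=float).ravel()
        if self.quad_diag.size != self.linear.size:
            raise ValueError("quad_diag / linear length mismatch")
        if self.upper_bound < 1:
            raise ValueError("upper_bound must be >= 1")

    @property
    def n_vars(self) -> int:
        return self.linear.size

    def energy(self, x) -> float:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.n_vars:
            raise ValueError("assignment length mismatch")
        if not np.allclose(x, np.round(x)) or x.min() < 0 or x.max() > self.upper_bound:
            raise ValueError(f"assignment must be integers in [0, {self.upper_bound}]")
        e = float(self.linear @ x) + float(self.quad_diag @ (x * x)) + self.constant
        for (i, j), v in self.quadratic.items():
            e += v * x[i] * x[j]
        return e


@dataclass
class BinaryEncoding:
    """Positional binary encoding: pixel p's value = sum_b 2^b z[p*bits + b]."""

    n_pixels: int
    bits: int

    @property
    def n_vars(self) -> int:
        return self.n_pixels * self.bits

    @property
    def weights(self) -> np.ndarray:
        return 2.0 ** np.arange(self.bits)

    def decode(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float).ravel()
        if z.size != self.n_vars:
            raise ValueError("bit-vector length mismatch")
        return z.reshape(self.n_pixels, self.bits) @ self.weights

    def encode(self, values) -> np.ndarray:
        values = np.asarray(values).ravel().astype(np.int64)
        if values.min() < 0 or values.max() > 2**self.bits - 1:
            raise ValueError("value out of encodable range")
        bits = (values[:, None] >> np.arange(self.bits)) & 1
        return bits.ravel().astype(np.int64)


def build_binary_qubo(M, y) -> QuboModel:
    """Map ||M x - y||^2 over binary x onto a QUBO (see module docstring)."""
    Mv = _as_matrix(M)
    yv = _as_vector(y)
    if Mv.shape[0] != yv.size:
        raise ValueError(f"M has {Mv.shape[0]} rows but y has {yv.size} entries")
    G = Mv.T @ Mv
    linear = np.diag(G) - 2.0 * (Mv.T @ yv)
    couplers = {}
    iu, ju = np.triu_indices(G.shape[0], k=1)
    vals = 2.0 * G[iu, ju]
    keep = np.abs(vals) > _COUPLER_EPS
    for i, j, v in zip(iu[keep].tolist(), ju[keep].tolist(), vals[keep].tolist()):
        couplers[(i, j)] = v
    model = QuboModel(linear=linear, couplers=couplers, offset=float(yv @ yv))
    dense = 2.0 * G
    np.fill_diagonal(dense, 0.0)
    dense[np.abs(dense) <= _COUPLER_EPS] = 0.0
    model._dense_couplings = dense
    return model


def build_integer_model(M, y, upper_bound: int) -> IntegerModel:
    """Map ||M x - y||^2 over integer x in [0, upper_bound]^n onto an IntegerModel."""
    if upper_bound < 1:
        raise ValueError("upper_bound must be >= 1")
    Mv = _as_matrix(M)
    yv = _as_vector(y)
    if Mv.shape[0] != yv.size:
        raise ValueError(f"M has {Mv.shape[0]} rows but y has {yv.size} entries")
    G = Mv.T @ Mv
    linear = -2.0 * (Mv.T @ yv)
    quad_diag = np.diag(G).copy()
    quadratic = {}
    iu, ju = np.triu_indices(G.shape[0], k=1)
    vals = 2.0 * G[iu, ju]
    keep = np.abs(vals) > _COUPLER_EPS
    for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
        quadratic[(int(i), int(j))] = float(v)
    return IntegerModel(
        linear=linear,
        quad_diag=quad_diag,
        quadratic=quadratic,
        constant=float(yv @ yv),
        upper_bound=int(upper_bound),
    )


def model_energy(model, x) -> float:
    """Objective value H(x) including the constant offset.

    For models built from (M, y) this equals ||M x - y||^2.  Raises on
    assignments outside the model's domain.
    """
    return model.energy(x)


def qubo_to_ising(model: QuboModel) -> IsingModel:
    """Exact change of variables x = (s + 1)/2; energies agree on all assignments."""
    n = model.n_vars
    h = model.linear / 2.0
    offset = model.offset + float(model.linear.sum()) / 2.0
    J = {}
    for (i, j), c in model.couplers.items():
        J[(i, j)] = c / 4.0
        h[i] += c / 4.0
        h[j] += c / 4.0
        offset += c / 4.0
    return IsingModel(h=h, J=J, offset=offset)


def encode_integer_as_binary(model: IntegerModel, bits: int) -> tuple[QuboModel, BinaryEncoding]:
    """Lower an integer model to a QUBO via R-bit positional encoding.

    The representable cap is 2^bits - 1; an error is raised if it cannot reach
    the model's upper bound.  (When the cap exceeds the bound, the encoded
    QUBO relaxes the box to [0, cap] — the energy identity holds on all of it.)
    The QUBO has n_vars * bits binary variables.
    """
    if bits < 1:
        raise ValueError("bits must be >= 1")
    cap = 2**bits - 1
    if cap < model.upper_bound:
        raise ValueError(
            f"{bits}-bit encoding caps at {cap} < upper_bound {model.upper_bound}"
        )
    n = model.n_vars
    enc = BinaryEncoding(n_pixels=n, bits=bits)
    w = enc.weights  # 2^0 .. 2^(bits-1)
    nz = n * bits
    linear = np.zeros(nz)
    couplers: dict = {}

    def add_coupler(a: int, b: int, v: float) -> None:
        key = (a, b) if a < b else (b, a)
        couplers[key] = couplers.get(key, 0.0) + v

    for p in range(n):
        base = p * bits
        # a_p * x_p  and  d_p * x_p^2 with z_b^2 = z_b
        for b in range(bits):
            linear[base + b] += model.linear[p] * w[b] + model.quad_diag[p] * w[b] ** 2
        for b in range(bits):
            for b2 in range(b + 1, bits):
                add_coupler(base + b, base + b2, 2.0 * model.quad_diag[p] * w[b] * w[b2])
    for (p, q), v in model.quadratic.items():
        for b in range(bits):
            for b2 in range(bits):
                add_coupler(p * bits + b, q * bits + b2, v * w[b] * w[b2])
    couplers = {k: v for k, v in couplers.items() if abs(v) > _COUPLER_EPS}
    return QuboModel(linear=linear, couplers=couplers, offset=model.constant), enc
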