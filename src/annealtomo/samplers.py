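"""QUBO solvers: exact enumeration, simulated annealing, and a QPU stub.

Hardware annealers return a *sample set*: a multiset of assignments, each with
its model energy and the number of times it occurred.  Both backends here honor
that contract, so reconstructions and uncertainty maps are solver-agnostic:

* ``solve_exact`` enumerates all 2^n assignments (a classical oracle for
  ground-truth minimization, feasible to ~22 variables) and returns every
  global minimizer plus up to 100 next-best states.
* ``solve_simulated_annealing`` runs independent single-spin-flip Metropolis
  anneals over a geometric inverse-temperature ladder, each finished with a
  zero-temperature greedy descent, as the classical stand-in for the
  quantum/hybrid hardware.  Fully deterministic per seed.

Tie-breaking everywhere is lexicographic on the bit-tuple, for reproducibility.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .qubo import BinaryEncoding, QuboModel

_TIE_TOL = 1e-9


@dataclass
class SampleRecord:
    assignment: np.ndarray  # int8 bits
    energy: float
    num_occurrences: int = 1


@dataclass
class SampleSet:
    """Energy-sorted solver output (ties ordered lexicographically)."""

    records: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def first(self) -> SampleRecord:
        if not self.records:
            raise ValueError("empty sample set")
        return self.records[0]

    def energies(self) -> np.ndarray:
        return np.array([r.energy for r in self.records])

    def to_json(self) -> str:
        return json.dumps(
            {
                "records": [
                    {
                        "assignment": "".join(str(int(b)) for b in r.assignment),
                        "energy": r.energy,
                        "num_occurrences": r.num_occurrences,
                    }
                    for r in self.records
                ],
                "metadata": self.metadata,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SampleSet":
        d = json.loads(text)
        recs = [
            SampleRecord(
                assignment=np.array([int(ch) for ch in r["assignment"]], dtype=np.int8),
                energy=float(r["energy"]),
                num_occurrences=int(r["num_occurrences"]),
            )
            for r in d["records"]
        ]
        return cls(records=recs, metadata=d.get("metadata", {}))


def _sort_records(records: list) -> list:
    return sorted(records, key=lambda r: (r.energy, tuple(int(b) for b in r.assignment)))


def _qubo_energies(X: np.ndarray, linear: np.ndarray, A: np.ndarray, offset: float) -> np.ndarray:
    """Energies of a batch of assignments (rows of X)."""
    return X @ linear + 0.5 * np.einsum("ij,ij->i", X, X @ A) + offset


def solve_exact(model: QuboModel, max_vars: int = 22) -> SampleSet:
    """Enumerate all 2^n binary assignments and rank them.

    Returns every global minimizer (energies within 1e-9 of the minimum are
    treated as tied) followed by up to 100 next-best states, ordered by
    (energy, lexicographic assignment).  Assignments are enumerated with bit 0
    as the most significant position, so integer order *is* lexicographic
    order on the bit-tuples.
    """
    n = model.n_vars
    if n > max_vars:
        raise ValueError(
            f"solve_exact refuses n_vars={n} > {max_vars}; "
            "use solve_simulated_annealing for larger models"
        )
    linear = model.linear
    A = model.coupling_matrix()
    total = 1 << n
    shifts = n - 1 - np.arange(n)
    energies = np.empty(total)
    chunk = 1 << 16
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        X = ((idx[:, None] >> shifts) & 1).astype(float)
        energies[start : start + idx.size] = _qubo_energies(X, linear, A, model.offset)
    order = np.argsort(energies, kind="stable")
    emin = energies[order[0]]
    tol = _TIE_TOL * max(1.0, abs(emin))
    n_ties = int(np.searchsorted(energies[order], emin + tol, side="right"))
    keep = min(total, n_ties + 100)
    records = []
    for rank in range(keep):
        i = int(order[rank])
        bits = ((i >> shifts) & 1).astype(np.int8)
        records.append(SampleRecord(bits, float(energies[i]), 1))
    records = _sort_records(records)
    return SampleSet(
        records=records,
        metadata={"sampler": "exact", "n_vars": n, "num_ground_states": n_ties},
    )


@njit(cache=True, fastmath=True)
def _anneal_kernel(linear, A, x, betas, uniforms):  # pragma: no cover - jitted
    n = x.size
    f = linear + A @ x.astype(np.float64)  # local fields: dE_i = (1-2x_i) f_i
    for t in range(betas.size):
        beta = betas[t]
        for i in range(n):
            dE = (1.0 - 2.0 * x[i]) * f[i]
            if dE <= 0.0 or uniforms[t, i] < np.exp(-beta * dE):
                delta = 1.0 - 2.0 * x[i]
                x[i] = 1 - x[i]
                row = A[i]  # A is symmetric: row i == column i, contiguous
                for j in range(n):
                    f[j] += row[j] * delta
    # zero-temperature greedy finish: strictly improving flips only
    improved = True
    while improved:
        improved = False
        for i in range(n):
            if (1.0 - 2.0 * x[i]) * f[i] < -1e-12:
                delta = 1.0 - 2.0 * x[i]
                x[i] = 1 - x[i]
                row = A[i]
                for j in range(n):
                    f[j] += row[j] * delta
                improved = True


def default_beta_range(model: QuboModel) -> tuple[float, float]:
    """Geometric annealing schedule endpoints derived from the largest possible
    single-flip energy change dE_max: hot beta = 1/dE_max (almost every move
    accepted), cold beta = 1000/dE_max."""
    A = model.coupling_matrix()
    de_max = float(np.max(np.abs(model.linear) + np.abs(A).sum(axis=1), initial=0.0))
    if de_max <= 0:
        return (0.1, 10.0)
    return (1.0 / de_max, 1000.0 / de_max)


def solve_simulated_annealing(
    model: QuboModel,
    reads: int = 50,
    sweeps: int = 1000,
    seed: int | None = None,
    beta_range: tuple[float, float] | None = None,
    time_limit: float | None = None,
) -> SampleSet:
    """Sample a QUBO with independent seeded Metropolis anneals.

    Each of ``reads`` runs starts from a uniformly random assignment, performs
    ``sweeps`` sweeps (one proposed flip per variable per sweep) along a
    geometric inverse-temperature ladder, then descends greedily to a
    single-flip local minimum.  Identical assignments are aggregated with
    occurrence counts; the result is deterministic per (model, reads, sweeps,
    seed).  ``time_limit`` is accepted for interface parity with hybrid
    solvers and recorded in the metadata only.
    """
    if reads < 1 or sweeps < 1:
        raise ValueError("reads and sweeps must be >= 1")
    n = model.n_vars
    linear = model.linear
    A = model.coupling_matrix()
    if beta_range is None:
        beta_range = default_beta_range(model)
    betas = np.geomspace(beta_range[0], beta_range[1], sweeps)
    rng = np.random.default_rng(seed)
    found: dict[bytes, int] = {}
    assignments: dict[bytes, np.ndarray] = {}
    for _ in range(reads):
        x = rng.integers(0, 2, size=n).astype(np.int8)
        uniforms = rng.random((sweeps, n))
        if n > 0:
            _anneal_kernel(linear, A, x, betas, uniforms)
        key = x.tobytes()
        found[key] = found.get(key, 0) + 1
        assignments[key] = x.copy()
    records = []
    for key, occ in found.items():
        x = assignments[key]
        e = float(_qubo_energies(x[None, :].astype(float), linear, A, model.offset)[0])
        records.append(SampleRecord(x, e, occ))
    records = _sort_records(records)
    return SampleSet(
        records=records,
        metadata={
            "sampler": "sa",
            "reads": reads,
            "sweeps": sweeps,
            "seed": seed,
            "beta_range": list(map(float, beta_range)),
            "time_limit": time_limit,
        },
    )


def solve_qpu_stub(model: QuboModel, **kwargs) -> SampleSet:
    """Placeholder for a remote quantum-annealer backend.

    Kept behind the same SampleSet contract so code written against it ports
    unchanged; disabled so no test or pipeline ever needs network access.
    """
    raise NotImplementedError(
        "the QPU backend is a stub with no hardware attached; "
        "use solve_exact or solve_simulated_annealing"
    )


def _decode_records(samples: SampleSet, encoding: BinaryEncoding | None) -> np.ndarray:
    if not samples.records:
        raise ValueError("empty sample set")
    rows = []
    for r in samples.records:
        if encoding is not None:
            rows.append(encoding.decode(r.assignment))
        else:
            rows.append(np.asarray(r.assignment, dtype=float))
    return np.stack(rows)


def best_sample(
    samples: SampleSet, encoding: BinaryEncoding | None = None, image_size: int | None = None
) -> np.ndarray:
    """Lowest-energy assignment (ties -> lexicographically smallest bit-tuple),
    decoded through ``encoding`` if given, reshaped row-major to N x N."""
    rec = samples.first
    vals = (
        encoding.decode(rec.assignment)
        if encoding is not None
        else np.asarray(rec.assignment, dtype=float)
    )
    if image_size is None:
        image_size = int(round(np.sqrt(vals.size)))
    if vals.size != image_size * image_size:
        raise ValueError(f"{vals.size} pixel values cannot form a {image_size}x{image_size} image")
    return vals.reshape(image_size, image_size)


def uncertainty_map(
    samples: SampleSet, encoding: BinaryEncoding | None = None, image_size: int | None = None
) -> np.ndarray:
    """Pixel-wise population variance of all returned samples.

    Weighted by occurrence counts and independent of the samples' energies —
    an interpretability by-product of stochastic solving (high variance marks
    pixels the sampler is unsure about).
    """
    values = _decode_records(samples, encoding)
    w = np.array([r.num_occurrences for r in samples.records], dtype=float)
    w = w / w.sum()
    mean = w @ values
    var = w @ (values**2) - mean**2
    var = np.clip(var, 0.0, None)  # guard tiny negative round-off
    if image_size is None:
        image_size = int(round(np.sqrt(var.size)))
    return var.reshape(image_size, image_size)


def scale_chain_strength(model: QuboModel) -> float:
    """Relative chain strength: max over |linear biases| and |couplers|.

    Consumed only by a physical-annealer backend (chains of physical qubits
    must not break); inert for the classical samplers.
    """
    vals = [float(np.max(np.abs(model.linear), initial=0.0))]
    if model.couplers:
        vals.append(max(abs(v) for v in model.couplers.values()))
    return max(vals)
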