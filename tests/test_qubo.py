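import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from annealtomo import (
    QuboModel,
    build_binary_qubo,
    build_integer_model,
    encode_integer_as_binary,
    model_energy,
    qubo_to_ising,
)
from conftest import enumerate_residuals


def all_assignments(n):
    shifts = n - 1 - np.arange(n)
    return ((np.arange(1 << n)[:, None] >> shifts) & 1).astype(float)


class TestBinaryQubo:
    def test_identity_system_coefficients(self):
        model = build_binary_qubo(np.eye(2), np.array([1.0, 0.0]))
        np.testing.assert_allclose(model.linear, [-1.0, 1.0])
        assert model.couplers == {}
        assert model.offset == pytest.approx(1.0)
        assert model.energy([1, 0]) == pytest.approx(0.0)

    def test_row_system_has_degenerate_minimum(self):
        model = build_binary_qubo(np.array([[1.0, 1.0]]), np.array([1.0]))
        np.testing.assert_allclose(model.linear, [-1.0, -1.0])
        assert model.couplers == {(0, 1): pytest.approx(2.0)}
        assert model.offset == pytest.approx(1.0)
        assert model.energy([1, 0]) == pytest.approx(0.0)
        assert model.energy([0, 1]) == pytest.approx(0.0)

    def test_zero_measurement_minimum_at_origin(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((5, 4))
        model = build_binary_qubo(M, np.zeros(5))
        np.testing.assert_allclose(model.linear, (M**2).sum(axis=0))
        assert model.offset == 0.0
        assert model.energy(np.zeros(4)) == 0.0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_binary_qubo(np.eye(3), np.zeros(2))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_energy_identity_full_enumeration(self, seed):
        # the module's load-bearing theorem: QUBO energy == ||Mx - y||^2 for
        # every binary assignment
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        M = rng.standard_normal((int(rng.integers(2, 10)), n))
        y = rng.standard_normal(M.shape[0])
        model = build_binary_qubo(M, y)
        oracle = enumerate_residuals(M, y)
        X = all_assignments(n)
        energies = np.array([model.energy(x) for x in X])
        np.testing.assert_allclose(energies, oracle, atol=1e-9)


class TestModelEnergy:
    def test_residual_at_zero_is_y_norm(self):
        rng = np.random.default_rng(4)
        M, y = rng.standard_normal((6, 5)), rng.standard_normal(6)
        model = build_binary_qubo(M, y)
        assert model_energy(model, np.zeros(5)) == pytest.approx(float(y @ y))

    def test_matches_residual_norm_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            M = rng.standard_normal((int(rng.integers(2, 8)), n))
            y = rng.standard_normal(M.shape[0])
            x = rng.integers(0, 2, n).astype(float)
            model = build_binary_qubo(M, y)
            r = M @ x - y
            assert abs(model_energy(model, x) - r @ r) < 1e-9

    def test_out_of_domain_assignment_rejected(self):
        model = build_binary_qubo(np.eye(2), np.zeros(2))
        with pytest.raises(ValueError):
            model_energy(model, [0, 2])
        integer = build_integer_model(np.eye(2), np.zeros(2), upper_bound=3)
        with pytest.raises(ValueError):
            model_energy(integer, [0, 4])


class TestIsingConversion:
    def test_zero_model_maps_to_zero(self):
        ising = qubo_to_ising(QuboModel(linear=np.zeros(3), offset=2.5))
        np.testing.assert_array_equal(ising.h, 0)
        assert ising.J == {}
        assert ising.offset == pytest.approx(2.5)

    def test_single_variable_closed_form(self):
        ising = qubo_to_ising(QuboModel(linear=np.array([1.0])))
        assert ising.h[0] == pytest.approx(0.5)
        assert ising.offset == pytest.approx(0.5)

    def test_energy_equivalence_on_all_assignments(self):
        rng = np.random.default_rng(7)
        linear = rng.standard_normal(6)
        couplers = {
            (i, j): float(rng.standard_normal()) for i in range(6) for j in range(i + 1, 6)
        }
        model = QuboModel(linear=linear, couplers=couplers, offset=rng.standard_normal())
        ising = qubo_to_ising(model)
        for x in all_assignments(6):
            assert abs(model.energy(x) - ising.energy(2 * x - 1)) < 1e-12


class TestIntegerModel:
    def test_scalar_system_minimized_at_target(self):
        model = build_integer_model(np.array([[1.0]]), np.array([3.0]), upper_bound=15)
        energies = [model_energy(model, [v]) for v in range(16)]
        assert int(np.argmin(energies)) == 3
        assert min(energies) == pytest.approx(0.0)

    def test_zero_measurement_minimized_at_origin(self):
        rng = np.random.default_rng(8)
        model = build_integer_model(rng.standard_normal((4, 3)), np.zeros(4), upper_bound=7)
        assert model_energy(model, [0, 0, 0]) == pytest.approx(0.0)

    def test_unit_bound_matches_binary_qubo_argmin(self):
        rng = np.random.default_rng(9)
        M = rng.standard_normal((8, 6))
        y = rng.standard_normal(8)
        integer = build_integer_model(M, y, upper_bound=1)
        qubo = build_binary_qubo(M, y)
        X = all_assignments(6)
        e_int = np.array([model_energy(integer, x) for x in X])
        e_bin = np.array([model_energy(qubo, x) for x in X])
        np.testing.assert_allclose(e_int, e_bin, atol=1e-9)
        assert set(np.flatnonzero(e_int <= e_int.min() + 1e-12)) == set(
            np.flatnonzero(e_bin <= e_bin.min() + 1e-12)
        )


class TestBinaryEncoding:
    def test_positional_weights(self):
        model = build_integer_model(np.eye(1), np.zeros(1), upper_bound=7)
        _, enc = encode_integer_as_binary(model, 3)
        np.testing.assert_array_equal(enc.encode([5]), [1, 0, 1])
        assert enc.decode([1, 0, 1])[0] == 5

    def test_variable_count_is_pixels_times_bits(self):
        model = build_integer_model(np.eye(4), np.zeros(4), upper_bound=15)
        qubo, enc = encode_integer_as_binary(model, 4)
        assert qubo.n_vars == 16 and enc.n_vars == 16

    def test_insufficient_bits_rejected(self):
        model = build_integer_model(np.eye(2), np.zeros(2), upper_bound=8)
        with pytest.raises(ValueError):
            encode_integer_as_binary(model, 3)

    def test_encoded_energy_matches_integer_objective_everywhere(self):
        rng = np.random.default_rng(11)
        M = rng.standard_normal((5, 3))
        y = rng.standard_normal(5)
        integer = build_integer_model(M, y, upper_bound=3)
        qubo, enc = encode_integer_as_binary(integer, 2)
        for v0 in range(4):
            for v1 in range(4):
                for v2 in range(4):
                    vals = np.array([v0, v1, v2])
                    bits = enc.encode(vals)
                    assert abs(qubo.energy(bits) - model_energy(integer, vals)) < 1e-9


def test_qubo_json_roundtrip_lossless():
    rng = np.random.default_rng(13)
    model = build_binary_qubo(rng.standard_normal((6, 5)), rng.standard_normal(6))
    back = QuboModel.from_json(model.to_json())
    np.testing.assert_array_equal(back.linear, model.linear)
    assert back.couplers == model.couplers
    assert back.offset == model.offset
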