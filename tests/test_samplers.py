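import numpy as np
import pytest

from annealtomo import (
    Geometry,
    QuboModel,
    SampleSet,
    best_sample,
    build_binary_qubo,
    build_integer_model,
    build_system_matrix,
    encode_integer_as_binary,
    make_phantom,
    model_energy,
    project,
    scale_chain_strength,
    solve_exact,
    solve_simulated_annealing,
    uncertainty_map,
)
from annealtomo.samplers import SampleRecord, solve_qpu_stub
from conftest import random_problem


class TestSolveExact:
    def test_degenerate_minimum_lexicographic_order(self):
        model = build_binary_qubo(np.array([[1.0, 1.0]]), np.array([1.0]))
        result = solve_exact(model)
        assert result.metadata["num_ground_states"] == 2
        np.testing.assert_array_equal(result.records[0].assignment, [0, 1])
        np.testing.assert_array_equal(result.records[1].assignment, [1, 0])

    def test_small_phantom_unique_minimizer_is_ground_truth(self):
        geom = Geometry(3, 3)
        phantom = make_phantom("molecule", 3, 2, seed=2)
        model = build_binary_qubo(build_system_matrix(geom), project(phantom, geom))
        result = solve_exact(model)
        assert result.metadata["num_ground_states"] == 1
        assert abs(result.first.energy) < 1e-9
        np.testing.assert_array_equal(best_sample(result, None, 3), phantom)

    def test_single_variable_negative_bias(self):
        result = solve_exact(QuboModel(linear=np.array([-1.0]), offset=0.5))
        np.testing.assert_array_equal(result.first.assignment, [1])
        assert result.first.energy == pytest.approx(-0.5)

    def test_refuses_oversized_model(self):
        with pytest.raises(ValueError, match="annealing"):
            solve_exact(QuboModel(linear=np.zeros(30)))

    def test_reported_energies_verify_against_model(self):
        rng = np.random.default_rng(0)
        model = build_binary_qubo(*random_problem(rng, n_max=8))
        for rec in solve_exact(model).records:
            assert abs(rec.energy - model_energy(model, rec.assignment)) < 1e-9


class TestSimulatedAnnealing:
    def test_single_read_single_record(self):
        model = build_binary_qubo(np.eye(3), np.array([1.0, 0.0, 1.0]))
        result = solve_simulated_annealing(model, reads=1, sweeps=10, seed=0)
        assert len(result) == 1
        assert result.first.num_occurrences == 1

    def test_occurrences_sum_to_reads(self):
        model = build_binary_qubo(np.eye(3), np.array([1.0, 0.0, 1.0]))
        result = solve_simulated_annealing(model, reads=25, sweeps=50, seed=1)
        assert sum(r.num_occurrences for r in result.records) == 25

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        model = build_binary_qubo(*random_problem(rng))
        a = solve_simulated_annealing(model, reads=10, sweeps=100, seed=7)
        b = solve_simulated_annealing(model, reads=10, sweeps=100, seed=7)
        assert a.to_json() == b.to_json()

    def test_energies_verify_and_never_beat_exact_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            model = build_binary_qubo(*random_problem(rng))
            exact_min = solve_exact(model).first.energy
            result = solve_simulated_annealing(model, reads=10, sweeps=200, seed=3)
            for rec in result.records:
                assert abs(rec.energy - model_energy(model, rec.assignment)) < 1e-9
            assert result.first.energy >= exact_min - 1e-9

    def test_finds_unique_minimum_with_high_reliability(self):
        rng = np.random.default_rng(4)
        hits = 0
        for trial in range(30):
            model = build_binary_qubo(*random_problem(rng))
            exact_min = solve_exact(model).first.energy
            result = solve_simulated_annealing(model, reads=50, sweeps=1000, seed=trial)
            hits += result.first.energy <= exact_min + 1e-9
        assert hits >= 28

    def test_noiseless_phantom_reaches_zero_energy(self, geom8, system8):
        phantom = make_phantom("foam", 8, 2, seed=1)
        model = build_binary_qubo(system8, project(phantom, geom8))
        successes = 0
        for seed in range(10):
            result = solve_simulated_annealing(model, reads=10, sweeps=500, seed=seed)
            successes += abs(result.first.energy) < 1e-6
        assert successes >= 8

    def test_invalid_parameters_raise(self):
        model = QuboModel(linear=np.zeros(2))
        with pytest.raises(ValueError):
            solve_simulated_annealing(model, reads=0)


class TestBestSample:
    def test_single_record(self):
        samples = SampleSet(records=[SampleRecord(np.array([1, 0, 0, 1], dtype=np.int8), 2.0)])
        np.testing.assert_array_equal(best_sample(samples, None, 2), [[1, 0], [0, 1]])

    def test_tie_break_prefers_lexicographically_smaller(self):
        # every one-hot assignment is a tied minimizer; lexicographic order wins
        model = build_binary_qubo(np.ones((1, 4)), np.array([1.0]))
        img = best_sample(solve_exact(model), None, 2)
        np.testing.assert_array_equal(img.ravel(), [0, 0, 0, 1])

    def test_decodes_through_encoding(self):
        # weight-sum oracle: bits (1,0) and (1,1) under weights (1,2) -> 1 and 3
        integer = build_integer_model(np.eye(4), np.zeros(4), upper_bound=3)
        _, enc = encode_integer_as_binary(integer, 2)
        bits = np.array([1, 0, 1, 1, 0, 0, 0, 1], dtype=np.int8)
        samples = SampleSet(records=[SampleRecord(bits, 0.0)])
        np.testing.assert_array_equal(best_sample(samples, enc, 2), [[1, 3], [0, 2]])

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            best_sample(SampleSet(), None, 2)


class TestUncertaintyMap:
    def test_identical_records_zero_variance(self):
        rec = SampleRecord(np.array([1, 0, 1, 1], dtype=np.int8), 0.0, 5)
        samples = SampleSet(records=[rec, SampleRecord(rec.assignment.copy(), 0.0, 3)])
        np.testing.assert_array_equal(uncertainty_map(samples, None, 2), np.zeros((2, 2)))

    def test_two_point_variance(self):
        samples = SampleSet(
            records=[
                SampleRecord(np.array([0, 0, 0, 0], dtype=np.int8), 0.0, 1),
                SampleRecord(np.array([1, 0, 0, 0], dtype=np.int8), 1.0, 1),
            ]
        )
        np.testing.assert_allclose(
            uncertainty_map(samples, None, 2), [[0.25, 0.0], [0.0, 0.0]]
        )

    def test_occurrence_weighted_variance(self):
        samples = SampleSet(
            records=[
                SampleRecord(np.array([0], dtype=np.int8), 0.0, 3),
                SampleRecord(np.array([1], dtype=np.int8), 1.0, 1),
            ]
        )
        assert uncertainty_map(samples, None, 1)[0, 0] == pytest.approx(3 / 16)


class TestChainStrength:
    def test_zero_model(self):
        assert scale_chain_strength(QuboModel(linear=np.zeros(3))) == 0.0

    def test_max_of_absolutes(self):
        model = QuboModel(linear=np.array([-1.0, 1.0]), couplers={(0, 1): 2.0})
        assert scale_chain_strength(model) == 2.0

    def test_homogeneous_scaling(self):
        rng = np.random.default_rng(6)
        model = build_binary_qubo(*random_problem(rng))
        scaled = QuboModel(
            linear=-3.0 * model.linear,
            couplers={k: -3.0 * v for k, v in model.couplers.items()},
            offset=model.offset,
        )
        assert scale_chain_strength(scaled) == pytest.approx(3.0 * scale_chain_strength(model))


def test_qpu_stub_refuses_to_run():
    with pytest.raises(NotImplementedError):
        solve_qpu_stub(QuboModel(linear=np.zeros(2)))


def test_integer_problems_through_encoding_obey_sampler_contract():
    rng = np.random.default_rng(15)
    M = rng.standard_normal((6, 4))
    y = rng.standard_normal(6)
    integer = build_integer_model(M, y, upper_bound=3)
    qubo, enc = encode_integer_as_binary(integer, 2)
    exact = solve_exact(qubo)
    sa = solve_simulated_annealing(qubo, reads=30, sweeps=500, seed=0)
    assert sa.first.energy >= exact.first.energy - 1e-9
    decoded = enc.decode(exact.first.assignment)
    assert abs(exact.first.energy - model_energy(integer, decoded)) < 1e-9
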