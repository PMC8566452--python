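"""Fractional-binary encoding, error functions and the GA engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellsqueeze.ga import (
    Bounds,
    DEFAULT_BOUNDS,
    GAConfig,
    N_BITS,
    decode,
    decode_vector,
    encode,
    error_entry,
    error_stretch,
    error_transit,
    ga_run,
)

# the worked 128-bit example string of the encoding scheme
EXAMPLE_BITS = (
    "0111111111011010101010001000110111100100111100100"
    "0111011011110110101011010101010000100001101010110"
    "110110101001001111000000110110"
)


class TestDecode:
    def test_worked_example(self):
        assert len(EXAMPLE_BITS) == 128
        assert round(decode(EXAMPLE_BITS, 0.0001, 10.0), 3) == 4.994

    def test_all_zero_hits_lower_bound(self):
        assert decode("0" * 128, 0.0001, 10.0) == 0.0001

    def test_all_one_approaches_upper_bound(self):
        v = decode("1" * 128, 0.0001, 10.0)
        assert v == pytest.approx(10.0, rel=1e-15)
        assert v <= 10.0

    def test_rejects_bad_strings(self):
        with pytest.raises(ValueError):
            decode("01" * 63 + "2x", 0.0, 1.0)
        with pytest.raises(ValueError):
            decode("0" * 100, 0.0, 1.0)

    def test_encode_decode_round_trip(self):
        for v in (0.0001, 1.234, 9.87):
            bits = encode(v, 0.0001, 10.0)
            assert decode(bits, 0.0001, 10.0) == pytest.approx(v, abs=1e-12)

    @given(
        st.integers(min_value=0, max_value=2**53 - 2),
        st.integers(min_value=0, max_value=2**53 - 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_bit_integer(self, a, b):
        """Decoding is monotone in the bit string read as an integer
        (exact for leading bit counts within float64 precision)."""
        lo, hi = (a, b) if a <= b else (b, a)
        if lo == hi:
            hi = lo + 1
        to_bits = lambda n: np.array(
            [(n >> (52 - k)) & 1 for k in range(53)] + [0] * 75, dtype=np.uint8
        )
        va = decode(to_bits(lo), 0.0, 1.0)
        vb = decode(to_bits(hi), 0.0, 1.0)
        assert va <= vb
        assert 0.0 <= va <= 1.0


class TestErrorFunctions:
    def test_stretch_zero_iff_equal(self, rng):
        a = rng.uniform(5, 10, 12)
        t = rng.uniform(1, 3, 12)
        assert error_stretch(a, t, a, t) == 0.0
        assert error_stretch([1.0], [2.0], [2.0], [4.0]) == pytest.approx(5.0)

    def test_stretch_matches_elementwise_oracle(self, rng):
        sa, st_, ea, et = (rng.uniform(4, 12, 12) for _ in range(4))
        brute = sum(
            (x - y) ** 2 + (u - v) ** 2 for x, y, u, v in zip(sa, ea, st_, et)
        )
        assert error_stretch(sa, st_, ea, et) == pytest.approx(brute, rel=1e-12)

    def test_entry_reported_values(self):
        # calculated vs measured entry times at the two flow rates
        assert error_entry([16595.0, 2094.0], [17540.0, 2470.0]) == pytest.approx(
            0.206, abs=5e-4
        )
        assert error_entry([90.0], [100.0]) == pytest.approx(0.1, rel=1e-12)
        assert error_entry([5.0, 7.0], [5.0, 7.0]) == 0.0

    def test_transit_reported_value(self):
        assert error_transit(532.0, 526.0) == pytest.approx(0.011, abs=5e-4)
        assert error_transit(150.0, 100.0) == pytest.approx(0.5, rel=1e-12)
        assert error_transit(3.0, 3.0) == 0.0

    def test_scale_invariance(self, rng):
        s = rng.uniform(10, 20, 2)
        e = rng.uniform(10, 20, 2)
        assert error_entry(3.7 * s, 3.7 * e) == pytest.approx(
            error_entry(s, e), rel=1e-12
        )
        assert error_transit(5 * s[0], 5 * e[0]) == pytest.approx(
            error_transit(s[0], e[0]), rel=1e-12
        )

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            error_entry([1.0], [0.0])
        with pytest.raises(ValueError):
            error_transit(1.0, 0.0)
        with pytest.raises(ValueError):
            error_stretch([1.0], [1.0], [1.0, 2.0], [1.0, 2.0])


class TestGARun:
    BOUNDS3 = Bounds(np.zeros(3), np.full(3, 10.0))

    def quadratic(self, target):
        return lambda p: float(((p - np.asarray(target)) ** 2).sum())

    def test_recovers_quadratic_optimum_all_seeds(self):
        target = [3.3, 7.1, 0.9]
        cfg = GAConfig(error_threshold=1e-8, max_iterations=30)
        for seed in range(5):
            res = ga_run(self.quadratic(target), self.BOUNDS3, cfg, seed)
            assert np.abs(res.best_params - np.asarray(target)).max() < 0.1
            # within 1% of the bound range
            assert np.abs(res.best_params - target).max() / 10.0 < 0.01

    def test_history_non_increasing(self):
        cfg = GAConfig(error_threshold=1e-12, max_iterations=15)
        res = ga_run(self.quadratic([5.0, 5.0, 5.0]), self.BOUNDS3, cfg, 3)
        assert all(a >= b for a, b in zip(res.history, res.history[1:]))

    def test_stops_on_threshold(self):
        cfg = GAConfig(error_threshold=5.0, max_iterations=50)
        res = ga_run(self.quadratic([5.0, 5.0, 5.0]), self.BOUNDS3, cfg, 0)
        assert res.stop_reason == "error_threshold"
        assert res.best_error < 5.0

    def test_stops_on_stall(self):
        # a flat objective can never improve: stops after the stall window
        cfg = GAConfig(
            population_size=10, candidates_per_iteration=10, elite_count=4,
            error_threshold=-1.0, stall_iterations=5, max_iterations=100,
        )
        res = ga_run(lambda p: 1.0, self.BOUNDS3, cfg, 0)
        assert res.stop_reason == "stall"
        assert len(res.history) <= 8

    def test_bit_reproducible(self):
        cfg = GAConfig(error_threshold=1e-10, max_iterations=8)
        r1 = ga_run(self.quadratic([2.0, 8.0, 4.0]), self.BOUNDS3, cfg, 11)
        r2 = ga_run(self.quadratic([2.0, 8.0, 4.0]), self.BOUNDS3, cfg, 11)
        assert r1.best_error == r2.best_error
        np.testing.assert_array_equal(r1.best_bits, r2.best_bits)
        assert r1.history == r2.history

    def test_failing_candidates_scored_infinite(self):
        calls = {"n": 0}

        def flaky(p):
            calls["n"] += 1
            if p[0] > 5.0:
                raise FloatingPointError("diverged")
            return float(p[0])

        cfg = GAConfig(
            population_size=10, candidates_per_iteration=10, elite_count=4,
            error_threshold=-1.0, stall_iterations=3, max_iterations=10,
        )
        res = ga_run(flaky, Bounds([0.0], [10.0]), cfg, 2)
        assert np.isfinite(res.best_error)
        assert res.best_params[0] <= 5.0
        assert len(res.failure_log) > 0

    def test_stretch_surrogate_recovery_below_unit_threshold(self):
        """Fitting the five elastic moduli to a synthetic 12-point axial/
        transverse stretch table drives the summed squared diameter error
        below the stop threshold of 1."""
        from cellsqueeze.forces import ElasticParams
        from cellsqueeze.ga import error_stretch
        from cellsqueeze.mesh import build_biconcave_mesh
        from cellsqueeze.simulation import run_stretch

        mesh = build_biconcave_mesh(radius=3.91, target_node_count=42)
        truth = ElasticParams(2.0, 1.0, 0.5, 2.0, 2.0, 0.0)
        forces = np.linspace(0.0, 40.0, 12)
        ref = run_stretch(mesh, truth, forces, residual_tol=1e-3)

        def objective(p):
            r = run_stretch(
                mesh, ElasticParams(p[0], p[1], p[2], p[3], p[4], 0.0),
                forces, residual_tol=1e-3, max_steps_per_force=20000,
            )
            return error_stretch(
                r.axial_diameter, r.transverse_diameter,
                ref.axial_diameter, ref.transverse_diameter,
            )

        bounds = Bounds(
            np.array([1e-4, 1e-4, 1e-4, 0.1, 0.1]), np.full(5, 10.0)
        )
        cfg = GAConfig(
            population_size=20, candidates_per_iteration=20, elite_count=8,
            error_threshold=1.0, max_iterations=30, stall_iterations=25,
        )
        res = ga_run(objective, bounds, cfg, seed=0)
        assert res.stop_reason == "error_threshold"
        assert res.best_error < 1.0

    def test_decoded_candidates_respect_bounds(self):
        b = Bounds.from_dict(DEFAULT_BOUNDS)
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, size=(6, N_BITS), dtype=np.uint8)
        v = decode_vector(bits, b)
        assert np.all(v >= b.lower) and np.all(v <= b.upper)
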