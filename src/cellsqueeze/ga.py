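"""Genetic-algorithm identification of the spring-network parameters.

Each parameter is encoded as a 128-bit fractional binary string mapped
affinely onto its bounds: q = Σ a_k 2^−(k+1), K = K_L + (K_U − K_L)·q.
Every iteration builds a pool of candidate parameter sets from the current
population by tournament selection, per-parameter single-point crossover
and per-bit mutation, injects the elite sets of the previous iteration
unchanged, evaluates everything, and keeps the best. The run stops when
the error drops below a threshold or the best candidate is unchanged for
a fixed number of iterations; elitism makes the best-error history
non-increasing.

The cancer-cell procedure is two-staged: the entry time is dominated by
deformability, so stage 1 identifies the six viscoelastic moduli against
entry times with wall friction switched off; stage 2 then freezes those
moduli and identifies the surface friction coefficient μ_f against the
transit time, separately for each flow rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "N_BITS",
    "Bounds",
    "DEFAULT_BOUNDS",
    "MU_F_BOUNDS",
    "GAConfig",
    "GAResult",
    "decode",
    "decode_vector",
    "encode",
    "error_stretch",
    "error_entry",
    "error_transit",
    "ga_run",
    "identify_cancer_cell",
    "IdentifiedParameters",
]

N_BITS = 128

#: Parameter bounds (K_L, K_U) for the six viscoelastic moduli.
DEFAULT_BOUNDS = {
    "k_s": (0.0001, 10.0),
    "k_b": (0.0001, 10.0),
    "k_al": (0.0001, 10.0),
    "k_ag": (0.1, 10.0),
    "k_V": (0.1, 10.0),
    "k_visc": (0.1, 10.0),
}
MU_F_BOUNDS = (0.0001, 1.0)


@dataclass(frozen=True)
class Bounds:
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_1d(np.asarray(self.lower, dtype=float))
        up = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lo.shape != up.shape or np.any(lo >= up):
            raise ValueError("need K_L < K_U per parameter")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @classmethod
    def from_dict(cls, d: dict) -> "Bounds":
        lo, up = zip(*d.values())
        return cls(np.array(lo), np.array(up))

    @property
    def n_params(self) -> int:
        return self.lower.size


_POW = 0.5 ** (np.arange(N_BITS) + 1)


def _as_bits(bits) -> np.ndarray:
    if isinstance(bits, str):
        if len(bits) != N_BITS or set(bits) - {"0", "1"}:
            raise ValueError(f"need a {N_BITS}-character binary string")
        bits = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    arr = np.asarray(bits, dtype=np.uint8)
    if arr.shape[-1] != N_BITS or np.any(arr > 1):
        raise ValueError(f"need {N_BITS} binary digits per parameter")
    return arr


def decode(bits, k_lower: float, k_upper: float) -> float:
    """Decode one 128-bit fractional binary string onto [K_L, K_U]."""
    if k_lower >= k_upper:
        raise ValueError("need K_L < K_U")
    q = float(_as_bits(bits) @ _POW)
    return k_lower + (k_upper - k_lower) * q


def decode_vector(bits: np.ndarray, bounds: Bounds) -> np.ndarray:
    """Decode an (n_params, 128) bit array to parameter values."""
    b = _as_bits(bits)
    q = b @ _POW
    return bounds.lower + (bounds.upper - bounds.lower) * q


def encode(value: float, k_lower: float, k_upper: float) -> np.ndarray:
    """Nearest 128-bit encoding of a value in [K_L, K_U] (test helper)."""
    q = (value - k_lower) / (k_upper - k_lower)
    if not 0.0 <= q <= 1.0:
        raise ValueError("value outside bounds")
    bits = np.zeros(N_BITS, dtype=np.uint8)
    for k in range(N_BITS):
        if q >= _POW[k]:
            bits[k] = 1
            q -= _POW[k]
    return bits


# ---------------------------------------------------------------------------
# error functions
# ---------------------------------------------------------------------------


def error_stretch(sim_axial, sim_transverse, exp_axial, exp_transverse) -> float:
    """Σ_i [(s_i^a − e_i^a)² + (s_i^t − e_i^t)²] over matched force points."""
    sa, st = np.asarray(sim_axial, float), np.asarray(sim_transverse, float)
    ea, et = np.asarray(exp_axial, float), np.asarray(exp_transverse, float)
    if not sa.shape == st.shape == ea.shape == et.shape:
        raise ValueError("mismatched table lengths")
    return float(((sa - ea) ** 2).sum() + ((st - et) ** 2).sum())


def error_entry(sim_entry_times, exp_entry_times) -> float:
    """Σ_n |1 − ET_s/ET_e| over the matched flow rates."""
    s = np.atleast_1d(np.asarray(sim_entry_times, float))
    e = np.atleast_1d(np.asarray(exp_entry_times, float))
    if s.shape != e.shape or s.size < 1:
        raise ValueError("need ≥ 1 matched entry-time pairs")
    if np.any(e == 0.0):
        raise ValueError("experimental entry time must be nonzero")
    return float(np.abs(1.0 - s / e).sum())


def error_transit(sim_transit_time: float, exp_transit_time: float) -> float:
    """|1 − TT_s/TT_e| for a single experiment."""
    if exp_transit_time == 0.0:
        raise ValueError("experimental transit time must be nonzero")
    return float(abs(1.0 - sim_transit_time / exp_transit_time))


# ---------------------------------------------------------------------------
# the GA engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GAConfig:
    """Search-control settings.

    Crossover and mutation follow the literal trigger rule: an event
    happens when a uniform draw exceeds the 0.8 threshold (i.e. at rate
    0.2); both thresholds are exposed. ``candidates_per_iteration`` is the
    pool evaluated each iteration (~400 in the production budget), and
    ``elite_count`` previous-best sets are injected unchanged.
    """

    population_size: int = 40
    candidates_per_iteration: int = 400
    elite_count: int = 20
    crossover_threshold: float = 0.8
    mutation_threshold: float = 0.8
    error_threshold: float = 1.0
    stall_iterations: int = 20
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.crossover_threshold < 1.0:
            raise ValueError("crossover threshold must lie in (0, 1)")
        if not 0.0 < self.mutation_threshold < 1.0:
            raise ValueError("mutation threshold must lie in (0, 1)")
        if self.elite_count >= self.candidates_per_iteration:
            raise ValueError("elite count must be below the candidate budget")


@dataclass
class GAResult:
    best_params: np.ndarray
    best_error: float
    best_bits: np.ndarray
    history: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    stop_reason: str = ""


def _evaluate(objective, bits, bounds, cache, log):
    key = bits.tobytes()
    if key in cache:
        return cache[key]
    params = decode_vector(bits, bounds)
    try:
        err = float(objective(params))
        if not math.isfinite(err):
            raise FloatingPointError(f"objective returned {err}")
    except Exception as exc:  # failed candidates score +inf, per contract
        log.append((params.copy(), repr(exc)))
        err = math.inf
    cache[key] = err
    return err


def ga_run(objective, bounds: Bounds, config: GAConfig, seed: int) -> GAResult:
    """Minimize ``objective(decoded parameter vector)`` over the bounds.

    Deterministic given (config, seed); candidate evaluation order cannot
    affect the result (the pool is built first, then evaluated, then
    sorted with a content-based tie-break). Failing candidates are scored
    +∞ and logged on the result as ``failure_log``.
    """
    rng = np.random.default_rng(seed)
    npar = bounds.n_params
    cache: dict[bytes, float] = {}
    failures: list = []

    def rand_pop(n):
        return rng.integers(0, 2, size=(n, npar, N_BITS), dtype=np.uint8)

    def tournament(pop, errs):
        i, j = rng.integers(0, len(pop), size=2)
        return pop[i] if errs[i] <= errs[j] else pop[j]

    def make_child(pop, errs):
        child = tournament(pop, errs).copy()
        if rng.random() > config.crossover_threshold:
            other = tournament(pop, errs)
            for p in range(npar):  # single-point crossover per parameter
                cut = int(rng.integers(1, N_BITS))
                child[p, cut:] = other[p, cut:]
        mask = rng.random(size=(npar, N_BITS)) > config.mutation_threshold
        child[mask] ^= 1
        return child

    population = rand_pop(config.population_size)
    errors = np.array(
        [_evaluate(objective, c, bounds, cache, failures) for c in population]
    )
    if not np.any(np.isfinite(errors)):
        raise RuntimeError(
            "every candidate in the initial population failed; last failure: "
            f"{failures[-1][1] if failures else 'unknown'}"
        )
    order = np.lexsort(
        (np.array([c.tobytes() for c in population]), errors)
    )
    population = population[order]
    errors = errors[order]
    history = [float(errors[0])]
    best_bits = population[0].copy()
    best_err = float(errors[0])
    stall = 0
    stop = "max_iterations"

    if best_err < config.error_threshold:
        stop = "error_threshold"
        result = GAResult(
            best_params=decode_vector(best_bits, bounds),
            best_error=best_err,
            best_bits=best_bits,
            history=history,
            n_evaluations=len(cache),
            stop_reason=stop,
        )
        result.failure_log = failures
        return result

    for _ in range(config.max_iterations):
        seen = {c.tobytes() for c in population[: config.elite_count]}
        pool = [population[i].copy() for i in range(min(config.elite_count, len(population)))]
        attempts = 0
        while (
            len(pool) < config.candidates_per_iteration
            and attempts < 20 * config.candidates_per_iteration
        ):
            child = make_child(population, errors)
            key = child.tobytes()
            attempts += 1
            if key not in seen:
                seen.add(key)
                pool.append(child)
        pool = np.array(pool)
        perr = np.array(
            [_evaluate(objective, c, bounds, cache, failures) for c in pool]
        )
        order = np.lexsort((np.array([c.tobytes() for c in pool]), perr))
        pool, perr = pool[order], perr[order]
        population = pool[: config.population_size]
        errors = perr[: config.population_size]
        if errors[0] < best_err:
            best_err = float(errors[0])
            best_bits = population[0].copy()
            stall = 0
        else:
            stall += 1
        history.append(best_err)
        if best_err < config.error_threshold:
            stop = "error_threshold"
            break
        if stall >= config.stall_iterations:
            stop = "stall"
            break

    result = GAResult(
        best_params=decode_vector(best_bits, bounds),
        best_error=best_err,
        best_bits=best_bits,
        history=history,
        n_evaluations=len(cache),
        stop_reason=stop,
    )
    result.failure_log = failures
    return result


# ---------------------------------------------------------------------------
# two-stage cancer-cell identification
# ---------------------------------------------------------------------------


@dataclass
class IdentifiedParameters:
    """Output of the two-stage identification."""

    k_s: float
    k_b: float
    k_al: float
    k_ag: float
    k_V: float
    k_visc: float
    mu_f: dict  # flow rate (µL/h) → μ_f
    stage1_error: float
    stage2_errors: dict  # flow rate → Eq-23 error
    stage1_history: list
    stage2_histories: dict

    def elastic_array(self) -> np.ndarray:
        return np.array(
            [self.k_s, self.k_b, self.k_al, self.k_ag, self.k_V, self.k_visc]
        )


def identify_cancer_cell(
    experiments,
    simulate,
    config: GAConfig,
    seed: int,
    bounds: Bounds | None = None,
    mu_bounds: tuple[float, float] = MU_F_BOUNDS,
    stage2_config: GAConfig | None = None,
) -> IdentifiedParameters:
    """Two-stage identification against entry/transit measurements.

    ``experiments`` is a sequence of (flow_rate_uL_h, entry_time, transit
    _time) rows; ``simulate(elastic_params_array, mu_f, flow_rate) ->
    (entry_time, transit_time)`` runs the passage model (raising or
    returning non-finite times marks the candidate failed). Stage 1
    minimizes the summed entry-time error with μ_f = 0; stage 2, with the
    stage-1 moduli frozen, minimizes the transit-time error per flow rate
    over μ_f alone.
    """
    rows = [(float(q), float(et), float(tt)) for q, et, tt in experiments]
    if not rows:
        raise ValueError("need at least one experiment row")
    if bounds is None:
        bounds = Bounds.from_dict(DEFAULT_BOUNDS)
    if stage2_config is None:
        stage2_config = config

    exp_et = np.array([r[1] for r in rows])

    def stage1_objective(params):
        sims = np.array([simulate(params, 0.0, q)[0] for q, _, _ in rows])
        if np.any(~np.isfinite(sims)):
            raise FloatingPointError("entry time not measurable")
        return error_entry(sims, exp_et)

    s1 = ga_run(stage1_objective, bounds, config, seed)
    elastic = s1.best_params

    mu_f: dict = {}
    s2_err: dict = {}
    s2_hist: dict = {}
    mu_b = Bounds(np.array([mu_bounds[0]]), np.array([mu_bounds[1]]))
    for i, (q, _, tt_e) in enumerate(rows):
        def stage2_objective(params, _q=q, _tt=tt_e):
            tt_s = simulate(elastic, float(params[0]), _q)[1]
            if not np.isfinite(tt_s):
                raise FloatingPointError("transit time not measurable")
            return error_transit(tt_s, _tt)

        s2 = ga_run(stage2_objective, mu_b, stage2_config, seed + 1000 + i)
        mu_f[q] = float(s2.best_params[0])
        s2_err[q] = s2.best_error
        s2_hist[q] = s2.history

    return IdentifiedParameters(
        *(float(v) for v in elastic),
        mu_f=mu_f,
        stage1_error=s1.best_error,
        stage2_errors=s2_err,
        stage1_history=s1.history,
        stage2_histories=s2_hist,
    )
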