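"""Population-based metaheuristic for bounded black-box minimization.

Candidates behave like objects immersed in a fluid: each carries a
position, a density, a volume and an acceleration.  Densities and volumes
drift toward the best object found so far, a *transfer operator*
``TF = exp((t - tmax)/tmax)`` switches the swarm from exploration
(collisions with a random object, TF <= 0.5) to exploitation (attraction
to the best object, TF > 0.5), and a time-decaying *density-decrease
factor* shrinks step sizes so the search turns from global to local.

The module doubles as the hyperparameter tuner for the feature extractor:
a search space of named dimensions (linear/log reals, integers,
categoricals) is decoded from the continuous positions and scored by the
classification error rate on a held-out validation set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ObjectiveError, ParameterError

__all__ = [
    "ObjectState",
    "AOAConfig",
    "BestRecord",
    "initialize_population",
    "transfer_operator",
    "density_decrease",
    "update_density_volume",
    "update_acceleration",
    "normalize_acceleration",
    "update_position",
    "fitness_error_rate",
    "optimize",
    "SearchDimension",
    "tune_hyperparameters",
]


@dataclass
class ObjectState:
    """One candidate: position plus its physical attributes."""

    x: np.ndarray          # position, within [lower, upper]
    density: np.ndarray    # in (0, 1)
    volume: np.ndarray     # in (0, 1)
    accel: np.ndarray
    fitness: float | None = None


@dataclass(frozen=True)
class AOAConfig:
    """Search hyperparameters.

    ``c1 = 2`` and ``c2 = 6`` scale the exploration and exploitation moves;
    ``c3`` shapes the time-increasing step fraction ``T = clip(c3*TF,
    c3*0.3, 1)``; ``c4`` offsets the direction-flag draw ``P = 2*rand - c4``.
    ``norm_l``/``norm_u`` are the acceleration-normalization limits (0.1,
    0.9), mapping the population minimum to 0.1 and maximum to 1.0.
    """

    population: int = 20
    max_iterations: int = 100
    lower: np.ndarray = field(default_factory=lambda: np.array([-1.0]))
    upper: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    c1: float = 2.0
    c2: float = 6.0
    c3: float = 2.0
    c4: float = 0.5
    norm_l: float = 0.1
    norm_u: float = 0.9
    seed: int = 0

    def __post_init__(self):
        lower = np.atleast_1d(np.asarray(self.lower, dtype=np.float64))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=np.float64))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape:
            raise ParameterError("lower and upper bounds must have equal length")
        if np.any(lower > upper):
            raise ParameterError("lower bound exceeds upper bound")
        if self.population < 2:
            raise ParameterError("population must be >= 2")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if not (0 < self.norm_l < self.norm_u):
            raise ParameterError("require 0 < norm_l < norm_u")

    @property
    def dim(self) -> int:
        return self.lower.size


@dataclass
class BestRecord:
    """Best object observed so far (minimum fitness)."""

    x: np.ndarray
    density: np.ndarray
    volume: np.ndarray
    accel: np.ndarray
    fitness: float
    iteration_found: int


def initialize_population(config: AOAConfig, rng: np.random.Generator) -> list[ObjectState]:
    """Draw the initial swarm.

    Positions and accelerations are uniform within the bounds; densities
    and volumes are uniform in (0, 1).  Reproducible for a fixed generator.
    """
    span = config.upper - config.lower
    pop = []
    for _ in range(config.population):
        x = config.lower + rng.random(config.dim) * span
        volume = rng.random(config.dim)
        density = rng.random(config.dim)
        accel = config.lower + rng.random(config.dim) * span
        pop.append(ObjectState(x, density, volume, accel))
    return pop


def transfer_operator(t: int, tmax: int) -> float:
    """Exploration-to-exploitation schedule ``exp((t - tmax)/tmax)``.

    Strictly increasing in ``t``; reaches exactly 1 at ``t = tmax``.
    """
    if tmax < 1:
        raise ParameterError("tmax must be >= 1")
    if not 0 <= t <= tmax:
        raise ParameterError(f"t must lie in [0, {tmax}], got {t}")
    return math.exp((t - tmax) / tmax)


def density_decrease(t: int, tmax: int) -> float:
    """Step-size decay ``exp((tmax - t)/tmax) - t/tmax``.

    Strictly decreasing in ``t``; equals ``e`` at ``t = 0`` and 0 at
    ``t = tmax``.
    """
    if tmax < 1:
        raise ParameterError("tmax must be >= 1")
    if not 0 <= t <= tmax:
        raise ParameterError(f"t must lie in [0, {tmax}], got {t}")
    return math.exp((tmax - t) / tmax) - t / tmax


def update_density_volume(obj: ObjectState, best: BestRecord,
                          rng: np.random.Generator) -> ObjectState:
    """Move volume and density toward the best object.

    Each component advances by an independent uniform(0,1) fraction of the
    gap, so the result always lies between the old value and the best
    value — densities and volumes therefore stay inside (0, 1).
    """
    obj.volume = obj.volume + rng.random(obj.volume.shape) * (best.volume - obj.volume)
    obj.density = obj.density + rng.random(obj.density.shape) * (best.density - obj.density)
    return obj


_DENOM_EPS = 1e-12


def update_acceleration(obj: ObjectState, population: Sequence[ObjectState],
                        best: BestRecord, tf: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Collision (TF <= 0.5) or best-attraction (TF > 0.5) acceleration.

    ``A = (D_src + V_src * A_src) / (D_i * V_i)`` where the source is a
    random population member during exploration and the best object during
    exploitation.  The denominator is guarded below 1e-12.
    """
    if tf <= 0.5:
        mr = population[int(rng.integers(len(population)))]
        num = mr.density + mr.volume * mr.accel
    else:
        num = best.density + best.volume * best.accel
    denom = obj.density * obj.volume
    denom = np.where(np.abs(denom) < _DENOM_EPS, _DENOM_EPS, denom)
    accel = num / denom
    if not np.all(np.isfinite(accel)):
        raise ParameterError("non-finite acceleration after denominator guard")
    return accel


def normalize_acceleration(accels: np.ndarray, l: float = 0.1, u: float = 0.9) -> np.ndarray:
    """Affine rescale ``u * (A - min) / (max - min) + l`` over the population.

    Min/max are taken per dimension across the population (axis 0).  The
    minimum maps to ``l``, the maximum to ``u + l``; if every member is
    equal in a dimension, all map to the midpoint ``l + u/2``.
    """
    accels = np.atleast_2d(np.asarray(accels, dtype=np.float64))
    if accels.shape[0] < 2:
        raise ParameterError("normalization needs a population of >= 2")
    amin = accels.min(axis=0)
    amax = accels.max(axis=0)
    span = amax - amin
    mid = np.full_like(accels, l + u / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = u * (accels - amin) / span + l
    return np.where(span > 0, scaled, mid)


def update_position(obj: ObjectState, best: BestRecord, x_rand: np.ndarray,
                    tf: float, d: float, t_frac: float,
                    norm_accel: np.ndarray, rng: np.random.Generator,
                    config: AOAConfig) -> np.ndarray:
    """Exploration or exploitation move, clamped to the bounds.

    TF <= 0.5:  x += c1 * rand * A_norm * d * (x_rand - x)
    TF >  0.5:  x  = x_best + F * c2 * rand * A_norm * d * t_frac * (x_best - x)
    with direction flag F = +1 if P <= 0.5 else -1, P = 2*rand - c4.
    """
    if tf <= 0.5:
        r = rng.random(obj.x.shape)
        new = obj.x + config.c1 * r * norm_accel * d * (x_rand - obj.x)
    else:
        p = 2.0 * rng.random() - config.c4
        f = 1.0 if p <= 0.5 else -1.0
        r = rng.random(obj.x.shape)
        new = best.x + f * config.c2 * r * norm_accel * d * t_frac * (best.x - obj.x)
    return np.clip(new, config.lower, config.upper)


def fitness_error_rate(predictions: Sequence, truth: Sequence) -> float:
    """Classification error rate in percent: 100 * misclassified / total."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0:
        raise ParameterError("empty label sequences")
    if predictions.shape != truth.shape:
        raise ParameterError(
            f"length mismatch: {predictions.shape} vs {truth.shape}"
        )
    return 100.0 * float(np.mean(predictions != truth))


def _evaluate(obj: ObjectState, objective: Callable[[np.ndarray], float]) -> float:
    val = float(objective(obj.x))
    if not math.isfinite(val):
        raise ObjectiveError(f"objective returned {val} ", position=obj.x.copy())
    return val


def optimize(objective: Callable[[np.ndarray], float], config: AOAConfig,
             rng: np.random.Generator | None = None):
    """Minimize ``objective`` over the bounded box.

    Each iteration evaluates the swarm, refreshes the best record, drifts
    densities/volumes toward the best, then applies the TF-gated
    acceleration and position updates.  Returns ``(best, trace)`` where the
    trace rows are ``(iteration, best_fitness, mean_fitness)`` and the
    best-fitness column is non-increasing.  Fully reproducible per seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pop = initialize_population(config, rng)
    best: BestRecord | None = None
    trace: list[tuple[int, float, float]] = []
    tmax = config.max_iterations
    for t in range(1, tmax + 1):
        for obj in pop:
            obj.fitness = _evaluate(obj, objective)
        leader = min(pop, key=lambda o: o.fitness)
        if best is None or leader.fitness < best.fitness:
            best = BestRecord(leader.x.copy(), leader.density.copy(),
                              leader.volume.copy(), leader.accel.copy(),
                              leader.fitness, t)
        trace.append((t, best.fitness, float(np.mean([o.fitness for o in pop]))))

        tf = transfer_operator(t, tmax)
        d = density_decrease(t, tmax)
        t_frac = min(max(config.c3 * tf, config.c3 * 0.3), 1.0)
        for obj in pop:
            update_density_volume(obj, best, rng)
        accels = np.stack([
            update_acceleration(obj, pop, best, tf, rng) for obj in pop
        ])
        norm = normalize_acceleration(accels, config.norm_l, config.norm_u)
        for i, obj in enumerate(pop):
            x_rand = pop[int(rng.integers(len(pop)))].x
            obj.x = update_position(obj, best, x_rand, tf, d, t_frac,
                                    norm[i], rng, config)
            obj.accel = accels[i]
    return best, trace


# ---------------------------------------------------------------------------
# Hyperparameter search space


@dataclass(frozen=True)
class SearchDimension:
    """One named, decodable search dimension.

    kind:
      * ``"real"`` — position used as-is within [lower, upper];
      * ``"log"``  — position is log10(value); decoded as 10**position;
      * ``"int"``  — decoded by round-half-up within [lower, upper];
      * ``"cat"``  — position in [0, len(choices)) binned by floor.
    """

    name: str
    kind: str = "real"
    lower: float = 0.0
    upper: float = 1.0
    choices: tuple = ()

    def __post_init__(self):
        if self.kind not in ("real", "log", "int", "cat"):
            raise ParameterError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "cat" and not self.choices:
            raise ParameterError("categorical dimension needs choices")

    @property
    def bounds(self) -> tuple[float, float]:
        if self.kind == "cat":
            return (0.0, float(len(self.choices)) - 1e-9)
        return (self.lower, self.upper)

    def decode(self, position: float):
        if self.kind == "real":
            return float(position)
        if self.kind == "log":
            return float(10.0 ** position)
        if self.kind == "int":
            return int(math.floor(position + 0.5))
        idx = min(int(math.floor(position)), len(self.choices) - 1)
        return self.choices[max(idx, 0)]


def decode_position(space: Sequence[SearchDimension], position: np.ndarray) -> dict:
    return {dim.name: dim.decode(position[i]) for i, dim in enumerate(space)}


def tune_hyperparameters(space: Sequence[SearchDimension],
                         objective: Callable[[dict], float],
                         population: int = 10, max_iterations: int = 10,
                         seed: int = 0, **config_kwargs):
    """Search a decoded hyperparameter space by the metaheuristic.

    ``objective`` receives the decoded ``{name: value}`` dict and returns
    the quantity to minimize (typically the validation error rate in
    percent).  Returns ``(best_params, best_fitness, log)`` where the log
    lists every decoded evaluation in order.
    """
    if not space:
        raise ParameterError("empty search space")
    lower = np.array([d.bounds[0] for d in space])
    upper = np.array([d.bounds[1] for d in space])
    config = AOAConfig(population=population, max_iterations=max_iterations,
                       lower=lower, upper=upper, seed=seed, **config_kwargs)
    log: list[tuple[dict, float]] = []

    def wrapped(x: np.ndarray) -> float:
        params = decode_position(space, x)
        val = float(objective(params))
        log.append((params, val))
        return val

    best, _trace = optimize(wrapped, config)
    return decode_position(space, best.x), best.fitness, log


def write_trace_csv(trace, path) -> None:
    """Persist an optimizer trace as ``iteration,best_fitness,mean_fitness``."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "best_fitness", "mean_fitness"])
        writer.writerows(trace)
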