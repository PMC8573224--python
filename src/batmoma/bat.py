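"""Bat-algorithm search over binary knockout vectors with MOMA fitness.

Each bat carries a continuous position ``x`` in [0,1]^d over the model's
knockable units, a velocity ``v``, an echolocation frequency ``f``, a
loudness ``A`` (decays by ``alpha`` on every accepted move) and a pulse rate
``r`` (grows toward ``r0``).  Per generation the bat flies toward the global
best,

    f_i = f_min + (f_max - f_min) * beta,      beta ~ U[0, 1]
    v_i <- v_i + (x_i - x*) * f_i
    x_i <- x_i + v_i                            (clipped to [0, 1])

and, with probability 1 - r_i, instead random-walks around the best solution,
``x_new = x* + eps * <A>`` with eps ~ U[-1, 1] per component and <A> the mean
population loudness.  Positions are decoded to binary knockout vectors by a
fixed 0.5 threshold (component < 0.5 means the unit is knocked out), repaired
to at most ``max_knockouts`` zeros, and scored by MOMA: fitness is the target
exchange flux if the mutant is viable (growth and production thresholds both
passed with an optimal QP), otherwise zero.  A candidate replaces a bat's
solution only when a uniform draw falls below the bat's loudness *and* the
fitness improves, after which loudness and pulse rate are updated

    A_i <- alpha * A_i,     r_i = r0 * (1 - exp(-gamma * t)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import gpr as _gpr
from .model_io import ConfigurationError, MetabolicModel
from .solvers import FluxDistribution, OPTIMAL, reference_flux, solve_moma


@dataclass(frozen=True)
class BatConfig:
    """Search parameters.

    Population and generation counts follow the published BATMOMA setup
    (n=20, 50 generations); frequency range, alpha and gamma are the
    canonical bat-algorithm defaults.  The viability gate requires growth
    > 0.1 h^-1 and production > 0.001 mmol gDW^-1 h^-1.
    """

    population_size: int = 20
    generations: int = 50
    f_min: float = 0.0
    f_max: float = 2.0
    alpha: float = 0.9
    gamma: float = 0.9
    initial_loudness: float = 1.5
    initial_pulse_rate: float = 0.5
    max_knockouts: int = 3
    growth_threshold: float = 0.1
    production_threshold: float = 0.001
    patience: int = 10
    convergence_tol: float = 1e-6
    rng_seed: int = 0
    knockout_mode: str = "reaction"  # or "gene": propagate deletions via GPRs

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.f_min > self.f_max:
            raise ValueError("f_min must not exceed f_max")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_knockouts < 1:
            raise ValueError("max_knockouts must be >= 1")
        if self.knockout_mode not in ("reaction", "gene"):
            raise ValueError("knockout_mode must be 'reaction' or 'gene'")


@dataclass
class FitnessResult:
    """MOMA outcome of one candidate knockout set."""

    production_rate: float
    growth_rate: float
    viable: bool
    solver_status: str
    residual: float | None = None
    distance: float = float("nan")

    @property
    def fitness_value(self) -> float:
        return self.production_rate if self.viable else 0.0


@dataclass
class BatState:
    """One candidate solution with its echolocation state."""

    position: np.ndarray
    velocity: np.ndarray
    frequency: float
    loudness: float
    pulse_rate: float
    binary: np.ndarray
    fitness: FitnessResult | None = None

    @property
    def fitness_value(self) -> float:
        return self.fitness.fitness_value if self.fitness is not None else -math.inf


@dataclass
class BatRunResult:
    """Outcome of one full search run."""

    best_binary: tuple[int, ...]
    best_units: tuple[str, ...]          # knocked-out units (reaction ids)
    best_genes: tuple[tuple[str, ...], ...]  # gene list per knocked-out unit
    best_fitness: FitnessResult
    history: list[float]                 # best fitness after each generation
    generations_run: int
    n_evaluations: int
    converged: bool
    seed: int

    def to_dict(self) -> dict:
        f = self.best_fitness
        return {
            "seed": self.seed,
            "best": {
                "knockout_units": list(self.best_units),
                "knockout_genes": [list(g) for g in self.best_genes],
                "production_rate": f.production_rate,
                "growth_rate": f.growth_rate,
                "viable": f.viable,
                "solver_status": f.solver_status,
                "residual": f.residual,
                "moma_distance": f.distance,
                "fitness": f.fitness_value,
            },
            "history": list(self.history),
            "generations_run": self.generations_run,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# update rules


def update_frequency(f_min: float, f_max: float, beta: float) -> float:
    return f_min + (f_max - f_min) * beta


def update_velocity_position(state: BatState, best_position: np.ndarray) -> BatState:
    """Guided global move toward the best position (componentwise)."""
    v = state.velocity + (state.position - best_position) * state.frequency
    x = np.clip(state.position + v, 0.0, 1.0)
    return replace(state, velocity=v, position=x)


def local_search(best_position: np.ndarray, epsilon: np.ndarray | float,
                 mean_loudness: float) -> np.ndarray:
    """Random walk around the best solution, scaled by mean loudness."""
    if mean_loudness < 0:
        raise ValueError("mean loudness must be non-negative")
    return np.clip(best_position + np.asarray(epsilon) * mean_loudness, 0.0, 1.0)


def update_loudness_pulse(state: BatState, alpha: float, gamma: float,
                          t: int, initial_pulse_rate: float) -> BatState:
    """Applied after an accepted move: quieter emission, faster pulses."""
    return replace(
        state,
        loudness=alpha * state.loudness,
        pulse_rate=initial_pulse_rate * (1.0 - math.exp(-gamma * t)),
    )


def binarize(position: np.ndarray) -> np.ndarray:
    """0/1 decoding: component < 0.5 -> 0 (knocked out), >= 0.5 -> 1."""
    return (np.asarray(position) >= 0.5).astype(np.int8)


def repair_cardinality(binary: np.ndarray, max_knockouts: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Randomly restore knockouts until at most ``max_knockouts`` remain."""
    binary = np.asarray(binary).copy()
    zeros = np.flatnonzero(binary == 0)
    if zeros.size > max_knockouts:
        restore = rng.choice(zeros, size=zeros.size - max_knockouts, replace=False)
        binary[restore] = 1
    return binary


# ---------------------------------------------------------------------------
# fitness


def disabled_reactions_for(model: MetabolicModel, units: Sequence[str],
                           binary: np.ndarray, mode: str = "reaction") -> set[str]:
    """Map a binary unit vector to the set of reactions pinned to zero.

    ``reaction`` mode removes each knocked-out unit's enzyme, disabling
    exactly that reaction.  ``gene`` mode deletes the union of the units'
    genes and propagates through all GPRs, so shared subunits may disable
    additional reactions while isozyme-backed units may survive.
    """
    off_units = [u for u, b in zip(units, binary) if not b]
    if mode == "reaction":
        return set(off_units)
    genes: set[str] = set()
    for u in off_units:
        genes |= _gpr.gpr_genes(model.gpr_rule(u))
    return _gpr.reactions_disabled(model, genes)


def evaluate_fitness(model: MetabolicModel, reference: FluxDistribution,
                     binary: np.ndarray, target_exchange: str,
                     config: BatConfig,
                     units: Sequence[str] | None = None) -> FitnessResult:
    """MOMA-score one binary knockout vector.

    Lethal or unsolved knockouts score zero rather than raising, so the
    search loop can keep flying.
    """
    units = _gpr.knockable_units(model) if units is None else units
    if len(binary) != len(units):
        raise ValueError("binary length does not match number of knockable units")
    disabled = disabled_reactions_for(model, units, binary, config.knockout_mode)
    sol = solve_moma(model, reference, disabled)
    if sol.fluxes is None:
        return FitnessResult(0.0, 0.0, False, sol.status)
    production = sol.flux(model, target_exchange)
    growth = sol.flux(model, model.biomass_reaction)
    viable = (
        sol.status == OPTIMAL
        and growth > config.growth_threshold
        and production > config.production_threshold
    )
    return FitnessResult(production, growth, viable, sol.status,
                         residual=sol.residual, distance=sol.objective_value)


# ---------------------------------------------------------------------------
# search loop


def optimize_binary(fitness_fn: Callable[[np.ndarray], float], n_dims: int,
                    config: BatConfig,
                    trace: list[tuple[int, "BatState"]] | None = None,
                    ) -> tuple[np.ndarray, float, list[float], int, int, bool]:
    """Core bat search over {0,1}^n_dims maximizing ``fitness_fn``.

    Returns (best binary, best fitness, per-generation best history,
    generations run, distinct candidates evaluated, converged flag).
    ``trace``, if given, collects ``(bat_index, state)`` for every accepted
    move, for invariant checking.  All randomness flows from
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    cache: dict[tuple[int, ...], float] = {}

    def score(binary: np.ndarray) -> float:
        key = tuple(int(b) for b in binary)
        if key not in cache:
            cache[key] = fitness_fn(binary)
        return cache[key]

    bats: list[BatState] = []
    for _ in range(config.population_size):
        x = rng.uniform(size=n_dims)
        b = repair_cardinality(binarize(x), config.max_knockouts, rng)
        bats.append(BatState(
            position=x,
            velocity=np.zeros(n_dims),
            frequency=update_frequency(config.f_min, config.f_max, rng.uniform()),
            loudness=config.initial_loudness,
            pulse_rate=0.0,
            binary=b,
        ))
    fitnesses = [score(b.binary) for b in bats]
    i_best = int(np.argmax(fitnesses))
    best_binary = bats[i_best].binary.copy()
    best_fitness = fitnesses[i_best]
    best_position = bats[i_best].position.copy()

    history: list[float] = []
    stall = 0
    generations_run = 0
    converged = False
    for t in range(1, config.generations + 1):
        generations_run = t
        mean_loudness = float(np.mean([b.loudness for b in bats]))
        for i, bat in enumerate(bats):
            freq = update_frequency(config.f_min, config.f_max, rng.uniform())
            moved = update_velocity_position(replace(bat, frequency=freq), best_position)
            if rng.uniform() > bat.pulse_rate:
                eps = rng.uniform(-1.0, 1.0, size=n_dims)
                cand_position = local_search(best_position, eps, mean_loudness)
            else:
                cand_position = moved.position
            cand_binary = repair_cardinality(binarize(cand_position),
                                             config.max_knockouts, rng)
            cand_fitness = score(cand_binary)
            accepted = rng.uniform() < bat.loudness and cand_fitness > fitnesses[i]
            new_state = replace(moved, position=cand_position if accepted else moved.position,
                                binary=cand_binary if accepted else bat.binary)
            if accepted:
                new_state = update_loudness_pulse(new_state, config.alpha,
                                                 config.gamma, t,
                                                 config.initial_pulse_rate)
                fitnesses[i] = cand_fitness
                if trace is not None:
                    trace.append((i, new_state))
            bats[i] = new_state
            if fitnesses[i] > best_fitness:
                best_fitness = fitnesses[i]
                best_binary = bats[i].binary.copy()
                best_position = bats[i].position.copy()
        improved = not history or best_fitness > history[-1] + config.convergence_tol
        history.append(best_fitness)
        stall = 0 if improved else stall + 1
        if stall >= config.patience:
            converged = True
            break
    return best_binary, best_fitness, history, generations_run, len(cache), converged


def run_batmoma(model: MetabolicModel, target_exchange: str, config: BatConfig,
                reference: FluxDistribution | None = None) -> BatRunResult:
    """Full BATMOMA search on one model/target.

    The wild-type reference is computed once (parsimonious FBA) and reused
    for every MOMA evaluation.  MOMA fitnesses are memoized per knockout
    set, so the cost is the number of *distinct* candidates visited.
    """
    model.index(target_exchange)
    if reference is None:
        reference = reference_flux(model)
    if not reference.optimal:
        raise ConfigurationError(
            f"wild-type model is not solvable (status {reference.status})"
        )
    units = _gpr.knockable_units(model)
    if not units:
        raise ConfigurationError("model has no knockable units")

    details: dict[tuple[int, ...], FitnessResult] = {}

    def fitness_fn(binary: np.ndarray) -> float:
        fr = evaluate_fitness(model, reference, binary, target_exchange,
                              config, units)
        details[tuple(int(b) for b in binary)] = fr
        return fr.fitness_value

    best_binary, _, history, gens, n_evals, converged = optimize_binary(
        fitness_fn, len(units), config)
    key = tuple(int(b) for b in best_binary)
    best_fr = details[key]
    off = tuple(u for u, b in zip(units, best_binary) if not b)
    return BatRunResult(
        best_binary=key,
        best_units=off,
        best_genes=tuple(_gpr.unit_genes(model, u) for u in off),
        best_fitness=best_fr,
        history=history,
        generations_run=gens,
        n_evaluations=n_evals,
        converged=converged,
        seed=config.rng_seed,
    )
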