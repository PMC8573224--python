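import itertools
import math

import numpy as np
import pytest

import batmoma as bm
from batmoma.bat import (
    BatConfig,
    BatState,
    binarize,
    evaluate_fitness,
    local_search,
    optimize_binary,
    repair_cardinality,
    update_frequency,
    update_loudness_pulse,
    update_velocity_position,
)
from batmoma.gpr import knockable_units
from batmoma.model_io import ConfigurationError


def _state(x, v=None, f=1.0, A=1.5, r=0.0):
    x = np.asarray(x, float)
    return BatState(position=x, velocity=np.zeros_like(x) if v is None else np.asarray(v, float),
                    frequency=f, loudness=A, pulse_rate=r,
                    binary=binarize(x))


@pytest.mark.parametrize("beta,expected", [(0.0, 0.0), (1.0, 2.0), (0.5, 1.0)])
def test_frequency_interpolates_range(beta, expected):
    assert update_frequency(0.0, 2.0, beta) == expected


class TestVelocityPosition:
    def test_at_best_position_velocity_unchanged(self):
        s = _state([0.3, 0.3], v=[0.1, -0.1])
        out = update_velocity_position(s, np.array([0.3, 0.3]))
        np.testing.assert_allclose(out.velocity, [0.1, -0.1])

    def test_hand_arithmetic(self):
        s = _state([0.5], v=[0.1], f=1.0)
        out = update_velocity_position(s, np.array([0.3]))
        assert out.velocity[0] == pytest.approx(0.3)
        assert out.position[0] == pytest.approx(0.8)

    def test_zero_frequency_zero_velocity_is_stationary(self):
        s = _state([0.4, 0.6], f=0.0)
        out = update_velocity_position(s, np.array([0.9, 0.1]))
        np.testing.assert_allclose(out.position, [0.4, 0.6])

    def test_position_clipped_to_unit_box(self):
        s = _state([0.9], v=[5.0], f=1.0)
        out = update_velocity_position(s, np.array([0.0]))
        assert 0.0 <= out.position[0] <= 1.0


class TestLocalSearch:
    def test_zero_epsilon_is_identity(self):
        np.testing.assert_allclose(local_search(np.array([0.2, 0.8]), 0.0, 1.5),
                                   [0.2, 0.8])

    def test_zero_loudness_is_identity(self):
        np.testing.assert_allclose(local_search(np.array([0.2, 0.8]),
                                                np.array([1.0, -1.0]), 0.0),
                                   [0.2, 0.8])

    def test_hand_arithmetic_and_clipping(self):
        out = local_search(np.array([0.2, 0.9]), np.array([1.0, 1.0]), 0.5)
        assert out[0] == pytest.approx(0.7)
        assert out[1] == pytest.approx(1.0)  # clipped


class TestLoudnessPulse:
    def test_loudness_decays(self):
        out = update_loudness_pulse(_state([0.5], A=1.0), 0.9, 0.9, t=3,
                                    initial_pulse_rate=0.5)
        assert out.loudness == pytest.approx(0.9)

    def test_pulse_rate_zero_at_t0(self):
        out = update_loudness_pulse(_state([0.5]), 0.9, 0.9, t=0,
                                    initial_pulse_rate=0.5)
        assert out.pulse_rate == pytest.approx(0.0)

    def test_pulse_rate_limits_to_initial(self):
        out = update_loudness_pulse(_state([0.5]), 0.9, 0.9, t=10_000,
                                    initial_pulse_rate=0.5)
        assert out.pulse_rate == pytest.approx(0.5, abs=1e-12)


def test_binarize_threshold_convention():
    x = np.array([0.0, 0.49, 0.5, 1.0])
    np.testing.assert_array_equal(binarize(x), [0, 0, 1, 1])


class TestRepair:
    def test_under_budget_unchanged(self):
        b = np.array([1, 0, 1, 0, 1], dtype=np.int8)
        out = repair_cardinality(b, 5, np.random.default_rng(0))
        np.testing.assert_array_equal(out, b)

    def test_over_budget_trimmed_to_exactly_k(self):
        b = np.zeros(7, dtype=np.int8)
        out = repair_cardinality(b, 3, np.random.default_rng(0))
        assert int((out == 0).sum()) == 3

    def test_seeded_repair_is_deterministic(self):
        b = np.zeros(10, dtype=np.int8)
        a = repair_cardinality(b, 4, np.random.default_rng(11))
        c = repair_cardinality(b, 4, np.random.default_rng(11))
        np.testing.assert_array_equal(a, c)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 1.0}, {"alpha": 0.0}, {"gamma": 0.0},
        {"f_min": 3.0, "f_max": 1.0}, {"population_size": 1},
        {"max_knockouts": 0}, {"knockout_mode": "enzyme"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BatConfig(**kwargs)


# -- fitness ----------------------------------------------------------------

class TestFitness:
    def test_all_ones_reproduces_wild_type(self, toy):
        ref = bm.reference_flux(toy)
        units = knockable_units(toy)
        fr = evaluate_fitness(toy, ref, np.ones(len(units), dtype=np.int8),
                              "EX_P", BatConfig())
        assert fr.growth_rate == pytest.approx(ref.objective_value, abs=1e-5)
        assert fr.production_rate == pytest.approx(ref.flux(toy, "EX_P"), abs=1e-5)
        assert fr.distance == pytest.approx(0.0, abs=1e-6)

    def test_growth_essential_knockout_scores_zero(self, toy):
        """Blocking the biomass branch drops growth below threshold."""
        ref = bm.reference_flux(toy)
        units = knockable_units(toy)
        binary = np.ones(len(units), dtype=np.int8)
        binary[units.index("R_BX")] = 0
        # LP confirms the knockout blocks growth entirely
        lb = toy.lower_bounds.copy(); ub = toy.upper_bounds.copy()
        lb[toy.index("R_BX")] = ub[toy.index("R_BX")] = 0.0
        assert bm.solve_fba(toy.with_bounds(lb, ub)).objective_value < 0.1
        fr = evaluate_fitness(toy, ref, binary, "EX_P", BatConfig())
        assert not fr.viable
        assert fr.fitness_value == 0.0

    def test_productive_knockout_is_viable(self, toy):
        ref = bm.reference_flux(toy)
        units = knockable_units(toy)
        binary = np.ones(len(units), dtype=np.int8)
        binary[units.index("R_RESP")] = 0
        fr = evaluate_fitness(toy, ref, binary, "EX_P", BatConfig())
        assert fr.viable
        assert fr.fitness_value == pytest.approx(fr.production_rate)
        assert fr.production_rate > 1.0

    def test_gene_mode_propagates_shared_subunits(self, core_model):
        """Gene mode deletes the unit's genes and follows all GPRs."""
        units = knockable_units(core_model)
        binary = np.ones(len(units), dtype=np.int8)
        from batmoma.bat import disabled_reactions_for

        # PDH shares lpdA with AKGDH: gene mode drags AKGDH down too,
        # reaction mode removes only the targeted enzyme.
        binary[units.index("PDH")] = 0
        assert disabled_reactions_for(core_model, units, binary, "reaction") == {"PDH"}
        assert disabled_reactions_for(core_model, units, binary, "gene") == {"PDH", "AKGDH"}


# -- the search loop --------------------------------------------------------

def test_pure_search_recovers_known_vector():
    """With a stub fitness, the optimizer finds the hidden binary target."""
    rng = np.random.default_rng(3)
    d = 12
    target = np.ones(d, dtype=np.int8)
    target[rng.choice(d, size=2, replace=False)] = 0
    hits = 0
    for seed in range(5):
        cfg = BatConfig(rng_seed=seed, max_knockouts=2, generations=60,
                        patience=60)
        best, fitness, *_ = optimize_binary(
            lambda b: -float(np.abs(b - target).sum()), d, cfg)
        hits += fitness == 0.0 and np.array_equal(best, target)
    assert hits >= 4


def test_search_invariants_on_trace(toy):
    ref = bm.reference_flux(toy)
    units = knockable_units(toy)
    cfg = BatConfig(rng_seed=5, max_knockouts=2, population_size=6,
                    generations=15)
    trace = []
    evaluated = []

    def fitness(binary):
        evaluated.append(binary.copy())
        fr = evaluate_fitness(toy, ref, binary, "EX_P", cfg, units)
        return fr.fitness_value

    best, _, history, *_ = optimize_binary(fitness, len(units), cfg, trace=trace)
    # best-fitness history is non-decreasing
    assert all(b >= a for a, b in zip(history, history[1:]))
    # every evaluated candidate is binary with at most K knockouts
    for b in evaluated:
        assert set(np.unique(b)) <= {0, 1}
        assert int((b == 0).sum()) <= cfg.max_knockouts
    # loudness non-increasing / pulse non-decreasing & bounded per bat
    per_bat = {}
    for i, state in trace:
        if i in per_bat:
            prev = per_bat[i]
            assert state.loudness <= prev.loudness + 1e-12
            assert state.pulse_rate >= prev.pulse_rate - 1e-12
        assert state.pulse_rate <= cfg.initial_pulse_rate + 1e-12
        per_bat[i] = state


def test_search_finds_enumerated_optimum(toy):
    """Single-run spot check against exhaustive knockout enumeration."""
    ref = bm.reference_flux(toy)
    units = knockable_units(toy)
    cfg = BatConfig(max_knockouts=2, rng_seed=1)
    best_enum = 0.0
    for k in range(0, 3):
        for combo in itertools.combinations(range(len(units)), k):
            binary = np.ones(len(units), dtype=np.int8)
            binary[list(combo)] = 0
            fr = evaluate_fitness(toy, ref, binary, "EX_P", cfg, units)
            best_enum = max(best_enum, fr.fitness_value)
    result = bm.run_batmoma(toy, "EX_P", cfg, reference=ref)
    assert result.best_fitness.fitness_value == pytest.approx(best_enum, abs=1e-5)


def test_wild_type_optimal_when_no_knockout_helps():
    """Growth-coupled production: the identity (no knockout) is the optimum."""
    import scipy.sparse as sp

    model = bm.MetabolicModel(
        reaction_ids=["EX_A", "R_AB", "R_BXP", "R_BW", "EX_W", "BIOMASS", "EX_P"],
        metabolite_ids=["A", "B", "X", "P", "W"],
        stoichiometry=sp.csc_matrix(np.array([
            [-1, -1, 0, 0, 0, 0, 0],
            [0, 1, -1, -1, 0, 0, 0],
            [0, 0, 0.5, 0, 0, -1, 0],
            [0, 0, 0.5, 0, 0, 0, -1],
            [0, 0, 0, 1, -1, 0, 0],
        ], dtype=float)),
        lower_bounds=np.array([-10, 0, 0, 0, 0, 0, 0], dtype=float),
        upper_bounds=np.array([0, 1000, 1000, 1000, 1000, 1000, 1000], dtype=float),
        gene_ids=["g1", "g2", "g3"],
        gpr_rules=["", "g1", "g2", "g3", "", "", ""],
        biomass_reaction="BIOMASS",
        exchange_reactions=frozenset({"EX_A", "EX_W", "EX_P"}),
    )
    ref = bm.reference_flux(model)
    cfg = BatConfig(max_knockouts=1, population_size=6, generations=15, rng_seed=0)
    result = bm.run_batmoma(model, "EX_P", cfg, reference=ref)
    assert result.best_fitness.fitness_value == pytest.approx(
        ref.flux(model, "EX_P"), abs=1e-5)


def test_same_seed_identical_runs(toy):
    cfg = BatConfig(max_knockouts=2, population_size=6, generations=10, rng_seed=9)
    a = bm.run_batmoma(toy, "EX_P", cfg)
    b = bm.run_batmoma(toy, "EX_P", cfg)
    assert a.history == b.history
    assert a.best_binary == b.best_binary
    assert a.to_dict() == b.to_dict()


def test_unknown_target_rejected(toy):
    with pytest.raises(ConfigurationError):
        bm.run_batmoma(toy, "EX_nope", BatConfig())
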