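# Methods

## Problem and model

`batmoma` searches a constraint-based metabolic model for small knockout
sets that raise the secretion of a target chemical (succinate or lactate in
the worked examples) while the mutant stays viable. Candidate mutants are
scored with MOMA (minimization of metabolic adjustment) rather than FBA:
after an abrupt genetic perturbation the cell is assumed not to leap to a
new growth optimum but to redistribute flux as little as possible, so the
mutant phenotype is the point of the mutant's feasible space

    Phi_ko = { v : S v = 0, lb <= v <= ub, v_k = 0 for knocked-out k }

closest in Euclidean distance to a wild-type reference flux `w`:

    v* = argmin_{v in Phi_ko} sum_j (v_j - w_j)^2 .

This is a strictly convex quadratic program with a unique solution. The
distance is taken over *all* reactions, exchanges included (the original,
unweighted form of the method).

### Wild-type reference

FBA growth maximization is almost always degenerate, and MOMA's answer
depends on which optimum is used as `w`. We therefore fix a unique,
reproducible reference by parsimonious tie-breaking: maximize growth with an
LP, pin growth at that optimum, then minimize total absolute flux
`sum_j |v_j|` in a second LP. Published mutant flux values obtained with a
different (unstated) reference can differ by several percent; this is the
main reason value-level comparisons below carry a ±5% band.

### Medium

Aerobic glucose minimal medium: glucose exchange lower bound −10
mmol gDW⁻¹ h⁻¹, ATP maintenance (ATPM) lower bound 7.6 mmol ATP gDW⁻¹ h⁻¹.
ATPM is a floor, not an equality — the standard COBRA treatment; FBA drives
it to the bound anyway. The oxygen exchange keeps the model's own bound
(−1000) unless a rate is given or `aerobic=False` closes it. Uptake is
negative flux, secretion positive.

### Model provenance

The bundled network is the textbook *E. coli* core model distributed inside
COBRApy (95 reactions, 72 metabolites, 137 genes), loaded offline from the
installed package. Historical "core" builds of *E. coli* central metabolism
circulated in several variants that differ in lumped reactions and cofactor
stoichiometry; under the medium above this build gives wild-type growth
0.8779 h⁻¹ and theoretical maxima of 16.45 (succinate) and 20.0 (lactate)
mmol gDW⁻¹ h⁻¹, whereas values of 0.9219 and 17.1429 have been reported for
a legacy core build that is no longer distributed. Flux-level comparisons
against numbers produced on that legacy build should be read with this
offset in mind; ratios and qualitative knockout rankings transfer well.

## Knockout encoding

The search operates on *knockable units*: internal, gene-associated
reactions excluding biomass and ATPM (69 units in the core model). A
candidate is a binary vector over units, 0 = knocked out. Unit-level
encoding matches how knockout results are conventionally reported (one
enzyme with its full gene list, e.g. PDH = aceE+aceF+lpdA counted as one
knockout).

Two semantics are provided (`BatConfig.knockout_mode`):

- `"reaction"` (default): a knocked-out unit's reaction is pinned to zero —
  the enzyme is removed. This is the semantics under which published
  enzyme-level knockout tables are reproducible; strict gene propagation
  would make some of them impossible (ACALD is backed by isozymes
  `b0351 or b1241`, and PDH shares *lpdA* with AKGDH).
- `"gene"`: the unit's genes are deleted and all GPRs re-evaluated, so
  shared subunits disable additional reactions. Stricter biologically,
  offered for completeness.

GPR rules use the grammar *id / and / or / parentheses*, case-insensitive
keywords; an empty rule means "not gene-controlled" and always evaluates
true. The parser is exercised against exhaustive truth-table enumeration
and an independent parser in the test suite.

## Bat search

Each of n=20 bats carries a continuous position x ∈ [0,1]^d over the d
units, velocity v, frequency f ∈ [0,2], loudness A (initial 1.5) and pulse
rate r (asymptote r⁰ = 0.5, starting at 0). Per generation t:

1. f = f_min + (f_max − f_min)β with β ~ U[0,1]; v ← v + (x − x*)f;
   x ← x + v, clipped to [0,1]. x* is the best position found so far.
2. With probability 1 − r the bat instead takes a local random walk around
   the best: x_new = x* + ε·Ā, ε ~ U[−1,1] per component, Ā the mean
   population loudness.
3. The position is decoded by a fixed 0.5 threshold (component < 0.5 →
   knocked out) and repaired by randomly restoring knockouts until at most
   K remain. The deterministic threshold was chosen over stochastic sigmoid
   sampling for reproducibility.
4. The candidate is scored by MOMA. Fitness = target secretion if the
   mutant is viable (growth > 0.1 h⁻¹, production > 0.001 mmol gDW⁻¹ h⁻¹,
   QP optimal), else 0.
5. The candidate replaces the bat's solution only if a uniform draw falls
   below A *and* fitness improves; then A ← αA, r = r⁰(1 − e^{−γt}), with
   α = γ = 0.9. Requiring improvement keeps the recorded best monotone.

The loop stops after 50 generations or when the best fitness has not
improved by more than 10⁻⁶ for 10 consecutive generations ("patience").
Fitness values are memoized per knockout set, so cost is proportional to
distinct candidates (typically a few hundred per run). All randomness —
initialization, β, ε, acceptance draws, repair — flows from one seed.

Design points that were genuinely open and how they were fixed:

- The pulse-rate growth law is implemented in its canonical form
  r⁰(1 − e^{−γt}); at t=0 this gives r=0 and it saturates at r⁰.
- Bats move in continuous space and are thresholded to binary; the update
  equations are continuous while the genotype encoding is binary, and a
  transfer rule is required to connect them.
- Local search is guided by the single global best solution.
- Lethal knockouts (infeasible QP) score fitness 0 instead of raising, so
  the swarm can fly through lethal regions.

## Numerical choices

- LP (FBA, parsimonious reference) through HiGHS (`scipy.optimize.linprog`).
- QP (MOMA) through OSQP at eps_abs = eps_rel = 10⁻⁹ with solution
  polishing; a solution whose worst constraint violation (mass balance or
  bounds, inf-norm) exceeds 10⁻⁶ is downgraded to `suboptimal`. The worst
  violation is stored per solution as its `residual`.
- A run's best solution counts as "valid" when that residual is below
  0.001; "optimal" accuracy counts runs whose final QP status is optimal.
  Both are fractions over a batch of runs.
- Mean/SD of best-solution growth over a batch use the sample (n−1)
  denominator; a single run reports SD 0.

## Repeated runs and reported sizes

A configuration is evaluated over 50 independent seeded runs (seeds
base..base+49); the reported mutant is the best run's. The acceptance
script runs 50-run batches for succinate (K=3) and lactate (K=5) on the
full core model — about 400 distinct MOMA solves per run — plus the six
reference knockout evaluations; the test suite exercises the same search
machinery at full scale for succinate and at toy scale (≤ 12 units, where
exhaustive enumeration of all knockout sets is the oracle) elsewhere.

## Toy networks and what they do / do not show

`make_toy_model` builds a mass-balanced branched network: substrate → branch
point B with a redox carrier H; exactly n_branches reactions consume B (a
biomass branch, a product branch that also re-oxidizes H, and inert
byproduct branches). Knocking out respiration forces flux through the
product branch — growth falls, production rises — so the optimal knockout is
non-trivial, while knocking the biomass branch is lethal. All FBA vertices
and MOMA KKT systems are enumerable by brute force, which is what the
oracle tests do.

The toys emulate the *structure* of the strain-design problem (competing
drains, redox coupling, lethal sets, degenerate optima) but not its scale,
its cofactor network, or realistic GPR complexity; passing toy oracles shows
solver and search correctness, not biological predictive power.

## Limitations

- Genome-scale models work in principle but each MOMA solve grows with
  model size; the bat loop does thousands of them.
- The distance metric is unweighted Euclidean over all reactions; MiMBl,
  ROOM or linear-MOMA variants are out of scope.
- Single-objective search; growth enters only as a viability threshold.
- `.mat` model files are not read; convert once to SBML/JSON with COBRApy
  (`cobra.io.load_matlab_model` + `save_json_model`).
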