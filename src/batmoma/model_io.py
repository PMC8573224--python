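"""Constraint-based model container, I/O, medium handling and toy fixtures.

The in-memory representation is a plain :class:`MetabolicModel` holding the
stoichiometric matrix ``S`` (metabolites x reactions, CSC sparse), per-reaction
flux bounds, and gene-protein-reaction (GPR) rule strings.  SBML (Level 3 +
FBC) and COBRA-style JSON files are read through COBRApy and converted; the
solvers in this package never go through COBRApy's own solver layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp


class ModelValidationError(ValueError):
    """A model violates a structural invariant (bounds, ids, shapes)."""


class ConfigurationError(ValueError):
    """A referenced reaction/gene id does not resolve against the model."""


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Fluxes are in mmol gDW^-1 h^-1; the biomass reaction's flux is the growth
    rate in h^-1 by convention.  ``stoichiometry`` has one row per metabolite
    and one column per reaction.  ``gpr_rules[j]`` is a boolean expression over
    ``gene_ids`` ("" means the reaction is not gene-controlled).
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    stoichiometry: sp.csc_matrix
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    gene_ids: list[str]
    gpr_rules: list[str]
    biomass_reaction: str
    exchange_reactions: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.stoichiometry = sp.csc_matrix(self.stoichiometry)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        n_met, n_rxn = self.stoichiometry.shape
        if n_rxn != len(self.reaction_ids) or n_met != len(self.metabolite_ids):
            raise ModelValidationError(
                f"S is {n_met}x{n_rxn} but model lists {len(self.metabolite_ids)} "
                f"metabolites and {len(self.reaction_ids)} reactions"
            )
        if len(self.lower_bounds) != n_rxn or len(self.upper_bounds) != n_rxn:
            raise ModelValidationError("bound vectors do not match reaction count")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            rid = self.reaction_ids[int(bad[0])]
            raise ModelValidationError(f"reaction {rid!r}: lower bound exceeds upper bound")
        if len(self.gpr_rules) != n_rxn:
            raise ModelValidationError("gpr_rules length does not match reaction count")
        if self.biomass_reaction not in self.reaction_ids:
            raise ConfigurationError(
                f"biomass reaction {self.biomass_reaction!r} is not in the model"
            )
        # every gene referenced by a rule must be declared
        from . import gpr as _gpr  # late import; gpr has no model dependency

        known = set(self.gene_ids)
        for rid, rule in zip(self.reaction_ids, self.gpr_rules):
            for g in _gpr.gpr_genes(rule):
                if g not in known:
                    raise ModelValidationError(
                        f"reaction {rid!r} references unknown gene {g!r}"
                    )
        self._index = {r: j for j, r in enumerate(self.reaction_ids)}

    # -- lookups ---------------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def index(self, reaction_id: str) -> int:
        try:
            return self._index[reaction_id]
        except KeyError:
            raise ConfigurationError(f"unknown reaction id {reaction_id!r}") from None

    @property
    def biomass_index(self) -> int:
        return self.index(self.biomass_reaction)

    def gpr_rule(self, reaction_id: str) -> str:
        return self.gpr_rules[self.index(reaction_id)]

    def with_bounds(self, lower: np.ndarray, upper: np.ndarray) -> "MetabolicModel":
        """Copy of the model with replaced bound vectors."""
        return replace(self, lower_bounds=np.array(lower, dtype=float),
                       upper_bounds=np.array(upper, dtype=float))


@dataclass(frozen=True)
class MediumSpec:
    """Growth-medium constraints applied as exchange/maintenance bounds.

    ``substrate_uptake_rate`` and ``atp_maintenance_flux`` are non-negative
    magnitudes (mmol gDW^-1 h^-1); the uptake sign convention (negative lower
    bound on the substrate exchange) is applied by :func:`apply_medium`.
    ``oxygen_uptake_rate=None`` keeps the model's own oxygen bound when
    aerobic; anaerobic closes oxygen uptake entirely.
    """

    substrate_exchange: str = "EX_glc__D_e"
    substrate_uptake_rate: float = 10.0
    atp_maintenance_reaction: str | None = "ATPM"
    atp_maintenance_flux: float = 7.6
    aerobic: bool = True
    oxygen_exchange: str | None = "EX_o2_e"
    oxygen_uptake_rate: float | None = None

    def __post_init__(self) -> None:
        if self.substrate_uptake_rate < 0:
            raise ValueError("substrate_uptake_rate must be non-negative")
        if self.atp_maintenance_flux < 0:
            raise ValueError("atp_maintenance_flux must be non-negative")


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy of ``model`` with the medium encoded in its bounds.

    Substrate exchange lower bound becomes ``-substrate_uptake_rate``; the ATP
    maintenance reaction's lower bound is raised to ``atp_maintenance_flux``
    (standard COBRA treatment: a floor, not an equality); oxygen uptake is
    opened or closed according to ``aerobic``.  Idempotent.
    """
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    j = model.index(medium.substrate_exchange)
    lb[j] = -medium.substrate_uptake_rate
    if medium.atp_maintenance_reaction:
        k = model.index(medium.atp_maintenance_reaction)
        lb[k] = medium.atp_maintenance_flux
    if medium.oxygen_exchange and medium.oxygen_exchange in model._index:
        o = model.index(medium.oxygen_exchange)
        if not medium.aerobic:
            lb[o] = 0.0
        elif medium.oxygen_uptake_rate is not None:
            lb[o] = -medium.oxygen_uptake_rate
    elif medium.oxygen_exchange and (not medium.aerobic or medium.oxygen_uptake_rate is not None):
        raise ConfigurationError(f"unknown oxygen exchange {medium.oxygen_exchange!r}")
    return model.with_bounds(lb, ub)


# ---------------------------------------------------------------------------
# reading / writing


def _detect_exchanges(reaction_ids: Sequence[str], S: sp.csc_matrix,
                      biomass: str) -> frozenset[str]:
    """Boundary reactions touching exactly one metabolite (biomass excluded)."""
    nnz = np.diff(S.indptr)
    return frozenset(
        rid for j, rid in enumerate(reaction_ids) if nnz[j] == 1 and rid != biomass
    )


def _detect_biomass(reaction_ids: Sequence[str],
                    objective: Sequence[str]) -> str | None:
    for rid in objective:
        return rid
    for rid in reaction_ids:
        if "biomass" in rid.lower():
            return rid
    return None


def from_cobra(cobra_model, biomass_reaction: str | None = None) -> MetabolicModel:
    """Convert a loaded ``cobra.Model`` into a :class:`MetabolicModel`."""
    reaction_ids = [r.id for r in cobra_model.reactions]
    metabolite_ids = [m.id for m in cobra_model.metabolites]
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    S = sp.lil_matrix((len(metabolite_ids), len(reaction_ids)))
    lb = np.empty(len(reaction_ids))
    ub = np.empty(len(reaction_ids))
    rules = []
    objective = []
    for j, rxn in enumerate(cobra_model.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = float(coef)
        lb[j], ub[j] = float(rxn.lower_bound), float(rxn.upper_bound)
        rules.append(rxn.gene_reaction_rule or "")
        if getattr(rxn, "objective_coefficient", 0):
            objective.append(rxn.id)
    biomass = biomass_reaction or _detect_biomass(reaction_ids, objective)
    if biomass is None:
        raise ConfigurationError(
            "no biomass reaction found (no objective, no id matching 'biomass'); "
            "pass biomass_reaction explicitly"
        )
    S = S.tocsc()
    return MetabolicModel(
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        stoichiometry=S,
        lower_bounds=lb,
        upper_bounds=ub,
        gene_ids=[g.id for g in cobra_model.genes],
        gpr_rules=rules,
        biomass_reaction=biomass,
        exchange_reactions=_detect_exchanges(reaction_ids, S, biomass),
    )


def read_model(path: str | Path, format: str | None = None,
               biomass_reaction: str | None = None) -> MetabolicModel:
    """Read an SBML (Level 3 + FBC) or COBRA-JSON model from ``path``.

    ``format`` is inferred from the suffix when omitted (".json" vs
    ".xml"/".sbml", optionally gzipped).
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise IOError(f"model file not found: {path}")
    if format is None:
        suffixes = "".join(path.suffixes).lower()
        format = "json" if ".json" in suffixes else "sbml"
    try:
        if format == "json":
            cm = cobra.io.load_json_model(str(path))
        elif format == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise ValueError(f"unknown model format {format!r}")
    except ValueError as exc:
        if "bound" in str(exc).lower():
            raise ModelValidationError(
                f"{path}: lower bound exceeds upper bound ({exc})") from exc
        raise
    return from_cobra(cm, biomass_reaction=biomass_reaction)


def write_model_json(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as COBRA-style JSON (round-trips through read_model)."""
    S = model.stoichiometry.tocsc()
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        col = S.getcol(j).tocoo()
        mets = {model.metabolite_ids[i]: float(v) for i, v in zip(col.row, col.data)}
        reactions.append({
            "id": rid,
            "name": rid,
            "metabolites": mets,
            "lower_bound": float(model.lower_bounds[j]),
            "upper_bound": float(model.upper_bounds[j]),
            "gene_reaction_rule": model.gpr_rules[j],
            "objective_coefficient": 1.0 if rid == model.biomass_reaction else 0.0,
        })
    doc = {
        "id": "model",
        "metabolites": [
            {"id": m, "name": m, "compartment": "c"} for m in model.metabolite_ids
        ],
        "reactions": reactions,
        "genes": [{"id": g, "name": g} for g in model.gene_ids],
        "compartments": {"c": "cytosol"},
        "version": "1",
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_ecoli_core() -> MetabolicModel:
    """Load the textbook *E. coli* core model bundled with COBRApy.

    95 reactions, 72 metabolites, 137 genes; biomass reaction
    ``Biomass_Ecoli_core``.  Available offline because the SBML file ships
    inside the installed ``cobra`` package.
    """
    from importlib import resources

    p = resources.files("cobra") / "data" / "textbook.xml.gz"
    with resources.as_file(p) as fp:
        return read_model(fp, format="sbml")


# ---------------------------------------------------------------------------
# toy fixture generator


def make_toy_model(n_branches: int = 2, seed: int = 0) -> MetabolicModel:
    """Small branched network with brute-force-checkable FBA/MOMA solutions.

    Layout: substrate A is taken up and split into branch-point metabolite B
    plus redox carrier H (``R_AB: A -> 0.5 B + 0.5 H``).  Exactly
    ``n_branches`` reactions consume B: a biomass-precursor branch
    (``R_BX: B -> X``), a target-product branch that also re-oxidizes H
    (``R_BP: B + 2 H -> 3 P``), and ``n_branches - 2`` inert byproduct
    branches (``R_BW_i: B -> W_i``).  H is otherwise drained by respiration
    (``R_RESP: H + O -> 2 Q``).  Knocking out respiration forces flux through
    the product branch (growth drops, production rises); knocking out the
    biomass branch is lethal -- so single-knockout optima are non-trivial but
    enumerable by hand.  For ``n_branches=2`` a competing byproduct drain off
    the substrate (``R_AW: A -> W0``) keeps a futile pathway in the network.

    Every internal reaction's stoichiometric column sums to zero.  GPRs assign
    one or two genes per internal reaction (structure drawn from ``seed``);
    identical seeds yield identical models.
    """
    if n_branches < 2:
        raise ValueError("n_branches must be >= 2")
    rng = np.random.default_rng(seed)

    mets: list[str] = ["A", "B", "H", "O", "X", "P", "Q"]
    reactions: list[tuple[str, dict[str, float], float, float]] = [
        ("EX_A", {"A": -1.0}, -10.0, 0.0),
        ("EX_O", {"O": -1.0}, -1000.0, 0.0),
        ("EX_P", {"P": -1.0}, 0.0, 1000.0),
        ("EX_Q", {"Q": -1.0}, 0.0, 1000.0),
        ("BIOMASS", {"X": -1.0}, 0.0, 1000.0),
        ("R_AB", {"A": -1.0, "B": 0.5, "H": 0.5}, 0.0, 1000.0),
        ("R_BX", {"B": -1.0, "X": 1.0}, 0.0, 1000.0),
        ("R_BP", {"B": -1.0, "H": -2.0, "P": 3.0}, 0.0, 1000.0),
        ("R_RESP", {"H": -1.0, "O": -1.0, "Q": 2.0}, 0.0, 1000.0),
    ]
    for i in range(n_branches - 2):
        w = f"W{i + 1}"
        mets.append(w)
        reactions.append((f"R_BW{i + 1}", {"B": -1.0, w: 1.0}, 0.0, 1000.0))
        reactions.append((f"EX_{w}", {w: -1.0}, 0.0, 1000.0))
    if n_branches == 2:
        mets.append("W0")
        reactions.append(("R_AW", {"A": -1.0, "W0": 1.0}, 0.0, 1000.0))
        reactions.append(("EX_W0", {"W0": -1.0}, 0.0, 1000.0))

    met_index = {m: i for i, m in enumerate(mets)}
    rids = [r[0] for r in reactions]
    S = sp.lil_matrix((len(mets), len(rids)))
    lb = np.zeros(len(rids))
    ub = np.zeros(len(rids))
    for j, (_, stoich, lo, hi) in enumerate(reactions):
        for m, c in stoich.items():
            S[met_index[m], j] = c
        lb[j], ub[j] = lo, hi

    # 1-2 genes per internal reaction, unique per reaction, seeded structure
    rules = []
    gene_ids: list[str] = []
    counter = 0
    for rid in rids:
        if rid.startswith("EX_") or rid == "BIOMASS":
            rules.append("")
            continue
        n_genes = int(rng.integers(1, 3))
        genes = [f"g{counter + k + 1}" for k in range(n_genes)]
        counter += n_genes
        gene_ids.extend(genes)
        if n_genes == 1:
            rules.append(genes[0])
        else:
            op = "and" if rng.random() < 0.5 else "or"
            rules.append(f"{genes[0]} {op} {genes[1]}")

    S = S.tocsc()
    return MetabolicModel(
        reaction_ids=rids,
        metabolite_ids=mets,
        stoichiometry=S,
        lower_bounds=lb,
        upper_bounds=ub,
        gene_ids=gene_ids,
        gpr_rules=rules,
        biomass_reaction="BIOMASS",
        exchange_reactions=_detect_exchanges(rids, S, "BIOMASS"),
    )
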