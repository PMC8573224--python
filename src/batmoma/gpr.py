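"""Gene-protein-reaction (GPR) rule parsing and knockout translation.

Grammar: identifiers, ``and``, ``or`` (case-insensitive) and parentheses.
``and`` binds tighter than ``or``.  An ``and`` models subunits of one enzyme
complex (all genes required), an ``or`` models isozymes (any gene suffices).
An empty rule means the reaction is not gene-controlled and can never be
disabled by gene deletions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, AbstractSet, Iterable, Union

if TYPE_CHECKING:  # pragma: no cover
    from .model_io import MetabolicModel


class GprParseError(ValueError):
    """Malformed GPR rule string."""


@dataclass(frozen=True)
class Gene:
    name: str

    def eval(self, deleted: AbstractSet[str]) -> bool:
        return self.name not in deleted

    def genes(self) -> frozenset[str]:
        return frozenset((self.name,))


@dataclass(frozen=True)
class And:
    children: tuple["Expr", ...]

    def eval(self, deleted: AbstractSet[str]) -> bool:
        return all(c.eval(deleted) for c in self.children)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))


@dataclass(frozen=True)
class Or:
    children: tuple["Expr", ...]

    def eval(self, deleted: AbstractSet[str]) -> bool:
        return any(c.eval(deleted) for c in self.children)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))


Expr = Union[Gene, And, Or]

_TOKEN = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(rule: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(rule):
        m = _TOKEN.match(rule, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_gpr(rule: str) -> Expr | None:
    """Parse a rule string into an expression tree (``None`` for empty)."""
    if rule is None or not rule.strip():
        return None
    tokens = _tokenize(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Expr:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and() -> Expr:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom() -> Expr:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in {rule!r}")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in {rule!r}")
        return Gene(take())

    expr = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in {rule!r}")
    return expr


def gpr_genes(rule: str | Expr | None) -> frozenset[str]:
    """All gene ids referenced by a rule."""
    expr = parse_gpr(rule) if isinstance(rule, str) or rule is None else rule
    return frozenset() if expr is None else expr.genes()


def evaluate_gpr(rule: str | Expr | None, deleted_genes: Iterable[str]) -> bool:
    """Truth value of the rule with deleted genes false, others true.

    Empty rule evaluates true: a reaction with no gene association keeps
    carrying flux under any deletion.
    """
    expr = parse_gpr(rule) if isinstance(rule, str) or rule is None else rule
    if expr is None:
        return True
    return expr.eval(frozenset(deleted_genes))


def reactions_disabled(model: "MetabolicModel",
                       deleted_genes: Iterable[str]) -> set[str]:
    """Reactions whose non-empty GPR evaluates false under the deletions."""
    deleted = frozenset(deleted_genes)
    unknown = deleted - set(model.gene_ids)
    if unknown:
        from .model_io import ConfigurationError

        raise ConfigurationError(f"unknown gene id(s): {sorted(unknown)}")
    out = set()
    for rid, rule in zip(model.reaction_ids, model.gpr_rules):
        if rule and not evaluate_gpr(rule, deleted):
            out.add(rid)
    return out


def knockable_units(model: "MetabolicModel",
                    exclude: Iterable[str] = ()) -> list[str]:
    """Reactions the search may knock out, in model order.

    A knockable unit is an internal (non-exchange), gene-associated reaction
    that is neither the biomass pseudo-reaction nor ATP maintenance.  Each
    unit corresponds to one enzyme; its gene list comes from the GPR.
    """
    excluded = set(exclude)
    units = []
    for rid, rule in zip(model.reaction_ids, model.gpr_rules):
        if rid in model.exchange_reactions or rid == model.biomass_reaction:
            continue
        if rid.lower() == "atpm" or rid in excluded or not rule:
            continue
        units.append(rid)
    return units


def unit_genes(model: "MetabolicModel", reaction_id: str) -> tuple[str, ...]:
    """Sorted gene list behind one knockable unit (for reporting)."""
    return tuple(sorted(gpr_genes(model.gpr_rule(reaction_id))))
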