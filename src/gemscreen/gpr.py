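"""Boolean gene-protein-reaction (GPR) rules.

A GPR states when a reaction's catalyst is available as a boolean
expression over gene (ORF) identifiers: ``and`` joins subunits of a
complex (all required), ``or`` joins isozymes (any suffices).  Deleting
a set of genes disables exactly those reactions whose GPR evaluates to
False.  ``and`` binds tighter than ``or`` (COBRA / SBML-FBC convention);
parentheses override.

Gene identifiers are opaque, case-sensitive strings (systematic ORF
names such as ``YPR021C`` are expected but not required).  Keywords
``and`` / ``or`` are matched case-insensitively.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "GeneAssociation",
    "GPRSyntaxError",
    "parse_gpr",
    "evaluate_gpr",
    "apply_deletions",
]


class GPRSyntaxError(ValueError):
    """Malformed GPR text; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GeneAssociation:
    """Node of a GPR expression tree.

    ``op`` is ``"gene"`` for a leaf (then ``gene`` is set), or ``"and"``
    / ``"or"`` for an internal node with ``children``.
    """

    op: str
    gene: str | None = None
    children: tuple["GeneAssociation", ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.op == "gene":
            if not self.gene:
                raise ValueError("leaf node requires a gene id")
        elif self.op in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"'{self.op}' node requires >= 2 children")
        else:
            raise ValueError(f"unknown GPR operator {self.op!r}")

    def genes(self) -> frozenset[str]:
        """All gene ids appearing in the expression."""
        if self.op == "gene":
            return frozenset([self.gene])
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        """True iff the reaction remains catalysed after deleting ``deleted``."""
        if self.op == "gene":
            return self.gene not in deleted
        if self.op == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def to_string(self) -> str:
        """Normalized serialization; parentheses always explicit."""
        if self.op == "gene":
            return self.gene
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "gene":
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> GeneAssociation:
    """Parse GPR text into an expression tree.

    Grammar: ``expr := term ("or" term)*``, ``term := atom ("and" atom)*``,
    ``atom := GENE | "(" expr ")"``, so ``and`` binds tighter than ``or``.

    Raises :class:`GPRSyntaxError` on empty input, unbalanced parentheses
    or dangling operators, with the offending character position.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRSyntaxError("empty GPR expression", 0)
    idx = 0

    def peek() -> tuple[str, int] | None:
        return tokens[idx] if idx < len(tokens) else None

    def expect_more(what: str):
        if idx >= len(tokens):
            raise GPRSyntaxError(f"expected {what}, found end of input", len(text))

    def parse_or() -> GeneAssociation:
        nonlocal idx
        terms = [parse_and()]
        while (tok := peek()) is not None and tok[0].lower() == "or":
            idx += 1
            expect_more("expression after 'or'")
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GeneAssociation("or", children=tuple(terms))

    def parse_and() -> GeneAssociation:
        nonlocal idx
        atoms = [parse_atom()]
        while (tok := peek()) is not None and tok[0].lower() == "and":
            idx += 1
            expect_more("expression after 'and'")
            atoms.append(parse_atom())
        if len(atoms) == 1:
            return atoms[0]
        return GeneAssociation("and", children=tuple(atoms))

    def parse_atom() -> GeneAssociation:
        nonlocal idx
        expect_more("gene id or '('")
        tok, pos = tokens[idx]
        if tok == "(":
            idx += 1
            node = parse_or()
            if peek() is None or tokens[idx][0] != ")":
                raise GPRSyntaxError("unbalanced parentheses: missing ')'", pos)
            idx += 1
            return node
        if tok == ")":
            raise GPRSyntaxError("unexpected ')'", pos)
        if tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected operator {tok!r}", pos)
        idx += 1
        return GeneAssociation("gene", gene=tok)

    tree = parse_or()
    if idx < len(tokens):
        raise GPRSyntaxError(f"unexpected token {tokens[idx][0]!r}", tokens[idx][1])
    return tree


def evaluate_gpr(assoc: GeneAssociation, deleted: set[str]) -> bool:
    """True iff the association survives deletion of ``deleted`` genes."""
    return assoc.evaluate(deleted)


def apply_deletions(model, deleted: set[str], warn_unknown: bool = True):
    """Return a copy of ``model`` with deletion-disabled reactions closed.

    Every reaction whose GPR evaluates False under ``deleted`` gets bounds
    (0, 0); reactions without a GPR are never touched.  Gene ids in
    ``deleted`` that the model does not contain are ignored (reference
    lists routinely cover the whole genome while models cover a subset);
    a warning is emitted unless ``warn_unknown`` is False.
    """
    deleted = set(deleted)
    unknown = deleted - model.genes
    if unknown and warn_unknown:
        warnings.warn(
            f"{len(unknown)} deleted gene id(s) not in model "
            f"{model.model_id!r}; ignored: {sorted(unknown)[:5]}...",
            stacklevel=2,
        )
    effective = deleted & model.genes
    out = model.copy()
    if not effective:
        return out
    for rxn in out.reactions.values():
        if rxn.gpr is not None and not rxn.gpr.evaluate(effective):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return out


def disabled_reactions(model, deleted: set[str]) -> set[str]:
    """Ids of reactions whose GPR evaluates False under ``deleted``."""
    effective = set(deleted) & model.genes
    return {
        r.id
        for r in model.reactions.values()
        if r.gpr is not None and not r.gpr.evaluate(effective)
    }
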