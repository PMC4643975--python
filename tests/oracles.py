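"""Independent oracles used by the tests.

Each function recomputes a quantity by a route deliberately different
from the implementation under test: Python's own expression evaluator
for GPR semantics, exhaustive vertex enumeration for small FBA
problems, and a direct sign-pattern sweep of the stoichiometric matrix
for dead ends.
"""

from __future__ import annotations

import itertools
import re

import numpy as np


def gpr_eval_via_python(text: str, deleted: set[str]) -> bool:
    """Evaluate GPR text with Python's own parser as the oracle.

    Gene tokens are replaced by True/False literals and the result is
    handed to ``eval`` — an entirely separate grammar implementation
    with the same and/or precedence convention.
    """
    def sub(match: re.Match) -> str:
        token = match.group(0)
        if token.lower() in ("and", "or"):
            return token.lower()
        return str(token not in deleted)

    expr = re.sub(r"[^\s()]+", sub, text)
    return bool(eval(expr))  # noqa: S307 - controlled test input


def fba_optimum_by_vertex_enumeration(model) -> float:
    """Maximum objective flux by brute-force vertex enumeration.

    The feasible set {v : S v = 0, lb <= v <= ub} is a polytope; its
    optimum lies at a vertex where n - rank(S) bounds are active.  Every
    choice of active-bound support and lb/ub sign pattern is enumerated
    and the best feasible objective returned.  Exponential — for toy
    models only.
    """
    S_sp, _mets, rxn_ids = model.stoichiometric_matrix()
    S = S_sp.toarray()
    n = len(rxn_ids)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    obj = rxn_ids.index(model.objective_reaction_id)
    best = None
    for fixed_idx in itertools.combinations(range(n), n_fixed):
        free_idx = [j for j in range(n) if j not in fixed_idx]
        S_free = S[:, free_idx]
        for pattern in itertools.product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, pick in zip(fixed_idx, pattern):
                v[j] = lb[j] if pick == 0 else ub[j]
            if not np.all(np.isfinite(v[list(fixed_idx)])):
                continue
            rhs = -S[:, list(fixed_idx)] @ v[list(fixed_idx)]
            sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
            if not np.allclose(S_free @ sol, rhs, atol=1e-8):
                continue  # inconsistent support
            v[free_idx] = sol
            if np.all(v >= lb - 1e-8) and np.all(v <= ub + 1e-8):
                if best is None or v[obj] > best:
                    best = v[obj]
    if best is None:
        raise RuntimeError("no feasible vertex found")
    return float(best)


def dead_ends_by_sign_pattern(model) -> set[str]:
    """Dead ends from a dense sweep over S and the bound sign pattern."""
    S_sp, met_ids, rxn_ids = model.stoichiometric_matrix()
    S = S_sp.toarray()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    out: set[str] = set()
    for i, met in enumerate(met_ids):
        cols = np.nonzero(S[i, :])[0]
        if len(cols) <= 1:
            out.add(met)
            continue
        producible = consumable = False
        for j in cols:
            c = S[i, j]
            if (c > 0 and ub[j] > 0) or (c < 0 and lb[j] < 0):
                producible = True
            if (c < 0 and ub[j] > 0) or (c > 0 and lb[j] < 0):
                consumable = True
        if not (producible and consumable):
            out.add(met)
    return out


def to_cobra(model):
    """Convert to a COBRApy model (independent FBA/FVA cross-check)."""
    import cobra

    cm = cobra.Model(model.model_id)
    mets = {}
    for met in model.metabolites.values():
        if met.is_boundary:
            continue
        mets[met.id] = cobra.Metabolite(met.id, compartment=met.compartment or "c")
    cm.add_metabolites(list(mets.values()))
    rxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id)
        cr.lower_bound = rxn.lower_bound
        cr.upper_bound = rxn.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for rxn in model.reactions.values():
        cm.reactions.get_by_id(rxn.id).add_metabolites(
            {
                mets[m]: coeff
                for m, coeff in rxn.stoichiometry.items()
                if m in mets
            }
        )
        if rxn.gpr is not None:
            cm.reactions.get_by_id(rxn.id).gene_reaction_rule = rxn.gpr.to_string()
    cm.objective = model.objective_reaction_id
    return cm
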