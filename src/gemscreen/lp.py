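"""Linear-programming core: FBA, one-norm-minimised FBA, flux
variability, blocked reactions and dead-end metabolites.

Flux balance analysis maximises the flux through the objective
(biomass) reaction subject to steady-state mass balance, S·v = 0 over
the non-boundary metabolites, and per-reaction flux bounds
lb ≤ v ≤ ub.  All problems are solved with the HiGHS solver through
:func:`scipy.optimize.linprog`, which is deterministic for a fixed
problem.  Alternate optima exist in genome-scale systems: only
objective values and one-norm-minimal norms are contractual, not the
individual fluxes of a particular optimal vertex.

Numerical tolerances: ``FEAS_TOL`` (1e-9) is the solver feasibility
scale; ``BLOCKED_TOL`` (1e-6) is the threshold below which a flux range
counts as "cannot carry flux", chosen on the same scale as the 1e-6
growth-essentiality cutoff used by the deletion screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import DEFAULT_BOUND, MetabolicModel

__all__ = [
    "FBAResult",
    "FluxRange",
    "InfeasibleModelError",
    "solve_fba",
    "solve_fba_l1min",
    "flux_variability",
    "blocked_reactions",
    "dead_end_metabolites",
    "dead_end_details",
    "FEAS_TOL",
    "BLOCKED_TOL",
]

FEAS_TOL = 1e-9
BLOCKED_TOL = 1e-6


class InfeasibleModelError(RuntimeError):
    """The model's constraint set admits no flux distribution."""


@dataclass
class FBAResult:
    """Outcome of one linear-programming simulation."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None = None
    fluxes: dict[str, float] | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def growth(self) -> float:
        """Objective value as a growth proxy: infeasible scores as zero
        growth, unbounded as infinite (a pathology callers report)."""
        if self.optimal:
            return self.objective_value
        return float("inf") if self.status == "unbounded" else 0.0


@dataclass
class FluxRange:
    reaction_id: str
    v_min: float
    v_max: float

    @property
    def blocked(self) -> bool:
        return abs(self.v_min) < BLOCKED_TOL and abs(self.v_max) < BLOCKED_TOL


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _lp_parts(model: MetabolicModel):
    S, _met_ids, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return S, rxn_ids, lb, ub


def _solve(c, A_eq, b_eq, lb, ub) -> tuple[str, np.ndarray | None, float | None]:
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return status, None, None
    return status, res.x, res.fun


def solve_fba(model: MetabolicModel, objective_reaction_id: str | None = None) -> FBAResult:
    """Maximise flux through the objective reaction.

    Returns an :class:`FBAResult`; ``status`` is ``"infeasible"`` when the
    constraints cannot be satisfied and ``"unbounded"`` when the objective
    can grow without limit (a model pathology the growth-scan workflow
    reports rather than clamps).
    """
    obj = objective_reaction_id or model.objective_reaction_id
    if obj is None or obj not in model.reactions:
        raise ValueError(f"objective reaction {obj!r} not in model")
    S, rxn_ids, lb, ub = _lp_parts(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(obj)] = -1.0  # linprog minimises
    status, x, fun = _solve(c, S, np.zeros(S.shape[0]), lb, ub)
    if status != "optimal":
        return FBAResult(status=status)
    return FBAResult(
        status="optimal",
        objective_value=-fun,
        fluxes=dict(zip(rxn_ids, x)),
    )


def solve_fba_l1min(model: MetabolicModel) -> FBAResult:
    """FBA followed by one-norm minimisation of the flux vector.

    The biomass flux is first maximised, then held at its optimum
    (within ``10 * FEAS_TOL``) while Σ|v| is minimised via split
    positive/negative flux variables.  The returned ``objective_value``
    is the unchanged biomass flux; the returned fluxes have minimal
    one-norm, which suppresses internal loops that carry no benefit to
    the objective.
    """
    first = solve_fba(model)
    if not first.optimal:
        return first
    opt = first.objective_value

    S, rxn_ids, lb, ub = _lp_parts(model)
    n = len(rxn_ids)
    m = S.shape[0]
    # v = p - q with p, q >= 0; min sum(p + q)
    Sd = sparse.hstack([S, -S], format="csr")
    obj_row = np.zeros(n)
    obj_row[rxn_ids.index(model.objective_reaction_id)] = 1.0
    obj_row_d = np.concatenate([obj_row, -obj_row])
    A_eq = sparse.vstack([Sd, sparse.csr_matrix(obj_row_d)], format="csr")
    b_eq = np.concatenate([np.zeros(m), [opt]])

    lb_p = np.maximum(lb, 0.0)
    ub_p = np.maximum(ub, 0.0)
    lb_q = np.maximum(-ub, 0.0)
    ub_q = np.maximum(-lb, 0.0)
    lo = np.concatenate([lb_p, lb_q])
    hi = np.concatenate([ub_p, ub_q])
    c = np.ones(2 * n)

    status, x, _fun = _solve(c, A_eq, b_eq, lo, hi)
    if status != "optimal":
        # numerically brittle equality; retry with a hair of slack
        slack = 10 * FEAS_TOL * max(1.0, abs(opt))
        A_ub = sparse.csr_matrix(-obj_row_d)
        res = linprog(
            c,
            A_eq=Sd,
            b_eq=np.zeros(m),
            A_ub=A_ub,
            b_ub=np.array([-(opt - slack)]),
            bounds=np.column_stack([lo, hi]),
            method="highs",
        )
        if res.status != 0:
            return FBAResult(status=_STATUS.get(res.status, "infeasible"))
        x = res.x
    v = x[:n] - x[n:]
    return FBAResult(
        status="optimal",
        objective_value=opt,
        fluxes=dict(zip(rxn_ids, v)),
    )


def flux_variability(
    model: MetabolicModel,
    reaction_ids: list[str] | None = None,
    fraction_of_optimum: float | None = None,
) -> list[FluxRange]:
    """Per-reaction minimum and maximum attainable flux.

    Each range comes from two LPs (minimise / maximise that reaction's
    flux) under the model's full constraint set.  By default no
    objective-fraction constraint is imposed — the biomass reaction is
    present but not fixed, so the ranges reflect network-structural
    freedom.  Pass ``fraction_of_optimum`` (e.g. 0.9) to additionally
    require the objective to stay at that fraction of its FBA optimum.
    """
    if fraction_of_optimum is not None:
        if not 0 <= fraction_of_optimum <= 1:
            raise ValueError("fraction_of_optimum must be in [0, 1]")
        base = solve_fba(model)
        if not base.optimal:
            raise InfeasibleModelError(f"FBA is {base.status}, check medium")
        model = model.copy()
        obj = model.reactions[model.objective_reaction_id]
        obj.lower_bound = max(
            obj.lower_bound, fraction_of_optimum * base.objective_value
        )
    S, rxn_ids, lb, ub = _lp_parts(model)
    targets = list(reaction_ids) if reaction_ids is not None else rxn_ids
    index = {r: i for i, r in enumerate(rxn_ids)}
    # feasibility check once
    feas = linprog(
        np.zeros(len(rxn_ids)),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if feas.status == 2:
        raise InfeasibleModelError("infeasible, check medium")
    out = []
    b_eq = np.zeros(S.shape[0])
    for rid in targets:
        if rid not in index:
            raise KeyError(f"unknown reaction {rid!r}")
        c = np.zeros(len(rxn_ids))
        c[index[rid]] = 1.0
        vmin_stat, x, fun_min = _solve(c, S, b_eq, lb, ub)
        vmax_stat, x, fun_max = _solve(-c, S, b_eq, lb, ub)
        v_min = fun_min if vmin_stat == "optimal" else (
            -np.inf if vmin_stat == "unbounded" else np.nan
        )
        v_max = -fun_max if vmax_stat == "optimal" else (
            np.inf if vmax_stat == "unbounded" else np.nan
        )
        out.append(FluxRange(reaction_id=rid, v_min=v_min, v_max=v_max))
    return out


def blocked_reactions(model: MetabolicModel, biomass=None) -> set[str]:
    """Reactions that cannot carry flux when all exchanges are open.

    Every exchange reaction's bounds are relaxed to (−1000, 1000) before
    the variability scan, so blockage reflects network structure rather
    than medium composition.  ``biomass`` (a BiomassDefinition) is
    substituted first when given, since blockage of biomass-coupled
    reactions depends on the objective's composition.
    """
    if biomass is not None:
        from .media import set_biomass

        model = set_biomass(model, biomass)
    opened = model.copy()
    for rxn in opened.reactions.values():
        if rxn.is_exchange:
            rxn.lower_bound = -DEFAULT_BOUND
            rxn.upper_bound = DEFAULT_BOUND
    ranges = flux_variability(opened)
    return {fr.reaction_id for fr in ranges if fr.blocked}


def dead_end_details(model: MetabolicModel) -> dict[str, str]:
    """Dead-end metabolites with the clause that classifies them.

    Two structural clauses, both independent of bounds on exchange
    reactions or biomass composition:

    * ``"single-reaction"`` — the metabolite participates in exactly one
      reaction;
    * ``"produced-only"`` / ``"consumed-only"`` — considering reaction
      reversibility, every participation can only create (or only
      remove) the metabolite.

    Boundary metabolites are outside the steady-state system and are
    never reported.
    """
    participation: dict[str, list[tuple[float, float, float]]] = {
        m.id: [] for m in model.metabolites.values() if not m.is_boundary
    }
    for rxn in model.reactions.values():
        for met_id, coeff in rxn.stoichiometry.items():
            if coeff != 0 and met_id in participation:
                participation[met_id].append(
                    (coeff, rxn.lower_bound, rxn.upper_bound)
                )
    out: dict[str, str] = {}
    for met_id, parts in participation.items():
        if len(parts) == 0:
            out[met_id] = "orphan"
            continue
        if len(parts) == 1:
            out[met_id] = "single-reaction"
            continue
        can_produce = any(
            (coeff > 0 and ub > 0) or (coeff < 0 and lb < 0)
            for coeff, lb, ub in parts
        )
        can_consume = any(
            (coeff < 0 and ub > 0) or (coeff > 0 and lb < 0)
            for coeff, lb, ub in parts
        )
        if not can_consume:
            out[met_id] = "produced-only"
        elif not can_produce:
            out[met_id] = "consumed-only"
    return out


def dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Ids of dead-end metabolites (see :func:`dead_end_details`)."""
    return set(dead_end_details(model))
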