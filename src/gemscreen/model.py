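"""In-memory representation of a genome-scale metabolic model.

The model is the stoichiometric system every analysis runs on: a set of
metabolites (rows of S), reactions with flux bounds (columns of S), a
gene set tied to reactions through boolean GPR rules, and a designated
objective (biomass) reaction.  Boundary metabolites — the ``_b`` species
COBRA-style models use to close exchange reactions — are carried but
excluded from the steady-state constraint S·v = 0.

Flux bounds are in model-relative units (mmol/gDW/h by convention); no
unit conversion is attempted.
"""

from __future__ import annotations

import copy as _copy
import logging
from dataclasses import dataclass, field

from scipy import sparse

from .gpr import GeneAssociation

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelSummary",
    "DEFAULT_BOUND",
    "summarize_model",
]

logger = logging.getLogger(__name__)

#: Default bound magnitude used when a file omits reaction bounds
#: (COBRA convention).
DEFAULT_BOUND = 1000.0

#: Boundary-species id suffix used by COBRA-style SBML files.
BOUNDARY_SUFFIX = "_b"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    #: ChEBI identifiers in file order; consumers choose (scope comparison
    #: uses the first).  Possibly empty.
    chebi_ids: tuple[str, ...] = ()
    #: Boundary metabolites close exchange reactions and are excluded
    #: from the steady-state constraint.
    is_boundary: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GeneAssociation | None = None
    #: Recomputed by :meth:`MetabolicModel.refresh_exchanges`; never
    #: trusted from input files.
    is_exchange: bool = False

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    model_id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: set[str] = field(default_factory=set)
    objective_reaction_id: str | None = None

    def __post_init__(self):
        self.validate()
        self.refresh_exchanges()

    # -- consistency ---------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity; raise ValueError on violation."""
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
            if rxn.gpr is not None:
                missing = rxn.gpr.genes() - self.genes
                if missing:
                    # GPR genes must be registered; auto-register quietly
                    # would hide typos, so this is a hard error.
                    raise ValueError(
                        f"reaction {rxn.id!r} GPR names genes not in model: "
                        f"{sorted(missing)}"
                    )
        if (
            self.objective_reaction_id is not None
            and self.objective_reaction_id not in self.reactions
        ):
            raise ValueError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )

    def refresh_exchanges(self) -> None:
        """Recompute the ``is_exchange`` flag on every reaction.

        A reaction is an exchange if it touches exactly one non-boundary
        metabolite, or its id carries a conventional ``EX_``/``R_EX_``
        prefix.  The flag is derived, never trusted from input.
        """
        for rxn in self.reactions.values():
            internal = [
                m for m in rxn.stoichiometry if not self.metabolites[m].is_boundary
            ]
            by_structure = len(internal) == 1
            by_prefix = rxn.id.startswith(("EX_", "R_EX_"))
            rxn.is_exchange = by_structure or by_prefix

    # -- views ---------------------------------------------------------

    @property
    def exchange_reactions(self) -> dict[str, Reaction]:
        return {rid: r for rid, r in self.reactions.items() if r.is_exchange}

    def exchanged_metabolite(self, reaction_id: str) -> str | None:
        """The single non-boundary metabolite an exchange reaction touches."""
        rxn = self.reactions[reaction_id]
        internal = [
            m for m in rxn.stoichiometry if not self.metabolites[m].is_boundary
        ]
        return internal[0] if len(internal) == 1 else None

    def stoichiometric_matrix(
        self, include_boundary: bool = False
    ) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """The S matrix with its row (metabolite) and column (reaction) ids.

        Boundary metabolites are excluded by default: they are not part of
        the steady-state constraint.
        """
        met_ids = [
            m.id
            for m in self.metabolites.values()
            if include_boundary or not m.is_boundary
        ]
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(rxn_ids):
            for met_id, coeff in self.reactions[rid].stoichiometry.items():
                i = met_index.get(met_id)
                if i is not None and coeff != 0:
                    rows.append(i)
                    cols.append(j)
                    vals.append(float(coeff))
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        return S, met_ids, rxn_ids

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    def with_objective(self, reaction_id: str) -> "MetabolicModel":
        if reaction_id not in self.reactions:
            raise ValueError(f"unknown reaction {reaction_id!r}")
        out = self.copy()
        out.objective_reaction_id = reaction_id
        return out

    # -- equality (round-trip contract) --------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.model_id == other.model_id
            and self.genes == other.genes
            and self.objective_reaction_id == other.objective_reaction_id
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )


@dataclass
class ModelSummary:
    """Headline descriptive statistics for one model.

    ``n_blocked_common_biomass`` is None (absent, not zero) when the
    common biomass definition cannot be applied to the model.
    """

    model_id: str
    n_genes: int
    n_dubious_genes: int
    n_metabolites: int
    n_dead_ends: int
    n_reactions: int
    n_gene_associated_reactions: int
    n_blocked_default_biomass: int
    n_blocked_common_biomass: int | None = None


def summarize_model(
    model: MetabolicModel,
    dubious_orfs: set[str] | None = None,
    common_biomass=None,
) -> ModelSummary:
    """Compute the per-model summary-statistics row.

    ``dubious_orfs``: ORFs annotated as unlikely to encode a protein
    (supplied as an input list, typically from SGD).  Blocked-reaction
    counts are evaluated with all exchange reactions opened, once with
    the model's own objective and — if ``common_biomass`` (a
    :class:`~gemscreen.media.BiomassDefinition`) applies — once with the
    common objective substituted.
    """
    # local imports: lp/media depend on this module
    from .lp import blocked_reactions, dead_end_metabolites
    from .media import BiomassResolutionError, set_biomass

    dubious_orfs = dubious_orfs or set()
    n_internal_mets = sum(1 for m in model.metabolites.values() if not m.is_boundary)
    n_blocked_common: int | None = None
    if common_biomass is not None:
        try:
            n_blocked_common = len(
                blocked_reactions(set_biomass(model, common_biomass))
            )
        except BiomassResolutionError as exc:
            logger.info(
                "common biomass inapplicable to %s: %s", model.model_id, exc
            )
            n_blocked_common = None
    return ModelSummary(
        model_id=model.model_id,
        n_genes=len(model.genes),
        n_dubious_genes=len(model.genes & dubious_orfs),
        n_metabolites=n_internal_mets,
        n_dead_ends=len(dead_end_metabolites(model)),
        n_reactions=len(model.reactions),
        n_gene_associated_reactions=sum(
            1 for r in model.reactions.values() if r.gpr is not None
        ),
        n_blocked_default_biomass=len(blocked_reactions(model)),
        n_blocked_common_biomass=n_blocked_common,
    )
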