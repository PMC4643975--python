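"""Medium and biomass standardization.

Published genome-scale models ship with tuned simulation parameters —
a default medium (the exchange-reaction bounds) and a default biomass
objective.  Comparing models on those defaults confounds the quality of
the underlying network reconstruction with parameter tuning, so this
module substitutes standardized media and a common biomass definition:

* :func:`apply_medium` closes every exchange uptake, then opens exactly
  the listed components.  Uptake is encoded as a negative lower bound on
  the exchange reaction; "unconstrained" means magnitude 1000 (COBRA
  convention).
* :func:`set_biomass` replaces the objective with a new reaction built
  from a named precursor stoichiometry.  Components are resolved by
  metabolite id first, then by ChEBI identifier; if any component cannot
  be resolved the substitution fails loudly with the full missing list —
  a model that cannot express the common biomass is excluded from
  common-biomass comparisons, never silently approximated.

Media and biomass definitions are plain YAML so per-model key maps can
be edited without touching code.  Every applied definition should be
echoed into run logs for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import DEFAULT_BOUND, MetabolicModel, Reaction

__all__ = [
    "MediumDefinition",
    "BiomassDefinition",
    "MediumResolutionError",
    "BiomassResolutionError",
    "apply_medium",
    "set_biomass",
    "load_medium",
    "load_biomass",
]

logger = logging.getLogger(__name__)

#: Default glucose uptake bound for the minimal glucose-limited medium:
#: a conventional "constrained uptake" magnitude, echoed in reports.
DEFAULT_GLUCOSE_UPTAKE = 10.0


class MediumResolutionError(KeyError):
    """A medium component could not be matched to an exchange reaction."""


class BiomassResolutionError(KeyError):
    """Biomass components missing from the model; carries the full list."""

    def __init__(self, model_id: str, missing: list[str]):
        super().__init__(
            f"model {model_id!r} lacks biomass component(s): {sorted(missing)}"
        )
        self.missing = sorted(missing)


@dataclass
class MediumDefinition:
    """Named exchange-bound assignment.

    ``uptake_bounds`` maps a component key — an exchange reaction id, the
    id of the exchanged metabolite, or a ChEBI identifier — to the
    (lower, upper) bounds to impose on the matching exchange reaction.
    ``supplements`` lists, per model id, extra exchanges opened fully for
    models that otherwise cannot grow (e.g. an iron exchange).
    """

    name: str
    uptake_bounds: dict[str, tuple[float, float]]
    supplements: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "uptake_bounds": {k: list(v) for k, v in self.uptake_bounds.items()},
            "supplements": dict(self.supplements),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MediumDefinition":
        return cls(
            name=d["name"],
            uptake_bounds={k: tuple(v) for k, v in d["uptake_bounds"].items()},
            supplements={k: list(v) for k, v in d.get("supplements", {}).items()},
        )


@dataclass
class BiomassDefinition:
    """Named biomass stoichiometry.

    ``stoichiometry`` maps a metabolite key (model metabolite id or ChEBI
    identifier) to its signed coefficient; negative = consumed precursor.
    At least one component must be consumed.
    """

    name: str
    stoichiometry: dict[str, float]

    def __post_init__(self):
        if not any(v < 0 for v in self.stoichiometry.values()):
            raise ValueError(
                f"biomass {self.name!r} consumes no component "
                "(no negative coefficient)"
            )

    def to_dict(self) -> dict:
        return {"name": self.name, "stoichiometry": dict(self.stoichiometry)}

    @classmethod
    def from_dict(cls, d: dict) -> "BiomassDefinition":
        return cls(name=d["name"], stoichiometry=dict(d["stoichiometry"]))


def load_medium(path: str | Path) -> MediumDefinition:
    return MediumDefinition.from_dict(yaml.safe_load(Path(path).read_text()))


def load_biomass(path: str | Path) -> BiomassDefinition:
    return BiomassDefinition.from_dict(yaml.safe_load(Path(path).read_text()))


def save_medium(medium: MediumDefinition, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(medium.to_dict(), sort_keys=False))


def save_biomass(biomass: BiomassDefinition, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(biomass.to_dict(), sort_keys=False))


def _exchange_index(model: MetabolicModel) -> dict[str, str]:
    """Component key -> exchange reaction id (id-first, then ChEBI)."""
    index: dict[str, str] = {}
    for rid, rxn in model.exchange_reactions.items():
        index.setdefault(rid, rid)
        met_id = model.exchanged_metabolite(rid)
        if met_id is not None:
            index.setdefault(met_id, rid)
            for token in model.metabolites[met_id].chebi_ids:
                index.setdefault(token, rid)
    return index


def resolve_exchange(model: MetabolicModel, key: str) -> str:
    """Exchange reaction id matching a medium component key."""
    index = _exchange_index(model)
    if key not in index:
        candidates = sorted(model.exchange_reactions)
        raise MediumResolutionError(
            f"medium component {key!r} matches no exchange reaction of "
            f"{model.model_id!r}; exchanges: {candidates}"
        )
    return index[key]


def apply_medium(model: MetabolicModel, medium: MediumDefinition) -> MetabolicModel:
    """Impose a medium: close all uptake, then open the listed components.

    Secretion (upper bounds) is left open unless the medium overrides it.
    Idempotent.  Unresolvable components are a hard error listing the
    model's exchange ids — a silently skipped nutrient would corrupt
    every downstream comparison.
    """
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.is_exchange:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    for key, (lb, ub) in medium.uptake_bounds.items():
        rid = resolve_exchange(out, key)
        out.reactions[rid].lower_bound = lb
        out.reactions[rid].upper_bound = ub
    for key in medium.supplements.get(model.model_id, []):
        rid = resolve_exchange(out, key)
        out.reactions[rid].lower_bound = -DEFAULT_BOUND
        out.reactions[rid].upper_bound = DEFAULT_BOUND
    logger.info("applied medium %s to %s", medium.name, model.model_id)
    return out


def _resolve_metabolite(model: MetabolicModel, key: str) -> str | None:
    if key in model.metabolites:
        return key
    for met in model.metabolites.values():
        if key in met.chebi_ids:
            return met.id
    return None


def set_biomass(model: MetabolicModel, biomass: BiomassDefinition) -> MetabolicModel:
    """Substitute the objective with a reaction built from ``biomass``.

    The previous objective reaction is closed (bounds 0, 0) so it cannot
    act as an uncontrolled drain, and a new reaction named
    ``biomass_<name>`` becomes the objective.  Substituting a definition
    identical to the model's own biomass therefore leaves every screen
    result unchanged.  Raises :class:`BiomassResolutionError` listing
    every unresolvable component.
    """
    resolved: dict[str, float] = {}
    missing: list[str] = []
    for key, coeff in biomass.stoichiometry.items():
        met_id = _resolve_metabolite(model, key)
        if met_id is None:
            missing.append(key)
        else:
            resolved[met_id] = resolved.get(met_id, 0.0) + coeff
    if missing:
        raise BiomassResolutionError(model.model_id, missing)

    out = model.copy()
    new_id = f"biomass_{biomass.name}"
    if out.objective_reaction_id is not None and out.objective_reaction_id != new_id:
        old = out.reactions[out.objective_reaction_id]
        old.lower_bound = 0.0
        old.upper_bound = 0.0
    out.reactions[new_id] = Reaction(
        id=new_id,
        name=f"biomass ({biomass.name})",
        stoichiometry=resolved,
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
    )
    out.objective_reaction_id = new_id
    out.refresh_exchanges()
    out.validate()
    logger.info("substituted biomass %s into %s", biomass.name, model.model_id)
    return out
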