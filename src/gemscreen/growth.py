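"""Constrained-growth scans, correlation with observed growth rates,
and the one-norm loop-diagnosis / reaction-removal workflow.

The scan clamps measured nutrient uptake rates (glucose, oxygen,
nitrogen sources, singly or jointly) onto the matching exchange
reactions and records the FBA biomass optimum per condition.  Predicted
maxima are compared with measured growth rates by Pearson
product-moment correlation — the relation is linear while a single
nutrient is the binding constraint, which is the regime of interest.

Models that overpredict biomass at high glucose:oxygen uptake ratios
tend to route unrealistically large fluxes through internal loops; the
diagnosis ranks internal reactions by |flux| in a one-norm-minimised
FBA solution, and :func:`remove_reaction_and_rescan` closes a suspect
reaction (bounds 0,0 — a soft removal with the same optima as deleting
the column) and repeats the scan to see whether correlations recover.
A lookup of the mitochondrial aspartate-transport reaction ids used by
the published yeast models is shipped for that workflow.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lp import solve_fba, solve_fba_l1min
from .media import resolve_exchange
from .model import MetabolicModel

__all__ = [
    "GrowthObservation",
    "ScanResult",
    "constrained_growth_scan",
    "pearson_correlation",
    "spearman_correlation",
    "diagnose_high_flux_reactions",
    "remove_reaction_and_rescan",
    "ASPARTATE_TRANSPORT_IDS",
    "resolve_aspartate_transport",
]

logger = logging.getLogger(__name__)

#: Mitochondrial aspartate transport reaction id per published model
#: (the reaction implicated in biomass overprediction at high
#: glucose:oxygen uptake ratios; annotated with ORF YPR021C where a gene
#: is assigned).  iFF708 and the Biomodels.db model have no separate
#: mitochondrial compartment and no such reaction.
ASPARTATE_TRANSPORT_IDS: dict[str, str] = {
    "iND750": "ASPt2M",
    "iIN800": "AGC1_2",
    "iMM904": "ASPt2m",
    "iMM904bs": "ASPt2m",
    "iAZ900": "ASSPt2M",
    "iTO977": "AGC1_2",
    "Yeast4": "r_1163",
    "Yeast5": "r_1117",
    "Yeast6": "r_1117",
    "Yeast7": "r_1117",
}


def resolve_aspartate_transport(model_id: str) -> str:
    """Reaction id of the mitochondrial aspartate transporter in a
    published model, resolved tolerantly (case/space/underscore)."""
    key = model_id.replace(" ", "").replace("_", "").lower()
    for name, rid in ASPARTATE_TRANSPORT_IDS.items():
        if name.replace(" ", "").lower() == key:
            return rid
    raise KeyError(
        f"no aspartate-transport id known for model {model_id!r}; "
        f"known models: {sorted(ASPARTATE_TRANSPORT_IDS)}"
    )


@dataclass
class GrowthObservation:
    """One measured condition: uptake constraints plus observed rate.

    ``uptake`` maps an exchange key (reaction id, metabolite id or ChEBI
    id) to the measured uptake magnitude in mmol/gDW/h; it is applied as
    a negative lower bound on the exchange.  ``growth_rate`` is in 1/h.
    """

    condition: str
    uptake: dict[str, float]
    growth_rate: float

    def __post_init__(self):
        for key, val in self.uptake.items():
            if val < 0:
                raise ValueError(
                    f"{self.condition}: uptake for {key!r} must be >= 0 "
                    "(applied as a negative lower bound)"
                )
        if self.growth_rate < 0:
            raise ValueError(f"{self.condition}: growth rate must be >= 0")


@dataclass
class ScanResult:
    model_id: str
    which: tuple[str, ...]
    conditions: list[str]
    predicted: list[float]
    observed: list[float]
    statuses: list[str]

    @property
    def any_unbounded(self) -> bool:
        return any(s == "unbounded" for s in self.statuses)

    def correlation(self, method: str = "pearson") -> float:
        """Correlation between predictions and observations.

        Aborts with a diagnostic if any scan point was unbounded —
        feeding an artificial large value into the correlation would
        manufacture agreement or disagreement out of a model pathology.
        """
        if self.any_unbounded:
            bad = [
                c for c, s in zip(self.conditions, self.statuses) if s == "unbounded"
            ]
            raise RuntimeError(
                f"model {self.model_id!r}: unbounded optimum at {bad}; "
                "fix or remove the loop before correlating"
            )
        if method == "pearson":
            return pearson_correlation(self.predicted, self.observed)
        if method == "spearman":
            return spearman_correlation(self.predicted, self.observed)
        raise ValueError(f"unknown correlation method {method!r}")


def constrained_growth_scan(
    model: MetabolicModel,
    observations: list[GrowthObservation],
    which: list[str] | None = None,
) -> ScanResult:
    """Predicted maximum biomass flux per observed condition.

    For each observation, the exchange reactions named by ``which``
    (default: every key the observation carries) get their lower bound
    clamped to −uptake; all other exchanges keep the model's current
    medium.  Unbounded and infeasible statuses are recorded per point.
    """
    conditions, predicted, observed, statuses = [], [], [], []
    for obs in observations:
        keys = which if which is not None else list(obs.uptake)
        scan_model = model.copy()
        for key in keys:
            if key not in obs.uptake:
                raise KeyError(
                    f"{obs.condition}: no measured uptake for {key!r}"
                )
            rid = resolve_exchange(scan_model, key)
            scan_model.reactions[rid].lower_bound = -obs.uptake[key]
        res = solve_fba(scan_model)
        conditions.append(obs.condition)
        predicted.append(res.objective_value if res.optimal else float("nan"))
        observed.append(obs.growth_rate)
        statuses.append(res.status)
        if res.status == "unbounded":
            logger.warning(
                "model %s unbounded at condition %s", model.model_id, obs.condition
            )
    return ScanResult(
        model_id=model.model_id,
        which=tuple(which) if which is not None else (),
        conditions=conditions,
        predicted=predicted,
        observed=observed,
        statuses=statuses,
    )


def pearson_correlation(predicted, observed) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Requires length >= 3 and nonzero variance on both sides; violating
    either is an error, never a silent zero.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape:
        raise ValueError("predicted and observed must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 points")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("correlation input contains NaN (failed scan point?)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")
    return float(stats.pearsonr(x, y).statistic)


def spearman_correlation(predicted, observed) -> float:
    """Spearman rank correlation (alternative to Pearson, behind a flag)."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size < 3:
        raise ValueError("correlation requires at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")
    return float(stats.spearmanr(x, y).statistic)


def diagnose_high_flux_reactions(
    model: MetabolicModel,
) -> list[tuple[str, float]]:
    """Internal reactions ranked by |flux| in a one-norm-minimised FBA
    solution (exchanges excluded; ties broken by reaction id).

    Unrealistically large entries at the top of this ranking are the
    signature of a loop that inflates the biomass optimum.
    """
    res = solve_fba_l1min(model)
    if not res.optimal:
        raise RuntimeError(
            f"model {model.model_id!r}: l1-min FBA returned {res.status}"
        )
    internal = [
        (rid, abs(flux))
        for rid, flux in res.fluxes.items()
        if not model.reactions[rid].is_exchange
    ]
    return sorted(internal, key=lambda t: (-t[1], t[0]))


@dataclass
class RemovalComparison:
    reaction_id: str
    before: ScanResult
    after: ScanResult
    correlation_before: float | None = None
    correlation_after: float | None = None


def remove_reaction_and_rescan(
    model: MetabolicModel,
    reaction_id: str,
    observations: list[GrowthObservation],
    which: list[str] | None = None,
) -> RemovalComparison:
    """Close one reaction (bounds 0,0) and repeat the growth scan.

    Returns before/after predictions and, where both scans are clean,
    before/after Pearson correlations.  Unknown reaction ids raise with
    the closest near-matches listed.
    """
    if reaction_id not in model.reactions:
        near = difflib.get_close_matches(reaction_id, model.reactions, n=5)
        raise KeyError(
            f"reaction {reaction_id!r} not in model {model.model_id!r}; "
            f"near matches: {near}"
        )
    before = constrained_growth_scan(model, observations, which)
    removed = model.copy()
    removed.reactions[reaction_id].lower_bound = 0.0
    removed.reactions[reaction_id].upper_bound = 0.0
    after = constrained_growth_scan(removed, observations, which)
    out = RemovalComparison(reaction_id=reaction_id, before=before, after=after)
    try:
        out.correlation_before = before.correlation()
        out.correlation_after = after.correlation()
    except (RuntimeError, ValueError) as exc:
        logger.warning("correlation unavailable: %s", exc)
    return out
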