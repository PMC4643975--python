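"""Toy metabolic models with constructively planted ground truth.

Every pipeline stage — FBA, deletion screens, blocked/dead-end scans,
scoring — needs inputs whose correct answers are known *without*
running the pipeline.  The generator builds small stoichiometric
networks whose truth is wired into the topology at construction time,
never computed by the LP machinery under test:

* ``n_linear_pathways`` chains of length ``pathway_length`` each feed a
  required biomass precursor, so every chain step is essential unless
  explicitly made redundant.
* A **complex** step carries an AND rule over two genes: both genes are
  planted essential.
* An **isozyme** step carries an OR rule over two genes: neither gene
  is individually essential, and the pair is a planted synthetic-lethal
  interaction.
* A **bypassed** step gains a duplicate reaction with no gene rule, so
  its single gene is planted non-essential (a dispensable route).
* Dead-end and blocked constructs hang off pathway sources,
  disconnected from biomass: a dead-end unit ``M -> D`` plants a
  dead-end metabolite D and one blocked reaction; a blocked unit
  ``M -> Z -> W`` plants two blocked reactions whose inner metabolite Z
  is *not* a dead end (W, at the tip, is).

Generation is a pure function of the spec (all randomness flows through
one seeded generator), so the same spec yields byte-identical files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .gpr import GeneAssociation
from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyModelSpec",
    "ToyModelTruth",
    "generate_toy_model",
    "generate_reference_lists",
    "generate_growth_observations",
    "expected_noisy_reference_mcc",
]

#: Default uptake bound on the carbon-source exchanges of generated toys.
TOY_UPTAKE = 10.0


@dataclass(frozen=True)
class ToyModelSpec:
    """Size knobs for one generated toy model.

    Defaults give ~60 genes and ~60 reactions: large enough that screens
    exercise every rule type, small enough that a full double-deletion
    screen finishes in seconds.
    """

    n_linear_pathways: int = 6
    pathway_length: int = 8
    n_isozyme_pairs: int = 6
    n_complexes: int = 4
    n_parallel_routes: int = 4
    n_dead_ends: int = 2
    n_blocked: int = 2
    n_compartments: int = 1
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_linear_pathways,
            self.pathway_length,
            self.n_isozyme_pairs,
            self.n_complexes,
            self.n_parallel_routes,
            self.n_dead_ends,
            self.n_blocked,
            self.n_compartments,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all spec counts must be >= 0")
        if self.n_linear_pathways > 0 and self.pathway_length < 1:
            raise ValueError("pathway_length must be >= 1 when pathways exist")
        special = self.n_isozyme_pairs + self.n_complexes + self.n_parallel_routes
        if special > self.n_steps:
            raise ValueError(
                f"{special} special steps requested but only "
                f"{self.n_steps} pathway steps exist"
            )
        if (self.n_dead_ends or self.n_blocked) and self.n_linear_pathways == 0:
            raise ValueError("dead-end/blocked constructs need a pathway to hang off")

    @property
    def n_steps(self) -> int:
        return self.n_linear_pathways * self.pathway_length


@dataclass
class ToyModelTruth:
    """Ground truth derived constructively during generation."""

    genes: frozenset[str]
    essential_genes: frozenset[str]
    synthetic_lethal_pairs: frozenset[tuple[str, str]]
    dead_end_metabolites: frozenset[str]
    blocked_reactions: frozenset[str]


def generate_toy_model(spec: ToyModelSpec) -> tuple[MetabolicModel, ToyModelTruth]:
    """Build a toy model and its planted truth; deterministic per spec."""
    rng = np.random.default_rng(spec.seed)
    metabolites: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}
    genes: set[str] = set()
    essential: set[str] = set()
    sl_pairs: set[tuple[str, str]] = set()
    dead_ends: set[str] = set()
    blocked: set[str] = set()

    def compartment(i: int) -> str:
        return f"c{i % max(spec.n_compartments, 1)}"

    # classify pathway steps: shuffle (pathway, step) slots, then carve
    # off complexes, isozyme pairs and bypassed steps
    slots = [
        (i, j)
        for i in range(spec.n_linear_pathways)
        for j in range(spec.pathway_length)
    ]
    order = rng.permutation(len(slots))
    shuffled = [slots[k] for k in order]
    complex_steps = set(shuffled[: spec.n_complexes])
    isozyme_steps = set(
        shuffled[spec.n_complexes : spec.n_complexes + spec.n_isozyme_pairs]
    )
    bypass_steps = set(
        shuffled[
            spec.n_complexes
            + spec.n_isozyme_pairs : spec.n_complexes
            + spec.n_isozyme_pairs
            + spec.n_parallel_routes
        ]
    )

    def leaf(g: str) -> GeneAssociation:
        return GeneAssociation("gene", gene=g)

    terminal_mets: list[str] = []
    for i in range(spec.n_linear_pathways):
        comp = compartment(i)
        chain = [f"p{i}m{j}" for j in range(spec.pathway_length + 1)]
        for met_id in chain:
            metabolites[met_id] = Metabolite(
                id=met_id,
                name=met_id,
                compartment=comp,
                chebi_ids=(f"CHEBI:9{i:02d}{chain.index(met_id):02d}",),
            )
        terminal_mets.append(chain[-1])
        reactions[f"EX_p{i}"] = Reaction(
            id=f"EX_p{i}",
            name=f"exchange of {chain[0]}",
            stoichiometry={chain[0]: -1.0},
            lower_bound=-TOY_UPTAKE,
            upper_bound=DEFAULT_BOUND,
        )
        for j in range(spec.pathway_length):
            rid = f"R_p{i}s{j}"
            stoich = {chain[j]: -1.0, chain[j + 1]: 1.0}
            if (i, j) in complex_steps:
                ga, gb = f"g_p{i}s{j}a", f"g_p{i}s{j}b"
                gpr = GeneAssociation("and", children=(leaf(ga), leaf(gb)))
                genes |= {ga, gb}
                essential |= {ga, gb}
            elif (i, j) in isozyme_steps:
                ga, gb = f"g_p{i}s{j}a", f"g_p{i}s{j}b"
                gpr = GeneAssociation("or", children=(leaf(ga), leaf(gb)))
                genes |= {ga, gb}
                sl_pairs.add(tuple(sorted((ga, gb))))
            else:
                g = f"g_p{i}s{j}"
                gpr = leaf(g)
                genes.add(g)
                if (i, j) in bypass_steps:
                    reactions[f"{rid}_alt"] = Reaction(
                        id=f"{rid}_alt",
                        name=f"gene-free duplicate of {rid}",
                        stoichiometry=dict(stoich),
                        lower_bound=0.0,
                        upper_bound=DEFAULT_BOUND,
                    )
                else:
                    essential.add(g)
            reactions[rid] = Reaction(
                id=rid,
                name=rid,
                stoichiometry=stoich,
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                gpr=gpr,
            )

    if spec.n_linear_pathways > 0:
        reactions["biomass"] = Reaction(
            id="biomass",
            name="biomass assembly",
            stoichiometry={t: -1.0 for t in terminal_mets},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )

    # dead-end units: source -> D (blocked producer, dead-end tip)
    for k in range(spec.n_dead_ends):
        anchor = f"p{k % spec.n_linear_pathways}m0"
        d = f"dead{k}"
        metabolites[d] = Metabolite(
            id=d, name=d, compartment=compartment(k)
        )
        rid = f"R_dead{k}"
        reactions[rid] = Reaction(
            id=rid,
            name=f"producer of dead-end {d}",
            stoichiometry={anchor: -1.0, d: 1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        dead_ends.add(d)
        blocked.add(rid)

    # blocked units: source -> Z -> W; both reactions blocked, Z is not a
    # dead end (produced by one, consumed by the other), W is
    for k in range(spec.n_blocked):
        anchor = f"p{k % spec.n_linear_pathways}m0"
        z, w = f"blkmid{k}", f"blktip{k}"
        for met_id in (z, w):
            metabolites[met_id] = Metabolite(
                id=met_id, name=met_id, compartment=compartment(k)
            )
        ra, rb = f"R_blk{k}a", f"R_blk{k}b"
        reactions[ra] = Reaction(
            id=ra,
            name=f"blocked chain {k} entry",
            stoichiometry={anchor: -1.0, z: 1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        reactions[rb] = Reaction(
            id=rb,
            name=f"blocked chain {k} tip",
            stoichiometry={z: -1.0, w: 1.0},
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
        )
        dead_ends.add(w)
        blocked |= {ra, rb}

    model = MetabolicModel(
        model_id=f"toy_seed{spec.seed}",
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        objective_reaction_id="biomass" if spec.n_linear_pathways > 0 else None,
    )
    truth = ToyModelTruth(
        genes=frozenset(genes),
        essential_genes=frozenset(essential),
        synthetic_lethal_pairs=frozenset(sl_pairs),
        dead_end_metabolites=frozenset(dead_ends),
        blocked_reactions=frozenset(blocked),
    )
    return model, truth


def generate_reference_lists(
    truth: ToyModelTruth,
    flip_rate: float = 0.0,
    seed: int = 0,
    include_pairs: bool = True,
) -> tuple[set[str], set[tuple[str, str]]]:
    """Noisy reference lists emulating imperfect experimental annotation.

    Every gene's essential/viable label, and (optionally) every
    unordered gene pair's synthetic-lethal label, is independently
    flipped with probability ``flip_rate``.  At rate 0 the lists equal
    the truth; the expected MCC of a perfect predictor scored against
    the noisy list is :func:`expected_noisy_reference_mcc`.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    essential_list: set[str] = set()
    for gene in sorted(truth.genes):
        label = gene in truth.essential_genes
        if flip_rate > 0 and rng.random() < flip_rate:
            label = not label
        if label:
            essential_list.add(gene)
    pair_list: set[tuple[str, str]] = set()
    if include_pairs:
        for pair in itertools.combinations(sorted(truth.genes), 2):
            label = pair in truth.synthetic_lethal_pairs
            if flip_rate > 0 and rng.random() < flip_rate:
                label = not label
            if label:
                pair_list.add(pair)
    return essential_list, pair_list


def expected_noisy_reference_mcc(
    n_viable: int, n_essential: int, flip_rate: float
) -> float:
    """Closed-form MCC of a perfect predictor vs. a label-flipped list.

    With each reference label independently flipped at rate p, the
    expected confusion counts of a predictor that knows the truth are
    TP = n_v(1-p), FP = n_v p, TN = n_e(1-p), FN = n_e p (positive =
    viable).  Substituting the expectations into the MCC formula gives

        n_v n_e (1-2p) / sqrt(n_v n_e (n_v(1-p)+n_e p)(n_e(1-p)+n_v p))

    which decreases monotonically in p and reaches 0 at p = 1/2.  For a
    balanced truth (n_v = n_e) it reduces to 1 - 2p.
    """
    p = flip_rate
    nv, ne = float(n_viable), float(n_essential)
    if nv == 0 or ne == 0:
        return 0.0
    num = nv * ne * (1.0 - 2.0 * p)
    den = np.sqrt(nv * ne * (nv * (1 - p) + ne * p) * (ne * (1 - p) + nv * p))
    return float(num / den)


def generate_growth_observations(
    model: MetabolicModel,
    constraint_grid: list[dict[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list:
    """Emulate a chemostat uptake/growth table for a model.

    For each grid point (a map of exchange keys to uptake magnitudes)
    the observed growth rate is the FBA optimum under those constraints
    scaled by a Gaussian factor N(1, noise_sd) truncated at zero.
    """
    from .growth import GrowthObservation
    from .lp import solve_fba
    from .media import resolve_exchange

    rng = np.random.default_rng(seed)
    observations = []
    for idx, uptake in enumerate(constraint_grid):
        scan_model = model.copy()
        for key, val in uptake.items():
            rid = resolve_exchange(scan_model, key)
            scan_model.reactions[rid].lower_bound = -val
        res = solve_fba(scan_model)
        if not res.optimal:
            raise RuntimeError(
                f"grid point {idx} is {res.status}; the observation grid "
                "must keep the model feasible"
            )
        factor = 1.0 + noise_sd * rng.standard_normal() if noise_sd > 0 else 1.0
        observations.append(
            GrowthObservation(
                condition=f"grid{idx}",
                uptake=dict(uptake),
                growth_rate=max(0.0, res.objective_value * factor),
            )
        )
    return observations
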