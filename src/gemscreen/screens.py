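"""Single- and double-gene deletion screens.

A single screen deletes each gene in turn, disables the reactions whose
GPR rule evaluates False, and records the maximum attainable biomass
flux of the mutant.  A gene is predicted **essential** when that flux
falls below the essentiality threshold (default 1e-6 flux units);
infeasible mutant LPs score as zero flux, hence essential.

A double screen evaluates every unordered gene pair under the model's
own default medium and biomass (pairwise interactions are screened on
the models as distributed).  A pair of individually dispensable genes
is predicted **synthetic lethal** when the double-mutant flux is at or
below 10% of the wild-type flux (the boundary is assigned to lethal;
"non-lethal" means strictly greater than 10%).

Double screens are quadratic in gene count, so results stream to disk
as TSV with a provenance header and can be checkpoint-resumed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .gpr import apply_deletions
from .lp import solve_fba
from .model import MetabolicModel
from .scoring import ConfusionMatrix

__all__ = [
    "ScreenConfig",
    "GeneRecord",
    "SingleScreenResult",
    "PairRecord",
    "DoubleScreenResult",
    "single_deletion_screen",
    "double_deletion_screen",
    "classify_synthetic_lethality",
]

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Decision thresholds for the deletion screens."""

    #: Mutant biomass flux below this is scored essential / lethal.
    essentiality_threshold: float = 1e-6
    #: Double-mutant flux at or below this fraction of wild type is
    #: scored synthetic lethal.
    sl_wildtype_fraction: float = 0.10

    def __post_init__(self):
        if self.essentiality_threshold <= 0:
            raise ValueError("essentiality_threshold must be > 0")
        if not 0 < self.sl_wildtype_fraction < 1:
            raise ValueError("sl_wildtype_fraction must be in (0, 1)")


@dataclass
class GeneRecord:
    gene: str
    max_biomass_flux: float | None  # None when the gene is not in the model
    essential: bool | None
    in_model: bool = True


@dataclass
class SingleScreenResult:
    model_id: str
    medium_name: str
    biomass_name: str
    wild_type_flux: float
    records: list[GeneRecord]
    config: ScreenConfig = field(default_factory=ScreenConfig)

    @property
    def essential_genes(self) -> set[str]:
        return {r.gene for r in self.records if r.in_model and r.essential}

    def flux_of(self, gene: str) -> float | None:
        for r in self.records:
            if r.gene == gene:
                return r.max_biomass_flux
        return None

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"# model\t{self.model_id}",
            f"# medium\t{self.medium_name}",
            f"# biomass\t{self.biomass_name}",
            f"# wild_type_flux\t{self.wild_type_flux!r}",
            f"# essentiality_threshold\t{self.config.essentiality_threshold!r}",
            "gene\tmax_biomass_flux\tessential\tin_model",
        ]
        for r in self.records:
            lines.append(
                "\t".join(
                    [
                        r.gene,
                        "" if r.max_biomass_flux is None else repr(r.max_biomass_flux),
                        "" if r.essential is None else ("1" if r.essential else "0"),
                        "1" if r.in_model else "0",
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class PairRecord:
    gene_a: str  # lexicographically smaller
    gene_b: str
    pair_flux: float


@dataclass
class DoubleScreenResult:
    model_id: str
    wild_type_flux: float
    pairs: list[PairRecord]
    singles: SingleScreenResult | None = None
    config: ScreenConfig = field(default_factory=ScreenConfig)

    def pair_flux_map(self) -> dict[tuple[str, str], float]:
        return {(p.gene_a, p.gene_b): p.pair_flux for p in self.pairs}

    @property
    def synthetic_lethal_pairs(self) -> set[tuple[str, str]]:
        """Pairs meeting the strict definition: neither gene individually
        essential, pair flux <= fraction * wild type."""
        if self.singles is None:
            raise ValueError("singles screen required to gate on single essentiality")
        essential = self.singles.essential_genes
        cutoff = self.config.sl_wildtype_fraction * self.wild_type_flux
        return {
            (p.gene_a, p.gene_b)
            for p in self.pairs
            if p.gene_a not in essential
            and p.gene_b not in essential
            and p.pair_flux <= cutoff
        }


def single_deletion_screen(
    model: MetabolicModel,
    medium=None,
    biomass=None,
    gene_universe: set[str] | None = None,
    config: ScreenConfig | None = None,
) -> SingleScreenResult:
    """Screen every gene of ``gene_universe`` for predicted essentiality.

    ``medium`` / ``biomass`` definitions, when given, are applied before
    the screen (order is immaterial; the two standardizations commute).
    ``gene_universe`` defaults to the model's genes; genes outside the
    model are recorded with ``in_model=False`` and no flux, and scored
    downstream according to the reference-list semantics.

    Raises RuntimeError when the wild type itself does not grow — an
    essentiality screen against a non-growing model is meaningless.
    """
    config = config or ScreenConfig()
    medium_name = "default"
    biomass_name = "default"
    if medium is not None:
        from .media import apply_medium

        model = apply_medium(model, medium)
        medium_name = medium.name
    if biomass is not None:
        from .media import set_biomass

        model = set_biomass(model, biomass)
        biomass_name = biomass.name

    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value < config.essentiality_threshold:
        raise RuntimeError(
            f"model {model.model_id!r} does not grow in medium "
            f"{medium_name!r} (status {wt.status}); screen is meaningless"
        )
    universe = set(gene_universe) if gene_universe is not None else set(model.genes)

    records: list[GeneRecord] = []
    for gene in sorted(universe):
        if gene not in model.genes:
            records.append(GeneRecord(gene, None, None, in_model=False))
            continue
        mutant = apply_deletions(model, {gene}, warn_unknown=False)
        flux = solve_fba(mutant).growth()
        records.append(
            GeneRecord(
                gene=gene,
                max_biomass_flux=flux,
                essential=flux < config.essentiality_threshold,
            )
        )
    return SingleScreenResult(
        model_id=model.model_id,
        medium_name=medium_name,
        biomass_name=biomass_name,
        wild_type_flux=wt.objective_value,
        records=records,
        config=config,
    )


def _write_pair_header(fh, model_id: str, wt_flux: float, config: ScreenConfig):
    fh.write(f"# model\t{model_id}\n")
    fh.write(f"# wild_type_flux\t{wt_flux!r}\n")
    fh.write(f"# sl_wildtype_fraction\t{config.sl_wildtype_fraction!r}\n")
    fh.write("gene_a\tgene_b\tpair_flux\n")


def double_deletion_screen(
    model: MetabolicModel,
    config: ScreenConfig | None = None,
    genes: set[str] | None = None,
    skip_neutral: bool = True,
    checkpoint: str | Path | None = None,
) -> DoubleScreenResult:
    """FBA flux of every unordered double mutant.

    Runs on the model as given — by design no medium or biomass
    standardization is applied here, matching how pairwise screens are
    benchmarked on models as distributed.  Pairs are enumerated once
    with ``gene_a < gene_b`` lexicographically.

    ``skip_neutral``: pairs where neither gene's deletion disables any
    reaction provably leave the network untouched and may reuse the
    wild-type flux without solving an LP.  The no-skip path exists for
    verification and gives identical fluxes.

    ``checkpoint``: path of a TSV streamed as pairs complete; if the file
    already holds rows for this model they are reused and the screen
    resumes after the last finished pair.
    """
    config = config or ScreenConfig()
    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value < config.essentiality_threshold:
        raise RuntimeError(
            f"model {model.model_id!r} does not grow with its default "
            f"medium/biomass (status {wt.status}); double screen is meaningless"
        )
    gene_list = sorted(genes if genes is not None else model.genes)
    # Genes mentioned by at least one GPR.  Only pairs where NEITHER gene
    # appears in any rule are provably neutral (joint deletion of two
    # rule-mentioned genes can disable a reaction even when each solo
    # deletion disables none — isozyme pairs are exactly that case).
    in_some_gpr: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.gpr is not None:
            in_some_gpr |= rxn.gpr.genes()

    done: dict[tuple[str, str], float] = {}
    fh = None
    if checkpoint is not None:
        checkpoint = Path(checkpoint)
        if checkpoint.exists():
            for line in checkpoint.read_text().splitlines():
                if line.startswith("#") or line.startswith("gene_a"):
                    continue
                a, b, flux = line.split("\t")
                done[(a, b)] = float(flux)
            fh = checkpoint.open("a")
        else:
            fh = checkpoint.open("w")
            _write_pair_header(fh, model.model_id, wt.objective_value, config)

    pairs: list[PairRecord] = []
    try:
        for a, b in itertools.combinations(gene_list, 2):
            if (a, b) in done:
                pairs.append(PairRecord(a, b, done[(a, b)]))
                continue
            neutral = a not in in_some_gpr and b not in in_some_gpr
            if skip_neutral and neutral:
                flux = wt.objective_value
            else:
                mutant = apply_deletions(model, {a, b}, warn_unknown=False)
                flux = solve_fba(mutant).growth()
            pairs.append(PairRecord(a, b, flux))
            if fh is not None:
                fh.write(f"{a}\t{b}\t{flux!r}\n")
    finally:
        if fh is not None:
            fh.close()
    return DoubleScreenResult(
        model_id=model.model_id,
        wild_type_flux=wt.objective_value,
        pairs=pairs,
        config=config,
    )


def classify_synthetic_lethality(
    singles: SingleScreenResult,
    doubles: DoubleScreenResult,
    reference_pairs: set[tuple[str, str]],
    config: ScreenConfig | None = None,
    labels: dict[str, str] | None = None,
) -> ConfusionMatrix:
    """Score a double screen against a reference synthetic-lethal list.

    Only pairs in which NEITHER gene is predicted individually essential
    enter the four MCC counts; a reference pair that fails that gate is
    an "other error" (the screen already mispredicted one of its genes as
    essential) and is excluded from the MCC.  Reference pairs naming a
    gene absent from the model are counted ``out_of_scope``.

    Predicted lethal means pair flux <= sl_wildtype_fraction x wild type.
    """
    config = config or doubles.config
    reference = {tuple(sorted(p)) for p in reference_pairs}
    essential = singles.essential_genes
    model_genes = {r.gene for r in singles.records if r.in_model}
    cutoff = config.sl_wildtype_fraction * doubles.wild_type_flux

    cm = ConfusionMatrix(labels=labels or {"model": doubles.model_id})
    for ref_pair in reference:
        if not set(ref_pair) <= model_genes:
            cm.out_of_scope += 1
    for rec in doubles.pairs:
        pair = (rec.gene_a, rec.gene_b)
        in_ref = pair in reference
        if rec.gene_a in essential or rec.gene_b in essential:
            if in_ref:
                cm.other_errors += 1
            continue
        predicted_lethal = rec.pair_flux <= cutoff
        if predicted_lethal and in_ref:
            cm.TP += 1
        elif predicted_lethal and not in_ref:
            cm.FP += 1
        elif not predicted_lethal and in_ref:
            cm.FN += 1
        else:
            cm.TN += 1
    return cm
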