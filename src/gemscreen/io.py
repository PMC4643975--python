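"""Model readers and writers.

Two formats are supported:

* **SBML** (Level 2 with COBRA-style kinetic-law bound parameters and
  notes-based gene associations, or Level 3 with the FBC extension),
  read through libSBML.  Boundary species are recognised by the SBML
  ``boundaryCondition`` attribute or by the COBRA ``_b`` id suffix,
  whichever the file uses.
* A **flat TSV dialect** with ``[metabolites]``, ``[reactions]``,
  ``[gpr]``, ``[objective]`` (and optional ``[genes]``) sections, so
  that toy models need no SBML tooling.  Documented in the README.

Both formats round-trip: ``read(write(m)) == m`` field-exact.
"""

from __future__ import annotations

import logging
from pathlib import Path

import libsbml

from .gpr import GeneAssociation, parse_gpr
from .model import BOUNDARY_SUFFIX, DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction

__all__ = [
    "read_model",
    "write_model",
    "read_flat_model",
    "write_flat_model",
    "read_sbml",
    "write_sbml",
    "ModelFormatError",
]

logger = logging.getLogger(__name__)


class ModelFormatError(ValueError):
    """Unreadable or internally inconsistent model file."""


# ---------------------------------------------------------------------------
# flat TSV dialect
# ---------------------------------------------------------------------------

_MET_COLUMNS = ["id", "name", "compartment", "chebi_ids", "is_boundary"]
_RXN_COLUMNS = ["id", "name", "stoichiometry", "lower_bound", "upper_bound"]


def _fmt_stoich(stoich: dict[str, float]) -> str:
    return ";".join(f"{m}:{v!r}" for m, v in stoich.items())


def _parse_stoich(text: str, rxn_id: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in filter(None, text.split(";")):
        met, _, coeff = part.rpartition(":")
        if not met:
            raise ModelFormatError(
                f"reaction {rxn_id!r}: malformed stoichiometry term {part!r}"
            )
        if met in out:
            raise ModelFormatError(
                f"reaction {rxn_id!r}: duplicate metabolite {met!r} in stoichiometry"
            )
        out[met] = float(coeff)
    return out


def write_flat_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the flat TSV dialect (bijective with the in-memory model)."""
    lines: list[str] = [f"model_id\t{model.model_id}", ""]
    lines.append("[metabolites]")
    lines.append("\t".join(_MET_COLUMNS))
    for m in model.metabolites.values():
        lines.append(
            "\t".join(
                [
                    m.id,
                    m.name,
                    m.compartment,
                    ";".join(m.chebi_ids),
                    "1" if m.is_boundary else "0",
                ]
            )
        )
    lines.append("")
    lines.append("[reactions]")
    lines.append("\t".join(_RXN_COLUMNS))
    for r in model.reactions.values():
        lines.append(
            "\t".join(
                [
                    r.id,
                    r.name,
                    _fmt_stoich(r.stoichiometry),
                    repr(r.lower_bound),
                    repr(r.upper_bound),
                ]
            )
        )
    lines.append("")
    lines.append("[gpr]")
    for r in model.reactions.values():
        if r.gpr is not None:
            lines.append(f"{r.id}\t{r.gpr.to_string()}")
    lines.append("")
    lines.append("[genes]")
    for g in sorted(model.genes):
        lines.append(g)
    lines.append("")
    lines.append("[objective]")
    if model.objective_reaction_id is not None:
        lines.append(model.objective_reaction_id)
    Path(path).write_text("\n".join(lines) + "\n")


def read_flat_model(path: str | Path) -> MetabolicModel:
    """Read the flat TSV dialect; hard error on duplicates or dangling refs."""
    text = Path(path).read_text()
    model_id = None
    section = None
    header: list[str] | None = None
    metabolites: dict[str, Metabolite] = {}
    reactions: dict[str, Reaction] = {}
    gprs: dict[str, GeneAssociation] = {}
    genes: set[str] = set()
    objective: str | None = None
    saw_objective_section = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            header = None
            if section == "objective":
                saw_objective_section = True
            continue
        fields = line.split("\t")
        if section is None:
            if fields[0] == "model_id" and len(fields) == 2:
                model_id = fields[1]
                continue
            raise ModelFormatError(f"line {lineno}: content outside any section")
        if section == "metabolites":
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            mid = row["id"]
            if mid in metabolites:
                raise ModelFormatError(f"duplicate metabolite id {mid!r}")
            metabolites[mid] = Metabolite(
                id=mid,
                name=row.get("name", ""),
                compartment=row.get("compartment", ""),
                chebi_ids=tuple(filter(None, row.get("chebi_ids", "").split(";"))),
                is_boundary=row.get("is_boundary", "0") == "1",
            )
        elif section == "reactions":
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            rid = row["id"]
            if rid in reactions:
                raise ModelFormatError(f"duplicate reaction id {rid!r}")
            reactions[rid] = Reaction(
                id=rid,
                name=row.get("name", ""),
                stoichiometry=_parse_stoich(row["stoichiometry"], rid),
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
            )
        elif section == "gpr":
            rid, _, rule = line.partition("\t")
            if rid not in reactions:
                raise ModelFormatError(f"[gpr] references unknown reaction {rid!r}")
            gprs[rid] = parse_gpr(rule)
        elif section == "genes":
            genes.add(fields[0])
        elif section == "objective":
            if objective is not None:
                raise ModelFormatError("multiple objective reactions listed")
            objective = fields[0]
        else:
            raise ModelFormatError(f"unknown section [{section}]")

    if not saw_objective_section or objective is None:
        raise ModelFormatError("no objective")
    if objective not in reactions:
        raise ModelFormatError(f"objective reaction {objective!r} not defined")
    for rid, assoc in gprs.items():
        reactions[rid].gpr = assoc
        genes |= assoc.genes()
    try:
        return MetabolicModel(
            model_id=model_id or Path(path).stem,
            metabolites=metabolites,
            reactions=reactions,
            genes=genes,
            objective_reaction_id=objective,
        )
    except ValueError as exc:  # dangling references etc.
        raise ModelFormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

_CHEBI_MARKERS = ("chebi/", "chebi:", "CHEBI:")


def _chebi_from_annotation(sbase) -> tuple[str, ...]:
    """ChEBI tokens from CV-term resource URIs, in file order."""
    out: list[str] = []
    for i in range(sbase.getNumCVTerms()):
        term = sbase.getCVTerm(i)
        for j in range(term.getNumResources()):
            uri = term.getResourceURI(j)
            if "chebi" in uri.lower():
                token = uri.rsplit("/", 1)[-1]
                if not token.upper().startswith("CHEBI"):
                    token = f"CHEBI:{token}"
                if token not in out:
                    out.append(token)
    return tuple(out)


def _gpr_from_fbc_association(assoc, fbc_model) -> GeneAssociation | None:
    """Recursively convert an FBC association object to our tree."""
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        gp = fbc_model.getGeneProduct(assoc.getGeneProduct())
        label = gp.getLabel() if gp is not None and gp.isSetLabel() else None
        return GeneAssociation("gene", gene=label or assoc.getGeneProduct())
    children = tuple(
        _gpr_from_fbc_association(assoc.getAssociation(i), fbc_model)
        for i in range(assoc.getNumAssociations())
    )
    if len(children) == 1:
        return children[0]
    op = "and" if assoc.isFbcAnd() else "or"
    return GeneAssociation(op, children=children)


def _gpr_from_notes(reaction) -> GeneAssociation | None:
    """COBRA L2 convention: 'GENE_ASSOCIATION: ...' inside the notes."""
    if not reaction.isSetNotes():
        return None
    notes = reaction.getNotesString()
    for line in notes.splitlines():
        text = line.strip()
        for tag in ("GENE_ASSOCIATION:", "GENE ASSOCIATION:"):
            if tag in text:
                rule = text.split(tag, 1)[1]
                for junk in ("</p>", "</body>", "</html>", "</notes>"):
                    rule = rule.replace(junk, "")
                rule = rule.strip()
                if rule:
                    return parse_gpr(rule)
    return None


def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML model (L2 kinetic-law bounds or L3 FBC).

    Boundary species are flagged via the ``boundaryCondition`` attribute
    or the ``_b`` id-suffix convention, whichever the file carries.
    Missing bounds default to (−1000, 1000) for reversible reactions and
    (0, 1000) otherwise, and the default is logged per reaction.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"unparsable SBML {path}: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    smodel = doc.getModel()
    if smodel is None:
        raise ModelFormatError(f"unparsable SBML {path}: no <model> element")
    fbc = smodel.getPlugin("fbc")

    metabolites: dict[str, Metabolite] = {}
    for sp in smodel.getListOfSpecies():
        sid = sp.getId()
        metabolites[sid] = Metabolite(
            id=sid,
            name=sp.getName() or "",
            compartment=sp.getCompartment() or "",
            chebi_ids=_chebi_from_annotation(sp),
            is_boundary=bool(sp.getBoundaryCondition())
            or sid.endswith(BOUNDARY_SUFFIX),
        )

    # FBC global parameters hold L3 bounds
    def _param_value(pid: str) -> float | None:
        p = smodel.getParameter(pid)
        return p.getValue() if p is not None else None

    reactions: dict[str, Reaction] = {}
    genes: set[str] = set()
    objective: str | None = None

    if fbc is not None and fbc.getNumObjectives() > 0:
        active = fbc.getActiveObjective() or fbc.getObjective(0)
        if active.getNumFluxObjectives() > 0:
            objective = active.getFluxObjective(0).getReaction()

    for srxn in smodel.getListOfReactions():
        rid = srxn.getId()
        stoich: dict[str, float] = {}
        for i in range(srxn.getNumReactants()):
            ref = srxn.getReactant(i)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (
                ref.getStoichiometry() or 1.0
            )
        for i in range(srxn.getNumProducts()):
            ref = srxn.getProduct(i)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (
                ref.getStoichiometry() or 1.0
            )

        lb = ub = None
        rplug = srxn.getPlugin("fbc")
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = _param_value(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = _param_value(rplug.getUpperFluxBound())
        klaw = srxn.getKineticLaw()
        if klaw is not None:
            for pname, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                p = klaw.getParameter(pname)
                if p is not None:
                    if setter == "lb":
                        lb = p.getValue()
                    else:
                        ub = p.getValue()
            pobj = klaw.getParameter("OBJECTIVE_COEFFICIENT")
            if pobj is not None and pobj.getValue() != 0 and objective is None:
                objective = rid
        if lb is None or ub is None:
            reversible = srxn.getReversible()
            lb = -DEFAULT_BOUND if (lb is None and reversible) else (lb or 0.0)
            ub = DEFAULT_BOUND if ub is None else ub
            logger.info(
                "reaction %s: missing bounds, defaulted to (%g, %g)", rid, lb, ub
            )

        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _gpr_from_fbc_association(
                rplug.getGeneProductAssociation().getAssociation(), fbc
            )
        if gpr is None:
            gpr = _gpr_from_notes(srxn)
        if gpr is not None:
            genes |= gpr.genes()

        reactions[rid] = Reaction(
            id=rid,
            name=srxn.getName() or "",
            stoichiometry=stoich,
            lower_bound=float(lb),
            upper_bound=float(ub),
            gpr=gpr,
        )

    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            genes.add(gp.getLabel() if gp.isSetLabel() else gp.getId())

    try:
        return MetabolicModel(
            model_id=smodel.getId() or Path(path).stem,
            metabolites=metabolites,
            reactions=reactions,
            genes=genes,
            objective_reaction_id=objective,
        )
    except ValueError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc


def _sid(raw: str) -> str:
    """Sanitize an identifier into an SBML SId."""
    out = "".join(c if (c.isalnum() or c == "_") else "_" for c in raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "x_" + out
    return out


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write SBML Level 3 Version 1 with the FBC v2 extension."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    smodel = doc.createModel()
    smodel.setId(_sid(model.model_id))
    smodel.setName(model.model_id)
    fbc = smodel.getPlugin("fbc")
    fbc.setStrict(True)

    compartments = {m.compartment or "default" for m in model.metabolites.values()}
    for comp in sorted(compartments):
        c = smodel.createCompartment()
        c.setId(_sid(comp))
        c.setName(comp)
        c.setConstant(True)

    for n, met in enumerate(model.metabolites.values()):
        sp = smodel.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(_sid(met.compartment or "default"))
        sp.setBoundaryCondition(met.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        if met.chebi_ids:
            sp.setMetaId(f"meta_{_sid(met.id)}_{n}")
            for token in met.chebi_ids:
                cv = libsbml.CVTerm()
                cv.setQualifierType(libsbml.BIOLOGICAL_QUALIFIER)
                cv.setBiologicalQualifierType(libsbml.BQB_IS)
                cv.addResource(
                    "http://identifiers.org/chebi/" + token.replace("chebi:", "CHEBI:")
                )
                sp.addCVTerm(cv)

    gene_ids: dict[str, str] = {}
    for g in sorted(model.genes):
        gp = fbc.createGeneProduct()
        gid = "G_" + _sid(g)
        gp.setId(gid)
        gp.setLabel(g)
        gene_ids[g] = gid

    def _bound_param(pid: str, value: float) -> str:
        existing = smodel.getParameter(pid)
        if existing is None:
            p = smodel.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
        return pid

    def _assoc_to_fbc(node: GeneAssociation, parent) -> None:
        if node.op == "gene":
            ref = parent.createGeneProductRef()
            ref.setGeneProduct(gene_ids[node.gene])
        elif node.op == "and":
            grp = parent.createAnd()
            for c in node.children:
                _assoc_to_fbc(c, grp)
        else:
            grp = parent.createOr()
            for c in node.children:
                _assoc_to_fbc(c, grp)

    for rxn in model.reactions.values():
        srxn = smodel.createReaction()
        srxn.setId(rxn.id)
        srxn.setName(rxn.name)
        srxn.setReversible(rxn.lower_bound < 0)
        srxn.setFast(False)
        for met_id, coeff in rxn.stoichiometry.items():
            ref = srxn.createReactant() if coeff < 0 else srxn.createProduct()
            ref.setSpecies(met_id)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = srxn.getPlugin("fbc")
        rplug.setLowerFluxBound(
            _bound_param(f"{_sid(rxn.id)}_lb", rxn.lower_bound)
        )
        rplug.setUpperFluxBound(
            _bound_param(f"{_sid(rxn.id)}_ub", rxn.upper_bound)
        )
        if rxn.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            _assoc_to_fbc(rxn.gpr, gpa)

    if model.objective_reaction_id is not None:
        obj = fbc.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(model.objective_reaction_id)
        fo.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# reference lists
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    """One ORF id per line; '#' comments and blank lines ignored."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if token and not token.startswith("#"):
            out.add(token.split("\t")[0])
    return out


def write_gene_list(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_pair_list(path: str | Path) -> set[tuple[str, str]]:
    """Two tab-separated ORF ids per line; pairs stored sorted."""
    out: set[tuple[str, str]] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        fields = token.split("\t")
        if len(fields) < 2:
            raise ModelFormatError(
                f"{path}:{lineno}: expected two tab-separated gene ids"
            )
        a, b = sorted(fields[:2])
        out.add((a, b))
    return out


def write_pair_list(pairs: set[tuple[str, str]], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{a}\t{b}" for a, b in sorted(pairs)) + "\n"
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_model(path: str | Path) -> MetabolicModel:
    """Read a model, dispatching on file extension (.xml/.sbml vs flat TSV)."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return read_sbml(path)
    return read_flat_model(path)


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model, dispatching on file extension (.xml/.sbml vs flat TSV)."""
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        write_sbml(model, path)
    else:
        write_flat_model(model, path)
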