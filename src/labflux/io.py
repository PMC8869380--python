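"""Model input/output: SBML Level 3 + FBC v2, a JSON dialect and a TSV dialect.

SBML is the interchange format of the constraint-based modeling community;
flux bounds, gene products and the objective ride on the FBC v2 package.
Reaction ``kind`` and ``subsystem`` — which SBML core does not model — are
carried in each reaction's notes block and recovered on load (with a
structural fallback for files written by other tools).

The JSON dialect is a single object::

    {"id": ..., "metabolites": [{"id", "name", "compartment", "formula"}],
     "reactions": [{"id", "name", "stoich": {...}, "lb", "ub", "gpr",
                    "subsystem", "kind"}],
     "genes": [...], "objective": reaction-id}

The TSV dialect is a directory holding ``metabolites.tsv`` (id, name,
compartment, formula) and ``reactions.tsv`` (id, name, equation, lb, ub,
gpr, subsystem, kind) with equations written ``2 A_c + B_c -> C_c``; the
objective id and orphan genes live in ``#`` header comments of the reactions
table.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import libsbml

from .core import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction, validate_model
from .errors import ModelFormatError
from .gpr import And, GeneRef, GPRNode, Or, gpr_genes, gpr_to_string, parse_gpr

__all__ = ["load_model", "save_model"]

_FORMATS = ("sbml", "json", "tsv")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ModelFormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    if path.suffix in (".xml", ".sbml"):
        return "sbml"
    if path.suffix == ".json":
        return "json"
    if path.is_dir() or path.suffix in ("", ".tsv"):
        return "tsv"
    raise ModelFormatError(f"cannot infer model format from {path}")


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load and validate a model from SBML, JSON or the TSV directory dialect."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt != "tsv" and not path.exists():
        raise ModelFormatError(f"no such file: {path}")
    if fmt == "sbml":
        model = _load_sbml(path)
    elif fmt == "json":
        model = _load_json(path)
    else:
        model = _load_tsv(path)
    validate_model(model)
    return model


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Validate then write a model; the file re-loads to an equal model."""
    validate_model(model)
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        _save_sbml(model, path)
    elif fmt == "json":
        _save_json(model, path)
    else:
        _save_tsv(model, path)


# --------------------------------------------------------------------------
# JSON dialect
# --------------------------------------------------------------------------

def _load_json(path: Path) -> MetabolicModel:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: invalid JSON: {exc}") from exc
    try:
        mets = [
            Metabolite(
                id=m["id"], name=m.get("name", ""),
                compartment=m.get("compartment", "c"),
                formula=m.get("formula"),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"], name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=float(r["lb"]), upper_bound=float(r["ub"]),
                gpr=parse_gpr(r.get("gpr", "")),
                subsystem=r.get("subsystem", ""), kind=r.get("kind", "internal"),
            )
            for r in data["reactions"]
        ]
        return MetabolicModel(
            id=data.get("id", path.stem), metabolites=mets, reactions=rxns,
            genes=list(data["genes"]), objective_reaction_id=data["objective"],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: malformed model JSON: {exc!r}") from exc


def _save_json(model: MetabolicModel, path: Path) -> None:
    data = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             **({"formula": m.formula} if m.formula else {})}
            for m in model.metabolites
        ],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoich": dict(sorted(r.stoichiometry.items())),
             "lb": r.lower_bound, "ub": r.upper_bound,
             "gpr": r.gpr_string, "subsystem": r.subsystem, "kind": r.kind}
            for r in model.reactions
        ],
        "genes": sorted(model.genes),
        "objective": model.objective_reaction_id,
    }
    path.write_text(json.dumps(data, indent=1) + "\n")


# --------------------------------------------------------------------------
# TSV dialect
# --------------------------------------------------------------------------

_ARROW = "->"


def _format_equation(stoich: dict[str, float]) -> str:
    def side(items: list[tuple[str, float]]) -> str:
        parts = []
        for mid, coef in items:
            parts.append(mid if coef == 1 else f"{coef!r} {mid}")
        return " + ".join(parts)

    lhs = sorted((m, -c) for m, c in stoich.items() if c < 0)
    rhs = sorted((m, c) for m, c in stoich.items() if c > 0)
    return f"{side(lhs)} {_ARROW} {side(rhs)}".strip()


def _parse_equation(eq: str, rxn_id: str) -> dict[str, float]:
    if _ARROW not in eq:
        raise ModelFormatError(f"reaction {rxn_id}: equation {eq!r} lacks '{_ARROW}'")
    lhs, rhs = eq.split(_ARROW, 1)
    stoich: dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise ModelFormatError(f"reaction {rxn_id}: empty term in {eq!r}")
            bits = term.split()
            if len(bits) == 1:
                mid, coef = bits[0], 1.0
            elif len(bits) == 2:
                try:
                    coef = float(bits[0])
                except ValueError as exc:
                    raise ModelFormatError(
                        f"reaction {rxn_id}: bad coefficient {bits[0]!r}"
                    ) from exc
                mid = bits[1]
            else:
                raise ModelFormatError(f"reaction {rxn_id}: bad term {term!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add(lhs, -1.0)
    add(rhs, +1.0)
    return stoich


def _load_tsv(path: Path) -> MetabolicModel:
    met_path = path / "metabolites.tsv"
    rxn_path = path / "reactions.tsv"
    for p in (met_path, rxn_path):
        if not p.exists():
            raise ModelFormatError(f"TSV model directory {path} lacks {p.name}")
    mets = []
    for line in met_path.read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("id\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ModelFormatError(f"{met_path}: short row {line!r}")
        mets.append(Metabolite(
            id=fields[0], name=fields[1], compartment=fields[2],
            formula=fields[3] or None if len(fields) > 3 else None,
        ))
    rxns = []
    model_id, objective, orphans = path.name, "", []
    for line in rxn_path.read_text().splitlines():
        if line.startswith("# objective="):
            objective = line.split("=", 1)[1].strip()
            continue
        if line.startswith("# genes="):
            orphans = [g for g in line.split("=", 1)[1].strip().split(",") if g]
            continue
        if line.startswith("# model="):
            model_id = line.split("=", 1)[1].strip()
            continue
        if not line.strip() or line.startswith("#") or line.startswith("id\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 8:
            raise ModelFormatError(
                f"{rxn_path}: expected 8 columns, got {len(fields)}: {line!r}"
            )
        rid, name, eq, lb, ub, gpr, subsystem, kind = fields
        try:
            lower, upper = float(lb), float(ub)
        except ValueError as exc:
            raise ModelFormatError(f"reaction {rid}: bad bounds {lb!r}/{ub!r}") from exc
        rxns.append(Reaction(
            id=rid, name=name, stoichiometry=_parse_equation(eq, rid),
            lower_bound=lower, upper_bound=upper, gpr=parse_gpr(gpr),
            subsystem=subsystem, kind=kind,
        ))
    genes = sorted(set(orphans) | {g for r in rxns for g in r.genes})
    return MetabolicModel(
        id=model_id, metabolites=mets, reactions=rxns, genes=genes,
        objective_reaction_id=objective,
    )


def _save_tsv(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    met_lines = ["id\tname\tcompartment\tformula"]
    for m in model.metabolites:
        met_lines.append(f"{m.id}\t{m.name}\t{m.compartment}\t{m.formula or ''}")
    (path / "metabolites.tsv").write_text("\n".join(met_lines) + "\n")
    rxn_lines = [
        f"# model={model.id}",
        f"# objective={model.objective_reaction_id}",
        f"# genes={','.join(sorted(model.genes))}",
        "id\tname\tequation\tlb\tub\tgpr\tsubsystem\tkind",
    ]
    for r in model.reactions:
        rxn_lines.append(
            f"{r.id}\t{r.name}\t{_format_equation(r.stoichiometry)}\t"
            f"{r.lower_bound!r}\t{r.upper_bound!r}\t{r.gpr_string}\t"
            f"{r.subsystem}\t{r.kind}"
        )
    (path / "reactions.tsv").write_text("\n".join(rxn_lines) + "\n")


# --------------------------------------------------------------------------
# SBML Level 3 + FBC v2
# --------------------------------------------------------------------------

_NOTES_KIND = re.compile(r"kind:\s*([a-z]+)")
_NOTES_SUBSYSTEM = re.compile(r"subsystem:\s*([^<\n]*)")


def _sbml_fail(message: str) -> None:
    raise ModelFormatError(message)


def _save_sbml(model: MetabolicModel, path: Path) -> None:
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.id)
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)
    for cid in ("c", "e"):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
        comp.setSize(1.0)
    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setInitialConcentration(0.0)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)
    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gp.setId(gene)
        gp.setLabel(gene)
    for r in model.reactions:
        for suffix, value in (("lb", r.lower_bound), ("ub", r.upper_bound)):
            par = sm.createParameter()
            par.setId(f"{suffix}_{r.id}")
            par.setValue(value)
            par.setConstant(True)
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for mid, coef in sorted(r.stoichiometry.items()):
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coef))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(f"lb_{r.id}")
        rplug.setUpperFluxBound(f"ub_{r.id}")
        if r.gpr is not None:
            gpa = rplug.createGeneProductAssociation()
            _write_association(gpa, r.gpr)
        notes = (
            '<body xmlns="http://www.w3.org/1999/xhtml">'
            f"<p>subsystem: {r.subsystem}</p><p>kind: {r.kind}</p></body>"
        )
        if rx.setNotes(notes) != libsbml.LIBSBML_OPERATION_SUCCESS:
            _sbml_fail(f"could not attach notes to reaction {r.id}")
    obj = mplug.createObjective()
    obj.setId("obj")
    obj.setType("maximize")
    fo = obj.createFluxObjective()
    fo.setReaction(model.objective_reaction_id)
    fo.setCoefficient(1.0)
    mplug.setActiveObjectiveId("obj")
    if not libsbml.writeSBMLToFile(doc, str(path)):
        _sbml_fail(f"could not write SBML to {path}")


def _write_association(parent, node: GPRNode) -> None:
    if isinstance(node, GeneRef):
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(node.gene)
    elif isinstance(node, And):
        grp = parent.createAnd()
        for t in node.terms:
            _write_association(grp, t)
    elif isinstance(node, Or):
        grp = parent.createOr()
        for t in node.terms:
            _write_association(grp, t)


def _read_association(assoc) -> GPRNode:
    if isinstance(assoc, libsbml.GeneProductRef):
        return GeneRef(assoc.getGeneProduct())
    terms = tuple(
        _read_association(assoc.getAssociation(i))
        for i in range(assoc.getNumAssociations())
    )
    if isinstance(assoc, libsbml.FbcAnd):
        return And(terms)
    if isinstance(assoc, libsbml.FbcOr):
        return Or(terms)
    raise ModelFormatError(f"unsupported GPR association node {assoc}")


def _infer_kind(rx, sm, stoich: dict[str, float]) -> str:
    rid = rx.getId().lower()
    if "biomass" in rid:
        return "biomass"
    comps = {sm.getSpecies(mid).getCompartment() for mid in stoich}
    if len(stoich) == 1 and comps == {"e"}:
        return "exchange"
    if len(comps) > 1:
        return "transport"
    return "internal"


def _load_sbml(path: Path) -> MetabolicModel:
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        _sbml_fail(f"{path}: SBML parse error: {err.getMessage().strip()}")
    sm = doc.getModel()
    if sm is None:
        _sbml_fail(f"{path}: no <model> element")
    mplug = sm.getPlugin("fbc")
    mets = []
    for i in range(sm.getNumSpecies()):
        sp = sm.getSpecies(i)
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        mets.append(Metabolite(
            id=sp.getId(), name=sp.getName(),
            compartment=sp.getCompartment(), formula=formula,
        ))
    genes = []
    if mplug is not None:
        genes = [mplug.getGeneProduct(i).getId()
                 for i in range(mplug.getNumGeneProducts())]
    rxns = []
    for i in range(sm.getNumReactions()):
        rx = sm.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb, ub = None, None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = sm.getParameter(rplug.getLowerFluxBound()).getValue()
            if rplug.isSetUpperFluxBound():
                ub = sm.getParameter(rplug.getUpperFluxBound()).getValue()
        if lb is None or ub is None:
            # bounds absent in the file: default by declared reversibility
            lb = -DEFAULT_BOUND if rx.getReversible() else 0.0 if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub
        gpr = None
        if rplug is not None and rplug.isSetGeneProductAssociation():
            gpr = _read_association(rplug.getGeneProductAssociation().getAssociation())
        notes = rx.getNotesString() if rx.isSetNotes() else ""
        kind_m = _NOTES_KIND.search(notes)
        sub_m = _NOTES_SUBSYSTEM.search(notes)
        kind = kind_m.group(1) if kind_m else _infer_kind(rx, sm, stoich)
        rxns.append(Reaction(
            id=rx.getId(), name=rx.getName(), stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            subsystem=sub_m.group(1).strip() if sub_m else "", kind=kind,
        ))
    objective = ""
    if mplug is not None and mplug.getNumObjectives() > 0:
        active = mplug.getActiveObjective() or mplug.getObjective(0)
        if active.getNumFluxObjectives() > 0:
            objective = active.getFluxObjective(0).getReaction()
    genes = sorted(set(genes) | {g for r in rxns for g in gpr_genes(r.gpr)})
    return MetabolicModel(
        id=sm.getId() or path.stem, metabolites=mets, reactions=rxns,
        genes=genes, objective_reaction_id=objective,
    )
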