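"""Domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is the usual constraint-based triplet: metabolites
across two compartments (cytoplasm ``c`` and extracellular space ``e``),
reactions with stoichiometry, flux bounds in mmol gDCW^-1 h^-1 and optional
GPR associations, and a biomass objective whose flux is the specific growth
rate (h^-1).

This module also builds the stoichiometric matrix S (metabolites x
reactions), summarizes model counts, derives the bipartite gene-metabolite
adjacency used by reporter-metabolite scoring, and checks elemental mass
balance where chemical formulas are attached.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np

from .errors import ModelValidationError
from .gpr import GPRNode, gpr_genes, gpr_to_string, parse_gpr

COMPARTMENTS = ("c", "e")
REACTION_KINDS = ("internal", "transport", "exchange", "biomass", "maintenance")

#: Default flux bound magnitude for effectively unbounded reactions
#: (mmol gDCW^-1 h^-1).
DEFAULT_BOUND = 1000.0

#: Currency metabolites excluded from gene-metabolite adjacency: cofactor and
#: inorganic pool species that would otherwise neighbor nearly every gene and
#: swamp reporter-metabolite neighborhoods. Matched on the id with its
#: compartment suffix stripped.
DEFAULT_CURRENCY = frozenset(
    {"atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "h", "h2o", "pi",
     "ppi", "co2", "nh4", "coa"}
)

__all__ = [
    "Metabolite", "Reaction", "MetabolicModel", "StoichMatrix",
    "COMPARTMENTS", "REACTION_KINDS", "DEFAULT_BOUND", "DEFAULT_CURRENCY",
    "validate_model", "stoichiometric_matrix", "model_summary",
    "gene_metabolite_adjacency", "mass_balance_report", "is_currency",
]


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None


@dataclass
class Reaction:
    """A (possibly reversible) reaction with gDCW-normalized flux bounds.

    Stoichiometry maps metabolite id to a signed coefficient: negative
    consumed, positive produced. ``kind`` distinguishes boundary and
    pseudo-reactions from ordinary chemistry; an exchange touches exactly one
    extracellular metabolite.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRNode | None = None
    subsystem: str = ""
    kind: str = "internal"

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)

    @property
    def gpr_string(self) -> str:
        return gpr_to_string(self.gpr)

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_reaction_id: str = ""

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            objective_reaction_id=self.objective_reaction_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.id == other.id
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
            and sorted(self.genes) == sorted(other.genes)
            and self.objective_reaction_id == other.objective_reaction_id
        )


def validate_model(model: MetabolicModel) -> None:
    """Check every structural invariant; raise with the full problem list."""
    problems: list[str] = []
    met_ids = [m.id for m in model.metabolites]
    met_set = set(met_ids)
    if len(met_set) != len(met_ids):
        dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
        problems.append(f"duplicate metabolite ids: {dupes}")
    for m in model.metabolites:
        if m.compartment not in COMPARTMENTS:
            problems.append(
                f"metabolite {m.id}: unknown compartment {m.compartment!r}"
            )
    rxn_ids = [r.id for r in model.reactions]
    if len(set(rxn_ids)) != len(rxn_ids):
        dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
        problems.append(f"duplicate reaction ids: {dupes}")
    gene_set = set(model.genes)
    comp_of = {m.id: m.compartment for m in model.metabolites}
    for r in model.reactions:
        if r.kind not in REACTION_KINDS:
            problems.append(f"reaction {r.id}: unknown kind {r.kind!r}")
        if r.lower_bound > r.upper_bound:
            problems.append(
                f"reaction {r.id}: lower_bound {r.lower_bound} > "
                f"upper_bound {r.upper_bound}"
            )
        dangling = sorted(set(r.stoichiometry) - met_set)
        if dangling:
            problems.append(f"reaction {r.id}: dangling metabolites {dangling}")
        unknown_genes = sorted(r.genes - gene_set)
        if unknown_genes:
            problems.append(f"reaction {r.id}: genes not in model {unknown_genes}")
        if r.kind == "exchange":
            if len(r.stoichiometry) != 1:
                problems.append(
                    f"exchange {r.id}: touches {len(r.stoichiometry)} "
                    "metabolites, expected exactly 1"
                )
            else:
                (met_id,) = r.stoichiometry
                if comp_of.get(met_id) != "e":
                    problems.append(
                        f"exchange {r.id}: metabolite {met_id} is not "
                        "extracellular"
                    )
    obj = model.objective_reaction_id
    by_id = {r.id: r for r in model.reactions}
    if obj not in by_id:
        problems.append(f"objective reaction {obj!r} not found")
    elif by_id[obj].kind != "biomass":
        problems.append(
            f"objective reaction {obj!r} has kind {by_id[obj].kind!r}, "
            "expected biomass"
        )
    if problems:
        raise ModelValidationError(problems)


class StoichMatrix(NamedTuple):
    S: np.ndarray
    metabolite_ids: list[str]
    reaction_ids: list[str]


def stoichiometric_matrix(model: MetabolicModel) -> StoichMatrix:
    """Dense stoichiometric matrix S with S[i, j] the coefficient of
    metabolite i in reaction j."""
    met_ids = [m.id for m in model.metabolites]
    rxn_ids = [r.id for r in model.reactions]
    met_index = {mid: i for i, mid in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[met_index[mid], j] = coef
    return StoichMatrix(S, met_ids, rxn_ids)


def model_summary(model: MetabolicModel) -> dict[str, int]:
    """Headline counts. ``gpr_associations`` counts reactions carrying a
    non-empty GPR; ``gene_reaction_pairs`` counts distinct (gene, reaction)
    pairs, since published tallies do not always say which they use."""
    with_gpr = [r for r in model.reactions if r.gpr is not None]
    return {
        "genes": len(model.genes),
        "metabolites": len(model.metabolites),
        "reactions": len(model.reactions),
        "gpr_associations": len(with_gpr),
        "gene_reaction_pairs": sum(len(r.genes) for r in with_gpr),
    }


def is_currency(met_id: str, currency: frozenset[str] = DEFAULT_CURRENCY) -> bool:
    """True if the id, with a trailing ``_c``/``_e`` compartment suffix
    stripped, names a currency metabolite."""
    base = re.sub(r"_(c|e)$", "", met_id)
    return base.lower() in currency


def gene_metabolite_adjacency(
    model: MetabolicModel,
    currency: frozenset[str] = DEFAULT_CURRENCY,
) -> dict[str, frozenset[str]]:
    """Bipartite adjacency, keyed by metabolite id, mapping to the set of
    genes appearing in the GPR of any reaction whose stoichiometry involves
    that metabolite. Currency metabolites are dropped entirely."""
    adj: dict[str, set[str]] = {}
    for r in model.reactions:
        genes = r.genes
        if not genes:
            continue
        for mid in r.stoichiometry:
            if is_currency(mid, currency):
                continue
            adj.setdefault(mid, set()).update(genes)
    return {mid: frozenset(gs) for mid, gs in adj.items()}


_FORMULA = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(formula: str) -> dict[str, int]:
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def mass_balance_report(
    model: MetabolicModel, kinds: Iterable[str] = ("internal",)
) -> dict[str, dict[str, float]]:
    """Elemental imbalance per reaction, for reactions of the given kinds
    whose participants all carry formulas. An empty dict per reaction means
    balanced; reactions with any formula-less participant are skipped."""
    formulas = {m.id: m.formula for m in model.metabolites}
    report: dict[str, dict[str, float]] = {}
    for r in model.reactions:
        if r.kind not in kinds:
            continue
        if any(formulas.get(mid) is None for mid in r.stoichiometry):
            continue
        balance: dict[str, float] = {}
        for mid, coef in r.stoichiometry.items():
            for elem, count in _parse_formula(formulas[mid]).items():
                balance[elem] = balance.get(elem, 0.0) + coef * count
        report[r.id] = {e: v for e, v in balance.items() if abs(v) > 1e-9}
    return report
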