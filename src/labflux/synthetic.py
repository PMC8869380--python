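"""Fixture factory: small LAB-like metabolic models with planted ground truth.

The mini-LAB network emulates the metabolic logic of a fastidious,
fermentative lactic acid bacterium at toy scale, so that every pipeline
stage has a fixture whose correct answer is known by construction:

* carbon sources funnel into a common hexose-phosphate pool with realistic
  ATP economics — hexoses cost one ATP to phosphorylate, disaccharides are
  hydrolyzed to hexoses, sucrose can instead be cleaved by an ATP-free
  phosphorylase (conserving the glycosidic bond energy as glucose
  6-phosphate), and raffinose is hydrolyzed to sucrose + galactose;
* a homolactic glycolysis lump yields 3 ATP per hexose phosphate, with
  lactate secreted;
* planted-essential amino acids and vitamins have uptake transporters but
  no biosynthesis (auxotrophies); planted substitutable pairs (by default
  glutamine/glutamate and asparagine/aspartate) are linked only by
  deamidation/synthetase interconversions; the remaining amino acids and
  thiamin have biosynthesis from central metabolism;
* biomass is assembled from a macromolecular composition with the planted
  growth-associated maintenance (GAM), and a maintenance reaction carries
  the non-growth ATP demand (NGAM) as a flux floor.

Everything a generator plants — essential singles, synthetic-essential
pairs, the strict carbon growth order implied by net ATP yields, the GAM —
is returned as a ground-truth manifest, and construction is fully
deterministic so the same spec always yields byte-identical files.

DEG-table generation plants coordinated up-regulation in chosen subsystems:
perturbed genes draw log2 fold changes around ``effect_lfc``, null genes
around zero, p-values follow from the fold change under the null spread, and
the FDR column is Benjamini-Hochberg over all genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core import MetabolicModel, Metabolite, Reaction, gene_metabolite_adjacency, validate_model
from .errors import LabfluxError
from .gpr import parse_gpr
from .medium import BiomassComposition, NutrientClasses, assemble_biomass
from .omission import NutrientPanel

__all__ = [
    "MiniLabSpec", "MiniLabTruth", "DEGTruth",
    "make_toy_chain", "make_mini_lab", "make_deg_table", "make_random_network",
    "mini_lab_nutrient_classes", "mini_lab_panel", "mini_lab_composition",
    "AMINO_ACIDS", "VITAMINS", "CARBON_NAMES",
]

# id, name, molecular weight (g/mol), protein mole fraction
AMINO_ACIDS = (
    ("ala", "L-Alanine", 89.09, 0.09),
    ("ser", "L-Serine", 105.09, 0.05),
    ("leu", "L-Leucine", 131.17, 0.09),
    ("ile", "L-Isoleucine", 131.17, 0.06),
    ("phe", "L-Phenylalanine", 165.19, 0.04),
    ("val", "L-Valine", 117.15, 0.07),
    ("tyr", "L-Tyrosine", 181.19, 0.03),
    ("his", "L-Histidine", 155.15, 0.02),
    ("met", "L-Methionine", 149.21, 0.02),
    ("trp", "L-Tryptophan", 204.23, 0.01),
    ("cys", "L-Cysteine", 121.16, 0.01),
    ("pro", "L-Proline", 115.13, 0.04),
    ("thr", "L-Threonine", 119.12, 0.05),
    ("arg", "L-Arginine", 174.20, 0.05),
    ("lys", "L-Lysine", 146.19, 0.07),
    ("gly", "Glycine", 75.07, 0.08),
    ("asn", "L-Asparagine", 132.12, 0.06),
    ("asp", "L-Aspartate", 133.10, 0.05),
    ("gln", "L-Glutamine", 146.15, 0.05),
    ("glu", "L-Glutamate", 147.13, 0.06),
)

# id, name, molecular weight (g/mol)
VITAMINS = (
    ("thm", "Thiamin (B1)", 265.35),
    ("nac", "Nicotinate (B3)", 123.11),
    ("pnto", "Pantothenate (B5)", 219.23),
    ("pydam", "Pyridoxamine (B6)", 168.19),
    ("btn", "Biotin (B7)", 244.31),
)

# carbon name -> short metabolite id
CARBON_NAMES = {
    "glucose": "glc", "fructose": "fru", "galactose": "gal",
    "sucrose": "suc", "maltose": "mal", "lactose": "lcts",
    "trehalose": "tre", "melibiose": "mel", "raffinose": "raf",
    "arabinose": "ara", "mannitol": "mtl",
}

_AA_IDS = tuple(a[0] for a in AMINO_ACIDS)
_VIT_IDS = tuple(v[0] for v in VITAMINS)

#: ATP yield of the lumped homolactic glycolysis, per hexose phosphate.
GLYCOLYSIS_ATP = 3.0


def _ex(base: str) -> str:
    return f"EX_{base}_e"


@dataclass(frozen=True)
class MiniLabSpec:
    """Blueprint for one mini-LAB fixture; fully determines the model."""

    seed: int = 0
    carbons: tuple[str, ...] = (
        "glucose", "fructose", "galactose", "sucrose", "maltose", "raffinose",
    )
    planted_essential: tuple[str, ...] = (
        "ala", "ser", "leu", "ile", "phe", "val", "tyr", "his", "met", "trp",
        "nac", "pnto", "pydam", "btn",
    )
    planted_pairs: tuple[tuple[str, str], ...] = (("gln", "glu"), ("asn", "asp"))
    gam: float = 40.0
    ngam: float = 0.37
    sucrose_route: str = "phosphorylase"  # or "hydrolase"

    def validate(self) -> None:
        known = set(_AA_IDS) | set(_VIT_IDS)
        bad = sorted(set(self.planted_essential) - known)
        if bad:
            raise LabfluxError(f"unknown planted nutrients: {bad}")
        unknown_c = sorted(set(self.carbons) - set(CARBON_NAMES))
        if unknown_c:
            raise LabfluxError(f"unknown carbons: {unknown_c}")
        if self.sucrose_route not in ("phosphorylase", "hydrolase"):
            raise LabfluxError(f"unknown sucrose route {self.sucrose_route!r}")
        pair_members = [m for pair in self.planted_pairs for m in pair]
        if len(set(pair_members)) != len(pair_members):
            raise LabfluxError("planted pairs share members")
        overlap = sorted(set(pair_members) & set(self.planted_essential))
        if overlap:
            raise LabfluxError(
                f"pair members also planted essential: {overlap}"
            )
        bad_pairs = sorted(set(pair_members) - set(_AA_IDS))
        if bad_pairs:
            raise LabfluxError(f"pair members must be amino acids: {bad_pairs}")
        if self.gam < 0 or self.ngam < 0:
            raise LabfluxError("gam and ngam must be >= 0")


@dataclass(frozen=True)
class MiniLabTruth:
    """Planted answers, consistent with the generated model by construction."""

    essential_singles: frozenset[str]  # exchange ids
    synthetic_essential_pairs: frozenset[frozenset[str]]
    #: (better, worse) exchange-id pairs: strictly higher growth at equal
    #: moderate uptake, from the strict net-ATP ordering of the routes.
    carbon_growth_order: tuple[tuple[str, str], ...]
    planted_gam: float


@dataclass(frozen=True)
class DEGTruth:
    perturbed_subsystems: frozenset[str]
    perturbed_genes: frozenset[str]
    #: metabolites whose scored gene neighborhood is majority-perturbed —
    #: the ones a reporter analysis should surface.
    reporter_metabolites: frozenset[str]


def mini_lab_panel() -> NutrientPanel:
    """The canonical 25-nutrient omission panel: 20 amino acids + 5 vitamins."""
    return NutrientPanel(tuple(_ex(x) for x in _AA_IDS + _VIT_IDS))


def mini_lab_nutrient_classes(spec: MiniLabSpec | None = None) -> NutrientClasses:
    spec = spec or MiniLabSpec()
    return NutrientClasses(
        amino_acids=tuple(_ex(a) for a in _AA_IDS),
        vitamins=tuple(_ex(v) for v in _VIT_IDS),
        lipids=(_ex("lipid"),),
        oxygen=(_ex("o2"),),
        carbons=tuple(_ex(CARBON_NAMES[c]) for c in spec.carbons),
        free=(_ex("h2o"), _ex("pi"), _ex("nh4")),
    )


def mini_lab_composition(spec: MiniLabSpec | None = None) -> BiomassComposition:
    """Macromolecular recipe of the mini-LAB biomass.

    Mass fractions are typical for lactic acid bacteria: protein-dominated
    dry weight, a trace vitamin (cofactor) fraction so vitamin auxotrophies
    are growth-coupled without making vitamins the binding substrate.
    """
    spec = spec or MiniLabSpec()
    weights = {f"{a}_c": mw for a, _, mw, _ in AMINO_ACIDS}
    weights.update({f"{v}_c": mw for v, _, mw in VITAMINS})
    weights.update({"carbmono_c": 162.14, "nucl_c": 339.5, "lipid_c": 750.0})
    return BiomassComposition(
        mass_fractions={
            "protein": 0.45, "carbohydrate": 0.25, "nucleotide": 0.1949,
            "lipid": 0.105, "vitamin": 0.0001,
        },
        monomer_ratios={
            "protein": {f"{a}_c": x for a, _, _, x in AMINO_ACIDS},
            "carbohydrate": {"carbmono_c": 1.0},
            "nucleotide": {"nucl_c": 1.0},
            "lipid": {"lipid_c": 1.0},
            "vitamin": {f"{v}_c": 0.2 for v, _, _ in VITAMINS},
        },
        monomer_weights=weights,
        gam=spec.gam,
        ngam=spec.ngam,
    )


class _Builder:
    """Accumulates metabolites/reactions with deterministic gene assignment."""

    def __init__(self):
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self._mets: set[str] = set()
        self._gene_counter = 0
        self._gpr_counter = 0
        self.genes: list[str] = []

    def met(self, mid: str, name: str = "", compartment: str = "c") -> str:
        if mid not in self._mets:
            self._mets.add(mid)
            self.metabolites.append(Metabolite(mid, name or mid, compartment))
        return mid

    def _next_gpr(self) -> str:
        # deterministic mix of single genes, isozyme pairs and complexes
        i = self._gpr_counter
        self._gpr_counter += 1

        def new_gene() -> str:
            self._gene_counter += 1
            g = f"g{self._gene_counter:03d}"
            self.genes.append(g)
            return g

        if i % 5 == 2:
            return f"{new_gene()} or {new_gene()}"
        if i % 7 == 3:
            return f"{new_gene()} and {new_gene()}"
        return new_gene()

    def rxn(self, rid: str, stoich: dict[str, float], *, name: str = "",
            lb: float = 0.0, ub: float = 1000.0, subsystem: str = "",
            kind: str = "internal", gene: bool = False) -> None:
        gpr = parse_gpr(self._next_gpr()) if gene else None
        self.reactions.append(Reaction(
            id=rid, name=name or rid, stoichiometry=stoich,
            lower_bound=lb, upper_bound=ub, gpr=gpr,
            subsystem=subsystem, kind=kind,
        ))

    def exchange(self, base: str, name: str = "") -> None:
        self.met(f"{base}_e", name or base, "e")
        self.rxn(_ex(base), {f"{base}_e": -1.0}, name=f"{name or base} exchange",
                 lb=0.0, ub=1000.0, subsystem="Exchange", kind="exchange")

    def transport(self, base: str, name: str = "", subsystem: str = "Transport",
                  gene: bool = True, reversible: bool = False) -> None:
        self.met(f"{base}_e", name or base, "e")
        self.met(f"{base}_c", name or base, "c")
        self.rxn(f"TR_{base}", {f"{base}_e": -1.0, f"{base}_c": 1.0},
                 name=f"{name or base} transport",
                 lb=-1000.0 if reversible else 0.0, ub=1000.0,
                 subsystem=subsystem, kind="transport", gene=gene)


def make_mini_lab(spec: MiniLabSpec | None = None) -> tuple[MetabolicModel, MiniLabTruth]:
    """Build a mini-LAB model and its ground-truth manifest."""
    spec = spec or MiniLabSpec()
    spec.validate()
    b = _Builder()

    # central pools (currency metabolites live only in the cytoplasm except
    # the freely exchanged inorganics)
    for mid, name in (("atp", "ATP"), ("adp", "ADP"), ("g6p", "Hexose 6-phosphate"),
                      ("lac", "Lactate"), ("carbmono", "Glycan monomer"),
                      ("nucl", "Nucleotide pool"), ("h", "Proton")):
        b.met(f"{mid}_c", name, "c")

    # freely supplied inorganics: exchange + reversible diffusion
    for mid, name in (("h2o", "Water"), ("pi", "Phosphate"), ("nh4", "Ammonium")):
        b.exchange(mid, name)
        b.transport(mid, name, subsystem="Inorganic transport", gene=False,
                    reversible=True)
    b.exchange("h", "Proton")
    b.transport("h", "Proton", subsystem="Inorganic transport", gene=False,
                reversible=True)

    # lactate secretion, oxygen (no consumer: trace uptake is tolerated)
    b.exchange("lac", "Lactate")
    b.rxn("TR_lac", {"lac_c": -1.0, "lac_e": 1.0}, name="Lactate export",
          subsystem="Fermentation", kind="transport", gene=True)
    b.exchange("o2", "Oxygen")

    # lipid uptake (no biosynthesis: always medium-supplied)
    b.exchange("lipid", "Lipid")
    b.transport("lipid", "Lipid", subsystem="Lipid transport")

    # cytosolic hexoses and their kinases are always present; carbon uptake
    # routes are added per selected carbon
    for mid, name in (("glc", "Glucose"), ("fru", "Fructose"), ("gal", "Galactose")):
        b.met(f"{mid}_c", name, "c")
    b.rxn("HEX1", {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
          name="Hexokinase", subsystem="Glycolysis", gene=True)
    b.rxn("FRUK", {"fru_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
          name="Fructokinase", subsystem="Glycolysis", gene=True)
    b.rxn("GALK", {"gal_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
          name="Galactokinase", subsystem="Galactose metabolism", gene=True)

    suc_net = 5.0 if spec.sucrose_route == "phosphorylase" else 4.0
    atp_net = {
        "glucose": 2.0, "fructose": 2.0, "galactose": 2.0, "mannitol": 2.0,
        "arabinose": GLYCOLYSIS_ATP * 5.0 / 6.0 - 1.0,
        "maltose": 4.0, "lactose": 4.0, "trehalose": 4.0, "melibiose": 4.0,
        "sucrose": suc_net, "raffinose": suc_net + 2.0,
    }
    for carbon in spec.carbons:
        cid = CARBON_NAMES[carbon]
        b.exchange(cid, carbon.capitalize())
        b.transport(cid, carbon.capitalize(), subsystem="Sugar transport")
        if carbon == "sucrose":
            if spec.sucrose_route == "phosphorylase":
                b.rxn("SUCP", {"suc_c": -1, "pi_c": -1, "g6p_c": 1, "fru_c": 1},
                      name="Sucrose phosphorylase",
                      subsystem="Starch and sucrose metabolism", gene=True)
            else:
                b.rxn("SUCH", {"suc_c": -1, "h2o_c": -1, "glc_c": 1, "fru_c": 1},
                      name="Sucrose hydrolase",
                      subsystem="Starch and sucrose metabolism", gene=True)
        elif carbon == "maltose":
            b.rxn("MALH", {"mal_c": -1, "h2o_c": -1, "glc_c": 2},
                  name="Maltose hydrolase",
                  subsystem="Starch and sucrose metabolism", gene=True)
        elif carbon == "trehalose":
            b.rxn("TREH", {"tre_c": -1, "h2o_c": -1, "glc_c": 2},
                  name="Trehalose hydrolase",
                  subsystem="Starch and sucrose metabolism", gene=True)
        elif carbon == "lactose":
            b.rxn("LCTSH", {"lcts_c": -1, "h2o_c": -1, "glc_c": 1, "gal_c": 1},
                  name="Beta-galactosidase",
                  subsystem="Galactose metabolism", gene=True)
        elif carbon == "melibiose":
            b.rxn("MELH", {"mel_c": -1, "h2o_c": -1, "glc_c": 1, "gal_c": 1},
                  name="Alpha-galactosidase",
                  subsystem="Galactose metabolism", gene=True)
        elif carbon == "raffinose":
            # sucrose metabolites/route required downstream
            b.met("suc_c", "Sucrose", "c")
            b.rxn("RAFH", {"raf_c": -1, "h2o_c": -1, "suc_c": 1, "gal_c": 1},
                  name="Raffinose galactohydrolase",
                  subsystem="Starch and sucrose metabolism", gene=True)
        elif carbon == "arabinose":
            b.rxn("ARAI", {"ara_c": -1, "atp_c": -1,
                           "g6p_c": float(f"{5.0 / 6.0:.12g}"), "adp_c": 1},
                  name="Arabinose assimilation",
                  subsystem="Pentose interconversions", gene=True)
        elif carbon == "mannitol":
            b.rxn("MTLD", {"mtl_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1},
                  name="Mannitol assimilation",
                  subsystem="Fructose and mannose metabolism", gene=True)
    if "raffinose" in spec.carbons and "sucrose" not in spec.carbons:
        # raffinose releases sucrose: give it the chosen cleavage route
        if spec.sucrose_route == "phosphorylase":
            b.rxn("SUCP", {"suc_c": -1, "pi_c": -1, "g6p_c": 1, "fru_c": 1},
                  name="Sucrose phosphorylase",
                  subsystem="Starch and sucrose metabolism", gene=True)
        else:
            b.rxn("SUCH", {"suc_c": -1, "h2o_c": -1, "glc_c": 1, "fru_c": 1},
                  name="Sucrose hydrolase",
                  subsystem="Starch and sucrose metabolism", gene=True)

    b.rxn("GLYC", {"g6p_c": -1, "adp_c": -GLYCOLYSIS_ATP, "pi_c": -(GLYCOLYSIS_ATP - 1),
                   "lac_c": 2, "atp_c": GLYCOLYSIS_ATP},
          name="Glycolysis (homolactic, lumped)", subsystem="Glycolysis", gene=True)

    # amino acids: all have uptake; biosynthesis only for the non-planted,
    # non-pair ones; pairs get interconversion only
    pair_members = {m for pair in spec.planted_pairs for m in pair}
    planted = set(spec.planted_essential)
    for aa, name, _, _ in AMINO_ACIDS:
        b.exchange(aa, name)
        b.transport(aa, name, subsystem="Amino acid transport")
        if aa not in planted and aa not in pair_members:
            b.rxn(f"SYN_{aa}", {"g6p_c": -0.5, "atp_c": -1, f"{aa}_c": 1,
                                "adp_c": 1, "pi_c": 1},
                  name=f"{name} biosynthesis",
                  subsystem="Amino acid biosynthesis", gene=True)
    for x, y in spec.planted_pairs:
        b.rxn(f"CNV_{x}_{y}", {f"{x}_c": -1, "h2o_c": -1, f"{y}_c": 1, "nh4_c": 1},
              name=f"{x} deamidation to {y}",
              subsystem="Amino acid interconversion", gene=True)
        b.rxn(f"CNV_{y}_{x}", {f"{y}_c": -1, "nh4_c": -1, "atp_c": -1,
                               f"{x}_c": 1, "adp_c": 1, "pi_c": 1},
              name=f"{x} synthetase from {y}",
              subsystem="Amino acid interconversion", gene=True)

    for vit, name, _ in VITAMINS:
        b.exchange(vit, name)
        b.transport(vit, name, subsystem="Vitamin transport")
        if vit not in planted:
            b.rxn(f"SYN_{vit}", {"g6p_c": -0.2, "atp_c": -2, f"{vit}_c": 1,
                                 "adp_c": 2, "pi_c": 2},
                  name=f"{name} salvage synthesis",
                  subsystem="Thiamine salvage" if vit == "thm" else "Vitamin biosynthesis",
                  gene=True)

    b.rxn("CARBS", {"g6p_c": -1, "atp_c": -1, "carbmono_c": 1, "adp_c": 1, "pi_c": 1},
          name="Storage glycan synthesis", subsystem="Carbohydrate storage", gene=True)
    b.rxn("NUCS", {"g6p_c": -0.5, "atp_c": -4, "nh4_c": -1,
                   "nucl_c": 1, "adp_c": 4, "pi_c": 3},
          name="Nucleotide pool synthesis", subsystem="Nucleotide biosynthesis",
          gene=True)
    b.rxn("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
          name="ATP maintenance", lb=spec.ngam, subsystem="Maintenance",
          kind="maintenance")

    comp = mini_lab_composition(spec)
    b.met("biomass_e", "Biomass", "e")
    biomass = assemble_biomass(comp, reaction_id="BIOMASS")
    b.reactions.append(biomass)
    b.rxn(_ex("biomass"), {"biomass_e": -1.0}, name="Biomass drain",
          lb=0.0, ub=1000.0, subsystem="Exchange", kind="exchange")

    model = MetabolicModel(
        id=f"minilab_s{spec.seed}_{spec.sucrose_route}",
        metabolites=b.metabolites, reactions=b.reactions,
        genes=sorted(b.genes), objective_reaction_id="BIOMASS",
    )
    validate_model(model)

    order = tuple(
        (_ex(CARBON_NAMES[a]), _ex(CARBON_NAMES[c]))
        for a in spec.carbons for c in spec.carbons
        if atp_net[a] > atp_net[c] + 1e-9
    )
    truth = MiniLabTruth(
        essential_singles=frozenset(_ex(x) for x in spec.planted_essential),
        synthetic_essential_pairs=frozenset(
            frozenset((_ex(x), _ex(y))) for x, y in spec.planted_pairs
        ),
        carbon_growth_order=order,
        planted_gam=spec.gam,
    )
    return model, truth


def make_toy_chain(
    n_steps: int, uptake_cap: float, yield_per_unit: float
) -> MetabolicModel:
    """Linear pathway with a closed-form optimum of uptake_cap * yield."""
    if n_steps < 1:
        raise LabfluxError("n_steps must be >= 1")
    b = _Builder()
    b.exchange("nut", "Nutrient")
    b.reactions[-1].lower_bound = -uptake_cap
    b.transport("nut", "Nutrient", gene=False)
    prev = "nut_c"
    for i in range(1, n_steps):
        nxt = b.met(f"m{i}_c", f"Intermediate {i}", "c")
        b.rxn(f"STEP{i}", {prev: -1.0, nxt: 1.0}, subsystem="Chain")
        prev = nxt
    b.met("biomass_e", "Biomass", "e")
    b.rxn("BIOMASS", {prev: -1.0 / yield_per_unit, "biomass_e": 1.0},
          name="Biomass", kind="biomass", subsystem="Biomass")
    b.rxn(_ex("biomass"), {"biomass_e": -1.0}, lb=0.0, kind="exchange",
          subsystem="Exchange")
    model = MetabolicModel(
        id=f"chain{n_steps}", metabolites=b.metabolites, reactions=b.reactions,
        genes=[], objective_reaction_id="BIOMASS",
    )
    validate_model(model)
    return model


def make_random_network(
    seed: int | np.random.Generator,
    max_metabolites: int = 4,
    max_reactions: int = 6,
) -> MetabolicModel:
    """Random small network with finite bounds straddling zero.

    Built for verifying the LP engine against exhaustive vertex enumeration:
    v = 0 is always feasible and all bounds are finite, so an optimum exists
    and sits on a vertex.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = int(rng.integers(1, max_metabolites + 1))
    n = int(rng.integers(2, max_reactions + 1))
    S = rng.integers(-2, 3, size=(m, n)).astype(float)
    S[rng.random((m, n)) < 0.3] = 0.0
    mets = [Metabolite(f"M{i}_c", compartment="c") for i in range(m)]
    rxns = []
    for j in range(n):
        stoich = {f"M{i}_c": float(S[i, j]) for i in range(m) if S[i, j] != 0}
        rxns.append(Reaction(
            id=f"R{j}", stoichiometry=stoich,
            lower_bound=-float(rng.integers(0, 11)),
            upper_bound=float(rng.integers(0, 11)),
            kind="biomass" if j == 0 else "internal",
        ))
    model = MetabolicModel(
        id="random_net", metabolites=mets, reactions=rxns, genes=[],
        objective_reaction_id="R0",
    )
    validate_model(model)
    return model


def make_deg_table(
    model: MetabolicModel,
    perturbed_subsystems,
    effect_lfc: float = 2.5,
    null_sd: float = 0.3,
    n_null_genes: int = 0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, DEGTruth]:
    """Simulate a DEG table with coordinated change planted in subsystems.

    Genes of perturbed subsystems draw log2FC ~ N(effect_lfc, null_sd); all
    others ~ N(0, null_sd). Each p-value is the two-sided tail of the
    observed fold change under the null spread (so null p-values are
    uniform), FDR is Benjamini-Hochberg over all genes, and FPKM is
    log-normal with ~1% of genes below the expression threshold.
    ``n_null_genes`` extra non-model genes pad the table the way a real
    transcriptome carries genes outside the metabolic network.
    """
    perturbed_subsystems = frozenset(perturbed_subsystems)
    subsystems = {r.subsystem for r in model.reactions if r.subsystem}
    unknown = sorted(perturbed_subsystems - subsystems)
    if unknown:
        raise LabfluxError(f"unknown subsystems: {unknown}")
    perturbed_genes = frozenset(
        g for r in model.reactions if r.subsystem in perturbed_subsystems
        for g in r.genes
    )
    genes = list(model.genes) + [f"null{i:04d}" for i in range(n_null_genes)]
    rng = np.random.default_rng(seed)
    mu = np.array([effect_lfc if g in perturbed_genes else 0.0 for g in genes])
    lfc = rng.normal(mu, null_sd)
    p = 2.0 * norm.sf(np.abs(lfc) / null_sd)
    fdr = multipletests(p, method="fdr_bh")[1]
    fpkm = np.exp2(rng.normal(3.5, 1.5, size=len(genes)))
    df = pd.DataFrame({
        "gene": genes, "log2fc": lfc, "p": p, "fdr": fdr, "fpkm": fpkm,
    })
    adjacency = gene_metabolite_adjacency(model)
    reporter_mets = frozenset(
        mid for mid, gs in adjacency.items()
        if len(gs & perturbed_genes) / len(gs) >= 0.5
    )
    truth = DEGTruth(
        perturbed_subsystems=perturbed_subsystems,
        perturbed_genes=perturbed_genes,
        reporter_metabolites=reporter_mets,
    )
    return df, truth
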