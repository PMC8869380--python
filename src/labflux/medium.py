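"""Medium specification and biomass-reaction assembly.

A medium maps exchange-reaction ids to maximum uptake rates (mmol gDCW^-1
h^-1). Applying a medium closes every exchange for uptake and then opens the
named ones with ``lower_bound = -uptake`` (uptake written as negative flux
through a ``met_e ->`` exchange); secretion bounds are never touched. Closing
unlisted exchanges is what makes omission analysis meaningful: a nutrient
cannot leak in through an exchange the medium does not grant.

Three named presets mirror the study conditions of the source workflow:

* ``validation`` — amino acids 5, lipids 5, vitamins 1e-4, oxygen 1e-10,
  carbon at the measured uptake rate;
* ``omission`` — glucose 25, lipid 1, oxygen 1e-10 (amino acids 5 and
  vitamins 1e-4 retained so each panel nutrient is present to omit);
* ``carbon_scan`` — amino acids 1, vitamins 1, lipid 1, oxygen 1e-10, no
  carbon (the scanned carbon is opened per grid point).

Inorganic species a defined medium always supplies (water, phosphate,
ammonium) are opened at the default bound in every preset.

Biomass assembly converts a macromolecular composition (g per gDCW mass
fractions, per-macromolecule monomer mole fractions, monomer molecular
weights) into a pseudo-reaction consuming ``1000 * f_macro * x_i / Mbar``
mmol gDCW^-1 of each monomer, where ``Mbar`` is the mole-fraction-weighted
mean monomer weight of the macromolecule — so total consumed monomer mass is
exactly 1 g per g biomass. Growth-associated maintenance (GAM, mmol ATP per
gDCW formed) rides inside the biomass reaction as an ATP + H2O -> ADP + Pi
+ H+ hydrolysis; non-growth-associated maintenance (NGAM, mmol ATP gDCW^-1
h^-1) is a flux floor on a dedicated maintenance reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import DEFAULT_BOUND, MetabolicModel, Reaction
from .errors import LabfluxError, MediumError

__all__ = [
    "MediumSpec", "NutrientClasses", "BiomassComposition",
    "apply_medium", "assemble_biomass", "set_ngam",
    "validation_medium", "omission_medium", "carbon_scan_background",
    "load_medium_tsv", "save_medium_tsv",
    "load_biomass_composition", "save_biomass_composition",
]

# Preset uptake rates, mmol gDCW^-1 h^-1
AA_UPTAKE_VALIDATION = 5.0
LIPID_UPTAKE_VALIDATION = 5.0
VITAMIN_UPTAKE = 1e-4
OXYGEN_UPTAKE = 1e-10
OMISSION_GLUCOSE_UPTAKE = 25.0
OMISSION_LIPID_UPTAKE = 1.0
SCAN_AA_UPTAKE = 1.0
SCAN_VITAMIN_UPTAKE = 1.0
SCAN_LIPID_UPTAKE = 1.0


@dataclass(frozen=True)
class MediumSpec:
    """Exchange id -> maximum uptake rate; all rates must be >= 0."""

    uptakes: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        bad = {k: v for k, v in self.uptakes.items() if v < 0}
        if bad:
            raise MediumError(f"negative uptake rates: {bad}")

    def with_uptake(self, exchange_id: str, rate: float) -> "MediumSpec":
        up = dict(self.uptakes)
        up[exchange_id] = rate
        return MediumSpec(up, self.name)

    def without(self, exchange_ids) -> "MediumSpec":
        drop = set(exchange_ids)
        return MediumSpec(
            {k: v for k, v in self.uptakes.items() if k not in drop}, self.name
        )

    def scaled(self, exchange_id: str, factor: float) -> "MediumSpec":
        if exchange_id not in self.uptakes:
            raise MediumError(f"{exchange_id} not in medium {self.name!r}")
        return self.with_uptake(exchange_id, self.uptakes[exchange_id] * factor)


@dataclass(frozen=True)
class NutrientClasses:
    """Exchange ids of a model grouped by nutrient class; used to build the
    named medium presets. ``free`` lists inorganics every defined medium
    supplies without limit (water, phosphate, ammonium)."""

    amino_acids: tuple[str, ...] = ()
    vitamins: tuple[str, ...] = ()
    lipids: tuple[str, ...] = ()
    oxygen: tuple[str, ...] = ()
    carbons: tuple[str, ...] = ()
    free: tuple[str, ...] = ()


def _base(classes: NutrientClasses, aa: float, lipid: float, vit: float) -> dict[str, float]:
    up: dict[str, float] = {}
    up.update({x: aa for x in classes.amino_acids})
    up.update({x: lipid for x in classes.lipids})
    up.update({x: vit for x in classes.vitamins})
    up.update({x: OXYGEN_UPTAKE for x in classes.oxygen})
    up.update({x: DEFAULT_BOUND for x in classes.free})
    return up


def validation_medium(
    classes: NutrientClasses, carbon_exchange: str, carbon_uptake: float
) -> MediumSpec:
    """Growth-validation conditions: rich amino acid/lipid supply, one carbon
    source at its measured uptake rate."""
    up = _base(classes, AA_UPTAKE_VALIDATION, LIPID_UPTAKE_VALIDATION, VITAMIN_UPTAKE)
    up[carbon_exchange] = carbon_uptake
    return MediumSpec(up, "validation")


def omission_medium(classes: NutrientClasses, glucose_exchange: str) -> MediumSpec:
    """Base medium for nutrient-omission scans: glucose 25, lipid 1, oxygen
    1e-10; panel nutrients present at validation rates."""
    up = _base(classes, AA_UPTAKE_VALIDATION, OMISSION_LIPID_UPTAKE, VITAMIN_UPTAKE)
    up[glucose_exchange] = OMISSION_GLUCOSE_UPTAKE
    return MediumSpec(up, "omission")


def carbon_scan_background(classes: NutrientClasses) -> MediumSpec:
    """Background for carbon scans: amino acids 1, vitamins 1, lipid 1,
    oxygen 1e-10, no carbon opened."""
    up = _base(classes, SCAN_AA_UPTAKE, SCAN_LIPID_UPTAKE, SCAN_VITAMIN_UPTAKE)
    return MediumSpec(up, "carbon_scan")


def apply_medium(model: MetabolicModel, medium: MediumSpec) -> MetabolicModel:
    """Return a copy with uptake bounds set from the medium.

    Every exchange not named in the medium is closed for uptake
    (``lower_bound = 0``); named exchanges get ``lower_bound = -uptake``.
    Secretion (upper) bounds are untouched. Idempotent by construction.
    """
    out = model.copy()
    exchange_ids = {r.id for r in out.reactions if r.kind == "exchange"}
    unmatched = sorted(set(medium.uptakes) - exchange_ids)
    if unmatched:
        raise MediumError(
            f"medium {medium.name!r} names non-exchange ids: {unmatched}"
        )
    for r in out.reactions:
        if r.kind != "exchange":
            continue
        r.lower_bound = -medium.uptakes.get(r.id, 0.0)
    return out


@dataclass(frozen=True)
class BiomassComposition:
    """Macromolecular biomass recipe.

    ``mass_fractions`` are g per gDCW over {protein, carbohydrate, lipid,
    nucleotide, vitamin}; each macromolecule's ``monomer_ratios`` are mole
    fractions over its monomer metabolite ids; ``monomer_weights`` are
    g mol^-1. ``gam`` is mmol ATP hydrolyzed per gDCW formed; ``ngam`` the
    maintenance flux floor in mmol ATP gDCW^-1 h^-1.
    """

    mass_fractions: dict[str, float]
    monomer_ratios: dict[str, dict[str, float]]
    monomer_weights: dict[str, float]
    gam: float = 0.0
    ngam: float = 0.0

    def validate(self, tol: float = 1e-6) -> None:
        if self.gam < 0 or self.ngam < 0:
            raise LabfluxError("gam and ngam must be >= 0")
        total = sum(self.mass_fractions.values())
        if abs(total - 1.0) > tol:
            raise LabfluxError(
                f"mass fractions sum to {total!r}, expected 1 +/- {tol}"
            )
        for macro, fraction in self.mass_fractions.items():
            if fraction < 0:
                raise LabfluxError(f"negative mass fraction for {macro}")
            if fraction == 0:
                continue
            ratios = self.monomer_ratios.get(macro)
            if not ratios:
                raise LabfluxError(f"no monomer ratios for macromolecule {macro}")
            rsum = sum(ratios.values())
            if abs(rsum - 1.0) > tol:
                raise LabfluxError(
                    f"{macro} monomer ratios sum to {rsum!r}, expected 1 +/- {tol}"
                )
            missing = sorted(set(ratios) - set(self.monomer_weights))
            if missing:
                raise LabfluxError(f"missing monomer weights: {missing}")


def assemble_biomass(
    comp: BiomassComposition,
    reaction_id: str = "BIOMASS",
    atp: str = "atp_c",
    adp: str = "adp_c",
    pi: str = "pi_c",
    h2o: str = "h2o_c",
    h: str = "h_c",
    biomass_metabolite: str = "biomass_e",
) -> Reaction:
    """Build the biomass pseudo-reaction from a composition.

    Consumes each monomer i of macromolecule M with coefficient
    ``1000 * mass_fraction(M) * mole_fraction(i) / Mbar(M)`` mmol gDCW^-1
    (``Mbar`` the weighted mean monomer weight), hydrolyzes ``gam`` mmol ATP,
    and produces one unit of the biomass pseudo-metabolite. Total consumed
    monomer mass is 1000 mg per gDCW by construction.
    """
    comp.validate()
    stoich: dict[str, float] = {}
    for macro, fraction in comp.mass_fractions.items():
        if fraction == 0:
            continue
        ratios = comp.monomer_ratios[macro]
        mbar = sum(x * comp.monomer_weights[mid] for mid, x in ratios.items())
        for mid, x in ratios.items():
            if x == 0:
                continue
            # 12 significant digits: far inside the mass-closure tolerance,
            # and short enough to survive any text serialization exactly
            coef = float(f"{1000.0 * fraction * x / mbar:.12g}")
            stoich[mid] = stoich.get(mid, 0.0) - coef
    if comp.gam > 0:
        for mid, sign in ((atp, -1), (h2o, -1), (adp, +1), (pi, +1), (h, +1)):
            stoich[mid] = stoich.get(mid, 0.0) + sign * comp.gam
    stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    return Reaction(
        id=reaction_id, name="Biomass synthesis", stoichiometry=stoich,
        lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="biomass",
        subsystem="Biomass",
    )


def set_ngam(model: MetabolicModel, ngam: float) -> MetabolicModel:
    """Return a copy whose maintenance reaction has ``lower_bound = ngam``,
    forcing the ATP-hydrolysis flux floor."""
    if ngam < 0:
        raise LabfluxError("ngam must be >= 0")
    out = model.copy()
    maint = [r for r in out.reactions if r.kind == "maintenance"]
    if not maint:
        raise LabfluxError("model has no maintenance reaction")
    for r in maint:
        r.lower_bound = ngam
    return out


# --------------------------------------------------------------------------
# File formats
# --------------------------------------------------------------------------

def load_medium_tsv(path: str | Path) -> MediumSpec:
    """Medium TSV: two columns, exchange_id and uptake_mmol_per_gDCW_h."""
    uptakes: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("exchange_id\t"):
            continue
        ex, rate = line.split("\t")[:2]
        uptakes[ex] = float(rate)
    return MediumSpec(uptakes, Path(path).stem)


def save_medium_tsv(medium: MediumSpec, path: str | Path) -> None:
    lines = ["exchange_id\tuptake_mmol_per_gDCW_h"]
    for ex, rate in sorted(medium.uptakes.items()):
        lines.append(f"{ex}\t{rate!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_biomass_composition(path: str | Path) -> BiomassComposition:
    """Biomass composition YAML with keys mass_fractions, monomer_ratios,
    monomer_weights, gam, ngam."""
    data = yaml.safe_load(Path(path).read_text())
    comp = BiomassComposition(
        mass_fractions={k: float(v) for k, v in data["mass_fractions"].items()},
        monomer_ratios={
            macro: {k: float(v) for k, v in ratios.items()}
            for macro, ratios in data["monomer_ratios"].items()
        },
        monomer_weights={k: float(v) for k, v in data["monomer_weights"].items()},
        gam=float(data.get("gam", 0.0)),
        ngam=float(data.get("ngam", 0.0)),
    )
    comp.validate()
    return comp


def save_biomass_composition(comp: BiomassComposition, path: str | Path) -> None:
    data = {
        "mass_fractions": comp.mass_fractions,
        "monomer_ratios": comp.monomer_ratios,
        "monomer_weights": comp.monomer_weights,
        "gam": comp.gam,
        "ngam": comp.ngam,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
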