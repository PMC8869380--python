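import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from labflux.errors import LabfluxError, MediumError
from labflux.fba import solve_fba
from labflux.medium import (
    BiomassComposition, MediumSpec, apply_medium, assemble_biomass, set_ngam,
    validation_medium,
)
from labflux.synthetic import MiniLabSpec, make_mini_lab, mini_lab_composition


def test_apply_medium_sets_uptake_and_closes_the_rest(lab):
    medium = MediumSpec({"EX_glc_e": 6.634, "EX_h2o_e": 1000.0}, "t")
    out = apply_medium(lab.model, medium)
    assert out.reaction("EX_glc_e").lower_bound == -6.634
    assert out.reaction("EX_ala_e").lower_bound == 0.0  # unlisted: closed
    # secretion untouched
    assert out.reaction("EX_lac_e").upper_bound == 1000.0
    # original model unchanged
    assert lab.model.reaction("EX_glc_e").lower_bound == 0.0


def test_empty_medium_closes_all_uptake(lab):
    out = apply_medium(lab.model, MediumSpec({}, "empty"))
    assert all(r.lower_bound == 0.0 for r in out.exchanges)


def test_oxygen_preset_rate(lab):
    assert lab.validation.uptakes["EX_o2_e"] == pytest.approx(1e-10)
    out = apply_medium(lab.model, lab.validation)
    assert out.reaction("EX_o2_e").lower_bound == pytest.approx(-1e-10)


def test_apply_medium_idempotent(lab):
    once = apply_medium(lab.model, lab.omission)
    twice = apply_medium(once, lab.omission)
    assert once == twice


def test_unknown_exchange_listed():
    model, _ = make_mini_lab(MiniLabSpec())
    with pytest.raises(MediumError, match="EX_ghost_e"):
        apply_medium(model, MediumSpec({"EX_ghost_e": 1.0}, "bad"))


def test_negative_uptake_rejected():
    with pytest.raises(MediumError):
        MediumSpec({"EX_glc_e": -1.0})


def test_single_monomer_biomass_coefficient():
    """100% protein of one amino acid at MW 100 gives 1000/100 = 10 mmol/gDCW."""
    comp = BiomassComposition(
        mass_fractions={"protein": 1.0},
        monomer_ratios={"protein": {"aa_c": 1.0}},
        monomer_weights={"aa_c": 100.0},
        gam=0.0,
    )
    rxn = assemble_biomass(comp)
    assert rxn.stoichiometry["aa_c"] == pytest.approx(-10.0)
    assert rxn.stoichiometry["biomass_e"] == 1.0
    assert "atp_c" not in rxn.stoichiometry


def test_gam_appears_as_atp_coefficient():
    comp = BiomassComposition(
        mass_fractions={"protein": 1.0},
        monomer_ratios={"protein": {"aa_c": 1.0}},
        monomer_weights={"aa_c": 100.0},
        gam=49.7,
    )
    rxn = assemble_biomass(comp)
    assert rxn.stoichiometry["atp_c"] == pytest.approx(-49.7)
    assert rxn.stoichiometry["adp_c"] == pytest.approx(49.7)
    assert rxn.stoichiometry["pi_c"] == pytest.approx(49.7)


def test_unnormalized_fractions_rejected():
    comp = BiomassComposition(
        mass_fractions={"protein": 0.7},
        monomer_ratios={"protein": {"aa_c": 1.0}},
        monomer_weights={"aa_c": 100.0},
    )
    with pytest.raises(LabfluxError, match="mass fractions"):
        assemble_biomass(comp)


def test_missing_monomer_weight_rejected():
    comp = BiomassComposition(
        mass_fractions={"protein": 1.0},
        monomer_ratios={"protein": {"aa_c": 1.0}},
        monomer_weights={},
    )
    with pytest.raises(LabfluxError, match="weights"):
        assemble_biomass(comp)


@st.composite
def compositions(draw):
    n_macro = draw(st.integers(1, 4))
    macros = [f"macro{i}" for i in range(n_macro)]
    raw = [draw(st.floats(0.05, 1.0)) for _ in macros]
    total = sum(raw)
    fractions = {m: v / total for m, v in zip(macros, raw)}
    ratios, weights = {}, {}
    counter = 0
    for m in macros:
        k = draw(st.integers(1, 5))
        rw = [draw(st.floats(0.05, 1.0)) for _ in range(k)]
        rs = sum(rw)
        ratios[m] = {}
        for v in rw:
            mid = f"mono{counter}_c"
            counter += 1
            ratios[m][mid] = v / rs
            weights[mid] = draw(st.floats(50.0, 600.0))
    gam = draw(st.floats(0.0, 80.0))
    return BiomassComposition(fractions, ratios, weights, gam=gam)


@given(compositions())
def test_biomass_mass_closure(comp):
    """Any valid composition consumes exactly 1 g monomer mass per gDCW,
    GAM species excluded."""
    rxn = assemble_biomass(comp)
    gam_species = {"atp_c", "adp_c", "pi_c", "h2o_c", "h_c", "biomass_e"}
    consumed_mg = -sum(
        coef * comp.monomer_weights[mid]
        for mid, coef in rxn.stoichiometry.items()
        if mid not in gam_species
    )
    assert consumed_mg == pytest.approx(1000.0, abs=1e-6)


def test_set_ngam(lab):
    out = set_ngam(lab.model, 0.37)
    assert out.reaction("ATPM").lower_bound == 0.37
    relaxed = set_ngam(lab.model, 0.0)
    assert relaxed.reaction("ATPM").lower_bound == 0.0
    chain_like = lab.model.copy()
    for r in chain_like.reactions:
        if r.kind == "maintenance":
            r.kind = "internal"
    with pytest.raises(LabfluxError, match="maintenance"):
        set_ngam(chain_like, 0.37)


def test_growth_non_increasing_in_maintenance(lab):
    """Raising NGAM or GAM can only cost growth."""
    base = apply_medium(lab.model, lab.validation)
    mu_ngam = [solve_fba(set_ngam(base, v)).growth_rate for v in (0.0, 0.37, 5.0)]
    assert mu_ngam[0] >= mu_ngam[1] >= mu_ngam[2]

    growths = []
    for gam in (10.0, 40.0, 70.0):
        spec = MiniLabSpec(gam=gam)
        model, _ = make_mini_lab(spec)
        growths.append(
            solve_fba(apply_medium(model, lab.validation)).growth_rate
        )
    assert growths[0] > growths[1] > growths[2]
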