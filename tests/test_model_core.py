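import numpy as np
import pytest
from hypothesis import given

from labflux.core import (
    MetabolicModel, Metabolite, Reaction, gene_metabolite_adjacency,
    mass_balance_report, model_summary, stoichiometric_matrix, validate_model,
)
from labflux.errors import ModelValidationError
from labflux.gpr import parse_gpr

from conftest import toy_models


def _two_met_model(**rxn_kwargs):
    mets = [Metabolite("A_c", compartment="c"), Metabolite("B_c", compartment="c")]
    rxn = Reaction(id="R1", stoichiometry={"A_c": -1.0, "B_c": 1.0},
                   lower_bound=0.0, **rxn_kwargs)
    biomass = Reaction(id="BIOMASS", stoichiometry={"B_c": -1.0},
                       lower_bound=0.0, kind="biomass")
    return MetabolicModel(metabolites=mets, reactions=[rxn, biomass],
                          genes=list(rxn.genes),
                          objective_reaction_id="BIOMASS")


def test_stoichiometric_matrix_columns():
    model = _two_met_model()
    sm = stoichiometric_matrix(model)
    assert sm.S.shape == (2, 2)
    j = sm.reaction_ids.index("R1")
    col = sm.S[:, j]
    assert col[sm.metabolite_ids.index("A_c")] == -1.0
    assert col[sm.metabolite_ids.index("B_c")] == 1.0


def test_exchange_column_single_entry():
    mets = [Metabolite("A_e", compartment="e"), Metabolite("A_c", compartment="c")]
    rxns = [
        Reaction(id="EX_A_e", stoichiometry={"A_e": -1.0}, kind="exchange"),
        Reaction(id="BIOMASS", stoichiometry={"A_c": -1.0}, lower_bound=0.0,
                 kind="biomass"),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=[],
                           objective_reaction_id="BIOMASS")
    sm = stoichiometric_matrix(model)
    col = sm.S[:, sm.reaction_ids.index("EX_A_e")]
    assert list(col) == [-1.0, 0.0]
    assert np.count_nonzero(col) == 1


@pytest.mark.parametrize(
    "mutate,fragment",
    [
        (lambda m: m.reactions[0].stoichiometry.update({"ghost_c": 1.0}),
         "dangling"),
        (lambda m: setattr(m.reactions[0], "lower_bound", 2000.0), "lower_bound"),
        (lambda m: setattr(m, "objective_reaction_id", "nope"), "objective"),
        (lambda m: setattr(m.reactions[1], "kind", "internal"), "kind"),
        (lambda m: m.metabolites.append(Metabolite("A_c")), "duplicate"),
    ],
)
def test_validation_reports_each_problem(mutate, fragment):
    model = _two_met_model()
    mutate(model)
    with pytest.raises(ModelValidationError, match=fragment):
        validate_model(model)


def test_exchange_invariant_enforced():
    model = _two_met_model()
    model.reactions[0].kind = "exchange"  # touches 2 cytosolic metabolites
    with pytest.raises(ModelValidationError, match="exchange"):
        validate_model(model)


def test_model_summary_counts(lab):
    summary = model_summary(lab.model)
    assert summary["metabolites"] == len(lab.model.metabolites)
    assert summary["reactions"] == len(lab.model.reactions)
    assert summary["genes"] == len(lab.model.genes)
    # reactions with non-empty GPR, independently recounted
    assert summary["gpr_associations"] == sum(
        1 for r in lab.model.reactions if r.gpr is not None
    )
    assert summary["gene_reaction_pairs"] >= summary["gpr_associations"]


def test_model_summary_empty_model():
    model = MetabolicModel()
    assert model_summary(model) == {
        "genes": 0, "metabolites": 0, "reactions": 0,
        "gpr_associations": 0, "gene_reaction_pairs": 0,
    }


def test_adjacency_single_reaction():
    model = _two_met_model(gpr=parse_gpr("g1"))
    adj = gene_metabolite_adjacency(model)
    assert adj["A_c"] == {"g1"} and adj["B_c"] == {"g1"}


def test_adjacency_empty_gpr_contributes_nothing():
    model = _two_met_model()
    assert gene_metabolite_adjacency(model) == {}


def test_adjacency_matches_bruteforce_scan(lab):
    """Adjacency equals an exhaustive scan over (reaction, gene, metabolite)
    triples with the same currency exclusion."""
    from labflux.core import is_currency

    expected: dict[str, set[str]] = {}
    for r in lab.model.reactions:
        for g in r.genes:
            for mid in r.stoichiometry:
                if not is_currency(mid):
                    expected.setdefault(mid, set()).add(g)
    got = gene_metabolite_adjacency(lab.model)
    assert {k: set(v) for k, v in got.items()} == expected
    # never references unknown ids
    all_genes = set(lab.model.genes)
    all_mets = {m.id for m in lab.model.metabolites}
    assert set(got) <= all_mets
    assert set().union(*got.values()) <= all_genes


def test_mass_balance_checker():
    mets = [
        Metabolite("glc_c", compartment="c", formula="C6H12O6"),
        Metabolite("lac_c", compartment="c", formula="C3H6O3"),
        Metabolite("x_c", compartment="c", formula="CH4"),
    ]
    rxns = [
        Reaction(id="SPLIT", stoichiometry={"glc_c": -1.0, "lac_c": 2.0},
                 lower_bound=0.0),
        Reaction(id="BROKEN", stoichiometry={"glc_c": -1.0, "x_c": 1.0},
                 lower_bound=0.0),
        Reaction(id="BIOMASS", stoichiometry={"lac_c": -1.0}, lower_bound=0.0,
                 kind="biomass"),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns, genes=[],
                           objective_reaction_id="BIOMASS")
    report = mass_balance_report(model)
    assert report["SPLIT"] == {}
    assert report["BROKEN"]["C"] == -5.0
    assert "BIOMASS" not in report  # pseudo-reactions are skipped


@given(toy_models())
def test_matrix_dimensions_match_model(model):
    sm = stoichiometric_matrix(model)
    assert sm.S.shape == (len(model.metabolites), len(model.reactions))
    assert sm.metabolite_ids == [m.id for m in model.metabolites]
    assert sm.reaction_ids == [r.id for r in model.reactions]
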