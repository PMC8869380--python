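import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from labflux.bruteforce import enumerate_lp_optimum
from labflux.core import stoichiometric_matrix
from labflux.errors import FitError, LabfluxError
from labflux.fba import (
    fit_gam, percent_error, solve_fba, steady_state_residual,
)
from labflux.medium import apply_medium, validation_medium
from labflux.synthetic import (
    MiniLabSpec, make_mini_lab, make_random_network, make_toy_chain,
    mini_lab_composition, mini_lab_nutrient_classes,
)


@pytest.mark.parametrize("n_steps", [1, 5])
def test_toy_chain_analytic_optimum(n_steps):
    model = make_toy_chain(n_steps, uptake_cap=10.0, yield_per_unit=0.1)
    sol = solve_fba(model)
    assert sol.optimal
    assert sol.growth_rate == pytest.approx(1.0, abs=1e-8)


def test_steady_state_residual_is_tiny(lab):
    sol = solve_fba(apply_medium(lab.model, lab.validation))
    assert sol.optimal
    assert steady_state_residual(apply_medium(lab.model, lab.validation), sol) < 1e-6


def test_bounds_respected(lab):
    constrained = apply_medium(lab.model, lab.validation)
    sol = solve_fba(constrained)
    for r in constrained.reactions:
        v = sol.fluxes[r.id]
        assert r.lower_bound - 1e-9 <= v <= r.upper_bound + 1e-9


def test_infeasible_status_reported():
    model = make_toy_chain(1, 10.0, 0.1)
    # force impossible: biomass floor above what uptake allows
    model.reaction("BIOMASS").lower_bound = 5.0
    sol = solve_fba(model)
    assert sol.status == "infeasible"
    assert np.isnan(sol.growth_rate)


def test_unbounded_status_reported():
    model = make_toy_chain(1, 10.0, 0.1)
    # objective produces from nothing with no finite cap
    model.reaction("BIOMASS").stoichiometry.clear()
    model.reaction("BIOMASS").stoichiometry["biomass_e"] = 1.0
    model.reaction("BIOMASS").upper_bound = float("inf")
    model.reaction("EX_biomass_e").upper_bound = float("inf")
    sol = solve_fba(model)
    assert sol.status == "unbounded"


def test_objective_matches_enumeration_oracle():
    """HiGHS agrees with exhaustive vertex enumeration on random tiny nets."""
    rng = np.random.default_rng(7)
    for _ in range(40):
        net = make_random_network(rng)
        sm = stoichiometric_matrix(net)
        lb = np.array([r.lower_bound for r in net.reactions])
        ub = np.array([r.upper_bound for r in net.reactions])
        c = np.zeros(len(net.reactions))
        c[sm.reaction_ids.index("R0")] = 1.0
        status, expected = enumerate_lp_optimum(sm.S, lb, ub, c)
        sol = solve_fba(net)
        assert sol.status == status == "optimal"
        assert sol.growth_rate == pytest.approx(expected, abs=1e-6)


def test_agrees_with_independent_solver(lab, tmp_path):
    """Cross-check against cobrapy + GLPK reading our own SBML export."""
    cobra = pytest.importorskip("cobra")
    from labflux.io import save_model

    constrained = apply_medium(lab.model, lab.validation)
    path = tmp_path / "m.xml"
    save_model(constrained, path, format="sbml")
    cm = cobra.io.read_sbml_model(str(path))
    cm.solver = "glpk"
    mu_ref = cm.optimize().objective_value
    assert solve_fba(constrained).growth_rate == pytest.approx(mu_ref, abs=1e-6)


@given(st.floats(0.0, 20.0), st.floats(0.0, 5.0))
def test_growth_monotone_in_uptake(extra, delta):
    """Opening an uptake bound further never lowers the optimum."""
    model = make_toy_chain(2, 1.0 + extra, 0.25)
    mu1 = solve_fba(model).growth_rate
    wider = model.copy()
    wider.reaction("EX_nut_e").lower_bound -= delta
    mu2 = solve_fba(wider).growth_rate
    assert mu2 >= mu1 - 1e-9


def test_percent_error():
    assert percent_error(0.151, 0.151) == 0.0
    assert percent_error(0.15, 0.10) == pytest.approx(50.0)
    assert percent_error(0.05, 0.10) == pytest.approx(50.0)
    with pytest.raises(LabfluxError):
        percent_error(0.1, 0.0)


class TestFitGam:
    def _setup(self, gam):
        spec = MiniLabSpec(gam=gam)
        model, _ = make_mini_lab(spec)
        classes = mini_lab_nutrient_classes(spec)
        medium = validation_medium(classes, "EX_glc_e", 6.634)
        comp = mini_lab_composition(spec)
        measured = solve_fba(apply_medium(model, medium)).growth_rate
        return model, comp, medium, measured

    @pytest.mark.parametrize("planted", [12.5, 40.0, 67.25])
    def test_recovers_planted_gam(self, planted):
        model, comp, medium, measured = self._setup(planted)
        fitted = fit_gam(model, comp, medium, measured, bounds=(5.0, 80.0))
        assert fitted == pytest.approx(planted, abs=1e-3)

    def test_boundary_returns_bracket_end(self):
        model, comp, medium, _ = self._setup(5.0)
        measured = solve_fba(apply_medium(model, medium)).growth_rate
        fitted = fit_gam(model, comp, medium, measured, bounds=(5.0, 80.0))
        assert fitted == 5.0

    def test_no_bracket_reports_both_ends(self):
        model, comp, medium, measured = self._setup(40.0)
        with pytest.raises(FitError, match="not bracketed"):
            fit_gam(model, comp, medium, measured * 10, bounds=(5.0, 80.0))

    def test_rejects_nonpositive_measurement(self):
        model, comp, medium, _ = self._setup(40.0)
        with pytest.raises(FitError):
            fit_gam(model, comp, medium, 0.0)
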