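"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from labflux.core import MetabolicModel, Metabolite, Reaction
from labflux.gpr import And, GeneRef, Or
from labflux.medium import (
    carbon_scan_background, omission_medium, validation_medium,
)
from labflux.synthetic import (
    MiniLabSpec, make_mini_lab, mini_lab_composition,
    mini_lab_nutrient_classes, mini_lab_panel,
)

settings.register_profile(
    "labflux",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("labflux")


@pytest.fixture(scope="session")
def lab():
    """The default mini-LAB fixture with its media, panel and composition."""
    spec = MiniLabSpec()
    model, truth = make_mini_lab(spec)
    classes = mini_lab_nutrient_classes(spec)
    return SimpleNamespace(
        spec=spec,
        model=model,
        truth=truth,
        classes=classes,
        panel=mini_lab_panel(),
        composition=mini_lab_composition(spec),
        validation=validation_medium(classes, "EX_glc_e", 6.634),
        omission=omission_medium(classes, "EX_glc_e"),
        scan_background=carbon_scan_background(classes),
    )


# ---------------------------------------------------------------------------
# hypothesis strategies
# ---------------------------------------------------------------------------

_genes = st.sampled_from([f"g{i}" for i in range(1, 9)])


@st.composite
def gpr_trees(draw, depth: int = 2, parent: str | None = None):
    """Normalized GPR trees: operator nodes have >= 2 children and never a
    child of the same operator, matching what the parser produces."""
    if depth == 0:
        return GeneRef(draw(_genes))
    choices = ["gene"]
    if parent != "and":
        choices.append("and")
    if parent != "or":
        choices.append("or")
    kind = draw(st.sampled_from(choices))
    if kind == "gene":
        return GeneRef(draw(_genes))
    n = draw(st.integers(2, 3))
    children = tuple(
        draw(gpr_trees(depth=depth - 1, parent=kind)) for _ in range(n)
    )
    return And(children) if kind == "and" else Or(children)


_coef = (
    st.floats(min_value=-20, max_value=20, allow_nan=False)
    .map(lambda v: float(f"{v:.12g}"))
    .filter(lambda v: abs(v) > 1e-6)
)


@st.composite
def toy_models(draw):
    """Small valid random models exercising every structural feature:
    both compartments, exchanges, GPRs (including empty), orphan genes."""
    n_c = draw(st.integers(1, 4))
    n_e = draw(st.integers(1, 2))
    mets = [Metabolite(f"m{i}_c", f"met {i}", "c") for i in range(n_c)]
    mets += [Metabolite(f"x{i}_e", f"ext {i}", "e", formula=draw(
        st.sampled_from([None, "C6H12O6", "H2O"]))) for i in range(n_e)]
    c_ids = [m.id for m in mets if m.compartment == "c"]
    e_ids = [m.id for m in mets if m.compartment == "e"]
    reactions = []
    for i, eid in enumerate(e_ids):
        reactions.append(Reaction(
            id=f"EX_{eid}", stoichiometry={eid: -1.0},
            lower_bound=draw(st.sampled_from([0.0, -5.0, -1000.0])),
            upper_bound=1000.0, kind="exchange",
        ))
    n_internal = draw(st.integers(1, 4))
    for i in range(n_internal):
        pool = draw(st.lists(st.sampled_from(c_ids + e_ids), min_size=1,
                             max_size=3, unique=True))
        stoich = {mid: draw(_coef) for mid in pool}
        gpr = draw(st.one_of(st.none(), gpr_trees()))
        reactions.append(Reaction(
            id=f"R{i}", stoichiometry=stoich,
            lower_bound=-10.0, upper_bound=10.0, gpr=gpr,
            subsystem=draw(st.sampled_from(["", "Core", "Transport"])),
            kind="internal",
        ))
    reactions.append(Reaction(
        id="BIOMASS", stoichiometry={draw(st.sampled_from(c_ids)): -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="biomass",
    ))
    genes = sorted({g for r in reactions for g in r.genes})
    if draw(st.booleans()):
        genes.append("orphan1")
    return MetabolicModel(
        id="toy", metabolites=mets, reactions=reactions, genes=genes,
        objective_reaction_id="BIOMASS",
    )
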