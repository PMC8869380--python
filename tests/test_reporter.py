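import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from labflux.core import MetabolicModel, Metabolite, Reaction
from labflux.errors import LabfluxError
from labflux.gpr import parse_gpr
from labflux.reporter import (
    filter_degs, read_deg_table, reporter_scores, summarize_routes,
)
from labflux.synthetic import make_deg_table

PERTURBED = ("Starch and sucrose metabolism", "Sugar transport")


def _degs(rows):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "p", "fdr", "fpkm"])


def test_filter_rule_on_known_records():
    df = _degs([
        ("keep", 2.0, 0.001, 0.01, 2.0),
        ("low_fpkm", 3.0, 0.001, 0.01, 0.5),
        ("small_lfc", 1.0, 0.001, 0.01, 2.0),
        ("bad_fdr", -2.0, 0.001, 0.2, 2.0),
    ])
    kept = filter_degs(df)
    assert list(kept["gene"]) == ["keep"]


def test_filter_boundaries_inclusive_exclusive():
    df = _degs([
        ("at_fpkm", 2.0, 0.001, 0.01, 1.0),    # fpkm >= 1: kept
        ("at_lfc", 1.5, 0.001, 0.01, 2.0),     # |lfc| >= 1.5: kept
        ("at_fdr", 2.0, 0.001, 0.05, 2.0),     # fdr < 0.05 strict: dropped
        ("neg_lfc", -1.5, 0.001, 0.01, 2.0),   # absolute value: kept
    ])
    assert set(filter_degs(df)["gene"]) == {"at_fpkm", "at_lfc", "neg_lfc"}


def test_filter_empty_input():
    assert filter_degs(_degs([])).empty


def test_filter_matches_independent_recount():
    rng = np.random.default_rng(11)
    n = 1000
    df = _degs([
        (f"g{i}", rng.normal(0, 2), rng.random(), rng.random(), rng.gamma(2, 2))
        for i in range(n)
    ])
    kept = set(filter_degs(df)["gene"])
    expected = {
        row.gene
        for row in df.itertuples()
        if row.fpkm >= 1.0 and abs(row.log2fc) >= 1.5 and row.fdr < 0.05
    }
    assert kept == expected


def test_read_deg_table_dialect_and_errors(tmp_path):
    p = tmp_path / "degs.tsv"
    p.write_text(
        "gene\tlog2fc\tp_value\tfdr\tfpkm_condition1\tfpkm_condition2\n"
        "gA\t2.0\t0.001\t0.01\t0.5\t3.0\n"
    )
    df = read_deg_table(p)
    assert df.loc[0, "fpkm"] == 3.0  # max of the two conditions
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene\tlog2fc\tp\tfdr\tfpkm\ngA\toops\t0.1\t0.1\t1\n")
    with pytest.raises(LabfluxError, match="line 2"):
        read_deg_table(bad)


def _tiny_model():
    mets = [
        Metabolite("a_c", compartment="c"), Metabolite("b_c", compartment="c"),
        Metabolite("x_c", compartment="c"),
    ]
    rxns = [
        Reaction(id="R1", stoichiometry={"a_c": -1, "b_c": 1},
                 gpr=parse_gpr("g1"), subsystem="S1", lower_bound=0),
        Reaction(id="R2", stoichiometry={"b_c": -1, "x_c": 1},
                 gpr=parse_gpr("g2 or g3"), subsystem="S2", lower_bound=0),
        Reaction(id="BIOMASS", stoichiometry={"x_c": -1}, lower_bound=0,
                 kind="biomass"),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns,
                          genes=["g1", "g2", "g3"],
                          objective_reaction_id="BIOMASS")


def test_uniform_pvalues_give_zero_raw_scores():
    model = _tiny_model()
    scores = reporter_scores(model, {"g1": 0.5, "g2": 0.5, "g3": 0.5}, seed=1)
    assert scores and all(s.z_raw == pytest.approx(0.0) for s in scores)


def test_background_matches_exhaustive_enumeration():
    """For k=1 on a tiny universe the sampled background must match the
    exact enumeration over single-gene draws within Monte-Carlo error."""
    model = _tiny_model()
    gene_p = {"g1": 0.01, "g2": 0.2, "g3": 0.9}
    scores = {s.metabolite: s for s in reporter_scores(
        model, gene_p, n_background=200_000, seed=3)}
    z = norm.isf(np.array(list(gene_p.values())))
    mu_exact, sd_exact = z.mean(), z.std()
    s = scores["a_c"]  # k=1 neighborhood (only g1 touches a_c)
    assert s.k == 1
    z_corr_exact = (s.z_raw - mu_exact) / sd_exact
    assert s.z_corrected == pytest.approx(z_corr_exact, abs=0.02)


def test_clamping_warns_on_degenerate_pvalues():
    model = _tiny_model()
    with pytest.warns(UserWarning, match="clamped"):
        reporter_scores(model, {"g1": 0.0, "g2": 0.5, "g3": 1.0}, seed=1)


def test_deterministic_given_seed(lab):
    degs, _ = make_deg_table(lab.model, PERTURBED, n_null_genes=50, seed=5)
    gene_p = dict(zip(degs["gene"], degs["p"]))
    a = reporter_scores(lab.model, gene_p, seed=9)
    b = reporter_scores(lab.model, gene_p, seed=9)
    assert a == b
    c = reporter_scores(lab.model, gene_p, seed=10)
    # another seed perturbs only the background correction, and only a little
    za = {s.metabolite: s.z_corrected for s in a}
    zc = {s.metabolite: s.z_corrected for s in c}
    drift = max(abs(za[m] - zc[m]) for m in za)
    assert 0 < drift < 0.3


def test_planted_pathway_tops_the_ranking(lab):
    degs, truth = make_deg_table(lab.model, PERTURBED, n_null_genes=100, seed=2)
    gene_p = dict(zip(degs["gene"], degs["p"]))
    scores = reporter_scores(lab.model, gene_p, seed=2)
    top = {s.metabolite for s in scores[: len(truth.reporter_metabolites)]}
    assert top == truth.reporter_metabolites


def test_permutation_destroys_enrichment(lab):
    """Shuffling gene labels reduces planted-metabolite recovery to chance."""
    degs, truth = make_deg_table(lab.model, PERTURBED, n_null_genes=100, seed=2)
    planted = truth.reporter_metabolites
    genes = list(degs["gene"])
    pvals = list(degs["p"])
    rng = np.random.default_rng(0)
    recoveries = []
    for i in range(20):
        shuffled = dict(zip(genes, rng.permutation(pvals)))
        scores = reporter_scores(lab.model, shuffled, seed=i)
        top = {s.metabolite for s in scores[: len(planted)]}
        recoveries.append(len(top & planted) / len(planted))
    assert np.mean(recoveries) < 0.5


def test_score_invariant_to_duplicate_reactions(lab):
    """Adjacency is a set: duplicating a reaction (same genes, same
    metabolites) must not change any score."""
    degs, _ = make_deg_table(lab.model, PERTURBED, seed=4)
    gene_p = dict(zip(degs["gene"], degs["p"]))
    doubled = lab.model.copy()
    dup = doubled.reaction("SUCP").copy()
    dup.id = "SUCP_copy"
    doubled.reactions.append(dup)
    assert reporter_scores(lab.model, gene_p, seed=6) == reporter_scores(
        doubled, gene_p, seed=6
    )


def test_summarize_routes(lab):
    degs, truth = make_deg_table(lab.model, PERTURBED, seed=2)
    gene_p = dict(zip(degs["gene"], degs["p"]))
    scores = reporter_scores(lab.model, gene_p, seed=2)
    assert summarize_routes(scores, lab.model, top_n=0).empty
    table = summarize_routes(scores, lab.model, top_n=5)
    assert len(table) == 5
    joined = " ".join(table["subsystems"])
    assert any(sub in joined for sub in truth.perturbed_subsystems)


def test_single_subsystem_toy_routes():
    model = _tiny_model()
    for r in model.reactions:
        r.subsystem = "Only"
    scores = reporter_scores(model, {"g1": 0.01, "g2": 0.3, "g3": 0.6}, seed=0)
    table = summarize_routes(scores, model, top_n=10)
    assert set(table["subsystems"]) == {"Only"}
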