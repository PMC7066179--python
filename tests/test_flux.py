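"""FBA, polytope sampling and the blockage screen's statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitosep.flux_screen import (block_and_constrain, cohens_d,
                                 compare_exports, gene_deletion_screen,
                                 rank_blockages, ranksum_p, sample_fluxes,
                                 BlockageComparison, FluxSampleSet)
from mitosep.metabolic_model import (MetabolicModel, Reaction, evaluate_gpr,
                                     fba_max, genes_in_gpr, read_sbml,
                                     write_sbml)
from mitosep.simulate import gen_toy_metabolic_model


def chain_model(bounds):
    """M0 -> M1 -> ... linear chain; objective is the last reaction."""
    mets = [f"M{i}" for i in range(len(bounds) - 1)]
    rxns = []
    for i, b in enumerate(bounds):
        stoich = {}
        if i > 0:
            stoich[mets[i - 1]] = -1
        if i < len(mets):
            stoich[mets[i]] = 1
        rxns.append(Reaction(f"R{i}", stoich, 0.0, float(b)))
    return MetabolicModel("chain", mets, rxns, objective_id=f"R{len(bounds)-1}")


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def test_three_reaction_chain_bottleneck():
    m = chain_model([5, 10, 7])
    res = fba_max(m)
    assert res.status == "optimal"
    assert res.objective_value == pytest.approx(5.0)


def test_chain_optimum_is_min_bound_random_cases():
    rng = np.random.default_rng(0)
    for _ in range(30):
        k = int(rng.integers(2, 11))
        bounds = rng.uniform(0.5, 20.0, size=k)
        res = fba_max(chain_model(bounds))
        assert res.objective_value == pytest.approx(bounds.min(), rel=1e-6)


def test_zero_upper_bound_objective():
    m = chain_model([5, 10, 7])
    m.reaction("R2").upper_bound = 0.0
    assert fba_max(m).objective_value == pytest.approx(0.0)


def test_infeasible_model_reported_not_zero():
    m = MetabolicModel(
        "bad", ["A"],
        [Reaction("in", {"A": 1}, 1.0, 2.0)],  # A produced, never consumed
        objective_id="in")
    assert fba_max(m).status == "infeasible"


def test_toy_optimum_matches_cobra_oracle(tmp_path):
    cobra = pytest.importorskip("cobra")
    m = gen_toy_metabolic_model()
    path = str(tmp_path / "toy.xml")
    write_sbml(m, path)
    cm = cobra.io.read_sbml_model(path)
    cm.objective = "OF_ATP_MitoCore"
    assert fba_max(m).objective_value == pytest.approx(
        cm.optimize().objective_value, rel=1e-6)


# ---------------------------------------------------------------------------
# model I/O and validation
# ---------------------------------------------------------------------------

def test_sbml_round_trip_preserves_structure(tmp_path):
    m = gen_toy_metabolic_model()
    path = str(tmp_path / "toy.xml")
    write_sbml(m, path)
    m2 = read_sbml(path, lactate_export_id="L_LACt2r",
                   succinate_export_id="SUMt_MitoCore")
    assert set(m2.metabolites) == set(m.metabolites)
    assert m2.reaction_ids == m.reaction_ids
    for rid in m.reaction_ids:
        a, b = m.reaction(rid), m2.reaction(rid)
        assert a.metabolites == b.metabolites
        assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        assert genes_in_gpr(a.gpr) == genes_in_gpr(b.gpr)
    assert m2.objective_id == "OF_ATP_MitoCore"


def test_json_round_trip_is_stable():
    m = gen_toy_metabolic_model()
    m2 = MetabolicModel.from_json(m.to_json())
    assert MetabolicModel.from_json(m2.to_json()).to_json() == m2.to_json()
    assert fba_max(m2).objective_value == pytest.approx(
        fba_max(m).objective_value)


def test_unknown_objective_id_rejected():
    with pytest.raises(ValueError, match="objective"):
        MetabolicModel("m", ["A"], [Reaction("r", {"A": 1}, 0, 1)],
                       objective_id="missing")


def test_toy_metabolites_are_all_connected():
    """Every metabolite has a producer and a consumer (incl. exchanges)."""
    m = gen_toy_metabolic_model()
    produced, consumed = set(), set()
    for r in m.reactions:
        for met, coeff in r.metabolites.items():
            if coeff > 0 or r.lower_bound < 0:
                produced.add(met)
            if coeff < 0 or r.lower_bound < 0:
                consumed.add(met)
    assert produced == set(m.metabolites)
    assert consumed == set(m.metabolites)


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("expr,ko,expect", [
    ("gA", {"gA"}, False),
    ("gA", {"gB"}, True),
    ("gA and gB", {"gA"}, False),
    ("gA or gB", {"gA"}, True),
    ("gA or gB", {"gA", "gB"}, False),
    ("(gA and gB) or gC", {"gA"}, True),
    ("(gA and gB) or gC", {"gA", "gC"}, False),
    ("", {"gA"}, True),
])
def test_gpr_evaluation(expr, ko, expect):
    assert evaluate_gpr(expr, ko) is expect


def test_malformed_gpr_raises():
    with pytest.raises(ValueError):
        evaluate_gpr("gA and (gB", {"gA"})


# ---------------------------------------------------------------------------
# blocking and the ATP constraint
# ---------------------------------------------------------------------------

def test_blocking_irrelevant_leak_keeps_capacity():
    m = gen_toy_metabolic_model()
    base = fba_max(m, "OF_ATP_MitoCore").objective_value
    cm = block_and_constrain(m, "LEAK")
    assert cm.status == "ok"
    assert cm.atp_capacity == pytest.approx(base, rel=1e-6)


def test_blocking_glucose_uptake_collapses_atp():
    cm = block_and_constrain(gen_toy_metabolic_model(), "EX_glc")
    assert cm.status == "collapses_atp"


def test_blocking_ciii_lowers_capacity_strictly():
    m = gen_toy_metabolic_model()
    base = fba_max(m).objective_value
    cm = block_and_constrain(m, "CIII")
    assert cm.status == "ok"
    assert cm.atp_capacity < base
    obj = cm.model.reaction("OF_ATP_MitoCore")
    assert obj.lower_bound == pytest.approx(0.9 * cm.atp_capacity)


def test_blocking_ciii_lactate_export_and_glycolysis_kills_atp():
    cm = block_and_constrain(gen_toy_metabolic_model(),
                             ["CIII", "L_LACt2r", "GLYC"])
    # no glycolytic ATP, no respiration: no ATP route remains
    assert cm.status == "collapses_atp"


def test_blocking_the_objective_is_a_collapse_not_a_crash():
    cm = block_and_constrain(gen_toy_metabolic_model(), "OF_ATP_MitoCore")
    assert cm.status == "collapses_atp"


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def one_dof_model():
    return MetabolicModel(
        "pipe", ["A"],
        [Reaction("in", {"A": 1}, 0, 1), Reaction("out", {"A": -1}, 0, 1)],
        objective_id="out")


def triangle_model():
    return MetabolicModel(
        "tri", ["A"],
        [Reaction("in1", {"A": 1}, 0, 1), Reaction("in2", {"A": 1}, 0, 1),
         Reaction("out", {"A": -1}, 0, 1)],
        objective_id="out")


def test_one_dof_uniform_moments():
    s = sample_fluxes(one_dof_model(), n=400, seed=3, warmup=100, thinning=5)
    x = s.samples["in"].to_numpy()
    assert x.min() >= 0 and x.max() <= 1
    se = (1 / np.sqrt(12)) / np.sqrt(len(x))
    # thinned MCMC samples are weakly correlated; allow 3 sigma on the
    # independent-sample standard error times a mixing margin
    assert abs(x.mean() - 0.5) < 3 * se * 3


def test_triangle_marginal_matches_analytic_density():
    s = sample_fluxes(triangle_model(), n=600, seed=9, warmup=200, thinning=10)
    x = s.samples["in1"].to_numpy()
    # marginal of a uniform triangle {x+y<=1}: CDF(x) = 1 - (1-x)^2
    res = stats.kstest(x, lambda t: 1 - (1 - np.clip(t, 0, 1)) ** 2)
    assert res.pvalue > 0.01


def test_samples_satisfy_all_constraints():
    m = gen_toy_metabolic_model()
    cm = block_and_constrain(m, "CIII")
    s = sample_fluxes(cm.model, n=200, seed=1, warmup=200, thinning=10)
    S = cm.model.stoichiometric_matrix()
    lb, ub = cm.model.bounds()
    V = s.samples.to_numpy()
    assert np.abs(S @ V.T).max() < 1e-6
    assert (V >= lb - 1e-9).all() and (V <= ub + 1e-9).all()
    atp = s.samples["OF_ATP_MitoCore"].to_numpy()
    assert (atp >= 0.9 * cm.atp_capacity - 1e-9).all()


def test_single_point_polytope_is_an_error():
    m = one_dof_model()
    m.reaction("in").lower_bound = 1.0   # forces in = out = 1 exactly
    with pytest.raises(ValueError, match="single point|no interior|empty"):
        sample_fluxes(m, n=10, seed=0, warmup=10, thinning=1)


def test_sampling_is_seed_deterministic():
    a = sample_fluxes(triangle_model(), n=50, seed=4, warmup=50, thinning=5)
    b = sample_fluxes(triangle_model(), n=50, seed=4, warmup=50, thinning=5)
    pd.testing.assert_frame_equal(a.samples, b.samples)


# ---------------------------------------------------------------------------
# comparison statistics
# ---------------------------------------------------------------------------

def test_cohens_d_antisymmetry_and_shift():
    rng = np.random.default_rng(2)
    x = rng.normal(size=200)
    y = rng.normal(size=200)
    d_xy, _ = cohens_d(x, y)
    d_yx, _ = cohens_d(y, x)
    assert d_xy == pytest.approx(-d_yx)
    c = 1.7
    d_shift, _ = cohens_d(x, x + c)
    pooled_sd = x.std(ddof=1)
    assert d_shift == pytest.approx(-c / pooled_sd)


def test_cohens_d_degenerate_zero_variance():
    d, degenerate = cohens_d(np.ones(5), np.ones(5))
    assert d == 0.0 and degenerate


def test_ranksum_exact_matches_enumeration():
    x = np.array([1.0, 2.0, 3.0, 10.0])
    y = np.array([4.0, 5.0, 6.0, 7.0])
    p = ranksum_p(x, y)
    # enumerate all 4-subsets of the pooled values as the "x" group
    pooled = np.concatenate([x, y])
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    n1, n2 = len(x), len(y)
    u_all = []
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = pooled[list(idx)]
        ranks = stats.rankdata(pooled)
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        u_all.append(u)
    u_all = np.array(u_all)
    lo, hi = min(u_obs, n1 * n2 - u_obs), max(u_obs, n1 * n2 - u_obs)
    p_enum = float(np.mean((u_all <= lo) | (u_all >= hi)))
    assert p == pytest.approx(p_enum)


def test_identical_sample_sets_give_null_comparison():
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"lac": rng.normal(size=100), "suc": rng.normal(size=100)})
    a = FluxSampleSet(df, 0, "a")
    b = FluxSampleSet(df.copy(), 0, "b")
    c = compare_exports(a, b, "lac", "suc")
    assert c.d_lactate == pytest.approx(0.0)
    assert c.p_lactate == pytest.approx(1.0)


def test_rank_blockages_discards_and_orders():
    comps = [BlockageComparison("A", 1.0, 1.0, 0.01, 0.01),
             BlockageComparison("B", 2.0, -0.1, 0.01, 0.01),
             BlockageComparison("C", 0.5, 0.4, 0.01, 0.01)]
    retained, discarded = rank_blockages(comps)
    assert [c.target_id for c in retained] == ["A", "C"]
    assert [c.rank for c in retained] == [1, 2]
    assert [c.target_id for c in discarded] == ["B"]


def test_all_negative_input_empty_ranking():
    comps = [BlockageComparison("A", -1.0, 1.0, 0.5, 0.5),
             BlockageComparison("B", 1.0, -1.0, 0.5, 0.5)]
    retained, discarded = rank_blockages(comps)
    assert retained == [] and len(discarded) == 2


# ---------------------------------------------------------------------------
# gene deletions
# ---------------------------------------------------------------------------

def test_single_gene_gpr_equals_direct_reaction_block():
    m = gen_toy_metabolic_model()
    direct = block_and_constrain(m, "CIV")
    by_gene_targets = [r.id for r in m.reactions
                       if r.gpr.strip() and not evaluate_gpr(r.gpr, {"gCIV"})]
    assert by_gene_targets == ["CIV"]
    via_gene = block_and_constrain(m, by_gene_targets)
    assert via_gene.atp_capacity == pytest.approx(direct.atp_capacity)


def test_or_rule_with_live_partner_blocks_nothing():
    m = gen_toy_metabolic_model()
    blocked = [r.id for r in m.reactions
               if r.gpr.strip() and not evaluate_gpr(r.gpr, {"gCV_a"})]
    assert blocked == []


def test_and_rule_blocks_with_either_gene():
    m = gen_toy_metabolic_model()
    for gene in ("gCIII_1", "gCIII_2"):
        blocked = [r.id for r in m.reactions
                   if r.gpr.strip() and not evaluate_gpr(r.gpr, {gene})]
        assert blocked == ["CIII"]


def test_gene_screen_top_deletion_cuts_the_respiratory_chain():
    """Deleting a CIII (or the polytope-equivalent CIV) gene ranks top."""
    m = gen_toy_metabolic_model()
    result = gene_deletion_screen(
        m, genes=["gCIII_1", "gCIV", "gCII", "gLDH", "gPC"],
        n_samples=400, seed=3, warmup=400, thinning=15)
    top = result.ranking.iloc[0]["target_id"]
    assert top in {"gCIII_1", "gCIV"}
    assert "gCII" not in set(result.ranking["target_id"])  # negative d_lactate


def test_gene_screen_flags_no_effect_genes():
    m = gen_toy_metabolic_model()
    result = gene_deletion_screen(m, genes=["gCV_a", "not_a_gene"],
                                  n_samples=30, seed=0, warmup=50, thinning=2)
    flagged = {c.target_id for c in result.comparisons if c.degenerate}
    assert {"gCV_a", "not_a_gene"} <= flagged
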