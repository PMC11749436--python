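import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy.special import logit

from oracles import (
    direct_mple,
    dyad_change_stats,
    global_statistic,
    naive_dyad_table,
)
from psnet.errors import ConfigError, EstimationError, SeparationWarning
from psnet.ergm import (
    ErgmFit,
    TermSpec,
    build_design,
    change_statistic,
    dyad_covariates,
    edges,
    fit_model_sequence,
    fit_mple,
    nodefactor,
    nodematch,
)
from psnet.synthetic_data import sample_ergm_network
import pandas as pd

from conftest import random_attributed_graph


def test_change_statistic_examples():
    attrs = {
        "u": {"occupation_group": "nurse", "municipality": "A"},
        "v": {"occupation_group": "nurse", "municipality": "B"},
        "w": {"occupation_group": "physician", "municipality": "A"},
    }
    nf = nodefactor("occupation_group", "physician")
    assert change_statistic(nf, ("u", "v"), attrs, level="nurse") == 2
    assert change_statistic(nf, ("u", "w"), attrs, level="nurse") == 1
    assert change_statistic(nf, ("w", "w"), attrs, level="nurse") == 0
    assert change_statistic(nodematch("municipality"), ("u", "v"), attrs) == 0
    assert change_statistic(nodematch("municipality"), ("u", "w"), attrs) == 1
    assert change_statistic(edges(), ("u", "v"), attrs) == 1
    with pytest.raises(ConfigError):
        change_statistic(nodefactor("missing_attr"), ("u", "v"), attrs, level="x")


def test_change_statistic_equals_global_statistic_difference():
    g = random_attributed_graph(3, n=6, p=0.5)
    nodes = sorted(g.nodes)
    columns = [
        ("edges",),
        ("nodefactor", "occupation_group", "nurse"),
        ("nodematch", "municipality"),
    ]
    terms_and_levels = [
        (edges(), None),
        (nodefactor("occupation_group", "physician"), "nurse"),
        (nodematch("municipality"), None),
    ]
    attrs = {n: g.nodes[n] for n in nodes}
    for u, v in combinations(nodes, 2):
        for col, (term, level) in zip(columns, terms_and_levels):
            with_tie = g.copy()
            with_tie.add_edge(u, v)
            without = g.copy()
            if without.has_edge(u, v):
                without.remove_edge(u, v)
            diff = global_statistic(with_tie, col) - global_statistic(without, col)
            assert change_statistic(term, (u, v), attrs, level=level) == diff


def test_design_three_nodes_edges_only():
    g = nx.Graph()
    g.add_nodes_from([1, 2, 3])
    g.add_edge(1, 2)
    design = build_design(g, [edges()])
    assert design.n_dyads == 3
    assert design.X.tolist() == [[1.0]]
    assert design.ties.tolist() == [1.0]
    assert design.absent.tolist() == [2.0]


def test_design_pattern_bound_two_by_two_groups():
    g = nx.Graph()
    for i, grp in enumerate(["a", "a", "b", "b"]):
        g.add_node(i, grp=grp)
    g.add_edge(0, 1)
    design = build_design(g, [edges(), nodematch("grp")])
    assert design.X.shape[0] <= 2  # patterns: match / no-match
    assert design.ties.sum() + design.absent.sum() == 6


def test_design_matches_naive_dyad_enumeration():
    g = random_attributed_graph(12, n=40, p=0.15)
    terms = [edges(), nodefactor("occupation_group"), nodematch("municipality")]
    design = build_design(g, terms)
    # rebuild column descriptors from the fitted labels
    columns = []
    for lab in design.labels:
        parts = lab.split(".")
        if parts[0] == "edges":
            columns.append(("edges",))
        elif parts[0] == "nodefactor":
            columns.append(("nodefactor", parts[1], ".".join(parts[2:])))
        else:
            columns.append(("nodematch", parts[1]))
    X, ties = naive_dyad_table(g, columns)
    assert X.shape[0] == design.n_dyads
    # aggregate the naive table and compare pattern counts
    seen = {}
    for row, t in zip(map(tuple, X), ties):
        a, b = seen.get(row, (0, 0))
        seen[row] = (a + t, b + (1 - t))
    got = {tuple(r): (t, a) for r, t, a in
           zip(map(tuple, design.X), design.ties, design.absent)}
    assert seen == got


def test_nodefactor_reference_level_omitted_from_design():
    g = random_attributed_graph(8, n=15, p=0.3)
    design = build_design(g, [edges(), nodefactor("occupation_group",
                                                  "physician")])
    assert "nodefactor.occupation_group.physician" not in design.labels
    assert "nodefactor.occupation_group.nurse" in design.labels


@pytest.mark.parametrize("n, e", [(10, 20), (30, 60), (1566, 145105)])
def test_edges_only_fit_has_closed_form(n, e):
    g = nx.gnm_random_graph(n, e, seed=1)
    fit = fit_mple(build_design(g, [edges()]))
    d = n * (n - 1) / 2
    assert fit.theta[0] == pytest.approx(logit(e / d), abs=1e-8)
    assert fit.odds_ratios[0] == pytest.approx(e / (d - e), rel=1e-8)


def test_half_dense_graph_gives_odds_ratio_one():
    g = nx.Graph()
    g.add_nodes_from(range(4))
    g.add_edges_from([(0, 1), (1, 2), (2, 3)])  # 3 of 6 dyads tied
    fit = fit_mple(build_design(g, [edges()]))
    assert fit.theta[0] == pytest.approx(0.0, abs=1e-10)
    assert fit.odds_ratios[0] == pytest.approx(1.0, abs=1e-10)


def test_fit_matches_direct_likelihood_maximisation():
    g = random_attributed_graph(21, n=7, p=0.5,
                                attributes={"grp": ["a", "b"]})
    g.add_edges_from([(0, 1), (2, 3)])
    design = build_design(g, [edges(), nodematch("grp")])
    fit = fit_mple(design)
    theta_oracle = direct_mple(design.X, design.ties, design.absent)
    assert fit.theta == pytest.approx(theta_oracle, abs=1e-6)


def test_fit_matches_statsmodels_glm():
    import statsmodels.api as sm

    g = random_attributed_graph(5, n=30, p=0.25)
    design = build_design(
        g, [edges(), nodefactor("occupation_group"), nodematch("municipality")]
    )
    fit = fit_mple(design)
    glm = sm.GLM(
        np.column_stack([design.ties, design.absent]),
        design.X,
        family=sm.families.Binomial(),
    ).fit()
    assert fit.theta == pytest.approx(glm.params, abs=1e-6)
    assert fit.se == pytest.approx(glm.bse, rel=1e-4)
    # GLM's llf carries the binomial coefficient of each grouped pattern;
    # the dyad-level Bernoulli log-likelihood omits that constant
    from scipy.special import gammaln

    m = design.ties + design.absent
    const = float(np.sum(gammaln(m + 1) - gammaln(design.ties + 1)
                         - gammaln(design.absent + 1)))
    assert fit.loglik == pytest.approx(glm.llf - const, abs=1e-6)


def test_aggregated_and_dyad_level_fits_agree():
    g = random_attributed_graph(14, n=25, p=0.3)
    terms = [edges(), nodematch("municipality")]
    design = build_design(g, terms)
    nodes = sorted(g.nodes)
    attrs = {n: g.nodes[n] for n in nodes}
    X, labels, iu, ju = dyad_covariates(nodes, attrs, terms)
    tie = np.array([g.has_edge(nodes[i], nodes[j]) for i, j in zip(iu, ju)],
                   dtype=float)
    from psnet.ergm import DyadDesign

    naive = DyadDesign(X=X.astype(float), ties=tie, absent=1.0 - tie,
                       labels=labels, n_nodes=len(nodes))
    assert fit_mple(design).theta == pytest.approx(fit_mple(naive).theta,
                                                   abs=1e-8)


def test_score_equations_hold_at_optimum():
    g = random_attributed_graph(2, n=35, p=0.2)
    terms = [edges(), nodefactor("occupation_group"), nodematch("municipality"),
             nodematch("service_group")]
    design = build_design(g, terms)
    fit = fit_mple(design)
    from scipy.special import expit

    p = expit(design.X @ fit.theta)
    fitted = design.X.T @ ((design.ties + design.absent) * p)
    observed = design.observed_statistics()
    assert fitted == pytest.approx(observed, rel=1e-8)


def test_bic_closed_forms():
    fit = ErgmFit(labels=["edges"], theta=np.array([0.0]),
                  se=np.array([1.0]), loglik=0.0, n_dyads=3,
                  converged=True, n_iter=1, separated=np.array([False]))
    assert fit.bic == pytest.approx(math.log(3))

    g = nx.gnm_random_graph(40, 120, seed=2)
    f = fit_mple(build_design(g, [edges()]))
    d = 40 * 39 / 2
    phat = 120 / d
    ll = d * (phat * math.log(phat) + (1 - phat) * math.log(1 - phat))
    assert f.loglik == pytest.approx(ll, rel=1e-10)
    assert f.bic == pytest.approx(-2 * ll + math.log(d), rel=1e-10)


def test_bic_rewards_true_signal_and_penalises_noise():
    attrs = pd.DataFrame(
        {"grp": ["a"] * 60 + ["b"] * 60,
         "noise": ["x", "y"] * 60},
        index=[f"n{i:03d}" for i in range(120)],
    )
    g = sample_ergm_network(attrs, [-2.0, 1.2], [edges(), nodematch("grp")],
                            seed=17)
    bic_null = fit_mple(build_design(g, [edges()])).bic
    bic_signal = fit_mple(build_design(g, [edges(), nodematch("grp")])).bic
    bic_noise = fit_mple(build_design(g, [edges(), nodematch("noise")])).bic
    assert bic_signal < bic_null
    assert bic_noise > bic_null


def test_separation_flagged_with_infinite_sentinel():
    g = nx.Graph()
    for i, grp in enumerate(["a"] * 4 + ["b"] * 4):
        g.add_node(i, grp=grp)
    for i, j in combinations(range(4), 2):
        g.add_edge(i, j)
    for i, j in combinations(range(4, 8), 2):
        g.add_edge(i, j)
    with pytest.warns(SeparationWarning):
        fit = fit_mple(build_design(g, [edges(), nodematch("grp")]))
    assert np.isinf(fit.theta[fit.separated]).all()


def test_collinear_terms_raise_naming_them():
    g = random_attributed_graph(4, n=10, p=0.4)
    with pytest.raises(EstimationError, match="nodematch.municipality"):
        fit_mple(build_design(g, [edges(), nodematch("municipality"),
                                  nodematch("municipality")]))


def test_degenerate_empty_and_complete_graphs_rejected():
    with pytest.raises(EstimationError):
        fit_mple(build_design(nx.empty_graph(5), [edges()]))
    with pytest.raises(EstimationError):
        fit_mple(build_design(nx.complete_graph(5), [edges()]))


def test_missing_node_attribute_is_config_error():
    g = nx.gnm_random_graph(6, 5, seed=0)
    with pytest.raises(ConfigError):
        build_design(g, [edges(), nodematch("municipality")])


def test_contrast_invariance_under_reference_change():
    from scipy.special import expit

    g = random_attributed_graph(6, n=20, p=0.35)
    probs = []
    for ref in ("nurse", "physician"):
        design = build_design(
            g, [edges(), nodefactor("occupation_group", ref)]
        )
        fit = fit_mple(design)
        nodes = sorted(g.nodes)
        attrs = {n: g.nodes[n] for n in nodes}
        X, _, _, _ = dyad_covariates(
            nodes, attrs, [edges(), nodefactor("occupation_group", ref)]
        )
        probs.append(expit(X @ fit.theta))
    assert probs[0] == pytest.approx(probs[1], abs=1e-8)


def test_model_sequence_recovers_generated_homophily():
    rng = np.random.default_rng(30)
    n = 150
    attrs = pd.DataFrame(
        {
            "municipality": rng.choice(["A", "B", "F"], n, p=[0.25, 0.25, 0.5]),
            "occupation_group": rng.choice(["physician", "nurse"], n),
            "service_group": rng.choice(["outpatient", "other"], n),
        },
        index=[f"h{i:03d}" for i in range(n)],
    )
    g = sample_ergm_network(
        attrs, [-2.0, 1.5], [edges(), nodematch("municipality")], seed=8
    )
    result = fit_model_sequence(g)
    fit2 = result.fits[1]
    j = fit2.labels.index("nodematch.municipality")
    lo, hi = fit2.ci95
    assert fit2.odds_ratios[j] > 1.0
    assert lo[j] > 1.0  # CI excludes 1 at this sample size
    # reference rows are absent from the design (largest categories)
    assert "nodefactor.municipality.F" not in fit2.labels


def test_model_sequence_on_permuted_attributes_prefers_null():
    rng = np.random.default_rng(44)
    n = 120
    attrs = pd.DataFrame(
        {
            "municipality": rng.choice(["A", "B"], n),
            "occupation_group": rng.choice(["physician", "nurse"], n),
            "service_group": rng.choice(["outpatient", "other"], n),
        },
        index=[f"h{i:03d}" for i in range(n)],
    )
    g = sample_ergm_network(attrs, [-1.5], [edges()], seed=9)  # no homophily
    result = fit_model_sequence(g)
    for fit in result.fits[1:]:
        for lab, orx, (lo, hi) in zip(fit.labels, fit.odds_ratios,
                                      zip(*fit.ci95)):
            if lab.startswith("nodematch"):
                assert lo < 1.0 < hi  # CI covers no-homophily
    assert result.best_model() == 1


def test_comparison_table_layout():
    g = random_attributed_graph(2, n=25, p=0.3)
    result = fit_model_sequence(g)
    table = result.comparison_table()
    assert list(table.columns) == ["model_1", "model_2", "model_3", "model_4"]
    assert table.loc["edges", "model_1"] != ""
    assert table.index[-1] == "BIC"
    assert (table.loc["nodematch.municipality", "model_1"] == "")
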