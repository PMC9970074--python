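"""Network construction: pruning, strengths, layout, export round trips."""

import numpy as np
import pytest

from sdmnet import (
    SkillsNetwork,
    build_physician_network,
    build_population_network,
    export_network,
    import_network,
    layout_network,
    prune_edges,
    true_edge_weights,
)
from sdmnet.networks import average_physician_network


def _toy_network(weights, mask, activation=None):
    K = 9
    W = np.zeros((K, K))
    M = np.zeros((K, K), dtype=bool)
    for (k, j), w in weights.items():
        W[k - 1, j - 1] = w
    for k, j in mask:
        M[k - 1, j - 1] = True
    act = np.full(K, 3.0) if activation is None else np.asarray(activation)
    return SkillsNetwork(
        label="toy",
        weights=W,
        mask=M,
        ci_low=W - 0.1,
        ci_high=W + 0.1,
        activation=act,
        level=0.95,
    )


def test_prune_edges_trivial_cases():
    retained = prune_edges(np.full(1000, 0.3))
    assert retained is True or retained == True  # noqa: E712 constant interval
    sym = np.random.default_rng(0).normal(0, 1, 1000)
    assert not prune_edges(sym - sym.mean())


def test_prune_edges_quantile_oracle():
    # Constructed sample whose empirical 2.5% quantile is negative while
    # the bulk is positive: pruned at 95%, and consistent with np.quantile.
    draws = np.concatenate([np.linspace(-0.02, -0.001, 40), np.linspace(0.01, 0.40, 960)])
    lo, hi = np.quantile(draws, [0.025, 0.975])
    assert lo < 0 < hi
    assert not prune_edges(draws, 0.95)
    # the same sample with the negative tail removed is retained
    pos = np.linspace(0.01, 0.40, 1000)
    assert prune_edges(pos, 0.95)


def test_prune_edges_validation():
    with pytest.raises(ValueError, match="500"):
        prune_edges(np.ones(100))
    with pytest.raises(ValueError, match="level"):
        prune_edges(np.ones(600), level=1.5)


def test_prune_monotonicity_on_fitted_edges(small_fits):
    """Nested equal-tailed intervals: every edge pruned at 0.95 is pruned
    at 0.99 (equivalently retained at 0.99 implies retained at 0.95)."""
    for fit in small_fits.values():
        for k in fit.predictor_skills:
            d = fit.population_slope_draws(k)
            if prune_edges(d, 0.99):
                assert prune_edges(d, 0.95)


def test_toy_strength_sums():
    net = _toy_network(
        weights={(1, 2): 0.5, (1, 3): 0.3, (4, 5): 9.9},
        mask=[(1, 2), (1, 3)],  # the 4->5 edge is pruned
    )
    assert net.outstrength[0] == pytest.approx(0.8)
    assert net.instrength[1] == pytest.approx(0.5)
    assert net.instrength[2] == pytest.approx(0.3)
    # pruned edges contribute zero to both strengths
    assert net.outstrength[3] == 0.0 and net.instrength[4] == 0.0


def test_all_edges_pruned_zero_strengths():
    net = _toy_network(weights={(1, 2): 0.5, (3, 4): -0.2}, mask=[])
    assert np.all(net.outstrength == 0.0)
    assert np.all(net.instrength == 0.0)
    assert np.all(net.activation == 3.0)  # activation untouched by pruning


def test_strength_additivity():
    net = _toy_network(
        weights={(1, 2): 0.5, (1, 3): 0.3, (2, 3): 0.4},
        mask=[(1, 2), (1, 3), (2, 3)],
    )
    before_out = net.outstrength.copy()
    before_in = net.instrength.copy()
    net.mask[0, 2] = False  # remove retained edge 1 -> 3 (weight 0.3)
    assert net.outstrength[0] == pytest.approx(before_out[0] - 0.3)
    assert net.instrength[2] == pytest.approx(before_in[2] - 0.3)
    # nothing else changes
    assert np.allclose(np.delete(net.outstrength, 0), np.delete(before_out, 0))
    assert np.allclose(np.delete(net.instrength, 2), np.delete(before_in, 2))


def test_brute_force_strengths_match_stored(small_networks):
    for net in small_networks.values():
        W = np.where(net.mask, net.weights, 0.0)
        for j in range(9):
            assert net.instrength[j] == sum(W[k, j] for k in range(9))
            assert net.outstrength[j] == sum(W[j, k] for k in range(9))


def test_physician_network_activation_from_own_ratings(small_fits, small_ratings):
    pid = sorted(small_ratings["physician_id"].unique())[0]
    net = build_physician_network(small_fits, small_ratings, pid)
    own = small_ratings[small_ratings["physician_id"] == pid]
    expected_act = own[[f"skill_{j}" for j in range(1, 10)]].mean().to_numpy()
    assert np.allclose(net.activation, expected_act)


def test_physician_edges_recover_truth_with_dense_data():
    """With many consultations per physician and real between-physician
    heterogeneity, retained physician edge weights track the true
    conditional coefficients of each physician's precision matrix."""
    from sdmnet import (
        GeneratorConfig,
        McmcConfig,
        fit_all_nodes,
        sample_true_model,
        simulate_ratings,
    )

    cfg = GeneratorConfig(n_physicians=8, n_recorded=8, heterogeneity=0.25,
                          instrument_coverage={})
    m = sample_true_model(cfg, seed=99)
    r = simulate_ratings(m, 200, discretize=False, seed=100)
    mc = McmcConfig(n_chains=2, iterations=1300, burn_in=300, thinning=2, seed=101)
    fits = fit_all_nodes(r, mcmc=mc)
    est, truth = [], []
    for idx, phys in enumerate(m.physician_ids):
        Wtrue = true_edge_weights(m.physician_precisions[idx])
        net = build_physician_network(fits, r, phys)
        sel = net.mask
        est.extend(net.weights[sel].tolist())
        truth.extend(Wtrue[sel].tolist())
    assert len(est) >= 50
    assert np.corrcoef(est, truth)[0, 1] >= 0.8


def test_unknown_physician_rejected(small_fits, small_ratings):
    with pytest.raises(ValueError, match="absent"):
        build_physician_network(small_fits, small_ratings, "nobody")


def test_population_network_vs_physician_mean(small_fits, small_ratings, small_networks):
    pop = build_population_network(small_fits, small_ratings)
    avg = average_physician_network(list(small_networks.values()))
    # fixed-effect weights agree with the mean of physician weights up to
    # shrinkage on balanced data
    assert np.abs(pop.weights - avg.weights).max() < 0.1
    assert np.allclose(pop.activation, avg.activation, atol=1e-9)


def test_population_activation_equal_weight_per_physician(small_fits, small_ratings):
    pop = build_population_network(small_fits, small_ratings)
    per_phys = small_ratings.groupby("physician_id")[
        [f"skill_{j}" for j in range(1, 10)]
    ].mean()
    assert np.allclose(pop.activation, per_phys.mean(axis=0).to_numpy())


def test_layout_deterministic_and_finite(small_population):
    c1 = layout_network(small_population, seed=5)
    c2 = layout_network(small_population, seed=5)
    assert np.array_equal(c1, c2)
    assert np.all(np.isfinite(c1)) and c1.shape == (9, 2)


def test_layout_two_cliques_separate():
    # Two weakly joined cliques: within-clique distances < between-clique.
    weights = {}
    mask = []
    for a in (1, 2, 3):
        for b in (1, 2, 3):
            if a < b:
                weights[(a, b)] = 1.0
                mask.append((a, b))
    for a in (4, 5, 6):
        for b in (4, 5, 6):
            if a < b:
                weights[(a, b)] = 1.0
                mask.append((a, b))
    weights[(3, 4)] = 0.05
    mask.append((3, 4))
    net = _toy_network(weights=weights, mask=mask)
    coords = layout_network(net, seed=2)
    within = [
        np.linalg.norm(coords[a - 1] - coords[b - 1])
        for grp in ((1, 2, 3), (4, 5, 6))
        for a in grp
        for b in grp
        if a < b
    ]
    between = [
        np.linalg.norm(coords[a - 1] - coords[b - 1])
        for a in (1, 2, 3)
        for b in (4, 5, 6)
    ]
    assert np.mean(within) < np.mean(between)


def test_layout_two_nodes_finite_nonzero_distance():
    net = _toy_network(weights={(1, 2): 0.5}, mask=[(1, 2)])
    coords = layout_network(net, seed=1)
    d = np.linalg.norm(coords[0] - coords[1])
    assert np.isfinite(d) and d > 0


@pytest.mark.parametrize("fmt", ["json", "graphml"])
def test_export_import_round_trip(small_population, tmp_path, fmt):
    layout_network(small_population, seed=3)
    path = tmp_path / f"net.{fmt}"
    export_network(small_population, path, fmt)
    back = import_network(path, fmt)
    assert np.allclose(back.weights, small_population.weights)
    assert np.array_equal(back.mask, small_population.mask)
    assert np.allclose(back.activation, small_population.activation)
    assert np.allclose(back.coordinates, small_population.coordinates)
    assert np.allclose(back.ci_low, small_population.ci_low)
    assert np.allclose(back.ci_high, small_population.ci_high)


def test_graphml_is_valid_xml(small_population, tmp_path):
    import networkx as nx
    from lxml import etree

    path = tmp_path / "net.graphml"
    export_network(small_population, path, "graphml")
    tree = etree.parse(str(path))
    root = tree.getroot()
    assert root.tag.endswith("graphml")
    # networkx can parse it back into a directed graph with 9 nodes
    g = nx.read_graphml(path)
    assert g.number_of_nodes() == 9


def test_edge_list_csv_contains_only_retained(small_population, tmp_path):
    import pandas as pd

    path = tmp_path / "edges.csv"
    export_network(small_population, path, "csv")
    edges = pd.read_csv(path)
    assert len(edges) == int(small_population.mask.sum())
    assert edges["retained"].all()
    # but the mask is fully reconstructible from the JSON bundle
    jpath = tmp_path / "net.json"
    export_network(small_population, jpath, "json")
    back = import_network(jpath, "json")
    assert np.array_equal(back.mask, small_population.mask)
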