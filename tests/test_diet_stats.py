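"""Normalization, the three-state mixture, and the diet-contrast tests."""

import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rumennet.diet_stats import (
    CountMatrix,
    fit_three_state,
    layer_correlation,
    lrt_diets,
    mean_layer_test,
    network_stat_contrast,
    node_statistics,
    normalize,
    per_node_tests,
    presence_absence,
    variance_contrast,
    vfa_correlation,
)
from rumennet.network_build import MetabolicGraph, NetworkNode


def _cm(counts: dict, forg: list[str], conc: list[str], totals: dict | None = None) -> CountMatrix:
    frame = pd.DataFrame(counts)
    totals = totals or {a: int(frame[a].sum()) for a in frame.columns}
    return CountMatrix(
        counts=frame,
        diets=pd.Series({a: "FORG" for a in forg} | {a: "CONC" for a in conc}),
        mapped_totals=pd.Series(totals),
    )


def _simple_cm(n_nodes=6, forg=4, conc=4, seed=0, reads=2000):
    rng = np.random.default_rng(seed)
    cols = {}
    names_f = [f"F{i}" for i in range(forg)]
    names_c = [f"C{i}" for i in range(conc)]
    p = rng.dirichlet(np.ones(n_nodes))
    for a in names_f + names_c:
        cols[a] = rng.multinomial(reads, p)
    cm = _cm(cols, names_f, names_c)
    cm.counts.index = [f"N{i}" for i in range(n_nodes)]
    return cm


# ---------------------------------------------------------------------------
# normalization

def test_normalize_unit_scale_and_zeros():
    cm = _cm({"F": [54, 0], "C": [10, 20]}, ["F"], ["C"],
             totals={"F": 10**6, "C": 10**6})
    nc = normalize(cm)
    assert nc.loc[0, "F"] == 54.0
    assert nc.loc[1, "F"] == 0.0


def test_normalize_is_scale_invariant():
    cm1 = _cm({"F": [5, 15], "C": [3, 7]}, ["F"], ["C"], totals={"F": 100, "C": 50})
    cm2 = _cm({"F": [10, 30], "C": [6, 14]}, ["F"], ["C"], totals={"F": 200, "C": 100})
    assert np.allclose(normalize(cm1), normalize(cm2))


def test_normalize_rejects_zero_totals():
    cm = _cm({"F": [1], "C": [1]}, ["F"], ["C"], totals={"F": 0, "C": 10})
    with pytest.raises(ValueError, match="mapped totals"):
        normalize(cm)


# ---------------------------------------------------------------------------
# three-state mixture

def _simulate_three_state(n, p0, p1, meanlog, sdlog, rng):
    u = rng.random(n)
    raw = np.where(u < p0, 0, np.where(u < p0 + p1, 1, 2)).astype(int)
    values = raw.astype(float)
    tail = raw == 2
    draws = np.exp(rng.normal(meanlog, sdlog, size=int(tail.sum())))
    while (draws <= 1).any():  # truncation to (1, inf)
        redo = draws <= 1
        draws[redo] = np.exp(rng.normal(meanlog, sdlog, size=int(redo.sum())))
    values[tail] = draws
    return raw, values


def test_all_zero_vector_is_pure_p0():
    fit = fit_three_state(np.zeros(20, dtype=int))
    assert fit.p0 == 1.0 and fit.p1 == 0.0
    assert math.isnan(fit.meanlog)


def test_three_state_recovers_simulated_parameters():
    rng = np.random.default_rng(11)
    raw, values = _simulate_three_state(4000, 0.3, 0.1, 3.0, 1.0, rng)
    fit = fit_three_state(raw, values)
    assert abs(fit.p0 - 0.3) < 0.03
    assert abs(fit.p1 - 0.1) < 0.02
    assert abs(fit.meanlog - 3.0) < 0.08
    assert abs(fit.sdlog - 1.0) < 0.06


def test_fitted_likelihood_beats_perturbed_grid():
    rng = np.random.default_rng(12)
    raw, values = _simulate_three_state(800, 0.2, 0.1, 2.5, 0.8, rng)
    fit = fit_three_state(raw, values)
    tail = values[raw >= 2]

    def tail_ll(mu, sigma):
        from scipy import stats as ss
        logx = np.log(tail)
        z = (logx - mu) / sigma
        return float(
            -len(tail) * (np.log(sigma) + 0.5 * np.log(2 * np.pi))
            - logx.sum() - 0.5 * (z**2).sum()
            - len(tail) * np.log(ss.norm.cdf(mu / sigma))
        )

    best = tail_ll(fit.meanlog, fit.sdlog)
    for dmu in np.linspace(-0.2, 0.2, 5):
        for dsd in np.linspace(-0.1, 0.1, 5):
            assert best >= tail_ll(fit.meanlog + dmu, max(fit.sdlog + dsd, 0.05)) - 1e-6


def test_too_few_tail_values_raise():
    raw = np.array([0] * 10 + [1] * 5 + [7, 7])
    with pytest.raises(ValueError, match="distinct values"):
        fit_three_state(raw)


def test_lrt_is_zero_for_identical_diets_and_large_for_shifted():
    rng = np.random.default_rng(13)
    raw, values = _simulate_three_state(3000, 0.25, 0.1, 3.0, 1.0, rng)
    fit = fit_three_state(raw, values)
    stat, df, p = lrt_diets(fit, fit, fit_three_state(np.concatenate([raw, raw]),
                                                      np.concatenate([values, values])))
    assert stat >= 0
    assert p > 0.9

    raw2, values2 = _simulate_three_state(3000, 0.25, 0.1, 5.0, 1.0, rng)
    pooled = fit_three_state(np.concatenate([raw, raw2]), np.concatenate([values, values2]))
    stat2, _, p2 = lrt_diets(fit, fit_three_state(raw2, values2), pooled)
    assert p2 < 1e-10


def test_lrt_df_is_configurable():
    rng = np.random.default_rng(14)
    raw, values = _simulate_three_state(500, 0.2, 0.1, 3.0, 1.0, rng)
    fit = fit_three_state(raw, values)
    pooled = fit_three_state(np.concatenate([raw, raw]), np.concatenate([values, values]))
    _, df4, _ = lrt_diets(fit, fit, pooled)
    _, df5, _ = lrt_diets(fit, fit, pooled, df=5)
    assert (df4, df5) == (4, 5)


# ---------------------------------------------------------------------------
# per-node tests

def test_tied_node_has_p_one_and_separated_node_exact_p():
    rng = np.random.default_rng(15)
    forg = [f"F{i}" for i in range(8)]
    conc = [f"C{i}" for i in range(8)]
    sep_f = 100 + rng.permutation(8)
    sep_c = 10 + rng.permutation(8)
    counts = {a: [5, int(sep_f[i])] for i, a in enumerate(forg)}
    counts |= {a: [5, int(sep_c[i])] for i, a in enumerate(conc)}
    cm = _cm(counts, forg, conc, totals={a: 10**6 for a in forg + conc})
    table = per_node_tests(cm)
    assert table.loc[0, "P"] == 1.0
    assert table.loc[1, "P"] == pytest.approx(2 / math.comb(16, 8))
    assert table.loc[1, "direction"] == "FORG"


def test_null_matrix_yields_no_fdr_significance():
    cm = _simple_cm(n_nodes=300, seed=16, reads=5000)
    table = per_node_tests(cm)
    assert table["significant"].mean() < 0.02


# ---------------------------------------------------------------------------
# randomization contrasts

def test_mean_layer_observed_weighted_difference():
    forg, conc = ["F0", "F1"], ["C0", "C1"]
    counts = {"F0": [0, 50], "F1": [0, 30], "C0": [40, 0], "C1": [60, 0]}
    cm = _cm(counts, forg, conc)
    cm.counts.index = ["N1", "N2"]
    res = mean_layer_test(cm, {"N1": 1, "N2": 2}, n_rand=99, seed=0)
    assert res.observed == pytest.approx(1.0)
    assert 0 < res.p_value <= 1


def test_identical_read_distributions_have_zero_difference():
    forg, conc = ["F0", "F1"], ["C0", "C1"]
    counts = {a: [10, 20, 30] for a in forg + conc}
    cm = _cm(counts, forg, conc)
    cm.counts.index = ["N1", "N2", "N3"]
    res = mean_layer_test(cm, {"N1": 0, "N2": 1, "N3": 2}, n_rand=99, seed=0)
    assert res.observed == 0.0


def test_unreachable_nodes_are_excluded_from_mean_layer():
    forg, conc = ["F0"], ["C0"]
    cm = _cm({"F0": [10, 99], "C0": [10, 99]}, forg, conc)
    cm.counts.index = ["N1", "N2"]
    res = mean_layer_test(cm, {"N1": 3, "N2": None}, n_rand=19, seed=0)
    assert res.observed == 0.0  # only N1 counts, same both sides


def _toy_graph(edges, metabolite_sets=None) -> MetabolicGraph:
    g = nx.Graph(edges)
    nodes = {
        n: NetworkNode(n, frozenset({n}), frozenset(metabolite_sets.get(n, {"M"}) if metabolite_sets else {"M"}), "microbial")
        for n in g.nodes
    }
    return MetabolicGraph(g, nodes, 25, frozenset(), "microbial", {n: n for n in g.nodes})


def test_star_and_triangle_closed_forms():
    star = _toy_graph([("c", f"l{i}") for i in range(5)])
    deg = node_statistics(star, "degree")
    clust = node_statistics(star, "clustering")
    assert deg["c"] == 5 and all(deg[f"l{i}"] == 1 for i in range(5))
    assert all(v == 0 for v in clust.values())
    triangle = _toy_graph([("a", "b"), ("b", "c"), ("a", "c")])
    assert all(v == 1.0 for v in node_statistics(triangle, "clustering").values())


def test_path_graph_betweenness_closed_form():
    path = _toy_graph([(f"n{i}", f"n{i+1}") for i in range(4)])
    bc = node_statistics(path, "betweenness")
    # interior node k of a 5-path mediates k*(4-k) pairs
    assert [bc[f"n{k}"] for k in range(5)] == [0.0, 3.0, 4.0, 3.0, 0.0]


def _brute_betweenness(g: nx.Graph) -> dict:
    bc = {n: 0.0 for n in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        if t not in dist:
            continue
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in g.neighbors(u):
                if dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                    extend(path + [v])

        extend([s])
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def test_betweenness_matches_path_enumeration_oracle():
    rng = np.random.default_rng(17)
    for _ in range(20):
        g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(2**31)))
        graph = _toy_graph(list(g.edges) or [(0, 1)])
        bc = node_statistics(graph, "betweenness")
        oracle = _brute_betweenness(graph.graph)
        for n in graph.nodes:
            assert bc[n] == pytest.approx(oracle[n])


def test_carbon_sum_contrast_uses_database(tiny_db):
    from rumennet.network_build import build_graph

    graph = build_graph(tiny_db, 25)
    values = node_statistics(graph, "carbon_sum", db=tiny_db)
    assert values["R1"] == 8.0  # A(3) + B(5)
    cm = _cm({"F0": [10, 0], "C0": [0, 10]}, ["F0"], ["C0"])
    cm.counts.index = ["R1", "R2"]
    res = network_stat_contrast(cm, graph, "carbon_sum", db=tiny_db, n_rand=49, seed=1)
    assert res.observed == pytest.approx(8.0 - 7.0)  # R2 = B(5) + C(2)


def test_unknown_statistic_rejected(tiny_db):
    from rumennet.network_build import build_graph

    graph = build_graph(tiny_db, 25)
    cm = _cm({"F0": [1], "C0": [1]}, ["F0"], ["C0"])
    cm.counts.index = ["R1"]
    with pytest.raises(ValueError, match="unknown statistic"):
        network_stat_contrast(cm, graph, "pagerank")


# ---------------------------------------------------------------------------
# layer correlation

def test_monotone_counts_give_negative_layer_correlation():
    forg, conc = ["F0", "F1"], ["C0", "C1"]
    counts = {a: [400, 200, 100, 50] for a in forg + conc}
    cm = _cm(counts, forg, conc)
    cm.counts.index = ["N0", "N1", "N2", "N3"]
    layers = {"N0": 0, "N1": 1, "N2": 2, "N3": 3}
    out = layer_correlation(cm, layers)
    for diet in ("FORG", "CONC"):
        assert out["per_diet_r"][diet][0] < 0
        assert out["cumulative_proportions"][diet].iloc[-1] == pytest.approx(1.0)


def test_fewer_than_three_layers_error():
    cm = _cm({"F0": [1, 2], "C0": [3, 4]}, ["F0"], ["C0"])
    cm.counts.index = ["N0", "N1"]
    with pytest.raises(ValueError, match="3 distinct layers"):
        layer_correlation(cm, {"N0": 0, "N1": 1})


# ---------------------------------------------------------------------------
# presence / absence

def test_presence_classification_and_significance():
    forg = [f"F{i}" for i in range(4)]
    conc = [f"C{i}" for i in range(4)]
    counts = {}
    for a in forg:
        counts[a] = [50, 0, 1 if a == "F0" else 0, 75]
    for a in conc:
        counts[a] = [40, 75, 0, 60]
    cm = _cm(counts, forg, conc, totals={a: 1000 for a in forg + conc})
    cm.counts.index = ["shared", "conc_only", "forg_single", "shared2"]
    out = presence_absence(cm, n_rand=2000, seed=2)
    assert out["n_shared"] == 2
    assert out["n_forg_only"] == 1 and out["n_conc_only"] == 1
    # a single read can never be exclusive beyond chance
    assert out["forg"]["p_values"]["forg_single"] > 0.01
    # 300 reads all in one diet under balanced depths is wildly unlikely
    assert out["conc"]["p_values"]["conc_only"] < 0.01
    assert out["max_reads_differential"] == 300.0


# ---------------------------------------------------------------------------
# variance contrast

def test_identical_diet_matrices_give_p_one():
    forg, conc = ["F0", "F1", "F2"], ["C0", "C1", "C2"]
    base = np.array([[10, 20, 5], [7, 3, 40], [0, 9, 9], [25, 25, 25]])
    counts = {a: base[:, i] for i, a in enumerate(forg)}
    counts |= {a: base[:, i] for i, a in enumerate(conc)}
    cm = _cm(counts, forg, conc, totals={a: 100 for a in forg + conc})
    out = variance_contrast(cm, subsample_reads=50, n_rep=5, seed=3)
    assert out["observed_p"] == 1.0


def test_heteroscedastic_conc_detected():
    rng = np.random.default_rng(18)
    forg = [f"F{i}" for i in range(6)]
    conc = [f"C{i}" for i in range(6)]
    base = rng.integers(50, 150, size=40)
    counts = {}
    for a in forg:
        counts[a] = rng.poisson(base)
    for a in conc:
        counts[a] = rng.poisson(base * rng.lognormal(0, 0.8, size=40))
    cm = _cm(counts, forg, conc)
    out = variance_contrast(cm, subsample_reads=1000, n_rep=10, seed=4)
    assert out["observed_p"] < 1e-4
    assert (out["resampled_p"] < 0.01).mean() >= 0.9
    assert out["flagged_animals"] == []  # depths exceed the subsample here
    shallow = variance_contrast(cm, subsample_reads=10**6, n_rep=2, seed=5)
    assert shallow["flagged_animals"] == sorted(forg + conc)


# ---------------------------------------------------------------------------
# VFA correlation

def _vfa_setup(concs):
    animals = [f"A{i}" for i in range(8)]
    counts = {a: [10 * (i + 1), 100] for i, a in enumerate(animals)}
    cm = _cm(counts, animals[:4], animals[4:], totals={a: 1000 for a in animals})
    cm.counts.index = ["vfa_node", "other"]
    conc_df = pd.DataFrame({"acetate": concs}, index=animals)
    return cm, conc_df


def test_monotone_vfa_fraction_gives_rho_one():
    cm, conc = _vfa_setup(list(range(1, 9)))
    out = vfa_correlation(cm, {"acetate": ["vfa_node"]}, conc)
    assert out.loc["acetate", "rho"] == pytest.approx(1.0)
    assert out.loc["acetate", "P"] < 0.01


def test_constant_concentrations_warn_and_return_nan():
    cm, conc = _vfa_setup([5.0] * 8)
    with pytest.warns(UserWarning, match="constant"):
        out = vfa_correlation(cm, {"acetate": ["vfa_node"]}, conc)
    assert math.isnan(out.loc["acetate", "rho"])


def test_too_few_paired_observations_error():
    cm, conc = _vfa_setup(list(range(1, 9)))
    conc.iloc[4:] = np.nan
    with pytest.raises(ValueError, match="fewer than 5"):
        vfa_correlation(cm, {"acetate": ["vfa_node"]}, conc)
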