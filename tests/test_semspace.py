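"""Semantic space: PPMI, walk expansion, neighbors, ratios, ego networks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lexidrift as lx
from lexidrift.errors import (
    ConfigurationError,
    ConvergenceError,
    CueLookupError,
    UndefinedScoreError,
)
from lexidrift.semspace import CueCountMatrix, ppmi_normalize


# ----------------------------------------------------------------------
# PPMI
# ----------------------------------------------------------------------

def test_ppmi_hand_example_uniform_marginal():
    # two words pointing only at each other: Q = [[0,1],[1,0]],
    # marginal p = (0.5, 0.5), ratios (0, 2; 2, 0) -> PPMI ln2 off-diagonal,
    # and re-normalization gives back the permutation matrix
    m = CueCountMatrix(vocabulary=["a", "b"],
                       counts=np.array([[0.0, 3.0], [5.0, 0.0]]))
    P = ppmi_normalize(m)
    assert np.allclose(P, [[0, 1], [1, 0]])
    raw = ppmi_normalize(m, renormalize=False)
    assert raw[0, 1] == pytest.approx(np.log(2.0))


def test_ppmi_rows_are_stochastic_or_zero(small_sim):
    ds, _ = small_sim
    m = lx.build_cue_count_matrix(ds)
    P = ppmi_normalize(m)
    sums = P.sum(axis=1)
    assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))
    assert np.all(P >= 0)


def test_ppmi_warns_on_zero_rows():
    m = CueCountMatrix(vocabulary=["a", "b", "c"],
                       counts=np.array([[0.0, 1.0, 1.0],
                                        [1.0, 0.0, 1.0],
                                        [0.0, 0.0, 0.0]]))
    with pytest.warns(UserWarning, match="all-zero"):
        P = ppmi_normalize(m)
    assert np.all(P[2] == 0)


def test_ppmi_unknown_marginal_raises():
    m = CueCountMatrix(vocabulary=["a", "b"],
                       counts=np.array([[0.0, 1.0], [1.0, 0.0]]))
    with pytest.raises(ConfigurationError):
        ppmi_normalize(m, marginal="banana")


# ----------------------------------------------------------------------
# Walk expansion
# ----------------------------------------------------------------------

def test_walk_alpha_zero_is_identity():
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert np.array_equal(lx.random_walk_expand(P, alpha=0.0), np.eye(2))


def test_walk_alpha_out_of_range():
    P = np.eye(2)
    with pytest.raises(ConfigurationError):
        lx.random_walk_expand(P, alpha=1.0)
    with pytest.raises(ConfigurationError):
        lx.random_walk_expand(P, alpha=-0.1)


def test_walk_divergent_matrix_raises():
    # spectral radius 2: alpha * rho >= 1 at the default alpha
    P = 2.0 * np.eye(3)
    with pytest.raises(ConvergenceError):
        lx.random_walk_expand(P, alpha=0.75)


def test_walk_satisfies_resolvent_identity():
    rng = np.random.default_rng(0)
    raw = rng.random((30, 30))
    P = raw / raw.sum(axis=1, keepdims=True)
    G = lx.random_walk_expand(P, alpha=0.75)
    assert np.allclose((np.eye(30) - 0.75 * P) @ G, np.eye(30), atol=1e-10)


# ----------------------------------------------------------------------
# Similarity and neighbors
# ----------------------------------------------------------------------

def test_cosine_rows_properties():
    G = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 0.0]])
    sim = lx.cosine_rows(G, ["a", "b", "z"])
    assert sim.sim("a", "a") == pytest.approx(1.0)
    assert sim.sim("a", "b") == pytest.approx(1 / np.sqrt(2))
    assert sim.sim("a", "z") == 0.0  # zero rows give similarity 0
    assert sim.sim("b", "a") == sim.sim("a", "b")


def test_top_neighbors_excludes_self_and_breaks_ties_lexically():
    vals = np.array([
        [1.0, 0.5, 0.5, 0.2],
        [0.5, 1.0, 0.1, 0.1],
        [0.5, 0.1, 1.0, 0.1],
        [0.2, 0.1, 0.1, 1.0],
    ])
    sim = lx.SimilarityMatrix(vocabulary=["a", "b", "c", "d"], values=vals)
    assert lx.top_neighbors(sim, "a", k=2) == ["b", "c"]  # tie -> lexical
    assert "a" not in lx.top_neighbors(sim, "a", k=3)


def test_neighbor_analysis_categories_and_ratios(default_spaces, default_sim):
    sim_pre, sim_cov = default_spaces
    _, truth = default_sim
    cue = truth.cues.loc[truth.cues["shifted"], "cue"].iloc[0]
    df = lx.neighbor_analysis(sim_pre, sim_cov, cue, k=20)
    assert set(df["category"]) <= {"precovid-only", "covid-only", "shared"}
    finite = df["ratio"][np.isfinite(df["ratio"])]
    assert (finite > 0).all()
    # a shifted cue moved: its neighborhood is not unchanged
    assert lx.mean_ratio_deviation(df) > 0


def test_neighbor_analysis_unknown_cue_raises(default_spaces):
    sim_pre, sim_cov = default_spaces
    with pytest.raises(CueLookupError):
        lx.neighbor_analysis(sim_pre, sim_cov, "palabra-inexistente")


def test_mean_ratio_deviation_requires_finite_ratios():
    df = pd.DataFrame({"ratio": [np.inf, np.inf]})
    with pytest.raises(UndefinedScoreError):
        lx.mean_ratio_deviation(df)


def test_ratio_table_and_model(default_spaces, default_sim):
    ds, _ = default_sim
    sim_pre, sim_cov = default_spaces
    table = lx.neighbor_ratio_table(sim_pre, sim_cov, ds.registry, k=20)
    assert {"cue", "neighbor", "category", "ratio", "cue_type"} <= set(table.columns)
    assert "filler" not in set(table["cue_type"])
    summary = lx.fit_ratio_model(table)
    assert summary.family == "gamma-inverse"
    assert 0.0 <= summary.p_value <= 1.0
    # delta = 0.5 on pandemic cues: the cue-type x neighbor-type
    # interaction is overwhelming at study scale
    assert summary.p_value < 0.001


# ----------------------------------------------------------------------
# Ego networks
# ----------------------------------------------------------------------

def test_ego_network_structure_and_export(small_sim, tmp_path):
    ds, truth = small_sim
    cue = truth.cues["cue"].iloc[0]
    g = lx.ego_network(ds, cue, min_occurrence=2)
    assert g.graph["focal_cue"] == cue
    assert g.nodes[cue]["category"] == "focal"
    others = [n for n in g.nodes if n != cue]
    assert others, "expected at least one neighbor node"
    for n in others:
        assert g.nodes[n]["category"] in {"old", "new", "shared"}
        assert g.nodes[n]["count"] >= 2
        assert 0 < g.nodes[n]["pct"] <= 100
        assert g.has_edge(cue, n)
    lx.write_ego_network(
        g, tmp_path / "nodes.tsv", tmp_path / "edges.tsv",
        tmp_path / "ego.graphml",
    )
    nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
    assert len(nodes) == g.number_of_nodes()
    assert (tmp_path / "ego.graphml").stat().st_size > 0


def test_ego_network_unknown_cue_raises(small_sim):
    ds, _ = small_sim
    with pytest.raises(CueLookupError):
        lx.ego_network(ds, "palabra-inexistente")
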