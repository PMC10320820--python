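"""Period-specific semantic spaces from association counts.

The representation pipeline is the spreading-activation one used with SWOW
norms: a cue-by-cue count matrix (rows: cue presented, columns: cue given as
response), row-normalized and PPMI-transformed into a transition-like matrix
P, then expanded through an attenuated random walk G = (I - alpha P)^-1 with
decay alpha = 0.75, so that the representation of a word aggregates direct
and indirect association paths.  Word similarity is the cosine between rows
of G.  Diachronic change is then read off by comparing each cue's top-k
nearest neighbors and their Covid/Precovid similarity ratios between the two
period spaces, and visualized through ego networks of a cue's responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import SENTINELS, AssociationDataset, POSITIONS
from .errors import (
    ConfigurationError,
    ConvergenceError,
    CueLookupError,
    DegenerateInputError,
    UndefinedScoreError,
)
from .inference import ModelSummary, fit_gamma_ratio_gee


@dataclass
class CueCountMatrix:
    """Square cue-by-cue response count matrix over an ordered vocabulary."""

    vocabulary: list[str]
    counts: np.ndarray

    def __post_init__(self):
        n = len(self.vocabulary)
        if self.counts.shape != (n, n):
            raise ValueError("counts must be square over the vocabulary")


@dataclass
class SemanticSpace:
    """PPMI-transformed walk space for one period."""

    vocabulary: list[str]
    P: np.ndarray
    alpha: float
    G: np.ndarray
    period: str = ""


@dataclass
class SimilarityMatrix:
    """Cosine similarities between rows of G for one period."""

    vocabulary: list[str]
    values: np.ndarray
    period: str = ""

    def __post_init__(self):
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def sim(self, w1: str, w2: str) -> float:
        try:
            return float(self.values[self._index[w1], self._index[w2]])
        except KeyError as e:
            raise CueLookupError(f"word {e.args[0]!r} not in vocabulary") from e

    def row(self, w: str) -> np.ndarray:
        if w not in self._index:
            raise CueLookupError(f"word {w!r} not in vocabulary")
        return self.values[self._index[w]]

    def __contains__(self, w: str) -> bool:
        return w in self._index


# ----------------------------------------------------------------------
# Matrix construction
# ----------------------------------------------------------------------

def build_cue_count_matrix(
    ds: AssociationDataset,
    positions: tuple[str, ...] = POSITIONS,
) -> CueCountMatrix:
    """Tabulate how often each cue is given as a response to each other cue.

    Responses that are not themselves cues are dropped; the vocabulary is
    the sorted set of registry cues that appear as presented cues.
    """
    trials = ds.trials[
        ds.trials["position"].isin(positions)
        & ~ds.trials["response"].isin(SENTINELS)
    ]
    vocab = sorted(set(ds.registry["cue"]) & set(trials["cue"]))
    if not vocab:
        raise DegenerateInputError("no cues left after vocabulary restriction")
    index = {w: i for i, w in enumerate(vocab)}
    sub = trials[trials["response"].isin(index)]
    counts = np.zeros((len(vocab), len(vocab)), dtype=np.int64)
    grouped = sub.groupby(["cue", "response"]).size()
    for (c, r), n in grouped.items():
        counts[index[c], index[r]] = n
    return CueCountMatrix(vocabulary=vocab, counts=counts)


def ppmi_normalize(
    m: CueCountMatrix,
    marginal: str = "uniform",
    renormalize: bool = True,
) -> np.ndarray:
    """Row-normalize, apply PPMI, and re-normalize to row-stochastic.

    PPMI(i, j) = max(0, ln(p(j|i) / p(j))), with the reference marginal
    p(j) taken as the mean of column j over rows of the row-normalized
    matrix (``uniform`` cue prior, the default) or as the column share of
    total counts (``count``).  The PPMI matrix is re-normalized to row sums
    of 1 so that the attenuated walk below converges; all-zero rows are
    reported in a warning and left as zeros.
    """
    counts = m.counts.astype(float)
    row_sums = counts.sum(axis=1)
    empty = row_sums == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} all-zero rows left as zeros: "
            f"{[m.vocabulary[i] for i in np.flatnonzero(empty)[:5]]}",
            stacklevel=2,
        )
    Q = np.divide(
        counts, row_sums[:, None],
        out=np.zeros_like(counts), where=row_sums[:, None] > 0,
    )
    if marginal == "uniform":
        nz = max(int((~empty).sum()), 1)
        pj = Q.sum(axis=0) / nz
    elif marginal == "count":
        total = counts.sum()
        pj = counts.sum(axis=0) / total if total > 0 else np.zeros(Q.shape[1])
    else:
        raise ConfigurationError(f"unknown marginal {marginal!r}")
    ratio = np.divide(
        Q, pj[None, :], out=np.zeros_like(Q), where=pj[None, :] > 0
    )
    P = np.log(ratio, out=np.zeros_like(ratio), where=ratio > 0)
    P = np.maximum(P, 0.0)
    if renormalize:
        ps = P.sum(axis=1)
        nz_rows = ps > 0
        P[nz_rows] = P[nz_rows] / ps[nz_rows, None]
    return P


def _spectral_radius(P: np.ndarray) -> float:
    n = P.shape[0]
    if n <= 600:
        return float(np.max(np.abs(np.linalg.eigvals(P))))
    # power iteration on |P| bounds the radius well enough for the check
    v = np.ones(n) / n
    for _ in range(50):
        w = np.abs(P).T @ v
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        v = w / nrm
    return float(v @ (np.abs(P).T @ v))


def neumann_expand(
    P: np.ndarray, alpha: float, tol: float = 1e-10, max_terms: int = 10_000
) -> np.ndarray:
    """Truncated Neumann series sum_n (alpha P)^n, to additive tolerance."""
    G = np.eye(P.shape[0])
    term = np.eye(P.shape[0])
    A = alpha * P
    for _ in range(max_terms):
        term = term @ A
        G += term
        if np.abs(term).max() < tol:
            break
    return G


def random_walk_expand(
    P: np.ndarray,
    alpha: float = 0.75,
    dense_threshold: int = 2000,
    tol: float = 1e-10,
) -> np.ndarray:
    """Attenuated random-walk expansion G = (I - alpha P)^-1.

    Computed by a dense linear solve up to ``dense_threshold`` rows and by
    the truncated Neumann series beyond; both agree within the tolerance on
    convergent inputs.
    """
    if not 0 <= alpha < 1:
        raise ConfigurationError(f"alpha must be in [0, 1), got {alpha}")
    n = P.shape[0]
    if alpha == 0:
        return np.eye(n)
    rho = _spectral_radius(P)
    if alpha * rho >= 1:
        raise ConvergenceError(
            f"alpha * spectral_radius = {alpha * rho:.4f} >= 1; "
            "re-normalize P to row-stochastic before expanding"
        )
    if n <= dense_threshold:
        return np.linalg.solve(np.eye(n) - alpha * P, np.eye(n))
    return neumann_expand(P, alpha, tol=tol)


def cosine_rows(G: np.ndarray, vocabulary: list[str], period: str = "") -> SimilarityMatrix:
    """Cosine similarity between all row pairs of G (zero rows give 0)."""
    norms = np.linalg.norm(G, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = G / safe[:, None]
    vals = U @ U.T
    vals[norms == 0, :] = 0.0
    vals[:, norms == 0] = 0.0
    np.clip(vals, 0.0, 1.0, out=vals)
    return SimilarityMatrix(vocabulary=list(vocabulary), values=vals, period=period)


def build_semantic_space(
    ds: AssociationDataset,
    alpha: float = 0.75,
    positions: tuple[str, ...] = POSITIONS,
    marginal: str = "uniform",
    period: str = "",
) -> tuple[SemanticSpace, SimilarityMatrix]:
    """Full pipeline: counts -> PPMI -> walk expansion -> cosine matrix."""
    m = build_cue_count_matrix(ds, positions=positions)
    P = ppmi_normalize(m, marginal=marginal)
    G = random_walk_expand(P, alpha=alpha)
    sim = cosine_rows(G, m.vocabulary, period=period)
    space = SemanticSpace(
        vocabulary=m.vocabulary, P=P, alpha=alpha, G=G, period=period
    )
    return space, sim


# ----------------------------------------------------------------------
# Nearest-neighbor / ratio analysis
# ----------------------------------------------------------------------

def top_neighbors(sim: SimilarityMatrix, cue: str, k: int = 20) -> list[str]:
    """Top-k most similar words to ``cue`` (self excluded), ties broken by
    descending similarity then lexicographic token order."""
    order = sorted(
        (w for w in sim.vocabulary if w != cue),
        key=lambda w: (-sim.sim(cue, w), w),
    )
    return order[:k]


def neighbor_analysis(
    sim_pre: SimilarityMatrix,
    sim_cov: SimilarityMatrix,
    cue: str,
    k: int = 20,
) -> pd.DataFrame:
    """Compare a cue's top-k neighborhoods between the two periods.

    Returns one row per neighbor in the union of the two top-k sets with its
    category (precovid-only / covid-only / shared) and the Covid/Precovid
    similarity ratio.  Neighbors with zero Precovid similarity get an
    infinite ratio and a warning; means downstream skip them.
    """
    for sim in (sim_pre, sim_cov):
        if cue not in sim:
            raise CueLookupError(f"cue {cue!r} not in vocabulary")
    shared_vocab = set(sim_pre.vocabulary) & set(sim_cov.vocabulary)
    pre_top = [w for w in top_neighbors(sim_pre, cue, k) if w in shared_vocab]
    cov_top = [w for w in top_neighbors(sim_cov, cue, k) if w in shared_vocab]
    union = sorted(set(pre_top) | set(cov_top))
    rows = []
    n_inf = 0
    for w in union:
        in_pre, in_cov = w in pre_top, w in cov_top
        category = "shared" if (in_pre and in_cov) else (
            "precovid-only" if in_pre else "covid-only"
        )
        s_pre = sim_pre.sim(cue, w)
        s_cov = sim_cov.sim(cue, w)
        if s_pre > 0:
            ratio = s_cov / s_pre
        else:
            ratio = np.inf
            n_inf += 1
        rows.append(
            {
                "cue": cue,
                "neighbor": w,
                "category": category,
                "sim_precovid": s_pre,
                "sim_covid": s_cov,
                "ratio": ratio,
            }
        )
    if n_inf:
        warnings.warn(
            f"cue {cue!r}: {n_inf} neighbor(s) with zero Precovid similarity; "
            "their ratios are infinite and excluded from means",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["cue", "neighbor", "category", "sim_precovid",
                 "sim_covid", "ratio"],
    )


def mean_ratio_deviation(comparisons: pd.DataFrame) -> float:
    """Mean |ratio - 1| over a cue's neighbors (finite ratios only)."""
    finite = comparisons["ratio"][np.isfinite(comparisons["ratio"])]
    if finite.empty:
        raise UndefinedScoreError("no finite similarity ratios to average")
    return float(np.abs(finite - 1.0).mean())


def neighbor_ratio_table(
    sim_pre: SimilarityMatrix,
    sim_cov: SimilarityMatrix,
    registry: pd.DataFrame,
    k: int = 20,
    include_types: tuple[str, ...] = ("control", "pandemic", "emotion", "routine"),
) -> pd.DataFrame:
    """Stack neighbor comparisons for every registry cue of the given types,
    adding the cue type; cues absent from either vocabulary are skipped."""
    frames = []
    reg = registry[registry["cue_type"].isin(include_types)]
    for _, entry in reg.sort_values("cue").iterrows():
        cue = entry["cue"]
        if cue not in sim_pre or cue not in sim_cov:
            continue
        df = neighbor_analysis(sim_pre, sim_cov, cue, k=k)
        df["cue_type"] = entry["cue_type"]
        frames.append(df)
    if not frames:
        raise DegenerateInputError("no cues available for the ratio table")
    return pd.concat(frames, ignore_index=True)


def fit_ratio_model(ratio_table: pd.DataFrame) -> ModelSummary:
    """Gamma/inverse model of similarity ratios with cue-level clustering.

    Expects columns cue, cue_type, category (neighbor type) and ratio;
    infinite ratios are dropped with a warning before fitting.
    """
    finite = np.isfinite(ratio_table["ratio"])
    if not finite.all():
        warnings.warn(
            f"dropping {int((~finite).sum())} infinite ratio(s) before the fit",
            stacklevel=2,
        )
    t = ratio_table[finite]
    summary, _ = fit_gamma_ratio_gee(
        t["ratio"], t["cue_type"], t["category"], t["cue"]
    )
    return summary


# ----------------------------------------------------------------------
# Ego networks
# ----------------------------------------------------------------------

def ego_network(
    ds: AssociationDataset,
    cue: str,
    min_occurrence: int = 2,
    positions: tuple[str, ...] = POSITIONS,
) -> nx.Graph:
    """Ego network of a cue's responses, colored by period membership.

    Nodes are the responses given to the focal cue (outgoing edges only)
    that occur at least ``min_occurrence`` times as responses to it across
    the whole dataset; each node is labeled old (Precovid only), new (Covid
    only) or shared, and weighted by its percentage of the cue's responses.
    Edges between adjacent nodes are included when one was given as a
    response to the other (in either period).
    """
    if cue not in set(ds.registry["cue"]):
        raise CueLookupError(f"cue {cue!r} not in registry")
    twp = ds.trials_with_period()
    twp = twp[twp["position"].isin(positions) & ~twp["response"].isin(SENTINELS)]
    focal = twp[twp["cue"] == cue]
    if focal.empty:
        raise CueLookupError(f"cue {cue!r} was never presented")
    counts = focal.groupby("response").size()
    periods = focal.groupby("response")["period"].agg(set)
    total = int(counts.sum())
    included = counts[counts >= min_occurrence].index

    g = nx.Graph(focal_cue=cue)
    g.add_node(cue, category="focal", count=total, pct=100.0)
    for w in included:
        p = periods[w]
        category = "shared" if p == {"precovid", "covid"} else (
            "old" if p == {"precovid"} else "new"
        )
        g.add_node(
            w,
            category=category,
            count=int(counts[w]),
            pct=100.0 * counts[w] / total,
        )
        g.add_edge(cue, w)
    # edges among adjacent vertices: a -> b association present in the data
    node_set = set(included)
    among = twp[twp["cue"].isin(node_set) & twp["response"].isin(node_set)]
    for a, b in among[["cue", "response"]].drop_duplicates().itertuples(index=False):
        if a != b:
            g.add_edge(a, b)
    return g


def write_ego_network(
    g: nx.Graph, nodes_path, edges_path, graphml_path=None
) -> None:
    """Serialize an ego network as node/edge TSVs and optionally GraphML."""
    nodes = pd.DataFrame(
        [
            {"node": n, **{k: d[k] for k in ("category", "count", "pct")}}
            for n, d in g.nodes(data=True)
        ]
    ).sort_values("node")
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges = pd.DataFrame(
        sorted((min(a, b), max(a, b)) for a, b in g.edges()),
        columns=["source", "target"],
    )
    edges.to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
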