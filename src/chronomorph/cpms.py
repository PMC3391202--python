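"""Ancestral state estimation under Brownian motion and construction of
phylomorphospace / chronophylomorphospace graphs.

A phylomorphospace draws the phylogeny inside a two-dimensional morphospace by
placing internal nodes at their maximum-likelihood ancestral trait values and
connecting nodes along tree edges.  The chronophylomorphospace (CPMS) adds
geological age as a third axis, so each node sits at (axis1, axis2, age) and
lineage trajectories through morphospace can be read through time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from .tree import TimeTree, TreeError, TreeNode
from .signal import _align_values, _pic_operator

__all__ = [
    "AncestralStates", "CpmsGraph",
    "ancestral_ml", "build_phylomorphospace", "build_cpms", "build_cpms_1d",
    "export_graph", "load_graph_json", "plot_cpms",
]

CI_MULTIPLIER = 1.96  # normal 95% interval


@dataclass
class AncestralStates:
    """Per-node trait estimates with estimation variances and 95% CIs.

    Tip rows carry the observed values with zero variance.  ``rate`` is the
    estimated Brownian-motion rate sigma^2 per trait (REML on contrasts by
    default).
    """

    estimates: pd.DataFrame     # node id x traits
    variances: pd.DataFrame     # node id x traits (sigma^2-scaled)
    rate: np.ndarray            # per-trait sigma^2
    is_tip: pd.Series
    method: str = "reml"

    def ci(self, trait) -> pd.DataFrame:
        half = CI_MULTIPLIER * np.sqrt(self.variances[trait])
        est = self.estimates[trait]
        return pd.DataFrame({"lower": est - half, "upper": est + half})


def _node_ids(tree: TimeTree) -> dict[int, str]:
    """Stable node identifiers: tip label for tips, 'node<i>' in preorder for
    internal nodes (root is node0)."""
    ids: dict[int, str] = {}
    i = 0
    for node in tree.preorder():
        if node.is_tip:
            ids[id(node)] = node.label
        else:
            ids[id(node)] = node.label or f"node{i}"
            i += 1
    return ids


def ancestral_ml(
    tree: TimeTree, x, method: str = "reml"
) -> AncestralStates:
    """Maximum-likelihood ancestral states under Brownian motion.

    Internal values minimize sum over edges of (change)^2/duration with tips
    fixed — the weighted squared-change solution, which is also the joint BM
    maximum-likelihood estimate.  Solved as one sparse linear system per
    trait-independent right-hand side; the per-node estimation variance is the
    corresponding diagonal of the system inverse scaled by the estimated rate
    sigma^2 (REML on independent contrasts by default, ``method='ml'`` for the
    n-divisor variant).
    """
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")
    tips = tree.tips()
    internal = tree.internal_nodes()
    if not internal:
        raise TreeError("tree has no internal nodes")
    X = np.atleast_2d(np.asarray(
        _align_matrix(x, [t.label for t in tips]), dtype=float
    ))
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape

    iidx = {id(nd): i for i, nd in enumerate(internal)}
    tidx = {id(t): i for i, t in enumerate(tips)}
    rows, cols, vals = [], [], []
    rhs = np.zeros((len(internal), p))
    diag = np.zeros(len(internal))
    for node in tree.preorder():
        if node.parent is None:
            continue
        d = node.duration
        if d is None or d <= 0:
            raise TreeError("ancestral_ml requires positive branch durations")
        w = 1.0 / d
        pi = iidx[id(node.parent)]
        diag[pi] += w
        if node.is_tip:
            rhs[pi] += w * X[tidx[id(node)]]
        else:
            ci = iidx[id(node)]
            diag[ci] += w
            rows += [pi, ci]
            cols += [ci, pi]
            vals += [-w, -w]
    m = len(internal)
    rows += list(range(m))
    cols += list(range(m))
    vals += list(diag)
    A = coo_matrix((vals, (rows, cols)), shape=(m, m)).tocsc()
    lu = splu(A)
    est_internal = lu.solve(rhs)
    # diagonal of A^-1 gives conditional variance of internals given tips
    inv_diag = np.array([lu.solve(_unit(m, i))[i] for i in range(m)])

    # sigma^2 from contrasts (REML divisor n-1, ML divisor n)
    C, _, tip_labels = _pic_operator(tree) if tree.is_binary else (None, None, None)
    if C is not None:
        contrasts = C @ X
        denom = (n - 1) if method == "reml" else n
        rate = (contrasts ** 2).sum(axis=0) / denom
    else:
        # polytomies: use the residual quadratic form of the fitted system
        q = np.zeros(p)
        node_val = {}
        for node in tree.preorder():
            if node.is_tip:
                node_val[id(node)] = X[tidx[id(node)]]
            else:
                node_val[id(node)] = est_internal[iidx[id(node)]]
        for node in tree.preorder():
            if node.parent is None:
                continue
            dx = node_val[id(node)] - node_val[id(node.parent)]
            q += dx * dx / node.duration
        denom = (n - 1) if method == "reml" else n
        rate = q / denom

    ids = _node_ids(tree)
    all_nodes = list(tree.preorder())
    idx = [ids[id(nd)] for nd in all_nodes]
    est = np.zeros((len(all_nodes), p))
    var = np.zeros((len(all_nodes), p))
    tip_flag = []
    for r, nd in enumerate(all_nodes):
        if nd.is_tip:
            est[r] = X[tidx[id(nd)]]
            tip_flag.append(True)
        else:
            est[r] = est_internal[iidx[id(nd)]]
            var[r] = inv_diag[iidx[id(nd)]] * rate
            tip_flag.append(False)
    cols_names = _trait_names(x, p)
    return AncestralStates(
        estimates=pd.DataFrame(est, index=idx, columns=cols_names),
        variances=pd.DataFrame(var, index=idx, columns=cols_names),
        rate=rate,
        is_tip=pd.Series(tip_flag, index=idx),
        method=method,
    )


def _unit(m: int, i: int) -> np.ndarray:
    e = np.zeros(m)
    e[i] = 1.0
    return e


def _align_matrix(x, tips: list[str]) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        missing = [t for t in tips if t not in x.index]
        if missing:
            raise TreeError(f"missing tip value(s): {missing}")
        return x.loc[tips].to_numpy(dtype=float)
    if isinstance(x, (pd.Series, dict)):
        return _align_values(x, tips)[:, None]
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != len(tips):
        raise TreeError("trait matrix row count does not match tip count")
    return arr


def _trait_names(x, p: int) -> list[str]:
    if isinstance(x, pd.DataFrame):
        return list(x.columns)
    if isinstance(x, pd.Series) and x.name:
        return [str(x.name)]
    return [f"trait{i + 1}" for i in range(p)]


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------

@dataclass
class CpmsGraph:
    """A phylogeny embedded in trait (and optionally time) coordinates.

    ``nodes`` indexes by node id and carries the trait coordinates, the age
    (NaN when the graph is a plain 2-D phylomorphospace), tip/internal flags
    and per-trait estimation variances; ``edges`` lists (parent, child) id
    pairs, one per tree edge.
    """

    nodes: pd.DataFrame
    edges: list[tuple[str, str]]
    trait_names: list[str]
    has_time: bool

    def projection_2d(self) -> pd.DataFrame:
        """Drop the time axis: the plain phylomorphospace coordinates."""
        return self.nodes[self.trait_names]


def _graph_from_states(
    tree: TimeTree, states: AncestralStates, with_time: bool
) -> CpmsGraph:
    ids = _node_ids(tree)
    if with_time and not tree.has_ages:
        raise TreeError("chronophylomorphospace requires a time-scaled tree")
    rows = []
    edges = []
    for node in tree.preorder():
        nid = ids[id(node)]
        row = {"id": nid, "is_tip": node.is_tip,
               "age": node.age if with_time else np.nan}
        for t in states.estimates.columns:
            row[t] = states.estimates.loc[nid, t]
            row[f"var_{t}"] = states.variances.loc[nid, t]
        rows.append(row)
        for child in node.children:
            edges.append((nid, ids[id(child)]))
    nodes = pd.DataFrame(rows).set_index("id")
    return CpmsGraph(
        nodes=nodes, edges=edges,
        trait_names=list(states.estimates.columns),
        has_time=with_time,
    )


def build_phylomorphospace(
    tree: TimeTree, scores: pd.DataFrame, method: str = "reml"
) -> CpmsGraph:
    """Embed the tree in a two-column trait space (ages ignored).

    Tips sit at their observed scores; internal nodes at the Brownian-motion
    maximum-likelihood ancestral estimates.
    """
    if scores.shape[1] != 2:
        raise ValueError("phylomorphospace needs exactly two trait columns")
    states = ancestral_ml(tree, scores, method=method)
    return _graph_from_states(tree, states, with_time=False)


def build_cpms(
    tree: TimeTree, scores: pd.DataFrame, method: str = "reml"
) -> CpmsGraph:
    """Chronophylomorphospace: phylomorphospace plus a node-age time axis.

    Every node's z coordinate is its age in Ma (extant tips at 0, fossil tips
    at their calibrated dates); parent age >= child age on every edge, and
    dropping the time axis reproduces :func:`build_phylomorphospace` exactly.
    """
    if scores.shape[1] != 2:
        raise ValueError("chronophylomorphospace needs exactly two trait columns")
    states = ancestral_ml(tree, scores, method=method)
    return _graph_from_states(tree, states, with_time=True)


def build_cpms_1d(
    tree: TimeTree, trait: pd.Series, method: str = "reml"
) -> CpmsGraph:
    """One-trait chronophylomorphospace: (trait, age) coordinates with 95%
    confidence bounds on every ancestral estimate."""
    states = ancestral_ml(tree, trait, method=method)
    graph = _graph_from_states(tree, states, with_time=True)
    name = states.estimates.columns[0]
    half = CI_MULTIPLIER * np.sqrt(graph.nodes[f"var_{name}"])
    graph.nodes["ci_lower"] = graph.nodes[name] - half
    graph.nodes["ci_upper"] = graph.nodes[name] + half
    return graph


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_graph(graph: CpmsGraph, path, format: str = "json") -> None:
    """Write a graph as JSON (single file), CSV (``<stem>_nodes.csv`` and
    ``<stem>_edges.csv``) or a static 3-D figure (``format='plot'``)."""
    import pathlib

    path = pathlib.Path(path)
    if format == "json":
        payload = {
            "trait_names": graph.trait_names,
            "has_time": graph.has_time,
            "nodes": json.loads(
                graph.nodes.reset_index().to_json(orient="records")
            ),
            "edges": [list(e) for e in graph.edges],
        }
        path.write_text(json.dumps(payload, indent=1))
    elif format == "csv":
        stem = path.with_suffix("")
        graph.nodes.reset_index().to_csv(f"{stem}_nodes.csv", index=False)
        pd.DataFrame(graph.edges, columns=["parent", "child"]).to_csv(
            f"{stem}_edges.csv", index=False
        )
    elif format == "plot":
        plot_cpms(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_graph_json(path) -> CpmsGraph:
    payload = json.loads(open(path).read())
    nodes = pd.DataFrame(payload["nodes"]).set_index("id")
    return CpmsGraph(
        nodes=nodes,
        edges=[tuple(e) for e in payload["edges"]],
        trait_names=payload["trait_names"],
        has_time=payload["has_time"],
    )


def plot_cpms(graph: CpmsGraph, path, elev: float = 20, azim: float = -60) -> None:
    """Static 3-D scatter-and-segments rendering of a CPMS (or a 2-D plot for
    a plain phylomorphospace / one-trait graph)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nodes = graph.nodes
    t = graph.trait_names
    fig = plt.figure(figsize=(7, 6))
    if graph.has_time and len(t) == 2:
        ax = fig.add_subplot(111, projection="3d")
        for parent, child in graph.edges:
            seg = nodes.loc[[parent, child]]
            ax.plot(seg[t[0]], seg[t[1]], seg["age"], c="0.5", lw=0.8)
        tips = nodes[nodes.is_tip]
        internal = nodes[~nodes.is_tip]
        ax.scatter(tips[t[0]], tips[t[1]], tips["age"], c="tab:blue", s=18)
        ax.scatter(internal[t[0]], internal[t[1]], internal["age"],
                   c="tab:red", s=10)
        ax.set_xlabel(t[0]); ax.set_ylabel(t[1]); ax.set_zlabel("age (Ma)")
        ax.invert_zaxis()  # past at the back
        ax.view_init(elev=elev, azim=azim)
    else:
        ax = fig.add_subplot(111)
        xcol = t[0]
        ycol = "age" if graph.has_time else t[1]
        for parent, child in graph.edges:
            seg = nodes.loc[[parent, child]]
            ax.plot(seg[xcol], seg[ycol], c="0.5", lw=0.8)
        if "ci_lower" in nodes.columns:
            err = nodes[~nodes.is_tip]
            ax.errorbar(
                err[xcol], err[ycol],
                xerr=(err[xcol] - err["ci_lower"], err["ci_upper"] - err[xcol]),
                fmt="none", ecolor="tab:red", alpha=0.6, lw=0.8,
            )
        ax.scatter(nodes[xcol], nodes[ycol],
                   c=np.where(nodes.is_tip, "tab:blue", "tab:red"), s=14)
        ax.set_xlabel(xcol); ax.set_ylabel(ycol)
        if graph.has_time:
            ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
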