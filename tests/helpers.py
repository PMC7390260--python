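"""Independent oracles and data constructors used across the test suite.

Everything here deliberately avoids the code paths it is used to check:
the CCA oracle maximizes the correlation numerically instead of using the
SVD route, the ontology resolver walks networkx shortest paths instead of
the package's hand-rolled BFS, and the exact-correlation constructor builds
data whose *sample* correlation matrix equals a target matrix exactly.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy.optimize import minimize

from omicslink import Namespace, OmicsMatrix


def make_matrix(values, namespace=Namespace.HGNC, prefix="f") -> OmicsMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsMatrix(
        [f"s{i + 1}" for i in range(n)],
        [f"{prefix}{j + 1}" for j in range(p)],
        values,
        namespace,
    )


def standardize(values: np.ndarray) -> np.ndarray:
    return (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)


def bruteforce_cca(Xv: np.ndarray, Yv: np.ndarray, restarts: int = 6) -> np.ndarray:
    """Sequential numerical maximization of cor(a'X, b'Y) with deflation.

    After each extracted pair the variate is regressed out of every column
    of its own block, which enforces the within-set orthogonality constraint
    of the next pair; the sequence of maxima equals the canonical
    correlations.
    """
    Ex, Ey = standardize(Xv).copy(), standardize(Yv).copy()
    k = min(Xv.shape[1], Yv.shape[1])
    rng = np.random.default_rng(987654321)
    rs = []
    for _ in range(k):
        p = Ex.shape[1]

        def negcorr(v):
            u = Ex @ v[:p]
            w = Ey @ v[p:]
            if u.std() < 1e-10 or w.std() < 1e-10:
                return 0.0
            return -float(np.corrcoef(u, w)[0, 1])

        best, bu, bw = -np.inf, None, None
        for _ in range(restarts):
            res = minimize(
                negcorr,
                rng.standard_normal(p + Ey.shape[1]),
                method="BFGS",
                options={"gtol": 1e-12, "maxiter": 2000},
            )
            if -res.fun > best:
                best = -res.fun
                bu, bw = Ex @ res.x[:p], Ey @ res.x[p:]
        rs.append(best)
        Ex = Ex - np.outer(bu, bu @ Ex) / (bu @ bu)
        Ey = Ey - np.outer(bw, bw @ Ey) / (bw @ bw)
    return np.array(rs)


def exact_corr_data(R: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Data whose *sample* correlation matrix equals R exactly.

    Draws Gaussian data, empirically whitens it (sample covariance becomes
    the identity), then recolors with the Cholesky factor of R.
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, k))
    Z -= Z.mean(axis=0)
    L = np.linalg.cholesky(np.cov(Z, rowvar=False))
    Zw = Z @ np.linalg.inv(L).T
    return Zw @ np.linalg.cholesky(R).T


def random_ontology(rng: np.random.Generator, n_nodes: int = 12, edge_prob: float = 0.25):
    """Random DAG over integer ids (edges child→parent only low→high id, so
    acyclicity is guaranteed) plus a random mapped subset."""
    ids = list(range(1, n_nodes + 1))
    G = nx.DiGraph()
    G.add_nodes_from(ids)
    for i in ids:
        for j in ids:
            if i < j and rng.random() < edge_prob:
                G.add_edge(i, j)  # i is the child of j
    n_mapped = int(rng.integers(1, max(2, n_nodes // 2)))
    mapped = set(rng.choice(ids, size=n_mapped, replace=False).tolist())
    return G, mapped


def bruteforce_resolve(G: nx.DiGraph, mapped: set[int], query: int):
    """Shortest-path resolver over the ontology, independent of the package's
    BFS: returns (status, representative, distance) using networkx distances."""
    if query in mapped:
        return "DIRECT", query, 0
    if query in G:
        # descendants: walk against edge direction (edges are child -> parent)
        desc = nx.single_source_shortest_path_length(G.reverse(copy=True), query)
        hits = [(d, node) for node, d in desc.items() if node in mapped and d > 0]
        if hits:
            d, node = min(hits)
            return "VIA_CHILD", node, d
        anc = nx.single_source_shortest_path_length(G, query)
        hits = [(d, node) for node, d in anc.items() if node in mapped and d > 0]
        if hits:
            d, node = min(hits)
            return "VIA_PARENT", node, d
    return "UNMAPPED", None, 0
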