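"""Brute-force oracle implementations of the ten network centralities,
independent of the package's computation path: explicit path enumeration,
power iteration, Katz series summation and per-pair current-flow solves.
Intended for small graphs (<= 8 nodes)."""

import itertools

import networkx as nx
import numpy as np


def oracle_centralities(g: nx.Graph, alpha: float = 0.1, beta: float = 1.0):
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    out = {v: {} for v in nodes}

    for v in nodes:
        out[v]["degree"] = len(list(g.neighbors(v)))
    for v in nodes:
        nbrs = list(g.neighbors(v))
        out[v]["average_neighbor_degree"] = (
            sum(out[u]["degree"] for u in nbrs) / len(nbrs) if nbrs else 0.0)

    for v in nodes:
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            out[v]["clustering"] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if g.has_edge(a, b))
        out[v]["clustering"] = 2 * links / (k * (k - 1))

    # square clustering (Lind et al. form)
    for v in nodes:
        nbrs = list(g.neighbors(v))
        num = den = 0.0
        for u, w in itertools.combinations(nbrs, 2):
            q = sum(1 for x in nodes
                    if x != v and g.has_edge(u, x) and g.has_edge(w, x))
            theta = 1 if g.has_edge(u, w) else 0
            a = (out[u]["degree"] - (1 + q + theta)) + (
                out[w]["degree"] - (1 + q + theta))
            num += q
            den += q + a
        out[v]["square_clustering"] = num / den if den > 0 else 0.0

    # all-pairs weighted shortest distances (Floyd-Warshall)
    INF = float("inf")
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for u, v, data in g.edges(data=True):
        i, j = idx[u], idx[v]
        d[i, j] = d[j, i] = min(d[i, j], data["weight"])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]

    for v in nodes:
        i = idx[v]
        reach = [j for j in range(n) if j != i and d[i, j] < INF]
        if not reach:
            out[v]["closeness"] = 0.0
            out[v]["eccentricity"] = 0.0
        else:
            s = sum(d[i, j] for j in reach)
            out[v]["closeness"] = (len(reach) / s) * (len(reach) / (n - 1))
            out[v]["eccentricity"] = max(d[i, j] for j in reach)

    # betweenness by exhaustive shortest-path enumeration
    bet = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        best = d[idx[s], idx[t]]
        if best == INF:
            continue
        paths = []

        def dfs(node, visited, w):
            if w > best + 1e-9:
                return
            if node == t:
                if abs(w - best) < 1e-9:
                    paths.append(list(visited))
                return
            for nb in g.neighbors(node):
                if nb not in visited:
                    dfs(nb, visited + [nb], w + g.edges[node, nb]["weight"])

        dfs(s, [s], 0.0)
        sigma = len(paths)
        for v in nodes:
            if v in (s, t):
                continue
            bet[v] += sum(1 for p in paths if v in p) / sigma
    norm = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    for v in nodes:
        out[v]["betweenness"] = bet[v] * norm

    for comp in nx.connected_components(g):
        cn = sorted(comp, key=lambda v: idx[v])
        k = len(cn)
        if k == 1:
            v = cn[0]
            out[v]["eigenvector"] = 1.0
            out[v]["katz"] = beta
            out[v]["flow_closeness"] = 0.0
            continue
        cidx = {v: i for i, v in enumerate(cn)}
        A = np.zeros((k, k))
        for u, v in g.edges(cn):
            if u in cidx and v in cidx:
                A[cidx[u], cidx[v]] = A[cidx[v], cidx[u]] = 1.0

        # power iteration on A + I (shift kills bipartite oscillation)
        x = np.ones(k)
        for _ in range(50_000):
            x2 = (A + np.eye(k)) @ x
            x2 /= np.linalg.norm(x2)
            if np.linalg.norm(x2 - x) < 1e-14:
                x = x2
                break
            x = x2
        for v in cn:
            out[v]["eigenvector"] = x[cidx[v]]

        # Katz as the truncated power series beta * sum alpha^k A^k 1
        kz = np.zeros(k)
        term = beta * np.ones(k)
        for _ in range(5_000):
            kz += term
            term = alpha * (A @ term)
            if np.abs(term).max() < 1e-15:
                break
        for v in cn:
            out[v]["katz"] = kz[cidx[v]]

        # current-flow closeness: per-pair grounded Laplacian solves with
        # conductance 1/weight; scaled by (k-1)/(n-1) as for closeness
        L = np.zeros((k, k))
        for u, v, data in g.edges(cn, data=True):
            if u in cidx and v in cidx:
                c = 1.0 / data["weight"]
                iu, iv = cidx[u], cidx[v]
                L[iu, iu] += c
                L[iv, iv] += c
                L[iu, iv] -= c
                L[iv, iu] -= c
        for v in cn:
            total = 0.0
            for w in cn:
                if w == v:
                    continue
                iu, iv = cidx[v], cidx[w]
                Lg = np.delete(np.delete(L, iv, 0), iv, 1)
                b = np.zeros(k)
                b[iu] = 1.0
                b = np.delete(b, iv)
                phi = np.insert(np.linalg.solve(Lg, b), iv, 0.0)
                total += phi[iu] - phi[iv]
            out[v]["flow_closeness"] = (k - 1) / total * ((k - 1) / (n - 1))
    return out
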