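"""Independent brute-force oracles for graph descriptors.

Everything here is computed from first principles (BFS shortest paths,
explicit geodesic counting, characteristic-polynomial roots) without
networkx, to cross-check the feature encoders.
"""

import itertools
from collections import deque

import numpy as np


def bfs_distances(nodes, edges, source):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def count_geodesics(nodes, edges, s, t):
    """(#shortest s-t paths, {v: #shortest s-t paths through interior v})."""
    ds = bfs_distances(nodes, edges, s)
    if t not in ds:
        return 0, {}
    d = ds[t]
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    paths = []

    def walk(path):
        u = path[-1]
        if u == t:
            paths.append(path)
            return
        for v in adj[u]:
            if v in ds and ds[v] == len(path) and ds.get(v, 99) <= d:
                wd = bfs_distances(nodes, edges, v).get(t)
                if wd is not None and len(path) + wd == d:
                    walk(path + [v])

    walk([s])
    through = {}
    for p in paths:
        for v in p[1:-1]:
            through[v] = through.get(v, 0) + 1
    return len(paths), through


def brute_topology(nodes, edges):
    """The 10 topology descriptors, by exhaustive computation."""
    nodes = sorted(nodes)
    n = len(nodes)
    if n == 1:
        return np.array([1.0] + [0.0] * 9)
    deg = {v: 0 for v in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    avg_deg_c = np.mean([deg[v] / (n - 1) for v in nodes])

    closeness = []
    for v in nodes:
        dist = bfs_distances(nodes, edges, v)
        reach = len(dist) - 1
        tot = sum(dist.values())
        closeness.append(
            (reach / (n - 1)) * (reach / tot) if tot > 0 else 0.0
        )
    avg_clo = np.mean(closeness)

    bet = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        sigma, through = count_geodesics(nodes, edges, s, t)
        if sigma == 0:
            continue
        for v, cnt in through.items():
            bet[v] += cnt / sigma
    norm = (n - 1) * (n - 2) / 2.0
    avg_bet = np.mean([bet[v] / norm for v in nodes]) if norm else 0.0

    # components; largest by (size, -min node)
    comps = []
    seen = set()
    for v in nodes:
        if v in seen:
            continue
        comp = set(bfs_distances(nodes, edges, v))
        comps.append(comp)
        seen |= comp
    comp = max(comps, key=lambda c: (len(c), -min(c)))
    if len(comp) > 1:
        ecc = {
            v: max(bfs_distances(sorted(comp),
                                 [e for e in edges if e[0] in comp and e[1] in comp],
                                 v).values())
            for v in comp
        }
        radius, diameter = float(min(ecc.values())), float(max(ecc.values()))
        avg_ecc = float(np.mean(list(ecc.values())))
    else:
        radius = diameter = avg_ecc = 0.0

    end_points = float(sum(1 for v in nodes if deg[v] == 1))

    clus = []
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    for v in nodes:
        k = deg[v]
        if k < 2:
            clus.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
        clus.append(2.0 * links / (k * (k - 1)))
    return np.array([
        float(n), float(len(edges)), avg_deg_c, avg_clo, avg_bet,
        radius, diameter, avg_ecc, end_points, float(np.mean(clus)),
    ])


def brute_spectrum(nodes, edges, tol=1e-4):
    """The 5 spectrum descriptors via the exact characteristic polynomial
    (sympy, integer arithmetic) and its high-precision real roots, with
    multiplicities read off the exact factorization."""
    import sympy

    nodes = sorted(nodes)
    n = len(nodes)
    if n == 1:
        return np.array([0.0, 0.0, 1.0, 0.0, 0.0])
    idx = {v: k for k, v in enumerate(nodes)}
    a = sympy.zeros(n, n)
    for u, v in edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
    lam = sympy.Symbol("lam")
    poly = a.charpoly(lam)
    roots = sympy.Poly(poly.as_expr(), lam).all_roots()
    eig = sorted((float(sympy.N(r, 30)) for r in roots), reverse=True)
    distinct = 1
    for k in range(1, n):
        if abs(eig[k] - eig[k - 1]) > tol:
            distinct += 1
    eig = np.array(eig)
    return np.array(
        [eig[0], eig[1], float(distinct), eig.sum(), np.abs(eig).sum()]
    )


def random_graph(rng, max_nodes=8):
    """A random labeled graph on 2..max_nodes nodes."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = list(range(1, n + 1))
    p = rng.uniform(0.15, 0.7)
    edges = [
        (a, b) for a, b in itertools.combinations(nodes, 2) if rng.random() < p
    ]
    return nodes, edges
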