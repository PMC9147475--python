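"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, for betweenness, the
algorithm) used by the package: betweenness is computed by exhaustive
enumeration of every shortest path, enrichment reports by plain Python
loops over explicit combinations.
"""

import itertools
import math
from collections import deque

import numpy as np


def enumerate_shortest_paths(adj: dict, s, t) -> list[list]:
    """All shortest s-t paths via BFS distances + backward DFS expansion."""
    dist = {s: 0}
    dq = deque([s])
    while dq:
        u = dq.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                dq.append(v)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == s:
            paths.append(path[::-1])
            return
        for v in adj[u]:
            if dist.get(v, -1) == dist[u] - 1:
                extend(path + [v])

    extend([t])
    return paths


def brute_force_betweenness(graph) -> dict:
    """Cb(n) by counting interior occurrences over all shortest paths.

    Unordered node pairs, endpoints excluded, unreachable pairs
    contribute nothing — the same convention as the pipeline's
    centrality table.
    """
    nodes = list(graph.nodes)
    adj = {n: sorted(graph.neighbors(n)) for n in nodes}
    cb = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        for n in nodes:
            if n == s or n == t:
                continue
            through = sum(1 for p in paths if n in p[1:-1])
            cb[n] += through / len(paths)
    return cb


def brute_force_consensus(signatures: dict, known: list, top_k: int):
    """Consensus ranking by explicit enumeration of every similarity list.

    ``signatures``: compound -> vector. Returns {candidate: (count,
    average_rank)} plus the final overall order.
    """

    def cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(np.dot(a, b) / (na * nb))

    ranks = {}
    for k in sorted(known):
        sims = [(c, cos(signatures[k], v)) for c, v in signatures.items() if c != k]
        sims.sort(key=lambda cv: (-cv[1], cv[0]))
        for pos, (c, _) in enumerate(sims[:top_k], start=1):
            if c in known:
                continue
            ranks.setdefault(c, []).append(pos)
    stats = {c: (len(r), sum(r) / len(r)) for c, r in ranks.items()}
    order = sorted(stats, key=lambda c: (-stats[c][0], stats[c][1], c))
    return stats, order


def brute_force_enrichment(vectors: dict, m: np.ndarray, max_size: int, alpha: float):
    """Every combination scored with the textbook formulas, loop by loop.

    Null per size k = Sc of all size-k combinations of the same drugs
    (exhaustive); p = (r+1)/(n+1) counting strictly greater nulls.
    """

    def sc(v):
        nv = np.linalg.norm(v.astype(float))
        nm = np.linalg.norm(m.astype(float))
        if nv == 0:
            return None
        return float(np.dot(v, m) / (nv * nm))

    names = sorted(vectors)
    out = {}
    for size in range(1, max_size + 1):
        combos = list(itertools.combinations(names, size))
        scores = {}
        for members in combos:
            net = np.sign(sum(vectors[d].astype(float) for d in members))
            scores[members] = sc(net)
        null = [v for v in scores.values() if v is not None]
        for members, s in scores.items():
            if s is None:
                out[members] = (None, None, False)
                continue
            r = sum(1 for v in null if v > s)
            p = (r + 1) / (len(null) + 1)
            out[members] = (s, p, p < alpha)
    return out
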