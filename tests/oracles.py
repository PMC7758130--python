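"""Independent brute-force oracles used by the test suite.

Each oracle is a literal, slow implementation written directly from the
definitions (exact rational arithmetic, exhaustive scans, path enumeration)
and deliberately shares no code with the package.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


# --- hypergeometric ---------------------------------------------------------

def exact_pmf(k: int, N: int, M: int, n: int) -> Fraction:
    if k < 0 or k > M or n - k > N - M or n - k < 0:
        return Fraction(0)
    return Fraction(comb(M, k) * comb(N - M, n - k), comb(N, n))


def exact_tail(k: int, N: int, M: int, n: int) -> Fraction:
    return sum((exact_pmf(j, N, M, n) for j in range(max(k, 0), min(M, n) + 1)),
               Fraction(0))


# --- meet/min ---------------------------------------------------------------

def bf_meet_min(a: frozenset, b: frozenset):
    if len(a) == 0 or len(b) == 0:
        return None
    common = sum(1 for x in a if x in b)
    return common / min(len(a), len(b))


# --- KS connectivity (literal max scan over Eq-style terms) ------------------

def bf_ks(tag_positions: list[int], n: int) -> tuple[float, float, float]:
    v = sorted(tag_positions)
    t = len(v)
    a = max(j / t - v[j - 1] / n for j in range(1, t + 1))
    b = max(v[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    ks = a if a > b else (-b if b > a else a)
    return a, b, ks


# --- overlap partition -------------------------------------------------------

def bf_overlap(de1: dict, de2: dict) -> dict:
    out = {"shared_up": set(), "shared_down": set(), "discordant": set(),
           "only_ctx1": set(), "only_ctx2": set()}
    for f in set(de1) | set(de2):
        if f in de1 and f in de2:
            if de1[f] == de2[f] == "up":
                out["shared_up"].add(f)
            elif de1[f] == de2[f] == "down":
                out["shared_down"].add(f)
            else:
                out["discordant"].add(f)
        elif f in de1:
            out["only_ctx1"].add(f)
        else:
            out["only_ctx2"].add(f)
    return out


# --- graph metrics -----------------------------------------------------------

def _bfs_dists(adj: dict, source) -> dict:
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def _count_shortest_paths(adj: dict, s, dist: dict):
    """Number of shortest s->x paths for every reachable x (DP over BFS levels)."""
    sigma = {x: 0 for x in dist}
    sigma[s] = 1
    for x in sorted(dist, key=dist.get):
        for w in adj[x]:
            if w in dist and dist[w] == dist[x] + 1:
                sigma[w] += sigma[x]
    return sigma


def bf_node_metrics(nodes: list, edges: list) -> dict:
    """degree / aspl / betweenness / closeness / topological coefficient.

    Betweenness by explicit shortest-path counting over all (s, t) pairs,
    normalized by (m-1)(m-2)/2 within each connected component.
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    out = {}
    dists = {v: _bfs_dists(adj, v) for v in nodes}
    for v in nodes:
        comp = set(dists[v])
        m = len(comp)
        # average shortest path length / closeness
        if m == 1:
            aspl = 0.0
            clo = 0.0
        else:
            aspl = sum(dists[v].values()) / (m - 1)
            clo = 1.0 / aspl
        # betweenness: fraction of shortest (s,t) paths through v
        btw = 0.0
        if m > 2:
            for s in comp:
                for t in comp:
                    if s == t or s == v or t == v:
                        continue
                    sigma = _count_shortest_paths(adj, s, dists[s])
                    if dists[s].get(t, -1) == dists[s].get(v, 1e9) + dists[v].get(t, 1e9):
                        sigma_v = _count_shortest_paths(adj, v, dists[v])
                        through = sigma[v] * sigma_v[t]
                    else:
                        through = 0
                    btw += through / sigma[t]
            btw /= 2.0  # each unordered pair counted twice
            btw /= (m - 1) * (m - 2) / 2.0
        # topological coefficient
        k = len(adj[v])
        if k <= 1:
            tc = 0.0
        else:
            partners = set()
            for u in adj[v]:
                partners.add(u)
                partners |= adj[u]
            partners.discard(v)
            vals = [
                (len(adj[v] & adj[p]) + (1 if p in adj[v] else 0)) / k
                for p in partners
            ]
            vals = [x for x in vals if x > 0]
            tc = sum(vals) / len(vals) if vals else 0.0
        out[v] = {
            "degree": len(adj[v]),
            "avg_shortest_path_length": aspl,
            "betweenness": btw,
            "closeness": clo,
            "topological_coefficient": tc,
        }
    return out
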