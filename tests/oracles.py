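"""Independent brute-force oracles, deliberately naive.

These re-derive quantities by the most literal route available (explicit
double loops, dense power iteration, depth-first search, all-pairs
enumeration) and share no code with the production paths they check.
"""

from __future__ import annotations

import numpy as np


def brute_coulomb(mol_i, mol_j, ff) -> float:
    """Explicit 9-term site-site Coulomb sum over H_a, H_b, M pairs."""
    sites_i = [(mol_i.pos_Ha, ff.q_H), (mol_i.pos_Hb, ff.q_H),
               (mol_i.pos_M, ff.q_M)]
    sites_j = [(mol_j.pos_Ha, ff.q_H), (mol_j.pos_Hb, ff.q_H),
               (mol_j.pos_M, ff.q_M)]
    total = 0.0
    for ri, qi in sites_i:
        for rj, qj in sites_j:
            r = ((ri[0] - rj[0]) ** 2 + (ri[1] - rj[1]) ** 2
                 + (ri[2] - rj[2]) ** 2) ** 0.5
            total += ff.f_coulomb * qi * qj / r
    return total


def brute_lennard_jones(mol_i, mol_j, ff) -> float:
    """Literal 4ε[(σ/r)^12 − (σ/r)^6] on the O-O distance."""
    d = mol_i.pos_O - mol_j.pos_O
    r = (d[0] ** 2 + d[1] ** 2 + d[2] ** 2) ** 0.5
    return 4.0 * ff.epsilon_OO * ((ff.sigma_OO / r) ** 12
                                  - (ff.sigma_OO / r) ** 6)


def dfs_components(nodes, edges) -> list[set]:
    """Connected components by explicit depth-first labelling."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack = [start]
        comp = set()
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.add(u)
            stack.extend(adj[u] - seen)
        comps.append(comp)
    return comps


def power_iteration_pagerank(nodes, edges, damping=0.85, tol=1e-14,
                             max_iter=100_000) -> dict:
    """Dense power iteration on the explicit damped transition matrix.

    Undirected edges are walked both ways; dangling (degree-0) nodes
    redistribute uniformly; teleportation is uniform.
    """
    nodes = list(nodes)
    n = len(nodes)
    index = {u: k for k, u in enumerate(nodes)}
    p = np.zeros((n, n))
    deg = {u: 0 for u in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    for a, b in edges:
        p[index[a], index[b]] += 1.0 / deg[a]
        p[index[b], index[a]] += 1.0 / deg[b]
    for u in nodes:
        if deg[u] == 0:
            p[index[u], :] = 1.0 / n
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        x_new = damping * (x @ p) + (1.0 - damping) / n
        if np.abs(x_new - x).sum() < tol:
            x = x_new
            break
        x = x_new
    return {u: float(x[index[u]]) for u in nodes}


def all_pairs_within(ids, coms, cutoff) -> set[tuple]:
    """O(N²) enumeration of unordered id pairs with COM distance <= cutoff."""
    out = set()
    n = len(ids)
    for a in range(n):
        for b in range(a + 1, n):
            if np.linalg.norm(coms[a] - coms[b]) <= cutoff:
                out.add((min(ids[a], ids[b]), max(ids[a], ids[b])))
    return out
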