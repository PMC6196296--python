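"""Independent brute-force oracles, kept deliberately naive.

These re-derive the quantities the package computes by routes that share
no code with the production path: exhaustive auxiliary-node assignment for
weighted isomer counts, orbit counting under full graph automorphisms for
the catalog size, and explicit pair enumeration for the Mann-Whitney AUC.
"""

from __future__ import annotations

import itertools

import numpy as np


# --- weighted isomer counting ------------------------------------------------

def brute_count(a: np.ndarray, template, i: int, j: int) -> float:
    """Sum over ordered injective auxiliary assignments of edge-factor
    products; `a` is the weight matrix (diagonal ignored)."""
    roles = template.roles
    n = a.shape[0]
    others = [x for x in range(n) if x not in (i, j)]
    n_aux = template.n_nodes - 2
    total = 0.0
    for aux in itertools.permutations(others, n_aux):
        assignment = {"i": i, "j": j}
        for role, node in zip(roles[2:], aux):
            assignment[role] = node
        prod = 1.0
        for r1, r2 in itertools.combinations(roles, 2):
            w = a[assignment[r1], assignment[r2]]
            if tuple(sorted((r1, r2), key="ijlm".index)) in template.present_edges:
                prod *= w
            else:
                prod *= 1.0 - w
        total += prod
    return total


def brute_tensor(a: np.ndarray, catalog) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros((n, n, len(catalog)))
    for k, tpl in enumerate(catalog):
        for i in range(n):
            for j in range(n):
                if i != j:
                    out[i, j, k] = brute_count(a, tpl, i, j)
    return out


# --- catalog size via unlabeled graphs + automorphism orbits -----------------

def _labeled_connected_graphs(n: int):
    """All connected graphs on nodes 0..n-1 as frozensets of edges."""
    pairs = list(itertools.combinations(range(n), 2))
    for mask in itertools.product((0, 1), repeat=len(pairs)):
        edges = frozenset(p for p, b in zip(pairs, mask) if b)
        # connectivity over all n nodes
        seen = {0}
        frontier = [0]
        while frontier:
            u = frontier.pop()
            for x, y in edges:
                for a_, b_ in ((x, y), (y, x)):
                    if a_ == u and b_ not in seen:
                        seen.add(b_)
                        frontier.append(b_)
        if len(seen) == n:
            yield edges


def _apply(perm, edges):
    return frozenset(frozenset((perm[a], perm[b])) for a, b in edges)


def _canonical(n: int, edges):
    frozen = frozenset(frozenset(e) for e in edges)
    return min(
        tuple(sorted(tuple(sorted(e)) for e in _apply(p, edges)))
        for p in itertools.permutations(range(n))
    ), frozen


def orbit_catalog(max_nodes: int = 4):
    """Role-placement orbits over all non-isomorphic connected graphs.

    For every isomorphism class of connected graphs on 2..max_nodes nodes,
    count the orbits of ordered node pairs (source, target) under the
    graph's full automorphism group.  Returns one canonical key per orbit:
    the minimum, over relabelings sending source to 0 and target to 1, of
    the sorted edge tuple.  The number of keys is the number of
    graphlet-interaction isomers.
    """
    keys = set()
    for n in range(2, max_nodes + 1):
        classes = {}
        for edges in _labeled_connected_graphs(n):
            canon, _ = _canonical(n, edges)
            classes.setdefault(canon, edges)
        for edges in classes.values():
            frozen = frozenset(frozenset(e) for e in edges)
            autos = [
                p for p in itertools.permutations(range(n))
                if _apply(p, edges) == frozen
            ]
            seen_pairs = set()
            for u, v in itertools.permutations(range(n), 2):
                orbit = frozenset((p[u], p[v]) for p in autos)
                if orbit in seen_pairs:
                    continue
                seen_pairs.add(orbit)
                keys.add(pair_canonical_key(n, edges, u, v))
    return keys


def pair_canonical_key(n: int, edges, u: int, v: int):
    """Canonical form of (graph, ordered pair): minimum over bijections to
    0..n-1 with u -> 0, v -> 1 of the sorted edge tuple."""
    rest = [x for x in range(n) if x not in (u, v)]
    best = None
    for perm_rest in itertools.permutations(range(2, n)):
        mapping = {u: 0, v: 1}
        mapping.update(dict(zip(rest, perm_rest)))
        mapped = tuple(sorted(tuple(sorted((mapping[a], mapping[b]))) for a, b in edges))
        if best is None or mapped < best:
            best = mapped
    return (n, best)


def template_canonical_key(template):
    """The same canonical form computed from a package catalog template."""
    role_index = {r: k for k, r in enumerate(template.roles)}
    edges = [(role_index[a], role_index[b]) for a, b in template.present_edges]
    return pair_canonical_key(template.n_nodes, edges, 0, 1)


# --- Mann-Whitney AUC by explicit pair enumeration ---------------------------

def mann_whitney_auc(pos, neg) -> float:
    """Fraction of (positive, negative) pairs ranked correctly, ties half."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
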