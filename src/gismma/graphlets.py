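"""Graphlet-interaction isomers and weighted counting on similarity networks.

A graphlet is a small connected subgraph; here graphlets of 2-4 nodes are
used.  A *graphlet interaction isomer* is a graphlet together with an
ordered placement of two distinguished nodes — the source role ``i`` and the
target role ``j`` — with placements identified when an automorphism of the
graphlet maps one onto the other while permuting only the auxiliary roles.
Enumerating every connected role-labeled configuration on 2-4 nodes and
deduplicating under the swap of the two auxiliary roles yields exactly 28
isomer templates, labeled I1..I28 in a fixed, stable order.

For an ordered node pair (i, j) in a weighted network with edge weights
``a`` in [0, 1], the weighted count of isomer I_k is a sum over ordered
assignments of *distinct* auxiliary nodes l, m (both outside {i, j}) of a
product of one factor per role pair:

    b_st = a_st        if the isomer has an edge between roles s and t,
    b_st = 1 - a_st    if it does not

(3-node templates sum over l only; the 2-node template is the single factor
b_ij).  Counts are then normalized per source node and isomer so that each
nonzero row over targets sums to 1; a source with no interaction mass keeps
an all-zero row.  Self-edges never participate: auxiliary roles range over
nodes distinct from i and j, and the pair (i, i) is never scored.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ValidationError
from .similarity import SimilarityMatrix

ROLE_ORDER = ("i", "j", "l", "m")

#: Edges are unordered role pairs stored as tuples sorted by ROLE_ORDER.
RolePair = tuple[str, str]


def _edge(a: str, b: str) -> RolePair:
    return tuple(sorted((a, b), key=ROLE_ORDER.index))  # type: ignore[return-value]


@dataclass(frozen=True)
class IsomerTemplate:
    """One graphlet-interaction isomer: a role-labeled edge configuration."""

    label: str
    n_nodes: int
    present_edges: frozenset[RolePair]
    absent_edges: frozenset[RolePair]

    @property
    def roles(self) -> tuple[str, ...]:
        return ROLE_ORDER[: self.n_nodes]

    @property
    def role_pairs(self) -> tuple[RolePair, ...]:
        return tuple(itertools.combinations(self.roles, 2))

    def has_edge(self, a: str, b: str) -> bool:
        return _edge(a, b) in self.present_edges


@dataclass(frozen=True)
class IsomerCatalog:
    """The fixed ordered catalog of the 28 isomer templates."""

    templates: tuple[IsomerTemplate, ...]

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def __getitem__(self, k: int) -> IsomerTemplate:
        return self.templates[k]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.templates)


def _is_connected(roles: tuple[str, ...], edges: frozenset[RolePair]) -> bool:
    """True when the edge set connects *all* roles (no isolated role)."""
    if not edges:
        return len(roles) == 1
    seen = {roles[0]}
    frontier = [roles[0]]
    adj: dict[str, list[str]] = {r: [] for r in roles}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    while frontier:
        cur = frontier.pop()
        for nxt in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return len(seen) == len(roles)


def _aux_canonical(
    roles: tuple[str, ...], edges: frozenset[RolePair]
) -> frozenset[RolePair]:
    """Canonical representative of an edge set under auxiliary-role swaps.

    Automorphisms that fix the interaction roles i and j can only permute
    the auxiliary roles; with at most two of them the group is {id, l<->m}.
    """
    aux = roles[2:]
    best = edges
    for perm in itertools.permutations(aux):
        mapping = dict(zip(aux, perm))
        mapping.update({"i": "i", "j": "j"})
        mapped = frozenset(_edge(mapping[a], mapping[b]) for a, b in edges)
        if sorted(mapped) < sorted(best):
            best = mapped
    return best


@lru_cache(maxsize=1)
def enumerate_isomers() -> IsomerCatalog:
    """Build the catalog of all 28 graphlet-interaction isomer templates.

    Generated at first use by exhaustive enumeration: every subset of role
    pairs on 2, 3 and 4 roles that connects all roles, deduplicated under
    the swap of the two auxiliary roles.  Ordering is stable: by node
    count, then edge count, then lexicographic edge list.
    """
    templates: list[IsomerTemplate] = []
    for n_nodes in (2, 3, 4):
        roles = ROLE_ORDER[:n_nodes]
        all_pairs = tuple(itertools.combinations(roles, 2))
        seen: set[frozenset[RolePair]] = set()
        configs: list[frozenset[RolePair]] = []
        for mask in itertools.product((False, True), repeat=len(all_pairs)):
            edges = frozenset(p for p, keep in zip(all_pairs, mask) if keep)
            if not _is_connected(roles, edges):
                continue
            canon = _aux_canonical(roles, edges)
            if canon in seen:
                continue
            seen.add(canon)
            configs.append(canon)
        configs.sort(key=lambda e: (len(e), sorted(e)))
        for edges in configs:
            templates.append(
                IsomerTemplate(
                    label="",  # assigned below once global order is fixed
                    n_nodes=n_nodes,
                    present_edges=edges,
                    absent_edges=frozenset(all_pairs) - edges,
                )
            )
    labeled = tuple(
        IsomerTemplate(f"I{k + 1}", t.n_nodes, t.present_edges, t.absent_edges)
        for k, t in enumerate(templates)
    )
    return IsomerCatalog(labeled)


@dataclass
class InteractionTensor:
    """Weighted isomer counts for every ordered node pair of one network.

    ``counts[i, j, k]`` is the weighted number of isomer ``k`` for the
    interaction from node ``i`` to node ``j``; ``normalized`` divides each
    (source, isomer) row over targets by its sum (zero rows stay zero).
    """

    entity_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)
    normalized: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    @property
    def n_isomers(self) -> int:
        return self.counts.shape[2]


def edge_factor(isomer: IsomerTemplate, role_pair: RolePair, weight: float) -> float:
    """The single-edge factor b_st: the weight where the isomer has an edge,
    one minus the weight where it does not."""
    if not 0.0 <= weight <= 1.0:
        raise ValidationError(f"edge weight {weight!r} outside [0, 1]")
    pair = _edge(*role_pair)
    if pair in isomer.present_edges:
        return weight
    if pair in isomer.absent_edges:
        return 1.0 - weight
    raise ValidationError(f"role pair {role_pair!r} not part of {isomer.label}")


def _weights_no_diag(network: SimilarityMatrix) -> np.ndarray:
    a = network.values.copy()
    np.fill_diagonal(a, 0.0)
    return a


def _factor_matrix(a: np.ndarray, present: bool) -> np.ndarray:
    return a.copy() if present else 1.0 - a


def _template_matrices(tpl: IsomerTemplate, a: np.ndarray) -> dict[RolePair, np.ndarray]:
    return {
        pair: _factor_matrix(a, pair in tpl.present_edges)
        for pair in tpl.role_pairs
    }


def _count_template(a: np.ndarray, tpl: IsomerTemplate, chunk: int = 64) -> np.ndarray:
    """Counts of one template for all ordered pairs; ``a`` has zero diagonal.

    The sum over ordered distinct auxiliary assignments reduces to matrix
    contractions: with per-role-pair factor matrices P=(i,l), Q=(j,l),
    P2=(i,m), Q2=(j,m), F=(l,m), the 4-node count is

        C[i,j] = B_ij[i,j] * ( sum_{l,m} P[i,l] Q[j,l] F[l,m] P2[i,m] Q2[j,m]
                               - sum_l  P[i,l] Q[j,l] F[l,l] P2[i,l] Q2[j,l] )

    where zeroing the diagonals of P, Q, P2, Q2 excludes auxiliaries equal
    to i or j and the subtracted term removes l = m.
    """
    n = a.shape[0]
    fm = _template_matrices(tpl, a)
    bij = fm[("i", "j")]
    if tpl.n_nodes == 2:
        out = bij.copy()
        np.fill_diagonal(out, 0.0)
        return out
    p = fm[("i", "l")]
    q = fm[("j", "l")]
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(q, 0.0)
    if tpl.n_nodes == 3:
        out = bij * (p @ q.T)
        np.fill_diagonal(out, 0.0)
        return out
    p2 = fm[("i", "m")]
    q2 = fm[("j", "m")]
    np.fill_diagonal(p2, 0.0)
    np.fill_diagonal(q2, 0.0)
    f = fm[("l", "m")]
    fdiag = np.diag(f).copy()
    out = np.empty((n, n))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m1 = p[lo:hi, None, :] * q[None, :, :]      # (c, j, l)
        m2 = p2[lo:hi, None, :] * q2[None, :, :]    # (c, j, m)
        full = np.einsum("cjl,lm,cjm->cj", m1, f, m2, optimize=True)
        diag = np.einsum("cjl,l,cjl->cj", m1, fdiag, m2, optimize=True)
        out[lo:hi] = bij[lo:hi] * (full - diag)
    np.fill_diagonal(out, 0.0)
    return out


def count_isomer(
    network: SimilarityMatrix,
    isomer: IsomerTemplate,
    source: str,
    target: str,
) -> float:
    """Weighted count of one isomer for the ordered pair (source, target)."""
    if source == target:
        raise ValidationError("source and target must differ")
    i = network.index_of(source)
    j = network.index_of(target)
    a = _weights_no_diag(network)
    fm = _template_matrices(isomer, a)
    bij = fm[("i", "j")][i, j]
    if isomer.n_nodes == 2:
        return float(bij)
    u = fm[("i", "l")][i] * fm[("j", "l")][j]
    u[[i, j]] = 0.0
    if isomer.n_nodes == 3:
        return float(bij * u.sum())
    v = fm[("i", "m")][i] * fm[("j", "m")][j]
    v[[i, j]] = 0.0
    f = fm[("l", "m")]
    total = u @ f @ v - float(np.sum(u * np.diag(f) * v))
    return float(bij * total)


def count_all(
    network: SimilarityMatrix,
    catalog: IsomerCatalog | None = None,
    *,
    chunk: int = 64,
) -> InteractionTensor:
    """Weighted counts of every isomer for every ordered node pair."""
    if catalog is None:
        catalog = enumerate_isomers()
    a = _weights_no_diag(network)
    n = a.shape[0]
    counts = np.empty((n, n, len(catalog)))
    for k, tpl in enumerate(catalog):
        counts[:, :, k] = _count_template(a, tpl, chunk=chunk)
    return InteractionTensor(network.entity_ids, counts)


def normalize_tensor(
    tensor: InteractionTensor, *, tol: float = 1e-12
) -> InteractionTensor:
    """Normalize counts per (source, isomer) so nonzero rows sum to 1.

    A source node whose counts over all targets sum to (numerically) zero
    has no interaction mass to distribute; its normalized row stays zero.
    """
    counts = tensor.counts
    row_sums = counts.sum(axis=1, keepdims=True)  # (n, 1, K)
    safe = np.where(np.abs(row_sums) > tol, row_sums, 1.0)
    normalized = np.where(np.abs(row_sums) > tol, counts / safe, 0.0)
    return InteractionTensor(tensor.entity_ids, counts, normalized)


def counted_and_normalized(
    network: SimilarityMatrix, catalog: IsomerCatalog | None = None
) -> InteractionTensor:
    """Convenience: :func:`count_all` followed by :func:`normalize_tensor`."""
    return normalize_tensor(count_all(network, catalog))
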