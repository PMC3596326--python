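"""Maximum-parsimony inference of rooted fold-family trees.

Characters are ordered (Wagner) 24-state proteome abundances polarized so
that the maximal state 23 ('N') is ancestral.  Rooting is Lundberg-style:
a hypothetical all-ancestral terminal is attached during the search and
the final tree is rooted on its branch, so no outgroup is needed.

Scoring uses two interchangeable engines:

* a Sankoff dynamic program over all 24 states (the reference
  implementation behind :func:`parsimony_score`, also supporting
  unordered/Fitch costs), and
* the Farris interval method for ordered characters (exact on binary
  trees and much faster; it drives the heuristic search).

The search is stepwise random addition followed by tree bisection and
reconnection (TBR) hill climbing, optionally wrapped in a parsimony
ratchet: alternating hill climbs on a reweighted and the original matrix
to escape local optima.  All randomness flows from a single seed and all
tie-breaks are deterministic, so identical configs give identical trees.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import dendropy
import numpy as np

from .coding import ANCESTOR_LABEL, ANCESTRAL_STATE, CharacterMatrix

_BIG = 1.0e12


@dataclasses.dataclass
class SearchConfig:
    """Heuristic-search settings.

    Defaults are desk-scale: 25 random-addition replicates and 50 ratchet
    iterations with a quarter of the characters upweighted twofold.  The
    published full-scale regime (1,000 addition replicates, 10 restarts of
    30 ratchet iterations) is reachable by raising the counts.
    """

    n_addition_replicates: int = 25
    ratchet_iterations: int = 50
    ratchet_perturb_fraction: float = 0.25
    ratchet_weight_factor: float = 2.0
    seed: int = 0
    max_trees_held: int = 100

    def validate(self) -> None:
        if self.n_addition_replicates < 1:
            raise ValueError("n_addition_replicates must be >= 1")
        if self.ratchet_iterations < 0:
            raise ValueError("ratchet_iterations must be >= 0")
        if not 0.0 < self.ratchet_perturb_fraction < 1.0:
            raise ValueError("ratchet_perturb_fraction must be in (0, 1)")
        if self.ratchet_weight_factor <= 1.0:
            raise ValueError("ratchet_weight_factor must be > 1")
        if self.max_trees_held < 1:
            raise ValueError("max_trees_held must be >= 1")


@dataclasses.dataclass
class SearchResult:
    """Best tree found, its score, and how many co-optimal trees were seen.

    Unpacks as ``(tree, score)`` for convenience.
    """

    tree: dendropy.Tree
    score: int
    n_cooptimal: int
    newick: str

    def __iter__(self):
        return iter((self.tree, self.score))


# ---------------------------------------------------------------------------
# internal unrooted-tree machinery
#
# Trees live as adjacency dicts {node: [neighbors]}.  Leaf ids are row
# indices into the states array (data taxa first, the pinned ancestor
# last); internal ids start at n_leaves.  All iteration orders are sorted,
# so every operation is deterministic.
# ---------------------------------------------------------------------------


def _edges(adj: dict[int, list[int]]) -> list[tuple[int, int]]:
    return sorted(
        (u, v) for u in adj for v in adj[u] if u < v
    )


def _copy_adj(adj):
    return {u: list(vs) for u, vs in adj.items()}


def _combine(c1, lo1, hi1, c2, lo2, hi2, weights):
    """Farris interval combination of two rooted-subtree values."""
    a = np.maximum(lo1, lo2)
    b = np.minimum(hi1, hi2)
    gap = np.maximum(a - b, 0)
    cost = c1 + c2 + float(gap @ weights)
    return cost, np.minimum(a, b), np.maximum(a, b)


def _postorder(adj, root):
    parent = {root: None}
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for v in sorted(adj[u]):
            if v not in parent:
                parent[v] = u
                order.append(v)
                stack.append(v)
    return order, parent


def _wagner_score(adj, states, weights, root_leaf) -> float:
    """Exact ordered-parsimony length via interval (Farris) optimization."""
    n_leaves = states.shape[0]
    order, parent = _postorder(adj, root_leaf)
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    cost = 0.0
    for u in reversed(order):
        if u < n_leaves:
            lo[u] = states[u]
            hi[u] = states[u]
            continue
        first = True
        for v in adj[u]:
            if parent.get(v) != u:
                continue
            if first:
                l, h = lo[v], hi[v]
                first = False
            else:
                a = np.maximum(l, lo[v])
                b = np.minimum(h, hi[v])
                cost += float(np.maximum(a - b, 0) @ weights)
                l, h = np.minimum(a, b), np.maximum(a, b)
        lo[u] = l
        hi[u] = h
    child = adj[root_leaf][0]
    a = np.maximum(states[root_leaf], lo[child])
    b = np.minimum(states[root_leaf], hi[child])
    cost += float(np.maximum(a - b, 0) @ weights)
    return cost


def _sankoff_score(adj, states, weights, root_leaf, cost_model="ordered") -> float:
    """Reference DP over all 24 states (ordered |i-j| or unordered Fitch costs)."""
    n_leaves, n_chars = states.shape
    n_states = ANCESTRAL_STATE + 1
    order, parent = _postorder(adj, root_leaf)
    vec: dict[int, np.ndarray] = {}

    def transition_min(c_child: np.ndarray) -> np.ndarray:
        # M(i) = min_j C(j) + w*step(i, j), vectorized over characters
        if cost_model == "ordered":
            m = c_child.copy()
            for j in range(1, n_states):
                np.minimum(m[:, j], m[:, j - 1] + weights, out=m[:, j])
            for j in range(n_states - 2, -1, -1):
                np.minimum(m[:, j], m[:, j + 1] + weights, out=m[:, j])
            return m
        best = c_child.min(axis=1, keepdims=True)
        return np.minimum(c_child, best + weights[:, None])

    w = np.asarray(weights, dtype=float)
    for u in reversed(order):
        if u < n_leaves:
            c = np.full((n_chars, n_states), _BIG)
            c[np.arange(n_chars), states[u]] = 0.0
            vec[u] = c
            continue
        total = np.zeros((n_chars, n_states))
        for v in adj[u]:
            if parent.get(v) == u:
                total += transition_min(vec[v])
        vec[u] = total
    child = adj[root_leaf][0]
    m = transition_min(vec[child])
    return float(m[np.arange(n_chars), states[root_leaf]].sum())


def _directed_values(adj, states, weights):
    """(cost, lo, hi) of the subtree on y's side rooted at y, for every
    directed edge (x, y) of an unrooted tree with >= 2 nodes."""
    n_leaves = states.shape[0]
    root = min(adj)
    order, parent = _postorder(adj, root)
    V: dict[tuple[int, int], tuple[float, np.ndarray, np.ndarray]] = {}

    def leaf_val(u):
        return 0.0, states[u], states[u]

    def rooted_at(u, exclude):
        vals = [V[(u, z)] for z in adj[u] if z != exclude]
        if not vals:
            return leaf_val(u)
        acc = vals[0]
        for v in vals[1:]:
            acc = _combine(*acc, *v, weights)
        return acc

    for u in reversed(order):
        if parent[u] is None:
            continue
        V[(parent[u], u)] = leaf_val(u) if u < n_leaves else rooted_at(u, parent[u])
    for u in order:
        for v in adj[u]:
            if parent.get(v) == u:
                V[(v, u)] = leaf_val(u) if u < n_leaves else rooted_at(u, v)
    return V


def _edge_rootings(adj, states, weights):
    """Per-edge (cost, lo, hi) of the whole tree rooted at a point
    subdividing that edge; returns (edge list, costs, los, his)."""
    if len(adj) == 1:
        u = next(iter(adj))
        return [None], np.zeros(1), states[[u]], states[[u]]
    V = _directed_values(adj, states, weights)
    edges = _edges(adj)
    costs = np.empty(len(edges))
    n_chars = states.shape[1]
    los = np.empty((len(edges), n_chars), dtype=states.dtype)
    his = np.empty_like(los)
    for i, (x, y) in enumerate(edges):
        c, lo, hi = _combine(*V[(y, x)], *V[(x, y)], weights)
        costs[i] = c
        los[i] = lo
        his[i] = hi
    return edges, costs, los, his


def _split_components(adj, u, v):
    """Node sets of the two components after cutting edge (u, v)."""
    comp = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if (x, y) == (u, v):
                continue
            if y not in comp:
                comp.add(y)
                stack.append(y)
    other = set(adj) - comp
    return comp, other


def _side_adjacency(adj, comp, cut_node, cut_neighbor):
    """Sub-adjacency of one side of a bisection, cut point suppressed."""
    side = {x: [y for y in adj[x] if y in comp] for x in comp}
    side[cut_node] = [y for y in side[cut_node] if y != cut_neighbor]
    if len(side[cut_node]) == 2:
        a, b = side[cut_node]
        side[a] = [b if z == cut_node else z for z in side[a]]
        side[b] = [a if z == cut_node else z for z in side[b]]
        del side[cut_node]
    elif len(side[cut_node]) == 0:
        side = {cut_node: []}
    return side


def _tbr_scan(adj, states, weights, current):
    """Best TBR rearrangement; returns (score, move) with move None when
    nothing beats ``current`` strictly."""
    best = current
    best_move = None
    for u, v in _edges(adj):
        comp_u, comp_v = _split_components(adj, u, v)
        su = _side_adjacency(adj, comp_u, u, v)
        sv = _side_adjacency(adj, comp_v, v, u)
        e1, c1, lo1, hi1 = _edge_rootings(su, states, weights)
        e2, c2, lo2, hi2 = _edge_rootings(sv, states, weights)
        a = np.maximum(lo1[:, None, :], lo2[None, :, :])
        b = np.minimum(hi1[:, None, :], hi2[None, :, :])
        join = np.maximum(a - b, 0) @ weights
        scores = c1[:, None] + c2[None, :] + join
        i, j = np.unravel_index(int(scores.argmin()), scores.shape)
        s = float(scores[i, j])
        if s < best - 1e-9:
            best = s
            best_move = ((u, v), e1[i], e2[j])
    return best, best_move


def _apply_tbr(adj, move):
    (u, v), e1, e2 = move
    adj = _copy_adj(adj)
    adj[u].remove(v)
    adj[v].remove(u)

    def detach(node):
        """Suppress the cut point if internal; return the spare node id."""
        if len(adj[node]) == 2:
            a, b = adj[node]
            adj[a] = [b if z == node else z for z in adj[a]]
            adj[b] = [a if z == node else z for z in adj[b]]
            adj[node] = []
            return node, True
        return node, False  # pendant leaf: reattaches directly

    def attach(spare, was_internal, edge):
        if not was_internal:
            return spare
        a, b = edge
        adj[a] = [spare if z == b else z for z in adj[a]]
        adj[b] = [spare if z == a else z for z in adj[b]]
        adj[spare] = [a, b]
        return spare

    nu, iu = detach(u)
    nv, iv = detach(v)
    pu = attach(nu, iu, e1)
    pv = attach(nv, iv, e2)
    adj[pu].append(pv)
    adj[pv].append(pu)
    return adj


def _tbr_climb(adj, states, weights, score=None):
    if score is None:
        score = _wagner_score(adj, states, weights, states.shape[0] - 1)
    while True:
        new_score, move = _tbr_scan(adj, states, weights, score)
        if move is None:
            return adj, score
        adj = _apply_tbr(adj, move)
        score = new_score


def _stepwise_addition(order, states, weights):
    """Greedy stepwise-addition tree over the leaf ids in ``order``."""
    if len(order) < 3:
        raise ValueError("need at least 3 terminals")
    nxt = states.shape[0]
    a, b, c = order[:3]
    adj = {a: [nxt], b: [nxt], c: [nxt], nxt: [a, b, c]}
    nxt += 1
    for leaf in order[3:]:
        edges, costs, los, his = _edge_rootings(adj, states, weights)
        s = states[leaf]
        gap = (
            np.maximum(np.maximum(los - s, 0), np.maximum(s - his, 0)) @ weights
        )
        best = int(np.argmin(costs + gap))
        x, y = edges[best]
        m = nxt
        nxt += 1
        adj[x] = [m if z == y else z for z in adj[x]]
        adj[y] = [m if z == x else z for z in adj[y]]
        adj[m] = [x, y, leaf]
        adj[leaf] = [m]
    return adj


# ---------------------------------------------------------------------------
# conversions between adjacency form and dendropy trees
# ---------------------------------------------------------------------------


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


def _adj_to_newick(adj, labels, ancestor_id, prune_ancestor=True) -> str:
    """Canonical (sorted) newick rooted on the ancestor's branch."""
    root = adj[ancestor_id][0]

    def rec(node, parent):
        if node < len(labels):
            lab = labels[node]
            return lab, _quote(lab)
        parts = []
        for child in adj[node]:
            if child == parent or child == ancestor_id:
                continue
            parts.append(rec(child, node))
        parts.sort(key=lambda t: t[0])
        return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

    if prune_ancestor:
        _, nwk = rec(root, None)
    else:
        key, sub = rec(root, None)
        anc = (labels[ancestor_id], _quote(labels[ancestor_id]))
        parts = sorted([(key, sub), anc], key=lambda t: t[0])
        nwk = "(" + ",".join(p[1] for p in parts) + ")"
    return nwk + ";"


def _adj_to_tree(adj, labels, ancestor_id, prune_ancestor=True) -> dendropy.Tree:
    nwk = _adj_to_newick(adj, labels, ancestor_id, prune_ancestor)
    return dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted")


def _tree_to_adj(tree: dendropy.Tree, cm: CharacterMatrix, ancestor_label: str):
    """Convert a dendropy tree into adjacency form with states rows.

    Leaf ids are the taxon's row in ``cm`` (the ancestor row is appended
    last); degree-2 internal nodes (e.g. the root of a rooted binary tree)
    are suppressed.  If the hypothetical ancestor is not among the leaves
    it is attached at the root.
    """
    row = {t: i for i, t in enumerate(cm.taxa)}
    n_leaves = cm.n_taxa + 1
    anc_id = n_leaves - 1
    ids: dict[int, int] = {}
    nxt = n_leaves
    adj: dict[int, list[int]] = {}
    seen_anc = False
    for node in tree.preorder_node_iter():
        label = None
        if node.is_leaf():
            label = str(node.taxon.label if node.taxon is not None else node.label)
            if label == ancestor_label:
                ids[id(node)] = anc_id
                seen_anc = True
            elif label in row:
                ids[id(node)] = row[label]
            else:
                raise ValueError(f"tree leaf {label!r} is not a taxon of the matrix")
        else:
            ids[id(node)] = nxt
            nxt += 1
        adj.setdefault(ids[id(node)], [])
        if node.parent_node is not None:
            p = ids[id(node.parent_node)]
            adj[p].append(ids[id(node)])
            adj[ids[id(node)]].append(p)
    leaf_ids = {i for i in adj if i < n_leaves}
    if len(leaf_ids - {anc_id}) != cm.n_taxa:
        missing = set(range(cm.n_taxa)) - leaf_ids
        raise ValueError(
            f"tree is missing taxa {[cm.taxa[i] for i in sorted(missing)]}"
        )
    if not seen_anc:
        root_id = ids[id(tree.seed_node)]
        adj[root_id].append(anc_id)
        adj[anc_id] = [root_id]
    # suppress internal degree-2 nodes (e.g. the original root)
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if node >= n_leaves and len(adj[node]) == 2:
                a, b = adj[node]
                adj[a] = [b if z == node else z for z in adj[a]]
                adj[b] = [a if z == node else z for z in adj[b]]
                del adj[node]
                changed = True
    states = np.vstack(
        [cm.states, np.full((1, cm.n_characters), ANCESTRAL_STATE, dtype=np.int16)]
    )
    return adj, states, anc_id


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def parsimony_score(
    tree: dendropy.Tree,
    cm: CharacterMatrix,
    ancestor_label: str = ANCESTOR_LABEL,
    cost_model: str = "ordered",
    method: str = "sankoff",
) -> int:
    """Parsimony length of a tree under the polarized abundance model.

    The hypothetical ancestor leaf (attached at the root if absent from
    the tree) is pinned at state 23 for every character.  ``cost_model``
    is ``"ordered"`` (Wagner, |i-j| steps; the default and the model the
    polarization implies) or ``"unordered"`` (Fitch).  ``method`` selects
    the scoring engine: the 24-state Sankoff DP or, for ordered
    characters, the faster ``"interval"`` (Farris) optimization.
    """
    if cost_model not in ("ordered", "unordered"):
        raise ValueError(f"unknown cost model {cost_model!r}")
    adj, states, anc_id = _tree_to_adj(tree, cm, ancestor_label)
    weights = np.ones(cm.n_characters)
    if method == "interval":
        if cost_model != "ordered":
            raise ValueError("interval scoring applies to ordered characters only")
        return int(round(_wagner_score(adj, states, weights, anc_id)))
    if method != "sankoff":
        raise ValueError(f"unknown method {method!r}")
    return int(round(_sankoff_score(adj, states, weights, anc_id, cost_model)))


def tbr_neighborhood(
    tree: dendropy.Tree, cm: CharacterMatrix, ancestor_label: str = ANCESTOR_LABEL
) -> dendropy.Tree:
    """Best tree in the TBR neighborhood (the input when nothing improves)."""
    adj, states, anc_id = _tree_to_adj(tree, cm, ancestor_label)
    if cm.n_taxa < 3:
        raise ValueError("TBR needs at least 4 terminals including the ancestor")
    weights = np.ones(cm.n_characters)
    current = _wagner_score(adj, states, weights, anc_id)
    _, move = _tbr_scan(adj, states, weights, current)
    if move is None:
        return tree
    labels = cm.taxa + [ancestor_label]
    return _adj_to_tree(_apply_tbr(adj, move), labels, anc_id)


def _ratchet_rounds(adj, score, states, config, rng):
    n_chars = states.shape[1]
    root_leaf = states.shape[0] - 1
    unit = np.ones(n_chars)
    best_adj, best = adj, score
    for _ in range(config.ratchet_iterations):
        mask = rng.random(n_chars) < config.ratchet_perturb_fraction
        perturbed = np.where(mask, config.ratchet_weight_factor, 1.0)
        wadj, _ = _tbr_climb(
            best_adj, states, perturbed,
            _wagner_score(best_adj, states, perturbed, root_leaf),
        )
        cand_adj, cand = _tbr_climb(
            wadj, states, unit, _wagner_score(wadj, states, unit, root_leaf)
        )
        if cand < best - 1e-9:
            best_adj, best = cand_adj, cand
    return best_adj, best


def ratchet(
    tree: dendropy.Tree,
    cm: CharacterMatrix,
    config: SearchConfig,
    ancestor_label: str = ANCESTOR_LABEL,
) -> dendropy.Tree:
    """Parsimony-ratchet refinement of a tree; never worsens the score."""
    config.validate()
    adj, states, anc_id = _tree_to_adj(tree, cm, ancestor_label)
    rng = np.random.default_rng(config.seed)
    weights = np.ones(cm.n_characters)
    score = _wagner_score(adj, states, weights, anc_id)
    best_adj, _ = _ratchet_rounds(adj, score, states, config, rng)
    return _adj_to_tree(best_adj, cm.taxa + [ancestor_label], anc_id)


def search_mp(
    cm: CharacterMatrix,
    config: SearchConfig | None = None,
    ancestor_label: str = ANCESTOR_LABEL,
) -> SearchResult:
    """Heuristic maximum-parsimony search with Lundberg rooting.

    Runs ``n_addition_replicates`` random-addition + TBR hill climbs,
    then a parsimony ratchet from the best tree found.  Returns the best
    tree (ancestor pruned, rooted at its attachment point), its ordered
    parsimony score, and the number of distinct co-optimal topologies
    encountered along the way (first-found is kept).
    """
    config = config or SearchConfig()
    config.validate()
    if cm.n_taxa < 3:
        raise ValueError("search_mp needs at least 3 data taxa")
    if cm.n_characters < 1:
        raise ValueError("empty character matrix")
    rng = np.random.default_rng(config.seed)
    n_leaves = cm.n_taxa + 1
    anc_id = n_leaves - 1
    states = np.vstack(
        [cm.states, np.full((1, cm.n_characters), ANCESTRAL_STATE, dtype=np.int16)]
    )
    weights = np.ones(cm.n_characters)
    labels = cm.taxa + [ancestor_label]

    best_adj = None
    best = np.inf
    cooptimal: set[str] = set()
    for _ in range(config.n_addition_replicates):
        order = [anc_id] + list(rng.permutation(cm.n_taxa))
        adj = _stepwise_addition(order, states, weights)
        adj, score = _tbr_climb(adj, states, weights)
        if score < best - 1e-9:
            best_adj, best = adj, score
            cooptimal = {_adj_to_newick(adj, labels, anc_id)}
        elif score < best + 1e-9 and len(cooptimal) < config.max_trees_held:
            cooptimal.add(_adj_to_newick(adj, labels, anc_id))
    ratchet_adj, ratchet_score = _ratchet_rounds(best_adj, best, states, config, rng)
    if ratchet_score < best - 1e-9:
        best_adj, best = ratchet_adj, ratchet_score
        cooptimal = {_adj_to_newick(best_adj, labels, anc_id)}
    nwk = _adj_to_newick(best_adj, labels, anc_id)
    return SearchResult(
        tree=_adj_to_tree(best_adj, labels, anc_id),
        score=int(round(best)),
        n_cooptimal=len(cooptimal),
        newick=nwk,
    )


# ---------------------------------------------------------------------------
# exhaustive enumeration (oracle-scale problems)
# ---------------------------------------------------------------------------


def enumerate_topologies(n_terminals: int) -> Iterable[dict[int, list[int]]]:
    """All distinct unrooted binary topologies on terminals 0..n-1.

    (2n-5)!! trees; intended for <= 8 terminals (oracles and tests).
    """
    if n_terminals < 3:
        raise ValueError("need at least 3 terminals")

    def grow(adj, next_leaf, next_internal):
        if next_leaf == n_terminals:
            yield adj
            return
        for x, y in _edges(adj):
            new = _copy_adj(adj)
            m = next_internal
            new[x] = [m if z == y else z for z in new[x]]
            new[y] = [m if z == x else z for z in new[y]]
            new[m] = [x, y, next_leaf]
            new[next_leaf] = [m]
            yield from grow(new, next_leaf + 1, next_internal + 1)

    base = {0: [n_terminals], 1: [n_terminals], 2: [n_terminals], n_terminals: [0, 1, 2]}
    yield from grow(base, 3, n_terminals + 1)


def exhaustive_mp(
    cm: CharacterMatrix, ancestor_label: str = ANCESTOR_LABEL
) -> SearchResult:
    """Exact maximum parsimony by enumerating every unrooted topology.

    Feasible only for small matrices (<= ~8 data taxa); used as the
    ground-truth oracle for the heuristic search.
    """
    n_terminals = cm.n_taxa + 1
    if n_terminals > 10:
        raise ValueError("exhaustive enumeration limited to <= 9 data taxa")
    anc_id = n_terminals - 1
    states = np.vstack(
        [cm.states, np.full((1, cm.n_characters), ANCESTRAL_STATE, dtype=np.int16)]
    )
    weights = np.ones(cm.n_characters)
    labels = cm.taxa + [ancestor_label]
    best_adj, best = None, np.inf
    n_best = 0
    for adj in enumerate_topologies(n_terminals):
        s = _wagner_score(adj, states, weights, anc_id)
        if s < best - 1e-9:
            best_adj, best, n_best = adj, s, 1
        elif s < best + 1e-9:
            n_best += 1
    return SearchResult(
        tree=_adj_to_tree(best_adj, labels, anc_id),
        score=int(round(best)),
        n_cooptimal=n_best,
        newick=_adj_to_newick(best_adj, labels, anc_id),
    )
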