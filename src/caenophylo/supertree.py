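"""Quartet-based species-tree estimation from gene trees.

The objective is the quartet score — the number of induced four-taxon
subtrees on which a candidate species tree agrees with the gene trees —
which is the quantity coalescent summary methods (ASTRAL-style) maximize.
Search here is desk scale: exhaustive enumeration of unrooted topologies up
to 8 taxa, or NNI hill-climbing for larger taxon sets.  Gene trees may miss
taxa (those quartets are simply not counted) and may contain polytomies
(polytomy-induced unresolved quartets count toward none of the three
resolutions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .trees import Node, Phylo, parse_newick, write_newick

__all__ = [
    "QuartetProfile",
    "build_quartet_profile",
    "quartet_score",
    "search_supertree",
    "perturb_topology",
    "enumerate_unrooted_topologies",
    "induced_quartet",
    "canonical_newick",
]

# A resolved quartet topology ab|cd is keyed by frozenset({frozenset({a,b}),
# frozenset({c,d})}); the profile maps each 4-taxon subset to the counts of
# its three possible resolutions.


@dataclass
class QuartetProfile:
    taxa: frozenset
    counts: dict = field(default_factory=dict)  # 4-subset -> {resolution: n}
    unresolved: dict = field(default_factory=dict)  # 4-subset -> n
    n_gene_trees: int = 0

    def add(self, subset: frozenset, resolution: Optional[frozenset]) -> None:
        if resolution is None:
            self.unresolved[subset] = self.unresolved.get(subset, 0) + 1
        else:
            per = self.counts.setdefault(subset, {})
            per[resolution] = per.get(resolution, 0) + 1

    @property
    def n_resolved_subsets(self) -> int:
        return len(self.counts)


def induced_quartet(tree: Phylo, quartet: Sequence[str]) -> Optional[frozenset]:
    """The unrooted topology induced on four leaves, or None if unresolved.

    ab|cd holds iff the a-b path and the c-d path are node-disjoint; exactly
    one of the three pairings can satisfy this, and none does when the four
    leaves meet at a single polytomy.
    """
    a, b, c, d = quartet
    nodes = {lab: tree.find_leaf(lab) for lab in quartet}

    def path_nodes(x: Node, y: Node) -> set:
        anc_x = []
        n = x
        while n is not None:
            anc_x.append(n)
            n = n.parent
        anc_set = {id(m): i for i, m in enumerate(anc_x)}
        path_y = []
        n = y
        while id(n) not in anc_set:
            path_y.append(n)
            n = n.parent
        meet = anc_set[id(n)]
        return {id(m) for m in anc_x[: meet + 1]} | {id(m) for m in path_y} | {id(n)}

    for (p, q), (r, s) in (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))):
        if not (path_nodes(nodes[p], nodes[q]) & path_nodes(nodes[r], nodes[s])):
            return frozenset({frozenset({p, q}), frozenset({r, s})})
    return None


def build_quartet_profile(
    gene_trees: Sequence[Phylo], taxa: Optional[Sequence[str]] = None
) -> QuartetProfile:
    """Count each gene tree's induced resolution for every 4-taxon subset."""
    if taxa is None:
        taxa = sorted(set().union(*(t.leaf_set() for t in gene_trees)))
    taxa_set = frozenset(taxa)
    profile = QuartetProfile(taxa=taxa_set, n_gene_trees=len(gene_trees))
    for gtree in gene_trees:
        present = sorted(gtree.leaf_set() & taxa_set)
        if len(present) < 4:
            continue
        for quartet in combinations(present, 4):
            profile.add(frozenset(quartet), induced_quartet(gtree, quartet))
    return profile


def quartet_score(candidate: Phylo, profile: QuartetProfile) -> int:
    """Sum over 4-subsets of the gene-tree count of the candidate's induced
    resolution."""
    missing = profile.taxa - candidate.leaf_set()
    if missing:
        raise ValueError(f"candidate tree missing taxa: {sorted(missing)}")
    score = 0
    for subset, per in profile.counts.items():
        res = induced_quartet(candidate, sorted(subset))
        if res is not None:
            score += per.get(res, 0)
    return score


# ---------------------------------------------------------------------------
# Topology enumeration and canonical form
# ---------------------------------------------------------------------------


def enumerate_unrooted_topologies(taxa: Sequence[str]):
    """Yield every unrooted binary topology on ``taxa`` as a Phylo.

    Stepwise addition: each tree on n taxa arises uniquely by inserting the
    nth taxon into one of the 2n-5 edges of a tree on the first n-1.  Trees
    are yielded rooted at an arbitrary internal node (scoring is unrooted).
    """
    taxa = sorted(taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")

    def insert_all(newick_nodes, label):
        # newick_nodes: nested-tuple representation; a tree is a 3-tuple at
        # the (arbitrary) root; leaves are strings.
        def edges(tree):
            # yields (path, subtree) for every edge below the root triple
            for i, child in enumerate(tree):
                yield (i,), child
                if isinstance(child, tuple):
                    for path, sub in edges_inner(child):
                        yield (i,) + path, sub

        def edges_inner(node):
            for i, child in enumerate(node):
                yield (i,), child
                if isinstance(child, tuple):
                    for path, sub in edges_inner(child):
                        yield (i,) + path, sub

        def replace(node, path, new):
            if len(path) == 1:
                return node[: path[0]] + (new,) + node[path[0] + 1 :]
            i = path[0]
            return node[:i] + (replace(node[i], path[1:], new),) + node[i + 1 :]

        for path, sub in edges(tree=newick_nodes):
            yield replace(newick_nodes, path, (sub, label))

    def to_phylo(tree) -> Phylo:
        def render(node) -> str:
            if isinstance(node, str):
                return node
            return "(" + ",".join(render(c) for c in node) + ")"

        return parse_newick(render(tree) + ";")

    stack = [(taxa[0], taxa[1], taxa[2])]
    for label in taxa[3:]:
        stack = [t for base in stack for t in insert_all(base, label)]
    for t in stack:
        yield to_phylo(t)


def canonical_newick(tree: Phylo) -> str:
    """Rooting-invariant canonical Newick of the unrooted topology (no
    lengths/supports): re-rooted conceptually at the smallest leaf, children
    sorted recursively."""

    # adjacency over node ids
    nodes = list(tree.preorder())
    adj: dict[int, list] = {id(n): [] for n in nodes}
    by_id = {id(n): n for n in nodes}
    for n in nodes:
        for c in n.children:
            adj[id(n)].append(id(c))
            adj[id(c)].append(id(n))
    # suppress degree-2 nodes (the root of a rooted binary tree)
    for nid, nbrs in list(adj.items()):
        if len(nbrs) == 2:
            a, b = nbrs
            adj[a] = [x for x in adj[a] if x != nid] + [b]
            adj[b] = [x for x in adj[b] if x != nid] + [a]
            del adj[nid]

    anchor = min(
        (n for n in nodes if n.is_leaf and id(n) in adj), key=lambda n: n.label
    )

    def render(nid: int, parent: int) -> str:
        node = by_id[nid]
        nbrs = [x for x in adj[nid] if x != parent]
        if not nbrs:
            return node.label
        parts = sorted(render(x, nid) for x in nbrs)
        return "(" + ",".join(parts) + ")"

    start = adj[id(anchor)][0]
    return f"({anchor.label},{render(start, id(anchor))});"


def _nni_neighbors(tree: Phylo) -> list[Phylo]:
    """All NNI neighbours of the unrooted topology of ``tree``."""
    base = canonical_newick(tree)
    t = parse_newick(base)
    # adjacency with stable integer ids
    nodes = list(t.preorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    labels = {i: n.label for i, n in enumerate(nodes)}
    adj: dict[int, set] = {i: set() for i in range(len(nodes))}
    for n in nodes:
        for c in n.children:
            adj[idx[id(n)]].add(idx[id(c)])
            adj[idx[id(c)]].add(idx[id(n)])
    for i, nbrs in list(adj.items()):
        if len(nbrs) == 2 and labels[i] is None:  # suppress the root
            a, b = nbrs
            adj[a].discard(i)
            adj[b].discard(i)
            adj[a].add(b)
            adj[b].add(a)
            del adj[i]

    def to_phylo(a: dict[int, set]) -> Phylo:
        leaf_ids = [i for i in a if len(a[i]) == 1 and labels[i]]
        root = min(leaf_ids, key=lambda i: labels[i])

        def render(i: int, parent: int) -> str:
            kids = [x for x in a[i] if x != parent]
            if not kids:
                return labels[i]
            return "(" + ",".join(render(x, i) for x in kids) + ")"

        start = next(iter(a[root]))
        return parse_newick(f"({labels[root]},{render(start, root)});")

    out = []
    internal_edges = [
        (u, v)
        for u in adj
        for v in adj[u]
        if u < v and len(adj[u]) == 3 and len(adj[v]) == 3
    ]
    for u, v in internal_edges:
        a_nbrs = sorted(adj[u] - {v})
        b_nbrs = sorted(adj[v] - {u})
        A, B = a_nbrs
        for C in b_nbrs:
            # swap B (attached to u) with C (attached to v)
            new = {k: set(s) for k, s in adj.items()}
            new[u].discard(B)
            new[B].discard(u)
            new[v].discard(C)
            new[C].discard(v)
            new[u].add(C)
            new[C].add(u)
            new[v].add(B)
            new[B].add(v)
            out.append(to_phylo(new))
    return out


def _random_topology(taxa: Sequence[str], rng: np.random.Generator) -> Phylo:
    taxa = list(taxa)
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    tree = (order[0], order[1], order[2])

    def edges(node, path=()):
        for i, child in enumerate(node):
            yield path + (i,), child
            if isinstance(child, tuple):
                yield from edges(child, path + (i,))

    def replace(node, path, new):
        i = path[0]
        if len(path) == 1:
            return node[:i] + (new,) + node[i + 1 :]
        return node[:i] + (replace(node[i], path[1:], new),) + node[i + 1 :]

    for label in order[3:]:
        all_edges = list(edges(tree))
        path, sub = all_edges[rng.integers(len(all_edges))]
        tree = replace(tree, path, (sub, label))

    def render(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(render(c) for c in node) + ")"

    return parse_newick(render(tree) + ";")


def perturb_topology(tree: Phylo, n_moves: int, seed=0) -> Phylo:
    """Apply ``n_moves`` random NNI moves to the unrooted topology — the
    package's stand-in for gene-tree discordance around a species tree."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = tree
    for _ in range(n_moves):
        neighbors = _nni_neighbors(current)
        current = neighbors[rng.integers(len(neighbors))]
    return current


@dataclass
class SupertreeResult:
    tree: Phylo
    score: int
    mode: str
    n_evaluated: int


def search_supertree(
    profile: QuartetProfile,
    taxa: Optional[Sequence[str]] = None,
    mode: str = "exhaustive",
    seed: int = 0,
    start: Optional[Phylo] = None,
    max_exhaustive_taxa: int = 8,
) -> SupertreeResult:
    """Maximize the quartet score over unrooted topologies.

    ``exhaustive`` enumerates all topologies (refused above 8 taxa; 10,395
    at n=8 is the ceiling), breaking ties by the lexicographically smallest
    canonical Newick.  ``nni`` hill-climbs from a random (seeded) or supplied
    start until no NNI neighbour improves the score.
    """
    if taxa is None:
        taxa = sorted(profile.taxa)
    taxa = sorted(taxa)
    if mode == "exhaustive":
        if len(taxa) > max_exhaustive_taxa:
            raise ValueError(
                f"exhaustive search refused for {len(taxa)} taxa "
                f"(> {max_exhaustive_taxa}); use mode='nni'"
            )
        best_tree, best_key, n_eval = None, None, 0
        for cand in enumerate_unrooted_topologies(taxa):
            s = quartet_score(cand, profile)
            n_eval += 1
            key = (-s, canonical_newick(cand))
            if best_key is None or key < best_key:
                best_key, best_tree = key, cand
        return SupertreeResult(best_tree, -best_key[0], "exhaustive", n_eval)
    if mode != "nni":
        raise ValueError(f"unknown search mode {mode!r}")
    rng = np.random.default_rng(seed)
    current = start if start is not None else _random_topology(taxa, rng)
    current_score = quartet_score(current, profile)
    n_eval = 1
    improved = True
    while improved:
        improved = False
        neighbors = _nni_neighbors(current)
        scored = []
        for nb in neighbors:
            s = quartet_score(nb, profile)
            n_eval += 1
            scored.append(((-s, canonical_newick(nb)), nb, s))
        scored.sort(key=lambda x: x[0])
        if scored and scored[0][2] > current_score:
            current, current_score = scored[0][1], scored[0][2]
            improved = True
    return SupertreeResult(current, current_score, "nni", n_eval)
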