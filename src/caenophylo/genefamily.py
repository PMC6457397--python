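"""Gene-family analysis: length filtering, duplication-node inference,
post-duplication rate comparison and ancestral domain-count reconstruction.

This mirrors how a single receptor family (e.g. the Notch-like receptors,
with their EGF-like repeat counts) is analysed: short sequences are removed,
duplication nodes are read from the rooted gene tree by species overlap,
substitution-rate divergence after a duplication is summarized as the mean
root-to-tip path length within each paralogue clade, and the ancestral
domain count is reconstructed by stochastic mapping of the observed counts
as unordered equal-rates Mk states on the gene tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from . import ancestral
from .trees import Node, Phylo, path_length

__all__ = [
    "ReconciledGeneTree",
    "RateComparison",
    "filter_by_length",
    "infer_duplication_nodes",
    "post_duplication_rates",
    "ancestral_domain_counts",
]


def filter_by_length(
    records: Mapping[str, int], min_len: int = 700
) -> tuple[dict[str, int], int]:
    """Retain sequences of length >= ``min_len`` (strictly shorter ones are
    dropped); returns (retained records, drop tally)."""
    for name, length in records.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {name!r}")
    kept = {n: l for n, l in records.items() if l >= min_len}
    return kept, len(records) - len(kept)


@dataclass
class ReconciledGeneTree:
    """A gene tree with every internal node labelled speciation or
    duplication (species-overlap rule), events keyed by clade leaf set."""

    tree: Phylo
    species_map: dict[str, str]
    events: dict[frozenset, str]  # clade leaf-set -> "duplication"|"speciation"

    @property
    def duplication_clades(self) -> set[frozenset]:
        return {c for c, e in self.events.items() if e == "duplication"}

    def duplicate_tip_species(self) -> dict[str, list[str]]:
        """Species represented by more than one tip (possible within-species
        duplicates or uncollapsed heterozygosity) — flagged, never removed."""
        by_sp: dict[str, list[str]] = {}
        for leaf, sp in self.species_map.items():
            by_sp.setdefault(sp, []).append(leaf)
        return {sp: sorted(ls) for sp, ls in by_sp.items() if len(ls) > 1}


def infer_duplication_nodes(
    gene_tree: Phylo, species_map: Mapping[str, str]
) -> ReconciledGeneTree:
    """Label each internal node by species overlap: a node is a duplication
    iff the species sets of at least two of its child subtrees intersect."""
    unmapped = [l for l in gene_tree.leaf_labels() if l not in species_map]
    if unmapped:
        raise ValueError(f"gene-tree leaves without a species mapping: {unmapped}")
    species_below: dict[Node, set] = {}
    events: dict[frozenset, str] = {}
    for node in gene_tree.postorder():
        if node.is_leaf:
            species_below[node] = {species_map[node.label]}
            continue
        sets = [species_below[c] for c in node.children]
        union: set = set()
        overlap = False
        for s in sets:
            if union & s:
                overlap = True
            union |= s
        species_below[node] = union
        events[gene_tree.leaf_set(node)] = "duplication" if overlap else "speciation"
    return ReconciledGeneTree(
        tree=gene_tree,
        species_map={l: species_map[l] for l in gene_tree.leaf_labels()},
        events=events,
    )


@dataclass
class RateComparison:
    """Mean root-to-tip path lengths (substitutions/site) from a duplication
    node within each of its child clades."""

    duplication_clade: frozenset
    clades: tuple[frozenset, ...]
    mean_paths: tuple[float, ...]
    tip_counts: tuple[int, ...]


def post_duplication_rates(
    reconciled: ReconciledGeneTree,
    dup_clade: frozenset | Sequence[str],
    mode: str = "path",
) -> RateComparison:
    """Compare substitution accumulation in the clades descending from a
    duplication node.

    ``mode='path'`` (default): per child clade, the mean over tips of the
    path length from the duplication node to the tip (the child's own branch
    included).  ``mode='edge'``: the mean of the individual edge lengths
    within the child clade (subtending branch included).
    """
    dup_clade = frozenset(dup_clade)
    if reconciled.events.get(dup_clade) != "duplication":
        raise ValueError(f"clade {sorted(dup_clade)} is not a duplication node")
    tree = reconciled.tree
    node = tree.mrca(sorted(dup_clade))
    clades, means, counts = [], [], []
    for child in node.children:
        tips = [l for l in tree.preorder() if l.is_leaf and _under(l, child)]
        clades.append(tree.leaf_set(child))
        counts.append(len(tips))
        if mode == "path":
            vals = [path_length(tree, node, tip) for tip in tips]
        elif mode == "edge":
            vals = [
                (n.length or 0.0)
                for n in tree.preorder()
                if n is child or (_under(n, child) and n is not child)
            ]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        means.append(float(np.mean(vals)))
    return RateComparison(
        duplication_clade=dup_clade,
        clades=tuple(clades),
        mean_paths=tuple(means),
        tip_counts=tuple(counts),
    )


def _under(node: Node, ancestor: Node) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def ancestral_domain_counts(
    gene_tree: Phylo,
    counts: Mapping[str, int],
    n_maps: int = 1000,
    seed: int = 0,
    alpha: Optional[float] = None,
) -> tuple[ancestral.NodePosterior, ancestral.MapSummary]:
    """Reconstruct ancestral domain counts by stochastic mapping.

    The distinct observed counts become unordered equal-rates Mk states; the
    rate is fitted by maximum likelihood unless ``alpha`` is given.  Returns
    the node posterior (state labels are the count values) and the full map
    summary.
    """
    missing = [l for l in gene_tree.leaf_labels() if l not in counts]
    if missing:
        raise ValueError(f"no domain count for leaves: {missing}")
    values = sorted({counts[l] for l in gene_tree.leaf_labels()})
    k = len(values)
    if k == 1:
        # monomorphic: posterior is an indicator at every node
        probs = {
            gene_tree.leaf_set(n): np.array([1.0])
            for n in gene_tree.preorder()
            if not n.is_leaf
        }
        posterior = ancestral.NodePosterior(probs, state_labels=tuple(values))
        summary = ancestral.MapSummary(
            posterior, np.array([gene_tree.total_length()]), 0.0, n_maps
        )
        return posterior, summary
    index = {v: i for i, v in enumerate(values)}
    character = {l: index[counts[l]] for l in gene_tree.leaf_labels()}
    if alpha is None:
        alpha = ancestral.fit_er_rate(gene_tree, character, k=k).alpha
    model = ancestral.MkModel(k=k, alpha=alpha)
    maps = ancestral.sample_stochastic_maps(
        gene_tree, character, model, n_maps=n_maps, seed=seed
    )
    summary = ancestral.summarize_maps(maps)
    posterior = ancestral.NodePosterior(
        summary.posterior.probs, state_labels=tuple(values)
    )
    summary.posterior = posterior
    return posterior, summary
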