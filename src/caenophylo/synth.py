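"""Synthetic data generators with recorded ground truth.

Every input class the pipeline consumes can be generated here with known
truth, so each downstream stage is testable without genome downloads:

* Yule (pure-birth) species trees,
* binary/k-state characters evolved under the equal-rates Markov process,
* continuous traits with a planted linear effect and Brownian residuals,
* gene families with planted duplications and losses,
* orthogroup tables with planted multi-copy species,
* toy assemblies + GFF3 annotations with controlled exon/intron/intergenic
  length distributions.

All generators are deterministic given a seed, and each returns its ground
truth alongside the data; recovery tests consume only the data and use the
truth solely for comparison.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .trees import Node, Phylo

__all__ = [
    "SimulationConfig",
    "sim_species_tree",
    "sim_discrete_character",
    "sim_brownian_traits",
    "sim_gene_family",
    "GeneFamily",
    "sim_orthogroup_table",
    "sim_annotation_and_assembly",
    "SimAnnotation",
]


@dataclass
class SimulationConfig:
    """Parameters controlling every generator.

    Defaults are chosen to resemble the study system: ~33 species,
    substitution-scale branch lengths, a slow binary character, a handful of
    genome-content predictors, and nematode-like gene structure (short exons,
    short introns, sub-kilobase intergenic gaps).
    """

    seed: int = 0
    n_species: int = 33
    birth_rate: float = 4.0  # yields root-to-tip depths ~ 1 subst/site
    er_rate: float = 0.5  # Mk total leaving rate alpha
    k_states: int = 2
    beta: tuple[float, ...] = (60.0, 0.8)  # intercept + planted slope
    sigma2: float = 25.0
    dup_rate: float = 0.3
    loss_rate: float = 0.0
    # orthogroup table
    n_orthogroups: int = 200
    planted_dup_fraction: float = 0.3
    # annotation / assembly
    n_scaffolds: int = 5
    genes_per_scaffold: int = 40
    exon_count_mean: float = 5.0  # 1 + Poisson(mean - 1)
    exon_len_mean: float = 220.0
    intron_len_mean: float = 70.0
    intergenic_mean: float = 600.0
    multi_isoform_fraction: float = 0.1
    overlap_fraction: float = 0.0
    n_base_fraction: float = 0.002

    def __post_init__(self) -> None:
        for name in ("birth_rate",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("er_rate", "sigma2", "dup_rate", "loss_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.planted_dup_fraction <= 1:
            raise ValueError("planted_dup_fraction must be in [0, 1]")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------


def sim_species_tree(
    n_species: int,
    birth_rate: float = 1.0,
    seed=0,
    prefix: str = "sp",
) -> tuple[Phylo, dict[str, float]]:
    """Simulate a Yule (pure-birth) tree with ``n_species`` leaves.

    Returns the ultrametric tree (leaves ``sp01``..) and the true node depths
    keyed by the sorted-leaf-set clade string.  Each of the n-1 split epochs
    lasts Exp(k*birth_rate) at k extant lineages, plus one final epoch so
    pendant branches are strictly positive.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = _rng(seed)
    root = Node()
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    active: list[tuple[Node, float]] = [(a, 0.0), (b, 0.0)]  # (node, birth time)
    t = 0.0
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = rng.integers(k)
        node, born = active.pop(idx)
        node.length = t - born
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        active.extend([(c1, t), (c2, t)])
    t += rng.exponential(1.0 / (n_species * birth_rate))
    width = max(2, len(str(n_species)))
    order = rng.permutation(n_species)
    for i, (node, born) in enumerate(active):
        node.length = t - born
        node.label = f"{prefix}{order[i] + 1:0{width}d}"
    tree = Phylo(root)
    depths = tree.depths()
    truth = {
        ",".join(sorted(tree.leaf_set(n))): d
        for n, d in depths.items()
        if not n.is_leaf
    }
    return tree, truth


# ---------------------------------------------------------------------------
# Discrete characters under the equal-rates Mk process
# ---------------------------------------------------------------------------


def sim_discrete_character(
    tree: Phylo,
    er_rate: float,
    k_states: int = 2,
    seed=0,
) -> tuple[dict[str, int], dict[frozenset, int], int]:
    """Evolve a k-state character under the equal-rates Markov process.

    The root state is uniform; along each branch the state leaves at total
    rate ``er_rate`` and jumps uniformly to one of the other k-1 states.
    Returns (tip states, true node states keyed by clade leaf set, total
    transition count).
    """
    if k_states < 2:
        raise ValueError("k_states must be >= 2")
    if er_rate < 0:
        raise ValueError("er_rate must be >= 0")
    rng = _rng(seed)
    states: dict[Node, int] = {tree.root: int(rng.integers(k_states))}
    transitions = 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        s = states[node.parent]
        remaining = node.length or 0.0
        if er_rate > 0:
            while True:
                wait = rng.exponential(1.0 / er_rate)
                if wait >= remaining:
                    break
                remaining -= wait
                jump = int(rng.integers(k_states - 1))
                s = jump if jump < s else jump + 1
                transitions += 1
        states[node] = s
    tips = {n.label: states[n] for n in tree.leaves()}
    internals = {
        tree.leaf_set(n): states[n] for n in tree.preorder() if not n.is_leaf
    }
    return tips, internals, transitions


# ---------------------------------------------------------------------------
# Brownian traits with a planted linear effect
# ---------------------------------------------------------------------------


def sim_brownian_traits(
    tree: Phylo,
    beta: Sequence[float],
    sigma2: float,
    seed=0,
    predictor_generator: Optional[Callable] = None,
    response: str = "genome_size",
    predictors: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate species traits: response = X @ beta + Brownian residuals.

    ``beta[0]`` is the intercept; one predictor column per remaining
    coefficient.  Residuals are multivariate normal with covariance
    sigma2 * C, C the Brownian tree covariance (shared root-to-MRCA path
    lengths).  Returns (trait table indexed by species, true beta).
    """
    from .pgls import bm_covariance  # local import to avoid a cycle

    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    beta = np.asarray(beta, dtype=float)
    species = sorted(tree.leaf_labels())
    n = len(species)
    p = len(beta) - 1
    if predictors is None:
        predictors = [f"x{i+1}" for i in range(p)]
    rng = _rng(seed)
    if predictor_generator is None:
        X = rng.standard_normal((n, p))
    else:
        X = np.asarray(predictor_generator(rng, n, p), dtype=float)
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    C = bm_covariance(tree, species)
    if sigma2 > 0:
        L = np.linalg.cholesky(C + 1e-12 * np.eye(n))
        eps = np.sqrt(sigma2) * (L @ rng.standard_normal(n))
    else:
        eps = np.zeros(n)
    y = design @ beta + eps
    table = pd.DataFrame(X, columns=list(predictors), index=pd.Index(species, name="species"))
    table.insert(0, response, y)
    return table, beta


# ---------------------------------------------------------------------------
# Gene families with planted duplications/losses
# ---------------------------------------------------------------------------


@dataclass
class GeneFamily:
    """A simulated gene family.

    ``tree`` is None when every copy was lost (empty-family signal).
    ``duplication_clades`` are the true duplication nodes, each keyed by the
    frozenset of surviving gene-tree leaf labels below it.
    """

    tree: Optional[Phylo]
    species_map: dict[str, str] = field(default_factory=dict)
    duplication_clades: set[frozenset] = field(default_factory=set)

    @property
    def empty(self) -> bool:
        return self.tree is None


class _GNode(Node):
    __slots__ = ("event",)

    def __init__(self, *a, **kw):
        super().__init__(*a, **kw)
        self.event = None  # "dup" | "spec" | None


def sim_gene_family(
    species_tree: Phylo,
    dup_rate: float,
    loss_rate: float,
    seed=0,
    root_duplication: bool = False,
) -> GeneFamily:
    """Evolve a gene family inside the species tree under a birth-death
    (duplication/loss) process.

    A single gene enters at the species-tree root (two, sharing a planted
    duplication node, when ``root_duplication``).  On each species-tree edge
    a gene lineage duplicates at rate ``dup_rate`` and dies at ``loss_rate``;
    gene-tree branch lengths follow the species-tree time scale.  Surviving
    leaves are labelled ``species__copyN``.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = _rng(seed)
    copy_counter: dict[str, int] = {}

    def evolve_edge(snode: Node, remaining: float) -> Optional[_GNode]:
        """Evolve one gene lineage over the rest of a species-tree edge into
        the subtree of ``snode``; returns the gene subtree root (edge length
        set) or None if the lineage left no descendants."""
        elapsed = 0.0
        total = dup_rate + loss_rate
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else np.inf
            if wait >= remaining:
                break
            remaining -= wait
            elapsed += wait
            if rng.random() < loss_rate / total:
                return None
            left = evolve_edge(snode, remaining)
            right = evolve_edge(snode, remaining)
            if left is None and right is None:
                return None
            if left is None or right is None:
                survivor = left or right
                survivor.length = (survivor.length or 0.0) + elapsed
                return survivor
            g = _GNode(length=elapsed)
            g.event = "dup"
            g.add_child(left)
            g.add_child(right)
            return g
        elapsed += remaining
        return at_species_node(snode, elapsed)

    def at_species_node(snode: Node, elapsed: float) -> Optional[_GNode]:
        if snode.is_leaf:
            sp = snode.label
            copy_counter[sp] = copy_counter.get(sp, 0) + 1
            leaf = _GNode(label=f"{sp}__copy{copy_counter[sp]}", length=elapsed)
            return leaf
        kids = []
        for child in snode.children:
            sub = evolve_edge(child, child.length or 0.0)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length = (kids[0].length or 0.0) + elapsed
            return kids[0]
        g = _GNode(length=elapsed)
        g.event = "spec"
        for k in kids:
            g.add_child(k)
        return g

    if root_duplication:
        left = at_species_node(species_tree.root, 0.0)
        right = at_species_node(species_tree.root, 0.0)
        if left is None and right is None:
            groot = None
        elif left is None or right is None:
            groot = left or right
        else:
            groot = _GNode()
            groot.event = "dup"
            groot.add_child(left)
            groot.add_child(right)
    else:
        groot = at_species_node(species_tree.root, 0.0)

    if groot is None:
        return GeneFamily(tree=None)
    groot.length = None
    gtree = Phylo(groot)
    dup_clades = {
        gtree.leaf_set(n)
        for n in gtree.preorder()
        if not n.is_leaf and getattr(n, "event", None) == "dup"
    }
    species_map = {lab: lab.rsplit("__", 1)[0] for lab in gtree.leaf_labels()}
    return GeneFamily(tree=gtree, species_map=species_map, duplication_clades=dup_clades)


# ---------------------------------------------------------------------------
# Orthogroup tables with planted multi-copy species
# ---------------------------------------------------------------------------


def sim_orthogroup_table(
    species: Sequence[str],
    n_ogs: int,
    planted_dup_species: Sequence[str] = (),
    planted_dup_fraction: float = 0.0,
    seed=0,
    presence_prob: float = 1.0,
):
    """Build an orthogroup membership table with known duplication ratios.

    Each orthogroup carries one sequence per present species, except the
    planted species which carry two copies in ``planted_dup_fraction`` of
    the orthogroups they occur in.  Returns (OrthogroupTable, true per-species
    duplication ratios).
    """
    from .orthology import OrthogroupTable

    if not 0 <= planted_dup_fraction <= 1:
        raise ValueError("planted_dup_fraction must be in [0, 1]")
    unknown = set(planted_dup_species) - set(species)
    if unknown:
        raise ValueError(f"planted species not in species list: {sorted(unknown)}")
    rng = _rng(seed)
    rows = []
    n_dup_ogs = int(round(planted_dup_fraction * n_ogs))
    dup_ogs = set(rng.choice(n_ogs, size=n_dup_ogs, replace=False).tolist())
    counts: dict[str, int] = {sp: 0 for sp in species}
    present_in: dict[str, int] = {sp: 0 for sp in species}
    for i in range(n_ogs):
        og = f"OG{i:07d}"
        for sp in species:
            if rng.random() > presence_prob:
                continue
            n_copies = 2 if (sp in planted_dup_species and i in dup_ogs) else 1
            present_in[sp] += 1
            for c in range(n_copies):
                counts[sp] += 1
                rows.append(
                    {
                        "orthogroup_id": og,
                        "species": sp,
                        "sequence_id": f"{sp}.g{i}.{c}",
                        "length_aa": int(rng.integers(100, 1500)),
                    }
                )
    table = OrthogroupTable(pd.DataFrame(rows))
    truth = {
        sp: counts[sp] / present_in[sp] for sp in species if present_in[sp] > 0
    }
    return table, truth


# ---------------------------------------------------------------------------
# Toy assemblies and annotations
# ---------------------------------------------------------------------------


@dataclass
class SimAnnotation:
    """A simulated assembly + annotation with per-gene ground truth."""

    annotation: "object"  # genomestats.AnnotationSet
    sequences: dict[str, str]
    gene_truth: pd.DataFrame  # gene_id, intron_count, intron_span, exon_span
    intergenic_truth: pd.DataFrame  # scaffold, left_gene, right_gene, distance


def sim_annotation_and_assembly(config: SimulationConfig, seed=0) -> SimAnnotation:
    """Simulate scaffolds of sequentially packed genes.

    Genes are placed left to right with Poisson-ish exon counts and
    exponential-like exon/intron/intergenic lengths; a configurable fraction
    of genes get a second (shorter) isoform, and a fraction may overlap their
    left neighbour.  Coordinates are 1-based inclusive (GFF3 convention).
    """
    from .genomestats import AnnotationSet, Exon, Gene, Transcript

    rng = _rng(seed)
    genes: list = []
    seqs: dict[str, str] = {}
    gene_rows, inter_rows = [], []
    alphabet = np.array(list("ACGT"))
    gid = 0
    for s in range(config.n_scaffolds):
        scaffold = f"scaffold_{s+1}"
        cursor = 0  # last occupied position (0 = none yet)
        prev_gene = None
        for _ in range(config.genes_per_scaffold):
            gap = int(rng.exponential(config.intergenic_mean)) + 1
            if prev_gene is not None and rng.random() < config.overlap_fraction:
                gap = -int(rng.integers(1, 50))
            start = max(1, cursor + gap + 1)
            n_exons = 1 + int(rng.poisson(max(config.exon_count_mean - 1, 0)))
            exon_lens = 1 + rng.poisson(config.exon_len_mean - 1, size=n_exons)
            intron_lens = (
                1 + rng.poisson(config.intron_len_mean - 1, size=max(n_exons - 1, 0))
            )
            exons, pos = [], start
            for j in range(n_exons):
                end = pos + int(exon_lens[j]) - 1
                exons.append(Exon(pos, end))
                if j < n_exons - 1:
                    pos = end + int(intron_lens[j]) + 1
            gid += 1
            gene_id = f"gene{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts = [Transcript(f"{gene_id}.t1", tuple(exons), strand)]
            if rng.random() < config.multi_isoform_fraction and n_exons > 1:
                transcripts.append(
                    Transcript(f"{gene_id}.t2", tuple(exons[:-1]), strand)
                )
            gene = Gene(gene_id, scaffold, tuple(transcripts))
            genes.append(gene)
            exon_span = int(sum(exon_lens))
            intron_span = int(sum(intron_lens)) if n_exons > 1 else 0
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "intron_count": n_exons - 1,
                    "intron_span": intron_span,
                    "exon_span": exon_span,
                }
            )
            if prev_gene is not None:
                inter_rows.append(
                    {
                        "scaffold": scaffold,
                        "left_gene": prev_gene.gene_id,
                        "right_gene": gene_id,
                        "distance": max(start - cursor - 1, 0),
                    }
                )
            cursor = max(cursor, exons[-1].end)
            prev_gene = gene
        scaffold_len = cursor + int(rng.exponential(config.intergenic_mean)) + 1
        seq = rng.choice(alphabet, size=scaffold_len)
        n_mask = rng.random(scaffold_len) < config.n_base_fraction
        seq[n_mask] = "N"
        seqs[scaffold] = "".join(seq)
    ann = AnnotationSet(
        genes=tuple(genes),
        scaffold_lengths={k: len(v) for k, v in seqs.items()},
    )
    return SimAnnotation(
        annotation=ann,
        sequences=seqs,
        gene_truth=pd.DataFrame(gene_rows),
        intergenic_truth=pd.DataFrame(inter_rows),
    )
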