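"""Rooted phylogenetic trees with branch lengths and node support.

The tree model used throughout the package: a rooted tree whose edges carry
branch lengths in substitutions per site and whose internal nodes may carry
integer bootstrap-style support values (0-100), stored in the Newick label
position.  Polytomies are permitted.  Trees are treated as rooted exactly as
written; no automatic re-rooting is performed.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

__all__ = [
    "Node",
    "Phylo",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "collapse_low_support",
    "path_length",
]


class NewickError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    """A structurally invalid tree (duplicate leaves, negative lengths...)."""


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    label : str or None
        Leaf name, or a non-numeric internal label.
    support : int or None
        Integer support in [0, 100] for internal nodes, if annotated.
    length : float or None
        Length of the edge subtending this node (None only at the root or
        when the input omitted it).
    children : list of Node
    parent : Node or None
    """

    __slots__ = ("label", "support", "length", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[int] = None,
    ):
        self.label = label
        self.support = support
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind}>"


class Phylo:
    """A rooted phylogeny; thin wrapper around a :class:`Node` root."""

    def __init__(self, root: Node):
        self.root = root
        self.validate()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def find_leaf(self, label: str) -> Node:
        for leaf in self.leaves():
            if leaf.label == label:
                return leaf
        raise KeyError(f"no leaf labelled {label!r}")

    # -- structure queries -------------------------------------------------

    def leaf_set(self, node: Optional[Node] = None) -> frozenset[str]:
        node = node or self.root
        stack, labels = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                labels.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(labels)

    def mrca(self, labels: Sequence[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        want = set(labels)
        if not want:
            raise ValueError("mrca of an empty label set")
        node = self.find_leaf(next(iter(want)))
        covered = self.leaf_set(node)
        while not want <= covered:
            node = node.parent
            if node is None:
                raise TreeValidationError(f"labels {want} not all in tree")
            covered = self.leaf_set(node)
        return node

    def depths(self) -> dict[Node, float]:
        """Root-to-node path length for every node (root depth 0)."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.preorder() if n is not self.root)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, each keyed by the side not holding
        the lexicographically smallest leaf (rooting-invariant)."""
        all_leaves = self.leaf_set()
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = self.leaf_set(node)
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    # -- housekeeping ------------------------------------------------------

    def copy(self) -> "Phylo":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length, node.support)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return Phylo(clone(self.root))

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length} at {node.label!r}"
                )
            if node.is_leaf:
                if not node.label:
                    raise TreeValidationError("leaf with empty label")
                if node.label in seen:
                    raise TreeValidationError(f"duplicate leaf label {node.label!r}")
                seen.add(node.label)

    def __str__(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_LABEL_FORBIDDEN = set("(),:;[] \t\n")


def parse_newick(text: str) -> Phylo:
    """Parse a single Newick statement into a :class:`Phylo`.

    Internal labels that parse as integers in [0, 100] are stored as node
    support; other internal labels are kept verbatim (and ignored by
    :func:`collapse_low_support`).
    """
    s = text.strip()
    if not s:
        raise NewickError("empty Newick string", 0)
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def read_label() -> str:
        nonlocal pos
        start = pos
        if pos < len(s) and s[pos] in "'\"":
            quote = s[pos]
            pos += 1
            while pos < len(s) and s[pos] != quote:
                pos += 1
            if pos >= len(s):
                raise error("unterminated quoted label")
            label = s[start + 1 : pos]
            pos += 1
            return label
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        return s[start:pos]

    def read_length() -> Optional[float]:
        nonlocal pos
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise error("unreadable branch length") from None
        return None

    def read_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.add_child(read_clade())
                if pos >= len(s):
                    raise error("unexpected end of input inside '('")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            label = read_label()
            if label:
                try:
                    val = int(label)
                except ValueError:
                    node.label = label
                else:
                    if 0 <= val <= 100:
                        node.support = val
                    else:
                        node.label = label
        else:
            label = read_label()
            if not label:
                raise error("expected a leaf label")
            node.label = label
        node.length = read_length()
        return node

    root = read_clade()
    if pos >= len(s) or s[pos] != ";":
        raise error("expected ';' terminating the tree")
    pos += 1
    if s[pos:].strip():
        raise error("trailing characters after ';'")
    return Phylo(root)


def _fmt_length(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: Phylo) -> str:
    """Serialize a tree; round-trips topology, lengths and supports."""

    def render(node: Node) -> str:
        if node.is_leaf:
            out = node.label or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            if node.support is not None:
                tag = str(node.support)
            else:
                tag = node.label or ""
            out = f"({inner}){tag}"
        if node.length is not None:
            out += f":{_fmt_length(node.length)}"
        return out

    return render(tree.root) + ";"


def read_newick_file(path) -> list[Phylo]:
    """Read one tree per non-empty line (or one per file) from ``path``."""
    trees = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


# ---------------------------------------------------------------------------
# Utilities used by the screening and gene-family stages
# ---------------------------------------------------------------------------


def collapse_low_support(tree: Phylo, threshold: int) -> Phylo:
    """Contract internal edges whose child support is strictly below
    ``threshold``.

    Edges without a support annotation are kept.  The contracted edge's own
    length is discarded; the re-attached children keep their lengths.  The
    leaf set is unchanged.  Returns a new tree.
    """
    if threshold < 0:
        raise TreeValidationError("collapse threshold must be non-negative")
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.preorder()):
            if (
                node is not out.root
                and not node.is_leaf
                and node.support is not None
                and node.support < threshold
            ):
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx : idx + 1] = node.children
                for child in node.children:
                    child.parent = parent
                changed = True
                break
    return out


def path_length(tree: Phylo, ancestor: Node, descendant: Node) -> float:
    """Sum of branch lengths on the unique ancestor→descendant path."""
    total = 0.0
    node = descendant
    while node is not ancestor:
        if node.parent is None:
            raise ValueError(
                f"{descendant.label or 'node'} is not a descendant of the "
                "given ancestor"
            )
        total += node.length or 0.0
        node = node.parent
    return total
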