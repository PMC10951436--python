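"""Minimal phylogenetic tree container with Newick round-tripping.

Trees are rooted data structures; an "unrooted" tree is represented with
a (usually trifurcating) root whose placement carries no meaning.
Branch lengths are in expected substitutions per site; internal-node
labels double as bootstrap supports when set by the bootstrap machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def copy(self) -> "Node":
        return Node(
            self.label,
            self.length,
            self.support,
            [c.copy() for c in self.children],
        )

    # -- Newick -------------------------------------------------------------
    def to_newick(self, _top: bool = True) -> str:
        if self.is_leaf:
            s = self.label or ""
        else:
            s = "(" + ",".join(c.to_newick(False) for c in self.children) + ")"
            if self.support is not None:
                s += format(self.support, "g")
            elif self.label:
                s += self.label
        if not _top and self.length is not None:
            s += f":{self.length:.10g}"
        return s + (";" if _top else "")


def parse_newick(text: str) -> Node:
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if text[pos] == ",":
                    pos += 1
                else:
                    break
            if text[pos] != ")":
                raise ValueError(f"unbalanced newick at {pos}")
            pos += 1
        # label and length
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        token = text[start:pos]
        if token:
            if node.children:
                try:
                    node.support = float(token)
                except ValueError:
                    node.label = token
            else:
                node.label = token
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",():;":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse_node()
    if pos != len(text):
        raise ValueError("trailing characters in newick string")
    return root


# ---------------------------------------------------------------------------
# Topology utilities


def bipartitions(root: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions (as the smaller-naming leaf set of each
    internal edge), rooting-invariant."""
    all_leaves = frozenset(root.leaf_labels())
    out = set()
    for node in root.postorder():
        if node is root or node.is_leaf:
            continue
        side = frozenset(node.leaf_labels())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def is_monophyletic(root: Node, taxa) -> bool:
    """True iff some node of the rooted tree has exactly `taxa` as leaves."""
    taxa = frozenset(taxa)
    known = frozenset(root.leaf_labels())
    unknown = taxa - known
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    return any(frozenset(n.leaf_labels()) == taxa for n in root.postorder())


def mrca(root: Node, taxa) -> Node:
    taxa = frozenset(taxa)
    for node in root.postorder():
        if taxa <= frozenset(node.leaf_labels()):
            return node
    raise ValueError("taxa not in tree")


def _parent_map(root: Node) -> dict[int, Node]:
    pm = {}
    for node in root.preorder():
        for c in node.children:
            pm[id(c)] = node
    return pm


def reroot_on_edge(root: Node, child: Node, fraction: float = 0.5) -> Node:
    """Return a new rooted tree with the root placed on the edge above
    ``child``, ``fraction`` of the branch length toward the old root."""
    root = root  # operate in place on a copy made by caller if needed
    pm = _parent_map(root)
    if id(child) not in pm:
        raise ValueError("child node is the root; no edge above it")
    blen = child.length if child.length is not None else 0.0
    new_root = Node()
    # path from child's parent up to old root gets reversed
    parent = pm[id(child)]
    parent.children.remove(child)
    new_root.children = [child]
    child.length = blen * (1.0 - fraction)
    prev = new_root
    carry = blen * fraction
    node = parent
    while node is not None:
        nxt = pm.get(id(node))
        if nxt is not None:
            nxt.children.remove(node)
        prev.children.append(node)
        node.length, carry = carry, node.length
        prev = node
        node = nxt
    # suppress a unary old root left dangling at the end of the path
    _suppress_unary(new_root)
    return new_root


def _suppress_unary(root: Node) -> None:
    for node in list(root.postorder()):
        node.children = [c for c in node.children]
        for i, c in enumerate(node.children):
            while len(c.children) == 1:
                g = c.children[0]
                g.length = (g.length or 0.0) + (c.length or 0.0)
                node.children[i] = g
                c = g


def root_by_clade(root: Node, clade_taxa) -> Node:
    """Root the (unrooted-interpretation) tree on the edge separating
    ``clade_taxa`` from everything else.

    Raises ``ValueError`` if the taxa do not form one side of a bipartition.
    """
    clade_taxa = frozenset(clade_taxa)
    all_leaves = frozenset(root.leaf_labels())
    unknown = clade_taxa - all_leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    tree = root.copy()
    for node in tree.postorder():
        if node is tree:
            continue
        side = frozenset(node.leaf_labels())
        if side == clade_taxa or side == all_leaves - clade_taxa:
            return reroot_on_edge(tree, node)
    raise ValueError("taxa are not monophyletic in the unrooted tree")
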