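"""Rooted phylogenetic trees, hypothesis-tree construction and branch-move
(SPR) topology enumeration.

The null model of the convergence scan is built from trees at branch-move
distance one or two from the species tree.  A single "branch move" is a
rooted subtree-prune-and-regraft (SPR): detach any non-root branch together
with the subtree below it, suppress the resulting degree-2 node, and
reattach the subtree onto any remaining branch (or above the root).  All
resulting topologies are canonicalised (branch lengths and child order
ignored) and deduplicated.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable

import dendropy

# Canonical taxon panel: 16 avian species, five-letter codes.
TAXA_16 = (
    "STRCA", "GALGA", "PHORU", "PODCR", "CALAN", "CAPCA", "GAVST", "PHACA",
    "EGRGA", "CATAU", "HALAL", "HALLE", "TYTAL", "PICPU", "FALPE", "TAEGU",
)


class TreeError(ValueError):
    """Raised for malformed or invalid tree inputs."""


class Node:
    """A node of a rooted binary tree."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None):
        self.name = name
        self.length = length
        self.children: list["Node"] = []
        self.parent: "Node | None" = None

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        clone = Node(self.name, self.length)
        for c in self.children:
            clone.add_child(c.copy())
        return clone


@dataclass
class PhyloTree:
    """Rooted tree over (a subset of) the 16-taxon panel.

    Branch lengths are optional; hypothesis and null topologies carry none
    and are re-optimised per gene by the likelihood engines.
    """

    root: Node
    name: str | None = None

    # -- basic queries ----------------------------------------------------
    def leaves(self) -> list[Node]:
        out = []

        def rec(n: Node) -> None:
            if n.is_leaf:
                out.append(n)
            for c in n.children:
                rec(c)

        rec(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def nodes(self) -> list[Node]:
        out = []

        def rec(n: Node) -> None:
            out.append(n)
            for c in n.children:
                rec(c)

        rec(self.root)
        return out

    def postorder(self) -> list[Node]:
        out = []

        def rec(n: Node) -> None:
            for c in n.children:
                rec(c)
            out.append(n)

        rec(self.root)
        return out

    def validate_binary(self) -> None:
        names = [l.name for l in self.leaves()]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TreeError(f"duplicate leaf label(s): {', '.join(dup)}")
        for n in self.nodes():
            if n.children and len(n.children) != 2:
                raise TreeError(
                    f"non-binary node with {len(n.children)} children"
                )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), name=self.name)

    def key(self) -> str:
        return canonical_key(self)

    def find_mrca(self, names: Iterable[str]) -> Node:
        names = set(names)
        best: Node | None = None

        def leafset(n: Node) -> set[str]:
            if n.is_leaf:
                return {n.name}
            return set().union(*(leafset(c) for c in n.children))

        def rec(n: Node) -> set[str]:
            nonlocal best
            s = {n.name} if n.is_leaf else set().union(*(rec(c) for c in n.children))
            if best is None and names <= s:
                best = n
            return s

        rec(self.root)
        if best is None:
            raise TreeError(f"taxa {sorted(names)} not all present")
        return best


# ---------------------------------------------------------------------------
# newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> Node:
    n = Node(
        dnode.taxon.label if dnode.taxon is not None else dnode.label,
        dnode.edge.length,
    )
    for c in dnode.child_nodes():
        n.add_child(_from_dendropy(c))
    return n


def parse_newick(text: str, name: str | None = None) -> PhyloTree:
    """Parse a rooted newick string into a :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"newick parse error: {exc}") from exc
    tree = PhyloTree(_from_dendropy(dtree.seed_node), name=name)
    if not tree.leaf_names() or tree.leaf_names() == [None]:
        raise TreeError("tree has no labelled leaves")
    return tree


def write_newick(tree: PhyloTree, lengths: bool = True) -> str:
    def rec(n: Node) -> str:
        if n.is_leaf:
            s = n.name or ""
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
            if n.name:
                s += n.name
        if lengths and n.length is not None and n.parent is not None:
            s += f":{n.length:.10g}"
        return s

    return rec(tree.root) + ";"


def canonical_key(tree: PhyloTree) -> str:
    """Canonical topology string: leaf names, sorted child order, no lengths.

    Two rooted trees have equal keys iff their topologies agree up to the
    ordering of children at each node.
    """

    def rec(n: Node) -> str:
        if n.is_leaf:
            return n.name
        return "(" + ",".join(sorted(rec(c) for c in n.children)) + ")"

    return rec(tree.root)


def tree_from_key(key: str) -> PhyloTree:
    """Rebuild a (length-free) tree from a canonical key string."""
    return parse_newick(key + ";")


# ---------------------------------------------------------------------------
# hypothesis construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvergenceHypothesis:
    """A named convergence hypothesis: a focal taxon set forced monophyletic.

    ``n_moves`` is the branch-move distance of the constrained tree from the
    species tree and selects the order of the null topology set.
    """

    name: str
    focal_taxa: frozenset[str]
    n_moves: int

    def constrained_tree(self, species_tree: PhyloTree) -> PhyloTree:
        t = force_monophyly(species_tree, self.focal_taxa)
        t.name = self.name
        return t


#: The three primary and five derived convergence hypotheses.
HYPOTHESES: dict[str, ConvergenceHypothesis] = {
    h.name: h
    for h in (
        ConvergenceHypothesis("H_noc", frozenset({"TYTAL", "CAPCA"}), 1),
        ConvergenceHypothesis(
            "H_foot", frozenset({"GAVST", "PHACA", "PODCR"}), 2
        ),
        ConvergenceHypothesis(
            "H_rap", frozenset({"FALPE", "CATAU", "HALAL", "HALLE"}), 1
        ),
        ConvergenceHypothesis("H_foot_a", frozenset({"GAVST", "PODCR"}), 1),
        ConvergenceHypothesis("H_foot_b", frozenset({"PHACA", "PODCR"}), 1),
        ConvergenceHypothesis("H_foot_c", frozenset({"GAVST", "PHACA"}), 1),
        ConvergenceHypothesis("H_rap_a", frozenset({"FALPE", "CATAU"}), 1),
        ConvergenceHypothesis(
            "H_rap_b", frozenset({"FALPE", "HALAL", "HALLE"}), 1
        ),
    )
}


def _leafset(n: Node) -> frozenset[str]:
    if n.is_leaf:
        return frozenset({n.name})
    return frozenset().union(*(_leafset(c) for c in n.children))


def _depth(n: Node) -> int:
    d = 0
    while n.parent is not None:
        d += 1
        n = n.parent
    return d


def _suppress_unary(n: Node) -> None:
    """Remove a degree-2 internal node, summing branch lengths."""
    (child,) = n.children
    parent = n.parent
    if parent is None:
        return
    if child.length is not None and n.length is not None:
        child.length += n.length
    elif n.length is not None:
        child.length = n.length
    parent.children[parent.children.index(n)] = child
    child.parent = parent


def _detach(tree: PhyloTree, node: Node) -> None:
    """Detach ``node``'s subtree; suppress the vacated parent in place.

    If the parent is the root, the sibling becomes the new root.
    """
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if len(parent.children) == 1:
        if parent.parent is None:
            (sib,) = parent.children
            sib.parent = None
            sib.length = None
            tree.root = sib
        else:
            _suppress_unary(parent)


def force_monophyly(tree: PhyloTree, focal: Iterable[str]) -> PhyloTree:
    """Constrain ``focal`` taxa to a single clade, placed away from STRCA.

    The focal lineage farthest (in node depth) from the root — hence from
    the basal STRCA split — anchors the clade; the remaining maximal focal
    lineages are pruned and regrafted, one by one in name order, onto the
    branch above the growing focal clade.  All non-focal relative
    relationships are preserved; the result is topology-only.
    """
    focal = frozenset(focal)
    leaves = set(tree.leaf_names())
    unknown = focal - leaves
    if unknown:
        raise TreeError(f"unknown focal taxa: {sorted(unknown)}")
    if len(focal) < 2:
        raise TreeError("need at least 2 focal taxa")

    work = tree.copy()
    for n in work.nodes():
        n.length = None

    def maximal_focal_clades() -> list[Node]:
        out: list[Node] = []

        def rec(n: Node) -> None:
            if _leafset(n) <= focal:
                out.append(n)
                return
            for c in n.children:
                rec(c)

        rec(work.root)
        return out

    clades = maximal_focal_clades()
    if len(clades) == 1:
        return work  # already monophyletic
    # anchor: the most nested focal lineage (deepest attachment); name ties
    # broken lexicographically for determinism
    anchor = max(clades, key=lambda n: (_depth(n), min(_leafset(n))))
    movers = sorted(
        (c for c in clades if c is not anchor), key=lambda n: min(_leafset(n))
    )
    for mover in movers:
        _detach(work, mover)
        # regraft onto the branch above the current focal clade
        parent = anchor.parent
        joint = Node()
        if parent is None:
            joint.add_child(anchor)
            joint.add_child(mover)
            work.root = joint
        else:
            parent.children[parent.children.index(anchor)] = joint
            joint.parent = parent
            joint.add_child(anchor)
            joint.add_child(mover)
        anchor = joint
    return work


# ---------------------------------------------------------------------------
# branch-move (SPR) neighbourhood enumeration
# ---------------------------------------------------------------------------

@dataclass
class TopologySet:
    """A deduplicated set of length-free topologies at fixed move distance."""

    keys: list[str]
    move_order: int
    source_key: str
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: str) -> bool:
        return key in set(self.keys)

    def trees(self) -> list[PhyloTree]:
        return [tree_from_key(k) for k in self.keys]

    def save(self, path) -> None:
        """Write newline-delimited newick plus a provenance JSON sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        path.write_text("".join(k + ";\n" for k in self.keys))
        meta = {
            "move_order": self.move_order,
            "source": self.source_key + ";",
            **self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2)
        )

    @classmethod
    def load(cls, path) -> "TopologySet":
        import json
        from pathlib import Path

        path = Path(path)
        keys = [
            canonical_key(parse_newick(line))
            for line in path.read_text().splitlines()
            if line.strip()
        ]
        meta = json.loads(
            path.with_suffix(path.suffix + ".json").read_text()
        )
        source = canonical_key(parse_newick(meta.pop("source")))
        return cls(keys, meta.pop("move_order"), source, provenance=meta)


def _spr_neighbor_keys(tree: PhyloTree) -> set[str]:
    """Canonical keys of every distinct topology one SPR move away."""
    src_key = canonical_key(tree)
    base = tree.copy()
    for n in base.nodes():
        n.length = None
    nodes = base.nodes()
    out: set[str] = set()
    for i, prune_node in enumerate(nodes):
        if prune_node.parent is None:
            continue  # cannot prune the root
        work = PhyloTree(base.root.copy())
        wnodes = work.nodes()
        pn = wnodes[i]
        _detach(work, pn)
        remaining = work.nodes()
        # regraft onto the branch above each remaining non-root node …
        for target in remaining:
            if target.parent is None:
                continue
            parent = target.parent
            joint = Node()
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
            joint.add_child(target)
            joint.add_child(pn.copy())
            key = canonical_key(work)
            # undo splice
            parent.children[parent.children.index(joint)] = target
            target.parent = parent
            if key != src_key:
                out.add(key)
        # … or above the root (new basal split)
        joint = Node()
        old_root = work.root
        joint.add_child(old_root)
        joint.add_child(pn.copy())
        work.root = joint
        key = canonical_key(work)
        work.root = old_root
        old_root.parent = None
        if key != src_key:
            out.add(key)
    return out


def one_move_neighbors(tree: PhyloTree) -> TopologySet:
    """All distinct topologies exactly one branch move from ``tree``."""
    if len(tree.leaves()) < 4:
        raise TreeError("SPR needs at least 4 leaves")
    src = canonical_key(tree)
    keys = sorted(_spr_neighbor_keys(tree))
    return TopologySet(
        keys, move_order=1, source_key=src, provenance={"rule": "rooted-SPR"}
    )


def two_move_neighbors(
    tree: PhyloTree, one_move: TopologySet | None = None
) -> TopologySet:
    """All distinct topologies in which two branch moves build one new clade.

    Two disjoint subtrees are pruned and regrafted so that, together with a
    third anchor lineage of the remaining tree, they form a single
    three-lineage clade (any of its three rooted shapes, at any anchor
    position).  This is the two-move analogue of a single prune-and-regraft,
    which likewise forces the mover and its target into a new clade: the set
    enumerates every restricted monophyly of three lineages at branch-move
    distance two.  The source topology and all one-move topologies are
    excluded.
    """
    if len(tree.leaves()) < 5:
        raise TreeError("two-branch moves need at least 5 leaves")
    if one_move is None:
        one_move = one_move_neighbors(tree)
    src = one_move.source_key
    base = tree.copy()
    for n in base.nodes():
        n.length = None
    nodes = base.nodes()
    lsets = {id(n): _leafset(n) for n in nodes}
    all_leaves = _leafset(base.root)
    out: set[str] = set()
    import itertools as _it

    for i1, i2 in _it.combinations(range(len(nodes)), 2):
        m1, m2 = nodes[i1], nodes[i2]
        if m1.parent is None or m2.parent is None:
            continue
        l1, l2 = lsets[id(m1)], lsets[id(m2)]
        if l1 & l2 or (l1 | l2) == all_leaves:
            continue
        pruned = PhyloTree(base.root.copy())
        wn = pruned.nodes()
        a1, a2 = wn[i1], wn[i2]
        _detach(pruned, a1)
        if a2.parent is None:
            continue
        _detach(pruned, a2)
        n_rem = len(pruned.nodes())
        for ib in range(n_rem):
            for shape in range(3):
                work = PhyloTree(pruned.root.copy())
                b = work.nodes()[ib]
                c1, c2 = a1.copy(), a2.copy()
                parent, slot = b.parent, None
                if parent is not None:
                    slot = parent.children.index(b)
                if shape == 0:
                    inner, outer = (c1, b), c2
                elif shape == 1:
                    inner, outer = (c2, b), c1
                else:
                    inner, outer = (c1, c2), b
                nin = Node()
                nin.add_child(inner[0])
                nin.add_child(inner[1])
                nout = Node()
                nout.add_child(nin)
                nout.add_child(outer)
                if parent is None:
                    work.root, nout.parent = nout, None
                else:
                    parent.children[slot] = nout
                    nout.parent = parent
                out.add(canonical_key(work))
    out -= set(one_move.keys)
    out.discard(src)
    return TopologySet(
        sorted(out),
        move_order=2,
        source_key=src,
        provenance={"rule": "anchored three-lineage clades, distance-exactly-2"},
    )


def sample_topologies(topo_set: TopologySet, n: int, seed: int) -> TopologySet:
    """Uniform sample of ``n`` topologies without replacement."""
    if n > len(topo_set.keys):
        raise TreeError(
            f"cannot sample {n} from a set of {len(topo_set.keys)}"
        )
    rng = random.Random(seed)
    keys = rng.sample(topo_set.keys, n)
    prov = dict(topo_set.provenance)
    prov.update({"sampled_n": n, "seed": seed})
    return TopologySet(keys, topo_set.move_order, topo_set.source_key, prov)


def drop_taxa(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Prune the listed leaves, suppressing unary nodes (lengths summed)."""
    taxa = set(taxa)
    present = set(tree.leaf_names())
    unknown = taxa - present
    if unknown:
        raise TreeError(f"unknown taxa: {sorted(unknown)}")
    if len(present - taxa) < 3:
        raise TreeError("fewer than 3 leaves would remain")
    work = tree.copy()
    for leaf in [l for l in work.leaves() if l.name in taxa]:
        _detach(work, leaf)
    # root may have become unary after detaching a basal leaf
    while len(work.root.children) == 1:
        (only,) = work.root.children
        only.parent = None
        only.length = None
        work.root = only
    return work
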