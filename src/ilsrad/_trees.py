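"""Lightweight rooted/unrooted tree structures shared across the package.

Gene trees produced by the coalescent simulator carry node ages (``time``,
coalescent units, tips at 0); trees built from data carry only branch
lengths.  Newick I/O for external files lives in :mod:`ilsrad.io`.
"""

from __future__ import annotations

import itertools
from collections import deque


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    name : str or None
        Leaf label (internal nodes usually unnamed).
    length : float or None
        Length of the branch above this node.
    children : list[Node]
    time : float or None
        Node age; set by the coalescent simulator (tips at 0).
    """

    __slots__ = ("name", "length", "children", "time", "clamped")

    def __init__(self, name=None, length=None, children=None, time=None):
        self.name = name
        self.length = length
        self.children = list(children) if children else []
        self.time = time
        self.clamped = False  # set by estimators that truncate branch lengths

    def is_leaf(self):
        return not self.children

    def walk(self):
        """Yield nodes in postorder."""
        for c in self.children:
            yield from c.walk()
        yield self

    def leaves(self):
        return [n for n in self.walk() if n.is_leaf()]

    def leaf_names(self):
        return [n.name for n in self.leaves()]

    def copy(self):
        n = Node(self.name, self.length, time=self.time)
        n.children = [c.copy() for c in self.children]
        return n

    def newick(self, lengths=True, comment=None):
        s = _newick(self, lengths)
        if comment:
            s = f"[&{comment}]{s}"
        return s + ";"

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.newick(lengths=False)}>"


def _newick(node, lengths):
    if node.is_leaf():
        s = node.name or ""
    else:
        s = "(" + ",".join(_newick(c, lengths) for c in node.children) + ")"
        if node.name:
            s += node.name
    if lengths and node.length is not None:
        s += f":{node.length:.10g}"
    return s


def from_nested(spec):
    """Build a topology-only tree from nested tuples of leaf names."""
    if isinstance(spec, str):
        return Node(name=spec)
    return Node(children=[from_nested(s) for s in spec])


def clade_map(root):
    """Map each node to the frozenset of its descendant leaf names."""
    out = {}
    for n in root.walk():
        if n.is_leaf():
            out[id(n)] = frozenset([n.name])
        else:
            out[id(n)] = frozenset().union(*(out[id(c)] for c in n.children))
    return out


def has_clade(root, names):
    names = frozenset(names)
    return any(c == names for c in clade_map(root).values())


def mrca(root, names):
    """Smallest clade containing ``names``; returns the Node."""
    names = frozenset(names)
    cm = clade_map(root)
    best = None
    for n in root.walk():
        c = cm[id(n)]
        if names <= c and (best is None or len(c) < len(cm[id(best)])):
            best = n
    return best


def mrca_time(root, names):
    return mrca(root, names).time


def induced_subtree(root, names):
    """Restrict a rooted tree to ``names``: drop other leaves, splice
    unifurcations (branch lengths added where present)."""
    names = set(names)

    def rec(n):
        if n.is_leaf():
            return n.copy() if n.name in names else None
        kids = [k for k in (rec(c) for c in n.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            k = kids[0]
            if k.length is not None and n.length is not None:
                k.length += n.length
            return k
        out = Node(n.name, n.length, time=n.time)
        out.children = kids
        return out

    sub = rec(root)
    if sub is None:
        raise ValueError("no requested leaves in tree")
    return sub


def _neighbor_map(root):
    nbrs = {}
    for n in root.walk():
        for c in n.children:
            nbrs.setdefault(id(n), []).append((c, c.length))
            nbrs.setdefault(id(c), []).append((n, c.length))
    return nbrs


def root_with_outgroup(tree, outgroup):
    """Re-root an (arbitrarily rooted) tree on the branch leading to ``outgroup``.

    Returns a new tree whose root has the outgroup leaf as one child and the
    ingroup subtree as the other.  Unifurcations left over from the old root
    are suppressed (branch lengths added).
    """
    leaves = {l.name: l for l in tree.leaves()}
    if outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    nbrs = _neighbor_map(tree)
    og = leaves[outgroup]
    if not nbrs.get(id(og)):
        raise ValueError("cannot root a single-leaf tree")
    anchor, blen = nbrs[id(og)][0]

    def build(n, parent, length):
        node = Node(name=n.name, length=length, time=n.time)
        for m, l in nbrs.get(id(n), []):
            if m is not parent:
                node.children.append(build(m, n, l))
        return node

    half = None if blen is None else blen / 2.0
    root = Node()
    root.children = [build(og, anchor, half), build(anchor, og, half)]
    _suppress_unifurcations(root)
    return root


def _suppress_unifurcations(root):
    for n in list(root.walk()):
        i = 0
        while i < len(n.children):
            c = n.children[i]
            if not c.is_leaf() and len(c.children) == 1:
                gc = c.children[0]
                if gc.length is not None and c.length is not None:
                    gc.length += c.length
                n.children[i] = gc
            else:
                i += 1


def topo_leaf_distances(tree):
    """Topological (edge-count) distances between all leaf pairs.

    Returns (names, dict-of-dict).  Works on the unrooted shape of the tree.
    """
    nbrs = _neighbor_map(tree)
    nodes = {id(n): n for n in tree.walk()}
    leaves = tree.leaves()
    dists = {}
    for leaf in leaves:
        d = {id(leaf): 0}
        q = deque([leaf])
        while q:
            cur = q.popleft()
            for m, _ in nbrs.get(id(cur), []):
                if id(m) not in d:
                    d[id(m)] = d[id(cur)] + 1
                    q.append(m)
        dists[leaf.name] = {
            other.name: d[id(other)] for other in leaves
        }
    return [l.name for l in leaves], dists


def quartet_split(dists, a, b, c, d):
    """Induced unrooted quartet topology from leaf distances.

    Returns a frozenset of two frozensets (the split), or None on a tie
    (star quartet).
    """
    s_ab = dists[a][b] + dists[c][d]
    s_ac = dists[a][c] + dists[b][d]
    s_ad = dists[a][d] + dists[b][c]
    m = min(s_ab, s_ac, s_ad)
    if [s_ab, s_ac, s_ad].count(m) > 1:
        return None
    if m == s_ab:
        return frozenset([frozenset([a, b]), frozenset([c, d])])
    if m == s_ac:
        return frozenset([frozenset([a, c]), frozenset([b, d])])
    return frozenset([frozenset([a, d]), frozenset([b, c])])


def all_unrooted_topologies(taxa):
    """Enumerate all unrooted binary topologies on ``taxa`` (n>=3).

    Standard recursive edge insertion; (2n-5)!! trees.  Each tree is
    returned rooted arbitrarily at an internal node of degree 3.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    base = Node(children=[Node(name=t) for t in taxa[:3]])
    trees = [base]
    for t in taxa[3:]:
        new = []
        for tr in trees:
            edges = [
                (n, i) for n in tr.walk() for i in range(len(n.children))
            ]
            for n, i in edges:
                tr2 = tr.copy()
                # locate the matching edge in the copy by parallel walk
                n2 = _parallel_node(tr, tr2, n)
                child = n2.children[i]
                mid = Node(children=[child, Node(name=t)])
                n2.children[i] = mid
                new.append(tr2)
        trees = new
    return trees


def _parallel_node(tree, tree_copy, target):
    stack = [(tree, tree_copy)]
    while stack:
        a, b = stack.pop()
        if a is target:
            return b
        stack.extend(zip(a.children, b.children))
    raise RuntimeError("node not found")  # pragma: no cover
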