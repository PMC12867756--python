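"""Per-window gene trees: NJ+JC estimation, support filtering, and
Tree1/Tree2/Tree3 classification with topology-frequency tests.

Windows are classified relative to three focal clades: F (the focal species
group), S (the sister genus) and G (the congeneric groups):

* Tree1 = (S,(F,G)) — the focal group is basal within its genus;
* Tree2 = ((F,S),G) — the focal group clusters with the sister genus;
* Tree3 = (F,(S,G)) — the focal group falls outside both.

The per-window tree method is neighbor joining on JC69 distances with a
site-resampling bootstrap; downstream statistics consume only the topology
label and its support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import two_proportion_z_test
from ._trees import Node, clade_map, root_with_outgroup
from .alignment import WindowAlignment

TOPOLOGY_LABELS = ("Tree1", "Tree2", "Tree3")
UNRESOLVED = "unresolved"

#: concordant genealogies (type0/type1) show the species-tree topology
GENEALOGY_TO_TREE = {"type0": "Tree1", "type1": "Tree1",
                     "type2": "Tree2", "type3": "Tree3"}

_SATURATION = 0.75


class SaturationError(ValueError):
    """Raised when a mismatch fraction is at or beyond the JC69 singularity."""


def jc_distance(p):
    """JC69-corrected distance d = -(3/4) ln(1 - 4p/3) for mismatch fraction p."""
    if not 0.0 <= p < _SATURATION:
        raise SaturationError(f"mismatch fraction {p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def mismatch_fractions(aln: WindowAlignment):
    """Pairwise mismatch fractions with pairwise deletion of gapped columns.

    Returns (P, n_sites) where P[i, j] is the mismatch fraction over columns
    ungapped in both rows and n_sites[i, j] the number of such columns.
    """
    data = aln.data
    ok = data < 4
    n = data.shape[0]
    P = np.zeros((n, n))
    N = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            N[i, j] = N[j, i] = m
            if m:
                P[i, j] = P[j, i] = float(
                    (data[i, both] != data[j, both]).mean())
    return P, N


def jc_distance_matrix(aln: WindowAlignment, saturation="error"):
    """Pairwise JC69 distances; ``saturation`` = 'error' or 'clamp'."""
    P, N = mismatch_fractions(aln)
    n = P.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if N[i, j] == 0:
                raise ValueError(
                    f"no shared ungapped sites between {aln.taxa[i]} and "
                    f"{aln.taxa[j]}")
            p = P[i, j]
            if p >= _SATURATION:
                if saturation == "error":
                    raise SaturationError(
                        f"saturated pair {aln.taxa[i]}/{aln.taxa[j]}")
                p = _SATURATION - 1e-6
            D[i, j] = D[j, i] = jc_distance(p)
    return D


def nj_tree(D, names):
    """Neighbor joining on a symmetric distance matrix.

    Negative branch-length estimates are clamped to 0 (flagged on the
    returned tree as ``tree.clamped``); tied minimal Q values join the
    lexicographically smallest label pair, where a cluster's label is its
    smallest leaf name.
    """
    D = np.asarray(D, dtype=float)
    names = list(names)
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (D < 0).any():
        raise ValueError("distances must be non-negative")

    nodes = [Node(name=nm) for nm in names]
    labels = list(names)
    D = D.copy()
    clamped = False

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0 or lj < 0:
            clamped = True
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[:-1, -1] = D2[-1, :-1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # three-point formulas close the unrooted tree
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    if min(la, lb, lc) < 0:
        clamped = True
    a.length, b.length, c.length = (max(la, 0.0), max(lb, 0.0), max(lc, 0.0))
    root = Node(children=[a, b, c])
    root.clamped = clamped  # type: ignore[attr-defined]
    return root


def root_and_classify(tree, outgroup, focal_sets):
    """Root on the outgroup and assign Tree1/Tree2/Tree3 or unresolved.

    ``focal_sets`` maps 'F', 'S', 'G' to sets of taxon names.  Each focal
    set must be monophyletic (or a singleton) in the rooted tree, otherwise
    the window is unresolved.
    """
    F = frozenset(focal_sets["F"])
    S = frozenset(focal_sets["S"])
    G = frozenset(focal_sets["G"])
    rooted = root_with_outgroup(tree, outgroup)
    clades = set(clade_map(rooted).values())
    for group in (F, S, G):
        if len(group) > 1 and group not in clades:
            return UNRESOLVED
    if F | G in clades:
        return "Tree1"
    if F | S in clades:
        return "Tree2"
    if S | G in clades:
        return "Tree3"
    return UNRESOLVED


@dataclass
class WindowTreeRecord:
    window_id: str
    tree: Node
    focal_support: float
    topology: str
    flagged: bool = False


def bootstrap_support(aln: WindowAlignment, B, rng, outgroup, focal_sets,
                      assigned=None):
    """Fraction of site-resampled NJ trees reproducing the window's topology.

    Columns containing any gap or ambiguity are wholly excluded from
    resampling.  An alignment with zero variable (ungapped) sites gets
    support 0 and is flagged.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    ok = aln.ungapped_columns()
    sub = aln.data[:, ok]
    variable = (sub != sub[0]).any(axis=0)
    if not variable.any():
        return 0.0, True
    if assigned is None:
        assigned = root_and_classify(
            nj_tree(jc_distance_matrix(aln, saturation="clamp"), aln.taxa),
            outgroup, focal_sets)
    L = sub.shape[1]
    hits = 0
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep = WindowAlignment(aln.taxa, sub[:, cols])
        topo = root_and_classify(
            nj_tree(jc_distance_matrix(rep, saturation="clamp"), rep.taxa),
            outgroup, focal_sets)
        hits += topo == assigned
    return hits / B, False


def build_window_tree(aln: WindowAlignment, outgroup, focal_sets, B=100,
                      rng=None):
    """NJ tree + topology label + bootstrap support for one window."""
    rng = rng if rng is not None else np.random.default_rng(0)
    tree = nj_tree(jc_distance_matrix(aln, saturation="clamp"), aln.taxa)
    topo = root_and_classify(tree, outgroup, focal_sets)
    support, flagged = bootstrap_support(aln, B, rng, outgroup, focal_sets,
                                         assigned=topo)
    return WindowTreeRecord(aln.window_id, tree, support, topo, flagged)


def analyze_windows(alignments, outgroup, focal_sets, B=100, seed=0):
    """Per-window records for a list of alignments, as a DataFrame."""
    streams = np.random.SeedSequence(seed).spawn(max(len(alignments), 1))
    rows = []
    for aln, ss in zip(alignments, streams):
        rec = build_window_tree(aln, outgroup, focal_sets, B=B,
                                rng=np.random.default_rng(ss))
        rows.append((rec.window_id, rec.topology, rec.focal_support,
                     rec.flagged, rec.tree.newick()))
    return pd.DataFrame(
        rows, columns=["window_id", "topology", "support", "flagged", "newick"])


def topology_frequencies(records, min_support=0.25):
    """Topology proportions over support-filtered windows plus pairwise
    two-proportion tests of Tree1 against Tree2 and Tree3.

    ``records``: DataFrame with 'topology' and 'support' columns (or a list
    of WindowTreeRecord).  Unresolved windows are excluded from the
    proportions and reported separately.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            [(r.window_id, r.topology, r.focal_support) for r in records],
            columns=["window_id", "topology", "support"])
    kept = records[records["support"] >= min_support]
    classified = kept[kept["topology"].isin(TOPOLOGY_LABELS)]
    n = len(classified)
    if n == 0:
        raise ValueError("no windows pass the support filter")
    counts = {t: int((classified["topology"] == t).sum())
              for t in TOPOLOGY_LABELS}
    props = {t: counts[t] / n for t in TOPOLOGY_LABELS}
    z12, p12 = two_proportion_z_test(counts["Tree1"], counts["Tree2"], n)
    z13, p13 = two_proportion_z_test(counts["Tree1"], counts["Tree3"], n)
    return {
        "n": n,
        "n_unresolved": int(len(kept) - n),
        "counts": counts,
        "proportions": props,
        "tests": {
            "Tree1_vs_Tree2": {"z": z12, "p": p12},
            "Tree1_vs_Tree3": {"z": z13, "p": p13},
        },
    }
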