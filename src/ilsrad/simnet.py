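"""Multispecies-coalescent simulation on a species network with known truth.

The generator emulates the statistical structure of a six-genome alignment
study: a species tree over five ingroup lineages plus an outgroup, with
divergence times in coalescent units (2N generations of the root
population), optional unidirectional introgression pulses, or a hybrid node
that sends each gene lineage to one of two parental branches.  Per window it
draws a gene tree from the multispecies coalescent (MSC), evolves JC69
sequences along it, and records the true genealogy class of the window
(type0/type1 concordant, type2/type3 discordant).

Branches are identified by the frozenset of taxa descending from them; time
runs backwards from the tips (age 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._trees import Node, mrca_time
from .alignment import WindowAlignment
from .patterns import site_pattern_probs

GENEALOGY_CLASSES = ("type0", "type1", "type2", "type3")


# ---------------------------------------------------------------------------
# network description


@dataclass(frozen=True)
class Pulse:
    """An introgression pulse: at ``time`` (coalescent units, backwards in
    time), each gene lineage sitting in the recipient branch moves to the
    donor branch with probability ``gamma``."""

    time: float
    donor: frozenset
    recipient: frozenset
    gamma: float


@dataclass(frozen=True)
class Hybrid:
    """A hybrid leaf: at ``time`` its lineage enters ``parent1`` with
    inheritance probability ``gamma``, else ``parent2``."""

    taxon: str
    parent1: frozenset
    parent2: frozenset
    time: float
    gamma: float


def _freeze(x):
    if isinstance(x, str):
        return frozenset([x])
    return frozenset(x)


def _flat_order(topology):
    order = []

    def rec(s):
        if isinstance(s, str):
            order.append(s)
        else:
            for x in s:
                rec(x)

    rec(topology)
    rank = {t: i for i, t in enumerate(order)}
    return lambda t: rank[t]


class SpeciesNetwork:
    """Rooted species tree with divergence times, plus optional introgression
    pulses or a hybrid node; the ground-truth demography for simulation and
    for the closed-form MSC expectations.

    Parameters
    ----------
    topology
        Nested tuples of backbone leaf names, e.g. ``((("A","B"),"C"),"O")``.
    node_times
        Mapping clade (iterable of names) -> divergence time in coalescent
        units.  Every internal node of ``topology`` needs a time; times must
        strictly increase root-ward.
    pop_sizes
        Optional mapping clade -> relative population size (scales the
        coalescent rate on that branch; default 1 everywhere).
    pulses, hybrid
        Introgression events; branch endpoints may be given as a taxon name
        or an iterable of names (the clade below the branch).
    outgroup
        If given, must attach at the root.
    """

    def __init__(self, topology, node_times, pop_sizes=None, pulses=(),
                 hybrid=None, outgroup=None, focal_triplet=None):
        self._children: dict[frozenset, list] = {}
        self._parent: dict[frozenset, frozenset | None] = {}
        self._time: dict[frozenset, float] = {}

        def build(spec):
            if isinstance(spec, str):
                c = frozenset([spec])
                self._time[c] = 0.0
                return c
            kids = [build(s) for s in spec]
            c = frozenset().union(*kids)
            self._children[c] = kids
            for k in kids:
                self._parent[k] = c
            return c

        self.root = build(topology)
        times = {_freeze(k): float(v) for k, v in dict(node_times).items()}
        for c in self._children:
            if c not in times:
                raise ValueError(f"missing node time for clade {sorted(c)}")
            self._time[c] = times[c]
        self._parent[self.root] = None

        for c, kids in self._children.items():
            for k in kids:
                if self._time[c] <= self._time[k]:
                    raise ValueError("node times must strictly increase root-ward")

        self.pop_sizes = {_freeze(k): float(v)
                          for k, v in (pop_sizes or {}).items()}
        self.backbone_taxa = tuple(sorted(self.root, key=_flat_order(topology)))
        self.outgroup = outgroup
        if outgroup is not None:
            if frozenset([outgroup]) not in self._children.get(self.root, []):
                raise ValueError("outgroup must attach at the root")

        self.hybrid: Hybrid | None = None
        if hybrid is not None:
            if not isinstance(hybrid, Hybrid):
                tx, p1, p2, t, g = hybrid
                hybrid = Hybrid(tx, _freeze(p1), _freeze(p2), float(t), float(g))
            else:
                hybrid = Hybrid(hybrid.taxon, _freeze(hybrid.parent1),
                                _freeze(hybrid.parent2), hybrid.time, hybrid.gamma)
            if not 0.0 <= hybrid.gamma <= 1.0:
                raise ValueError("hybrid gamma must be in [0, 1]")
            if hybrid.taxon in self.root:
                raise ValueError("hybrid taxon must not be part of the backbone")
            self._time[frozenset([hybrid.taxon])] = 0.0
            self.hybrid = hybrid
            for br in (hybrid.parent1, hybrid.parent2):
                if not self._alive(br, hybrid.time):
                    raise ValueError("hybrid parents must be alive at the hybrid time")

        self.pulses: list[Pulse] = []
        for p in pulses:
            if isinstance(p, Pulse):
                p = Pulse(p.time, _freeze(p.donor), _freeze(p.recipient), p.gamma)
            else:
                t, d, r, g = p
                p = Pulse(float(t), _freeze(d), _freeze(r), float(g))
            if not 0.0 <= p.gamma <= 1.0:
                raise ValueError("pulse gamma must be in [0, 1]")
            for br in (p.donor, p.recipient):
                if not self._alive(br, p.time):
                    raise ValueError(
                        f"pulse time {p.time} outside lifespan of branch {sorted(br)}")
            self.pulses.append(p)

        self.taxa = self.backbone_taxa + (
            (self.hybrid.taxon,) if self.hybrid else ())
        self.focal_triplet = focal_triplet

    # -- branch bookkeeping -------------------------------------------------

    def _alive(self, branch, t):
        if branch not in self._time:
            return False
        return self._time[branch] <= t < self._t_top(branch)

    def _t_top(self, branch):
        if self.hybrid and branch == frozenset([self.hybrid.taxon]):
            return self.hybrid.time
        parent = self._parent.get(branch)
        return math.inf if parent is None else self._time[parent]

    def pop_size(self, branch):
        return self.pop_sizes.get(branch, 1.0)

    def node_time(self, clade):
        return self._time[_freeze(clade)]

    def split_time(self, names):
        """Time of the smallest backbone clade containing ``names``."""
        names = frozenset(names)
        best = None
        for c in self._children:
            if names <= c and (best is None or len(c) < len(best)):
                best = c
        if best is None:
            raise ValueError(f"no backbone clade contains {sorted(names)}")
        return self._time[best]

    def internal_events(self):
        """(time, clade) merge events sorted by time."""
        return sorted(((self._time[c], c) for c in self._children),
                      key=lambda x: x[0])

    # -- stock networks -----------------------------------------------------

    @classmethod
    def triplet(cls, T, tau1=1.0, outgroup_time=None, pulses=()):
        """Species tree ((A,B),C)[+O] with an internal branch of length ``T``."""
        tau2 = tau1 + T
        if outgroup_time is None:
            return cls((("A", "B"), "C"),
                       {("A", "B"): tau1, ("A", "B", "C"): tau2},
                       pulses=pulses, focal_triplet=("A", "B", "C"))
        return cls(((("A", "B"), "C"), "O"),
                   {("A", "B"): tau1, ("A", "B", "C"): tau2,
                    ("A", "B", "C", "O"): outgroup_time},
                   pulses=pulses, outgroup="O",
                   focal_triplet=("A", "B", "C"))

    @classmethod
    def quartet(cls, tau1=1.0, tau2=1.5184, tau_out=4.0, pulses=()):
        """((P1,P2),P3)+O — the ABBA-BABA configuration."""
        return cls(((("P1", "P2"), "P3"), "O"),
                   {("P1", "P2"): tau1, ("P1", "P2", "P3"): tau2,
                    ("P1", "P2", "P3", "O"): tau_out},
                   pulses=pulses, outgroup="O",
                   focal_triplet=("P1", "P2", "P3"))

    @classmethod
    def dfoil(cls, tau12=0.5, tau34=1.0, tau_anc=1.5, tau_out=4.0, pulses=()):
        """(((P1,P2),(P3,P4)),O) — the five-taxon D_FOIL configuration.

        The (P1,P2) split must be more recent than the (P3,P4) split.
        """
        if not tau12 < tau34:
            raise ValueError("D_FOIL requires the (P1,P2) split to be more "
                             "recent than the (P3,P4) split")
        return cls(((("P1", "P2"), ("P3", "P4")), "O"),
                   {("P1", "P2"): tau12, ("P3", "P4"): tau34,
                    ("P1", "P2", "P3", "P4"): tau_anc,
                    ("P1", "P2", "P3", "P4", "O"): tau_out},
                   pulses=pulses, outgroup="O")

    @classmethod
    def study_default(cls, T_focal=0.5184, pulses=(), hybrid=None):
        """Six-taxon network shaped like a langur-type study system.

        ``F`` = focal species group (basal within its genus), ``G1``..``G3``
        = congeneric species groups, ``S`` = sister genus, ``O`` = outgroup.
        The internal branch between the genus MRCA and the split from ``S``
        is ``T_focal`` coalescent units; the default reproduces ~60/20/20
        triplet discordance for the (F, congener, S) triplet.
        """
        t_genus = 1.0
        return cls(
            ((((("G3", "G2"), "G1"), "F"), "S"), "O"),
            {("G3", "G2"): 0.4,
             ("G3", "G2", "G1"): 0.7,
             ("G3", "G2", "G1", "F"): t_genus,
             ("G3", "G2", "G1", "F", "S"): t_genus + T_focal,
             ("G3", "G2", "G1", "F", "S", "O"): 3.0},
            pulses=pulses, hybrid=hybrid, outgroup="O",
            focal_triplet=("F", "G1", "S"))


# ---------------------------------------------------------------------------
# closed-form MSC expectations


def msc_topology_probs(T):
    """Rooted triplet topology probabilities under the MSC.

    For an internal branch of ``T`` coalescent units the two discordant
    topologies each have probability exp(-T)/3 and the concordant topology
    1 - (2/3) exp(-T).

    Returns ``(p_concordant, p_minor1, p_minor2)``.
    """
    if T < 0:
        raise ValueError("internal branch length must be non-negative")
    m = math.exp(-T) / 3.0
    return (1.0 - 2.0 * m, m, m)


# ---------------------------------------------------------------------------
# gene-tree sampling


def _coalesce_interval(nodes, t0, t1, pop, rng):
    """Coalesce ``nodes`` (in place) between t0 and t1 at rate k(k-1)/2/pop."""
    t = t0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 * pop / (k * (k - 1)))
        if t >= t1:
            break
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = Node(children=[a, b], time=t)
        a.length = t - a.time
        b.length = t - b.time
        for idx in sorted((i, j), reverse=True):
            nodes.pop(idx)
        nodes.append(parent)


def sample_gene_tree(network, rng, taxa=None, return_info=False):
    """Draw one gene tree from the MSC on ``network``.

    Within each species-tree branch, k lineages coalesce at rate
    k(k-1)/2 / pop_size per coalescent unit; pulses move each recipient
    lineage to the donor branch with probability gamma; a hybrid lineage
    enters parent1 with probability gamma.

    Returns the rooted, ultrametric gene tree (node ages in coalescent
    units).  With ``return_info=True`` also returns a dict with the list of
    lineage ``migrations`` that actually happened.
    """
    taxa = list(taxa) if taxa is not None else list(network.taxa)
    unknown = set(taxa) - set(network.taxa)
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")

    branches: dict[frozenset, list[Node]] = {}
    for t in taxa:
        branches.setdefault(frozenset([t]), []).append(Node(name=t, time=0.0))

    events = []  # (time, priority, kind, payload)
    for p in network.pulses:
        events.append((p.time, 0, "pulse", p))
    if network.hybrid:
        events.append((network.hybrid.time, 0, "hybrid", network.hybrid))
    for t, clade in network.internal_events():
        events.append((t, 1, "merge", clade))
    events.sort(key=lambda e: (e[0], e[1]))
    events.append((math.inf, 2, "end", None))

    info = {"migrations": []}
    t_now = 0.0
    for ev_time, _prio, kind, payload in events:
        for br, nodes in branches.items():
            if len(nodes) > 1:
                _coalesce_interval(nodes, t_now, ev_time,
                                   network.pop_size(br), rng)
        t_now = ev_time
        if kind == "merge":
            pooled = []
            for kid in network._children[payload]:
                pooled.extend(branches.pop(kid, []))
            if pooled:
                branches.setdefault(payload, []).extend(pooled)
        elif kind == "pulse":
            src = branches.get(payload.recipient, [])
            moved = [n for n in src if rng.random() < payload.gamma]
            if moved:
                branches[payload.recipient] = [n for n in src if n not in moved]
                branches.setdefault(payload.donor, []).extend(moved)
                info["migrations"].append(
                    ("pulse", payload.time,
                     "+".join(sorted(payload.donor)),
                     "+".join(sorted(payload.recipient))))
        elif kind == "hybrid":
            hb = frozenset([payload.taxon])
            src = branches.pop(hb, [])
            for n in src:
                if rng.random() < payload.gamma:
                    branches.setdefault(payload.parent1, []).append(n)
                    parent_label = "parent1"
                else:
                    branches.setdefault(payload.parent2, []).append(n)
                    parent_label = "parent2"
                info["migrations"].append(
                    ("hybrid", payload.time, parent_label, payload.taxon))
        else:  # end of time: everything should be in the root branch
            remaining = [n for nodes in branches.values() for n in nodes]
            if len(remaining) != 1:  # pragma: no cover - guarded by validation
                raise RuntimeError("lineages failed to coalesce")
            root = remaining[0]
            root.length = None
            return (root, info) if return_info else root


def classify_triplet_topology(tree, triplet):
    """Rooted triplet topology: 0 if (A,B) is the cherry, 1 if (A,C), 2 if (B,C)."""
    a, b, c = triplet
    times = (mrca_time(tree, (a, b)), mrca_time(tree, (a, c)),
             mrca_time(tree, (b, c)))
    return int(np.argmin(times))


def classify_genealogy(tree, network, triplet=None):
    """Truth class of a gene tree for the focal triplet (A,B,C), species
    relation ((A,B),C).

    type0: (A,B) cherry with coalescence inside the A+B ancestral branch
    (below the deeper split); type1: (A,B) cherry but deep coalescence;
    type2: (A,C) cherry; type3: (B,C) cherry.
    """
    triplet = triplet or network.focal_triplet
    if triplet is None:
        raise ValueError("no focal triplet given")
    a, b, c = triplet
    tau_split = network.split_time((a, b, c))
    topo = classify_triplet_topology(tree, triplet)
    if topo == 1:
        return "type2"
    if topo == 2:
        return "type3"
    return "type0" if mrca_time(tree, (a, b)) <= tau_split else "type1"


# ---------------------------------------------------------------------------
# sequence evolution


def evolve_sequences(tree, window_len, theta, rng):
    """Evolve JC69 sequences along a gene tree.

    Branch lengths in expected substitutions/site are the coalescent-unit
    lengths times theta/2 (theta = population-scaled mutation rate/site).
    Returns {taxon: int8 codes}; the alignment is ungapped.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    L = int(window_len)
    seqs = {}

    def rec(node, seq):
        if node.is_leaf():
            seqs[node.name] = seq
            return
        for c in node.children:
            b = (node.time - c.time) * theta / 2.0
            p = 0.75 * (1.0 - math.exp(-4.0 * b / 3.0))
            s = seq.copy()
            if p > 0:
                mask = rng.random(L) < p
                n = int(mask.sum())
                if n:
                    s[mask] = (s[mask] + rng.integers(1, 4, n,
                                                      dtype=np.int8)) % 4
            rec(c, s)

    root_seq = rng.integers(0, 4, L, dtype=np.int8)
    rec(tree, root_seq)
    return seqs


# ---------------------------------------------------------------------------
# whole-genome simulation


@dataclass
class SimulationConfig:
    """Layout and parameters of one simulated genome.

    Windows are laid end-to-end on a single synthetic chromosome; a fixed
    ``seed`` gives bitwise-identical output (per-window substreams are
    spawned from the master seed, so windows are independent of ordering).
    """

    n_windows: int
    window_len: int = 1000
    theta: float = 0.01
    seed: int = 0
    chrom: str = "chr1"
    taxa: tuple | None = None
    truth_triplet: tuple | None = None
    gene_models: list = field(default_factory=list)
    suppress_ils_in_cds: bool = False
    max_resample: int = 1000

    def __post_init__(self):
        if self.n_windows < 0:
            raise ValueError("n_windows must be >= 0")
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


@dataclass
class SimulatedGenome:
    config: SimulationConfig
    network: SpeciesNetwork
    windows: list
    trees: list
    truth: pd.DataFrame

    @property
    def genome_len(self):
        return self.config.n_windows * self.config.window_len

    def write(self, outdir):
        from . import io as _io
        _io.write_simulated_genome(self, outdir)


TRUTH_COLUMNS = ["window_id", "chrom", "start", "end",
                 "genealogy_class", "introgressed", "origin"]


def simulate_genome(config, network):
    """Simulate a windowed genome: MSC gene trees, JC69 alignments, truth
    labels, and (optionally) embedded gene models.

    With ``suppress_ils_in_cds`` set, windows overlapping a CDS resample
    their genealogy until it is concordant (type0/type1) — a crude stand-in
    for purifying selection removing discordance from coding regions.
    """
    taxa = list(config.taxa) if config.taxa else list(network.taxa)
    triplet = config.truth_triplet or network.focal_triplet
    if triplet is None:
        raise ValueError("a truth triplet is required (set truth_triplet "
                         "or use a network with a focal_triplet)")
    L = config.window_len
    cds = sorted(
        (s, e) for g in config.gene_models for (s, e) in g.cds)

    streams = np.random.SeedSequence(config.seed).spawn(max(config.n_windows, 1))
    windows, trees, rows = [], [], []
    for w in range(config.n_windows):
        rng = np.random.default_rng(streams[w])
        start, end = w * L, (w + 1) * L
        in_cds = any(s < end and start < e for s, e in cds)
        for _ in range(config.max_resample):
            tree, info = sample_gene_tree(network, rng, taxa=taxa,
                                          return_info=True)
            cls = classify_genealogy(tree, network, triplet)
            if not (config.suppress_ils_in_cds and in_cds
                    and cls in ("type2", "type3")):
                break
        seqs = evolve_sequences(tree, L, config.theta, rng)
        wid = f"win_{w:06d}"
        aln = WindowAlignment.from_seqs(
            {t: seqs[t] for t in taxa}, window_id=wid,
            chrom=config.chrom, start=start)
        migrations = info["migrations"]
        rows.append((wid, config.chrom, start, end, cls,
                     bool(migrations),
                     migrations[0][2] if migrations else "."))
        windows.append(aln)
        trees.append(tree)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return SimulatedGenome(config, network, windows, trees, truth)


def make_gene_models(n_genes, genome_len, chrom="chr1", n_cds=3,
                     cds_len=200, intron_len=300):
    """Evenly spaced synthetic gene models with ``n_cds`` CDS exons each."""
    from .ilsgenes import GeneModel
    span = n_cds * cds_len + (n_cds - 1) * intron_len
    if n_genes * span > genome_len:
        raise ValueError("genes do not fit in the genome")
    step = genome_len // max(n_genes, 1)
    genes = []
    for g in range(n_genes):
        start = g * step
        cds = [(start + i * (cds_len + intron_len),
                start + i * (cds_len + intron_len) + cds_len)
               for i in range(n_cds)]
        genes.append(GeneModel(f"gene{g + 1:04d}", chrom, "+", cds))
    return genes


# ---------------------------------------------------------------------------
# site-level genealogy mosaics (input for the genealogy HMM)


def simulate_mosaic(network, n_sites, mean_tract, theta, rng, taxa=None,
                    triplet=None, chrom="chr1"):
    """A single alignment whose genealogy switches along the sequence.

    Tract lengths are geometric with the given mean; each tract gets an
    independent MSC gene tree.  This emulates recombination fragmenting
    genealogies at the site level (the window simulator instead assumes free
    recombination between windows and none within).

    Returns (WindowAlignment, per-site class labels 0..3, tract table).
    """
    taxa = list(taxa) if taxa is not None else list(network.taxa)
    triplet = triplet or network.focal_triplet
    cols, labels, rows = [], [], []
    pos = 0
    while pos < n_sites:
        tract = min(int(rng.geometric(1.0 / mean_tract)), n_sites - pos)
        tree = sample_gene_tree(network, rng, taxa=taxa)
        cls = classify_genealogy(tree, network, triplet)
        seqs = evolve_sequences(tree, tract, theta, rng)
        cols.append(np.vstack([seqs[t] for t in taxa]))
        labels.append(np.full(tract, GENEALOGY_CLASSES.index(cls)))
        rows.append((chrom, pos, pos + tract, cls))
        pos += tract
    data = (np.hstack(cols) if cols
            else np.empty((len(taxa), 0), dtype=np.int8))
    aln = WindowAlignment(taxa, data, window_id="mosaic", chrom=chrom, start=0)
    lab = (np.concatenate(labels) if labels
           else np.empty(0, dtype=np.int64))
    tracts = pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])
    return aln, lab, tracts


# ---------------------------------------------------------------------------
# targeted fast samplers (exact, vectorized special cases)


def sample_triplet_branch_lengths(n, class_mix, rng):
    """Internal branch lengths under the ILS/introgression mixture.

    ``class_mix = (p_intro, lam, C)``: with probability 1-p_intro the length
    is Exp(lam) (lam is the mean), otherwise C + Exp(lam).
    """
    p_intro, lam, C = class_mix
    if not 0.0 <= p_intro <= 1.0:
        raise ValueError("p_intro must be in [0, 1]")
    if lam <= 0:
        raise ValueError("lam must be positive")
    if C < 0:
        raise ValueError("C must be non-negative")
    x = rng.exponential(lam, size=n)
    intro = rng.random(n) < p_intro
    x[intro] += C
    return x


def sample_triplet_coalescents(T, n, rng, tau1=1.0, pulse_time=None,
                               pulse_gamma=0.0):
    """Vectorized MSC draws on ((A,B),C), optionally with a recent pulse.

    The pulse (backwards in time) moves A's lineage into C's branch at
    ``pulse_time`` < tau1 with probability ``pulse_gamma`` — i.e. forward in
    time, C donated genome to A more recently than any speciation.

    Returns a dict of arrays: ``cls`` (0..3 as in GENEALOGY_CLASSES),
    ``topology`` (0 = (A,B) cherry, 1 = (A,C), 2 = (B,C)), pairwise
    coalescent times ``t_ab, t_ac, t_bc``, and the rooted-triplet
    ``internal`` branch length (coalescent units).

    Distribution-identical to :func:`sample_gene_tree` on the corresponding
    network (checked in the test suite); used where very many independent
    triplets are needed.
    """
    if T < 0:
        raise ValueError("T must be non-negative")
    tau2 = tau1 + T
    if pulse_time is not None and not (0.0 <= pulse_time < tau1):
        raise ValueError("pulse must predate the first speciation")

    t_ab = np.empty(n)
    t_ac = np.empty(n)
    t_bc = np.empty(n)
    cls = np.empty(n, dtype=np.int64)

    moved = (rng.random(n) < pulse_gamma) if pulse_time is not None \
        else np.zeros(n, dtype=bool)

    # moved lineages: A sits in C's branch on [pulse_time, tau2)
    v = rng.exponential(size=n)
    ac_in = moved & (v < tau2 - (pulse_time or 0.0))
    t1 = np.where(ac_in, (pulse_time or 0.0) + v, np.nan)

    # unmoved: A,B may coalesce inside the internal branch [tau1, tau2)
    u = rng.exponential(size=n)
    ab_in = ~moved & (u < T)

    deep = ~(ac_in | ab_in)
    n_deep = int(deep.sum())
    w1 = rng.exponential(scale=1.0 / 3.0, size=n_deep)
    w2 = rng.exponential(size=n_deep)
    pair = rng.integers(0, 3, size=n_deep)  # 0:(A,B) 1:(A,C) 2:(B,C)

    # fill the three cases
    root_shallow = tau2 + rng.exponential(size=n)

    # case: (A,C) inside C's branch (recent introgression genealogy)
    t_ac[ac_in] = t1[ac_in]
    t_ab[ac_in] = root_shallow[ac_in]
    t_bc[ac_in] = root_shallow[ac_in]
    cls[ac_in] = 2

    # case: (A,B) inside the internal branch (type0)
    t_ab[ab_in] = tau1 + u[ab_in]
    t_ac[ab_in] = root_shallow[ab_in]
    t_bc[ab_in] = root_shallow[ab_in]
    cls[ab_in] = 0

    # case: all three lineages in the root population
    first = tau2 + w1
    second = first + w2
    di = np.flatnonzero(deep)
    t_ab[di] = np.where(pair == 0, first, second)
    t_ac[di] = np.where(pair == 1, first, second)
    t_bc[di] = np.where(pair == 2, first, second)
    cls[di] = np.choose(pair, [1, 2, 3])

    stacked = np.stack([t_ab, t_ac, t_bc])
    topology = stacked.argmin(axis=0)
    t_cherry = stacked.min(axis=0)
    t_deep = stacked.max(axis=0)
    return {
        "cls": cls, "topology": topology,
        "t_ab": t_ab, "t_ac": t_ac, "t_bc": t_bc,
        "t_cherry": t_cherry, "t_deep": t_deep,
        "internal": t_deep - t_cherry,
    }


def sample_triplet_topology_mixture(gamma, T, n, rng, T2=None):
    """Triplet topology counts under a one-reticulation network.

    With probability ``gamma`` the hybrid lineage follows parent 1 (species
    tree placing it with parent 1, internal branch T), else parent 2
    (internal branch T2, default T).  Returns counts over the three rooted
    topologies: (hybrid+parent1, hybrid+parent2, parent1+parent2).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    T2 = T if T2 is None else T2
    c1, m1, _ = msc_topology_probs(T)
    c2, m2, _ = msc_topology_probs(T2)
    p_parent1 = np.array([c1, m1, m1])            # topo order: (H,P1),(H,P2),(P1,P2)
    p_parent2 = np.array([m2, c2, m2])
    k1 = rng.binomial(n, gamma)
    counts = (rng.multinomial(k1, p_parent1)
              + rng.multinomial(n - k1, p_parent2))
    return tuple(int(x) for x in counts)


def simulate_site_pattern_counts(network, taxa_order, n_windows, window_len,
                                 theta, rng, return_trees=False):
    """Per-window site-pattern counts without materialising sequences.

    Given the gene tree, sites are iid, so a window's pattern counts are one
    multinomial draw from the pruning-computed pattern probabilities — the
    exact collapsed form of :func:`evolve_sequences` (equivalence is
    tested).  Returns an (n_windows, 4**k) integer array.
    """
    k = len(taxa_order)
    out = np.empty((n_windows, 4 ** k), dtype=np.int64)
    trees = []
    for w in range(n_windows):
        tree = sample_gene_tree(network, rng, taxa=taxa_order)
        probs = site_pattern_probs(tree, taxa_order, theta=theta)
        out[w] = rng.multinomial(window_len, probs)
        if return_trees:
            trees.append(tree)
    return (out, trees) if return_trees else out


# ---------------------------------------------------------------------------
# planted-fixture helpers


PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def planted_shared_genotype_alignment(taxa, group_ab, n_cols, planted, rng):
    """Protein alignment with group-diagnostic residues at known columns.

    At each planted column every taxon in ``group_ab`` carries one residue
    and every other taxon a single different residue; remaining columns are
    invariant.  Used to validate the shared-residue scan end to end.
    """
    group_ab = set(group_ab)
    n_taxa = len(taxa)
    base = rng.integers(0, len(PROTEIN_ALPHABET), size=n_cols)
    data = np.tile(base, (n_taxa, 1))
    for col in planted:
        r1, r2 = rng.choice(len(PROTEIN_ALPHABET), size=2, replace=False)
        for i, t in enumerate(taxa):
            data[i, col] = r1 if t in group_ab else r2
    return {
        t: "".join(PROTEIN_ALPHABET[c] for c in data[i])
        for i, t in enumerate(taxa)
    }
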