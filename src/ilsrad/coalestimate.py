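"""Species-tree and network estimation from gene-tree topologies.

Contains the exact quartet-agreement species-tree search (the estimand of
ASTRAL-style methods, solved exactly at small taxon counts), the closed-form
inversion from minor-topology frequencies to the internal branch length in
coalescent units, the hybrid-speciation topology test, and maximum
likelihood for the inheritance probability gamma of a one-reticulation
network from rooted triplet frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._stats import conditional_binomial_test
from ._trees import all_unrooted_topologies, quartet_split, topo_leaf_distances


# ---------------------------------------------------------------------------
# species-tree estimation


def exact_quartet_species_tree(gene_trees, max_taxa=8):
    """Species topology maximizing total quartet agreement with the gene trees.

    Scores every unrooted candidate topology by the summed number of gene
    tree quartets whose induced split it reproduces, and returns all
    maximizers (ties are reported explicitly).  Feasible for <= 8 taxa.
    """
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    taxa = sorted(gene_trees[0].leaf_names())
    if len(taxa) > max_taxa:
        raise ValueError(f"too many taxa for exact search ({len(taxa)})")
    for t in gene_trees:
        if sorted(t.leaf_names()) != taxa:
            raise ValueError("gene trees must share one leaf set")

    quartets = list(itertools.combinations(taxa, 4))
    tally = {q: {} for q in quartets}
    for tree in gene_trees:
        _, d = topo_leaf_distances(tree)
        for q in quartets:
            split = quartet_split(d, *q)
            if split is not None:
                tally[q][split] = tally[q].get(split, 0) + 1

    best_score, best = -1, []
    for cand in all_unrooted_topologies(taxa):
        _, d = topo_leaf_distances(cand)
        score = 0
        for q in quartets:
            split = quartet_split(d, *q)
            score += tally[q].get(split, 0)
        if score > best_score:
            best_score, best = score, [cand]
        elif score == best_score:
            best.append(cand)
    return {"topologies": best, "score": best_score, "tied": len(best) > 1,
            "n_trees": len(gene_trees)}


@dataclass
class TripletT:
    """Internal branch length recovered from minor-topology frequency."""

    T: float
    flag: str | None = None  # None | 'infinite' | 'anomaly'


def triplet_T_hat(p_minor_avg):
    """Invert the MSC minor-topology probability: T = -ln(3 p_minor).

    p_minor_avg = 0 maps to +inf (flagged); values above 1/3 are impossible
    under the MSC on a tree (anomaly flag, T = 0 returned).
    """
    if p_minor_avg < 0 or p_minor_avg > 1:
        raise ValueError("p_minor_avg must be a probability")
    if p_minor_avg == 0:
        return TripletT(math.inf, "infinite")
    if p_minor_avg > 1.0 / 3.0:
        return TripletT(0.0, "anomaly")
    return TripletT(-math.log(3.0 * p_minor_avg))


@dataclass
class TripletSummary:
    taxa: tuple
    counts: tuple
    p_major: float
    T_hat: TripletT


def summarize_triplet(counts, taxa=("F", "G", "S")):
    """Counts over the three rooted triplet topologies -> branch-length summary.

    The major topology is the modal one; T is inverted from the average of
    the two minor frequencies.
    """
    counts = tuple(int(c) for c in counts)
    n = sum(counts)
    if n == 0:
        raise ValueError("empty counts")
    major = max(range(3), key=counts.__getitem__)
    minors = [counts[i] / n for i in range(3) if i != major]
    return TripletSummary(tuple(taxa), counts, counts[major] / n,
                          triplet_T_hat(sum(minors) / 2.0))


# ---------------------------------------------------------------------------
# hybrid-speciation test


def hybrid_speciation_test(counts, parental=(0, 1), alpha=0.05):
    """Topology-proportion test of the hybrid-speciation hypothesis.

    Under hybrid speciation the focal lineage should cluster equally often
    with each parental candidate, and more often with either parent than
    with the non-parental topology.  ``counts`` are the (Tree1, Tree2,
    Tree3) window counts; ``parental`` gives the indices of the two
    topologies that place the focal clade with each putative parent.

    The decision is conjunctive: 'rejected' if the parental counts differ
    (two-sided, exact conditional binomial) or if either parental proportion
    fails to exceed the non-parental one (one-sided).
    """
    counts = tuple(int(c) for c in counts)
    if sum(counts) == 0:
        raise ValueError("zero total count")
    i, j = parental
    (k,) = set(range(3)) - set(parental)
    p_equal = conditional_binomial_test(counts[i], counts[j])
    p_dom = {
        idx: conditional_binomial_test(counts[idx], counts[k],
                                       alternative="greater")
        for idx in parental
    }
    rejected = (p_equal < alpha) or any(p >= alpha for p in p_dom.values())
    return {
        "decision": "rejected" if rejected else "consistent-with-hybrid",
        "p_parental_equality": p_equal,
        "p_parental_dominance": p_dom,
        "alpha": alpha,
        "counts": counts,
    }


# ---------------------------------------------------------------------------
# inheritance probability (gamma) from triplet frequencies


def _mixture_probs(gamma, T):
    a = math.exp(-T)
    p1 = gamma * (1.0 - 2.0 * a / 3.0) + (1.0 - gamma) * a / 3.0
    p2 = gamma * a / 3.0 + (1.0 - gamma) * (1.0 - 2.0 * a / 3.0)
    p3 = a / 3.0
    return p1, p2, p3


@dataclass
class TripletMixtureResults:
    """ML estimates for the one-reticulation triplet mixture."""

    gamma_hat: float
    T_hat: float
    loglik: float
    ci_gamma: tuple
    counts: tuple
    n: int
    identifiable: bool
    history: list = field(default_factory=list, repr=False)

    @property
    def parental_branch_lengths(self):
        # one hybridization time => a shared internal branch on both sides
        return (self.T_hat, self.T_hat)

    def summary(self):
        lo, hi = self.ci_gamma
        lines = [
            "Triplet topology mixture (one reticulation)",
            "=" * 46,
            f"n gene trees            {self.n}",
            f"counts (H+P1,H+P2,P1P2) {self.counts}",
            f"gamma_hat               {self.gamma_hat:.4f}",
            f"95% profile CI          [{lo:.4f}, {hi:.4f}]",
            f"T_hat (coalescent units){self.T_hat: .4f}",
            f"log-likelihood          {self.loglik:.3f}",
        ]
        if not self.identifiable:
            lines.append("WARNING: configuration near non-identifiability "
                         "(internal branch ~ 0)")
        return "\n".join(lines)


class TripletTopologyMixture:
    """ML model for the inheritance probability of a hybrid lineage.

    Observed data are counts of the three rooted triplet topologies for
    (hybrid, parent1, parent2): the topology placing the hybrid with parent
    1, with parent 2, and the parent1+parent2 topology.  The model is
    P(topo) = gamma * P_MSC(topo | parent-1 tree, T)
            + (1-gamma) * P_MSC(topo | parent-2 tree, T),
    with a single internal branch length T shared by the two parental trees
    (a hybridization event at one time implies equal branches; with free
    branch lengths the triplet mixture is not identifiable).
    """

    def __init__(self, counts):
        counts = tuple(int(c) for c in counts)
        if len(counts) != 3 or min(counts) < 0:
            raise ValueError("counts must be three non-negative integers")
        if sum(counts) == 0:
            raise ValueError("empty counts")
        self.counts = counts
        self.n = sum(counts)

    def loglik(self, gamma, T):
        probs = _mixture_probs(gamma, T)
        return sum(c * math.log(max(p, 1e-300))
                   for c, p in zip(self.counts, probs))

    def fit(self, ci=True, ci_level=0.95, gamma_grid=401):
        n1, n2, n3 = self.counts
        n = self.n
        p3 = n3 / n
        a0 = min(3.0 * p3, 1.0 - 1e-9)
        T0 = -math.log(max(a0, 1e-12))
        if a0 < 1.0 - 1e-6:
            g0 = (n1 / n - a0 / 3.0) / (1.0 - a0)
        else:
            g0 = 0.5
        g0 = min(max(g0, 1e-6), 1.0 - 1e-6)

        history = []

        def nll(x):
            return -self.loglik(x[0], x[1])

        x0 = np.array([g0, max(T0, 1e-6)])
        history.append(-nll(x0))
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B",
            bounds=[(0.0, 1.0), (1e-9, 50.0)],
            callback=lambda xk: history.append(-nll(xk)))
        gamma_hat, T_hat = float(res.x[0]), float(res.x[1])
        ll = -float(res.fun)
        history.append(ll)

        identifiable = T_hat > 1e-3
        ci_gamma = (0.0, 1.0)
        if ci:
            crit = stats.chi2.ppf(ci_level, df=1) / 2.0
            grid = np.linspace(0.0, 1.0, gamma_grid)
            keep = []
            for g in grid:
                prof = optimize.minimize_scalar(
                    lambda T: -self.loglik(g, T),
                    bounds=(1e-9, 50.0), method="bounded")
                if ll - (-prof.fun) <= crit:
                    keep.append(g)
            if keep:
                ci_gamma = (float(min(keep)), float(max(keep)))
        return TripletMixtureResults(
            gamma_hat=gamma_hat, T_hat=T_hat, loglik=ll, ci_gamma=ci_gamma,
            counts=self.counts, n=n, identifiable=identifiable,
            history=history)


def gamma_triplet_ml(counts, **kw):
    """Functional wrapper around :class:`TripletTopologyMixture`."""
    return TripletTopologyMixture(counts).fit(**kw)
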