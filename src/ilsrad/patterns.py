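"""Site-pattern probabilities on small trees under JC69.

The probability of every labelled nucleotide pattern at a site, for a rooted
tree with branch lengths in expected substitutions/site, is computed by
Felsenstein pruning.  With k taxa there are 4**k patterns, indexed with the
first taxon as the most significant base-4 digit.

These vectors serve two purposes: they are the emission distributions of the
genealogy HMM, and they let simulations collapse per-site sequence evolution
into one multinomial draw per window (sites are iid given the gene tree).
"""

from __future__ import annotations

import numpy as np

from ._trees import Node


def jc_transition_matrix(b: float) -> np.ndarray:
    """JC69 transition matrix for a branch of ``b`` substitutions/site."""
    if b < 0:
        raise ValueError("negative branch length")
    e = np.exp(-4.0 * b / 3.0)
    off = 0.25 * (1.0 - e)
    m = np.full((4, 4), off)
    np.fill_diagonal(m, 0.25 + 0.75 * e)
    return m


def _leaf_onehots(taxa_order: tuple) -> dict:
    k = len(taxa_order)
    npat = 4 ** k
    out = {}
    for i, t in enumerate(taxa_order):
        digits = (np.arange(npat) // 4 ** (k - 1 - i)) % 4
        oh = np.zeros((npat, 4))
        oh[np.arange(npat), digits] = 1.0
        out[t] = oh
    return out


_ONEHOT_CACHE: dict = {}


def site_pattern_probs(tree: Node, taxa_order, theta: float | None = None) -> np.ndarray:
    """Probability of each of the 4**k labelled site patterns.

    Parameters
    ----------
    tree
        Rooted tree over ``taxa_order``.  If ``theta`` is given, branch
        lengths are derived from node ages (coalescent units) as
        ``dt * theta / 2``; otherwise ``node.length`` is taken to be in
        substitutions/site already.
    taxa_order
        Taxon order defining the pattern index (first taxon = most
        significant digit).
    """
    taxa_order = tuple(taxa_order)
    npat = 4 ** len(taxa_order)
    if taxa_order not in _ONEHOT_CACHE:
        _ONEHOT_CACHE[taxa_order] = _leaf_onehots(taxa_order)
    onehots = _ONEHOT_CACHE[taxa_order]

    def partial(node, parent_time):
        if node.is_leaf():
            lik = onehots[node.name]
        else:
            lik = np.ones((npat, 4))
            for c in node.children:
                lik = lik * partial(c, node.time)
        b = _branch_subs(node, parent_time, theta)
        if b is None:  # root
            return lik
        return lik @ jc_transition_matrix(b).T

    root_lik = partial(tree, None)
    probs = 0.25 * root_lik.sum(axis=1)
    return probs


def _branch_subs(node, parent_time, theta):
    if parent_time is None and theta is not None:
        return None
    if theta is not None:
        return (parent_time - node.time) * theta / 2.0
    if node.length is None:
        return None
    return node.length


def pattern_index(aln_codes: np.ndarray) -> np.ndarray:
    """Column pattern indices for a (k, L) coded alignment; -1 where gapped."""
    k, L = aln_codes.shape
    idx = np.zeros(L, dtype=np.int64)
    for i in range(k):
        idx = idx * 4 + aln_codes[i]
    idx[(aln_codes >= 4).any(axis=0)] = -1
    return idx


def pattern_to_codes(idx: np.ndarray, k: int) -> np.ndarray:
    """Invert :func:`pattern_index` for ungapped patterns: (k, L) codes."""
    out = np.empty((k, len(idx)), dtype=np.int8)
    for i in range(k):
        out[i] = (idx // 4 ** (k - 1 - i)) % 4
    return out


def biallelic_derived_masks(k: int):
    """For k ingroup taxa + 1 outgroup (last digit), map the 4**(k+1) pattern
    space to binary derived/ancestral patterns polarized by the outgroup.

    Returns (valid, binary) where ``valid`` marks patterns with exactly two
    alleles overall (outgroup carrying one of them) and ``binary`` gives, for
    valid patterns, the integer whose bit i (from the first taxon, MSB) is 1
    iff taxon i carries the derived (non-outgroup) allele.
    """
    n = k + 1
    npat = 4 ** n
    idx = np.arange(npat)
    states = np.stack(
        [(idx // 4 ** (n - 1 - i)) % 4 for i in range(n)], axis=0
    )
    out = states[-1]
    derived = states[:-1] != out  # (k, npat)
    # allele carried by each derived taxon must be the same single allele
    alt = np.where(derived, states[:-1], -1)
    alt_max = alt.max(axis=0)
    ok_single = np.ones(npat, dtype=bool)
    for i in range(k):
        ok_single &= (alt[i] == -1) | (alt[i] == alt_max)
    has_derived = derived.any(axis=0)
    valid = ok_single & has_derived
    binary = np.zeros(npat, dtype=np.int64)
    for i in range(k):
        binary += derived[i].astype(np.int64) << (k - 1 - i)
    return valid, binary
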