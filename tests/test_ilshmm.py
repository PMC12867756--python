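"""Genealogy HMM: emissions, forward-backward, EM, segments, statistics."""

import itertools
import math

import numpy as np
import pytest

from ilsrad import simnet
from ilsrad._trees import Node
from ilsrad.ilshmm import (HmmParams, IlsSegment, call_ils_sites,
                           chrom_aggregation, emission_probs,
                           forward_backward, fit_hmm_em, merge_segments,
                           segment_stats, state_genealogy)
from ilsrad.patterns import jc_transition_matrix, pattern_index

TAXA = ("A", "B", "C", "O")


def _params(s=1e-3, pi=(0.55, 0.15, 0.15, 0.15)):
    return HmmParams.from_divergence(0.003, 0.005, 0.02, 0.004, pi=pi, s=s,
                                     taxa=TAXA)


# ---------------------------------------------------------------------------
# emissions


def test_zero_branch_lengths_emit_constant_patterns():
    tree = state_genealogy("type0", 1.0, 2.0, 3.0, 1.0, TAXA)
    for n in tree.walk():
        n.time = 0.0
    probs = emission_probs(tree, TAXA)
    constant = [sum(i * 4 ** p for p in range(4)) for i in range(4)]
    assert probs[constant] == pytest.approx([0.25] * 4)
    assert probs.sum() == pytest.approx(1.0)
    others = np.delete(probs, constant)
    assert np.all(others < 1e-12)


def test_emission_probs_match_bruteforce_enumeration(rng):
    tree = state_genealogy("type2", 0.004, 0.007, 0.02, 0.005, TAXA)
    probs = emission_probs(tree, TAXA)

    # brute force: sum over the three internal-node states
    def edges(node, parent_time, acc):
        for c in node.children:
            acc.append((node, c, (node.time - c.time)))
            edges(c, node.time, acc)

    acc = []
    edges(tree, None, acc)
    P = {id(c): jc_transition_matrix(dt) for (_, c, dt) in acc}
    internals = [n for n in tree.walk() if not n.is_leaf()]
    leaves = {n.name: n for n in tree.leaves()}
    brute = np.zeros(256)
    for pat in range(256):
        leaf_state = {t: (pat // 4 ** (3 - i)) % 4
                      for i, t in enumerate(TAXA)}
        total = 0.0
        for assign in itertools.product(range(4), repeat=len(internals)):
            st = {id(n): a for n, a in zip(internals, assign)}
            p = 0.25
            for (parent, child, _) in acc:
                cs = (leaf_state[child.name] if child.is_leaf()
                      else st[id(child)])
                p *= P[id(child)][st[id(parent)], cs]
            total += p
        brute[pat] = total
    assert np.allclose(probs, brute, atol=1e-12)


def test_emission_probs_normalized_random_lengths(rng):
    for _ in range(5):
        t1, t2, t3 = np.sort(rng.uniform(0.001, 0.05, 3))
        tree = state_genealogy("type1", t1, t2 + 1e-4, t3 + 2e-4,
                               rng.uniform(0.001, 0.02), TAXA)
        assert emission_probs(tree, TAXA).sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# forward-backward


def test_posterior_rows_sum_to_one(rng):
    params = _params()
    codes, _ = params.simulate(2000, rng)
    post, ll = forward_backward(codes, params)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)
    assert math.isfinite(ll)


def test_degenerate_chain_recovers_pure_state(rng):
    # deeper divergences give well-separated emissions; with s ~ 0 the
    # whole sequence shares one state and the posterior pins it everywhere
    params = HmmParams.from_divergence(0.01, 0.02, 0.05, 0.01, s=1e-6,
                                       taxa=TAXA)
    em0 = params.emissions[0]
    idx = rng.choice(256, size=20000, p=em0)
    from ilsrad.patterns import pattern_to_codes
    codes = pattern_to_codes(idx, 4)
    post, _ = forward_backward(codes, params)
    assert post[:, 0].min() > 0.99


def test_loglik_matches_path_enumeration(rng):
    params = _params(s=5e-3)
    codes, _ = params.simulate(9, rng)
    idx = pattern_index(codes)
    E = params.emissions[:, idx].T
    A = params.transition_matrix()
    total = 0.0
    for path in itertools.product(range(4), repeat=9):
        p = params.pi[path[0]] * E[0, path[0]]
        for t in range(1, 9):
            p *= A[path[t - 1], path[t]] * E[t, path[t]]
        total += p
    _, ll = forward_backward(codes, params)
    assert ll == pytest.approx(math.log(total), abs=1e-9)


def test_gapped_columns_are_state_uninformative(rng):
    params = _params()
    codes, _ = params.simulate(500, rng)
    codes[:, 100] = 4  # gap column
    post, ll = forward_backward(codes, params)
    assert np.allclose(post.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# EM


def test_em_monotone_and_recovers_parameters(rng):
    truth = _params(s=5e-3, pi=(0.5, 0.17, 0.165, 0.165))
    codes, _ = truth.simulate(100_000, rng)
    init = _params(s=2e-2, pi=(0.3, 0.3, 0.2, 0.2))
    res = fit_hmm_em(codes, init, max_iter=40, tol=1e-5)
    path = res.loglik_path
    assert all(b >= a - 1e-6 for a, b in zip(path, path[1:]))
    assert res.params.s == pytest.approx(5e-3, rel=0.3)
    assert res.params.pi[0] == pytest.approx(0.5, abs=0.06)


def test_em_initialized_at_truth_barely_moves(rng):
    truth = _params(s=5e-3)
    codes, _ = truth.simulate(40_000, rng)
    res = fit_hmm_em(codes, truth, max_iter=2, tol=1e-12)
    # at the generating parameters the M-step is already near a fixed point
    assert res.params.s == pytest.approx(truth.s, rel=0.5)
    assert np.abs(res.params.pi - truth.pi).max() < 0.05


def test_constant_alignment_is_degenerate():
    codes = np.zeros((4, 500), dtype=np.int8)
    res = fit_hmm_em(codes, _params())
    assert res.degenerate and not res.converged


# ---------------------------------------------------------------------------
# site calls and segments


def test_call_ils_sites_rule():
    post = np.array([[0.1, 0.1, 0.5, 0.3],
                     [0.5, 0.5, 0.0, 0.0],
                     [0.2, 0.2, 0.3, 0.3]])
    assert call_ils_sites(post).tolist() == [True, False, True]
    assert call_ils_sites(post, threshold=1.0).sum() == 0


def test_merge_segments_examples():
    calls = [1, 1, 1, 0, 1, 1]
    segs = merge_segments(calls, max_gap=0)
    assert [(s.start, s.end) for s in segs] == [(0, 3), (4, 6)]
    segs = merge_segments(calls, max_gap=1)
    assert [(s.start, s.end) for s in segs] == [(0, 6)]
    assert merge_segments([0, 0, 0]) == []


def test_segment_stats_arithmetic():
    ils = [IlsSegment("c", 0, 700, 0.9), IlsSegment("c", 800, 1584, 0.9)]
    rep = segment_stats(ils, [], 10000)
    assert rep["mean_length"] == pytest.approx(742.0)
    small = [IlsSegment("c", 0, 89, 0.9)]
    rep = segment_stats(small, [], 1000)
    assert rep["genome_fraction"] == pytest.approx(0.089)
    same = [IlsSegment("c", i * 10, i * 10 + 5, 0.5) for i in range(4)]
    rep = segment_stats(same[:2], same[2:], 1000)
    assert rep["welch_p"] == 1.0
    with pytest.raises(ValueError):
        segment_stats(ils, [], 0)


def test_segment_stats_coding_fraction():
    ils = [IlsSegment("c", 150, 250, 0.9)]
    rep = segment_stats(ils, [], 1000, cds_intervals=[(100, 400)])
    assert rep["coding_fraction"] == pytest.approx(100 / 300)


def test_chrom_aggregation_cases():
    segs = {c: [IlsSegment(c, 0, 100, 0.9)]
            for c in ("chr1", "chr2", "chr3", "chrX")}
    lens = {c: 1_000_000 for c in segs}
    klass = {"chr1": "autosome", "chr2": "autosome", "chr3": "autosome",
             "chrX": "X"}
    res = chrom_aggregation(segs, lens, klass)
    assert res["ratio"] == pytest.approx(1.0)
    # doubled X density is detected
    segs["chrX"] = [IlsSegment("chrX", 0, 200, 0.9)]
    res = chrom_aggregation(segs, lens, klass)
    assert res["ratio"] == pytest.approx(2.0)
    # zero segments: flagged
    res = chrom_aggregation({}, lens, klass)
    assert res["flag"] is not None
    with pytest.raises(ValueError):
        chrom_aggregation(segs, lens, {"chr1": "autosome"})


# ---------------------------------------------------------------------------
# decoding performance


def test_decoding_recovers_ils_sites_on_self_consistent_data(rng):
    params = _params(s=1e-3, pi=(0.45, 0.15, 0.2, 0.2))
    codes, states = params.simulate(40_000, rng)
    post, _ = forward_backward(codes, params)
    calls = call_ils_sites(post)
    true_ils = states >= 2
    recall = (calls & true_ils).sum() / true_ils.sum()
    assert recall >= 0.85


def test_segment_length_decreases_with_switch_rate(rng):
    # recombination (the switch rate) fragments ILS tracts
    means = []
    for s in (1e-4, 1e-3, 1e-2):
        params = _params(s=s, pi=(0.4, 0.14, 0.23, 0.23))
        codes, _ = params.simulate(120_000, rng)
        post, _ = forward_backward(codes, params)
        segs = merge_segments(call_ils_sites(post))
        assert segs, f"no ILS segments called at s={s}"
        means.append(np.mean([sg.length for sg in segs]))
    assert means[0] > means[1] > means[2]


def test_ils_segments_shorter_than_non_ils_when_concordance_dominates(rng):
    params = _params(s=2e-3, pi=(0.6, 0.14, 0.13, 0.13))
    codes, _ = params.simulate(60_000, rng)
    post, _ = forward_backward(codes, params)
    calls = call_ils_sites(post)
    ils = merge_segments(calls)
    non = merge_segments(~calls)
    rep = segment_stats(ils, non, 60_000)
    assert rep["mean_length"] < np.mean([s.length for s in non])
    assert rep["welch_p"] < 0.05


def test_network_mosaic_decoding(rng):
    """Decoding a sequence-level mosaic simulated from the species network
    (not from the HMM itself) still recovers most ILS sites."""
    theta = 0.01
    net = simnet.SpeciesNetwork.triplet(0.5184, outgroup_time=3.0)
    aln, labels, _ = simnet.simulate_mosaic(net, 30_000, mean_tract=1000,
                                            theta=theta, rng=rng)
    half = theta / 2
    c, m, _ = simnet.msc_topology_probs(0.5184)
    params = HmmParams.from_divergence(
        1.0 * half, 1.5184 * half, 3.0 * half, half,
        pi=(c - m, m, m, m), s=1e-3, taxa=tuple(aln.taxa))
    post, _ = forward_backward(aln.data, params)
    calls = call_ils_sites(post)
    true_ils = labels >= 2
    recall = (calls & true_ils).sum() / true_ils.sum()
    assert recall >= 0.6
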