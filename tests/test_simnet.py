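"""Simulator: MSC expectations, sequence evolution, genome plumbing."""

import math

import numpy as np
import pytest
from scipy import stats

from ilsrad import simnet, windowtrees
from ilsrad._trees import induced_subtree, mrca_time
from ilsrad.simnet import (GENEALOGY_CLASSES, SimulationConfig,
                           SpeciesNetwork, classify_genealogy,
                           evolve_sequences, msc_topology_probs,
                           sample_gene_tree, sample_triplet_branch_lengths,
                           sample_triplet_coalescents, simulate_genome)


# ---------------------------------------------------------------------------
# closed-form MSC probabilities


def test_msc_probs_star_and_deep():
    assert msc_topology_probs(0) == pytest.approx((1 / 3, 1 / 3, 1 / 3))
    c, m1, m2 = msc_topology_probs(50.0)
    assert c == pytest.approx(1.0) and m1 == pytest.approx(0.0, abs=1e-20)
    with pytest.raises(ValueError):
        msc_topology_probs(-0.1)


def test_msc_probs_study_value():
    # closed form at the study-level discordance: 60.30 / 19.85 / 19.85 %
    c, m1, m2 = msc_topology_probs(0.5184)
    assert c == pytest.approx(0.6030, abs=5e-5)
    assert m1 == pytest.approx(0.1985, abs=5e-5) and m1 == m2


# ---------------------------------------------------------------------------
# the MSC sampler


def test_pairwise_tmrca_is_standard_exponential(rng):
    net = SpeciesNetwork(("A", "B"), {("A", "B"): 0.0 + 1e-9})
    # two lineages in (essentially) one population: TMRCA ~ Exp(1)
    times = [sample_gene_tree(net, rng).time for _ in range(20000)]
    assert np.mean(times) == pytest.approx(1.0, abs=3 * 1.0 / math.sqrt(20000))


@pytest.mark.parametrize("T", [1e-9, 0.25, 0.5, 1.0, 2.0])
def test_topology_frequencies_match_closed_form(T, rng):
    net = SpeciesNetwork.triplet(T)
    n = 30000
    counts = np.zeros(3)
    for _ in range(n):
        tree = sample_gene_tree(net, rng)
        counts[simnet.classify_triplet_topology(tree, ("A", "B", "C"))] += 1
    probs = msc_topology_probs(T)
    chi2 = stats.chisquare(counts, n * np.array(probs))
    assert chi2.pvalue > 0.001


def test_vectorized_triplet_sampler_matches_general(rng):
    T = 0.5184
    vec = sample_triplet_coalescents(T, 50000, rng)
    vec_freq = np.bincount(vec["cls"], minlength=4) / 50000
    net = SpeciesNetwork.triplet(T)
    counts = np.zeros(4)
    n = 20000
    for _ in range(n):
        cls = classify_genealogy(sample_gene_tree(net, rng), net)
        counts[GENEALOGY_CLASSES.index(cls)] += 1
    chi2 = stats.chisquare(counts, n * vec_freq)
    assert chi2.pvalue > 0.001
    # expected class split: type0 = 1-e^-T, others e^-T/3 each
    e = math.exp(-T)
    assert vec_freq == pytest.approx([1 - e, e / 3, e / 3, e / 3], abs=0.01)


def test_hybrid_gamma_one_follows_parent1(rng):
    # gamma=1: hybrid H always enters P's branch -> MSC on ((H,P),Q)
    net = SpeciesNetwork(
        (("P", "Q"), "O"),
        {("P", "Q"): 1.5, ("P", "Q", "O"): 4.0},
        hybrid=("H", "P", "Q", 0.9, 1.0), outgroup="O")
    n = 8000
    counts = np.zeros(3)
    for _ in range(n):
        tree = sample_gene_tree(net, rng, taxa=("H", "P", "Q"))
        counts[simnet.classify_triplet_topology(tree, ("H", "P", "Q"))] += 1
    T = 1.5 - 0.9
    chi2 = stats.chisquare(counts, n * np.array(msc_topology_probs(T)))
    assert chi2.pvalue > 0.001


def test_pulse_validation_rejects_dead_branches():
    with pytest.raises(ValueError):
        SpeciesNetwork.triplet(0.5, pulses=[(2.5, "C", "A", 0.1)])
    with pytest.raises(ValueError):
        SpeciesNetwork.triplet(0.5, pulses=[(0.5, "C", "A", 1.5)])


def test_msprime_cross_check(rng):
    """Independent oracle: msprime's MSC gives the same topology law."""
    msprime = pytest.importorskip("msprime")
    T, tau1 = 0.8, 1.0
    demography = msprime.Demography()
    for pop in ("A", "B", "C", "AB", "ABC"):
        demography.add_population(name=pop, initial_size=1.0)
    demography.add_population_split(time=tau1, derived=["A", "B"],
                                    ancestral="AB")
    demography.add_population_split(time=tau1 + T, derived=["AB", "C"],
                                    ancestral="ABC")
    n = 8000
    counts = np.zeros(3)
    reps = msprime.sim_ancestry(
        samples={"A": 1, "B": 1, "C": 1}, demography=demography, ploidy=1,
        num_replicates=n, random_seed=7)
    for ts in reps:
        t = ts.first()
        tmrcas = [t.tmrca(0, 1), t.tmrca(0, 2), t.tmrca(1, 2)]
        counts[int(np.argmin(tmrcas))] += 1
    probs = msc_topology_probs(T)
    chi2 = stats.chisquare(counts, n * np.array(probs))
    assert chi2.pvalue > 0.001


# ---------------------------------------------------------------------------
# sequence evolution


def test_theta_zero_gives_identical_rows(triplet_net, rng):
    tree = sample_gene_tree(triplet_net, rng)
    seqs = evolve_sequences(tree, 500, 0.0, rng)
    rows = list(seqs.values())
    for r in rows[1:]:
        assert np.array_equal(rows[0], r)


def test_jc_divergence_matches_closed_form(rng):
    # two taxa at fixed TMRCA t: mismatch fraction ~ (3/4)(1-e^{-4d/3})
    t, theta, L = 1.7, 0.02, 100000
    net = SpeciesNetwork(("A", "B"), {("A", "B"): t})
    tree = None
    while tree is None or abs(tree.time - t) > 1e-12:
        # condition on immediate coalescence by building the tree directly
        from ilsrad._trees import Node
        a, b = Node(name="A", time=0.0), Node(name="B", time=0.0)
        tree = Node(children=[a, b], time=t)
        a.length = b.length = t
    seqs = evolve_sequences(tree, L, theta, rng)
    p = float((seqs["A"] != seqs["B"]).mean())
    d = 2 * t * theta / 2
    expect = 0.75 * (1 - math.exp(-4 * d / 3))
    se = math.sqrt(expect * (1 - expect) / L)
    assert p == pytest.approx(expect, abs=3 * se)


def test_sequence_determinism(triplet_net):
    def run():
        r = np.random.default_rng(42)
        tree = sample_gene_tree(triplet_net, r)
        return evolve_sequences(tree, 300, 0.01, r)

    s1, s2 = run(), run()
    for k in s1:
        assert np.array_equal(s1[k], s2[k])


# ---------------------------------------------------------------------------
# genome simulation


def test_zero_windows_is_empty_but_valid(study_net, tmp_path):
    cfg = SimulationConfig(n_windows=0, seed=1)
    sim = simulate_genome(cfg, study_net)
    assert len(sim.windows) == 0 and len(sim.truth) == 0
    sim.write(tmp_path)
    bed = (tmp_path / "truth.bed").read_text()
    assert bed.startswith("#chrom")
    gff = (tmp_path / "genes.gff3").read_text()
    assert gff.startswith("##gff-version 3")


def test_truth_partitions_chromosome(small_genome):
    truth = small_genome.truth
    assert truth["start"].iloc[0] == 0
    assert (truth["end"].iloc[:-1].to_numpy()
            == truth["start"].iloc[1:].to_numpy()).all()
    assert truth["end"].iloc[-1] == small_genome.genome_len


def test_no_pulses_no_introgression_truth(small_genome):
    assert not small_genome.truth["introgressed"].any()


def test_truth_label_matches_tree_classification(small_genome, study_net):
    """Truth classes agree with the window-tree classifier applied to the
    true gene tree (restricted to the focal triplet + outgroup)."""
    trip = study_net.focal_triplet
    focal = {"F": {trip[0]}, "G": {trip[1]}, "S": {trip[2]}}
    for tree, cls in zip(small_genome.trees, small_genome.truth["genealogy_class"]):
        sub = induced_subtree(tree, set(trip) | {"O"})
        label = windowtrees.root_and_classify(sub, "O", focal)
        assert label == windowtrees.GENEALOGY_TO_TREE[cls]


def test_fixed_seed_reproduces_files(study_net, tmp_path):
    cfg = SimulationConfig(n_windows=6, window_len=300, theta=0.01, seed=5)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_genome(cfg, study_net).write(d1)
    simulate_genome(cfg, study_net).write(d2)
    for name in ["truth.bed", "genes.gff3", "genetrees.nwk"]:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
    for f in sorted((d1 / "windows").iterdir()):
        assert f.read_bytes() == (d2 / "windows" / f.name).read_bytes()


def test_suppress_ils_in_cds(study_net):
    genes = simnet.make_gene_models(3, 12000, cds_len=400, intron_len=100)
    cfg = SimulationConfig(n_windows=12, window_len=1000, theta=0.01, seed=3,
                           gene_models=genes, suppress_ils_in_cds=True)
    sim = simulate_genome(cfg, study_net)
    cds = [(s, e) for g in genes for s, e in g.cds]
    for _, r in sim.truth.iterrows():
        in_cds = any(s < r["end"] and r["start"] < e for s, e in cds)
        if in_cds:
            assert r["genealogy_class"] in ("type0", "type1")


# ---------------------------------------------------------------------------
# mixture branch-length generator


def test_branch_length_mixture_properties(rng):
    lam = 0.7
    x = sample_triplet_branch_lengths(20000, (0.0, lam, 2.0), rng)
    assert x.mean() == pytest.approx(lam, abs=3 * lam / math.sqrt(20000))
    y = sample_triplet_branch_lengths(5000, (1.0, lam, 5 * lam), rng)
    assert y.min() >= 5 * lam
    # C=0 is indistinguishable from a single exponential
    z = sample_triplet_branch_lengths(5000, (0.6, lam, 0.0), rng)
    ks = stats.kstest(z, "expon", args=(0, lam))
    assert ks.pvalue > 0.001
    for bad in [(-0.1, 1, 1), (0.5, 0, 1), (0.5, 1, -2)]:
        with pytest.raises(ValueError):
            sample_triplet_branch_lengths(10, bad, rng)


def test_mosaic_labels_partition(study_net, rng):
    net = SpeciesNetwork.triplet(0.5184, outgroup_time=3.0)
    aln, labels, tracts = simnet.simulate_mosaic(
        net, 4000, mean_tract=300, theta=0.01, rng=rng,
        taxa=("A", "B", "C", "O"))
    assert aln.length == 4000 and len(labels) == 4000
    assert tracts["end"].iloc[-1] == 4000
    # tract labels agree with the per-site expansion
    for _, r in tracts.iterrows():
        seg = labels[r["start"]:r["end"]]
        assert (seg == GENEALOGY_CLASSES.index(r["class"])).all()
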