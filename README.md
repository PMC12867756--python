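# ilsrad

Phylogenomic discordance among closely related lineages — different genomic
windows supporting different trees — can be produced by three processes:
**hybrid speciation**, **gene flow** (introgression), and **incomplete
lineage sorting** (ILS, the random sorting of ancestral polymorphism across
speciation events). Telling them apart matters: a species group with mixed
morphological traits may carry them because it is a hybrid, because it
exchanged genes with a neighbor, or simply because it retained ancestral
variants. `ilsrad` implements the window-based decision framework used in
primate comparative genomics (five ingroup genomes plus an outgroup) as a
tested Python package, together with a multispecies-coalescent (MSC)
simulator with known truth so every statistic can be validated end to end.

## What it computes

For a focal triplet (focal group *F*, congeners *G*, sister genus *S*) the
MSC predicts the rooted gene-tree topology frequencies from the internal
branch length *T* (in coalescent units of 2N generations):

    P(concordant) = 1 − (2/3) e^(−T),   P(each discordant) = e^(−T) / 3

Around this law the package provides, one module per analysis stage:

- **`simnet`** — MSC gene-tree simulator on a species network
  (divergence times, per-branch population sizes, introgression pulses, or
  a hybrid node with inheritance probability γ), JC69 sequence evolution,
  windowed genomes with truth BED/GFF3/Newick output, and site-level
  genealogy mosaics.
- **`windowtrees`** — per-window NJ+JC trees, bootstrap support, the
  Tree1/Tree2/Tree3 classification, and topology-frequency tests.
- **`coalestimate`** — exact quartet-agreement species tree (ASTRAL's
  estimand solved exactly at ≤8 taxa), the inversion `T = −ln(3 p_minor)`,
  the hybrid-speciation topology test, and ML estimation of γ from triplet
  frequencies (`TripletTopologyMixture.fit()`).
- **`admixstats`** — ABBA-BABA *D* with the weighted block jackknife
  (significance |Z| > 3), the five-taxon D_FOIL scan whose sign signature
  separates ancestral from recent introgression and identifies the donor /
  recipient pair, and a permutation test for contiguity of flagged windows.
- **`quiblmix`** — QuIBL-style test: internal branch lengths of a
  discordant topology are fitted as a single exponential (ILS-only) vs a
  two-component shifted-exponential mixture (ILS + introgression), decided
  by ΔBIC > 10 (`QuiblModel.fit()`).
- **`timeorder`** — divergence-ordering test: under ILS the discordant
  pair's divergence predates speciation (older), under gene flow it
  postdates it (younger); Mann-Whitney on clock-based JC divergences.
- **`ilshmm`** — CoalHMM-style 4-state genealogy HMM (type0/type1
  concordant, type2/type3 discordant = ILS) with exact pruning emissions,
  scaled forward-backward, Baum-Welch fitting, ILS segment calling and the
  segment statistics (mean length, genome fraction, coding fraction,
  Welch's t, X-vs-autosome aggregation) (`CoalescentHmm.fit()`).
- **`ilsgenes`** — ILS genes by the strict >30% CDS-coverage rule and the
  scan for amino-acid sites where the focal group + sister genus are fixed
  for one residue and all other congeners for a different one.

## Worked example

Simulate 500 one-kilobase windows for a triplet with the study-level
internal branch (T = 0.5184), build window trees, and run the discordance
analysis:

```python
import numpy as np
from ilsrad import simnet, windowtrees, coalestimate

net = simnet.SpeciesNetwork.triplet(0.5184, outgroup_time=3.0)
cfg = simnet.SimulationConfig(n_windows=500, window_len=1000,
                              theta=0.01, seed=7,
                              truth_triplet=("A", "B", "C"))
sim = simnet.simulate_genome(cfg, net)

focal = {"F": {"A"}, "G": {"B"}, "S": {"C"}}
records = windowtrees.analyze_windows(sim.windows, "O", focal, B=50, seed=1)
freq = windowtrees.topology_frequencies(records, min_support=0.25)
c = freq["counts"]
print(freq["proportions"])
print(coalestimate.hybrid_speciation_test((c["Tree1"], c["Tree2"], c["Tree3"])))
print(coalestimate.summarize_triplet((c["Tree1"], c["Tree2"], c["Tree3"])).T_hat)
```

prints (seed 7):

```
proportions: {'Tree1': 0.587, 'Tree2': 0.192, 'Tree3': 0.22}
Tree1 vs Tree2 p = 5.93e-29
hybrid test: rejected  p_equality = 2.77e-24
T_hat = 0.479 coalescent units
```

Read: the concordant topology dominates (58.7% vs the analytic 60.3%), the
two minor topologies are roughly equal — the ILS fingerprint; the
hybrid-speciation test rejects (a hybrid would cluster equally with both
parents); inverting the minor-topology frequency recovers the internal
branch length (0.48 vs the true 0.5184).

The same objects drive the rest of the pipeline: `admixstats.dstat_windows`
on the window alignments, `QuiblModel(lengths).fit().summary()` on internal
branch lengths, `CoalescentHmm(aln, params).fit().ils_segments()` on a
4-taxon alignment. A thin CLI mirrors the modules:

```bash
ilsrad simulate --n-windows 500 --seed 7 --out sim/
ilsrad trees --windows sim/windows --outgroup O --focal F --sister S \
             --congeners G1,G2,G3 --out records.tsv
ilsrad topofreq --records records.tsv --min-support 0.25
ilsrad hybridtest --counts 603,203,194
```

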