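# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices a maintainer would need to know. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Coalescent model and units

Time is measured backwards from the tips in coalescent units of 2N
generations of the root population. Within a species-tree branch carrying
k gene lineages, coalescences occur at rate k(k−1)/2 divided by the
branch's relative population size (default 1 everywhere). With these units
the rooted-triplet topology law is exact: for an internal branch of length
T, each discordant topology has probability e^(−T)/3. The default networks
use T = 0.5184 because 1 − (2/3)e^(−T) = 0.603 — the major-topology
proportion observed at study scale — so the simulated study conditions and
the analytic law meet at the same point.

Introgression events are instantaneous pulses: backwards in time, each
lineage in the recipient branch jumps to the donor branch with probability
γ (forward in time: the donor contributed a fraction γ of the recipient's
genome). A hybrid node is the special case where a leaf's entire lineage
chooses parent 1 with probability γ at a single hybridization time.

Sequences evolve under JC69; a branch of Δt coalescent units carries
Δt·θ/2 expected substitutions/site, with θ the population-scaled mutation
rate per site (default 0.01 for the window analyses, a deliberately
information-rich setting; see the D_FOIL exception below). Windows are
unlinked (free recombination between windows, none within); the HMM input
is instead a site-level mosaic whose genealogy tracts have geometric
lengths.

Two mathematically equivalent sequence simulators exist: the literal
per-site JC walk along the tree, and a collapsed form that computes the
site-pattern distribution of a gene tree by Felsenstein pruning and draws
one multinomial per window (sites are iid given the genealogy). The heavy
calibration runs use the collapsed form; their equivalence is itself a
test.

Determinism: one master seed; per-window substreams come from
`numpy.random.SeedSequence.spawn`, so outputs are byte-identical across
runs and windows are independent of evaluation order.

## Window trees and topology frequencies

Per-window trees are neighbor joining on JC distances (pairwise deletion
of gapped columns), with a site-resampling bootstrap (default B=100,
gap-containing columns wholly excluded). NJ tie-breaks join the
lexicographically smallest label pair; negative branch estimates clamp to
zero and are flagged. The "clade probability < 25%" filter is
operationalized as bootstrap support of the assigned topology < 0.25.
Multi-species focal clades must be monophyletic to classify; otherwise the
window is `unresolved` and excluded from proportions (counted separately).
The two-proportion test between topology counts of the same window sample
uses the multinomial variance Var(p̂1−p̂2) = [p1+p2−(p1−p2)²]/n.

A measured limitation: with θ=0.01 and 1 kb windows, NJ classification
accuracy against simulated truth is ≈89% at T≈0.52 (deep-coalescent gene
trees leave too few informative sites on the short internal branch) and
≥92% from T≈1. The test suite checks the ≥90% accuracy property at T=1.

## Species tree, hybrid test, γ

The species-tree estimator maximizes total quartet agreement exactly by
enumerating all unrooted topologies (feasible to 8 taxa; (2n−5)!!
candidates), reporting ties. This is the ASTRAL estimand without heuristic
search. The triplet pseudolikelihood reduction replaces MP-EST: the
internal branch is inverted from the average minor-topology frequency,
T = −ln(3·p_minor); p_minor = 0 flags infinity, p_minor > 1/3 flags the
anomaly zone and returns T = 0.

The hybrid-speciation test is conjunctive: hybrids predict (a) equal
clustering with both parents (exact conditional binomial on the two
parental counts — the correct two-category test of one multinomial) and
(b) each parental proportion exceeding the non-parental one (one-sided),
both at α = 0.05 with no multiplicity correction (the decision requires
both).

γ is estimated by multinomial ML on the mixture
P(topo) = γ·P_MSC(topo | parent-1 tree, T) + (1−γ)·P_MSC(topo | parent-2
tree, T) with a **shared** internal branch T. With free (T1, T2) the model
maps three parameters onto a two-dimensional simplex and is not
identifiable; a single hybridization time implies T1 = T2 exactly, so the
constraint is the biology, not a shortcut. The MLE has a closed form away
from the boundary (a = 3·p̂3, γ = (p̂1 − a/3)/(1 − a)) and is polished by
L-BFGS-B; the 95% CI is a profile likelihood over a 401-point γ grid.
Near T = 0 the mixture degenerates (all topologies equiprobable under both
parents) and the result is flagged non-identifiable.

## D statistic and D_FOIL

Sites are polarized by the outgroup allele; only biallelic fully resolved
columns count. The jackknife is the weighted delete-one form for unequal
block sizes (Busing-style), blocks defaulting to 50 site-balanced groups
of windows; significance is |Z| > 3. Under ILS-only simulation at the
default conditions (θ=0.01, 4000 × 1 kb windows) the false-positive rate
measured over 200 replicate genomes is ≤1%; a γ=0.1 pulse at 0.1
coalescent units before the first speciation gives Z ≈ 5–7.

D_FOIL uses the symmetric five-taxon tree (((P1,P2),(P3,P4)),O) with the
(P1,P2) split strictly younger. The four components are the standard
contrasts of the 16 derived/ancestral pattern classes; each component is
tested per window by χ² = (L−R)²/(L+R) at α = 0.01 (unspecified in the
source study; chosen conservative) and its sign set to 0 when
non-significant. The signature → scenario lookup table shipped in
`admixstats.DFOIL_SIGNATURES` was derived from this package's own MSC
simulator (modal significant signature per scenario at high signal) and is
re-derived by a shipped test for all eight directional recent scenarios
and both ancestral ones; the rows respect the exact symmetries (P1↔P2
swaps DFO↔DIL and negates DFI/DOL; P3↔P4 negates DFO/DIL and swaps
DFI↔DOL). Introgression *into* the (P1,P2) ancestor (rather than out of
it) produces only a weak, near-noise signature and is not a table row.

The D_FOIL study conditions were calibrated once, before the tests were
frozen: θ = 0.001/site with 250 bp genealogy tracts inside 100 kb windows.
The per-component χ² assumes independent sites; genealogy sharing within a
window overdisperses the counts, and at θ=0.01 with 1 kb tracts the
ILS-only "none" rate collapses to ~45%. At the chosen defaults the
measured none rate is ~97%. This is a property of the χ² design (kept as
specified), not of the implementation.

Contiguity of flagged windows is a permutation test on the number of
adjacent flagged pairs (uniform random placement as the null); recent
introgression predicts contiguous runs, ILS discrete windows.

## Branch-length mixture (QuIBL-style)

For gene trees of one triplet topology, the internal branch is Exp(mean λ)
under ILS-only and C + Exp(λ) for introgressed trees; the mixture shares λ
across components. Fitting: EM over (p, λ) at fixed shift C — both updates
closed-form — with C profiled on a 200-point grid over [0, max t) (the
grid EM is vectorized across all grid points) and refined by bounded
scalar minimization; convergence |Δlogℓ| < 1e−8 or 500 iterations,
non-convergence flagged with the best fit. BIC uses k=1 vs k=3; the
decision is three-valued with a symmetric threshold: ΔBIC = BIC_single −
BIC_mixture > 10 ⇒ ILS+introgression, < −10 ⇒ ILS-only, else
inconclusive (the source rule names only the threshold, not the
indeterminate zone).

## Divergence ordering

Per window, a pair's divergence is the JC distance halved (a relative
molecular clock; no absolute calibration, since only the ordering carries
the inference). The discordant sample is the discordant cherry pair's
divergence (e.g. F–S in Tree2 windows); the reference sample is the
**species-tree cherry pair** (F–G in Tree1 windows), a per-window proxy
for the youngest speciation involving the focal taxon. Under ILS the
discordant clade coalesces in the ancestral population — older than every
speciation, hence older than the reference; under recent gene flow it
coalesces after even the youngest speciation — younger. The naive
alternative (same pair, both window classes) is directionally degenerate
under the MSC: conditional on discordance, the first-of-three coalescence
(mean 1/3) is *younger* than the two-lineage root coalescence in
concordant windows (mean 1), so ILS would masquerade as introgression.
Direction is decided by one-sided Mann-Whitney tests at α = 0.05, rank-
based and hence invariant to monotone rescaling.

## Genealogy HMM

States are the four genealogy scenarios of (A,B,C)+O; ILS = type2 ∪ type3
(topology-discordant); type1 (deep but concordant) is reported separately.
Each state emits site patterns from one representative genealogy with
point coalescent times — mid-branch for type0, ancestral means (first of
three = θ_anc/3, plus θ_anc for the second) for type1–3 — rather than
time-integrated emissions; emissions are exact pruning probabilities over
the 256 patterns. The transition matrix is A = (1−s)I + s·1πᵀ: a single
switch rate mixing straight to the stationary distribution π (with
π_type2 = π_type3 enforced, the two discordant genealogies being
exchangeable). This is a documented simplification of full CoalHMM — no
genealogy-adjacency constraints, no estimation of ancestral Ne or
speciation times in years.

Forward-backward runs scaled; gapped columns emit 1 under every state.
Baum-Welch updates (s, π) with a numeric M-step under the constrained
transition structure (a generalized EM: the observed likelihood is
non-decreasing each iteration, asserted in tests); emissions can be
profiled over a coarse grid of parameter templates. Convergence
|Δlogℓ| < 1e−6 or 200 iterations; constant alignments are flagged
degenerate. ILS sites are called where P(type2)+P(type3) > 0.5 (threshold
and merge gap are configuration, the source thresholds being unstated);
segments are maximal called runs with runs separated by ≤ max_gap fused.
Segment statistics: mean/median length, genome fraction, fraction of CDS
bases covered, Welch's t between ILS and non-ILS length samples (identical
samples defined to give p=1); chromosome aggregation reports ILS bp/Mb per
chromosome, the X / median-autosome ratio, and a one-sample t test of the
autosome densities against the X value.

## ILS genes

CDS coverage is strand-agnostic interval arithmetic in genome coordinates,
additive over segments; the filter is strictly greater than 0.30 of CDS
length (a gene at exactly 30% is dropped). The shared-residue scan flags
gap-free columns where every taxon of the focal+sister group carries one
residue and every other taxon a single different residue (fixity in both
groups; a relaxed majority rule is deliberately not the default).

## What the simulator does not emulate

No intra-window recombination (except the HMM mosaics), no indels or
alignment error, no substitution-model misspecification (JC69 both sides),
no selection (the purifying-selection switch merely resamples concordant
genealogies inside CDS), no diploid genotypes. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to alignment artefacts or model violation in real
genomes.

## Problem sizes used by the test suite

Chosen as the package's own validation scale: 50,000 triplet gene trees
for the MSC-consistency check; 200 ILS-only + 100 pulse genomes of 4000 ×
1 kb windows for D calibration; 200 × 100 kb windows (null) and 10 × 5 ×
2 Mb windows (scenario table) for D_FOIL; 200 + 200 replicates of n=1000
branch lengths for QuIBL calibration/detection and n=5000 for recovery;
200 + 200 ordering replicates of 2000 windows; 50–120 kb mosaics for HMM
decoding; 20,000 triplets for γ recovery.
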