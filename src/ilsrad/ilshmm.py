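"""Genealogy hidden Markov model along a 4-taxon alignment (CoalHMM-style).

Hidden states are the four local genealogy scenarios for taxa (A,B,C)+O
with species relation ((A,B),C):

* type0 — concordant topology, A/B coalesce in their own ancestral branch;
* type1 — concordant topology, deep coalescence (still no discordance);
* type2 — discordant, A with C;
* type3 — discordant, B with C.

ILS sites are those decoded as type2 or type3 (topology-discordant); type1
is deep but concordant and reported separately.  Each state emits site
patterns from a fixed representative genealogy (point coalescent times:
mid-branch for type0, ancestral means for type1-3) under JC69; the
transition matrix has the single-switch-rate form
A = (1-s) I + s 1 pi^T, so pi is its stationary distribution and s mixes
the chain toward it — recombination fragmenting genealogy tracts.

Times are in expected substitutions/site throughout this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from ._trees import Node
from .alignment import WindowAlignment
from .patterns import pattern_index, pattern_to_codes, site_pattern_probs

STATES = ("type0", "type1", "type2", "type3")


# ---------------------------------------------------------------------------
# parameters and emissions


def _tree4(pairing, t1, t2, t3, names):
    """Rooted 4-leaf caterpillar ((x,y),z),o with coalescences at t1<t2<t3."""
    a, b, c, o = names
    first = {"ab": (a, b, c), "ac": (a, c, b), "bc": (b, c, a)}[pairing]
    x, y, z = first
    n_xy = Node(children=[Node(name=x, time=0.0), Node(name=y, time=0.0)],
                time=t1)
    n_xyz = Node(children=[n_xy, Node(name=z, time=0.0)], time=t2)
    return Node(children=[n_xyz, Node(name=o, time=0.0)], time=t3)


def state_genealogy(state, tau1, tau2, tau3, theta_anc, taxa=("A", "B", "C", "O")):
    """Representative genealogy for one HMM state.

    tau1/tau2/tau3 are the speciation times (subs/site) of the (A,B),
    (A,B,C) and root splits; theta_anc scales the ancestral coalescent
    waiting added on top (mean 2-lineage waiting = theta_anc, first-of-three
    = theta_anc/3).
    """
    t_root = tau3 + theta_anc
    if state == "type0":
        return _tree4("ab", (tau1 + tau2) / 2.0, tau2 + theta_anc, t_root, taxa)
    t_first = tau2 + theta_anc / 3.0
    t_second = t_first + theta_anc
    t_root = max(t_root, t_second + theta_anc / 10.0)
    pairing = {"type1": "ab", "type2": "ac", "type3": "bc"}[state]
    return _tree4(pairing, t_first, t_second, t_root, taxa)


def emission_probs(tree, taxa):
    """Emission vector over the 256 site patterns for one state genealogy.

    Node times are substitutions/site, so pruning runs with theta=2 (branch
    = dt * theta/2).  Sums to 1; validated against brute-force enumeration
    over internal-node states in the test suite.
    """
    probs = site_pattern_probs(tree, taxa, theta=2.0)
    return probs / probs.sum()


@dataclass
class HmmParams:
    """Parameters of the 4-state genealogy HMM.

    ``pi`` is the stationary distribution (type2/type3 symmetrized — the
    two discordant genealogies are exchangeable under the MSC) and ``s``
    the per-site switch probability.
    """

    taxa: tuple
    pi: np.ndarray
    s: float
    emissions: np.ndarray              # (4, 256)
    trees: list = field(default_factory=list, repr=False)
    tau: tuple | None = None
    theta_anc: float | None = None

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or (pi < 0).any():
            raise ValueError("pi must be 4 non-negative weights")
        pi = pi / pi.sum()
        sym = 0.5 * (pi[2] + pi[3])
        pi[2] = pi[3] = sym
        self.pi = pi
        if not 0.0 < self.s < 1.0:
            raise ValueError("switch rate s must be in (0, 1)")
        self.emissions = np.asarray(self.emissions, dtype=float)
        if self.emissions.shape != (4, 256):
            raise ValueError("emissions must be (4, 256)")

    @classmethod
    def from_divergence(cls, tau1, tau2, tau3, theta_anc,
                        pi=(0.55, 0.15, 0.15, 0.15), s=1e-3,
                        taxa=("A", "B", "C", "O")):
        if not 0 < tau1 < tau2 < tau3:
            raise ValueError("need 0 < tau1 < tau2 < tau3")
        trees = [state_genealogy(st, tau1, tau2, tau3, theta_anc, taxa)
                 for st in STATES]
        emis = np.vstack([emission_probs(t, taxa) for t in trees])
        return cls(tuple(taxa), np.asarray(pi, float), float(s), emis,
                   trees=trees, tau=(tau1, tau2, tau3), theta_anc=theta_anc)

    def transition_matrix(self):
        return (1.0 - self.s) * np.eye(4) + self.s * np.outer(
            np.ones(4), self.pi)

    def simulate(self, n_sites, rng):
        """Simulate (coded alignment, true states) from the HMM itself."""
        resets = rng.random(n_sites) < self.s
        resets[0] = True
        seg_ids = np.cumsum(resets) - 1
        seg_states = rng.choice(4, size=seg_ids[-1] + 1, p=self.pi)
        states = seg_states[seg_ids]
        idx = np.empty(n_sites, dtype=np.int64)
        for k in range(4):
            m = states == k
            idx[m] = rng.choice(256, size=int(m.sum()), p=self.emissions[k])
        return pattern_to_codes(idx, 4), states


def _observed_index(aln):
    if isinstance(aln, WindowAlignment):
        data = aln.data
    else:
        data = np.asarray(aln)
    if data.shape[0] != 4:
        raise ValueError("need a 4-row alignment (A, B, C, outgroup)")
    return pattern_index(data)


def _site_emissions(params, obs_idx):
    E = np.ones((len(obs_idx), 4))
    ok = obs_idx >= 0
    E[ok] = params.emissions[:, obs_idx[ok]].T
    return E


# ---------------------------------------------------------------------------
# forward-backward


def forward_backward(aln, params):
    """Scaled forward-backward pass.

    Returns (posteriors (L,4), loglik).  Gapped columns emit 1 under every
    state (state-uninformative).  Row sums of the posterior matrix are 1.
    """
    obs = _observed_index(aln)
    E = _site_emissions(params, obs)
    post, ll, *_ = _forward_backward_E(E, params.pi, params.s)
    return post, ll


def _forward_backward_E(E, pi, s):
    L = E.shape[0]
    if L == 0:
        raise ValueError("empty alignment")
    alpha = np.empty((L, 4))
    c = np.empty(L)
    a = pi * E[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    one_m_s = 1.0 - s
    for t in range(1, L):
        a = E[t] * (one_m_s * alpha[t - 1] + s * pi)
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((L, 4))
    beta[-1] = 1.0
    for t in range(L - 2, -1, -1):
        eb = E[t + 1] * beta[t + 1]
        beta[t] = (one_m_s * eb + s * (pi @ eb)) / c[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    ll = float(np.log(c).sum())
    return post, ll, alpha, beta, c


# ---------------------------------------------------------------------------
# EM fitting


def _mstep(xi, gamma0, s0, pi0):
    """Maximize the expected complete-data log-likelihood over (s, pi).

    pi is constrained to the symmetric form (p0, p1, pI/2, pI/2).
    """

    def unpack(x):
        s = 1.0 / (1.0 + math.exp(-x[0]))
        w = np.exp(x[1:] - np.max(x[1:]))
        w = w / w.sum()
        pi = np.array([w[0], w[1], w[2] / 2.0, w[2] / 2.0])
        return s, pi

    def negq(x):
        s, pi = unpack(x)
        A = (1.0 - s) * np.eye(4) + s * np.outer(np.ones(4), pi)
        return -(np.sum(xi * np.log(np.maximum(A, 1e-300)))
                 + np.sum(gamma0 * np.log(np.maximum(pi, 1e-300))))

    x0 = np.array([math.log(s0 / (1.0 - s0)),
                   math.log(max(pi0[0], 1e-9)),
                   math.log(max(pi0[1], 1e-9)),
                   math.log(max(pi0[2] + pi0[3], 1e-9))])
    res = optimize.minimize(negq, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-10,
                                     "maxiter": 2000})
    if res.fun > negq(x0):          # generalized EM: never move downhill
        return s0, np.asarray(pi0, float)
    return unpack(res.x)


@dataclass
class HmmResults:
    """Fitted genealogy HMM with per-site posteriors."""

    params: HmmParams
    posteriors: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    loglik_path: list = field(default_factory=list, repr=False)
    degenerate: bool = False

    def ils_posterior(self):
        return self.posteriors[:, 2] + self.posteriors[:, 3]

    def call_ils_sites(self, threshold=0.5):
        return call_ils_sites(self.posteriors, threshold)

    def ils_segments(self, threshold=0.5, max_gap=0, chrom=None, offset=0):
        calls = self.call_ils_sites(threshold)
        return merge_segments(calls, max_gap=max_gap, chrom=chrom,
                              offset=offset, posterior=self.ils_posterior())

    def summary(self):
        p = self.params
        lines = [
            "Genealogy HMM (4 states)",
            "=" * 46,
            f"sites                 {len(self.posteriors)}",
            f"log-likelihood        {self.loglik:.3f}",
            f"switch rate s         {p.s:.3g}",
            "stationary pi         "
            + "  ".join(f"{st}={w:.3f}" for st, w in zip(STATES, p.pi)),
            f"EM iterations         {self.n_iter}"
            + ("" if self.converged else "  (NOT converged)"),
            f"mean P(ILS)           {self.ils_posterior().mean():.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, start=0, end=None):
        """Posterior ILS probability along the sequence."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        y = self.ils_posterior()[start:end]
        ax.plot(np.arange(start, start + len(y)), y, lw=0.5)
        ax.axhline(0.5, color="grey", ls=":")
        ax.set_ylabel("P(type2 or type3)")
        ax.set_xlabel("site")
        return ax


def fit_hmm_em(aln, params, max_iter=200, tol=1e-6, update=("s", "pi")):
    """Baum-Welch for (s, pi) with emissions fixed per state genealogy.

    The M-step is numeric under the single-switch-rate transition structure
    (generalized EM: the observed log-likelihood is non-decreasing every
    iteration).  A constant alignment is degenerate: flagged and returned
    unfitted.
    """
    obs = _observed_index(aln)
    if len(obs) < 2:
        raise ValueError("alignment too short")
    resolved = obs[obs >= 0]
    if len(np.unique(resolved)) <= 1:
        post = np.tile(params.pi, (len(obs), 1))
        return HmmResults(params, post, -np.inf, False, 0, degenerate=True)

    E = _site_emissions(params, obs)
    pi, s = params.pi.copy(), params.s
    path = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post, ll, alpha, beta, c = _forward_backward_E(E, pi, s)
        path.append(ll)
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        eb = E[1:] * beta[1:] / c[1:, None]
        M = alpha[:-1].T @ eb
        A = (1.0 - s) * np.eye(4) + s * np.outer(np.ones(4), pi)
        xi = A * M
        s_new, pi_new = _mstep(xi, post[0], s, pi)
        if "s" in update:
            s = float(np.clip(s_new, 1e-8, 1 - 1e-8))
        if "pi" in update:
            pi = pi_new
    fitted = replace(params, pi=pi, s=s)
    post, ll, *_ = _forward_backward_E(E, pi, s)
    return HmmResults(fitted, post, ll, converged, it, loglik_path=path)


class CoalescentHmm:
    """Model object: a 4-taxon alignment plus initial HMM parameters.

    ``fit`` runs Baum-Welch; ``profile`` optionally supplies alternative
    parameter templates (e.g. a coarse grid over genealogy branch lengths),
    each fitted and the best likelihood kept.
    """

    def __init__(self, aln, params):
        self.aln = aln
        self.params = params

    def loglik(self):
        return forward_backward(self.aln, self.params)[1]

    def decode(self):
        post, ll = forward_backward(self.aln, self.params)
        return HmmResults(self.params, post, ll, True, 0)

    def fit(self, profile=None, **kw):
        templates = [self.params] + list(profile or [])
        best = None
        for tpl in templates:
            res = fit_hmm_em(self.aln, tpl, **kw)
            if best is None or res.loglik > best.loglik:
                best = res
        return best


# ---------------------------------------------------------------------------
# site calls, segments, statistics


def call_ils_sites(posteriors, threshold=0.5):
    """Site is ILS iff posterior(type2) + posterior(type3) > threshold."""
    post = np.asarray(posteriors)
    return (post[:, 2] + post[:, 3]) > threshold


@dataclass
class IlsSegment:
    chrom: str | None
    start: int
    end: int
    mean_posterior: float
    state: str = "ils"

    @property
    def length(self):
        return self.end - self.start


def merge_segments(calls, max_gap=0, chrom=None, offset=0, posterior=None):
    """Maximal runs of called sites; runs separated by <= max_gap uncalled
    sites are fused.  Coordinates are 0-based half-open (plus ``offset``)."""
    calls = np.asarray(calls, dtype=bool)
    idx = np.flatnonzero(calls)
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    segs = []
    for s, e in zip(starts, ends):
        mp = float(np.mean(posterior[s:e])) if posterior is not None \
            else float("nan")
        segs.append(IlsSegment(chrom, int(s) + offset, int(e) + offset, mp))
    return segs


def _overlap_total(segments, intervals):
    total = 0
    for seg in segments:
        for (s, e) in intervals:
            total += max(0, min(seg.end, e) - max(seg.start, s))
    return total


def segment_stats(segments, non_ils_segments, genome_len, cds_intervals=()):
    """Length/coverage report for ILS vs non-ILS segments.

    genome fraction = total ILS bp / genome length; coding fraction = ILS bp
    inside CDS / total CDS bp.  Welch's t test compares the two length
    samples (identical samples give p = 1).
    """
    if genome_len <= 0:
        raise ValueError("genome length must be positive")
    ils_len = np.array([s.length for s in segments], dtype=float)
    non_len = np.array([s.length for s in non_ils_segments], dtype=float)
    report = {
        "n_segments": len(segments),
        "mean_length": float(ils_len.mean()) if len(ils_len) else 0.0,
        "median_length": float(np.median(ils_len)) if len(ils_len) else 0.0,
        "genome_fraction": float(ils_len.sum()) / genome_len,
    }
    cds_total = sum(e - s for (s, e) in cds_intervals)
    report["coding_fraction"] = (
        _overlap_total(segments, cds_intervals) / cds_total
        if cds_total else None)
    if len(ils_len) >= 2 and len(non_len) >= 2:
        if np.ptp(ils_len) == 0 and np.ptp(non_len) == 0:
            t, p = (0.0, 1.0) if ils_len.mean() == non_len.mean() \
                else (math.inf, 0.0)
        else:
            t, p = stats.ttest_ind(ils_len, non_len, equal_var=False)
        report["welch_t"] = float(t)
        report["welch_p"] = float(p)
    else:
        report["welch_t"] = report["welch_p"] = None
    return report


def chrom_aggregation(segments_by_chrom, chrom_lengths, chrom_class):
    """Per-chromosome ILS density and the X-vs-autosome contrast.

    density = ILS bp per Mb.  ratio = density(X) / median(autosome
    densities); the X value is tested against the autosome distribution with
    a one-sample t test.
    """
    xs = [c for c, k in chrom_class.items() if k == "X"]
    autos = [c for c, k in chrom_class.items() if k == "autosome"]
    if not xs or not autos:
        raise ValueError("need at least one autosome and the X")
    dens = {}
    for c, L in chrom_lengths.items():
        bp = sum(s.length for s in segments_by_chrom.get(c, []))
        dens[c] = bp / (L / 1e6)
    x_dens = float(np.mean([dens[c] for c in xs]))
    a_dens = np.array([dens[c] for c in autos])
    med = float(np.median(a_dens))
    out = {"density": dens, "x_density": x_dens,
           "autosome_median": med,
           "ratio": x_dens / med if med > 0 else math.inf}
    if np.ptp(a_dens) == 0 or len(a_dens) < 2:
        out["p"] = None
        out["flag"] = "test undefined (degenerate autosome densities)"
    else:
        t, p = stats.ttest_1samp(a_dens, x_dens)
        out["p"] = float(p)
        out["flag"] = None
    if all(v == 0 for v in dens.values()):
        out["flag"] = "no segments"
    return out
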