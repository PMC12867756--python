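"""Introgression statistics: ABBA-BABA D with weighted block jackknife,
the five-taxon D_FOIL scan, and the flagged-window contiguity test.

Site patterns are polarized by the outgroup allele (ancestral = A, derived
= B); only biallelic, fully resolved columns are counted.  For the
symmetric five-taxon tree (((P1,P2),(P3,P4)),O) — with the (P1,P2) split
strictly more recent than (P3,P4) — the four D_FOIL components are linear
contrasts of the 16 derived/ancestral patterns whose joint sign signature
separates ancestral from recent introgression and identifies the recent
donor/recipient pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import WindowAlignment
from .patterns import biallelic_derived_masks, pattern_index

# ---------------------------------------------------------------------------
# four-taxon ABBA-BABA

_VALID4, _BIN4 = biallelic_derived_masks(3)   # (P1,P2,P3)+O
_VALID5, _BIN5 = biallelic_derived_masks(4)   # (P1,P2,P3,P4)+O

_ABBA = 0b011  # P2,P3 derived
_BABA = 0b101  # P1,P3 derived


def count_patterns_4taxon(aln, order=None):
    """(ABBA, BABA) counts for a 4-row alignment in (P1, P2, P3, O) order.

    Columns with gaps/ambiguity, more than two alleles, or an outgroup
    allele private to the outgroup pattern class are excluded.
    """
    if isinstance(aln, WindowAlignment):
        if order is not None:
            aln = aln.subset(order)
        data = aln.data
    else:
        data = np.asarray(aln)
    if data.shape[0] != 4:
        raise ValueError("need exactly 4 rows (P1, P2, P3, outgroup)")
    idx = pattern_index(data)
    ok = idx >= 0
    sub = idx[ok]
    valid = _VALID4[sub]
    binary = _BIN4[sub][valid]
    return int((binary == _ABBA).sum()), int((binary == _BABA).sum())


def abba_baba_from_patterns(vec256):
    """(ABBA, BABA) from a 4**4 site-pattern count/probability vector."""
    vec256 = np.asarray(vec256)
    abba = vec256[_VALID4 & (_BIN4 == _ABBA)].sum()
    baba = vec256[_VALID4 & (_BIN4 == _BABA)].sum()
    return abba, baba


def d_stat(abba, baba):
    """D = (ABBA - BABA) / (ABBA + BABA)."""
    tot = abba + baba
    if tot == 0:
        raise ValueError("D undefined: no informative sites")
    return (abba - baba) / tot


@dataclass
class DstatResult:
    D: float
    SE: float
    Z: float
    significant: bool
    n_blocks: int
    abba: int
    baba: int

    def summary(self):
        return (f"D = {self.D:.4f}  SE = {self.SE:.4g}  Z = {self.Z:.2f}  "
                f"({'significant' if self.significant else 'not significant'}"
                f" at |Z| > 3; {self.n_blocks} blocks)")


def weighted_block_jackknife(abba_blocks, baba_blocks, weights=None,
                             z_crit=3.0):
    """Delete-one weighted block jackknife for the D statistic.

    Block weights default to the block's informative-site count.  The
    variance follows the weighted delete-one jackknife for unequal block
    sizes (Busing et al. 1999).  Significance uses the |Z| > ``z_crit``
    rule.  Blocks with no informative sites are dropped; at least two
    informative blocks are required.
    """
    abba = np.asarray(abba_blocks, dtype=float)
    baba = np.asarray(baba_blocks, dtype=float)
    if weights is None:
        weights = abba + baba
    w = np.asarray(weights, dtype=float)
    keep = w > 0
    abba, baba, w = abba[keep], baba[keep], w[keep]
    g = len(w)
    if g < 2:
        raise ValueError("need at least two blocks with informative sites")

    A, B = abba.sum(), baba.sum()
    D = d_stat(A, B)
    n = w.sum()
    loo = (A - abba - (B - baba)) / (A - abba + B - baba)
    h = n / w
    theta_J = g * D - ((1.0 - w / n) * loo).sum()
    tau = h * D - (h - 1.0) * loo
    var = ((tau - theta_J) ** 2 / (h - 1.0)).sum() / g
    se = math.sqrt(max(var, 0.0))
    if se <= 1e-12 * max(1.0, abs(D)):  # numerically constant blocks
        se = 0.0
    if se == 0.0:
        return DstatResult(D, 0.0, math.inf if D != 0 else 0.0,
                           D != 0, g, int(A), int(B))
    z = D / se
    return DstatResult(D, se, z, abs(z) > z_crit, g, int(A), int(B))


def dstat_windows(alignments, order, n_blocks=50):
    """Genome-wide D from window alignments: count patterns per window,
    pool windows into ``n_blocks`` site-balanced blocks, jackknife."""
    counts = np.array([count_patterns_4taxon(a, order) for a in alignments])
    if len(counts) == 0:
        raise ValueError("no windows")
    edges = np.linspace(0, len(counts), min(n_blocks, len(counts)) + 1,
                        dtype=int)
    abba = np.add.reduceat(counts[:, 0], edges[:-1])
    baba = np.add.reduceat(counts[:, 1], edges[:-1])
    return weighted_block_jackknife(abba, baba)


# ---------------------------------------------------------------------------
# D_FOIL

#: pattern-class indices, bit order P1..P4 (MSB = P1), derived = 1
DFOIL_COMPONENTS = {
    "DFO": ((0b1010, 0b1110, 0b0101, 0b0001),
            (0b1001, 0b1101, 0b0110, 0b0010)),
    "DIL": ((0b0110, 0b1110, 0b1001, 0b0001),
            (0b0101, 0b1101, 0b1010, 0b0010)),
    "DFI": ((0b1010, 0b1011, 0b0101, 0b0100),
            (0b0110, 0b0111, 0b1001, 0b1000)),
    "DOL": ((0b1001, 0b1011, 0b0110, 0b0100),
            (0b0101, 0b0111, 0b1010, 0b1000)),
}

#: sign signature (DFO, DIL, DFI, DOL) -> classification.  The recent rows
#: are directional: e.g. '31' means P3 was the donor and P1 the recipient.
#: Ancestral rows involve the P1P2 ancestor (direction not identifiable).
#: Re-derived from MSC simulations of each scenario in the test suite.
DFOIL_SIGNATURES = {
    (0, 0, 0, 0): "none",
    (1, 1, 0, 0): "ancestral(P12<->P3)",
    (-1, -1, 0, 0): "ancestral(P12<->P4)",
    (1, 0, 1, 1): "recent(P3->P1)",
    (1, 1, 1, 0): "recent(P1->P3)",
    (0, 1, -1, -1): "recent(P3->P2)",
    (1, 1, -1, 0): "recent(P2->P3)",
    (-1, 0, 1, 1): "recent(P4->P1)",
    (-1, -1, 0, 1): "recent(P1->P4)",
    (0, -1, -1, -1): "recent(P4->P2)",
    (-1, -1, 0, -1): "recent(P2->P4)",
}


def binary_pattern_counts(aln, order=None):
    """16 derived/ancestral pattern counts for a 5-row (P1..P4, O) alignment."""
    if isinstance(aln, WindowAlignment):
        if order is not None:
            aln = aln.subset(order)
        data = aln.data
    else:
        data = np.asarray(aln)
    if data.shape[0] != 5:
        raise ValueError("need exactly 5 rows (P1..P4, outgroup)")
    idx = pattern_index(data)
    sub = idx[idx >= 0]
    valid = _VALID5[sub]
    binary = _BIN5[sub][valid]
    return np.bincount(binary, minlength=16)


def binary_counts_from_patterns(vec1024):
    """Collapse a 4**5 pattern-count vector to the 16 binary classes."""
    vec1024 = np.asarray(vec1024)
    out = np.zeros(16, dtype=vec1024.dtype)
    np.add.at(out, _BIN5[_VALID5], vec1024[_VALID5])
    return out


def dfoil_components(counts16, alpha=0.01):
    """The four D_FOIL statistics with chi-square significance and signs.

    Each component compares its left and right pattern sums; the sign is 0
    when the chi-square test (df=1) is not significant at ``alpha``.
    """
    counts16 = np.asarray(counts16, dtype=float)
    out = {}
    signs = []
    for name, (left, right) in DFOIL_COMPONENTS.items():
        L = counts16[list(left)].sum()
        R = counts16[list(right)].sum()
        tot = L + R
        d = (L - R) / tot if tot > 0 else 0.0
        chi2 = (L - R) ** 2 / tot if tot > 0 else 0.0
        p = stats.chi2.sf(chi2, 1) if tot > 0 else 1.0
        sign = 0 if p >= alpha else (1 if d > 0 else -1)
        out[name] = {"D": d, "left": L, "right": R, "chi2": chi2, "p": p,
                     "sign": sign}
        signs.append(sign)
    out["signature"] = tuple(signs)
    out["classification"] = classify_signature(tuple(signs))
    return out


def classify_signature(signature):
    """Map a (DFO, DIL, DFI, DOL) sign signature to its scenario."""
    return DFOIL_SIGNATURES.get(tuple(signature), "other")


def dfoil_scan(window_counts, alpha=0.01, window_ids=None):
    """Per-window D_FOIL classification plus genome-wide proportions.

    ``window_counts``: iterable of 16-long binary pattern count vectors
    (see :func:`binary_pattern_counts`).  Returns (DataFrame, summary dict
    with the none/ancestral/recent/other proportions).
    """
    rows = []
    for i, c16 in enumerate(window_counts):
        comp = dfoil_components(c16, alpha=alpha)
        wid = window_ids[i] if window_ids is not None else f"win_{i:06d}"
        rows.append({
            "window_id": wid,
            **{k: comp[k]["D"] for k in DFOIL_COMPONENTS},
            **{f"{k}_p": comp[k]["p"] for k in DFOIL_COMPONENTS},
            "signature": "".join({1: "+", 0: "0", -1: "-"}[s]
                                 for s in comp["signature"]),
            "classification": comp["classification"],
        })
    df = pd.DataFrame(rows)
    if len(df) == 0:
        raise ValueError("no windows")
    cls = df["classification"]
    n = len(df)
    summary = {
        "n_windows": n,
        "prop_none": float((cls == "none").mean()),
        "prop_ancestral": float(cls.str.startswith("ancestral").mean()),
        "prop_recent": float(cls.str.startswith("recent").mean()),
        "prop_other": float((cls == "other").mean()),
    }
    return df, summary


def dfoil_scan_alignments(alignments, order, alpha=0.01, network=None):
    """D_FOIL scan from 5-taxon window alignments.

    If a species network is supplied, the taxon-depth precondition is
    checked: the (P1,P2) split must be more recent than (P3,P4).
    """
    if network is not None:
        p1, p2, p3, p4 = order[:4]
        if not network.split_time((p1, p2)) < network.split_time((p3, p4)):
            raise ValueError("(P1,P2) must split more recently than (P3,P4)")
    counts = [binary_pattern_counts(a, order) for a in alignments]
    ids = [getattr(a, "window_id", f"win_{i:06d}")
           for i, a in enumerate(alignments)]
    return dfoil_scan(counts, alpha=alpha, window_ids=ids)


# ---------------------------------------------------------------------------
# contiguity of flagged windows


def contiguity_test(flagged, n_windows, n_perm=10000, rng=None):
    """Permutation test for genomic clustering of flagged windows.

    Statistic: number of adjacent flagged pairs.  The null redistributes the
    same number of flags uniformly over the windows; p is the fraction of
    placements with adjacency >= observed.  Introgressed tracts are expected
    to be contiguous; a non-significant p says the flags are discrete and
    noncontiguous.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    flagged = np.asarray(sorted(set(int(i) for i in flagged)))
    k = len(flagged)
    if k == 0 or k >= n_windows:
        raise ValueError("contiguity undefined: need 0 < n_flagged < n_windows")
    if (flagged < 0).any() or (flagged >= n_windows).any():
        raise ValueError("flagged indices out of range")
    obs = int((np.diff(flagged) == 1).sum())
    ge = 0
    for _ in range(n_perm):
        perm = np.sort(rng.choice(n_windows, size=k, replace=False))
        ge += int((np.diff(perm) == 1).sum()) >= obs
    return obs, (1 + ge) / (1 + n_perm)
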