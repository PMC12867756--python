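"""Divergence-time ordering: does the discordant clade pre- or post-date
speciation?

Under ILS, a discordant gene tree arises from coalescences in the ancestral
population, so the divergence of the discordant pair PREdates every
speciation event involving those taxa (older).  Gene flow happens after
speciation, so an introgressed discordant clade's divergence POSTdates even
the most recent speciation (younger).  The reference sample is therefore
the species-tree cherry-pair divergence measured on concordant windows — a
per-window proxy for the youngest speciation time involving the focal
taxon.  Divergences are clock-based: JC distance between the pair halved;
relative units only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alignment import WindowAlignment
from .windowtrees import SaturationError, jc_distance


def window_pair_divergence(aln: WindowAlignment, pair):
    """Clock divergence of a taxon pair on one window: JC distance / 2.

    Gapped columns are excluded; saturation (mismatch >= 0.75) raises
    :class:`SaturationError`.
    """
    a, b = (aln.row(t) for t in pair)
    ok = (a < 4) & (b < 4)
    if not ok.any():
        raise ValueError("no shared ungapped sites for the pair")
    p = float((a[ok] != b[ok]).mean())
    return jc_distance(p) / 2.0


@dataclass
class OrderingResult:
    direction: str            # 'older' | 'younger' | 'none'
    p_older: float
    p_younger: float
    median_discordant: float
    median_reference: float
    interpretation: str
    n_discordant: int
    n_reference: int

    def summary(self):
        return (
            f"discordant median = {self.median_discordant:.5g}  "
            f"reference median = {self.median_reference:.5g}\n"
            f"one-sided Mann-Whitney: p(older) = {self.p_older:.3g}, "
            f"p(younger) = {self.p_younger:.3g}\n"
            f"direction = {self.direction} => {self.interpretation}")


def ordering_test(divs_discordant, divs_speciestree, alpha=0.05):
    """One-sided Mann-Whitney tests of the discordant-pair divergences
    against the species-tree reference divergences.

    direction = 'older' when the discordant sample is significantly larger
    (ILS signature: coalescence predates speciation), 'younger' when
    significantly smaller (introgression signature: divergence postdates
    speciation), 'none' otherwise.
    """
    x = np.asarray(divs_discordant, dtype=float)
    y = np.asarray(divs_speciestree, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both divergence samples must be non-empty")
    p_older = stats.mannwhitneyu(x, y, alternative="greater").pvalue
    p_younger = stats.mannwhitneyu(x, y, alternative="less").pvalue
    mx, my = float(np.median(x)), float(np.median(y))
    if p_older < alpha and mx > my:
        direction, interp = "older", "consistent with ILS"
    elif p_younger < alpha and mx < my:
        direction, interp = "younger", "consistent with introgression"
    else:
        direction, interp = "none", "no ordering signal"
    return OrderingResult(direction, float(p_older), float(p_younger),
                          mx, my, interp, len(x), len(y))


def ordering_analysis(alignments, topologies, discordant_label,
                      discordant_pair, reference_label, reference_pair,
                      alpha=0.05):
    """End-to-end ordering test from window alignments + topology labels.

    ``discordant_pair`` is the pair forming the discordant cherry (e.g.
    focal group + sister genus in Tree2 windows); ``reference_pair`` is the
    species-tree cherry (e.g. focal group + congener in Tree1 windows).
    Saturated windows are skipped.
    """
    disc, ref = [], []
    for aln, topo in zip(alignments, topologies):
        try:
            if topo == discordant_label:
                disc.append(window_pair_divergence(aln, discordant_pair))
            elif topo == reference_label:
                ref.append(window_pair_divergence(aln, reference_pair))
        except SaturationError:
            continue
    return ordering_test(disc, ref, alpha=alpha)
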