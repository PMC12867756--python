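"""ILS genes: CDS-coverage filtering of ILS segments and the scan for
group-diagnostic shared amino-acid residues.

A gene is an "ILS gene" when ILS segments cover strictly more than 30% of
its coding sequence.  The residue scan flags protein-alignment columns
where one taxon group (e.g. the focal group plus the sister genus, which
share ancestral polymorphism under ILS) is fixed for one residue and all
remaining taxa are fixed for a single different residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class GeneModel:
    """A gene's CDS intervals in 0-based half-open genome coordinates."""

    gene_id: str
    chrom: str
    strand: str
    cds: list

    def __post_init__(self):
        cds = sorted((int(s), int(e)) for (s, e) in self.cds)
        for (s, e) in cds:
            if e <= s:
                raise ValueError(f"empty CDS interval in {self.gene_id}")
        for (_, e1), (s2, _) in zip(cds, cds[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS in {self.gene_id}")
        self.cds = cds

    @property
    def cds_length(self):
        return sum(e - s for (s, e) in self.cds)

    @property
    def span(self):
        return (self.cds[0][0], self.cds[-1][1])


def cds_coverage(segments, gene: GeneModel):
    """Fraction of the gene's CDS covered by the (disjoint) segments.

    Segment bases falling in introns do not count; coverage is additive
    over segments (coordinates strand-agnostic).
    """
    if gene.cds_length == 0:
        raise ValueError("gene has zero CDS length")
    covered = 0
    for seg in segments:
        start = getattr(seg, "start", None)
        if start is None:
            start, end = seg
        else:
            end = seg.end
            if getattr(seg, "chrom", None) not in (None, gene.chrom):
                continue
        for (s, e) in gene.cds:
            covered += max(0, min(end, e) - max(start, s))
    return covered / gene.cds_length


def filter_ils_genes(coverages, min_frac=0.30):
    """Genes whose CDS coverage strictly exceeds ``min_frac``.

    ``coverages``: mapping gene id -> coverage fraction.  Returned sorted by
    coverage descending (a fully covered gene ranks first), ties by id.
    """
    kept = [(g, c) for g, c in coverages.items() if c > min_frac]
    kept.sort(key=lambda x: (-x[1], x[0]))
    return [g for g, _ in kept]


GAP_CHARS = set("-.X*")


def shared_residue_scan(protein_aln, group_ab, others):
    """Columns where ``group_ab`` and the remaining taxa are reciprocally
    fixed for different residues.

    ``protein_aln``: mapping taxon -> aligned protein sequence (equal
    lengths).  Columns containing any gap/ambiguity character across the
    scanned taxa are skipped.  Returns a DataFrame with 0-based ``column``,
    ``group_residue`` and ``other_residue``; symmetric in the two groups.
    """
    group_ab, others = list(group_ab), list(others)
    if not group_ab or not others:
        raise ValueError("both groups must be non-empty")
    if set(group_ab) & set(others):
        raise ValueError("groups overlap")
    seqs = {t: protein_aln[t] for t in group_ab + others}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("unequal alignment rows")
    (L,) = lengths
    rows = []
    for col in range(L):
        res = {t: seqs[t][col] for t in seqs}
        if any(r in GAP_CHARS for r in res.values()):
            continue
        ab = {res[t] for t in group_ab}
        ot = {res[t] for t in others}
        if len(ab) == 1 and len(ot) == 1 and ab != ot:
            rows.append((col, ab.pop(), ot.pop()))
    return pd.DataFrame(rows, columns=["column", "group_residue",
                                       "other_residue"])


def ils_gene_report(segments, genes, min_frac=0.30):
    """Coverage table + filtered gene list for a set of gene models."""
    cov = {g.gene_id: cds_coverage(segments, g) for g in genes}
    table = pd.DataFrame(
        sorted(cov.items(), key=lambda x: (-x[1], x[0])),
        columns=["gene_id", "cds_coverage"])
    table["ils_gene"] = table["cds_coverage"] > min_frac
    return table, filter_ils_genes(cov, min_frac)
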