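"""File formats: window FASTAs, truth/segment BED, GFF3 gene models,
Newick gene-tree lists, YAML run manifests.

Coordinates are 0-based half-open internally (BED-native); GFF3 is
converted to/from its 1-based closed convention on I/O.
"""

from __future__ import annotations

import pathlib

import dendropy
import pandas as pd
import yaml

from ._trees import Node
from .alignment import WindowAlignment
from .ilsgenes import GeneModel

BED_TRUTH_HEADER = ["chrom", "start", "end", "window_id", "genealogy_class",
                    "introgressed", "origin"]


# ---------------------------------------------------------------------------
# BED


def write_truth_bed(truth: pd.DataFrame, path):
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BED_TRUTH_HEADER) + "\n")
        for _, r in truth.iterrows():
            fh.write("\t".join([
                str(r["chrom"]), str(r["start"]), str(r["end"]),
                str(r["window_id"]), str(r["genealogy_class"]),
                str(int(r["introgressed"])), str(r["origin"]),
            ]) + "\n")


def read_truth_bed(path):
    df = pd.read_csv(path, sep="\t", comment=None, header=0)
    df.columns = [c.lstrip("#") for c in df.columns]
    if not df.empty:
        df["introgressed"] = df["introgressed"].astype(bool)
    return df


def write_segments_bed(segments, path):
    """ILS segments as BED with the mean posterior in the score column."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstate\tmean_posterior\n")
        for s in segments:
            fh.write(f"{s.chrom or '.'}\t{s.start}\t{s.end}\t{s.state}"
                     f"\t{s.mean_posterior:.4f}\n")


def read_plain_bed(path):
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    return df


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes, path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            fh.write(f"{g.chrom}\tilsrad\tgene\t{gs + 1}\t{ge}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(f"{g.chrom}\tilsrad\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t0\tID={g.gene_id}.cds{i};"
                         f"Parent={g.gene_id}\n")


def read_gff3(path):
    """Gene models (CDS intervals, 0-based half-open) from a GFF3 file."""
    cols = ["chrom", "source", "type", "start", "end", "score", "strand",
            "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    genes = []
    cds = df[df["type"] == "CDS"]
    if cds.empty:
        return genes
    parents = cds["attributes"].str.extract(r"Parent=([^;]+)")[0]
    for gid, sub in cds.groupby(parents, sort=True):
        intervals = [(int(s) - 1, int(e))
                     for s, e in zip(sub["start"], sub["end"])]
        genes.append(GeneModel(gid, sub["chrom"].iloc[0],
                               sub["strand"].iloc[0], intervals))
    return genes


# ---------------------------------------------------------------------------
# Newick


def _from_dendropy(node):
    n = Node(name=node.taxon.label if node.taxon else None,
             length=node.edge.length)
    n.children = [_from_dendropy(c) for c in node.child_nodes()]
    return n


def parse_newick(s) -> Node:
    t = dendropy.Tree.get(data=s, schema="newick")
    return _from_dendropy(t.seed_node)


def write_gene_trees(trees, ids, path):
    """One Newick per line, window id as a leading bracket comment."""
    with open(path, "w") as fh:
        for wid, tree in zip(ids, trees):
            fh.write(tree.newick(comment=f"window={wid}") + "\n")


def read_gene_trees(path):
    """Returns list of (window_id or None, Node)."""
    out = []
    for line in open(path):
        line = line.strip()
        if not line:
            continue
        wid = None
        if line.startswith("[&window="):
            end = line.index("]")
            wid = line[9:end]
            line = line[end + 1:]
        out.append((wid, parse_newick(line)))
    return out


# ---------------------------------------------------------------------------
# simulated-genome bundle


def write_simulated_genome(sim, outdir):
    out = pathlib.Path(outdir)
    (out / "windows").mkdir(parents=True, exist_ok=True)
    for aln in sim.windows:
        aln.to_fasta(out / "windows" / f"{aln.window_id}.fa")
    write_truth_bed(sim.truth, out / "truth.bed")
    write_gff3(sim.config.gene_models, out / "genes.gff3")
    write_gene_trees(sim.trees, list(sim.truth["window_id"]),
                     out / "genetrees.nwk")
    cfg = sim.config
    manifest = {
        "n_windows": cfg.n_windows, "window_len": cfg.window_len,
        "theta": cfg.theta, "seed": cfg.seed, "chrom": cfg.chrom,
        "taxa": list(cfg.taxa or sim.network.taxa),
        "genome_len": sim.genome_len,
        "n_gene_models": len(cfg.gene_models),
        "suppress_ils_in_cds": cfg.suppress_ils_in_cds,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_windows(directory):
    """Window alignments from a directory of per-window FASTAs, sorted."""
    paths = sorted(pathlib.Path(directory).glob("*.fa"))
    return [WindowAlignment.from_fasta(p, window_id=p.stem) for p in paths]
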