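"""Window alignments: the gapped multiple alignment over one genomic window.

Sequences are stored as ``int8`` codes: 0..3 = A,C,G,T; 4 = gap or
ambiguity.  Coordinates are 0-based half-open genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

_CODE = np.full(256, 4, dtype=np.int8)
for i, ch in enumerate("ACGT"):
    _CODE[ord(ch)] = i
    _CODE[ord(ch.lower())] = i
_DECODE = np.array(list("ACGT-"), dtype="U1")

GAP = 4


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])


@dataclass
class WindowAlignment:
    """A multiple alignment of the study taxa over one window."""

    taxa: list[str]
    data: np.ndarray  # (n_taxa, length) int8
    window_id: str = "win"
    chrom: str | None = None
    start: int = 0
    end: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be (n_taxa, length)")
        if self.end is None:
            self.end = self.start + self.data.shape[1]

    @property
    def length(self):
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def subset(self, taxa) -> "WindowAlignment":
        idx = [self.taxa.index(t) for t in taxa]
        return WindowAlignment(
            list(taxa), self.data[idx], self.window_id, self.chrom,
            self.start, self.end,
        )

    def ungapped_columns(self) -> np.ndarray:
        """Boolean mask of columns free of gaps/ambiguity in every row."""
        return (self.data < 4).all(axis=0)

    @classmethod
    def from_seqs(cls, seqs: dict[str, np.ndarray], **kw) -> "WindowAlignment":
        taxa = list(seqs)
        return cls(taxa, np.vstack([seqs[t] for t in taxa]), **kw)

    @classmethod
    def from_fasta(cls, path, window_id=None, chrom=None, start=0) -> "WindowAlignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        if not recs:
            raise ValueError(f"empty FASTA: {path}")
        taxa = [r.id for r in recs]
        data = np.vstack([encode(str(r.seq)) for r in recs])
        return cls(taxa, data, window_id=window_id or "win",
                   chrom=chrom, start=start)

    def to_fasta(self, path):
        with open(path, "w") as fh:
            for t, row in zip(self.taxa, self.data):
                fh.write(f">{t}\n{decode(row)}\n")
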