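"""Packaged synthetic reference genome for demonstrations and tests.

`toy_genome` builds a deterministic, fully synthetic 16,300-bp circular
genome whose compartment layout mirrors a mouse mitochondrial genome:
a 877-bp D-loop, 13 protein-coding genes totalling 11,331 bp, 22 tRNA
genes totalling 1,499 bp, two rRNA genes totalling 2,536 bp, and a
57-bp noncoding origin-like stretch.  Base composition approximates the
light strand of mouse mtDNA (A- and C-rich, G-poor).  Protein-coding
genes are valid CDSs under the vertebrate mitochondrial code (ATG
start, TAA stop, no internal stops); one gene is encoded on the heavy
strand, as ND6 is in the real genome.

The sequence is synthetic — it is *not* the RefSeq mouse sequence — but
its coordinate arithmetic, compartment totals and codon structure make
it a faithful stand-in for annotation-dependent logic.
"""

from __future__ import annotations

import numpy as np

from .mtgenome import Feature, MtGenome, revcomp

__all__ = ["toy_genome", "TOY_GENOME_SEED"]

TOY_GENOME_SEED = 20089

# L-strand base composition of mouse mtDNA, approximately
_BASES = np.array(list("ACGT"))
_BASE_W = np.array([0.345, 0.245, 0.120, 0.290])

_MITO_STOPS = {"TAA", "TAG", "AGA", "AGG"}

# (kind, length, strand) blocks laid end-to-end; totals per compartment:
# D-loop 877, protein-coding 11331, tRNA 1499 (21x68 + 71), rRNA 2536,
# noncoding 57 -> 16300 bp
_LAYOUT: list[tuple[str, int, str]] = [
    ("tRNA", 68, "L"),
    ("rRNA", 956, "L"),
    ("tRNA", 68, "L"),
    ("rRNA", 1580, "L"),
    ("tRNA", 68, "L"),
    ("protein-coding", 957, "L"),
    ("tRNA", 68, "L"),
    ("tRNA", 68, "H"),
    ("protein-coding", 1038, "L"),
    ("tRNA", 68, "L"),
    ("protein-coding", 345, "L"),
    ("tRNA", 68, "L"),
    ("tRNA", 68, "H"),
    ("noncoding", 57, "L"),
    ("tRNA", 68, "H"),
    ("tRNA", 68, "H"),
    ("protein-coding", 1377, "L"),
    ("tRNA", 68, "H"),
    ("tRNA", 68, "L"),
    ("protein-coding", 516, "L"),
    ("protein-coding", 186, "L"),
    ("tRNA", 68, "L"),
    ("protein-coding", 1539, "L"),
    ("tRNA", 68, "L"),
    ("tRNA", 68, "L"),
    ("protein-coding", 204, "L"),
    ("protein-coding", 414, "L"),
    ("tRNA", 68, "L"),
    ("protein-coding", 285, "L"),
    ("tRNA", 68, "L"),
    ("protein-coding", 894, "L"),
    ("protein-coding", 2436, "L"),
    ("tRNA", 68, "H"),
    ("protein-coding", 1140, "H"),
    ("tRNA", 68, "H"),
    ("tRNA", 68, "L"),
    ("tRNA", 68, "L"),
    ("tRNA", 71, "L"),
    ("D-loop", 877, "L"),
]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n, p=_BASE_W))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """Random CDS: ATG start, TAA stop, internal codons avoid mito stops."""
    assert length % 3 == 0 and length >= 9
    codons = ["ATG"]
    for _ in range(length // 3 - 2):
        while True:
            codon = _random_bases(rng, 3)
            if codon not in _MITO_STOPS:
                break
        codons.append(codon)
    codons.append("TAA")
    return "".join(codons)


def toy_genome(seed: int = TOY_GENOME_SEED, name: str = "toy-mt") -> MtGenome:
    """Build the deterministic synthetic mitochondrial reference genome."""
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    features: list[Feature] = []
    pos = 1
    counters = {"tRNA": 0, "rRNA": 0, "protein-coding": 0}
    for kind, length, strand in _LAYOUT:
        if kind == "protein-coding":
            cds = _random_cds(rng, length)
            chunk = revcomp(cds) if strand == "H" else cds
        else:
            chunk = _random_bases(rng, length)
        label = kind
        if kind in counters:
            counters[kind] += 1
            prefix = {"tRNA": "trn", "rRNA": "rrn", "protein-coding": "gene"}[kind]
            label = f"{prefix}{counters[kind]}"
        elif kind == "D-loop":
            label = "D-loop"
        else:
            label = "oriL-like"
        features.append(
            Feature(kind=kind, name=label, start=pos, end=pos + length - 1, strand=strand)
        )
        chunks.append(chunk)
        pos += length
    return MtGenome(name=name, sequence="".join(chunks), features=features)
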