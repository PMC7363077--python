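"""Circular mitochondrial reference genome with functional annotation.

The mouse mitochondrial genome is a ~16.3-kb circular molecule whose
positions fall into a small set of functional compartments: the
noncoding control region (D-loop), 13 protein-coding genes, 22 tRNA
genes, two rRNA genes, and a few short noncoding stretches (e.g. the
origin of light-strand replication).  Every downstream analysis in this
package — mutation-frequency denominators, trinucleotide spectra,
synonymous/nonsynonymous site counting — is conditioned on this
annotation, so the genome model lives in one place.

Conventions
-----------
* Coordinates are 1-based inclusive; the genome is circular and every
  positional query wraps silently.
* The stored sequence is the light (L) strand, the strand mutation
  types are reported against.
* Overlapping features are resolved to a single compartment per
  position with precedence D-loop > protein-coding > tRNA > rRNA >
  noncoding; positions covered by no feature are noncoding.
* Codon logic uses the vertebrate mitochondrial genetic code
  (NCBI translation table 2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "Feature",
    "MtGenome",
    "MITO_TABLE",
    "COMPARTMENTS",
    "PRECEDENCE",
    "revcomp",
    "translate_codon",
    "collapse_substitution",
    "read_fasta",
    "read_feature_table",
    "read_genbank_features",
]

COMPARTMENTS = ("D-loop", "protein-coding", "tRNA", "rRNA", "noncoding")
#: compartment precedence for positions covered by more than one feature
PRECEDENCE = {kind: rank for rank, kind in enumerate(COMPARTMENTS)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]
_MITO_STOPS = frozenset(MITO_TABLE.stop_codons)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon under the vertebrate mitochondrial code.

    Returns the one-letter amino acid, or ``"*"`` for a stop codon.
    """
    if codon in _MITO_STOPS:
        return "*"
    return MITO_TABLE.forward_table[codon]


@dataclass(frozen=True)
class Feature:
    """One annotated feature on the mitochondrial genome.

    ``start``/``end`` are 1-based inclusive on the L-strand coordinate
    system.  ``strand`` is ``"L"`` when the feature's sense sequence is
    the reference strand and ``"H"`` when it is the reverse complement.
    ``frame`` is the codon offset of ``start`` within the reading frame
    (0 unless the annotation starts mid-codon).
    """

    kind: str
    name: str
    start: int
    end: int
    strand: str = "L"
    frame: int = 0

    def __post_init__(self) -> None:
        if self.kind not in COMPARTMENTS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("L", "H"):
            raise ValueError(f"strand must be 'L' or 'H', got {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MtGenome:
    """Circular mtDNA reference sequence plus functional annotation."""

    name: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
        for f in self.features:
            if f.end > self.length:
                raise ValueError(f"feature {f.name} extends past genome end ({f.end} > {self.length})")
        self._compartment_index = self._build_compartment_index()

    @property
    def length(self) -> int:
        return len(self.sequence)

    # ------------------------------------------------------------------
    # positional queries

    def _build_compartment_index(self) -> np.ndarray:
        idx = np.full(self.length, PRECEDENCE["noncoding"], dtype=np.int8)
        # apply in reverse precedence so higher-precedence kinds overwrite
        for kind in reversed(COMPARTMENTS[:-1]):
            for f in self.features:
                if f.kind == kind:
                    idx[f.start - 1 : f.end] = PRECEDENCE[kind]
        return idx

    def wrap(self, position: int) -> int:
        """Map an arbitrary integer onto the circular 1..length range."""
        return (position - 1) % self.length + 1

    def _check(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")

    def base(self, position: int) -> str:
        """Reference (L-strand) base at a circular position."""
        return self.sequence[self.wrap(position) - 1]

    def compartment_of(self, position: int) -> str:
        """Single compartment label of a position after precedence resolution."""
        self._check(position)
        return COMPARTMENTS[self._compartment_index[position - 1]]

    def compartment_sizes(self) -> dict[str, int]:
        """Total bp per compartment; values sum to the genome length."""
        counts = np.bincount(self._compartment_index, minlength=len(COMPARTMENTS))
        return {kind: int(counts[PRECEDENCE[kind]]) for kind in COMPARTMENTS}

    def feature_at(self, position: int, kind: str | None = None) -> Feature | None:
        """Highest-precedence feature covering a position (optionally of one kind)."""
        self._check(position)
        hits = [f for f in self.features if f.start <= position <= f.end]
        if kind is not None:
            hits = [f for f in hits if f.kind == kind]
        if not hits:
            return None
        return min(hits, key=lambda f: PRECEDENCE[f.kind])

    def context_of(self, position: int, strand: str = "L") -> tuple[str, bool]:
        """Trinucleotide context centred on a site, plus its CpG status.

        The context is returned on the requested strand; circularity
        supplies neighbours at the genome ends.  A site is flagged CpG
        when it participates in a 5'-CG-3' dinucleotide on either
        strand, i.e. it is a C immediately followed by G or a G
        immediately preceded by C on the reference.
        """
        self._check(position)
        left = self.base(position - 1)
        mid = self.base(position)
        right = self.base(position + 1)
        tri = left + mid + right
        cpg = (mid == "C" and right == "G") or (mid == "G" and left == "C")
        if strand == "H":
            tri = revcomp(tri)
        elif strand != "L":
            raise ValueError(f"strand must be 'L' or 'H', got {strand!r}")
        return tri, cpg

    def cds_sequence(self, feature: Feature) -> str:
        """Coding-strand sequence of a protein-coding feature."""
        seq = self.sequence[feature.start - 1 : feature.end]
        return revcomp(seq) if feature.strand == "H" else seq

    # ------------------------------------------------------------------
    # pedigree-specific edits

    def apply_edits(self, edits: Sequence[tuple]) -> "MtGenome":
        """Return a new genome with substitutions/insertions applied.

        ``edits`` is a sequence of ``("sub", position, base)`` or
        ``("ins", position_after, bases)`` tuples, sorted by position
        and non-overlapping.  Insertions go *after* the stated position
        (the field convention for naming inserted sites, e.g. an
        insertion "at 9821.2", means a base between 9821 and 9822).
        Feature coordinates downstream of an insertion are remapped.
        """
        seq = list(self.sequence)
        offsets: list[tuple[int, int]] = []  # (position_after, shift)
        shift = 0
        last_pos = 0
        for edit in edits:
            op, pos = edit[0], edit[1]
            if not 1 <= pos <= self.length:
                raise IndexError(f"edit position {pos} outside 1..{self.length}")
            if pos < last_pos:
                raise ValueError("edits must be sorted by position")
            last_pos = pos
            if op == "sub":
                base = edit[2].upper()
                if base not in "ACGT":
                    raise ValueError(f"bad substitution base {base!r}")
                seq[pos - 1 + shift] = base
            elif op == "ins":
                bases = edit[2].upper()
                if set(bases) - set("ACGT"):
                    raise ValueError(f"bad insertion bases {bases!r}")
                seq[pos + shift : pos + shift] = list(bases)
                shift += len(bases)
                offsets.append((pos, len(bases)))
            else:
                raise ValueError(f"unknown edit op {op!r}")

        def remap(coord: int) -> int:
            # an insertion after `pos_after` shifts every coordinate beyond
            # it; a feature spanning the insertion point is thereby extended
            return coord + sum(n for pos_after, n in offsets if coord > pos_after)

        new_features = [
            dataclasses.replace(f, start=remap(f.start), end=remap(f.end))
            for f in self.features
        ]
        return MtGenome(name=self.name, sequence="".join(seq), features=new_features)


def collapse_substitution(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    """Collapse a substitution + context to the pyrimidine-centred form.

    Spectrum conventions list each mutation once per complementary pair:
    a purine-reference change (e.g. G>T in context TGT) is reported as
    its reverse complement (C>A at ACA).  Returns ``(ref, alt, context)``
    in the collapsed representation.
    """
    if ref in "AG":
        return revcomp(ref), revcomp(alt), revcomp(context)
    return ref, alt, context


# ----------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Read the first record of a FASTA file; returns (name, sequence)."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def read_feature_table(path: str | Path) -> list[Feature]:
    """Read a feature TSV with columns kind, name, start, end, strand[, frame]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"kind", "name", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    feats = []
    for row in df.itertuples(index=False):
        feats.append(
            Feature(
                kind=str(row.kind),
                name=str(row.name),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                frame=int(getattr(row, "frame", 0) or 0),
            )
        )
    return feats


def write_feature_table(features: Iterable[Feature], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(f) for f in features])
    df.to_csv(path, sep="\t", index=False)


_GENBANK_KIND = {
    "CDS": "protein-coding",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "D-loop",
}


def read_genbank_features(path: str | Path) -> list[Feature]:
    """Extract compartment features from a GenBank flat file.

    Supports use of a real RefSeq mitochondrial record: CDS, tRNA, rRNA
    and D-loop features are mapped onto the package's feature model;
    everything else is left to the implicit noncoding compartment.
    Compound (join) locations are split into one Feature per exon part.
    """
    record = next(SeqIO.parse(str(path), "genbank"))
    feats: list[Feature] = []
    for sf in record.features:
        kind = _GENBANK_KIND.get(sf.type)
        if kind is None:
            continue
        name = sf.qualifiers.get("gene", sf.qualifiers.get("product", [sf.type]))[0]
        for part in sf.location.parts:
            strand = "H" if part.strand == -1 else "L"
            feats.append(
                Feature(
                    kind=kind,
                    name=name,
                    start=int(part.start) + 1,
                    end=int(part.end),
                    strand=strand,
                    frame=int(sf.qualifiers.get("codon_start", ["1"])[0]) - 1,
                )
            )
    return feats
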