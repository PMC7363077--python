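"""Barcode-error-corrected duplex consensus calling.

Reads carry a random tag (default 12 nt) and an invariant spacer at the
start of each mate.  Reads sharing a (corrected) tag pair form a
single-strand family; a single-strand consensus sequence (SSCS) is
called per family when at least `min_family` reads agree at a 70%
per-position majority.  The two families of one DNA duplex carry the
same tags in opposite mate order, so a family keyed αβ pairs with the
family keyed βα; their duplex consensus sequence (DCS) keeps only
positions on which both strand consensuses agree and is the
error-suppressed product used for variant calling.

Tag correction merges rare tags into higher-count tags within a Hamming
distance budget (default 3 mismatches across the combined 24-nt pair),
deterministically: the largest family wins, ties break lexicographically.
The exact-match search uses a pigeonhole block index, so correction is
linear-time in practice while remaining exact.

The caller is reference-free: no alignment is used or needed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .mtgenome import revcomp
from .simulate import ReadPair

__all__ = [
    "ReadFamily",
    "ConsensusRead",
    "ConsensusStats",
    "correct_tags",
    "build_sscs",
    "sscs_consensus",
    "duplex_consensus",
    "build_dcs",
    "pair_duplexes",
    "trim_head",
    "call_consensus",
]


@dataclass
class ReadFamily:
    """Reads sharing one corrected oriented tag pair (one template strand)."""

    tag: str  # corrected combined tag, mate-1 tag first
    members: list[tuple[str, str]] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ConsensusRead:
    """SSCS or DCS with paired-mate sequences over {A,C,G,T,N}."""

    level: str  # "SSCS" | "DCS"
    tag: str  # oriented tag (SSCS) or canonical duplex key (DCS)
    seq1: str
    seq2: str
    family_sizes: tuple[int, ...]  # (n,) for SSCS, (n_ab, n_ba) for DCS


@dataclass
class ConsensusStats:
    """Filter funnel for one consensus run."""

    n_read_pairs: int = 0
    n_rejected_short: int = 0
    n_raw_tags: int = 0
    n_corrected_tags: int = 0
    n_families: int = 0
    n_families_small: int = 0
    n_families_mixed_length: int = 0
    n_sscs: int = 0
    n_dcs: int = 0
    n_dropped_short_consensus: int = 0
    family_size_histogram: dict[int, int] = field(default_factory=dict)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class _BlockIndex:
    """Pigeonhole index: tags within <= n_blocks-1 mismatches of an
    accepted tag must share at least one exact block with it."""

    def __init__(self, tag_len: int, n_blocks: int) -> None:
        bounds = np.linspace(0, tag_len, n_blocks + 1).astype(int)
        self.slices = [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
        self.maps: list[dict[str, list[str]]] = [defaultdict(list) for _ in self.slices]

    def add(self, tag: str) -> None:
        for m, sl in zip(self.maps, self.slices):
            m[tag[sl]].append(tag)

    def candidates(self, tag: str) -> set[str]:
        out: set[str] = set()
        for m, sl in zip(self.maps, self.slices):
            out.update(m.get(tag[sl], ()))
        return out


def correct_tags(
    reads: list[ReadPair],
    tag_length: int = 12,
    spacer_length: int = 5,
    max_mismatch: int = 3,
    stats: ConsensusStats | None = None,
) -> dict[str, ReadFamily]:
    """Group read pairs into tag families after barcode error correction.

    The combined tag (mate-1 tag + mate-2 tag) keys each family.  Tags
    are visited in decreasing count order (ties lexicographic); a tag
    within `max_mismatch` of an already-accepted tag merges into the
    accepted tag with the largest family (ties lexicographic), otherwise
    it founds a new family.  Members are returned stripped of tag and
    spacer.  Reads too short to contain tag + spacer are rejected.
    """
    stats = stats if stats is not None else ConsensusStats()
    head = tag_length + spacer_length
    raw: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for r in reads:
        stats.n_read_pairs += 1
        if len(r.seq1) <= head or len(r.seq2) <= head:
            stats.n_rejected_short += 1
            continue
        combined = r.seq1[:tag_length] + r.seq2[:tag_length]
        raw[combined].append((r.seq1[head:], r.seq2[head:]))

    stats.n_raw_tags = len(raw)
    counts = Counter({t: len(v) for t, v in raw.items()})
    order = sorted(counts, key=lambda t: (-counts[t], t))

    index = _BlockIndex(2 * tag_length, max_mismatch + 1)
    merged_into: dict[str, str] = {}
    accepted: list[str] = []
    for tag in order:
        cands = [
            c
            for c in index.candidates(tag)
            if counts[c] >= counts[tag] and _hamming(c, tag) <= max_mismatch
        ]
        if cands:
            target = min(cands, key=lambda c: (-counts[c], c))
            merged_into[tag] = target
        else:
            accepted.append(tag)
            index.add(tag)

    families: dict[str, ReadFamily] = {t: ReadFamily(tag=t) for t in accepted}
    for tag, members in raw.items():
        families[merged_into.get(tag, tag)].members.extend(members)
    stats.n_corrected_tags = len(families)
    stats.n_families = len(families)
    for fam in families.values():
        stats.family_size_histogram[fam.size] = (
            stats.family_size_histogram.get(fam.size, 0) + 1
        )
    return families


def sscs_consensus(seqs: list[str], threshold: float = 0.7) -> str:
    """Per-position majority consensus: base called iff count/size >= threshold."""
    n = len(seqs)
    mat = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, -1)
    out = np.full(mat.shape[1], ord("N"), dtype=np.uint8)
    need = threshold * n
    for base in b"ACGT":
        cnt = (mat == base).sum(axis=0)
        out[cnt >= need] = base
    return out.tobytes().decode()


def build_sscs(
    family: ReadFamily,
    min_family: int = 3,
    threshold: float = 0.7,
    stats: ConsensusStats | None = None,
) -> ConsensusRead | None:
    """SSCS of one family, or None if the family is too small or malformed."""
    if family.size < min_family:
        if stats is not None:
            stats.n_families_small += 1
        return None
    lens = {(len(a), len(b)) for a, b in family.members}
    if len(lens) > 1:
        if stats is not None:
            stats.n_families_mixed_length += 1
        return None
    seq1 = sscs_consensus([a for a, _ in family.members], threshold)
    seq2 = sscs_consensus([b for _, b in family.members], threshold)
    if stats is not None:
        stats.n_sscs += 1
    return ConsensusRead(
        level="SSCS", tag=family.tag, seq1=seq1, seq2=seq2, family_sizes=(family.size,)
    )


def duplex_consensus(a: str, b: str) -> str:
    """Positionwise duplex agreement: keep the base where the two strand
    consensuses agree; disagreement or any N yields N."""
    if len(a) != len(b):
        raise ValueError("strand consensuses must have equal length")
    return "".join(x if (x == y and x != "N") else "N" for x, y in zip(a, b))


def build_dcs(sscs_ab: ConsensusRead, sscs_ba: ConsensusRead) -> ConsensusRead:
    """DCS from the two strand consensuses of one duplex.

    Orientation reconciliation: the opposite-strand family's mate 2
    reads the same fragment end, on the same physical strand and in the
    same direction, as this family's mate 1 (and vice versa), so the
    positionwise agreement pairs mate 1 with the partner's mate 2
    directly.
    """
    seq1 = duplex_consensus(sscs_ab.seq1, sscs_ba.seq2)
    seq2 = duplex_consensus(sscs_ab.seq2, sscs_ba.seq1)
    tag_a = sscs_ab.tag
    tag_b = sscs_ba.tag
    canonical = min(tag_a, tag_b)
    return ConsensusRead(
        level="DCS",
        tag=canonical,
        seq1=seq1,
        seq2=seq2,
        family_sizes=(sscs_ab.family_sizes[0], sscs_ba.family_sizes[0]),
    )


def pair_duplexes(
    sscs_by_tag: dict[str, ConsensusRead],
    tag_length: int = 12,
    stats: ConsensusStats | None = None,
) -> list[ConsensusRead]:
    """Pair opposite-strand SSCSs (tag αβ with tag βα) into DCSs.

    A lone SSCS (no partner family passed the size gate) yields no DCS;
    this is a normal outcome, not an error.  For each duplex, the
    lexicographically smaller oriented tag is treated as the `ab`
    strand, so output is independent of input order.
    """
    out = []
    for tag, sscs in sorted(sscs_by_tag.items()):
        alpha, beta = tag[:tag_length], tag[tag_length:]
        partner = beta + alpha
        if partner < tag:
            continue  # handled when we visited the partner, or will be below
        if partner == tag:
            continue  # palindromic tag pair: cannot resolve strands
        other = sscs_by_tag.get(partner)
        if other is None:
            continue
        if len(sscs.seq1) != len(other.seq2) or len(sscs.seq2) != len(other.seq1):
            continue
        out.append(build_dcs(sscs, other))
    if stats is not None:
        stats.n_dcs += len(out)
    return out


def trim_head(consensus: ConsensusRead, n: int = 12, stats: ConsensusStats | None = None) -> ConsensusRead | None:
    """Drop the first n bases of each mate (end-repair artifact zone).

    Returns None (record dropped) when a mate is not longer than n.
    """
    if len(consensus.seq1) <= n or len(consensus.seq2) <= n:
        if stats is not None:
            stats.n_dropped_short_consensus += 1
        return None
    return ConsensusRead(
        level=consensus.level,
        tag=consensus.tag,
        seq1=consensus.seq1[n:],
        seq2=consensus.seq2[n:],
        family_sizes=consensus.family_sizes,
    )


def call_consensus(
    reads: list[ReadPair],
    tag_length: int = 12,
    spacer_length: int = 5,
    max_mismatch: int = 3,
    min_family: int = 3,
    threshold: float = 0.7,
    trim: int = 12,
) -> tuple[list[ConsensusRead], list[ConsensusRead], ConsensusStats]:
    """Full consensus chain: families -> SSCS -> DCS -> head trim.

    Returns (trimmed DCSs, trimmed SSCSs, stats).  SSCSs are returned for
    all families passing the size gate, including those without a duplex
    partner, because heteroplasmy analyses use SSCS-level counts.
    """
    stats = ConsensusStats()
    families = correct_tags(reads, tag_length, spacer_length, max_mismatch, stats)
    sscs_by_tag: dict[str, ConsensusRead] = {}
    for tag, fam in families.items():
        sscs = build_sscs(fam, min_family, threshold, stats)
        if sscs is not None:
            sscs_by_tag[tag] = sscs
    dcs = pair_duplexes(sscs_by_tag, tag_length, stats)
    trimmed_dcs = [t for c in dcs if (t := trim_head(c, trim, stats)) is not None]
    trimmed_sscs = [
        t for c in sscs_by_tag.values() if (t := trim_head(c, trim, stats)) is not None
    ]
    return trimmed_dcs, trimmed_sscs, stats
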