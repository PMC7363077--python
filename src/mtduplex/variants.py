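"""Per-site allele counting and variant calling from consensus reads.

Two input paths feed the same pileup:

* **Sidecar path** (default, reference-free) — the simulator's sidecar
  table records each template's true circular start, so trimmed
  consensus mates are placed exactly without a read mapper.
* **SAM path** — externally aligned consensus reads are read with
  pysam, filtered on mapping quality, pairing and base quality, and
  mate overlaps are clipped so each template contributes one
  observation per site.

Pileup treats the genome as circular, which makes the edge-window
remapping used with linearized references unnecessary; a window filter
is provided for parity with two-pass linear mapping workflows.

Calling is maximally sensitive: every non-reference, non-N base seen in
at least one DCS becomes a call, because duplex consensus has already
suppressed sequencing errors.  Minor-allele frequencies fall back to
SSCS counts when the DCS minor-allele depth is below 5 molecules, where
DCS frequencies are too granular to be reliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusRead
from .mtgenome import MtGenome, revcomp

__all__ = [
    "Pileup",
    "clip_overlap",
    "filter_alignments",
    "sidecar_observations",
    "sam_observations",
    "pileup",
    "call_variants",
    "select_window",
]

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _CODE_LUT[ord(_b)] = _i

#: an observation is (level, 0-based positions, base codes 0..3)
Observation = tuple[str, np.ndarray, np.ndarray]


@dataclass
class Pileup:
    """Per-site allele counts at DCS and SSCS level for one sample."""

    genome_length: int
    dcs: np.ndarray = field(default=None)  # (4, L) counts
    sscs: np.ndarray = field(default=None)
    dcs_n: np.ndarray = field(default=None)  # excluded N observations
    sscs_n: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        L = self.genome_length
        if self.dcs is None:
            self.dcs = np.zeros((4, L), dtype=np.int32)
        if self.sscs is None:
            self.sscs = np.zeros((4, L), dtype=np.int32)
        if self.dcs_n is None:
            self.dcs_n = np.zeros(L, dtype=np.int32)
        if self.sscs_n is None:
            self.sscs_n = np.zeros(L, dtype=np.int32)

    def depth(self, level: str = "DCS") -> np.ndarray:
        """Called-base depth per site (N observations excluded)."""
        return (self.dcs if level == "DCS" else self.sscs).sum(axis=0)

    def coverage(self, level: str = "DCS") -> np.ndarray:
        """Total covering observations per site, including N bases."""
        if level == "DCS":
            return self.dcs.sum(axis=0) + self.dcs_n
        return self.sscs.sum(axis=0) + self.sscs_n

    def mean_depth(self, level: str = "DCS") -> float:
        return float(self.depth(level).mean())


def clip_overlap(
    mate1: tuple[int, int], mate2: tuple[int, int]
) -> tuple[int, int] | None:
    """Clip the second mate's half-open interval so any region covered by
    both mates is counted once.  Returns the clipped interval or None if
    the second mate is entirely contained in the first."""
    s1, e1 = mate1
    s2, e2 = mate2
    if s2 < e1 and e2 > s1:  # overlap
        if s2 >= s1 and e2 <= e1:
            return None
        if s2 >= s1:
            return (max(s2, e1), e2)
        return (s2, min(e2, s1))
    return (s2, e2)


def sidecar_observations(
    consensus_reads: list[ConsensusRead],
    sidecar: pd.DataFrame,
    genome: MtGenome,
    trim: int = 12,
) -> list[Observation]:
    """Place trimmed consensus mates on the circular reference.

    Mate 1 of a consensus read covers the fragment start and mate 2 the
    (reverse-complemented) fragment end; which physical strand mate 1
    came from is read off the sidecar's `top_tag`.  The mate-overlap
    region in short fragments is clipped from mate 2 so each template
    contributes at most one observation per site.
    """
    G = genome.length
    info = {
        row.tag_pair: (row.top_tag, row.start - 1, row.fragment_length)
        for row in sidecar.itertuples(index=False)
    }
    by_top = {row.top_tag: (row.start - 1, row.fragment_length) for row in sidecar.itertuples(index=False)}
    out: list[Observation] = []
    for cr in consensus_reads:
        if cr.level == "DCS":
            rec = info.get(cr.tag)
            if rec is None:
                continue
            top_tag, start0, L = rec
            mate1_is_top = cr.tag == top_tag
        else:
            if cr.tag in by_top:
                start0, L = by_top[cr.tag]
                mate1_is_top = True
            else:
                flipped = cr.tag[len(cr.tag) // 2 :] + cr.tag[: len(cr.tag) // 2]
                rec = by_top.get(flipped)
                if rec is None:
                    continue
                start0, L = rec
                mate1_is_top = False
        m = len(cr.seq1) + trim  # untrimmed mate span
        if mate1_is_top:
            # mate 1 reads the fragment start in top orientation; mate 2
            # reads the fragment end from the bottom strand
            left_seq, right_seq = cr.seq1, revcomp(cr.seq2)
        else:
            # mate 1 reads the fragment end (bottom strand); mate 2 reads
            # the fragment start and is already in top orientation
            left_seq, right_seq = cr.seq2, revcomp(cr.seq1)
        # mate covering fragment start occupies insert [trim, m);
        # mate covering fragment end occupies insert [L-m, L-trim)
        left_iv = (trim, m)
        right_iv = (max(L - m, 0), max(L - trim, 0))
        clipped = clip_overlap(left_iv, right_iv)
        segs: list[tuple[int, str]] = [(left_iv[0], left_seq)]
        if clipped is not None:
            cs, ce = clipped
            offset = cs - (L - m)
            segs.append((cs, right_seq[offset : offset + (ce - cs)]))
        pos_parts, code_parts = [], []
        for off, seq in segs:
            codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
            pos = (start0 + off + np.arange(len(seq))) % G
            pos_parts.append(pos)
            code_parts.append(codes)
        out.append(
            (cr.level, np.concatenate(pos_parts), np.concatenate(code_parts))
        )
    return out


def filter_alignments(
    records,
    min_mapq: int = 20,
    require_proper_pair: bool = True,
    counts: dict | None = None,
):
    """Yield pysam records passing the alignment filters.

    Mapping quality must be strictly greater than `min_mapq`; reads must
    be paired (and properly paired with a mapped mate when
    `require_proper_pair`).  Removal counts per reason are accumulated
    into `counts` when given.
    """
    counts = counts if counts is not None else {}
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            counts["unmapped_or_secondary"] = counts.get("unmapped_or_secondary", 0) + 1
            continue
        if rec.mapping_quality <= min_mapq:
            counts["low_mapq"] = counts.get("low_mapq", 0) + 1
            continue
        if not rec.is_paired:
            counts["unpaired"] = counts.get("unpaired", 0) + 1
            continue
        if require_proper_pair and (not rec.is_proper_pair or rec.mate_is_unmapped):
            counts["improper_pair"] = counts.get("improper_pair", 0) + 1
            continue
        yield rec


def sam_observations(
    path: str,
    level: str,
    genome: MtGenome,
    min_mapq: int = 20,
    require_proper_pair: bool = True,
    min_base_quality: int = 20,
) -> list[Observation]:
    """Read externally aligned consensus reads from SAM/BAM.

    Substitution-only scope: only aligned (match/mismatch) columns are
    consumed.  Overlapping mate coverage is clipped from the
    second-in-pair mate.
    """
    import pysam

    out: list[Observation] = []
    first_mate_span: dict[str, tuple[int, int]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in filter_alignments(fh, min_mapq, require_proper_pair):
            pairs = rec.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            qseq = rec.query_sequence
            quals = rec.query_qualities
            pos, codes = [], []
            span = (rec.reference_start, rec.reference_end)
            clip_iv = None
            if rec.query_name in first_mate_span:
                clip_iv = clip_overlap(first_mate_span.pop(rec.query_name), span)
                if clip_iv is None:
                    continue
            else:
                first_mate_span[rec.query_name] = span
            for qpos, rpos in pairs:
                if clip_iv is not None and not clip_iv[0] <= rpos < clip_iv[1]:
                    continue
                base = qseq[qpos]
                if base == "N":
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                pos.append(rpos % genome.length)
                codes.append(_BASE_INDEX[base])
            if pos:
                out.append((level, np.array(pos), np.array(codes, dtype=np.uint8)))
    return out


def pileup(observations: list[Observation], genome: MtGenome) -> Pileup:
    """Accumulate observations into per-site allele counts.

    Base code 255 marks an N (or quality-excluded) base: it is counted
    as covering but not as a called base, so conservation of
    observations (depth + N count) holds at every site.
    """
    pu = Pileup(genome_length=genome.length)
    for level, pos, codes in observations:
        counts, ncounts = (
            (pu.dcs, pu.dcs_n) if level == "DCS" else (pu.sscs, pu.sscs_n)
        )
        called = codes < 4
        np.add.at(counts, (codes[called], pos[called]), 1)
        if (~called).any():
            np.add.at(ncounts, pos[~called], 1)
    return pu


def call_variants(
    pu: Pileup,
    genome: MtGenome,
    sample_id: str,
    min_dcs_count: int = 1,
    sscs_fallback_depth: int = 5,
) -> pd.DataFrame:
    """Call every non-reference base supported by >= min_dcs_count DCSs.

    Returns a tidy table with DCS and SSCS counts, the alt-allele
    fraction at DCS level, and a minor-allele frequency whose source
    switches to SSCS when the DCS minor-allele depth is below
    `sscs_fallback_depth` molecules.
    """
    ref_codes = _CODE_LUT[np.frombuffer(genome.sequence.encode(), dtype=np.uint8)]
    dcs_depth = pu.depth("DCS")
    sscs_depth = pu.depth("SSCS")
    rows = []
    alt_mask = pu.dcs >= min_dcs_count
    alt_mask[ref_codes, np.arange(genome.length)] = False
    for code, pos0 in zip(*np.nonzero(alt_mask)):
        pos = int(pos0) + 1
        ref = genome.sequence[pos0]
        alt = "ACGT"[code]
        dcs_alt = int(pu.dcs[code, pos0])
        d_depth = int(dcs_depth[pos0])
        sscs_alt = int(pu.sscs[code, pos0])
        s_depth = int(sscs_depth[pos0])
        af_dcs = dcs_alt / d_depth if d_depth else 0.0
        dcs_minor = min(dcs_alt, d_depth - dcs_alt)
        if dcs_minor < sscs_fallback_depth and s_depth > 0:
            af = sscs_alt / s_depth
            source = "SSCS"
        else:
            af = af_dcs
            source = "DCS"
        rows.append(
            {
                "sample_id": sample_id,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "dcs_alt_count": dcs_alt,
                "dcs_depth": d_depth,
                "sscs_alt_count": sscs_alt,
                "sscs_depth": s_depth,
                "alt_fraction_dcs": af_dcs,
                "maf": min(af, 1.0 - af),
                "maf_source": source,
            }
        )
    dtypes = {
        "sample_id": str,
        "position": np.int64,
        "ref": str,
        "alt": str,
        "dcs_alt_count": np.int64,
        "dcs_depth": np.int64,
        "sscs_alt_count": np.int64,
        "sscs_depth": np.int64,
        "alt_fraction_dcs": np.float64,
        "maf": np.float64,
        "maf_source": str,
    }
    df = pd.DataFrame(rows, columns=list(dtypes)).astype(dtypes)
    return df.sort_values(["position", "alt"]).reset_index(drop=True)


def select_window(calls: pd.DataFrame, keep_ranges: list[tuple[int, int]]) -> pd.DataFrame:
    """Keep calls whose position falls in any inclusive (start, end) range.

    Parity helper for two-pass workflows that call edge positions
    against a relinearized reference and merge the windows afterwards.
    """
    mask = np.zeros(len(calls), dtype=bool)
    for a, b in keep_ranges:
        mask |= (calls["position"] >= a) & (calls["position"] <= b)
    return calls[mask].reset_index(drop=True)
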