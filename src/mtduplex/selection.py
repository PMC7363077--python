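"""Nonsynonymous/synonymous rate ratio (hN/hS) with a bootstrap null.

For low-frequency intra-individual variants the dN/dS machinery of
divergence data is replaced by hN/hS: the count of nonsynonymous
mutations per nonsynonymous site over the count of synonymous mutations
per synonymous site.  Site counts follow Nei and Gojobori: each codon
position contributes a synonymous fraction equal to the share of its
three possible substitutions that preserve the amino acid (vertebrate
mitochondrial code), so every codon contributes exactly 3 sites split
between the two categories.

Under neutrality hN/hS is expected to equal 1.  Deviation is judged
against a bootstrap null: replicates place the observed number of
mutations on coding sites at random, proportionally to the observed
12-type spectrum and each type's base opportunity in coding regions,
and the ratio is recomputed; the empirical two-sided p-value uses the
add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mtgenome import MITO_TABLE, MtGenome, translate_codon
from .simulate import MUTATION_TYPES

__all__ = [
    "SiteCountsNG",
    "HnHsResult",
    "ng_sites",
    "ng_sites_genome",
    "classify_coding_mutation",
    "hn_hs",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SiteCountsNG:
    """Fractional Nei-Gojobori site counts for a CDS (or set of CDSs)."""

    nonsynonymous: float
    synonymous: float

    @property
    def total(self) -> float:
        return self.nonsynonymous + self.synonymous


@dataclass
class HnHsResult:
    hn: float
    hs: float
    #: None when hS = 0 (ratio undefined)
    ratio: float | None
    n_nonsynonymous: int
    n_synonymous: int
    sites: SiteCountsNG
    null_ratios: np.ndarray | None = None
    p_value: float | None = None


def ng_sites(cds: str) -> SiteCountsNG:
    """Nei-Gojobori site counts for one coding sequence.

    Per codon position the synonymous fraction is the share of the
    three possible substitutions preserving the amino acid; stop-gaining
    changes count as nonsynonymous.  Codons containing a stop (e.g. a
    terminal TAA) contribute no sites.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    syn = 0.0
    total = 0.0
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = translate_codon(codon)
        if aa == "*":
            continue
        for j in range(3):
            for b in "ACGT":
                if b == codon[j]:
                    continue
                mutant = codon[:j] + b + codon[j + 1 :]
                if translate_codon(mutant) == aa:
                    syn += 1 / 3
        total += 3.0
    return SiteCountsNG(nonsynonymous=total - syn, synonymous=syn)


def ng_sites_genome(genome: MtGenome) -> SiteCountsNG:
    """Summed Nei-Gojobori sites over all protein-coding features."""
    n = s = 0.0
    for f in genome.features:
        if f.kind != "protein-coding":
            continue
        counts = ng_sites(genome.cds_sequence(f))
        n += counts.nonsynonymous
        s += counts.synonymous
    return SiteCountsNG(nonsynonymous=n, synonymous=s)


def classify_coding_mutation(genome: MtGenome, position: int, alt: str) -> str:
    """Coding effect of a substitution at a protein-coding position.

    Returns one of synonymous, nonsynonymous, stop_gained, stop_lost,
    start_lost.  The codon is read on the coding strand of the feature
    resolved by compartment precedence.
    """
    feature = genome.feature_at(position, kind="protein-coding")
    if feature is None or genome.compartment_of(position) != "protein-coding":
        raise ValueError(f"position {position} is not protein-coding")
    cds = genome.cds_sequence(feature)
    if feature.strand == "L":
        offset = position - feature.start - feature.frame
        alt_coding = alt
    else:
        offset = feature.end - position - feature.frame
        alt_coding = _COMPLEMENT[alt]
    if offset < 0:
        raise ValueError("position precedes the reading frame start")
    ci, cj = divmod(offset, 3)
    codon = cds[3 * ci : 3 * ci + 3]
    if len(codon) < 3:
        raise ValueError("position falls in an incomplete terminal codon")
    mutant = codon[:cj] + alt_coding + codon[cj + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(mutant)
    if ci == 0 and mutant not in MITO_TABLE.start_codons:
        # the annotated initiation codon no longer supports initiation
        return "start_lost"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_lost"
    if aa_ref != "*" and aa_alt == "*":
        return "stop_gained"
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def _is_nonsyn(effect: str) -> bool:
    return effect in ("nonsynonymous", "stop_gained", "stop_lost", "start_lost")


def _nonsyn_lookup(genome: MtGenome):
    """Per-genome cache: coding positions by reference base, and for each
    substitution type a parallel boolean array of amino-acid impact."""
    cached = getattr(genome, "_nonsyn_lookup", None)
    if cached is not None:
        return cached
    by_base: dict[str, list[int]] = {b: [] for b in "ACGT"}
    for pos in range(1, genome.length + 1):
        if genome.compartment_of(pos) == "protein-coding":
            by_base[genome.base(pos)].append(pos)
    positions = {b: np.array(v, dtype=np.int32) for b, v in by_base.items()}
    impact: dict[str, np.ndarray] = {}
    for t in MUTATION_TYPES:
        ref, alt = t[0], t[2]
        impact[t] = np.array(
            [
                _is_nonsyn(classify_coding_mutation(genome, int(p), alt))
                for p in positions[ref]
            ],
            dtype=bool,
        )
    genome._nonsyn_lookup = (positions, impact)
    return positions, impact


def hn_hs(
    mutations: pd.DataFrame,
    genome: MtGenome,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
    spectrum: dict | None = None,
) -> HnHsResult:
    """hN/hS over coding-region mutations with a bootstrap neutrality test.

    ``mutations`` needs columns position and alt (one row per event);
    non-coding rows are ignored.  The null distribution re-places the
    same number of mutations on coding positions at random, weighting
    each of the 12 substitution types by the observed spectrum
    (genome-wide unless ``spectrum`` is given) times its base
    opportunity in coding regions, then recomputes the ratio.  The
    two-sided p-value is 2 x min(tail fractions) with the add-one
    correction; it is not computed when hS = 0 or the observed ratio is
    undefined.
    """
    rng = np.random.default_rng() if rng is None else rng
    sites = ng_sites_genome(genome)
    if sites.synonymous <= 0:
        raise ValueError("no synonymous-capable sites in the genome")
    positions_by_base, impact = _nonsyn_lookup(genome)
    pos_index = {
        b: {int(p): i for i, p in enumerate(arr)} for b, arr in positions_by_base.items()
    }

    n_total = 0
    n_nonsyn = 0
    for row in mutations.itertuples(index=False):
        pos = int(row.position)
        idx = pos_index[row.ref].get(pos)
        if idx is None:  # not protein-coding under precedence
            continue
        n_total += 1
        n_nonsyn += bool(impact[f"{row.ref}>{row.alt}"][idx])
    n_syn = n_total - n_nonsyn
    hn = n_nonsyn / sites.nonsynonymous
    hs = n_syn / sites.synonymous
    ratio = None if hs == 0 else hn / hs

    if spectrum is None:
        counts = (
            (mutations["ref"] + ">" + mutations["alt"]).value_counts()
            if len(mutations)
            else pd.Series(dtype=int)
        )
        spectrum = {t: float(counts.get(t, 0)) for t in MUTATION_TYPES}
    weight_total = sum(spectrum.values())
    if weight_total <= 0 or n_total == 0 or ratio is None:
        return HnHsResult(hn, hs, ratio, n_nonsyn, n_syn, sites)

    type_w = np.array(
        [spectrum.get(t, 0.0) * positions_by_base[t[0]].size for t in MUTATION_TYPES],
        dtype=float,
    )
    type_w = type_w / type_w.sum()
    null = np.empty(n_boot)
    for b in range(n_boot):
        type_counts = rng.multinomial(n_total, type_w)
        k_non = 0
        for t, k in zip(MUTATION_TYPES, type_counts):
            if k == 0:
                continue
            idx = rng.integers(positions_by_base[t[0]].size, size=k)
            k_non += int(impact[t][idx].sum())
        k_syn = n_total - k_non
        if k_syn == 0:
            null[b] = np.inf
        else:
            null[b] = (k_non / sites.nonsynonymous) / (k_syn / sites.synonymous)

    lo = int((null <= ratio + 1e-12).sum())
    hi = int((null >= ratio - 1e-12).sum())
    p = min(1.0, 2 * (min(lo, hi) + 1) / (n_boot + 1))
    return HnHsResult(hn, hs, ratio, n_nonsyn, n_syn, sites, null, p)
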