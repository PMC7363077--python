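"""Synthetic duplex-sequencing data generator.

Emulates the structure of a two-pedigree mouse mtDNA study: eight
~10-month-old mothers and 28 ~20-day-old pups across two pedigrees,
with brain and muscle sampled for every animal and single oocytes plus
an oocyte pool for females.  Three layers are generated:

1. **Pedigree truth** — inherited heteroplasmies (default 28 sites with
   founder minor-allele frequencies spanning ~0.3%–30%) transmitted
   mother-to-offspring through a binomial germline bottleneck, and
   per-sample de novo mutations drawn at tissue- and age-specific
   rates around 10⁻⁷–10⁻⁶ per bp, D-loop-enriched and
   transition-biased, mostly on single molecules.
2. **Template molecules** — random fragments of the (circular) genome
   carrying the planted alleles.
3. **Duplex read families** — for each template, both strands are
   amplified into tag families (12-nt random tags, 5-nt spacer,
   family size ≈ 6–12 reads) with a flat per-base error rate, ready
   for consensus calling.  A sidecar table records each template's
   true position so downstream stages can run without a read mapper.

All randomness flows from a single seed through documented substreams
(one per sample), so partial re-runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .mtgenome import MtGenome, revcomp
from .references import toy_genome

__all__ = [
    "PedigreeSpec",
    "SimConfig",
    "TruthSet",
    "ReadPair",
    "default_pedigree",
    "simulate_transmission",
    "simulate_pedigree",
    "emit_read_families",
    "write_fastq",
]

_BASES = np.array(list("ACGT"))

#: the 12 directed substitution types on the reference (L) strand
MUTATION_TYPES = [
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
]

TRANSITIONS = {"A>G", "G>A", "C>T", "T>C"}

# Default single-study mutation spectrum: transition-biased
# (Ti/Tv = 3) with the G>A over C>T and T>C over A>G excesses that
# deamination on the heavy strand produces.
DEFAULT_SPECTRUM = {
    "G>A": 0.28,
    "T>C": 0.24,
    "C>T": 0.12,
    "A>G": 0.11,
    **{t: 0.03125 for t in MUTATION_TYPES if t not in TRANSITIONS},
}

# Median per-tissue mutation frequencies (substitutions per bp) by age
# group, used as the generator's default de novo rates.
DEFAULT_MU = {
    ("brain", "mother"): 1.2e-6,
    ("brain", "pup"): 4.7e-7,
    ("muscle", "mother"): 1.2e-6,
    ("muscle", "pup"): 4.5e-7,
    ("single_oocyte", "mother"): 1.0e-6,
    ("single_oocyte", "pup"): 3.9e-7,
    ("oocyte_pool", "mother"): 3.5e-7,
    ("oocyte_pool", "pup"): 2.4e-7,
}

# Median DCS depths by tissue (study-scale defaults; demo configs
# override these downward and scale rates up correspondingly).
DEFAULT_DEPTH = {
    "brain": 2050.0,
    "muscle": 1986.0,
    "single_oocyte": 133.0,
    "oocyte_pool": 932.0,
}


@dataclass(frozen=True)
class Individual:
    id: str
    pedigree: str
    generation: str  # "mother" | "pup"
    sex: str  # "F" | "M"
    mother_id: str | None
    n_single_oocytes: int = 0
    oocyte_pool_size: int = 0  # 0 -> no pool


@dataclass
class PedigreeSpec:
    """Pedigree membership; every pup's mother must be listed."""

    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = {ind.id for ind in self.individuals}
        for ind in self.individuals:
            if ind.generation == "pup" and ind.mother_id not in ids:
                raise ValueError(f"pup {ind.id} has no mother in the pedigree")

    def mothers(self) -> list[Individual]:
        return [i for i in self.individuals if i.generation == "mother"]

    def pups_of(self, mother_id: str) -> list[Individual]:
        return [i for i in self.individuals if i.mother_id == mother_id]

    def by_id(self, iid: str) -> Individual:
        for i in self.individuals:
            if i.id == iid:
                return i
        raise KeyError(iid)


def default_pedigree(rng: np.random.Generator | None = None) -> PedigreeSpec:
    """Two 2-generation pedigrees: 4+4 mothers, 11+17 pups (19 F, 9 M).

    Mothers carry 4 single oocytes and an oocyte pool each; female pups
    carry 3 single oocytes and a pool.  Oocyte-pool sizes are drawn in
    the study's 4–47 range (fixed here for determinism).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    individuals: list[Individual] = []
    pup_sexes = ["F"] * 19 + ["M"] * 9
    k = 0
    for ped, n_pups in (("A", 11), ("B", 17)):
        mother_ids = [f"{ped}-M{j + 1}" for j in range(4)]
        for mid in mother_ids:
            individuals.append(
                Individual(
                    id=mid,
                    pedigree=ped,
                    generation="mother",
                    sex="F",
                    mother_id=None,
                    n_single_oocytes=4,
                    oocyte_pool_size=int(rng.integers(4, 48)),
                )
            )
        for j in range(n_pups):
            sex = pup_sexes[k]
            k += 1
            mid = mother_ids[j % 4] if ped == "A" else mother_ids[j % 4]
            individuals.append(
                Individual(
                    id=f"{ped}-P{j + 1:02d}",
                    pedigree=ped,
                    generation="pup",
                    sex=sex,
                    mother_id=mid,
                    n_single_oocytes=3 if sex == "F" else 0,
                    oocyte_pool_size=int(rng.integers(4, 48)) if sex == "F" else 0,
                )
            )
    return PedigreeSpec(individuals)


@dataclass
class SimConfig:
    """All generator parameters; defaults are the emulated study conditions."""

    seed: int = 0
    genome: MtGenome = field(default_factory=toy_genome)
    pedigree: PedigreeSpec = field(default_factory=default_pedigree)
    bottleneck_N: int = 85
    n_heteroplasmies: int = 28
    #: counts per sharing category (pup-only, mother-and-pups, several-mothers)
    sharing_counts: tuple[int, int, int] = (17, 7, 4)
    #: founder minor-allele-frequency ranges per category (log-uniform)
    founder_maf_ranges: dict = field(
        default_factory=lambda: {
            "pup_only": (0.003, 0.03),
            "mother_and_pups": (0.005, 0.10),
            "several_mothers": (0.03, 0.30),
        }
    )
    mu: dict = field(default_factory=lambda: dict(DEFAULT_MU))
    depth: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH))
    #: one global multiplier applied to de novo and artifact rates, used
    #: together with reduced depths for scaled-down demo runs
    rate_scale: float = 1.0
    spectrum: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    dloop_multiplier: float = 3.0
    #: probability that a de novo event occupies 1, 2 or 3 molecules
    multimolecule_probs: tuple[float, ...] = (0.92, 0.06, 0.02)
    #: extra binomial turnover rounds for oocytes of mothers (0 = off)
    mother_oocyte_turnover_rounds: int = 0
    mother_oocyte_turnover_N: int = 85
    tag_length: int = 12
    spacer_length: int = 5
    spacer: str = "TGACT"
    read_length: int = 250
    fragment_mean: float = 400.0
    fragment_sd: float = 60.0
    fragment_min: int = 280
    fragment_max: int = 460
    #: per-strand reads per family = min_reads + Poisson(extra_mean)
    family_min_reads: int = 3
    family_extra_mean: float = 5.0
    #: consensus head-trim the downstream caller will apply; de novo
    #: events are only planted on molecules that retain the site after
    #: this trim, so every planted event stays reachable
    head_trim: int = 12
    error_rate: float = 1e-3
    #: A>T/T>A template-level artifact rate (per bp per genome copy) in
    #: enzymatically fragmented samples
    enzymatic_artifact_rate: float = 2e-7
    #: fraction of single oocytes prepared with enzymatic fragmentation
    enzymatic_oocyte_fraction: float = 0.8

    def __post_init__(self) -> None:
        w = sum(self.spectrum.values())
        if not np.isclose(w, 1.0):
            raise ValueError(f"spectrum weights sum to {w}, expected 1")
        if any(v < 0 for v in self.mu.values()) or self.rate_scale < 0:
            raise ValueError("rates must be non-negative")
        if self.bottleneck_N < 1:
            raise ValueError("bottleneck_N must be >= 1")
        if len(self.spacer) != self.spacer_length:
            self.spacer = (self.spacer * self.spacer_length)[: self.spacer_length]
        if self.fragment_max > 2 * (self.read_length - self.tag_length - self.spacer_length):
            raise ValueError("fragment_max exceeds what paired reads can cover")


@dataclass
class TruthSet:
    """Planted truth emitted by `simulate_pedigree`.

    samples: one row per sequencing library (sample_id, individual,
        pedigree, generation, tissue, fragmentation, depth, pool size).
    het_sites: one row per inherited heteroplasmy (site, ref, alt,
        pedigree, sharing category, founder frequency).
    het_mafs: true per-sample minor-allele frequencies (long form).
    de_novo: planted tissue-specific events (sample_id, position, ref,
        alt, mutation type, number of carrier molecules, artifact flag).
    """

    samples: pd.DataFrame
    het_sites: pd.DataFrame
    het_mafs: pd.DataFrame
    de_novo: pd.DataFrame


# ----------------------------------------------------------------------
# transmission


def simulate_transmission(
    founder_maf: float,
    bottleneck_N: int,
    n_offspring: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Offspring allele frequencies after one binomial bottleneck.

    Each offspring frequency is Binomial(N, founder)/N, giving expected
    variance founder·(1−founder)/N around an unbiased mean.
    """
    if not 0.0 <= founder_maf <= 1.0:
        raise ValueError(f"founder_maf must be in [0, 1], got {founder_maf}")
    if bottleneck_N < 1:
        raise ValueError("bottleneck_N must be >= 1")
    return rng.binomial(bottleneck_N, founder_maf, size=n_offspring) / bottleneck_N


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Deterministic per-sample substream derived from the master seed."""
    tokens = [ord(c) for c in sample_id]
    return np.random.default_rng(np.random.SeedSequence([seed, *tokens]))


# ----------------------------------------------------------------------
# pedigree truth


def _build_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for ind in config.pedigree.individuals:
        tissues: list[tuple[str, int]] = [("brain", 0), ("muscle", 0)]
        tissues += [("single_oocyte", k + 1) for k in range(ind.n_single_oocytes)]
        if ind.oocyte_pool_size > 0:
            tissues.append(("oocyte_pool", 0))
        for tissue, k in tissues:
            sid = f"{ind.id}|{tissue}" + (f"#{k}" if k else "")
            if tissue == "single_oocyte":
                frag = (
                    "enzymatic"
                    if rng.random() < config.enzymatic_oocyte_fraction
                    else "covaris"
                )
            else:
                frag = "covaris"
            rows.append(
                {
                    "sample_id": sid,
                    "individual": ind.id,
                    "pedigree": ind.pedigree,
                    "generation": ind.generation,
                    "tissue": tissue,
                    "oocyte_index": k,
                    "fragmentation": frag,
                    "depth": float(config.depth[tissue]),
                    "pool_size": ind.oocyte_pool_size if tissue == "oocyte_pool" else 0,
                }
            )
    return pd.DataFrame(rows)


def _place_heteroplasmies(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    genome = config.genome
    n = config.n_heteroplasmies
    counts = list(config.sharing_counts)
    if sum(counts) != n:
        raise ValueError("sharing_counts must sum to n_heteroplasmies")
    sites = rng.choice(genome.length, size=n, replace=False) + 1
    mothers = config.pedigree.mothers()
    rows = []
    categories = (
        ["pup_only"] * counts[0]
        + ["mother_and_pups"] * counts[1]
        + ["several_mothers"] * counts[2]
    )
    for site, cat in zip(sites, categories):
        ref = genome.base(int(site))
        alt = rng.choice([b for b in "ACGT" if b != ref])
        lo, hi = config.founder_maf_ranges[cat]
        founder = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        origin = mothers[int(rng.integers(len(mothers)))]
        rows.append(
            {
                "site": int(site),
                "ref": ref,
                "alt": alt,
                "category": cat,
                "pedigree": origin.pedigree,
                "origin_mother": origin.id,
                "founder_maf": founder,
            }
        )
    return pd.DataFrame(rows).sort_values("site").reset_index(drop=True)


def _transmit(
    config: SimConfig,
    het_sites: pd.DataFrame,
    samples: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """True per-sample MAF for every heteroplasmy, via bottleneck draws."""
    ped = config.pedigree
    N = config.bottleneck_N
    records = []
    for hs in het_sites.itertuples(index=False):
        # somatic frequency per individual
        somatic: dict[str, float] = {ind.id: 0.0 for ind in ped.individuals}
        germline: dict[str, float] = dict(somatic)

        def draw(freq: float) -> float:
            return float(simulate_transmission(freq, N, 1, rng)[0])

        if hs.category == "several_mothers":
            # present in the (unsampled) grandmother: every sister mother
            # of the pedigree draws from the founder frequency
            for m in ped.mothers():
                if m.pedigree == hs.pedigree:
                    somatic[m.id] = draw(hs.founder_maf)
                    germline[m.id] = somatic[m.id]
        elif hs.category == "mother_and_pups":
            somatic[hs.origin_mother] = hs.founder_maf
            germline[hs.origin_mother] = hs.founder_maf
        else:  # pup_only: arose in the origin mother's germline only
            germline[hs.origin_mother] = hs.founder_maf

        for m in ped.mothers():
            for pup in ped.pups_of(m.id):
                if germline[m.id] > 0:
                    somatic[pup.id] = draw(germline[m.id])
                    germline[pup.id] = somatic[pup.id]

        for s in samples.itertuples(index=False):
            base_freq = somatic[s.individual]
            gen = ped.by_id(s.individual).generation
            if s.tissue in ("brain", "muscle"):
                maf = base_freq
            elif s.tissue == "single_oocyte":
                src = base_freq
                if hs.category == "pup_only" and gen == "mother":
                    # the new germline lineage: mother somatic is 0 and her
                    # sampled oocytes are defined as non-carriers
                    src = 0.0
                maf = draw(src) if src > 0 else 0.0
                if gen == "mother" and config.mother_oocyte_turnover_rounds > 0 and maf > 0:
                    for _ in range(config.mother_oocyte_turnover_rounds):
                        maf = float(
                            simulate_transmission(
                                maf, config.mother_oocyte_turnover_N, 1, rng
                            )[0]
                        )
            else:  # oocyte_pool: mean over pooled oocytes
                src = base_freq
                if hs.category == "pup_only" and gen == "mother":
                    src = 0.0
                npool = max(int(s.pool_size), 1)
                maf = (
                    float(simulate_transmission(src, N, npool, rng).mean())
                    if src > 0
                    else 0.0
                )
            if maf > 0:
                records.append(
                    {"sample_id": s.sample_id, "site": hs.site, "true_maf": maf}
                )
    return pd.DataFrame(records, columns=["sample_id", "site", "true_maf"])


def _site_weights(genome: MtGenome, dloop_multiplier: float) -> np.ndarray:
    w = np.ones(genome.length)
    for f in genome.features:
        if f.kind == "D-loop":
            w[f.start - 1 : f.end] = dloop_multiplier
    return w


def _plant_de_novo(
    config: SimConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    genome = config.genome
    weights = _site_weights(genome, config.dloop_multiplier)
    ref_arr = np.frombuffer(genome.sequence.encode(), dtype="S1").astype("U1")
    spectrum_types = list(config.spectrum)
    spectrum_w = np.array([config.spectrum[t] for t in spectrum_types])
    spectrum_w = spectrum_w / spectrum_w.sum()
    mm = np.array(config.multimolecule_probs)
    mm = mm / mm.sum()
    rows = []
    for s in samples.itertuples(index=False):
        mu = config.mu[(s.tissue, s.generation)] * config.rate_scale
        expected = mu * genome.length * s.depth
        n_events = rng.poisson(expected)
        art_rate = (
            config.enzymatic_artifact_rate * config.rate_scale
            if s.fragmentation == "enzymatic"
            else 0.0
        )
        n_artifacts = rng.poisson(art_rate * genome.length * s.depth)
        for i in range(n_events + n_artifacts):
            artifact = i >= n_events
            if artifact:
                mtype = "A>T" if rng.random() < 0.5 else "T>A"
            else:
                mtype = spectrum_types[int(rng.choice(len(spectrum_types), p=spectrum_w))]
            ref, alt = mtype.split(">")
            eligible = np.flatnonzero(ref_arr == ref)
            w = weights[eligible]
            pos = int(eligible[rng.choice(eligible.size, p=w / w.sum())]) + 1
            n_mol = 1 if artifact else int(rng.choice(len(mm), p=mm)) + 1
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "position": pos,
                    "ref": ref,
                    "alt": alt,
                    "mutation_type": mtype,
                    "n_molecules": n_mol,
                    "artifact": artifact,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "position",
            "ref",
            "alt",
            "mutation_type",
            "n_molecules",
            "artifact",
        ],
    )


def simulate_pedigree(config: SimConfig) -> TruthSet:
    """Generate the full planted truth for a configured pedigree."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    samples = _build_samples(config, rng)
    het_sites = _place_heteroplasmies(config, rng)
    het_mafs = _transmit(config, het_sites, samples, rng)
    de_novo = _plant_de_novo(config, samples, rng)
    return TruthSet(samples=samples, het_sites=het_sites, het_mafs=het_mafs, de_novo=de_novo)


# ----------------------------------------------------------------------
# read families


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read as emitted by the sequencer."""

    id: str
    seq1: str
    seq2: str
    qual1: str = ""
    qual2: str = ""


# byte-level encodings for fast read synthesis
_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_LUT = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_COMP_LUT = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP_LUT[_x] = _y


def _mutate_matrix(mat: np.ndarray, rng: np.random.Generator, error_rate: float) -> None:
    """Inject per-base substitution errors into an ASCII byte matrix, in place."""
    if error_rate <= 0:
        return
    mask = rng.random(mat.shape) < error_rate
    n = int(mask.sum())
    if n:
        shifts = rng.integers(1, 4, size=n)
        mat[mask] = _ASCII[(_CODE_LUT[mat[mask]] + shifts) % 4]


def _random_tag(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def emit_read_families(
    truth: TruthSet,
    config: SimConfig,
    sample_ids: list[str] | None = None,
) -> Iterator[tuple[str, list[ReadPair], pd.DataFrame]]:
    """Yield (sample_id, read pairs, sidecar) per sample.

    Each template molecule produces two tag families (one per strand);
    reads are tag + spacer + insert bases with per-base errors.  The
    sidecar records the template's canonical tag pair, 1-based circular
    start and fragment length for alignment-free downstream use.
    """
    genome = config.genome
    G = genome.length
    seq_bytes = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    m_span = config.read_length - config.tag_length - config.spacer_length
    mean_eff = min(config.fragment_mean, 2 * m_span) - 24.0  # post-trim coverage
    wanted = truth.samples
    if sample_ids is not None:
        wanted = wanted[wanted["sample_id"].isin(sample_ids)]

    for s in wanted.itertuples(index=False):
        rng = _sample_rng(config.seed, s.sample_id)
        n_molecules = max(1, int(round(G * s.depth / mean_eff)))
        starts = rng.integers(0, G, size=n_molecules)  # 0-based
        lengths = np.clip(
            rng.normal(config.fragment_mean, config.fragment_sd, size=n_molecules),
            config.fragment_min,
            config.fragment_max,
        ).astype(int)

        # planted alleles per molecule: {mol_index: {offset: alt}}
        planted: dict[int, dict[int, str]] = {}

        def covering(pos0: int, effective: bool = False) -> np.ndarray:
            off = (pos0 - starts) % G
            if effective:  # survives the downstream consensus head trim
                t = config.head_trim
                return np.flatnonzero((off >= t) & (off < lengths - t))
            return np.flatnonzero(off < lengths)

        hets = truth.het_mafs[truth.het_mafs["sample_id"] == s.sample_id]
        site_alt = dict(zip(truth.het_sites["site"], truth.het_sites["alt"]))
        for h in hets.itertuples(index=False):
            pos0 = h.site - 1
            idx = covering(pos0)
            if idx.size == 0:
                continue
            carriers = idx[rng.random(idx.size) < h.true_maf]
            for mol in carriers:
                planted.setdefault(int(mol), {})[int((pos0 - starts[mol]) % G)] = site_alt[h.site]

        dn = truth.de_novo[truth.de_novo["sample_id"] == s.sample_id]
        for d in dn.itertuples(index=False):
            pos0 = d.position - 1
            idx = covering(pos0, effective=True)
            if idx.size == 0:
                continue
            chosen = rng.choice(idx, size=min(d.n_molecules, idx.size), replace=False)
            for mol in np.atleast_1d(chosen):
                planted.setdefault(int(mol), {})[int((pos0 - starts[mol]) % G)] = d.alt

        reads: list[ReadPair] = []
        sidecar_rows = []
        spacer_bytes = np.frombuffer(config.spacer.encode(), dtype=np.uint8)
        for mol in range(n_molecules):
            start, L = int(starts[mol]), int(lengths[mol])
            idx = (start + np.arange(L)) % G
            insert = seq_bytes[idx].copy()
            for off, alt in planted.get(mol, {}).items():
                insert[off] = ord(alt)
            top = insert
            bottom = _COMP_LUT[insert[::-1]]
            tag_a = _random_tag(rng, config.tag_length)
            tag_b = _random_tag(rng, config.tag_length)
            canonical = min(tag_a + tag_b, tag_b + tag_a)
            sidecar_rows.append(
                {
                    "sample_id": s.sample_id,
                    "tag_pair": canonical,
                    "top_tag": tag_a + tag_b,
                    "start": start + 1,
                    "fragment_length": L,
                }
            )
            tag_a_b = np.frombuffer(tag_a.encode(), dtype=np.uint8)
            tag_b_b = np.frombuffer(tag_b.encode(), dtype=np.uint8)
            for strand, (t1, t2, r1_src, r2_src) in (
                ("ab", (tag_a_b, tag_b_b, top, bottom)),
                ("ba", (tag_b_b, tag_a_b, bottom, top)),
            ):
                n_reads = config.family_min_reads + rng.poisson(config.family_extra_mean)
                # whole-read templates (tag + spacer + insert bases); errors
                # hit tags and spacers the same way they hit insert bases
                tpl1 = np.concatenate([t1, spacer_bytes, r1_src[:m_span]])
                tpl2 = np.concatenate([t2, spacer_bytes, r2_src[:m_span]])
                mat1 = np.tile(tpl1, (n_reads, 1))
                mat2 = np.tile(tpl2, (n_reads, 1))
                _mutate_matrix(mat1, rng, config.error_rate)
                _mutate_matrix(mat2, rng, config.error_rate)
                for r in range(n_reads):
                    reads.append(
                        ReadPair(
                            id=f"{s.sample_id}:{mol}:{strand}:{r}",
                            seq1=mat1[r].tobytes().decode(),
                            seq2=mat2[r].tobytes().decode(),
                        )
                    )
        sidecar = pd.DataFrame(
            sidecar_rows,
            columns=["sample_id", "tag_pair", "top_tag", "start", "fragment_length"],
        )
        yield s.sample_id, reads, sidecar


def write_fastq(reads: list[ReadPair], path1: str, path2: str) -> None:
    """Write read pairs as two standard 4-line FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for r in reads:
            q1 = r.qual1 or "I" * len(r.seq1)
            q2 = r.qual2 or "I" * len(r.seq2)
            f1.write(f"@{r.id}/1\n{r.seq1}\n+\n{q1}\n")
            f2.write(f"@{r.id}/2\n{r.seq2}\n+\n{q2}\n")
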