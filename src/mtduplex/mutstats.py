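"""Mutation-frequency computation and its statistical battery.

Frequencies are counts of mutation events divided by the number of
sequenced nucleotides at risk: genome- or region-wide, the denominator
is region length x mean duplex-consensus depth summed over samples; for
type-resolved frequencies (e.g. the frequency of C>T changes) it is the
number of sequenced nucleotides that could yield the type (sequenced C
bases on the reference strand, for C>T).  Aggregation always sums
numerators and denominators — frequencies are never averaged.

Tests offered here mirror the standard toolkit for sparse mutation
counts: exact Poisson (Garwood) confidence intervals on counts,
Fisher's exact test for frequency comparisons with shared denominators,
binomial observed-versus-expected tests for regional enrichment,
one-sided permutation tests on group medians (exhaustive when feasible),
Monte-Carlo chi-squared spectrum comparisons, and
Benjamini-Hochberg/Benjamini-Yekutieli false-discovery-rate control.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .mtgenome import MtGenome, collapse_substitution
from .simulate import MUTATION_TYPES, TRANSITIONS

__all__ = [
    "FrequencyCell",
    "mutation_frequency",
    "poisson_ci",
    "fisher_compare",
    "observed_expected_binomial",
    "permutation_median_test",
    "adjust_fdr",
    "sequenced_nt_by_base",
    "strand_bias_table",
    "spectrum_table",
    "titv_ratio",
    "chi2_montecarlo",
    "frequency_by_group",
]

#: complementary mutation-type pairs for strand-bias analysis
RECIPROCAL_PAIRS = [
    ("C>T", "G>A"),
    ("A>G", "T>C"),
    ("C>A", "G>T"),
    ("C>G", "G>C"),
    ("A>T", "T>A"),
    ("A>C", "T>G"),
]


@dataclass(frozen=True)
class FrequencyCell:
    """One stratified frequency observation with its denominator."""

    stratum: str
    n_mutations: int
    denominator_bp: float
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def frequency(self) -> float:
        return self.n_mutations / self.denominator_bp


def mutation_frequency(n_mutations: int, region_length_bp: float, mean_dcs_depth: float) -> float:
    """Events per sequenced base pair: n / (length x depth).

    For aggregates over samples, pass the summed length x depth product
    as ``region_length_bp`` with ``mean_dcs_depth=1``.
    """
    denom = region_length_bp * mean_dcs_depth
    if denom <= 0:
        raise ValueError("denominator must be positive")
    if n_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    return n_mutations / denom


def poisson_ci(count: int, denominator: float = 1.0, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval for a count, per unit denominator."""
    if count < 0:
        raise ValueError("count must be non-negative")
    alpha = 1.0 - level
    lo = 0.0 if count == 0 else sps.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = sps.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    return lo / denominator, hi / denominator


def fisher_compare(
    n1: int, d1: float, n2: int, d2: float, alternative: str = "two-sided"
) -> tuple[float, float, float]:
    """Fisher's exact test of two frequencies sharing count denominators.

    The 2x2 table is {mutated, unmutated} x {group1, group2} with
    unmutated = denominator - mutated.  Returns (fold change of group1
    over group2, odds ratio, p).
    """
    table = [[n1, round(d1) - n1], [n2, round(d2) - n2]]
    odds, p = sps.fisher_exact(table, alternative=alternative)
    f1 = n1 / d1
    f2 = n2 / d2
    fold = np.inf if f2 == 0 else f1 / f2
    return fold, odds, p


def observed_expected_binomial(
    observed_in_region: int,
    total_mutations: int,
    region_length: float,
    genome_length: float,
    alternative: str = "greater",
) -> float:
    """Binomial test of regional enrichment against the length fraction.

    Under a uniform mutation placement, the number of the
    `total_mutations` events falling in a region of the given length is
    Binomial(total, region/genome); the tail probability quantifies
    enrichment (``greater``) or depletion (``less``).
    """
    if region_length > genome_length:
        raise ValueError("region cannot exceed the genome")
    p = region_length / genome_length
    return sps.binomtest(observed_in_region, total_mutations, p, alternative=alternative).pvalue


def permutation_median_test(
    group_a,
    group_b,
    n_perm: int = 100_000,
    alternative: str = "a_greater",
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided permutation test on the difference of group medians.

    The statistic is median(a) - median(b); group labels are permuted.
    When the number of distinct label arrangements is at most `n_perm`
    the test enumerates all of them and returns the exact tail
    fraction; otherwise it Monte-Carlo samples with the add-one
    estimator (#{perm >= obs} + 1)/(n_perm + 1), which can never
    return zero.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative == "b_greater":
        a, b = b, a
    elif alternative != "a_greater":
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = np.median(a) - np.median(b)

    total = comb(n, na)
    if total <= n_perm:
        hits = 0
        idx_all = frozenset(range(n))
        for pick in combinations(range(n), na):
            pa = pooled[list(pick)]
            pb = pooled[list(idx_all - set(pick))]
            if np.median(pa) - np.median(pb) >= observed - 1e-12:
                hits += 1
        return hits / total

    rng = np.random.default_rng() if rng is None else rng
    hits = 0
    chunk = max(1, min(n_perm, 2_000_000 // n))
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        mat = rng.permuted(np.tile(pooled, (k, 1)), axis=1)
        stat = np.median(mat[:, :na], axis=1) - np.median(mat[:, na:], axis=1)
        hits += int((stat >= observed - 1e-12).sum())
        done += k
    return (hits + 1) / (n_perm + 1)


def adjust_fdr(p_values, method: str = "BY") -> np.ndarray:
    """False-discovery-rate adjustment (Benjamini-Yekutieli by default,
    plain Benjamini-Hochberg with ``method="BH"``)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    key = {"BY": "fdr_by", "BH": "fdr_bh"}[method.upper()]
    return multipletests(p, method=key)[1]


# ----------------------------------------------------------------------
# denominators and spectra


def sequenced_nt_by_base(
    depth_by_site: np.ndarray, genome: MtGenome, compartment: str | None = None
) -> dict[str, float]:
    """Sequenced nucleotides per reference base identity.

    ``depth_by_site`` is per-site consensus depth (0-based array over
    the genome); restricting to a compartment sums only sites with that
    label.  These are the type-capable denominators: the number of
    sequenced X bases bounds how many X>Y mutations could be seen.
    """
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    mask = np.ones(genome.length, dtype=bool)
    if compartment is not None:
        labels = np.array([genome.compartment_of(i + 1) for i in range(genome.length)])
        mask = labels == compartment
    out = {}
    for base in "ACGT":
        sel = mask & (seq == ord(base))
        out[base] = float(depth_by_site[sel].sum())
    return out


def frequency_by_group(
    records: pd.DataFrame,
    denominators: pd.DataFrame,
    group_cols: list[str],
    level: float = 0.95,
) -> pd.DataFrame:
    """Aggregate event counts and denominators by group; never averages
    frequencies.  ``denominators`` carries the same group columns plus
    ``denominator_bp`` (one row per sample contribution)."""
    n = records.groupby(group_cols)["n_events"].sum().rename("n_mutations")
    d = denominators.groupby(group_cols)["denominator_bp"].sum()
    df = pd.concat([n, d], axis=1).fillna({"n_mutations": 0}).reset_index()
    df["n_mutations"] = df["n_mutations"].astype(int)
    df["frequency"] = df["n_mutations"] / df["denominator_bp"]
    cis = [poisson_ci(k, dd, level) for k, dd in zip(df["n_mutations"], df["denominator_bp"])]
    df["ci_low"] = [c[0] for c in cis]
    df["ci_high"] = [c[1] for c in cis]
    return df


def spectrum_table(
    records: pd.DataFrame,
    nt_by_base: dict[str, float],
) -> pd.DataFrame:
    """12-type mutation counts and frequencies with type-capable denominators.

    The denominator for X>Y is the number of sequenced X nucleotides on
    the reference strand.  Includes the 6-type collapsed
    (pyrimidine-centred) label and the transition flag.
    """
    counts = records.groupby("mutation_type")["n_events"].sum()
    rows = []
    for t in MUTATION_TYPES:
        ref, alt = t.split(">")
        n = int(counts.get(t, 0))
        denom = nt_by_base[ref]
        collapsed_ref, collapsed_alt, _ = collapse_substitution(ref, alt, "N" + ref + "N")
        rows.append(
            {
                "mutation_type": t,
                "collapsed_type": f"{collapsed_ref}>{collapsed_alt}",
                "is_transition": t in TRANSITIONS,
                "n_mutations": n,
                "denominator_bp": denom,
                "frequency": n / denom if denom > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def titv_ratio(records: pd.DataFrame) -> float:
    """Transition/transversion ratio of event counts (inf if no transversions)."""
    ti = int(records.loc[records["mutation_type"].isin(TRANSITIONS), "n_events"].sum())
    tv = int(records.loc[~records["mutation_type"].isin(TRANSITIONS), "n_events"].sum())
    return np.inf if tv == 0 else ti / tv


def strand_bias_table(
    records: pd.DataFrame,
    nt_by_base: dict[str, float],
) -> pd.DataFrame:
    """Frequencies of complementary mutation types with Fisher comparison.

    For each reciprocal pair (e.g. G>A vs C>T) the two frequencies use
    type-capable denominators (sequenced G vs sequenced C bases); a
    significant difference is strand bias, since without bias and with
    symmetric base content the reciprocal types are two readings of the
    same underlying events.
    """
    spec = spectrum_table(records, nt_by_base).set_index("mutation_type")
    rows = []
    for t1, t2 in RECIPROCAL_PAIRS:
        n1, d1 = int(spec.loc[t1, "n_mutations"]), spec.loc[t1, "denominator_bp"]
        n2, d2 = int(spec.loc[t2, "n_mutations"]), spec.loc[t2, "denominator_bp"]
        fold, odds, p = fisher_compare(n1, d1, n2, d2)
        rows.append(
            {
                "type_1": t1,
                "type_2": t2,
                "n_1": n1,
                "denominator_1": d1,
                "n_2": n2,
                "denominator_2": d2,
                "frequency_1": n1 / d1,
                "frequency_2": n2 / d2,
                "fold_1_over_2": fold,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def chi2_montecarlo(
    counts_a,
    counts_b,
    n_sim: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo chi-squared test of independence between two spectra.

    Simulates tables with the observed margins (as R's chisq.test does
    with simulated p-values), which is required when expected counts
    are small.  Returns the add-one Monte-Carlo p-value.
    """
    rng = np.random.default_rng() if rng is None else rng
    obs = np.array([counts_a, counts_b], dtype=float)
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2 or obs.sum() == 0:
        return 1.0

    def stat(table: np.ndarray) -> float:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = (table - expected) ** 2 / expected
        return float(np.nansum(terms))

    s_obs = stat(obs)
    row = obs.sum(axis=1).astype(int)
    col = obs.sum(axis=0).astype(int)
    sim = sps.random_table(row, col).rvs(n_sim, random_state=rng)
    hits = sum(stat(np.asarray(t, dtype=float)) >= s_obs - 1e-12 for t in sim)
    return (hits + 1) / (n_sim + 1)
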