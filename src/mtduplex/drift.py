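"""Inherited-heteroplasmy analyses: sharing, drift, and the germline bottleneck.

Heteroplasmic allele frequencies shift between tissues and generations
by random genetic drift.  The effective germline bottleneck N — the
number of independently segregating mtDNA units that would produce the
observed variance of offspring allele frequencies around the maternal
frequency — is estimated per (individual, site) as

    N_ij = p_ij (1 - p_ij) / sigma^2_ij,

where p_ij is the mean allele frequency across the individual's two
somatic tissues and sigma^2_ij is the mean squared deviation of the
n_ij offspring (oocyte or pup) frequencies from p_ij.  The point
estimate averages the N_ij and its confidence interval resamples them
with replacement.

Because 1/sigma^2 is convex, the mean-of-N_ij estimator is biased
upward by roughly n/(n-2) for n offspring (about 1.5x at n = 6); an
optional small-sample correction multiplies each N_ij by
(n_ij - 2)/n_ij and makes the estimator approximately unbiased in
simulations.  The uncorrected form is the default for comparability
with the published estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BottleneckEntry",
    "BottleneckResult",
    "categorize_sharing",
    "maf_correlation",
    "normalized_variance",
    "select_maf_source",
    "bottleneck_estimate",
    "subsample_equal",
]


@dataclass(frozen=True)
class BottleneckEntry:
    """One (individual, site) comparison: maternal/somatic mean frequency
    and the offspring (oocyte or pup) frequencies."""

    individual: str
    site: int
    p: float
    offspring: tuple[float, ...]


@dataclass
class BottleneckResult:
    estimate: float
    n_entries: int
    n_excluded: int
    ci_low: float
    ci_high: float
    ci_level: float
    n_ij: np.ndarray
    corrected: bool
    comparison: str = ""


def categorize_sharing(
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Label each heteroplasmic site by its pedigree sharing pattern.

    ``presence`` has columns sample_id, site (one row per sample where
    the heteroplasmy was detected); metadata maps samples to
    individual, generation and pedigree.  Categories: ``pup_only``
    (detected only in pups), ``mother_and_pups`` (one mother plus pups),
    ``several_mothers`` (more than one mother).  A site seen in exactly
    one generation of mothers only is grouped with mother_and_pups or
    several_mothers by its mother count, matching how origin is
    inferred: pup-only sites arose in the maternal germline, shared
    sites in the mother or earlier.
    """
    df = presence.merge(
        metadata[["sample_id", "individual", "generation", "pedigree"]],
        on="sample_id",
        how="left",
        validate="many_to_one",
    )
    rows = []
    for site, grp in df.groupby("site"):
        mothers = set(grp.loc[grp["generation"] == "mother", "individual"])
        if len(mothers) == 0:
            cat = "pup_only"
        elif len(mothers) == 1:
            cat = "mother_and_pups"
        else:
            cat = "several_mothers"
        rows.append(
            {
                "site": site,
                "category": cat,
                "n_mothers": len(mothers),
                "n_pups": grp.loc[grp["generation"] == "pup", "individual"].nunique(),
                "pedigree": grp["pedigree"].iloc[0],
            }
        )
    return pd.DataFrame(rows)


def maf_correlation(x, y) -> float:
    """Squared Pearson correlation of paired untransformed frequencies."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def normalized_variance(values, p: float) -> float:
    """Population variance of frequencies divided by p(1-p).

    p is the average allele frequency of the unit being compared
    (across single oocytes, or between the two somatic tissues); under
    a binomial bottleneck of N units the expectation is 1/N.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be inside (0, 1)")
    return float(np.mean((v - v.mean()) ** 2) / (p * (1 - p)))


def select_maf_source(
    dcs_minor_depth: int, dcs_maf: float, sscs_maf: float, min_dcs: int = 5
) -> tuple[float, str]:
    """DCS frequency when the minor allele has enough DCS molecules
    (strictly fewer than `min_dcs` switches to the SSCS frequency)."""
    if dcs_minor_depth < min_dcs:
        return sscs_maf, "SSCS"
    return dcs_maf, "DCS"


def bottleneck_estimate(
    entries: list[BottleneckEntry],
    n_boot: int = 1000,
    ci_level: float = 0.95,
    rng: np.random.Generator | None = None,
    small_sample_correction: bool = False,
    comparison: str = "",
) -> BottleneckResult:
    """Effective bottleneck size from allele-frequency comparisons.

    Entries with p outside (0, 1) or with zero offspring variance are
    excluded (they would yield undefined or infinite N_ij) and counted.
    The percentile bootstrap resamples the N_ij values with replacement
    `n_boot` times.  ``small_sample_correction`` applies the
    (n_ij - 2)/n_ij de-biasing factor (entries with n_ij <= 2 are then
    excluded as uninformative for the corrected form).
    """
    rng = np.random.default_rng() if rng is None else rng
    n_ij = []
    excluded = 0
    for e in entries:
        off = np.asarray(e.offspring, dtype=float)
        if off.size < 1 or not 0.0 < e.p < 1.0:
            excluded += 1
            continue
        sigma2 = float(np.mean((off - e.p) ** 2))
        if sigma2 == 0.0:
            excluded += 1
            continue
        value = e.p * (1 - e.p) / sigma2
        if small_sample_correction:
            if off.size <= 2:
                excluded += 1
                continue
            value *= (off.size - 2) / off.size
        n_ij.append(value)
    n_ij = np.asarray(n_ij)
    if n_ij.size == 0:
        raise ValueError("no usable entries for bottleneck estimation")
    estimate = float(n_ij.mean())
    idx = rng.integers(n_ij.size, size=(n_boot, n_ij.size))
    boots = n_ij[idx].mean(axis=1)
    alpha = (1 - ci_level) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return BottleneckResult(
        estimate=estimate,
        n_entries=int(n_ij.size),
        n_excluded=excluded,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_ij=n_ij,
        corrected=small_sample_correction,
        comparison=comparison,
    )


def subsample_equal(
    groups: dict[str, list],
    n: int,
    n_repeats: int = 10,
    rng: np.random.Generator | None = None,
) -> list[dict[str, list]]:
    """Repeatedly subsample each group down to n elements (seeded).

    Report helper for comparisons requiring equal group sizes; callers
    average the statistic over the repeats.
    """
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for _ in range(n_repeats):
        out.append(
            {
                k: [v[i] for i in rng.choice(len(v), size=min(n, len(v)), replace=False)]
                for k, v in groups.items()
            }
        )
    return out
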