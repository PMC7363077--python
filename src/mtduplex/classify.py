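"""Classification of variant calls across tissues and pedigree members.

A variant call is assigned exactly one class:

* ``inherited`` — present in both somatic and germline tissues of one
  individual, or in two generations of a pedigree: a segregating
  heteroplasmy, not a tissue-specific event.
* ``early_somatic`` — present in both somatic tissues of an individual
  but absent from its oocytes: a mutation fixed early in somatic
  development, before germ-layer separation.
* ``de_novo_tissue_specific`` — everything else that survives the
  exclusion filters below; these are the putative tissue-specific de
  novo mutations.
* ``excluded_recurrent`` — the same substitution called as a candidate
  in more than `max_recurrent` samples dataset-wide: a mutational hot
  spot or a low-frequency segregating variant, indistinguishable from
  each other and therefore removed.
* ``excluded_fragmentation_artifact`` — A>T/T>A calls in enzymatically
  fragmented samples, a known false-positive class of that chemistry.
* ``excluded_listed`` — positions on a user-supplied exclusion list
  (hook for nuclear-mitochondrial paralog or contamination screens).

Each surviving record counts as a single mutation event per sample
regardless of how many molecules carry it (multi-molecule observations
are assumed to descend from one event); molecule support is retained
for reporting.
"""

from __future__ import annotations

import pandas as pd

from .mtgenome import MtGenome
from .simulate import PedigreeSpec

__all__ = [
    "classify_variants",
    "filter_recurrent",
    "collapse_multimolecule",
    "filter_artifacts",
    "annotate",
    "classify_pipeline",
]

SOMATIC_TISSUES = ("brain", "muscle")
GERMLINE_TISSUES = ("single_oocyte", "oocyte_pool")

CLASSES = (
    "de_novo_tissue_specific",
    "early_somatic",
    "inherited",
    "excluded_recurrent",
    "excluded_fragmentation_artifact",
    "excluded_listed",
)


def _require_metadata(calls: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    missing = set(calls["sample_id"]) - set(metadata["sample_id"])
    if missing:
        raise KeyError(f"samples without metadata: {sorted(missing)[:5]}")
    cols = ["sample_id", "individual", "pedigree", "generation", "tissue", "fragmentation"]
    return calls.merge(metadata[cols], on="sample_id", how="left", validate="many_to_one")


def classify_variants(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    pedigree: PedigreeSpec,
) -> pd.DataFrame:
    """Assign the base class (inherited / early_somatic / de novo candidate).

    Presence is keyed on (position, alt).  Germline presence for an
    individual means presence in any of its single oocytes or its
    oocyte pool.  Early-somatic detection needs both somatic tissues
    assayed and oocytes sampled; an individual missing either cannot
    produce that class.
    """
    df = _require_metadata(calls, metadata)
    df["is_germline"] = df["tissue"].isin(GERMLINE_TISSUES)

    key = ["position", "alt"]
    per_ind = (
        df.groupby(key + ["individual"])
        .agg(
            somatic_tissues=("tissue", lambda t: len(set(t) & set(SOMATIC_TISSUES))),
            in_germline=("is_germline", "any"),
            generation=("generation", "first"),
            pedigree=("pedigree", "first"),
        )
        .reset_index()
    )
    ind_oocytes = {
        ind.id: (ind.n_single_oocytes > 0 or ind.oocyte_pool_size > 0)
        for ind in pedigree.individuals
    }

    # inherited within an individual: somatic AND germline presence
    per_ind["inherited_within"] = (per_ind["somatic_tissues"] > 0) & per_ind["in_germline"]
    # inherited across generations: same substitution in a mother and in
    # any pup of the same pedigree
    gens = (
        per_ind.groupby(key + ["pedigree"])["generation"]
        .agg(lambda g: len(set(g)))
        .rename("n_generations")
        .reset_index()
    )
    per_ind = per_ind.merge(gens, on=key + ["pedigree"], how="left")
    per_ind["inherited_any"] = per_ind["inherited_within"] | (per_ind["n_generations"] >= 2)
    per_ind["early_somatic"] = (
        ~per_ind["inherited_any"]
        & (per_ind["somatic_tissues"] == 2)
        & ~per_ind["in_germline"]
        & per_ind["individual"].map(ind_oocytes).fillna(False)
    )

    variant_inherited = per_ind.groupby(key)["inherited_any"].any().rename("site_inherited")
    df = df.merge(variant_inherited, on=key, how="left")
    df = df.merge(
        per_ind[key + ["individual", "early_somatic"]],
        on=key + ["individual"],
        how="left",
    )
    df["class"] = "de_novo_tissue_specific"
    df.loc[df["early_somatic"].fillna(False).astype(bool), "class"] = "early_somatic"
    df.loc[df["site_inherited"].fillna(False).astype(bool), "class"] = "inherited"
    return df.drop(columns=["is_germline", "site_inherited", "early_somatic"])


def filter_recurrent(records: pd.DataFrame, max_samples: int = 3) -> pd.DataFrame:
    """Exclude candidate substitutions recurring in too many samples.

    A (position, alt) called as a de novo candidate in more than
    `max_samples` samples across the whole dataset (both pedigrees) is
    reclassified ``excluded_recurrent``; up to `max_samples` recurrences
    are expected by chance at these mutation frequencies and are kept.
    """
    records = records.copy()
    cand = records["class"] == "de_novo_tissue_specific"
    n_samples = (
        records[cand]
        .groupby(["position", "alt"])["sample_id"]
        .nunique()
        .rename("n_samples_with_candidate")
    )
    records = records.merge(n_samples, on=["position", "alt"], how="left")
    hot = cand & (records["n_samples_with_candidate"] > max_samples)
    records.loc[hot, "class"] = "excluded_recurrent"
    return records.drop(columns=["n_samples_with_candidate"])


def collapse_multimolecule(records: pd.DataFrame) -> pd.DataFrame:
    """One mutation event per (sample, position, alt).

    Multiple supporting molecules are assumed to descend from a single
    mutation event; support is kept in ``n_supporting_dcs``.  Two
    different alternate bases at one site in one sample remain two
    events.
    """
    records = records.copy()
    records["n_events"] = 1
    if "dcs_alt_count" in records.columns:
        records["n_supporting_dcs"] = records["dcs_alt_count"]
    return records


def filter_artifacts(
    records: pd.DataFrame,
    exclusion_sites: list[int] | None = None,
) -> pd.DataFrame:
    """Flag fragmentation-chemistry artifacts and excluded sites.

    A>T and T>A candidate calls in enzymatically fragmented samples are
    false positives of that library chemistry and are flagged; calls at
    listed positions are flagged ``excluded_listed`` (a hook replacing
    sequence-similarity screens for nuclear paralogs/contamination).
    """
    records = records.copy()
    cand = records["class"] == "de_novo_tissue_specific"
    at_ta = (records["ref"] + ">" + records["alt"]).isin(["A>T", "T>A"])
    enz = records["fragmentation"] == "enzymatic"
    records.loc[cand & at_ta & enz, "class"] = "excluded_fragmentation_artifact"
    if exclusion_sites:
        listed = records["position"].isin(set(exclusion_sites))
        records.loc[listed, "class"] = "excluded_listed"
    return records


def annotate(records: pd.DataFrame, genome: MtGenome) -> pd.DataFrame:
    """Add mutation type, transition flag, compartment, context and CpG."""
    records = records.copy()
    records["mutation_type"] = records["ref"] + ">" + records["alt"]
    transitions = {"A>G", "G>A", "C>T", "T>C"}
    records["is_transition"] = records["mutation_type"].isin(transitions)
    records["compartment"] = records["position"].map(genome.compartment_of)
    ctx = records["position"].map(lambda p: genome.context_of(int(p), "L"))
    records["context"] = ctx.map(lambda t: t[0])
    records["cpg"] = ctx.map(lambda t: t[1])
    return records


def classify_pipeline(
    calls: pd.DataFrame,
    metadata: pd.DataFrame,
    pedigree: PedigreeSpec,
    genome: MtGenome,
    max_recurrent: int = 3,
    exclusion_sites: list[int] | None = None,
) -> pd.DataFrame:
    """Full classification chain; a partition of the input calls.

    Output retains one row per input (sample, position, alt) with a
    single class label, plus annotation columns.  The result is
    independent of input row order.
    """
    df = classify_variants(calls, metadata, pedigree)
    df = filter_recurrent(df, max_samples=max_recurrent)
    df = collapse_multimolecule(df)
    df = filter_artifacts(df, exclusion_sites)
    df = annotate(df, genome)
    return df.sort_values(["sample_id", "position", "alt"]).reset_index(drop=True)
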