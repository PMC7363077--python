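"""Mutation classification: class assignment, recurrence, artifacts."""

import numpy as np
import pandas as pd
import pytest

from mtduplex.classify import (
    CLASSES,
    classify_pipeline,
    classify_variants,
    collapse_multimolecule,
    filter_artifacts,
    filter_recurrent,
)
from mtduplex.simulate import Individual, PedigreeSpec


@pytest.fixture
def pedigree():
    return PedigreeSpec(
        [
            Individual("M1", "A", "mother", "F", None, n_single_oocytes=2, oocyte_pool_size=8),
            Individual("P1", "A", "pup", "F", "M1", n_single_oocytes=2, oocyte_pool_size=8),
            Individual("P2", "A", "pup", "M", "M1"),
            Individual("P3", "A", "pup", "M", "M1"),
            Individual("P4", "A", "pup", "M", "M1"),
        ]
    )


@pytest.fixture
def metadata(pedigree):
    rows = []
    for ind in pedigree.individuals:
        tissues = ["brain", "muscle"]
        if ind.n_single_oocytes:
            tissues += ["single_oocyte", "oocyte_pool"]
        for t in tissues:
            rows.append(
                {
                    "sample_id": f"{ind.id}|{t}",
                    "individual": ind.id,
                    "pedigree": ind.pedigree,
                    "generation": ind.generation,
                    "tissue": t,
                    "fragmentation": "enzymatic" if t == "single_oocyte" else "covaris",
                }
            )
    return pd.DataFrame(rows)


def call(sample, pos, ref, alt, dcs=1):
    return {
        "sample_id": sample,
        "position": pos,
        "ref": ref,
        "alt": alt,
        "dcs_alt_count": dcs,
        "maf": 0.01,
        "maf_source": "DCS",
    }


class TestBaseClasses:
    def test_somatic_plus_germline_of_pup_absent_from_mother_is_inherited(
        self, metadata, pedigree
    ):
        calls = pd.DataFrame(
            [
                call("P1|brain", 100, "A", "G"),
                call("P1|muscle", 100, "A", "G"),
                call("P1|single_oocyte", 100, "A", "G"),
            ]
        )
        out = classify_variants(calls, metadata, pedigree)
        assert (out["class"] == "inherited").all()

    def test_two_generations_is_inherited_even_without_oocytes(self, metadata, pedigree):
        calls = pd.DataFrame([call("M1|brain", 100, "A", "G"), call("P2|brain", 100, "A", "G")])
        out = classify_variants(calls, metadata, pedigree)
        assert (out["class"] == "inherited").all()

    def test_both_somatic_without_oocytes_is_early_somatic(self, metadata, pedigree):
        calls = pd.DataFrame([call("P1|brain", 200, "C", "T"), call("P1|muscle", 200, "C", "T")])
        out = classify_variants(calls, metadata, pedigree)
        assert (out["class"] == "early_somatic").all()

    def test_early_somatic_requires_oocytes_assayed(self, metadata, pedigree):
        # P2 is male: both somatic tissues, no oocytes to check -> cannot
        # distinguish early somatic from inherited; stays a candidate
        calls = pd.DataFrame([call("P2|brain", 200, "C", "T"), call("P2|muscle", 200, "C", "T")])
        out = classify_variants(calls, metadata, pedigree)
        assert (out["class"] == "de_novo_tissue_specific").all()

    def test_single_tissue_variant_is_de_novo_candidate(self, metadata, pedigree):
        calls = pd.DataFrame([call("M1|brain", 300, "G", "A")])
        out = classify_variants(calls, metadata, pedigree)
        assert out.loc[0, "class"] == "de_novo_tissue_specific"

    def test_sample_without_metadata_is_an_error(self, metadata, pedigree):
        calls = pd.DataFrame([call("ghost|brain", 300, "G", "A")])
        with pytest.raises(KeyError):
            classify_variants(calls, metadata, pedigree)


class TestFilters:
    def test_recurrence_in_four_samples_excluded_three_kept(self, metadata, pedigree):
        # same-generation samples so the two-generation inheritance rule
        # does not fire first
        calls = pd.DataFrame(
            [call(s, 400, "G", "T") for s in ("P1|brain", "P2|brain", "P3|brain", "P4|brain")]
            + [call(s, 500, "G", "T") for s in ("P1|brain", "P2|brain", "P3|brain")]
        )
        out = classify_variants(calls, metadata, pedigree)
        out = filter_recurrent(out, max_samples=3)
        at400 = out[out["position"] == 400]
        at500 = out[out["position"] == 500]
        assert (at400["class"] == "excluded_recurrent").all()
        assert (at500["class"] == "de_novo_tissue_specific").all()

    def test_recurrence_keyed_on_site_and_alt(self, metadata, pedigree):
        # four samples at one site but with two different alt bases: two
        # independent events, neither recurrent beyond the cutoff of 3
        calls = pd.DataFrame(
            [call(s, 600, "G", "T") for s in ("P1|brain", "P2|brain")]
            + [call(s, 600, "G", "A") for s in ("P3|brain", "P4|brain")]
        )
        out = filter_recurrent(classify_variants(calls, metadata, pedigree), max_samples=3)
        assert (out["class"] == "de_novo_tissue_specific").all()

    def test_multimolecule_support_collapses_to_one_event(self, metadata, pedigree):
        calls = pd.DataFrame([call("M1|brain", 700, "A", "C", dcs=5)])
        out = collapse_multimolecule(classify_variants(calls, metadata, pedigree))
        assert out.loc[0, "n_events"] == 1
        assert out.loc[0, "n_supporting_dcs"] == 5

    def test_two_alts_at_one_site_are_two_events(self, metadata, pedigree):
        calls = pd.DataFrame(
            [call("M1|brain", 700, "A", "C", dcs=2), call("M1|brain", 700, "A", "G", dcs=1)]
        )
        out = collapse_multimolecule(classify_variants(calls, metadata, pedigree))
        assert out["n_events"].sum() == 2

    def test_at_ta_in_enzymatic_sample_flagged_covaris_kept(self, metadata, pedigree):
        calls = pd.DataFrame(
            [call("P1|single_oocyte", 800, "T", "A"), call("M1|muscle", 900, "T", "A")]
        )
        out = filter_artifacts(classify_variants(calls, metadata, pedigree))
        assert out.loc[out["position"] == 800, "class"].iloc[0] == "excluded_fragmentation_artifact"
        assert out.loc[out["position"] == 900, "class"].iloc[0] == "de_novo_tissue_specific"

    def test_exclusion_list_overrides(self, metadata, pedigree):
        calls = pd.DataFrame([call("M1|brain", 950, "G", "A")])
        out = filter_artifacts(classify_variants(calls, metadata, pedigree), exclusion_sites=[950])
        assert out.loc[0, "class"] == "excluded_listed"


class TestPipelineProperties:
    def make_calls(self, rng, genome, n=60):
        samples = [
            "M1|brain",
            "M1|muscle",
            "M1|single_oocyte",
            "P1|brain",
            "P1|muscle",
            "P2|brain",
        ]
        rows = []
        for _ in range(n):
            pos = int(rng.integers(1, genome.length + 1))
            ref = genome.base(pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append(call(str(rng.choice(samples)), pos, ref, alt, dcs=int(rng.integers(1, 4))))
        return pd.DataFrame(rows).drop_duplicates(["sample_id", "position", "alt"])

    def test_classification_is_a_partition(self, metadata, pedigree, genome, rng):
        calls = self.make_calls(rng, genome)
        out = classify_pipeline(calls, metadata, pedigree, genome)
        assert len(out) == len(calls)
        assert set(out["class"]) <= set(CLASSES)
        key = ["sample_id", "position", "alt"]
        assert out[key].sort_values(key).reset_index(drop=True).equals(
            calls[key].sort_values(key).reset_index(drop=True)
        )

    def test_order_independence(self, metadata, pedigree, genome, rng):
        calls = self.make_calls(rng, genome)
        out1 = classify_pipeline(calls, metadata, pedigree, genome)
        shuffled = calls.sample(frac=1.0, random_state=7).reset_index(drop=True)
        out2 = classify_pipeline(shuffled, metadata, pedigree, genome)
        pd.testing.assert_frame_equal(out1, out2)

    def test_annotation_columns_are_consistent(self, metadata, pedigree, genome, rng):
        out = classify_pipeline(self.make_calls(rng, genome), metadata, pedigree, genome)
        assert (out["mutation_type"] == out["ref"] + ">" + out["alt"]).all()
        assert set(out["compartment"]) <= {
            "D-loop",
            "protein-coding",
            "tRNA",
            "rRNA",
            "noncoding",
        }
        # context centre base must equal the reference base
        assert (out["context"].str[1] == out["ref"]).all()
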