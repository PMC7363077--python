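"""Shared fixtures: the toy genome and two reusable simulation runs.

The session-scoped pipeline runs are the expensive fixtures; every test
that needs realistic calls shares them instead of re-simulating.
"""

from __future__ import annotations

import numpy as np
import pytest

from mtduplex.pipeline import run_all, run_calling, run_classification
from mtduplex.references import toy_genome
from mtduplex.simulate import Individual, PedigreeSpec, SimConfig, default_pedigree


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_pedigree() -> PedigreeSpec:
    """Two pedigrees, 2 mothers + 3 pups each; oocytes for females."""
    inds = []
    for ped in ("A", "B"):
        for m in range(2):
            mid = f"{ped}-M{m + 1}"
            inds.append(
                Individual(mid, ped, "mother", "F", None, n_single_oocytes=3, oocyte_pool_size=10)
            )
            for p in range(3):
                sex = "F" if p < 2 else "M"
                inds.append(
                    Individual(
                        f"{ped}-P{m + 1}{p + 1}",
                        ped,
                        "pup",
                        sex,
                        mid,
                        n_single_oocytes=3 if sex == "F" else 0,
                        oocyte_pool_size=10 if sex == "F" else 0,
                    )
                )
    return PedigreeSpec(inds)


@pytest.fixture(scope="session")
def small_config(genome):
    """All-tissue configuration at reduced depth with rates scaled up by
    the same factor, preserving expected mutation counts per cell."""
    return SimConfig(
        seed=11,
        genome=genome,
        pedigree=small_pedigree(),
        depth={"brain": 30.0, "muscle": 30.0, "single_oocyte": 15.0, "oocyte_pool": 25.0},
        rate_scale=60.0,
        n_heteroplasmies=12,
        sharing_counts=(6, 4, 2),
    )


@pytest.fixture(scope="session")
def small_run(small_config, tmp_path_factory):
    """Full pipeline on the small all-tissue configuration."""
    outdir = tmp_path_factory.mktemp("small_run")
    return run_all(small_config, outdir, n_perm=5000, progress=False)


@pytest.fixture(scope="session")
def e2e_config(genome):
    """Study-sized pedigree (8 mothers, 28 pups), brain and oocyte pools
    only, at scaled depth; the planted age effects are the study's
    tissue-specific rate ratios (2.6x in brain, 1.5x in pools)."""
    return SimConfig(
        seed=29,
        genome=genome,
        pedigree=default_pedigree(),
        depth={"brain": 40.0, "muscle": 40.0, "single_oocyte": 20.0, "oocyte_pool": 75.0},
        rate_scale=60.0,
    )


@pytest.fixture(scope="session")
def e2e_run(e2e_config, tmp_path_factory):
    """Brain + oocyte-pool pipeline run at study pedigree size."""
    from mtduplex.simulate import simulate_pedigree

    truth = simulate_pedigree(e2e_config)
    keep = truth.samples.loc[
        truth.samples["tissue"].isin(["brain", "oocyte_pool"]), "sample_id"
    ].tolist()
    result = run_calling(e2e_config, truth, keep, progress=False)
    run_classification(result, e2e_config)
    return result
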