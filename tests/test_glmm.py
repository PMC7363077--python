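"""Binomial mixed model: cell construction, GLM boundary, pseudo-R^2."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from mtduplex.glmm import (
    BASELINES,
    LEVELS,
    build_cells,
    design_matrix,
    fit_glmm,
    likelihood_ratio_tests,
    pseudo_r2,
)


def simulate_cells(
    rng,
    n_individuals=30,
    sigma_u=0.3,
    beta=None,
    w_range=(300_000, 2_000_000),
):
    beta = beta or {
        "(Intercept)": -13.0,
        "age[pup]": -1.0,
        "tissue[muscle]": 0.1,
        "compartment[non-D-loop]": -1.0,
        "mutation_class[AG_TC]": 0.5,
        "mutation_class[CT_GA]": 1.0,
    }
    rows = []
    for i in range(n_individuals):
        age = "mother" if i < n_individuals // 4 else "pup"
        u = rng.normal(0, sigma_u)
        for tissue in ("brain", "muscle"):
            for comp in ("D-loop", "non-D-loop"):
                for mc in ("transversion", "AG_TC", "CT_GA"):
                    eta = beta["(Intercept)"] + u
                    eta += beta["age[pup]"] * (age == "pup")
                    eta += beta["tissue[muscle]"] * (tissue == "muscle")
                    eta += beta["compartment[non-D-loop]"] * (comp == "non-D-loop")
                    eta += beta.get(f"mutation_class[{mc}]", 0.0) * (mc != "transversion")
                    w = int(rng.integers(*w_range))
                    rows.append(
                        {
                            "individual": f"I{i}",
                            "age": age,
                            "tissue": tissue,
                            "compartment": comp,
                            "mutation_class": mc,
                            "k": rng.binomial(w, special.expit(eta)),
                            "w": w,
                        }
                    )
    return pd.DataFrame(rows)


class TestBuildCells:
    @staticmethod
    def inputs():
        metadata = pd.DataFrame(
            [
                {"sample_id": "M1|brain", "individual": "M1", "generation": "mother", "tissue": "brain"},
                {"sample_id": "M1|single_oocyte#1", "individual": "M1", "generation": "mother", "tissue": "single_oocyte"},
                {"sample_id": "M1|single_oocyte#2", "individual": "M1", "generation": "mother", "tissue": "single_oocyte"},
            ]
        )
        nt_rows = []
        for sid, scale in [("M1|brain", 1.0), ("M1|single_oocyte#1", 0.4), ("M1|single_oocyte#2", 0.6)]:
            for comp in ("D-loop", "non-D-loop"):
                for base in "ACGT":
                    nt_rows.append(
                        {"sample_id": sid, "compartment": comp, "base": base, "nt": 150_000 * scale}
                    )
        records = pd.DataFrame(
            [
                {"sample_id": "M1|brain", "position": 10, "mutation_type": "C>T", "compartment": "D-loop", "n_events": 1},
                {"sample_id": "M1|single_oocyte#1", "position": 20, "mutation_type": "A>G", "compartment": "protein-coding", "n_events": 1},
                {"sample_id": "M1|single_oocyte#2", "position": 30, "mutation_type": "T>C", "compartment": "rRNA", "n_events": 1},
            ]
        )
        return records, pd.DataFrame(nt_rows), metadata

    def test_single_oocytes_combine_per_individual(self):
        records, nt, metadata = self.inputs()
        cells = build_cells(records, nt, metadata, min_nt=100_000)
        oo = cells[cells["tissue"] == "single_oocyte"]
        # the two oocytes of M1 merged: AG_TC outside D-loop has both events
        row = oo[(oo["compartment"] == "non-D-loop") & (oo["mutation_class"] == "AG_TC")]
        assert len(row) == 1
        assert row["k"].iloc[0] == 2
        # A + T bases summed over the two oocytes
        assert row["w"].iloc[0] == pytest.approx(2 * 150_000 * (0.4 + 0.6))

    def test_low_denominator_cells_dropped(self):
        records, nt, metadata = self.inputs()
        cells = build_cells(records, nt, metadata, min_nt=10_000_000)
        assert cells.empty

    def test_type_capable_denominators(self):
        records, nt, metadata = self.inputs()
        cells = build_cells(records, nt, metadata, min_nt=1.0)
        brain_dloop = cells[(cells["tissue"] == "brain") & (cells["compartment"] == "D-loop")]
        by_class = brain_dloop.set_index("mutation_class")["w"]
        # AG_TC sees A+T bases, CT_GA sees C+G, transversions see all four
        assert by_class["AG_TC"] == pytest.approx(300_000)
        assert by_class["CT_GA"] == pytest.approx(300_000)
        assert by_class["transversion"] == pytest.approx(600_000)


class TestDesign:
    def test_baselines_are_absorbed_into_intercept(self, rng):
        cells = simulate_cells(rng, n_individuals=4)
        X, names = design_matrix(cells)
        assert names[0] == "(Intercept)"
        for var, baseline in BASELINES.items():
            assert f"{var}[{baseline}]" not in names

    def test_aliased_design_rejected(self, rng):
        cells = simulate_cells(rng, n_individuals=4)
        # make tissue perfectly confounded with age
        cells["tissue"] = np.where(cells["age"] == "pup", "muscle", "brain")
        with pytest.raises(ValueError, match="rank deficient"):
            design_matrix(cells)

    def test_interactions_add_products(self, rng):
        cells = simulate_cells(rng, n_individuals=4)
        X0, n0 = design_matrix(cells)
        X1, n1 = design_matrix(cells, include_interactions=True)
        assert len(n1) > len(n0)
        assert any(":" in n for n in n1)


class TestFit:
    def test_sigma_zero_matches_weighted_glm_oracle(self, rng):
        import statsmodels.api as sm

        cells = simulate_cells(rng, n_individuals=10, sigma_u=0.0)
        fit = fit_glmm(cells, random_effect=False)
        X, _ = design_matrix(cells)
        oracle = sm.GLM(
            np.column_stack([cells["k"], cells["w"] - cells["k"]]),
            X,
            family=sm.families.Binomial(),
        ).fit()
        assert np.abs(fit.beta - oracle.params).max() < 1e-4
        assert fit.loglik == pytest.approx(oracle.llf, abs=1e-4)

    def test_zero_between_individual_variance_degenerates(self, rng):
        cells = simulate_cells(rng, n_individuals=48, sigma_u=0.0)
        fit = fit_glmm(cells)
        assert fit.sigma2 < 0.03
        assert fit.conditional_r2 == pytest.approx(fit.marginal_r2, abs=0.008)

    def test_conditional_at_least_marginal(self, rng):
        cells = simulate_cells(rng, n_individuals=24, sigma_u=0.5)
        fit = fit_glmm(cells)
        assert fit.conditional_r2 >= fit.marginal_r2
        assert fit.sigma2 > 0.05

    def test_interaction_model_nests_main_effects(self, rng):
        cells = simulate_cells(rng, n_individuals=12)
        main = fit_glmm(cells)
        inter = fit_glmm(cells, include_interactions=True)
        assert inter.loglik >= main.loglik - 1e-6

    def test_lrt_table_detects_true_effects(self, rng):
        cells = simulate_cells(rng, n_individuals=24, sigma_u=0.2)
        fit = fit_glmm(cells)
        tests = likelihood_ratio_tests(cells, fit).set_index("term")
        assert tests.loc["age", "p_value"] < 1e-4
        assert tests.loc["compartment", "p_value"] < 1e-4
        assert (tests["lrt_chi2"] >= 0).all()
        # partial R^2 of strong predictors is positive
        assert tests.loc["compartment", "partial_pseudo_r2"] > 0


class TestPseudoR2:
    def test_partial_formula_hand_computed(self):
        # ((1 - 0.1) - (1 - 0.2282)) / (1 - 0.1) = 0.14244...
        assert pseudo_r2(0.2282, 0.1) == pytest.approx(0.14244, abs=1e-4)

    def test_removing_null_variable_gives_near_zero_partial(self, rng):
        beta = {
            "(Intercept)": -13.0,
            "age[pup]": -1.0,
            "tissue[muscle]": 0.0,  # tissue truly has no effect
            "compartment[non-D-loop]": -1.0,
            "mutation_class[AG_TC]": 0.5,
            "mutation_class[CT_GA]": 1.0,
        }
        cells = simulate_cells(rng, n_individuals=24, sigma_u=0.1, beta=beta)
        fit = fit_glmm(cells)
        tests = likelihood_ratio_tests(cells, fit).set_index("term")
        assert abs(tests.loc["tissue", "partial_pseudo_r2"]) < 0.01
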