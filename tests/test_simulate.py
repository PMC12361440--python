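"""Tests of the synthetic study generator: cohorts, layers, fractions, balance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from interomics import (
    CommunitySpec,
    CompositionShift,
    GaEffect,
    GroundTruth,
    LayerSpec,
    SignatureSpec,
    clr_transform,
    describe_cohort,
    generate_cohort,
    generate_fractions,
    generate_layers,
    loading_for_correlation,
)
from interomics.network import spearman
from interomics.simulate import analyte_id, default_ground_truth, default_layer_specs


class TestGenerateCohort:
    def test_default_sizes_give_321_samples(self):
        cohort = generate_cohort(seed=0)
        assert len(cohort) == 321
        assert cohort["condition"].value_counts().to_dict() == {
            "Control": 113, "PE": 71, "PTD": 71, "FGR": 36, "FGR+HDP": 30,
        }

    def test_single_sample_cohort(self):
        cohort = generate_cohort({"Control": 1}, seed=0)
        assert len(cohort) == 1
        assert cohort["condition"].iloc[0] == "Control"

    def test_same_seed_identical(self):
        a = generate_cohort(seed=5)
        b = generate_cohort(seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(seed=6)
        assert not a["ga_weeks"].equals(c["ga_weeks"])

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            generate_cohort({"Kontrol": 10})

    def test_invariants(self):
        cohort = generate_cohort(seed=3)
        assert cohort.index.is_unique
        assert cohort.notna().all().all()
        assert cohort["ga_weeks"].between(23, 42).all()
        # preterm groups deliver earlier than controls
        med = cohort.groupby("condition")["ga_weeks"].median()
        assert med["PTD"] < med["Control"]
        assert med["FGR+HDP"] < med["Control"]

    @pytest.mark.parametrize("bad", [{"Control": 0}, {"Control": -3}])
    def test_nonpositive_sizes_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_cohort(bad)


class TestGenerateLayers:
    def _specs(self):
        return [
            LayerSpec("metabolites", "abundance", 6, baseline_mean=10.0),
            LayerSpec("mrna", "counts", 6, baseline_mean=7.0),
        ]

    def test_noiseless_ga_slope_recovered_exactly(self):
        cohort = generate_cohort({"Control": 30, "PTD": 30}, seed=1)
        truth = GroundTruth(ga_effects=[GaEffect("metabolites", analyte_id("metabolites", 0), "both", 0.5)])
        layers, _ = generate_layers(cohort, truth, self._specs(), noise_sd=0.0, seed=2)
        y = layers[0].values[analyte_id("metabolites", 0)].to_numpy()
        ga = cohort["ga_weeks"].to_numpy()
        slope = np.polyfit(ga, y, 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-10)

    def test_zero_loading_plants_no_correlation(self):
        cohort = generate_cohort({"Control": 60}, seed=1)
        members = [("metabolites", analyte_id("metabolites", 0)), ("mrna", analyte_id("mrna", 0))]
        truth = GroundTruth(communities=[CommunitySpec("Control", members, members[0], 0.0)])
        layers, _ = generate_layers(cohort, truth, self._specs(), noise_sd=0.5, seed=2)
        rho, _ = spearman(
            layers[0].values[analyte_id("metabolites", 0)].to_numpy(),
            np.log(layers[1].values[analyte_id("mrna", 0)].to_numpy() + 1),
        )
        assert abs(rho) < 0.3

    def test_member_spearman_matches_latent_factor_target(self):
        """Monte-Carlo: loading for rho=0.8 gives mean pairwise Spearman ~0.8."""
        loading = loading_for_correlation(0.8, noise_sd=0.5)
        members = [("metabolites", analyte_id("metabolites", 0)), ("mrna", analyte_id("mrna", 0))]
        rhos = []
        for rep in range(200):
            cohort = generate_cohort({"Control": 30}, seed=rep)
            truth = GroundTruth(
                communities=[CommunitySpec("Control", members, members[0], loading)]
            )
            layers, _ = generate_layers(cohort, truth, self._specs(), noise_sd=0.5, seed=rep + 1000)
            rho, _ = spearman(
                layers[0].values[analyte_id("metabolites", 0)].to_numpy(),
                layers[1].values[analyte_id("mrna", 0)].to_numpy(),
            )
            rhos.append(rho)
        assert abs(np.mean(rhos) - 0.8) < 0.1

    def test_signature_log2fc_planted_on_count_means(self):
        cohort = generate_cohort({"Control": 150, "FGR+HDP": 150}, seed=3)
        members = [("mrna", analyte_id("mrna", k)) for k in range(3)]
        truth = GroundTruth(
            communities=[CommunitySpec("FGR+HDP", members, members[0], 0.0)],
            signature=SignatureSpec("FGR+HDP", members, log2fc=1.5),
        )
        layers, _ = generate_layers(cohort, truth, self._specs(), noise_sd=0.3, seed=4)
        vals = layers[1].values
        in_cond = cohort["condition"] == "FGR+HDP"
        lfc = np.log2(vals.loc[in_cond].mean() / vals.loc[~in_cond].mean())
        assert np.allclose(lfc[[analyte_id("mrna", k) for k in range(3)]], 1.5, atol=0.35)

    def test_signature_outside_community_rejected(self):
        cohort = generate_cohort({"Control": 10}, seed=0)
        truth = GroundTruth(
            signature=SignatureSpec("Control", [("mrna", analyte_id("mrna", 0))], 1.0)
        )
        with pytest.raises(ValueError, match="subset of one planted community"):
            generate_layers(cohort, truth, self._specs(), seed=0)

    def test_counts_are_nonnegative_integers(self):
        cohort = generate_cohort({"Control": 20}, seed=0)
        layers, _ = generate_layers(cohort, GroundTruth(), self._specs(), noise_sd=0.5, seed=0)
        counts = layers[1].values.to_numpy()
        assert (counts >= 0).all()
        assert np.allclose(counts, np.round(counts))

    def test_determinism(self):
        cohort = generate_cohort({"Control": 15}, seed=0)
        a, _ = generate_layers(cohort, GroundTruth(), self._specs(), seed=9)
        b, _ = generate_layers(cohort, GroundTruth(), self._specs(), seed=9)
        for la, lb in zip(a, b):
            pd.testing.assert_frame_equal(la.values, lb.values)

    def test_default_ground_truth_nests_signature_in_community(self):
        specs = default_layer_specs(0.12)
        truth = default_ground_truth(specs)
        control = truth.communities[0]
        assert set(truth.signature.members) <= set(control.members)
        assert len(truth.signature.members) == 12
        assert len(control.members) == 100
        hubs = {c.hub for c in truth.communities}
        assert len(hubs) == 2  # distinct hubs in control and disease


class TestGenerateFractions:
    def test_rows_on_simplex(self):
        cohort = generate_cohort({"Control": 1}, seed=0)
        fr = generate_fractions(cohort, {"a": 1.0, "b": 1.0, "c": 1.0}, seed=0)
        assert fr.to_numpy().sum() == pytest.approx(1.0, abs=1e-9)
        assert (fr.to_numpy() >= 0).all()

    def test_null_shift_leaves_distributions_identical(self):
        cohort = generate_cohort({"Control": 300, "PE": 300}, seed=1)
        fr = generate_fractions(cohort, seed=2)
        clr = clr_transform(fr)
        ctrl = clr.loc[cohort["condition"] == "Control"]
        cond = clr.loc[cohort["condition"] == "PE"]
        # same Dirichlet for every sample: per-type means agree within noise
        assert np.abs(ctrl.mean() - cond.mean()).max() < 0.2

    def test_planted_clr_shift_recovered(self):
        """Monte-Carlo: mean clr difference within 0.15 of the planted 1.0."""
        shift = CompositionShift("FGR+HDP", "extravillous_trophoblast", 1.0)
        diffs = []
        for rep in range(200):
            cohort = generate_cohort({"Control": 113, "FGR+HDP": 30}, seed=rep)
            fr = generate_fractions(cohort, shift=shift, seed=rep + 5000)
            clr = clr_transform(fr)
            in_cond = cohort["condition"] == "FGR+HDP"
            diffs.append(
                clr.loc[in_cond, "extravillous_trophoblast"].mean()
                - clr.loc[~in_cond, "extravillous_trophoblast"].mean()
            )
        assert abs(np.mean(diffs) - 1.0) < 0.15

    def test_unknown_cell_type_rejected(self):
        cohort = generate_cohort({"Control": 5}, seed=0)
        with pytest.raises(ValueError, match="unknown cell type"):
            generate_fractions(cohort, {"a": 1.0}, CompositionShift("Control", "b", 1.0))

    def test_nonpositive_alpha_rejected(self):
        cohort = generate_cohort({"Control": 5}, seed=0)
        with pytest.raises(ValueError, match="positive"):
            generate_fractions(cohort, {"a": 1.0, "b": 0.0})


class TestDescribeCohort:
    def _paired_cohort(self):
        """Cohort whose covariates are identical in both sexes (duplicated)."""
        half = generate_cohort({"Control": 30, "PE": 10}, seed=11)
        a = half.copy()
        b = half.copy()
        a["fetal_sex"] = "female"
        b["fetal_sex"] = "male"
        b.index = [f"{i}m" for i in b.index]
        return pd.concat([a, b])

    def test_identical_groups_give_p_one_for_continuous(self):
        table = describe_cohort(self._paired_cohort())
        cont = table[table["test"] == "t-test"]
        assert np.allclose(cont["p_value"], 1.0)

    def test_zero_category_dropped_before_chi_square(self):
        half = generate_cohort({"Control": 30, "PE": 10, "PTD": 10}, seed=11)
        a, b = half.copy(), half.copy()
        a["fetal_sex"] = "female"
        b["fetal_sex"] = "male"
        b.index = [f"{i}m" for i in b.index]
        cohort = pd.concat([a, b])
        # remove every female PE sample: PE now has a zero cell for females
        cohort = cohort[~((cohort["fetal_sex"] == "female") & (cohort["condition"] == "PE"))]
        table = describe_cohort(cohort)
        row = table[table["variable"] == "condition"].iloc[0]
        assert "PE" in row["note"]
        assert np.isfinite(row["p_value"])  # test still ran on surviving levels

    def test_fisher_odds_ratio_matches_cross_product(self):
        # 2x2 table [[8,2],[1,5]] -> OR = (8*5)/(2*1) = 20
        rows = []
        for sex, zeros, ones in [("female", 8, 2), ("male", 1, 5)]:
            for v in [0] * zeros + [1] * ones:
                rows.append(dict(condition="Control", fetal_sex=sex, ga_weeks=39.0,
                                 bmi=25.0, labor_init=v, smoking=0, drug_use=0))
        cohort = pd.DataFrame(rows, index=[f"S{i}" for i in range(len(rows))])
        table = describe_cohort(cohort)
        row = table[table["variable"] == "labor_init"].iloc[0]
        assert row["statistic"] == pytest.approx(20.0)

    def test_more_than_two_levels_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="exactly 2 levels"):
            describe_cohort(small_cohort, group_var="condition")
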