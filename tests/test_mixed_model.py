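import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tagmove import (
    distance_reduction_per_100mg,
    fit_movement_sum_model,
    simulate_movement_sum,
)
from tagmove.reference_values import reported_mixed_model_coefficients

TRUE_COEFFS = {
    "(Intercept)": 0.85,
    "high temperature": -10.5,
    "low temperature": 10.9,
    "tag weight": -0.0077,
    "animal weight": 0.0217,
    "high temperature:tag weight": 0.0052,
    "low temperature:tag weight": -0.0063,
    "high temperature:animal weight": 0.0077,
    "low temperature:animal weight": -0.0109,
}


def cohort_covariates(seed=0, n_per_temp=60, days=3):
    """Covariate frame mirroring the experiment layout (between-subject
    temperature and weights, repeated over days)."""
    rng = np.random.default_rng(seed)
    rows = []
    masses = {"control": 0.0, "light": 199.0, "medium": 549.0, "heavy": 759.0}
    for temp in ("low", "intermediate", "high"):
        for i in range(n_per_temp):
            cat = list(masses)[i % 4]
            tag = masses[cat] + (rng.normal(0, 5.0) if cat != "control" else 0.0)
            animal = float(rng.normal(768, 117))
            for day in range(1, days + 1):
                rows.append(
                    {
                        "cricket_id": f"{temp}{i:02d}",
                        "temperature_category": temp,
                        "tag_weight_mg": tag,
                        "animal_weight_mg": animal,
                        "day": day,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def fitted():
    data = simulate_movement_sum(
        cohort_covariates(seed=0), TRUE_COEFFS, 3.0, 4.0, seed=42
    )
    return data, fit_movement_sum_model(data)


class TestFit:
    def test_recovers_generating_coefficients(self, fitted):
        _, fit = fitted
        est = fit.coefficients.set_index("term")
        for term, truth in TRUE_COEFFS.items():
            row = est.loc[term]
            assert abs(row["Estimate"] - truth) < 3 * row["Std. Error"], term

    def test_variance_components_plausible(self, fitted):
        _, fit = fitted
        assert 1.0 < fit.random_intercept_variance < 30.0  # truth 9
        assert 8.0 < fit.residual_variance < 32.0  # truth 16
        assert fit.random_effect_p < 1e-6

    def test_matches_lmer_reference(self, fitted, tmp_path):
        """Independent oracle: the same REML fit in R's lme4/lmerTest."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        data, fit = fitted
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$temperature_category <- relevel(factor(d$temperature_category), ref="intermediate")
            m <- lmer(movementSum ~ temperature_category*tag_weight_mg
                      + temperature_category*animal_weight_mg + (1|cricket_id), data=d)
            co <- summary(m)$coefficients
            write.csv(data.frame(est=co[,1], se=co[,2], df=co[,3]), "{tmp_path}/ref.csv")
        """)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv", index_col=0)
        name_map = {
            "(Intercept)": "(Intercept)",
            "temperature_categoryhigh": "high temperature",
            "temperature_categorylow": "low temperature",
            "tag_weight_mg": "tag weight",
            "animal_weight_mg": "animal weight",
            "temperature_categoryhigh:tag_weight_mg": "high temperature:tag weight",
            "temperature_categorylow:tag_weight_mg": "low temperature:tag weight",
            "temperature_categoryhigh:animal_weight_mg": "high temperature:animal weight",
            "temperature_categorylow:animal_weight_mg": "low temperature:animal weight",
        }
        est = fit.coefficients.set_index("term")
        for r_name, label in name_map.items():
            row_ref, row = ref.loc[r_name], est.loc[label]
            assert row["Estimate"] == pytest.approx(row_ref["est"], rel=1e-3, abs=1e-6)
            assert row["Std. Error"] == pytest.approx(row_ref["se"], rel=1e-3)
            assert row["df"] == pytest.approx(row_ref["df"], rel=0.02)

    def test_shifting_response_moves_only_intercept(self, fitted):
        data, fit = fitted
        shifted = data.copy()
        shifted["movementSum"] = shifted["movementSum"] + 5.0
        fit2 = fit_movement_sum_model(shifted)
        a = fit.coefficients.set_index("term")["Estimate"]
        b = fit2.coefficients.set_index("term")["Estimate"]
        assert b["(Intercept)"] - a["(Intercept)"] == pytest.approx(5.0, abs=1e-6)
        for term in TRUE_COEFFS:
            if term != "(Intercept)":
                assert b[term] == pytest.approx(a[term], abs=1e-8)

    def test_relabeling_individuals_invariant(self, fitted):
        data, fit = fitted
        relabeled = data.copy()
        relabeled["cricket_id"] = "x" + relabeled["cricket_id"]
        fit2 = fit_movement_sum_model(relabeled)
        assert np.allclose(
            fit.coefficients["Estimate"], fit2.coefficients["Estimate"], atol=1e-8
        )

    def test_zero_group_variance_collapses_to_boundary(self):
        data = simulate_movement_sum(
            cohort_covariates(seed=3), TRUE_COEFFS, 0.0, 4.0, seed=7
        )
        fit = fit_movement_sum_model(data)
        assert fit.random_intercept_variance <= 1e-6 * fit.residual_variance

    def test_single_observation_per_individual_rejected(self):
        data = simulate_movement_sum(
            cohort_covariates(seed=1, days=1), TRUE_COEFFS, 3.0, 4.0, seed=1
        )
        with pytest.raises(ValueError, match="random intercept"):
            fit_movement_sum_model(data)

    def test_rank_deficient_design_rejected(self):
        cov = cohort_covariates(seed=2)
        cov = cov[
            (cov["temperature_category"] != "low") | (cov["tag_weight_mg"] == 0)
        ]  # low temperature has no tagged crickets
        data = simulate_movement_sum(cov, TRUE_COEFFS, 3.0, 4.0, seed=2)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_movement_sum_model(data)


class TestDistanceReduction:
    def test_reported_coefficients_give_1p4_at_low(self):
        coeffs = reported_mixed_model_coefficients()
        assert distance_reduction_per_100mg(coeffs, "low") == pytest.approx(1.4)

    def test_reference_level_uses_main_effect_only(self):
        coeffs = reported_mixed_model_coefficients()
        assert distance_reduction_per_100mg(coeffs, "intermediate") == pytest.approx(0.77)

    def test_zero_coefficients_give_zero(self):
        coeffs = pd.DataFrame(
            {"term": ["tag weight", "low temperature:tag weight"], "Estimate": [0.0, 0.0]}
        )
        assert distance_reduction_per_100mg(coeffs, "low") == 0.0

    def test_missing_term_errors(self):
        coeffs = pd.DataFrame({"term": ["tag weight"], "Estimate": [-0.0077]})
        with pytest.raises(KeyError):
            distance_reduction_per_100mg(coeffs, "low")
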