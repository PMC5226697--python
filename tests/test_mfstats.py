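"""Quasi-Poisson dose-response GLM and the LRT outlier screen."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from mutamosaic.mfstats import (
    ConvergenceError,
    MFRecord,
    MutantFrequencyModel,
    fit_quasipoisson,
    group_mutant_frequency,
    homogeneity_lrt,
    lrt_outlier_screen,
    mutant_frequency,
    screen_records,
)


def _frame(doses, mutants, totals):
    return pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(len(doses))],
            "tissue": "liver",
            "dose": doses,
            "mutants": mutants,
            "total": totals,
        }
    )


class TestMutantFrequency:
    def test_basic(self):
        assert mutant_frequency(28, 500_000) == pytest.approx(5.6e-5)
        assert mutant_frequency(MFRecord("a", "liver", 0, 0, 1000)) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            mutant_frequency(1, 0)

    def test_group_mf_pools_counts_not_animal_means(self):
        df = _frame([0, 0], [10, 0], [10_000, 90_000])
        g = group_mutant_frequency(df)
        # pooled: 10/100000 = 1e-4; mean of animal MFs would be 5e-4
        assert g["mf"].item() == pytest.approx(1e-4)


class TestQuasiPoissonFit:
    def test_saturated_means_and_exact_fold(self):
        df = _frame([0, 0, 0, 40, 40, 40], [3, 3, 3, 30, 30, 30], [10_000] * 6)
        res = MutantFrequencyModel(df).fit()
        assert res.fold_changes()["fold"].item() == pytest.approx(10.0)
        assert res.dispersion == pytest.approx(0.0, abs=1e-9)

    def test_dispersion_matches_hand_computed_pearson(self, worked_counts):
        res = MutantFrequencyModel(worked_counts).fit()
        assert res.dispersion == pytest.approx((2 / 3 + 20 / 3) / 4)
        assert res.fold_changes()["fold"].item() == pytest.approx(10.0)

    def test_fitted_group_means_equal_observed_group_means(self, rng):
        """Canonical-link factor fits reproduce group means exactly (IRLS oracle)."""
        for _ in range(20):
            n_per = rng.integers(2, 6)
            doses = np.repeat([0, 10, 20], n_per)
            totals = rng.integers(5_000, 50_000, size=doses.size)
            mu = 1e-4 * totals * np.where(doses == 0, 1, doses)
            mutants = rng.poisson(mu) + 1
            df = _frame(doses, mutants, totals)
            res = MutantFrequencyModel(df).fit()
            for d in (0, 10, 20):
                sel = doses == d
                np.testing.assert_allclose(
                    res.fittedvalues[sel].sum(), mutants[sel].sum(), rtol=1e-10
                )

    def test_matches_statsmodels_glm(self, worked_counts):
        """Independent cross-check against the reference GLM implementation."""
        import statsmodels.api as sm

        res = MutantFrequencyModel(worked_counts).fit()
        X = np.column_stack(
            [np.ones(6), (worked_counts["dose"] == 40).astype(float)]
        )
        ref = sm.GLM(
            worked_counts["mutants"].to_numpy(),
            X,
            family=sm.families.Poisson(),
            offset=np.log(worked_counts["total"].to_numpy()),
        ).fit(scale="X2")
        np.testing.assert_allclose(res.params.to_numpy(), ref.params, rtol=1e-8)
        np.testing.assert_allclose(res.bse.to_numpy(), ref.bse, rtol=1e-8)
        assert res.dispersion == pytest.approx(ref.scale)

    def test_poisson_scale_restores_plain_standard_errors(self, worked_counts):
        res = MutantFrequencyModel(worked_counts).fit()
        se_quasi = res.bse.to_numpy()
        np.testing.assert_allclose(
            se_quasi / np.sqrt(res.dispersion),
            np.sqrt(np.diag(res.cov_unscaled)),
            rtol=1e-12,
        )

    def test_fold_invariant_to_rescaling_totals(self, worked_counts):
        res1 = MutantFrequencyModel(worked_counts).fit()
        scaled = worked_counts.assign(total=worked_counts["total"] * 7)
        res2 = MutantFrequencyModel(scaled).fit()
        assert res1.fold_changes()["fold"].item() == pytest.approx(
            res2.fold_changes()["fold"].item()
        )

    def test_continuous_coding_trend(self, worked_counts):
        res = MutantFrequencyModel(worked_counts, dose_coding="continuous").fit()
        t = res.trend()
        assert t["rate_ratio_per_unit"] == pytest.approx(10 ** (1 / 40), rel=1e-6)

    def test_factor_coding_requires_control(self):
        df = _frame([10, 10, 20, 20], [1, 2, 3, 4], [1000] * 4)
        with pytest.raises(ValueError, match="control"):
            MutantFrequencyModel(df)

    def test_all_zero_dose_group_warns(self):
        df = _frame([0, 0, 40, 40], [3, 4, 0, 0], [1000] * 4)
        with pytest.warns(UserWarning, match="all-zero"):
            MutantFrequencyModel(df).fit()

    def test_summary_mentions_dispersion_and_folds(self, worked_counts):
        s = MutantFrequencyModel(worked_counts).fit().summary()
        assert "dispersion" in s and "fold" in s

    def test_functional_wrapper(self, worked_counts):
        records = [
            MFRecord(str(r.animal_id), r.tissue, float(r.dose), int(r.mutants), int(r.total))
            for r in worked_counts.itertuples()
        ]
        res = fit_quasipoisson(records)
        assert res.fold_changes()["fold"].item() == pytest.approx(10.0)


class TestLRTScreen:
    def test_equal_replicates_not_removed(self):
        G, df, p = homogeneity_lrt([5, 5], [1000, 1000])
        assert G == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_vs_ten_closed_form(self):
        G, df, p = homogeneity_lrt([0, 10], [1000, 1000])
        assert G == pytest.approx(20 * np.log(2))
        assert df == 1
        assert p == pytest.approx(chi2.sf(20 * np.log(2), 1))
        assert p == pytest.approx(2.0e-4, rel=0.05)

    def test_discordant_replicate_removed_with_trace(self):
        units = pd.DataFrame({"mutants": [5, 6, 40], "total": [1000] * 3})
        kept, removed, trace = lrt_outlier_screen(units, alpha=0.05)
        assert removed["mutants"].tolist() == [40]
        assert kept["mutants"].tolist() == [5, 6]
        assert trace[0]["removed"] is not None and trace[-1]["removed"] is None

    def test_homogeneous_group_untouched(self):
        units = pd.DataFrame({"mutants": [5, 6, 7], "total": [1000] * 3})
        kept, removed, trace = lrt_outlier_screen(units, alpha=0.05)
        assert removed.empty and len(kept) == 3

    def test_single_unit_noop_with_warning(self):
        with pytest.warns(UserWarning):
            kept, removed, _ = lrt_outlier_screen(
                pd.DataFrame({"mutants": [5], "total": [1000]})
            )
        assert len(kept) == 1

    def test_false_removal_rate_bounded_by_alpha(self, rng):
        """On homogeneous Poisson groups the screen removes ~alpha or fewer."""
        removals = 0
        n_groups = 1000
        for _ in range(n_groups):
            y = rng.poisson(20, size=4)
            units = pd.DataFrame({"mutants": y, "total": [100_000] * 4})
            _, removed, _ = lrt_outlier_screen(units, alpha=0.05)
            removals += int(len(removed) > 0)
        # chi-square is asymptotic; allow binomial noise around alpha
        assert removals / n_groups <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_groups)

    def test_two_stage_screen_replicates_then_animals(self):
        df = pd.DataFrame(
            {
                "animal_id": ["a1", "a1", "a2", "a2", "a3", "a3"],
                "tissue": "liver",
                "dose": 0.0,
                "replicate_id": ["r1", "r2"] * 3,
                "mutants": [5, 6, 6, 60, 5, 6],  # a2 replicates are discordant
                "total": [100_000] * 6,
            }
        )
        screened, trace = screen_records(df, alpha=0.05)
        # replicate stage: the a2 pair rejects homogeneity and loses its more
        # discordant member (the low count deviates further in deviance terms)
        a2 = screened[screened["animal_id"] == "a2"]
        assert a2.empty or a2["mutants"].item() == 60
        # animal stage: a2's surviving count is then discordant with a1/a3
        # and the whole animal is screened out of the dose group
        assert a2.empty
        assert sorted(screened["mutants"]) == [11, 11]
        stages = {t["stage"] for t in trace}
        assert stages == {"replicates", "animals"}
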