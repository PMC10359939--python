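import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chemolib import (ScreenConfig, ScreenPlateSet, SynthScreenConfig,
                      ValidationError, activity_threshold, analyze_screen,
                      build_profiles, classify_strong_hits, dose_auc,
                      fit_background_mixture, sf_zscore, survival_fraction,
                      synth_screen)

PLATE_COLS = ["plate_id", "patient_id", "well", "role", "compound_id",
              "concentration_nM", "nuclei_count"]


def plate_set(rows):
    return ScreenPlateSet(pd.DataFrame(rows, columns=PLATE_COLS))


def simple_plate(dmso_counts, treated, plate="p1", patient="P1"):
    rows = [(plate, patient, f"D{i}", "dmso", "", np.nan, c)
            for i, c in enumerate(dmso_counts)]
    rows += [(plate, patient, f"T{i}", "treated", cid, conc, c)
             for i, (cid, conc, c) in enumerate(treated)]
    return plate_set(rows)


class TestSurvivalFraction:
    def test_treated_over_dmso_mean(self):
        plates = simple_plate([900, 1100], [("c1", 300, 500)])
        df = survival_fraction(plates)
        assert df.loc[df["role"] == "treated", "sf"].iloc[0] == pytest.approx(0.5)

    def test_dmso_wells_average_to_one(self):
        plates = simple_plate([800, 900, 1000, 1300], [("c1", 300, 500)])
        df = survival_fraction(plates)
        assert df.loc[df["role"] == "dmso", "sf"].mean() == pytest.approx(1.0)

    def test_zero_dmso_counts_error_names_plate(self):
        plates = simple_plate([0, 0], [("c1", 300, 500)])
        with pytest.raises(ValidationError, match="p1"):
            survival_fraction(plates)


class TestZScore:
    def test_hand_arithmetic_case(self):
        # DMSO SFs {0.9, 1.1}: mean 1, sd ~0.1414; SF 0.7172 -> Z ~ -2
        plates = simple_plate([900, 1100], [("c1", 300, 717.2)])
        df = sf_zscore(plates)
        z = df.loc[df["role"] == "treated", "zscore"].iloc[0]
        sd = np.std([0.9, 1.1], ddof=1)
        assert z == pytest.approx((0.7172 - 1.0) / sd, abs=1e-9)
        assert z == pytest.approx(-2.0, abs=1e-3)

    def test_sf_at_dmso_mean_gives_zero(self):
        plates = simple_plate([900, 1100], [("c1", 300, 1000)])
        df = sf_zscore(plates)
        assert df.loc[df["role"] == "treated", "zscore"].iloc[0] == \
            pytest.approx(0.0)

    def test_single_dmso_well_yields_missing_z(self):
        plates = simple_plate([1000], [("c1", 300, 500)])
        df = sf_zscore(plates)
        assert df["zscore"].isna().all()


class TestDoseAUC:
    CONC = [3, 30, 300, 3000]

    @pytest.mark.parametrize("sf,expected", [
        ([1, 1, 1, 1], 1.0),
        ([0, 0, 0, 0], 0.0),
        ([1, 1, 0, 0], 0.5),   # hand trapezoid on equal log spacing
    ])
    def test_closed_form_cases(self, sf, expected):
        assert dose_auc(sf, self.CONC) == pytest.approx(expected)

    def test_bounded_by_sf_range_and_relabel_invariant(self, rng):
        for _ in range(20):
            sf = rng.uniform(0, 1.3, 4)
            auc = dose_auc(sf, self.CONC)
            assert sf.min() - 1e-12 <= auc <= sf.max() + 1e-12
            # uniform relabeling that preserves log spacing
            assert dose_auc(sf, [c * 10 for c in self.CONC]) == \
                pytest.approx(auc)

    def test_missing_dose_rejected(self):
        with pytest.raises(ValidationError):
            dose_auc([1.0, np.nan, 1.0, 1.0], self.CONC)


class TestMixtureFit:
    def test_pure_background_recovered(self, rng):
        x = rng.normal(1, 0.05, 2000)
        fit = fit_background_mixture(x)
        assert abs(fit.background_mean - 1) < 0.01

    def test_planted_mixture_recovered(self, rng):
        lab = rng.random(2000) < 0.1
        x = np.where(lab, rng.normal(0.3, 0.10, 2000),
                     rng.normal(1, 0.05, 2000))
        fit = fit_background_mixture(x)
        active = 1 - fit.background_index
        assert fit.means[active] == pytest.approx(0.3, abs=0.05)
        assert fit.weights[active] == pytest.approx(0.1, abs=0.05)

    def test_loglik_nondecreasing(self, rng):
        lab = rng.random(500) < 0.2
        x = np.where(lab, rng.normal(0.4, 0.1, 500), rng.normal(1, 0.06, 500))
        fit = fit_background_mixture(x)
        assert np.all(np.diff(fit.loglik_trace) > -1e-8)

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValidationError):
            fit_background_mixture(rng.normal(1, 0.05, 10))

    def test_agrees_with_sklearn_em(self, rng):
        """Independent EM implementation reaches the same solution."""
        from sklearn.mixture import GaussianMixture
        lab = rng.random(3000) < 0.15
        x = np.where(lab, rng.normal(0.35, 0.1, 3000),
                     rng.normal(1, 0.05, 3000))
        fit = fit_background_mixture(x)
        gm = GaussianMixture(2, means_init=[[1.0], [0.35]], tol=1e-7,
                             random_state=0).fit(x.reshape(-1, 1))
        ref_bg = int(np.argmin(np.abs(gm.means_.ravel() - 1)))
        assert fit.background_mean == pytest.approx(
            gm.means_.ravel()[ref_bg], abs=1e-3)
        assert fit.background_sd == pytest.approx(
            np.sqrt(gm.covariances_.ravel()[ref_bg]), abs=1e-3)


class TestActivityThreshold:
    def test_normal_quantile_oracle(self):
        fit = fit_background_mixture(
            np.random.default_rng(0).normal(1, 0.05, 2000))
        fit.means = (1.0, 1.0)
        fit.sds = (0.05, 0.05)
        thr = activity_threshold(fit, 0.01)
        assert thr == pytest.approx(1 + stats.norm.ppf(1e-4) * 0.05)
        assert thr == pytest.approx(0.8140, abs=5e-4)

    def test_median_percentile_gives_mean_and_degenerate_sd(self):
        fit = fit_background_mixture(
            np.random.default_rng(0).normal(1, 0.05, 2000))
        fit.means, fit.sds = (1.0, 1.0), (0.05, 0.05)
        assert activity_threshold(fit, 50) == pytest.approx(1.0)
        fit.sds = (0.0, 0.0)
        with pytest.warns(UserWarning):
            assert activity_threshold(fit, 0.01) == 1.0

    def test_monotone_in_percentile_and_sd(self):
        fit = fit_background_mixture(
            np.random.default_rng(0).normal(1, 0.05, 2000))
        fit.means = (1.0, 1.0)
        fit.sds = (0.05, 0.05)
        t1 = activity_threshold(fit, 0.01)
        t2 = activity_threshold(fit, 1.0)
        assert t1 < t2
        fit.sds = (0.10, 0.10)
        assert activity_threshold(fit, 0.01) < t1


class TestStrongHits:
    def _profiles(self, sf_by_conc):
        rows = [("P1", "c1", c, v, np.nan) for c, v in sf_by_conc.items()]
        df = pd.DataFrame(rows, columns=["patient_id", "compound_id",
                                         "concentration_nM", "sf", "zscore"])
        return df.assign(auc=np.nan)

    def test_below_at_all_doses_is_strong_hit(self):
        thr = {("P1", c): 0.8 for c in (3.0, 30.0, 300.0, 3000.0)}
        prof = self._profiles({3.0: 0.5, 30.0: 0.4, 300.0: 0.3, 3000.0: 0.2})
        calls = classify_strong_hits(prof, thr)
        assert calls[0].is_strong_hit

    def test_below_at_three_of_four_is_not(self):
        thr = {("P1", c): 0.8 for c in (3.0, 30.0, 300.0, 3000.0)}
        prof = self._profiles({3.0: 0.9, 30.0: 0.4, 300.0: 0.3, 3000.0: 0.2})
        assert not classify_strong_hits(prof, thr)[0].is_strong_hit

    def test_exact_threshold_equality_is_not_below(self):
        thr = {("P1", c): v for c, v in
               [(3.0, 0.9), (30.0, 0.8), (300.0, 0.7), (3000.0, 0.6)]}
        prof = self._profiles({3.0: 0.5, 30.0: 0.8, 300.0: 0.5, 3000.0: 0.5})
        assert not classify_strong_hits(prof, thr)[0].is_strong_hit

    def test_missing_threshold_rejected(self):
        prof = self._profiles({3.0: 0.5, 30.0: 0.4, 300.0: 0.3, 3000.0: 0.2})
        with pytest.raises(ValidationError):
            classify_strong_hits(prof, {("P1", 3.0): 0.8})


class TestEndToEnd:
    def test_planted_hits_recovered(self, small_screen):
        result = analyze_screen(small_screen.plates)
        truth = small_screen.hit_compounds
        hits = result.strong_hits
        assert len(hits & truth) / len(truth) >= 0.9
        assert len(hits - truth) == 0
        for fit in result.fits:
            assert np.all(np.diff(fit.loglik_trace) > -1e-8)

    def test_profiles_carry_auc_on_sf_scale(self, small_screen):
        prof = build_profiles(small_screen.plates)
        per = prof.groupby(["patient_id", "compound_id"])
        for _, g in list(per)[:20]:
            assert g["auc"].iloc[0] <= g["sf"].max() + 1e-12
            assert g["auc"].iloc[0] >= g["sf"].min() - 1e-12

    def test_zscore_readout_mode_runs(self, small_screen):
        cfg = ScreenConfig(readout="zscore")
        result = analyze_screen(small_screen.plates, cfg)
        truth = small_screen.hit_compounds
        assert len(result.strong_hits & truth) / len(truth) >= 0.9
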