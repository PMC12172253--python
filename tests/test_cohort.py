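"""Synthetic cohort generator: determinism, parameter recovery, missingness."""

import numpy as np
import pandas as pd
import pytest

from interopipe import (
    CohortConfig,
    EGGParams,
    HBCTParams,
    IBIParams,
    OutcomeParams,
    WLTParams,
    apply_missingness,
    cronbach_alpha,
    egg_band_powers,
    fit_ols,
    frequency_domain_hrv,
    hbct_accuracy,
    preprocess_egg,
    simulate_cohort,
    simulate_egg_signal,
    simulate_hbct_session,
    simulate_ibi_series,
    simulate_outcomes,
    simulate_wlt_record,
    standardize,
    wlt_indices,
)
from interopipe.cohort import default_betas
from interopipe.exceptions import InvalidParameterError
from interopipe.scoring import COVARIATE, OUTCOMES, PREDICTORS


class TestIBISimulation:
    def test_degenerate_constant_series(self):
        params = IBIParams(mean_ibi=1000, lf_amplitude=0, hf_amplitude=0, noise_sd=0)
        series = simulate_ibi_series(params, 300.0, seed=0)
        assert len(series) == 300
        np.testing.assert_allclose(series.intervals, 1000.0)
        assert series.duration_s == pytest.approx(300.0)

    def test_duration_approximately_covered(self):
        series = simulate_ibi_series(IBIParams(), 300.0, seed=1)
        assert 300.0 <= series.duration_s <= 302.0

    def test_seed_determinism(self):
        params = IBIParams()
        a = simulate_ibi_series(params, 200.0, seed=42)
        b = simulate_ibi_series(params, 200.0, seed=42)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_hf_only_yields_high_hfnu(self):
        params = IBIParams(mean_ibi=800, lf_amplitude=0, hf_amplitude=30, noise_sd=0)
        series = simulate_ibi_series(params, 300.0, seed=2)
        _, _, hfnu = frequency_domain_hrv(series)
        assert hfnu >= 95.0

    @pytest.mark.parametrize("kwargs", [{"mean_ibi": 0}, {"mean_ibi": -100}])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            IBIParams(**kwargs)

    def test_too_short_duration(self):
        with pytest.raises(InvalidParameterError):
            simulate_ibi_series(IBIParams(mean_ibi=1000), 5.0, seed=0)


class TestEGGSimulation:
    def test_pure_normogastric_composition(self):
        params = EGGParams(band_fractions=(0, 1, 0), noise_fraction=0)
        rec = simulate_egg_signal(params, seed=0)
        bands = egg_band_powers(preprocess_egg(rec))
        assert bands.normo_pct >= 95.0

    def test_equal_mixture_recovered(self):
        params = EGGParams(band_fractions=(0.5, 0.5, 0), noise_fraction=0)
        rec = simulate_egg_signal(params, seed=1)
        bands = egg_band_powers(preprocess_egg(rec))
        assert bands.brady_pct == pytest.approx(50.0, abs=3.0)
        assert bands.normo_pct == pytest.approx(50.0, abs=3.0)

    def test_pure_noise_has_no_dominant_band(self):
        params = EGGParams(band_fractions=(0, 0, 0), noise_fraction=1.0)
        rec = simulate_egg_signal(params, seed=2)
        bands = egg_band_powers(preprocess_egg(rec))
        assert max(bands.brady_pct, bands.normo_pct, bands.tachy_pct) < 80.0

    def test_fraction_validation(self):
        with pytest.raises(InvalidParameterError):
            EGGParams(band_fractions=(0.6, 0.5, 0.2))
        with pytest.raises(InvalidParameterError):
            EGGParams(duration_s=200)


class TestHBCTSimulation:
    def _beats(self, mean_ibi=850.0):
        return simulate_ibi_series(
            IBIParams(mean_ibi=mean_ibi, lf_amplitude=0, hf_amplitude=0, noise_sd=0),
            200.0,
            seed=0,
        )

    def test_perfect_perceiver(self):
        params = HBCTParams(report_noise_sd=0)
        session = simulate_hbct_session(self._beats(), params, seed=0, perception_gain=1.0)
        assert hbct_accuracy(session) == 1.0

    def test_zero_gain_reports_nothing(self):
        params = HBCTParams(report_noise_sd=0)
        session = simulate_hbct_session(self._beats(), params, seed=0, perception_gain=0.0)
        assert all(t.reported_count == 0 for t in session.trials)
        assert hbct_accuracy(session) == 0.0

    def test_fractional_gain_formula(self):
        params = HBCTParams(report_noise_sd=0)
        session = simulate_hbct_session(self._beats(), params, seed=1, perception_gain=0.7)
        for t in session.trials:
            assert t.reported_count == round(0.7 * t.actual_count)
        assert hbct_accuracy(session) == pytest.approx(0.7, abs=0.02)

    def test_durations_randomized_but_complete(self):
        session = simulate_hbct_session(self._beats(), HBCTParams(), seed=5)
        assert sorted(t.duration_s for t in session.trials) == [25, 35, 45, 55]

    def test_short_series_rejected(self):
        short = simulate_ibi_series(IBIParams(), 100.0, seed=0)
        with pytest.raises(InvalidParameterError):
            simulate_hbct_session(short, HBCTParams(), seed=0)


class TestWLTSimulation:
    def test_deterministic_rating_map(self):
        params = WLTParams(rating_noise_sd=0.0, na_noise_sd=0.0)
        rec = simulate_wlt_record(params, seed=3)
        pct = wlt_indices(rec).pct_satiation_of_max
        expected = float(
            np.clip(round(params.rating_offset + params.rating_slope * pct), 1, 7)
        )
        assert rec.ratings["t1"].satiation == expected

    def test_ratings_respect_bounds(self):
        rng = np.random.default_rng(0)
        for seed in rng.integers(0, 2**31, size=20):
            rec = simulate_wlt_record(WLTParams(), seed=int(seed))
            for tp in ("t0", "t1", "t2"):
                r = rec.ratings[tp]
                assert 1 <= r.satiation <= 7 and 1 <= r.fullness <= 7
                assert all(1 <= v <= 7 for v in r.na_items)

    def test_high_loadings_give_high_alpha(self):
        params = WLTParams(na_loadings=(2.0,) * 5, na_noise_sd=0.05)
        items = np.array(
            [simulate_wlt_record(params, seed=s).ratings["t2"].na_items
             for s in range(400)]
        )
        assert cronbach_alpha(items) > 0.95

    def test_default_reliability_is_acceptable(self):
        # one-factor item model should land near the typical ~0.8 consistency
        items = np.array(
            [simulate_wlt_record(WLTParams(), seed=s).ratings["t2"].na_items
             for s in range(400)]
        )
        assert 0.6 < cronbach_alpha(items) < 0.95


class TestOutcomeSimulation:
    def _features(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        cols = PREDICTORS + [COVARIATE]
        df = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)
        df[COVARIATE] = rng.integers(0, 2, size=n)
        return df

    def test_zero_beta_zero_noise_constant(self):
        betas = default_betas() * 0.0
        out, _ = simulate_outcomes(
            self._features(50), OutcomeParams(betas=betas, residual_sd=0.0), seed=0
        )
        for c in OUTCOMES:
            assert out[c].nunique() == 1

    def test_noiseless_identifiability(self):
        params = OutcomeParams(residual_sd=0.0)
        out, _ = simulate_outcomes(self._features(300), params, seed=1)
        table = standardize(out[PREDICTORS + [COVARIATE] + OUTCOMES])
        res = fit_ols(table, "debq_emotional", PREDICTORS, [COVARIATE])
        truth = params.betas["debq_emotional"]
        # outcome standardization rescales all coefficients by 1/sd(X beta)
        scale = res.params[truth.index].to_numpy() @ truth.to_numpy() / (truth @ truth)
        np.testing.assert_allclose(
            res.params[truth.index].to_numpy(), scale * truth.to_numpy(), atol=1e-8
        )
        assert res.rsquared == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        feats = self._features(50).drop(columns=["hfnu"])
        with pytest.raises(InvalidParameterError):
            simulate_outcomes(feats, OutcomeParams(), seed=0)

    def test_outcomes_within_debq_range(self):
        out, _ = simulate_outcomes(self._features(200), OutcomeParams(), seed=2)
        for c in OUTCOMES:
            assert out[c].between(1, 5).all()


class TestCohortAssembly:
    def test_seed_determinism_bitwise(self):
        cfg = CohortConfig(n_participants=6, seed=99)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.features, b.features)
        for pid in a.beat_series:
            np.testing.assert_array_equal(
                a.beat_series[pid].intervals, b.beat_series[pid].intervals
            )
            np.testing.assert_array_equal(
                a.egg_recordings[pid].samples, b.egg_recordings[pid].samples
            )

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortConfig(n_participants=6, seed=1))
        b = simulate_cohort(CohortConfig(n_participants=6, seed=2))
        assert not a.features.equals(b.features)

    def test_feature_table_complete_without_missingness(self, small_cohort):
        assert not small_cohort.features[PREDICTORS + OUTCOMES].isna().any().any()
        assert len(small_cohort.features) == 60

    def test_instrument_bounds(self, small_cohort):
        f = small_cohort.features
        assert f["hbct_accuracy"].between(0, 1).all()
        assert f["hbct_confidence"].between(0, 8).all()
        assert f["cardiac_insight"].between(0, 100).all()
        assert f["gastric_insight"].between(0, 100).all()
        assert f[OUTCOMES].apply(lambda c: c.between(1, 5)).all().all()


class TestMissingness:
    def test_zero_rates_leave_cohort_unchanged(self, small_cohort):
        out = apply_missingness(small_cohort, {}, seed=0)
        pd.testing.assert_frame_equal(out.features, small_cohort.features)
        assert len(out.missing_log) == 0

    def test_binomial_rate(self):
        cohort = simulate_cohort(CohortConfig(n_participants=200, seed=5))
        out = apply_missingness(cohort, {"egg": 0.1}, seed=11)
        n_missing = out.features["normo_pct"].isna().sum()
        # binomial(200, 0.1): mean 20, sd ~4.2
        assert 7 <= n_missing <= 33
        assert (out.missing_log["instrument"] == "egg").sum() == n_missing

    def test_listwise_count_matches_complete_rows(self):
        cohort = simulate_cohort(CohortConfig(n_participants=100, seed=6))
        out = apply_missingness(cohort, {"egg": 0.1, "hbct": 0.1}, seed=3)
        used = PREDICTORS + [COVARIATE] + OUTCOMES
        complete = out.features.dropna(subset=used)
        n_affected = out.missing_log["participant"].nunique()
        assert len(complete) == 100 - n_affected

    def test_dropout_removes_all_lab_instruments(self, small_cohort):
        out = apply_missingness(small_cohort, {"dropout": 0.3}, seed=4)
        dropped = out.missing_log.loc[
            out.missing_log["instrument"] == "dropout", "participant"
        ]
        assert len(dropped) > 0
        for pid in dropped:
            assert out.beat_series[pid] is None
            assert out.egg_recordings[pid] is None
            assert np.isnan(out.features.loc[pid, "hbct_accuracy"])
            # questionnaire outcomes survive dropout
            assert not np.isnan(out.features.loc[pid, "debq_emotional"])

    def test_invalid_rate_rejected(self, small_cohort):
        with pytest.raises(InvalidParameterError):
            apply_missingness(small_cohort, {"egg": 1.0}, seed=0)
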