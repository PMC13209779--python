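"""Deployment path: full-data training, profile prediction, external scoring."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

from plgarelease.data import FormulationRecord, ReleaseProfile
from plgarelease.pipeline import (
    ExternalEvaluation,
    ExtrapolationWarning,
    TwoStageReleaseModel,
    train_full,
)


@pytest.fixture(scope="module")
def fitted_model(small_dataset):
    return train_full(small_dataset.features, small_dataset.profiles,
                      algorithm="xgb", seed=1)


@pytest.fixture(scope="module")
def in_range_record(small_dataset):
    """A query built from training medians, guaranteed inside all ranges."""
    from plgarelease.data import FEATURE_COLUMNS

    med = small_dataset.features[FEATURE_COLUMNS].median()
    return FormulationRecord(
        formulation_id="Q1", drug_id="QD",
        acid_endcap=int(med["acid_endcap"] >= 0.5),
        **{f: float(med[f]) for f in FEATURE_COLUMNS if f != "acid_endcap"},
    )


def olaparib_record():
    """Olaparib-loaded microspheres from published formulation details:
    RG503H (24-38 kDa midpoint 31, 50:50, acid-terminated), 20 mg drug /
    80 mg polymer, 100 rpm, 80 mg polymer in a 1.6 mL organic phase."""
    organic_phase_mass = 1.6 * 1320  # DCM:DMSO 1:1, ~1.32 g/mL
    return FormulationRecord(
        formulation_id="OLA", drug_id="olaparib",
        polymer_mw=31.0, la_ga=1.0, initial_dm_ratio=20 / 80,
        drug_mw=434.5, drug_tpsa=82.1, drug_logp=1.9,
        particle_size=85.0, dlc=0.16, ee=0.8, se=0.5,
        agitation_rpm=100.0, polymer_concentration=80 / organic_phase_mass,
        acid_endcap=1,
    )


class TestTrainFull:
    def test_in_sample_predictions_deterministic(self, small_dataset):
        a = train_full(small_dataset.features, small_dataset.profiles, "xgb", seed=2)
        b = train_full(small_dataset.features, small_dataset.profiles, "xgb", seed=2)
        row = small_dataset.features.iloc[[0]]
        grid = [1.0, 5.0, 20.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            pa = a.predict_full_profile(row, grid).predicted_release
            pb = b.predict_full_profile(row, grid).predicted_release
        np.testing.assert_array_equal(pa, pb)

    def test_meta_feature_is_oof_in_training(self, fitted_model):
        # training matrix carries out-of-fold, not full-model, probabilities
        oof = fitted_model.oof_probabilities_.set_index("formulation_id")
        mx = fitted_model.matrix_
        merged = mx.groupby("formulation_id")["predicted_slow_release"].first()
        np.testing.assert_allclose(
            merged.sort_index(), oof["predicted_slow_release"].sort_index(),
            atol=1e-12)

    def test_serialization_round_trip(self, fitted_model, in_range_record, tmp_path):
        path = tmp_path / "model.joblib"
        fitted_model.save(path)
        loaded = TwoStageReleaseModel.load(path)
        grid = np.array([1.0, 7.0, 21.0])
        np.testing.assert_array_equal(
            fitted_model.predict_full_profile(in_range_record, grid).predicted_release,
            loaded.predict_full_profile(in_range_record, grid).predicted_release,
        )

    def test_extreme_slow_vs_fast_probability_ordering(self, small_dataset):
        model = train_full(small_dataset.features, small_dataset.profiles,
                           "xgb", seed=1)
        feats = small_dataset.features
        lo, hi = feats.quantile(0.05, numeric_only=True), \
            feats.quantile(0.95, numeric_only=True)
        base = {f: float(feats[f].median()) for f in
                ("la_ga", "drug_logp", "particle_size", "dlc", "ee", "se",
                 "initial_dm_ratio")}
        slow = FormulationRecord(
            "S", "s", polymer_mw=float(hi["polymer_mw"]),
            drug_mw=float(hi["drug_mw"]), drug_tpsa=float(lo["drug_tpsa"]),
            agitation_rpm=float(lo["agitation_rpm"]),
            polymer_concentration=float(hi["polymer_concentration"]),
            acid_endcap=0, **base)
        fast = FormulationRecord(
            "F", "f", polymer_mw=float(lo["polymer_mw"]),
            drug_mw=float(lo["drug_mw"]), drug_tpsa=float(hi["drug_tpsa"]),
            agitation_rpm=float(hi["agitation_rpm"]),
            polymer_concentration=float(lo["polymer_concentration"]),
            acid_endcap=1, **base)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            p_slow = model.predict_slow_release(slow)
            p_fast = model.predict_slow_release(fast)
        assert p_slow > p_fast


class TestPredictFullProfile:
    def test_grid_length_and_range(self, fitted_model, in_range_record):
        grid = [0.5, 1, 4, 7, 10, 13, 19]
        result = fitted_model.predict_full_profile(in_range_record, grid)
        assert len(result.predicted_release) == 7
        assert np.all((result.predicted_release >= 0)
                      & (result.predicted_release <= 1))
        assert 0 <= result.slow_release_probability <= 1

    def test_duplicate_timepoints_identical_predictions(self, fitted_model, in_range_record):
        result = fitted_model.predict_full_profile(in_range_record, [5.0, 5.0, 9.0])
        assert result.predicted_release[0] == result.predicted_release[1]

    def test_empty_grid_rejected(self, fitted_model, in_range_record):
        with pytest.raises(ValueError, match="empty"):
            fitted_model.predict_full_profile(in_range_record, [])

    def test_missing_descriptor_named(self, fitted_model, small_dataset):
        broken = small_dataset.features.drop(columns=["agitation_rpm"]).iloc[[0]]
        with pytest.raises(ValueError, match="agitation_rpm"):
            fitted_model.predict_full_profile(broken, [1.0])

    def test_out_of_range_descriptor_warns(self, fitted_model, in_range_record):
        import dataclasses

        far = dataclasses.replace(in_range_record, drug_mw=90000.0)
        with pytest.warns(ExtrapolationWarning, match="drug_mw"):
            fitted_model.predict_full_profile(far, [1.0, 5.0])


class TestEvaluateExternal:
    def test_self_consistency_mae_zero(self, fitted_model, in_range_record):
        grid = np.array([1.0, 4.0, 9.0, 15.0])
        pred = fitted_model.predict_full_profile(in_range_record, grid)
        observed = pd.DataFrame({
            "time_days": grid,
            "cumulative_release": pred.predicted_release,
        })
        report = fitted_model.evaluate_external(in_range_record, observed)
        assert report.mae == pytest.approx(0.0, abs=1e-12)
        if not np.isnan(report.pearson_r):
            assert report.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_olaparib_record_smoke(self, fitted_model):
        """The published olaparib formulation parses and predicts end to end."""
        obs = pd.DataFrame({
            "time_days": [0.5, 1, 4, 7, 10, 13, 19],
            "cumulative_release": [0.1, 0.18, 0.35, 0.55, 0.7, 0.82, 0.95],
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            report = fitted_model.evaluate_external(olaparib_record(), obs)
        assert 0 <= report.mae <= 1
        assert 0 <= report.prediction.slow_release_probability <= 1

    def test_single_observation_mae_only(self, fitted_model, in_range_record):
        obs = pd.DataFrame({"time_days": [5.0], "cumulative_release": [0.4]})
        with pytest.warns(RuntimeWarning, match="single observation"):
            report = fitted_model.evaluate_external(in_range_record, obs)
        assert np.isnan(report.pearson_r)
        assert report.mae >= 0

    def test_report_json_round_trip(self, fitted_model, in_range_record, tmp_path):
        obs = pd.DataFrame({"time_days": [1.0, 5.0, 9.0],
                            "cumulative_release": [0.2, 0.5, 0.8]})
        report = fitted_model.evaluate_external(in_range_record, obs)
        path = tmp_path / "report.json"
        report.to_json(path)
        back = ExternalEvaluation.from_dict(json.loads(path.read_text()))
        assert back.mae == report.mae
        np.testing.assert_array_equal(back.observed_release,
                                      report.observed_release)
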