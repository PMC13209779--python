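"""Dataset I/O, inclusion filtering, slow-release labeling, table assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plgarelease.data import (
    FEATURE_COLUMNS,
    LABEL_COLUMN,
    ReferentialIntegrityError,
    ReleaseProfile,
    SchemaError,
    apply_inclusion_filters,
    build_feature_table,
    label_slow_release,
    label_table,
    read_dataset,
    release_at_day,
    write_dataset,
)


def _write_pair(tmp_path, features, profiles):
    f, p = tmp_path / "features.csv", tmp_path / "profiles.csv"
    features.to_csv(f, index=False)
    profiles.to_csv(p, index=False)
    return f, p


def _profiles_for(ids):
    return pd.concat([
        pd.DataFrame({"formulation_id": fid,
                      "time_days": [1.0, 3.0, 10.0],
                      "cumulative_release": [0.1, 0.3, 0.8]})
        for fid in ids
    ], ignore_index=True)


class TestReadDataset:
    def test_round_trip(self, toy_features, tmp_path):
        profiles = _profiles_for(toy_features["formulation_id"])
        f, p = _write_pair(tmp_path, toy_features, profiles)
        ds = read_dataset(f, p)
        assert len(ds.features) == len(toy_features)
        assert ds.features["formulation_id"].tolist() == \
            toy_features["formulation_id"].tolist()
        # write/read reproduces the tables up to float formatting
        f2, p2 = tmp_path / "f2.csv", tmp_path / "p2.csv"
        write_dataset(ds.features, ds.profiles, f2, p2)
        ds2 = read_dataset(f2, p2)
        pd.testing.assert_frame_equal(ds.features, ds2.features)
        pd.testing.assert_frame_equal(ds.profiles, ds2.profiles)

    def test_headers_case_insensitive_and_order_free(self, toy_features, tmp_path):
        profiles = _profiles_for(toy_features["formulation_id"])
        shuffled = toy_features.rename(columns=str.upper)
        shuffled = shuffled[list(shuffled.columns)[::-1]]
        f, p = _write_pair(tmp_path, shuffled, profiles)
        ds = read_dataset(f, p)
        assert len(ds.features) == len(toy_features)

    def test_missing_mandatory_feature_drops_row_with_reason(self, toy_features, tmp_path):
        feats = toy_features.copy()
        feats.loc[0, "agitation_rpm"] = np.nan
        profiles = _profiles_for(feats["formulation_id"])
        f, p = _write_pair(tmp_path, feats, profiles)
        ds = read_dataset(f, p)
        assert len(ds.features) == len(feats) - 1
        dropped = feats.loc[0, "formulation_id"]
        assert dropped not in set(ds.features["formulation_id"])
        reasons = ds.exclusions.set_index("formulation_id")["reason"]
        assert reasons[dropped].startswith("missing:agitation_rpm")

    def test_unknown_column_is_schema_error(self, toy_features, tmp_path):
        feats = toy_features.assign(bogus=1.0)
        f, p = _write_pair(tmp_path, feats, _profiles_for(feats["formulation_id"]))
        with pytest.raises(SchemaError, match="bogus"):
            read_dataset(f, p)

    def test_orphan_profile_is_referential_error(self, toy_features, tmp_path):
        profiles = _profiles_for(list(toy_features["formulation_id"]) + ["GHOST"])
        f, p = _write_pair(tmp_path, toy_features, profiles)
        with pytest.raises(ReferentialIntegrityError, match="GHOST"):
            read_dataset(f, p)

    def test_mass_balance_violation_excluded(self, toy_features, tmp_path):
        feats = toy_features.copy()
        feats.loc[1, "dlc"] = 0.95  # far above EE*DM/(1+EE*DM)
        f, p = _write_pair(tmp_path, feats, _profiles_for(feats["formulation_id"]))
        ds = read_dataset(f, p)
        assert "mass_balance" in set(ds.exclusions["reason"])


class TestInclusionFilters:
    def _profile(self, fid, times, releases):
        return pd.DataFrame({"formulation_id": fid, "time_days": times,
                             "cumulative_release": releases})

    def test_short_profile_excluded(self):
        prof = self._profile("A", [0.5, 2.0], [0.3, 0.9])
        out, excl = apply_inclusion_filters(prof, return_exclusions=True)
        assert out.empty
        assert excl["reason"].iloc[0] == "span_lt_72h"

    def test_low_final_release_excluded(self):
        prof = self._profile("A", [1.0, 5.0], [0.2, 0.55])
        out, excl = apply_inclusion_filters(prof, return_exclusions=True)
        assert out.empty
        assert excl["reason"].iloc[0] == "final_release_le_60pct"

    def test_compliant_profile_retained(self):
        prof = self._profile("A", [1.0, 15.0, 30.0], [0.1, 0.5, 0.85])
        out = apply_inclusion_filters(prof)
        assert set(out["formulation_id"]) == {"A"}

    def test_idempotence(self, small_dataset):
        once = apply_inclusion_filters(small_dataset.profiles)
        twice = apply_inclusion_filters(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input_is_empty_output(self):
        empty = pd.DataFrame(columns=["formulation_id", "time_days",
                                      "cumulative_release"])
        assert apply_inclusion_filters(empty).empty


class TestSlowReleaseLabel:
    def test_interpolated_day3_release(self):
        # hand interpolation: 0.10 + (0.50-0.10)*(3-1)/(5-1) = 0.30 -> fast
        prof = ReleaseProfile("A", [1.0, 5.0], [0.10, 0.50])
        assert release_at_day(prof.time_days, prof.cumulative_release) == \
            pytest.approx(0.30)
        assert label_slow_release(prof) == 0

    def test_exact_day3_boundary_is_slow(self):
        prof = ReleaseProfile("A", [1.0, 3.0, 10.0], [0.05, 0.20, 0.9])
        assert label_slow_release(prof) == 1

    def test_all_zero_profile_is_slow(self):
        prof = ReleaseProfile("A", [1.0, 5.0], [0.0, 0.0])
        assert label_slow_release(prof) == 1

    def test_short_profile_raises(self):
        prof = ReleaseProfile("A", [0.5, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError, match="spans only"):
            label_slow_release(prof)

    def test_interpolation_agrees_with_exact_observation(self):
        with_obs = ReleaseProfile("A", [1.0, 3.0, 5.0], [0.1, 0.3, 0.5])
        without = ReleaseProfile("A", [1.0, 5.0], [0.1, 0.5])
        assert release_at_day(with_obs.time_days, with_obs.cumulative_release) \
            == pytest.approx(
                release_at_day(without.time_days, without.cumulative_release),
                abs=1e-12)

    @given(
        shift=st.floats(min_value=0.0, max_value=0.5),
        base=st.lists(st.floats(min_value=0.0, max_value=0.4),
                      min_size=2, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_uniform_increase_never_flips_fast_to_slow(self, shift, base):
        releases = np.minimum.accumulate(np.sort(base)[::-1])[::-1]
        times = np.linspace(1.0, 10.0, len(releases))
        before = label_slow_release(ReleaseProfile("A", times, releases))
        after = label_slow_release(
            ReleaseProfile("A", times, np.clip(releases + shift, 0, 1)))
        # raising every observation can only make day-3 release larger
        assert not (before == 0 and after == 1)


class TestBuildFeatureTable:
    def test_join_and_canonical_order(self, toy_features):
        labels = pd.DataFrame({
            "formulation_id": toy_features["formulation_id"],
            LABEL_COLUMN: [0, 1] * 4,
        })
        table = build_feature_table(toy_features, labels)
        assert list(table.columns) == \
            ["formulation_id", "drug_id"] + FEATURE_COLUMNS + [LABEL_COLUMN]
        assert len(table) == len(toy_features)

    def test_missing_label_names_id(self, toy_features):
        labels = pd.DataFrame({
            "formulation_id": toy_features["formulation_id"].iloc[:-1],
            LABEL_COLUMN: 0,
        })
        missing_id = toy_features["formulation_id"].iloc[-1]
        with pytest.raises(ValueError, match=missing_id):
            build_feature_table(toy_features, labels)

    def test_join_is_order_independent(self, toy_features):
        labels = pd.DataFrame({
            "formulation_id": toy_features["formulation_id"],
            LABEL_COLUMN: [0, 1] * 4,
        })
        shuffled = build_feature_table(
            toy_features.sample(frac=1, random_state=3),
            labels.sample(frac=1, random_state=4),
        )
        sorted_inputs = build_feature_table(
            toy_features.sort_values("formulation_id"),
            labels.sort_values("formulation_id"),
        )
        pd.testing.assert_frame_equal(shuffled, sorted_inputs)

    def test_duplicate_id_raises(self, toy_features):
        dup = pd.concat([toy_features, toy_features.iloc[[0]]])
        labels = pd.DataFrame({"formulation_id": dup["formulation_id"],
                               LABEL_COLUMN: 0})
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(dup, labels)


def test_label_table_covers_every_formulation(small_dataset):
    labels = label_table(small_dataset.profiles)
    assert set(labels["formulation_id"]) == \
        set(small_dataset.profiles["formulation_id"])
    assert labels[LABEL_COLUMN].isin([0, 1]).all()
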