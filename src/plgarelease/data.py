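"""Domain types, dataset I/O, inclusion filtering and slow-release labeling.

The package works on two tables:

* a *feature table* — one row per formulation, keyed by ``formulation_id``
  and ``drug_id``, carrying the 13 formulation descriptors
  (:data:`FEATURE_COLUMNS`);
* a long-format *profile table* — one row per release observation:
  ``(formulation_id, time_days, cumulative_release)`` with release stored
  as a fraction in [0, 1].

Formulations whose cumulative release is at most 20% within the first three
days are *slow-release systems*; that binary indicator is the stage-1
classification target and, as an out-of-fold predicted probability, the
stacked meta-feature of the stage-2 regression.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["formulation_id", "drug_id"]

#: The 13 formulation descriptors used as predictors (time excluded).
FEATURE_COLUMNS = [
    "polymer_mw",            # PLGA molecular weight, kDa
    "la_ga",                 # LA:GA molar ratio (50:50 -> 1.0, 75:25 -> 3.0)
    "initial_dm_ratio",      # initial drug-to-polymer mass ratio
    "drug_mw",               # drug molecular weight, Da
    "drug_tpsa",             # topological polar surface area, A^2
    "drug_logp",             # octanol-water partition coefficient
    "particle_size",         # microsphere diameter, um
    "dlc",                   # drug loading capacity, mass fraction in [0, 1]
    "ee",                    # encapsulation efficiency, fraction in [0, 1]
    "se",                    # solubility enhancer concentration, % w/v
    "agitation_rpm",         # in vitro agitation rate, rpm
    "polymer_concentration", # polymer weight fraction of the organic phase
    "acid_endcap",           # 1 = acid-terminated PLGA, 0 = ester-terminated
]

LABEL_COLUMN = "slow_release"
PROB_COLUMN = "predicted_slow_release"
TIME_COLUMN = "time_days"
RELEASE_COLUMN = "cumulative_release"
PROFILE_COLUMNS = ["formulation_id", TIME_COLUMN, RELEASE_COLUMN]

#: Fields that may not be missing; a row missing any of them is excluded.
MANDATORY_FIELDS = KEY_COLUMNS + FEATURE_COLUMNS

#: Inclusion filters: study span and final cumulative release.
MIN_SPAN_DAYS = 3.0       # "at least 72 h"
MIN_FINAL_RELEASE = 0.60  # "exceeding 60%"

#: Slow-release rule: cumulative release at day 3 at most this fraction.
SLOW_RELEASE_THRESHOLD = 0.20
SLOW_RELEASE_DAY = 3.0

#: Relative tolerance on the DLC mass-balance consistency check.
MASS_BALANCE_RTOL = 0.10

#: Measurement overshoot tolerated on input before clipping to [0, 1].
RELEASE_OVERSHOOT = 1.1


class SchemaError(ValueError):
    """A CSV header does not match the documented dataset schema."""


class ReferentialIntegrityError(ValueError):
    """A release profile references a formulation absent from the features."""


@dataclass
class FormulationRecord:
    """One formulation's descriptors plus its grouping keys."""

    formulation_id: str
    drug_id: str
    polymer_mw: float
    la_ga: float
    initial_dm_ratio: float
    drug_mw: float
    drug_tpsa: float
    drug_logp: float
    particle_size: float
    dlc: float
    ee: float
    se: float
    agitation_rpm: float
    polymer_concentration: float
    acid_endcap: int

    def to_frame(self) -> pd.DataFrame:
        row = dataclasses.asdict(self)
        return pd.DataFrame([row], columns=KEY_COLUMNS + FEATURE_COLUMNS)

    @classmethod
    def from_dict(cls, d: dict) -> "FormulationRecord":
        missing = [f for f in MANDATORY_FIELDS if f not in d or pd.isna(d[f])]
        if missing:
            raise ValueError(f"missing mandatory descriptor(s): {missing}")
        kwargs = {f: d[f] for f in MANDATORY_FIELDS}
        kwargs["acid_endcap"] = int(kwargs["acid_endcap"])
        return cls(**kwargs)


@dataclass
class ReleaseProfile:
    """Ordered (time, cumulative release fraction) observations."""

    formulation_id: str
    time_days: np.ndarray
    cumulative_release: np.ndarray

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=float)
        self.cumulative_release = np.asarray(self.cumulative_release, dtype=float)
        if self.time_days.size != self.cumulative_release.size:
            raise ValueError("time and release vectors differ in length")
        if self.time_days.size < 2:
            raise ValueError("a release profile needs at least 2 observations")
        if np.any(np.diff(self.time_days) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.time_days < 0):
            raise ValueError("observation times must be non-negative")
        if np.any(self.cumulative_release < 0) or np.any(
            self.cumulative_release > RELEASE_OVERSHOOT
        ):
            raise ValueError(
                f"cumulative release must lie in [0, {RELEASE_OVERSHOOT}]"
            )
        # slight >1 measurement overshoot tolerated on input, clipped here
        self.cumulative_release = np.clip(self.cumulative_release, 0.0, 1.0)

    @property
    def span_days(self) -> float:
        return float(self.time_days[-1])

    @property
    def final_release(self) -> float:
        return float(self.cumulative_release[-1])


class Dataset(NamedTuple):
    """A validated feature table / profile table pair plus exclusion log."""

    features: pd.DataFrame
    profiles: pd.DataFrame
    exclusions: pd.DataFrame


def _canonicalize_headers(df: pd.DataFrame, required: Sequence[str], path: str,
                          optional: Sequence[str] = ()) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key not in required and key not in optional:
            raise SchemaError(f"{path}: unknown column {col!r}")
        mapping[col] = key
    df = df.rename(columns=mapping)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_dataset(features_path, profiles_path) -> Dataset:
    """Read and validate a features CSV and a long-format profiles CSV.

    Headers are matched case-insensitively and order-free. Feature rows with
    any missing mandatory descriptor, violating the DLC mass balance beyond
    10% relative, or lacking a matching release profile are dropped and
    recorded in the returned exclusion log with a reason code. A profile
    referencing a formulation absent from the feature table raises
    :class:`ReferentialIntegrityError`.
    """
    try:
        features = pd.read_csv(features_path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{features_path}: malformed CSV ({exc})") from exc
    try:
        profiles = pd.read_csv(profiles_path)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{profiles_path}: malformed CSV ({exc})") from exc

    # a label column is tolerated on input; labels are recomputed from the
    # profiles, so it is dropped rather than trusted
    features = _canonicalize_headers(features, MANDATORY_FIELDS,
                                     str(features_path),
                                     optional=[LABEL_COLUMN])
    features = features.drop(columns=[LABEL_COLUMN], errors="ignore")
    profiles = _canonicalize_headers(profiles, PROFILE_COLUMNS, str(profiles_path))
    features["formulation_id"] = features["formulation_id"].astype(str)
    features["drug_id"] = features["drug_id"].astype(str)
    profiles["formulation_id"] = profiles["formulation_id"].astype(str)

    exclusions: list[dict] = []

    # missing mandatory descriptors -> drop the formulation, no imputation
    for fid, row in features.set_index("formulation_id").iterrows():
        missing = [f for f in FEATURE_COLUMNS + ["drug_id"] if pd.isna(row.get(f))]
        if missing:
            exclusions.append(
                {"formulation_id": fid, "reason": "missing:" + ",".join(missing)}
            )
    bad = {e["formulation_id"] for e in exclusions}
    features = features[~features["formulation_id"].isin(bad)].copy()

    if features["formulation_id"].duplicated().any():
        dups = features.loc[
            features["formulation_id"].duplicated(), "formulation_id"
        ].tolist()
        raise SchemaError(f"duplicate formulation_id(s): {dups}")

    bad_endcap = ~features["acid_endcap"].isin([0, 1])
    if bad_endcap.any():
        raise SchemaError(
            "acid_endcap must be binary 0/1; offending formulation(s): "
            f"{features.loc[bad_endcap, 'formulation_id'].tolist()}"
        )

    # DLC mass-balance consistency: DLC <= EE*DM/(1+EE*DM) within 10% relative
    with np.errstate(invalid="ignore"):
        implied = (
            features["ee"] * features["initial_dm_ratio"]
            / (1.0 + features["ee"] * features["initial_dm_ratio"])
        )
    inconsistent = features["dlc"] > implied * (1.0 + MASS_BALANCE_RTOL)
    for fid in features.loc[inconsistent, "formulation_id"]:
        exclusions.append({"formulation_id": fid, "reason": "mass_balance"})
        bad.add(fid)
    features = features[~inconsistent].copy()

    unknown = set(profiles["formulation_id"]) - set(features["formulation_id"])
    orphaned = unknown - bad  # excluded-row profiles are dropped, not an error
    if orphaned:
        raise ReferentialIntegrityError(
            f"profiles reference unknown formulation_id(s): {sorted(orphaned)}"
        )
    profiles = profiles[
        profiles["formulation_id"].isin(set(features["formulation_id"]))
    ].copy()

    # validate each profile through the ReleaseProfile invariants
    kept_profiles = []
    for fid, grp in profiles.groupby("formulation_id", sort=False):
        grp = grp.sort_values(TIME_COLUMN)
        prof = ReleaseProfile(fid, grp[TIME_COLUMN].to_numpy(),
                              grp[RELEASE_COLUMN].to_numpy())
        kept_profiles.append(
            pd.DataFrame(
                {
                    "formulation_id": fid,
                    TIME_COLUMN: prof.time_days,
                    RELEASE_COLUMN: prof.cumulative_release,
                }
            )
        )
    profiles = (
        pd.concat(kept_profiles, ignore_index=True)
        if kept_profiles
        else pd.DataFrame(columns=PROFILE_COLUMNS)
    )

    # every retained formulation must have a release profile
    profiled = set(profiles["formulation_id"])
    unprofiled = ~features["formulation_id"].isin(profiled)
    for fid in features.loc[unprofiled, "formulation_id"]:
        exclusions.append({"formulation_id": fid, "reason": "no_profile"})
    features = features[~unprofiled].reset_index(drop=True)

    exclusion_log = pd.DataFrame(exclusions, columns=["formulation_id", "reason"])
    for _, e in exclusion_log.iterrows():
        logger.info("excluded formulation %s (%s)", e["formulation_id"], e["reason"])

    features = features[KEY_COLUMNS + FEATURE_COLUMNS]
    return Dataset(features, profiles.reset_index(drop=True), exclusion_log)


def write_dataset(features: pd.DataFrame, profiles: pd.DataFrame,
                  features_path, profiles_path) -> None:
    """Write the canonical CSV pair (UTF-8, '.' decimal, fixed column order)."""
    cols = [c for c in KEY_COLUMNS + FEATURE_COLUMNS + [LABEL_COLUMN]
            if c in features.columns]
    features[cols].to_csv(features_path, index=False)
    profiles[PROFILE_COLUMNS].to_csv(profiles_path, index=False)


def apply_inclusion_filters(
    profiles: pd.DataFrame, return_exclusions: bool = False
):
    """Keep profiles spanning >= 72 h with final cumulative release > 60%.

    Idempotent: re-filtering an already-filtered table is a no-op. With
    ``return_exclusions=True`` also returns a log naming the rule that fired.
    """
    if profiles.empty:
        out = profiles.copy()
        return (out, pd.DataFrame(columns=["formulation_id", "reason"])) if return_exclusions else out

    last = (
        profiles.sort_values(TIME_COLUMN)
        .groupby("formulation_id", sort=False)
        .agg(span=(TIME_COLUMN, "max"), final=(RELEASE_COLUMN, "last"))
    )
    too_short = last.index[last["span"] < MIN_SPAN_DAYS]
    too_low = last.index[(last["span"] >= MIN_SPAN_DAYS)
                         & (last["final"] <= MIN_FINAL_RELEASE)]
    excl = pd.DataFrame(
        [{"formulation_id": f, "reason": "span_lt_72h"} for f in too_short]
        + [{"formulation_id": f, "reason": "final_release_le_60pct"} for f in too_low],
        columns=["formulation_id", "reason"],
    )
    for _, e in excl.iterrows():
        logger.info("filtered out %s (%s)", e["formulation_id"], e["reason"])
    keep = set(last.index) - set(excl["formulation_id"])
    out = profiles[profiles["formulation_id"].isin(keep)].reset_index(drop=True)
    return (out, excl) if return_exclusions else out


def release_at_day(time_days: np.ndarray, cumulative_release: np.ndarray,
                   day: float = SLOW_RELEASE_DAY) -> float:
    """Cumulative release at ``day``: exact observation if present, else
    linear interpolation between the bracketing observations."""
    t = np.asarray(time_days, dtype=float)
    y = np.asarray(cumulative_release, dtype=float)
    if t[-1] < day:
        raise ValueError(
            f"profile spans only {t[-1]} days; cannot evaluate day {day} "
            "(should have been excluded by the inclusion filters)"
        )
    return float(np.interp(day, t, y))


def label_slow_release(profile: ReleaseProfile | pd.DataFrame) -> int:
    """Binary slow-release indicator: 1 iff release at day 3 is <= 0.20.

    The boundary is inclusive (exactly 20% at day 3 labels slow). Accepts a
    :class:`ReleaseProfile` or one formulation's rows of a profile table.
    """
    if isinstance(profile, pd.DataFrame):
        grp = profile.sort_values(TIME_COLUMN)
        t, y = grp[TIME_COLUMN].to_numpy(), grp[RELEASE_COLUMN].to_numpy()
    else:
        t, y = profile.time_days, profile.cumulative_release
    return int(release_at_day(t, y) <= SLOW_RELEASE_THRESHOLD)


def label_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Slow-release labels for every formulation in a profile table."""
    rows = [
        {"formulation_id": fid, LABEL_COLUMN: label_slow_release(grp)}
        for fid, grp in profiles.groupby("formulation_id", sort=False)
    ]
    return pd.DataFrame(rows, columns=["formulation_id", LABEL_COLUMN])


def build_feature_table(features: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Join labels onto the feature table (order-independent, canonical
    column order). Raises on duplicate or unmatched formulation ids."""
    if features["formulation_id"].duplicated().any():
        raise ValueError("duplicate formulation_id in feature table")
    if labels["formulation_id"].duplicated().any():
        raise ValueError("duplicate formulation_id in label table")
    missing = set(features["formulation_id"]) - set(labels["formulation_id"])
    if missing:
        raise ValueError(f"no label for formulation_id(s): {sorted(missing)}")
    merged = features.merge(
        labels[["formulation_id", LABEL_COLUMN]], on="formulation_id", how="left"
    )
    merged = merged.sort_values("formulation_id", kind="stable").reset_index(drop=True)
    return merged[KEY_COLUMNS + FEATURE_COLUMNS + [LABEL_COLUMN]]


def profiles_to_objects(profiles: pd.DataFrame) -> list[ReleaseProfile]:
    """Profile table -> list of :class:`ReleaseProfile` (sorted by id)."""
    out = []
    for fid, grp in profiles.groupby("formulation_id", sort=True):
        grp = grp.sort_values(TIME_COLUMN)
        out.append(ReleaseProfile(fid, grp[TIME_COLUMN].to_numpy(),
                                  grp[RELEASE_COLUMN].to_numpy()))
    return out
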