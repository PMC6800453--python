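"""Epigenetic (DNAm) age prediction and age-acceleration statistics.

A linear clock predicts a transformed age from a weighted sum of clock-CpG
β-values; the Horvath-style transform is log-linear below ``adult_age``
and linear above it, so prediction errors scale multiplicatively in
childhood and additively in adults.  Two acceleration measures are
derived: the age-acceleration difference AAD = DNAmAge − chronological
age, and the age-acceleration residual AAR, the residual of DNAmAge
regressed on chronological age across the analysed cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ClockModel",
    "age_transform",
    "inverse_age_transform",
    "read_clock",
    "write_clock",
    "predict_dnam_age",
    "age_acceleration",
]


@dataclass
class ClockModel:
    """Intercept + per-probe weight table defining a linear DNAm-age clock.

    ``intercept`` is in transformed-age units; ``weights`` maps probe_id
    to its coefficient; ``adult_age`` (years, default 20) is the knot of
    the age transform.
    """

    intercept: float
    weights: pd.Series
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        self.weights = pd.Series(self.weights, dtype=float)
        if len(self.weights) == 0:
            raise ValidationError("clock requires at least one weighted probe")
        if self.adult_age <= 0:
            raise ValidationError("adult_age must be positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.weights.index


def age_transform(age, adult_age: float = 20.0):
    """Horvath age transform F: log-linear below adult_age, linear above.

    F(a) = log(a+1) − log(adult+1) for a ≤ adult_age, else
    (a − adult_age) / (adult_age + 1); continuous (both branches are 0 at
    adult_age) and strictly increasing.  Accepts scalars or arrays.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise ValidationError("age must exceed -1 year")
    out = np.where(
        age <= adult_age,
        np.log1p(age) - np.log1p(adult_age),
        (age - adult_age) / (adult_age + 1.0),
    )
    return float(out) if out.ndim == 0 else out


def inverse_age_transform(t, adult_age: float = 20.0):
    """Exact inverse of :func:`age_transform`."""
    t = np.asarray(t, dtype=float)
    out = np.where(
        t <= 0,
        np.expm1(t + np.log1p(adult_age)),
        t * (adult_age + 1.0) + adult_age,
    )
    return float(out) if out.ndim == 0 else out


def read_clock(path: str | Path) -> ClockModel:
    """Read a clock coefficient CSV with header (probe_id, weight).

    The rows with probe_id ``intercept`` and ``adult_age`` carry the model
    metadata; all other rows are probe weights.
    """
    df = pd.read_csv(path, comment="#", dtype={"probe_id": str, "weight": float})
    meta = df[df["probe_id"].isin(["intercept", "adult_age"])].set_index("probe_id")
    if "intercept" not in meta.index:
        raise ValidationError("clock file lacks an intercept row")
    probes = df[~df["probe_id"].isin(["intercept", "adult_age"])]
    adult = float(meta.loc["adult_age", "weight"]) if "adult_age" in meta.index else 20.0
    return ClockModel(
        intercept=float(meta.loc["intercept", "weight"]),
        weights=pd.Series(probes["weight"].to_numpy(), index=probes["probe_id"]),
        adult_age=adult,
    )


def write_clock(clock: ClockModel, path: str | Path) -> None:
    rows = [("intercept", clock.intercept), ("adult_age", clock.adult_age)]
    rows += list(clock.weights.items())
    pd.DataFrame(rows, columns=["probe_id", "weight"]).to_csv(path, index=False)


def predict_dnam_age(
    bm: BetaMatrix, clock: ClockModel, min_coverage: float = 0.5
) -> pd.Series:
    """Per-sample DNAm age from the linear clock.

    The linear predictor is ``intercept + Σ w_j β_j`` over the clock
    probes present in the matrix; probes present but missing in a sample
    are imputed at the probe's cohort mean β, probes absent from the
    matrix are dropped (count logged).  Coverage below ``min_coverage``
    raises, listing the missing probes.
    """
    present = clock.probe_ids[clock.probe_ids.isin(bm.probe_ids)]
    missing = clock.probe_ids.difference(present)
    coverage = len(present) / len(clock.probe_ids)
    if coverage < min_coverage:
        raise ValidationError(
            f"only {len(present)}/{len(clock.probe_ids)} clock probes present "
            f"(coverage {coverage:.2f} < {min_coverage}); missing: "
            f"{missing.tolist()[:10]}"
        )
    if len(missing):
        logger.warning("predict_dnam_age: %d clock probes absent, dropped", len(missing))
    sub = bm.data.loc[present]
    n_imputed = int(sub.isna().to_numpy().sum())
    if n_imputed:
        logger.info("predict_dnam_age: imputing %d missing β at cohort means", n_imputed)
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
    predictor = clock.intercept + clock.weights.loc[present].to_numpy() @ sub.to_numpy()
    dnam = inverse_age_transform(predictor, clock.adult_age)
    return pd.Series(dnam, index=bm.sample_ids, name="dnam_age")


def age_acceleration(
    dnam_ages: pd.Series,
    sheet: SampleSheet,
    group_a: str = "BCVY",
    group_b: str = "BCO",
) -> tuple[pd.DataFrame, dict]:
    """Age-acceleration table and group comparison.

    Returns ``(estimates, comparison)``.  ``estimates`` has one row per
    sample with dnam_age, chronological_age, accel_diff (AAD) and
    accel_residual (AAR, residual of a single cohort-wide least-squares
    line; mean 0 by construction).  ``comparison`` holds the two-sided
    rank-sum p for group_a vs group_b on both acceleration measures,
    per-group Pearson r of DNAmAge vs chronological age, and group means.
    """
    from .diffmeth import rank_sum_test  # shared test, late import avoids cycle

    df = sheet.data.set_index("sample_id").loc[dnam_ages.index]
    chron = df["age"].astype(float)
    est = pd.DataFrame(
        {
            "sample_id": dnam_ages.index,
            "group": df["group"].to_numpy(),
            "dnam_age": dnam_ages.to_numpy(),
            "chronological_age": chron.to_numpy(),
        }
    )
    est["accel_diff"] = est["dnam_age"] - est["chronological_age"]
    slope, intercept = np.polyfit(est["chronological_age"], est["dnam_age"], 1)
    est["accel_residual"] = est["dnam_age"] - (slope * est["chronological_age"] + intercept)

    comparison: dict = {
        "regression_slope": float(slope),
        "regression_intercept": float(intercept),
        "group_mean_dnam_age": est.groupby("group")["dnam_age"].mean().to_dict(),
        "group_mean_accel_diff": est.groupby("group")["accel_diff"].mean().to_dict(),
    }
    for group in (group_a, group_b):
        sub = est[est["group"] == group]
        if len(sub) >= 3 and sub["chronological_age"].nunique() > 1:
            r, p = stats.pearsonr(sub["chronological_age"], sub["dnam_age"])
            comparison[f"pearson_r_{group}"] = float(r)
            comparison[f"pearson_p_{group}"] = float(p)
    a = est.loc[est["group"] == group_a]
    b = est.loc[est["group"] == group_b]
    if len(a) < 2 or len(b) < 2:
        logger.warning("age_acceleration: a group has <2 samples, comparison skipped")
    else:
        for measure in ("accel_diff", "accel_residual"):
            _, p = rank_sum_test(a[measure].to_numpy(), b[measure].to_numpy())
            comparison[f"rank_sum_p_{measure}"] = float(p)
    return est, comparison
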