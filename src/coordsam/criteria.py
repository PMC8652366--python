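"""Validity criteria, normative profile, observability, and the model frame.

Constructs the ingredients of the social accuracy model from tabular rating
data:

* the per-target **validity criterion** C_jk — the target's self-report,
  averaged (two-stage) with the mean of up to three close-other reports;
* the **normative profile** N_k — the mean self-report of all targets on
  each item;
* the **distinctive criterion** D_jk = C_jk - N_k;
* the **observability profile** O_k — reverse-scored, item-averaged,
  grand-mean-centered observability ratings;
* the long model frame with one row per (perceiver, target, item).

All tables use tidy long CSV conventions: self_reports (target_id, item_id,
value), other_reports (target_id, rater_id, item_id, value), perceptions
(perceiver_id, target_id, item_id, value), observability (rater_id,
item_id, value), moderators (target_id, name, value); ratings on a 1-7
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AccuracyCriteria",
    "ObservabilityProfile",
    "build_accuracy_criterion",
    "compute_normative_profile",
    "prepare_observability",
    "assemble_long_data",
]


@dataclass
class AccuracyCriteria:
    """Per-target x item criterion, normative, and distinctive values."""

    criterion: pd.DataFrame  # index target_id, columns item_id
    normative: pd.Series  # index item_id
    distinctive: pd.DataFrame
    provenance: pd.Series  # target_id -> "self_only" | "self_plus_others"


@dataclass
class ObservabilityProfile:
    """Centered item-observability profile; higher = more observable."""

    centered: pd.Series  # index item_id, grand-mean-centered
    sd: float  # SD of the item profile (ddof=1); probe step for +/-1 SD
    raw_means: pd.Series  # reverse-scored item means before centering


def _pivot_reports(df: pd.DataFrame, index: str) -> pd.DataFrame:
    wide = df.pivot_table(index=index, columns="item_id", values="value", aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"missing report entries for items {missing}; no imputation")
    return wide


def build_accuracy_criterion(
    self_reports: pd.DataFrame, other_reports: pd.DataFrame | None = None
) -> AccuracyCriteria:
    """Two-stage composite criterion per target and item.

    With at least one close-other report the criterion is
    ``(self + mean over close others) / 2`` — the close-other reports are
    averaged together *first*, then averaged with the self-report, never
    pooled as a flat mean of all reports.  Targets without any close-other
    report fall back to their self-report alone.

    The normative profile and the distinctive criterion (C - N) are filled
    in afterwards via :func:`compute_normative_profile`.
    """
    self_wide = _pivot_reports(self_reports, "target_id")
    items = self_wide.columns
    criterion = self_wide.copy()
    provenance = pd.Series("self_only", index=self_wide.index, dtype=object)

    if other_reports is not None and len(other_reports):
        per_rater = other_reports.pivot_table(
            index=["target_id", "rater_id"], columns="item_id", values="value"
        )
        if set(per_rater.columns) != set(items) or per_rater.isna().any().any():
            raise ValueError(
                "close-other reports must cover exactly the panel's item set"
            )
        others_mean = per_rater.groupby(level="target_id").mean()
        unknown = others_mean.index.difference(self_wide.index)
        if len(unknown):
            raise ValueError(f"close-other reports for unknown targets: {list(unknown)}")
        covered = others_mean.index
        criterion.loc[covered] = (
            self_wide.loc[covered] + others_mean.loc[covered, items]
        ) / 2.0
        provenance.loc[covered] = "self_plus_others"

    normative = compute_normative_profile(self_reports)
    distinctive = criterion.sub(normative, axis=1)
    return AccuracyCriteria(
        criterion=criterion,
        normative=normative,
        distinctive=distinctive,
        provenance=provenance,
    )


def compute_normative_profile(self_reports: pd.DataFrame) -> pd.Series:
    """Mean self-report of all panel targets on each item."""
    wide = _pivot_reports(self_reports, "target_id")
    if len(wide) < 2:
        raise ValueError("a normative profile needs at least 2 targets")
    return wide.mean(axis=0)


def prepare_observability(raw_ratings: pd.DataFrame) -> ObservabilityProfile:
    """Reverse-score (8 - raw), average per item, grand-mean-center.

    Raters agreed/disagreed that each item is highly observable on a
    1 (strongly agree) - 7 (strongly disagree) scale, so low raw values mean
    high observability; reversal makes higher = more observable.
    """
    vals = raw_ratings["value"].to_numpy(dtype=float)
    if np.any(vals < 1.0) or np.any(vals > 7.0) or not np.all(np.isfinite(vals)):
        raise ValueError("observability ratings must lie in [1, 7]")
    reversed_ = raw_ratings.assign(value=8.0 - raw_ratings["value"])
    means = reversed_.groupby("item_id")["value"].mean()
    centered = means - means.mean()
    sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    return ObservabilityProfile(centered=centered, sd=sd, raw_means=means)


def assemble_long_data(
    perceptions: pd.DataFrame,
    criteria: AccuracyCriteria,
    observability: ObservabilityProfile,
    moderators: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One model row per (perceiver, target, item) rating.

    Columns: ``y`` (the perceiver's rating), ``distinctive`` (D_jk),
    ``normative`` (N_k), ``observability`` (centered O_k), plus one column
    per target-level moderator/covariate, standardized across targets
    (mean 0, SD 1, ddof=1).  Interaction products are formed later by the
    model's design builder, keeping this frame free of redundancy.

    Frame attrs record the observability profile SD (the +/-1 SD probe
    step) and each moderator's original mean/SD for back-scaling.
    """
    frame = perceptions.rename(columns={"value": "y"}).copy()
    d_long = criteria.distinctive.stack().rename("distinctive").reset_index()
    d_long.columns = ["target_id", "item_id", "distinctive"]
    frame = frame.merge(d_long, on=["target_id", "item_id"], how="left")
    if frame["distinctive"].isna().any():
        bad = frame.loc[frame["distinctive"].isna(), ["target_id", "item_id"]]
        raise ValueError(
            f"perceptions reference targets/items without criteria: "
            f"{bad.drop_duplicates().head().to_dict('records')}"
        )
    frame["normative"] = frame["item_id"].map(criteria.normative)
    frame["observability"] = frame["item_id"].map(observability.centered)
    if frame["observability"].isna().any():
        raise ValueError("observability profile missing for some rated items")

    scales = {}
    mod_names, cov_names = [], []
    for table, bucket in ((moderators, mod_names), (covariates, cov_names)):
        if table is None or not len(table):
            continue
        wide = table.pivot_table(index="target_id", columns="name", values="value")
        missing = frame.loc[~frame["target_id"].isin(wide.index), "target_id"].unique()
        if len(missing) or wide.isna().any().any():
            raise ValueError(f"moderator values missing for targets: {list(missing)}")
        for name in wide.columns:
            mu = float(wide[name].mean())
            sd = float(wide[name].std(ddof=1))
            if sd == 0.0:
                raise ValueError(f"moderator {name!r} has zero spread across targets")
            frame[name] = frame["target_id"].map((wide[name] - mu) / sd)
            scales[name] = {"mean": mu, "sd": sd}
            bucket.append(name)

    frame.attrs["observability_sd"] = observability.sd
    frame.attrs["moderator_scales"] = scales
    frame.attrs["moderators"] = mod_names
    frame.attrs["covariates"] = cov_names
    return frame
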