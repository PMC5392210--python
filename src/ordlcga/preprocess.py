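"""Raw assessment records -> wave-bucketed ordinal series.

Implements the pre-modeling decisions: sum-scoring the 10-item true/false
depressive-symptom screener, discretizing the 0-10 score into four severity
categories (cutoffs at 2, 4 and 7; 4+ is the conventional clinical cut),
bucketing irregular assessment times into five waves (baseline, 0.5-3, 3-6,
6-9, 9-15 months), and restricting to participants observed at two or more
waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import N_WAVES

DAYS_PER_MONTH = 30.44
#: wave windows in months, lower-exclusive / upper-inclusive; wave 1 is day 0
WAVE_EDGES_MONTHS = [(0.5, 3.0), (3.0, 6.0), (6.0, 9.0), (9.0, 15.0)]

CATEGORY_LABELS = {1: "minimal", 2: "subthreshold", 3: "moderate", 4: "severe"}


@dataclass
class OrdinalSeries:
    """One participant's bucketed 5-wave ordinal record plus baseline data."""

    participant_id: object
    categories: np.ndarray  # length 5; 0 = missing, else 1..4
    covariates: dict = field(default_factory=dict)
    wpai_total: float | None = None

    @property
    def n_observed(self) -> int:
        return int((self.categories > 0).sum())


def score_cesd(items) -> int:
    """Sum the 10 binary screener items (0-10)."""
    arr = np.asarray(items)
    if arr.shape != (10,):
        raise ValueError("exactly 10 items required")
    if not np.isin(arr, [0, 1]).all():
        raise ValueError("items must be binary 0/1")
    return int(arr.sum())


def categorize_severity(score: int) -> int:
    """Map a 0-10 score to severity: 0-1 minimal, 2-3 subthreshold,
    4-6 moderate, 7-10 severe."""
    score = int(score)
    if not 0 <= score <= 10:
        raise ValueError(f"score {score} outside 0-10")
    if score <= 1:
        return 1
    if score <= 3:
        return 2
    if score <= 6:
        return 3
    return 4


def bucket_time(day_offset: float) -> int | None:
    """Assign days-since-baseline to a wave index 1..5, or None if the offset
    falls in the unassigned (0, 0.5]-month gap or beyond 15 months."""
    if day_offset < 0:
        raise ValueError("day_offset must be non-negative")
    if day_offset == 0:
        return 1
    months = day_offset / DAYS_PER_MONTH
    for w, (lo, hi) in enumerate(WAVE_EDGES_MONTHS, start=2):
        if lo < months <= hi:
            return w
    return None


def build_series(
    records: pd.DataFrame,
    *,
    score_col: str = "cesd_score",
    day_col: str = "day_offset",
    id_col: str = "participant_id",
    wpai_col: str = "wpai_total",
    covariate_cols: list[str] | None = None,
    within_bucket: str = "earliest",
) -> OrdinalSeries | None:
    """Bucket one participant's assessment rows into an :class:`OrdinalSeries`.

    Returns None when fewer than two waves are filled (exclusion rule).
    ``within_bucket`` resolves multiple responses in one wave: "earliest"
    (default; closest to the wave's intended timing), "latest", or "mean"
    (average score before categorization).
    """
    if len(records) == 0:
        raise ValueError("empty record list")
    records = records.sort_values(day_col, kind="stable")
    days = records[day_col].to_numpy()
    if days[0] != 0:
        raise ValueError("first record must be at day_offset 0 (baseline)")
    scores = records[score_col].to_numpy()
    bucket_scores: dict[int, list[float]] = {}
    for d, s in zip(days, scores):
        w = bucket_time(d)
        if w is not None:
            bucket_scores.setdefault(w, []).append(float(s))
    cats = np.zeros(N_WAVES, dtype=int)
    for w, vals in bucket_scores.items():
        if within_bucket == "earliest":
            s = vals[0]
        elif within_bucket == "latest":
            s = vals[-1]
        elif within_bucket == "mean":
            s = round(float(np.mean(vals)))
        else:
            raise ValueError(f"unknown within_bucket rule {within_bucket!r}")
        cats[w - 1] = categorize_severity(s)
    if (cats > 0).sum() < 2:
        return None
    first = records.iloc[0]
    covs = {c: first[c] for c in (covariate_cols or []) if c in records.columns}
    wpai = float(first[wpai_col]) if wpai_col in records.columns and pd.notna(first[wpai_col]) else None
    return OrdinalSeries(first[id_col], cats, covs, wpai)


def build_cohort(
    long_df: pd.DataFrame,
    *,
    covariate_cols: list[str] | None = None,
    within_bucket: str = "earliest",
    **col_kwargs,
) -> pd.DataFrame:
    """Apply :func:`build_series` per participant over a long-format table.

    Returns a wide per-participant frame with columns ``y1..y5`` (0 = missing
    wave), ``n_observed``, baseline covariates and the distal outcome.
    Participants with fewer than two filled waves are dropped.
    """
    id_col = col_kwargs.get("id_col", "participant_id")
    if covariate_cols is None:
        reserved = {id_col, col_kwargs.get("day_col", "day_offset"),
                    col_kwargs.get("score_col", "cesd_score"),
                    col_kwargs.get("wpai_col", "wpai_total")}
        covariate_cols = [c for c in long_df.columns if c not in reserved]
    rows = []
    for pid, grp in long_df.groupby(id_col, sort=False):
        series = build_series(
            grp, covariate_cols=covariate_cols, within_bucket=within_bucket, **col_kwargs
        )
        if series is None:
            continue
        row = {id_col: pid}
        row.update({f"y{t + 1}": int(series.categories[t]) for t in range(N_WAVES)})
        row["n_observed"] = series.n_observed
        row.update(series.covariates)
        row["wpai_total"] = series.wpai_total
        rows.append(row)
    return pd.DataFrame(rows)


def category_matrix(wide_df: pd.DataFrame) -> np.ndarray:
    """Extract the (N, 5) category matrix (0 = missing) from a wide cohort."""
    return wide_df[[f"y{t}" for t in range(1, N_WAVES + 1)]].to_numpy(dtype=int)
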