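"""Delimited-text readers and writers for pipeline artifacts.

Inputs are long-format assessment tables (one row per completed assessment,
UTF-8, header required).  Malformed rows are not silently dropped: they are
collected into a reject report with line numbers and reasons.  All outputs
are plain text (CSV/JSON); every numeric table is spot-checked against its
defining formulas on write.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import score_cesd

_ITEM_COLS = [f"cesd_item{i}" for i in range(1, 11)]


def read_cohort(path, column_map: dict | None = None, sep: str = ","):
    """Read a long-format assessment table.

    ``column_map`` maps file columns to canonical names (``participant_id``,
    ``day_offset``, ``cesd_score``, optional ``cesd_item1..10``,
    ``wpai_total`` and covariates).  Rows with out-of-range scores or negative
    offsets are rejected with a reason; a score conflicting with the item sum
    raises.  Returns ``(records, rejects)``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    if len(df) == 0:
        raise ValueError(f"{path} contains a header but no data rows")
    if column_map:
        missing = [c for c in column_map if c not in df.columns]
        if missing:
            raise ValueError(f"mapped column(s) not in file: {missing}")
        df = df.rename(columns=column_map)
    for required in ("participant_id", "day_offset"):
        if required not in df.columns:
            raise ValueError(f"required column {required!r} missing")

    has_items = all(c in df.columns for c in _ITEM_COLS)
    if "cesd_score" not in df.columns and not has_items:
        raise ValueError("need either 'cesd_score' or all 10 'cesd_item*' columns")
    if has_items:
        sums = df[_ITEM_COLS].apply(lambda r: score_cesd(r.to_numpy()), axis=1)
        if "cesd_score" in df.columns:
            bad = df["cesd_score"].notna() & (df["cesd_score"] != sums)
            if bad.any():
                lines = (df.index[bad] + 2).tolist()[:5]
                raise ValueError(
                    f"cesd_score conflicts with item sum at file line(s) {lines}"
                )
        df["cesd_score"] = sums

    reasons = pd.Series("", index=df.index)
    day = pd.to_numeric(df["day_offset"], errors="coerce")
    score = pd.to_numeric(df["cesd_score"], errors="coerce")
    reasons[day.isna()] = "non-numeric day_offset"
    reasons[day < 0] = "negative day_offset"
    reasons[score.isna()] = "missing or non-numeric cesd_score"
    reasons[(score < 0) | (score > 10)] = "cesd_score outside 0-10"
    bad = reasons != ""
    rejects = pd.DataFrame(
        {"line": df.index[bad] + 2, "reason": reasons[bad],
         "participant_id": df.loc[bad, "participant_id"]}
    ).reset_index(drop=True)
    good = df[~bad].copy()
    good["day_offset"] = day[~bad].astype(int)
    good["cesd_score"] = score[~bad].astype(int)
    return good, rejects


def write_cohort(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_results(outdir, *, fit=None, enum_result=None, predictors=None,
                  distal=None, run_info: dict | None = None) -> list[str]:
    """Write an artifact bundle: fit parameters in per-class-table layout,
    the fit-statistics table, predictor/contrast/distal tables, and a plain
    run log.  Returns the relative paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if fit is not None:
        with open(outdir / "fit.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        written.append("fit.json")

    if enum_result is not None:
        table = enum_result.table.copy()
        # self-consistency: BIC column must reproduce from LL and p
        from .selection import information_criteria

        for _, row in table.iterrows():
            bic, _, _ = information_criteria(row["loglik"], int(row["n_params"]),
                                             enum_result.fits[int(row["K"])].n_obs)
            if abs(bic - row["BIC"]) > 1e-6:
                raise AssertionError("fit-statistic table failed its BIC identity")
        table.to_csv(outdir / "fit_stats.csv", index=False)
        written.append("fit_stats.csv")

    if predictors is not None:
        if predictors.coefficients is not None:
            bad = ~np.isclose(np.exp(predictors.coefficients["log_odds"]),
                              predictors.coefficients["odds_ratio"])
            if bad.any():
                raise AssertionError("odds-ratio column failed exp(log odds) identity")
            predictors.coefficients.to_csv(outdir / "predictors.csv", index=False)
            written.append("predictors.csv")
        if predictors.contrasts is not None:
            predictors.contrasts.to_csv(outdir / "contrasts.csv", index=False)
            written.append("contrasts.csv")

    if distal is not None and distal.distal is not None:
        distal.distal.to_csv(outdir / "distal_means.csv", index=False)
        distal.distal_pairs.to_csv(outdir / "distal_pairs.csv", index=False)
        written.extend(["distal_means.csv", "distal_pairs.csv"])

    info = dict(run_info or {})
    info.setdefault("timestamp", time.strftime("%Y-%m-%dT%H:%M:%S"))
    info.setdefault("python", platform.python_version())
    info.setdefault("numpy", np.__version__)
    info.setdefault("pandas", pd.__version__)
    with open(outdir / "run_log.txt", "w") as fh:
        for key, val in info.items():
            fh.write(f"{key}: {val}\n")
        fh.write("artifacts: " + ", ".join(written) + "\n")
    written.append("run_log.txt")
    return written


def read_fit(path):
    from .em import MixtureFit
    from .model import MixtureSpec

    with open(path) as fh:
        d = json.load(fh)
    return MixtureFit(
        spec=MixtureSpec.from_dict(d["spec"]),
        loglik=d["loglik"],
        posterior=np.empty((0, len(d["spec"]["proportions"]))),
        n_obs=d["n_obs"],
        converged=d["converged"],
        seed=d["seed"],
        n_starts=d["n_starts"],
        n_replicated=d["n_replicated"],
        start_logliks=d.get("start_logliks", []),
        degenerate=d.get("degenerate", False),
    )
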