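"""End-to-end orchestration: simulate/load -> preprocess -> enumerate ->
3-step predictors and distal outcome -> missingness diagnostics.

The stages mirror the analytic workflow of the motivating study.  Each stage
writes its artifacts as soon as it completes, so a failure downstream leaves
earlier outputs intact; :func:`run_pipeline` raises :class:`StageError`
naming the failed stage.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .preprocess import build_cohort, category_matrix
from .selection import enumerate_classes
from .three_step import (
    classification_error,
    modal_assign,
    screen_predictors,
    standardize_predictors,
    step3_distal,
    step3_predictors,
)

log = logging.getLogger("ordlcga")

_CONTINUOUS_DEFAULT = [
    "age", "life_quality", "health_quality", "sleep_quality",
    "sleep_hours", "stress", "alcohol",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    out: str
    input: str | None = None
    simulate_n: int | None = None
    k_max: int = 5
    n_starts: int = 50
    n_final: int = 20
    seed: int = 0
    tol: float = 1e-8
    predictors: list = field(default_factory=list)
    continuous: list = field(default_factory=lambda: list(_CONTINUOUS_DEFAULT))
    distal: str | None = "wpai_total"
    contrasts: list = field(default_factory=list)  # (class_a, class_b) 1-based
    screen_alpha: float = 0.01
    imputations: int = 10
    force: bool = False

    def __post_init__(self) -> None:
        if self.input is None and self.simulate_n is None:
            raise ValueError("either input or simulate_n is required")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a dict of in-memory results."""
    outdir = Path(config.out)
    if outdir.exists() and any(outdir.iterdir()) and not config.force:
        raise StageError("setup", FileExistsError(
            f"{outdir} already contains outputs; pass force=True to overwrite"))
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    results: dict = {}

    stage = "input"
    try:
        if config.simulate_n is not None:
            from .simulate import generate_cohort, default_study_config

            cfg = default_study_config(config.simulate_n)
            long_df, truth = generate_cohort(cfg, config.seed)
            io_mod.write_cohort(long_df, outdir / "cohort.csv")
            results["truth"] = truth
        else:
            long_df, rejects = io_mod.read_cohort(config.input)
            if len(rejects):
                rejects.to_csv(outdir / "rejects.csv", index=False)
        results["long"] = long_df
        log.info("input: %d assessment rows", len(long_df))

        stage = "preprocess"
        wide = build_cohort(long_df)
        io_mod.write_cohort(wide, outdir / "wide.csv")
        results["wide"] = wide
        log.info("preprocess: %d included participants", len(wide))

        stage = "enumerate"
        y = category_matrix(wide)
        enum_res = enumerate_classes(
            y, config.k_max, seed=config.seed,
            n_starts=config.n_starts, n_final=config.n_final, tol=config.tol,
        )
        results["enumeration"] = enum_res
        k_sel = enum_res.recommended_k or config.k_max
        fit = enum_res.fits[k_sel]
        results["fit"] = fit
        io_mod.write_results(outdir, fit=fit, enum_result=enum_res,
                             run_info={"seed": config.seed, "k_selected": k_sel})
        log.info("enumerate: selected K=%d (loglik %.1f)", k_sel, fit.loglik)

        stage = "three_step"
        if fit.spec.n_classes >= 2 and config.distal in wide.columns:
            modal = modal_assign(fit.posterior)
            err = classification_error(fit.posterior, modal)
            results["error_matrix"] = err
            pred_cols = config.predictors or [
                c for c in wide.columns
                if c in set(_CONTINUOUS_DEFAULT) | {"female", "treatment",
                                                    "physical_activity"}
            ]
            x = wide[pred_cols].apply(pd.to_numeric, errors="coerce")
            x = standardize_predictors(x, config.continuous)
            focal = [(a - 1, b - 1) for a, b in config.contrasts] or \
                _default_contrasts(fit.spec.n_classes)
            complete = x.dropna()
            idx = complete.index.to_numpy()
            if focal:
                kept = screen_predictors(
                    modal[idx], err, complete, focal,
                    alpha=config.screen_alpha,
                )
            else:
                kept = list(complete.columns)
            results["screened"] = kept
            if kept:
                res_pred = step3_predictors(
                    modal[idx], err, complete[kept], contrast_pairs=focal,
                )
                results["predictors"] = res_pred
            else:
                res_pred = None
            yvals = pd.to_numeric(wide[config.distal], errors="coerce").to_numpy()
            res_distal = step3_distal(modal, err, yvals)
            results["distal"] = res_distal
            io_mod.write_results(outdir, fit=fit, enum_result=enum_res,
                                 predictors=res_pred, distal=res_distal,
                                 run_info={"seed": config.seed, "k_selected": k_sel})
            log.info("three_step: %d predictor(s) retained", len(kept))
        else:
            log.info("three_step: skipped (K=1 or no distal column)")

        stage = "missingness"
        from .missing import assessment_count_model, sensitivity_refit

        num_cols = [c for c in wide.columns
                    if c not in {"participant_id", "n_observed", "wpai_total"}
                    and not c.startswith("y")]
        xnum = wide[num_cols].apply(pd.to_numeric, errors="coerce")
        xnum = xnum.dropna(axis=1, how="all").dropna()
        try:
            acm = assessment_count_model(xnum, wide.loc[xnum.index, "n_observed"])
            acm.to_csv(outdir / "assessment_count_model.csv")
            results["assessment_count_model"] = acm
            sig = [c for c in acm.index
                   if c != "const" and acm.loc[c, "p"] < 0.01 and not acm.loc[c, "separated"]]
            if sig and fit.spec.n_classes >= 2:
                full = wide[sig].apply(pd.to_numeric, errors="coerce").fillna(
                    xnum[sig].mean())
                sens = sensitivity_refit(y, fit, full)
                results["sensitivity"] = sens
                pd.DataFrame({
                    "unconditional": sens["unconditional"],
                    "refit": sens["proportions"],
                    "delta": sens["deltas"],
                }).to_csv(outdir / "sensitivity_proportions.csv", index=False)
        except ValueError as exc:
            log.info("missingness: diagnostics skipped (%s)", exc)
        log.info("pipeline complete in %.1fs", time.time() - t0)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(stage, exc) from exc
    return results


def _default_contrasts(k: int):
    """When five size-ordered classes are present, the focal contrasts are
    (low-risk-sized vs deteriorating-sized) and (remitting-sized vs
    chronic-sized): indices (1, 4) and (2, 3) 0-based."""
    if k == 5:
        return [(4, 1), (3, 2)]
    return []
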