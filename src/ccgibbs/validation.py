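"""Leave-one-out cross-validation and interval-calibration reporting.

Each unique chemical reaction is held out in turn — all of its replicate
measurements leave the training set together — the estimator is retrained on
the remainder from scratch, and the held-out reaction is scored.  Folds are
classified by whether the held-out vector lies in the span of the remaining
measured reactions (where the reactant-contribution layer applies in full).
Prediction-interval hits are recorded per replicate observation, matching
how calibration is assessed against repeated measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ReactionVector, aggregate_replicates, key_to_reaction
from .groups import GroupIncidence
from .model import CCConfig, estimate, prediction_interval, train

__all__ = ["FoldResult", "CVResult", "loocv", "summarize"]

DEFAULT_LEVELS = (0.68, 0.90, 0.95, 0.99)


@dataclass
class FoldResult:
    reaction: ReactionVector
    observed: float
    n_replicates: int
    cc_estimate: float
    cc_se: float
    gc_estimate: float
    covered: bool
    in_range: bool
    rc_fraction: float
    interval_hits: dict[float, int]  # level -> replicate observations inside
    median_hits: dict[float, bool] = field(default_factory=dict)  # aggregated value inside
    skipped: bool = False

    @property
    def residual_cc(self) -> float:
        return self.observed - self.cc_estimate

    @property
    def residual_gc(self) -> float:
        return self.observed - self.gc_estimate


@dataclass
class CVResult:
    folds: list[FoldResult]
    levels: tuple[float, ...] = DEFAULT_LEVELS

    def to_frame(self) -> pd.DataFrame:
        from .dataset import format_reaction

        rows = []
        for f in self.folds:
            row = {
                "reaction": format_reaction(f.reaction),
                "observed": f.observed,
                "n_replicates": f.n_replicates,
                "cc_estimate": f.cc_estimate,
                "cc_se": f.cc_se,
                "gc_estimate": f.gc_estimate,
                "residual_cc": f.residual_cc,
                "residual_gc": f.residual_gc,
                "covered": f.covered,
                "in_range": f.in_range,
                "rc_fraction": f.rc_fraction,
                "skipped": f.skipped,
            }
            for lvl in self.levels:
                row[f"hits_{int(round(lvl * 100))}"] = f.interval_hits.get(lvl, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def loocv(
    standardized: list[tuple[ReactionVector, float, float, str]],
    gi: GroupIncidence,
    config: CCConfig | None = None,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    in_range_tol: float = 1e-8,
) -> CVResult:
    """Leave-one-unique-reaction-out cross-validation.

    ``standardized`` is the output of :func:`ccgibbs.dataset.standardize`
    (chemical ΔG° per raw observation).  For each fold the full training
    pipeline — aggregation, projection bookkeeping, two-layer fit — is redone
    on the remaining observations; no quantity derived from the held-out
    replicates enters it.  Folds whose remainder cannot support variance
    estimation are marked skipped.
    """
    config = config or CCConfig()
    full = aggregate_replicates(standardized, compound_index=gi.compound_index)
    if full.n_reactions < 3:
        raise ValueError("leave-one-out needs at least 3 unique reactions")

    from .dataset import canonicalize_reaction

    folds: list[FoldResult] = []
    for j, key in enumerate(full.reaction_index):
        held_rxn = key_to_reaction(key)
        held_values = full.replicate_values[j]
        observed = full.dG_obs[j]
        rest = [
            s
            for s in standardized
            if canonicalize_reaction(s[0])[0] != key
        ]
        try:
            td = aggregate_replicates(rest, compound_index=gi.compound_index)
            model = train(td, gi, config)
        except ValueError:
            folds.append(
                FoldResult(
                    reaction=held_rxn,
                    observed=observed,
                    n_replicates=len(held_values),
                    cc_estimate=float("nan"),
                    cc_se=float("nan"),
                    gc_estimate=float("nan"),
                    covered=False,
                    in_range=False,
                    rc_fraction=float("nan"),
                    interval_hits={},
                    skipped=True,
                )
            )
            continue

        est = estimate(model, held_rxn)
        x = held_rxn.to_dense(gi.compound_index)
        in_range = (
            float(np.linalg.norm(model.P_N @ x))
            <= in_range_tol * max(float(np.linalg.norm(x)), 1.0)
        )
        dg_gc_vec = model.dg_gc
        try:
            gvec = gi.G.T @ x
            gc_est = float(gvec @ dg_gc_vec)
        except Exception:
            gc_est = float("nan")
        hits: dict[float, int] = {}
        med_hits: dict[float, bool] = {}
        for lvl in levels:
            lo, hi = prediction_interval(model, held_rxn, lvl)
            hits[lvl] = int(sum(1 for v in held_values if lo <= v <= hi))
            med_hits[lvl] = bool(lo <= observed <= hi)
        folds.append(
            FoldResult(
                reaction=held_rxn,
                observed=observed,
                n_replicates=len(held_values),
                cc_estimate=est.dG0,
                cc_se=est.standard_error,
                gc_estimate=gc_est,
                covered=est.covered,
                in_range=in_range,
                rc_fraction=est.rc_fraction,
                interval_hits=hits,
                median_hits=med_hits,
            )
        )
    return CVResult(folds=folds, levels=levels)


def summarize(cv: CVResult) -> dict:
    """Aggregate a cross-validation run into the headline statistics.

    Median absolute residual per method, split by range class; empirical
    prediction-interval coverage per level (counted over replicate
    observations); a |residual| CDF table; and a paired sign test comparing
    the two methods' absolute residuals (the choice of test is an
    implementation default — any paired location test would do).
    """
    active = [f for f in cv.folds if not f.skipped and f.covered]
    if not active:
        raise ValueError("no scored folds to summarize")

    def med_abs(folds, attr):
        vals = [abs(getattr(f, attr)) for f in folds]
        return float(np.median(vals)) if vals else float("nan")

    in_r = [f for f in active if f.in_range]
    out_r = [f for f in active if not f.in_range]
    coverage = {}
    coverage_median = {}
    for lvl in cv.levels:
        n_obs = sum(f.n_replicates for f in active)
        n_hit = sum(f.interval_hits.get(lvl, 0) for f in active)
        coverage[lvl] = n_hit / n_obs if n_obs else float("nan")
        with_med = [f for f in active if lvl in f.median_hits]
        coverage_median[lvl] = (
            sum(f.median_hits[lvl] for f in with_med) / len(with_med)
            if with_med
            else float("nan")
        )

    # paired sign test on |residual_cc| vs |residual_gc|
    diffs = [abs(f.residual_cc) - abs(f.residual_gc) for f in active]
    wins = sum(1 for d in diffs if d < 0)
    ties = sum(1 for d in diffs if d == 0)
    n_eff = len(diffs) - ties
    p_sign = (
        float(stats.binomtest(wins, n_eff, 0.5).pvalue) if n_eff > 0 else float("nan")
    )

    abs_res = np.sort([abs(f.residual_cc) for f in active])
    cdf = {
        "abs_residual": abs_res.tolist(),
        "cum_fraction": (np.arange(1, len(abs_res) + 1) / len(abs_res)).tolist(),
    }
    return {
        "n_folds": len(cv.folds),
        "n_scored": len(active),
        "n_skipped": sum(1 for f in cv.folds if f.skipped),
        "median_abs_residual_cc": med_abs(active, "residual_cc"),
        "median_abs_residual_gc": med_abs(active, "residual_gc"),
        "median_abs_residual_cc_in_range": med_abs(in_r, "residual_cc"),
        "median_abs_residual_gc_in_range": med_abs(in_r, "residual_gc"),
        "median_abs_residual_cc_out_of_range": med_abs(out_r, "residual_cc"),
        "median_abs_residual_gc_out_of_range": med_abs(out_r, "residual_gc"),
        "n_in_range": len(in_r),
        "n_out_of_range": len(out_r),
        "interval_coverage": {str(k): v for k, v in coverage.items()},
        "interval_coverage_median": {str(k): v for k, v in coverage_median.items()},
        "sign_test_p_value": p_sign,
        "cdf": cdf,
    }
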