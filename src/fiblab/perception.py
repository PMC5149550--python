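"""Perception-test scoring and movement-perception association.

Turns raw judge x clip rating tables into the study's outcome measures:

* per-clip *percent-lie* (how often each clip was called a lie),
* per-judge x condition mean lie response, tested against chance (50%)
  and compared across conditions with a within-subject ANOVA plus
  Bonferroni post hocs,
* relative frequencies of the questionnaire cue regions among lie
  responses,
* the Spearman association between clip movement and lie perception,
* Wilcoxon condition and region contrasts on the movement scores, with
  children as the pairing units.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import stats as _stats
from .stats import DegenerateSampleError, TestResult

__all__ = [
    "validate_ratings",
    "percent_lie_per_clip",
    "judge_condition_scores",
    "condition_analysis",
    "cue_region_frequencies",
    "movement_perception_association",
    "condition_movement_tests",
]

logger = logging.getLogger("fiblab.perception")

CONDITIONS = ("Tc", "Ly1", "Ly2")
CUE_COLUMNS = ("cue_face", "cue_shoulders", "cue_legs", "cue_feet", "cue_other")
MOVEMENT_MEASURES = ("total", "head", "trunk", "legs")


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check and clean a rating table.

    Requires ``judge_id, clip_id, condition, response_lie`` columns;
    duplicate judge x clip records raise; records flagging cue regions on
    a "truth" response are dropped with a logged warning (the
    questionnaire only asks for cues after a "lie" answer).
    """
    required = {"judge_id", "clip_id", "condition", "response_lie"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"rating table missing columns {sorted(missing)}")
    if ratings.duplicated(["judge_id", "clip_id"]).any():
        raise ValueError("rating table has duplicate judge x clip records")
    out = ratings.copy()
    out["response_lie"] = out["response_lie"].astype(int)
    if not out["response_lie"].isin((0, 1)).all():
        raise ValueError("response_lie must be binary")
    cue_cols = [c for c in CUE_COLUMNS if c in out.columns]
    if cue_cols:
        flagged = out[cue_cols].astype(int).sum(axis=1) > 0
        bad = flagged & (out["response_lie"] == 0)
        if bad.any():
            logger.warning(
                "dropping %d records with cue flags on a truth response", int(bad.sum())
            )
            out = out[~bad].reset_index(drop=True)
    return out


def percent_lie_per_clip(ratings: pd.DataFrame) -> pd.DataFrame:
    """Percentage of judges classifying each clip as a lie.

    Returns ``clip_id, condition, percent_lie, n_judges``; clips with no
    responses are simply absent (logged if the table was empty).
    """
    ratings = validate_ratings(ratings)
    if ratings.empty:
        logger.warning("empty rating table: no clip scores")
        return pd.DataFrame(columns=["clip_id", "condition", "percent_lie", "n_judges"])
    grouped = ratings.groupby(["clip_id", "condition"], sort=True)["response_lie"]
    out = grouped.agg(["mean", "count"]).reset_index()
    out["percent_lie"] = 100.0 * out.pop("mean")
    out = out.rename(columns={"count": "n_judges"})
    return out[["clip_id", "condition", "percent_lie", "n_judges"]]


def judge_condition_scores(ratings: pd.DataFrame) -> pd.DataFrame:
    """Mean lie response per judge x condition (proportions in [0, 1]).

    Judges missing any condition are excluded with a warning so the table
    stays complete for the within-subject tests.
    """
    ratings = validate_ratings(ratings)
    scores = (
        ratings.groupby(["judge_id", "condition"], sort=True)["response_lie"]
        .mean()
        .reset_index(name="mean_lie_response")
    )
    conditions = sorted(ratings["condition"].unique())
    counts = scores.groupby("judge_id")["condition"].nunique()
    incomplete = counts[counts < len(conditions)].index
    if len(incomplete):
        logger.warning(
            "excluding %d judges missing one or more conditions", len(incomplete)
        )
        scores = scores[~scores["judge_id"].isin(incomplete)]
    return scores.reset_index(drop=True)


def _scores_wide(scores: pd.DataFrame, conditions: Sequence[str]) -> pd.DataFrame:
    wide = scores.pivot(index="judge_id", columns="condition", values="mean_lie_response")
    return wide[[c for c in conditions if c in wide.columns]]


def condition_analysis(scores: pd.DataFrame, chance: float = 0.5) -> dict:
    """Full perception analysis on a judge x condition score table.

    Per condition, a one-sample t-test of the judges' mean lie responses
    against chance; across conditions, the repeated-measures ANOVA and
    Bonferroni-corrected pairwise comparisons.  ``scores`` is the tidy
    output of :func:`judge_condition_scores`.
    """
    conditions = [c for c in CONDITIONS if c in set(scores["condition"])]
    conditions += sorted(set(scores["condition"]) - set(conditions))
    wide = _scores_wide(scores, conditions)
    if wide.isna().any().any():
        raise ValueError("incomplete judge x condition table")
    chance_tests = {
        c: _stats.one_sample_t(wide[c].to_numpy(), chance) for c in conditions
    }
    report: dict = {
        "conditions": conditions,
        "n_judges": int(wide.shape[0]),
        "chance_level": chance,
        "chance_tests": chance_tests,
        "condition_means": {c: float(wide[c].mean()) for c in conditions},
        "condition_sds": {c: float(wide[c].std(ddof=1)) for c in conditions},
    }
    if len(conditions) >= 2:
        report["anova"] = _stats.rm_anova_oneway(wide)
        report["pairwise"] = _stats.bonferroni_pairwise(wide.to_numpy(), conditions)
    return report


def cue_region_frequencies(ratings: pd.DataFrame) -> dict[str, float]:
    """Relative frequency (percent) of each cue region among lie responses.

    The denominator is the number of responses where the judge answered
    "lie" (whether or not the clip really was one); multi-select flags may
    therefore sum to more than 100%.  Returns an empty dict when there are
    no lie responses.
    """
    ratings = validate_ratings(ratings)
    lies = ratings[ratings["response_lie"] == 1]
    if lies.empty:
        logger.warning("no lie responses: cue frequencies undefined")
        return {}
    out: dict[str, float] = {}
    for col in CUE_COLUMNS:
        if col in lies.columns:
            region = col.removeprefix("cue_")
            out[region] = 100.0 * float(lies[col].astype(int).mean())
    return out


def movement_perception_association(
    clip_scores: pd.DataFrame,
    movement: pd.DataFrame,
    region: str | None = None,
) -> TestResult:
    """Spearman correlation between percent-lie and clip movement.

    All clips are pooled across conditions.  ``region=None`` correlates
    against the overall movement score; naming a region (``"head"`` etc.)
    uses that region's score instead.  The clip sets must match
    one-to-one.
    """
    col = "total" if region is None else region
    if col not in movement.columns:
        raise ValueError(f"movement table has no '{col}' column")
    if set(clip_scores["clip_id"]) != set(movement["clip_id"]):
        raise ValueError("clip sets of ratings and movement scores do not match")
    merged = clip_scores.merge(movement[["clip_id", col]], on="clip_id", validate="1:1")
    res = _stats.spearman(merged[col].to_numpy(), merged["percent_lie"].to_numpy())
    res.extra["movement_measure"] = col
    return res


def _wilcoxon_or_degenerate(a, b, tag: str, method: str) -> TestResult:
    try:
        res = _stats.wilcoxon_signed_rank(a, b)
    except DegenerateSampleError as exc:
        return TestResult(
            method=method,
            statistic=float("nan"),
            p_value=float("nan"),
            extra={"comparison": tag, "error": str(exc)},
        )
    res.method = method
    res.extra["comparison"] = tag
    return res


def condition_movement_tests(movement: pd.DataFrame) -> list[TestResult]:
    """Wilcoxon contrasts on the movement scores, paired by child.

    Two families of signed-rank tests, children as pairing units:

    * condition contrasts Tc-vs-Ly1 and Tc-vs-Ly2 on the overall score and
      on each region score;
    * region contrasts (head-vs-trunk, head-vs-legs, trunk-vs-legs) within
      each condition.

    Children lacking any of the three conditions are excluded with a
    warning.  Degenerate pairs (identical scores) are reported as
    flagged placeholder results rather than aborting the whole family.
    """
    required = {"child_id", "condition"} | set(MOVEMENT_MEASURES)
    missing = required - set(movement.columns)
    if missing:
        raise ValueError(f"movement table missing columns {sorted(missing)}")
    counts = movement.groupby("child_id")["condition"].nunique()
    complete = counts[counts == len(CONDITIONS)].index
    dropped = set(movement["child_id"]) - set(complete)
    if dropped:
        logger.warning("excluding %d children with incomplete condition triplets", len(dropped))
    m = movement[movement["child_id"].isin(complete)]
    results: list[TestResult] = []
    for measure in MOVEMENT_MEASURES:
        wide = m.pivot(index="child_id", columns="condition", values=measure)
        for other in ("Ly1", "Ly2"):
            tag = f"{measure}:Tc-vs-{other}"
            results.append(
                _wilcoxon_or_degenerate(
                    wide["Tc"].to_numpy(), wide[other].to_numpy(), tag,
                    "wilcoxon-condition",
                )
            )
    for cond in CONDITIONS:
        sub = m[m["condition"] == cond].set_index("child_id")
        for r1, r2 in (("head", "trunk"), ("head", "legs"), ("trunk", "legs")):
            tag = f"{cond}:{r1}-vs-{r2}"
            results.append(
                _wilcoxon_or_degenerate(
                    sub[r1].to_numpy(), sub[r2].to_numpy(), tag, "wilcoxon-region"
                )
            )
    return results
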