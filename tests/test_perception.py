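"""Tests of the perception-test scoring and movement-perception linkage."""

import numpy as np
import pandas as pd
import pytest

from fiblab.perception import (
    condition_analysis,
    condition_movement_tests,
    cue_region_frequencies,
    judge_condition_scores,
    movement_perception_association,
    percent_lie_per_clip,
    validate_ratings,
)
from fiblab.stats import DegenerateSampleError


def make_ratings(responses, clip_conditions=None, cues=None):
    """Build a rating table from a judge x clip 0/1 response matrix."""
    responses = np.asarray(responses)
    n_judges, n_clips = responses.shape
    conditions = clip_conditions or ["Tc"] * n_clips
    rows = []
    for j in range(n_judges):
        for c in range(n_clips):
            row = {
                "judge_id": f"j{j:02d}",
                "clip_id": f"c{c:02d}",
                "condition": conditions[c],
                "response_lie": int(responses[j, c]),
            }
            if cues is not None:
                row.update({k: int(v and responses[j, c]) for k, v in cues.items()})
            rows.append(row)
    return pd.DataFrame(rows)


class TestPercentLie:
    def test_twelve_of_twenty(self):
        responses = np.zeros((20, 1), dtype=int)
        responses[:12, 0] = 1
        out = percent_lie_per_clip(make_ratings(responses))
        assert out["percent_lie"].iloc[0] == 60.0
        assert out["n_judges"].iloc[0] == 20

    def test_single_judge_lie_is_hundred(self):
        out = percent_lie_per_clip(make_ratings([[1]]))
        assert out["percent_lie"].iloc[0] == 100.0

    def test_perfect_judges_zero_vs_hundred(self, small_study):
        ratings = small_study.ratings.copy()
        ratings["response_lie"] = ratings["condition"].isin(["Ly1", "Ly2"]).astype(int)
        for col in [c for c in ratings.columns if c.startswith("cue_")]:
            ratings[col] = ratings[col].astype(int) & ratings["response_lie"]
        out = percent_lie_per_clip(ratings)
        assert (out.loc[out["condition"] == "Tc", "percent_lie"] == 0.0).all()
        assert (out.loc[out["condition"] != "Tc", "percent_lie"] == 100.0).all()

    def test_invariant_to_row_order(self, small_study):
        ratings = small_study.ratings
        shuffled = ratings.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = percent_lie_per_clip(ratings)
        b = percent_lie_per_clip(shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestJudgeConditionScores:
    def test_mean_of_thirty_clips(self):
        responses = np.zeros((1, 30), dtype=int)
        responses[0, :9] = 1
        scores = judge_condition_scores(make_ratings(responses))
        assert scores["mean_lie_response"].iloc[0] == pytest.approx(0.3)

    def test_always_lie_judges(self):
        scores = judge_condition_scores(make_ratings(np.ones((4, 6), dtype=int)))
        assert (scores["mean_lie_response"] == 1.0).all()

    def test_incomplete_judge_excluded(self, caplog):
        df = make_ratings(np.ones((2, 2), dtype=int), ["Tc", "Ly1"])
        df = df.drop(df[(df.judge_id == "j01") & (df.condition == "Ly1")].index)
        with caplog.at_level("WARNING"):
            scores = judge_condition_scores(df)
        assert set(scores["judge_id"]) == {"j00"}
        assert "excluding" in caplog.text

    def test_balanced_design_identity(self, small_study):
        """Mean judge score per condition equals mean clip percent-lie / 100."""
        ratings = small_study.ratings
        judge = judge_condition_scores(ratings).groupby("condition")["mean_lie_response"].mean()
        clip = percent_lie_per_clip(ratings).groupby("condition")["percent_lie"].mean() / 100
        for cond in judge.index:
            assert judge[cond] == pytest.approx(clip[cond], rel=1e-12)


class TestConditionAnalysis:
    def test_report_shape_and_df(self, small_study):
        scores = judge_condition_scores(small_study.ratings)
        report = condition_analysis(scores)
        assert report["conditions"] == ["Tc", "Ly1", "Ly2"]
        assert report["n_judges"] == 20
        assert report["anova"].df == (2.0, 38.0)
        assert len(report["pairwise"]) == 3

    def test_two_conditions_anova_df(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            {
                "judge_id": np.repeat([f"j{i}" for i in range(8)], 2),
                "condition": ["Tc", "Ly1"] * 8,
                "mean_lie_response": rng.random(16),
            }
        )
        report = condition_analysis(scores)
        assert report["anova"].df == (1.0, 7.0)

    def test_chance_scores_rarely_significant(self):
        rejections = {c: 0 for c in ("Tc", "Ly1", "Ly2")}
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            rows = []
            for j in range(20):
                for cond in rejections:
                    rows.append(
                        {
                            "judge_id": f"j{j:02d}",
                            "condition": cond,
                            "mean_lie_response": 0.5 + rng.normal(0, 0.05),
                        }
                    )
            report = condition_analysis(pd.DataFrame(rows))
            for cond, res in report["chance_tests"].items():
                rejections[cond] += res.p_value < 0.05
        for cond, k in rejections.items():
            assert k <= n_seeds * 0.1, f"{cond} rejected {k}/{n_seeds}"

    def test_default_study_posthoc_pattern(self):
        """Both lying conditions separate from truth; Ly1 vs Ly2 does not."""
        hits = 0
        n_seeds = 10
        from fiblab import generate_study

        for seed in range(n_seeds):
            bundle = generate_study(n_children=30, seed=400 + seed, with_gaze=False,
                                    keep_clips=False)
            report = condition_analysis(judge_condition_scores(bundle.ratings))
            pw = {r.extra["comparison"]: r.p_value for r in report["pairwise"]}
            hits += (
                pw["Tc-vs-Ly1"] < 0.05
                and pw["Tc-vs-Ly2"] < 0.05
                and pw["Ly1-vs-Ly2"] >= 0.05
            )
        assert hits > n_seeds / 2


class TestCueFrequencies:
    def test_three_of_four_flag_face(self):
        responses = np.array([[1, 1, 1, 1, 0]])
        df = make_ratings(responses)
        df["cue_face"] = [1, 1, 1, 0, 0]
        assert cue_region_frequencies(df)["face"] == 75.0

    def test_single_flag_partition_sums_to_hundred(self):
        responses = np.ones((1, 6), dtype=int)
        df = make_ratings(responses)
        for col in ("cue_face", "cue_shoulders", "cue_legs", "cue_feet", "cue_other"):
            df[col] = 0
        df.loc[:1, "cue_face"] = 1
        df.loc[2:3, "cue_legs"] = 1
        df.loc[4:5, "cue_feet"] = 1
        freqs = cue_region_frequencies(df)
        assert sum(freqs.values()) == pytest.approx(100.0)

    def test_no_flags_all_zero(self):
        df = make_ratings(np.ones((2, 3), dtype=int))
        df["cue_face"] = 0
        assert cue_region_frequencies(df)["face"] == 0.0

    def test_no_lie_responses_empty(self):
        assert cue_region_frequencies(make_ratings(np.zeros((2, 3), dtype=int))) == {}

    def test_truth_with_cue_flags_dropped(self, caplog):
        df = make_ratings(np.zeros((1, 2), dtype=int))
        df["cue_face"] = [1, 0]
        with caplog.at_level("WARNING"):
            clean = validate_ratings(df)
        assert len(clean) == 1
        assert "dropping" in caplog.text

    def test_duplicate_records_rejected(self):
        df = make_ratings(np.ones((1, 1), dtype=int))
        with pytest.raises(ValueError):
            validate_ratings(pd.concat([df, df]))


class TestAssociation:
    def test_constant_movement_degenerate(self, small_study):
        movement = small_study.movement.copy()
        movement["total"] = 1.0
        clip_scores = percent_lie_per_clip(small_study.ratings)
        with pytest.raises(DegenerateSampleError):
            movement_perception_association(clip_scores, movement)

    def test_mismatched_clips_rejected(self, small_study):
        clip_scores = percent_lie_per_clip(small_study.ratings)
        movement = small_study.movement.iloc[:-1]
        with pytest.raises(ValueError):
            movement_perception_association(clip_scores, movement)

    def test_positive_association_with_default_effects(self, small_study):
        clip_scores = percent_lie_per_clip(small_study.ratings)
        res = movement_perception_association(clip_scores, small_study.movement)
        assert res.statistic > 0

    def test_head_region_usually_below_pooled(self):
        from fiblab import generate_study

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            bundle = generate_study(n_children=30, seed=200 + seed, with_gaze=False,
                                    keep_clips=False)
            cs = percent_lie_per_clip(bundle.ratings)
            total = movement_perception_association(cs, bundle.movement).statistic
            head = movement_perception_association(cs, bundle.movement, "head").statistic
            wins += head < total
        assert wins > n_seeds / 2


class TestConditionMovementTests:
    @staticmethod
    def movement_frame(n_children=6, offsets=(0.0, 0.0, 1.0)):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(n_children):
            base = rng.uniform(2, 6)
            for cond, off in zip(("Tc", "Ly1", "Ly2"), offsets):
                rows.append(
                    {
                        "clip_id": f"ch{i}_{cond}",
                        "child_id": f"ch{i}",
                        "condition": cond,
                        "total": base + off,
                        "head": base + off + 1,
                        "trunk": base + off,
                        "legs": base + off - 1,
                    }
                )
        return pd.DataFrame(rows)

    def test_constant_shift_gives_minimum_exact_p(self):
        m = self.movement_frame(n_children=6, offsets=(0.0, 0.5, 1.0))
        results = {r.extra["comparison"]: r for r in condition_movement_tests(m)}
        res = results["total:Tc-vs-Ly2"]
        # all six differences negative: most extreme of 2^6 patterns
        assert res.p_value == pytest.approx(2 / 64)
        assert res.extra["w_minus"] == 21.0  # Tc - Ly2 < 0 everywhere

    def test_identical_conditions_flagged_degenerate(self):
        m = self.movement_frame(offsets=(0.0, 0.0, 1.0))
        results = {r.extra["comparison"]: r for r in condition_movement_tests(m)}
        assert "error" in results["total:Tc-vs-Ly1"].extra
        assert "error" not in results["total:Tc-vs-Ly2"].extra

    def test_incomplete_child_excluded(self, caplog):
        m = self.movement_frame()
        m = m[~((m.child_id == "ch0") & (m.condition == "Ly2"))]
        with caplog.at_level("WARNING"):
            results = condition_movement_tests(m)
        assert "incomplete" in caplog.text
        res = next(r for r in results if r.extra["comparison"] == "total:Tc-vs-Ly2")
        assert res.extra["n_nonzero"] == 5  # ch0 dropped

    def test_region_contrast_direction(self):
        m = self.movement_frame()
        results = {r.extra["comparison"]: r for r in condition_movement_tests(m)}
        res = results["Tc:head-vs-legs"]
        assert res.extra["w_plus"] == 21.0  # head > legs for every child
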