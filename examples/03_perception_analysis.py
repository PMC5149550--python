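"""Score a perception test and link lie judgments to clip movement.

Reproduces the analysis chain of a judge study: percent-lie per clip,
per-condition accuracy against chance (50%), the within-subject ANOVA
with Bonferroni post hocs, cue-region frequencies, and the Spearman
association between movement and perceived deception.
"""

from fiblab import (
    condition_analysis,
    cue_region_frequencies,
    generate_study,
    judge_condition_scores,
    movement_perception_association,
    percent_lie_per_clip,
)

bundle = generate_study(n_children=30, seed=11, with_gaze=False)
ratings = bundle.ratings

report = condition_analysis(judge_condition_scores(ratings))
print("mean lie-response rate per condition (judges' average, chance = 0.5):")
for cond in report["conditions"]:
    t = report["chance_tests"][cond]
    print(
        f"  {cond:>3}: M = {report['condition_means'][cond]:.2f} "
        f"(SD = {report['condition_sds'][cond]:.2f}), "
        f"t({t.df:.0f}) = {t.statistic:.2f}, p = {t.p_value:.4f}"
    )
anova = report["anova"]
print(
    f"\ncondition effect: F({anova.df[0]:.0f},{anova.df[1]:.0f}) = "
    f"{anova.statistic:.2f}, p = {anova.p_value:.2g}"
)
for res in report["pairwise"]:
    print(f"  {res.extra['comparison']:>10}: Bonferroni p = {res.p_value:.4f}")

print("\ncue regions flagged on 'lie' answers (% of lie responses, multi-select):")
for region, pct in sorted(cue_region_frequencies(ratings).items(), key=lambda kv: -kv[1]):
    print(f"  {region:>9}: {pct:.1f}%")

assoc = movement_perception_association(percent_lie_per_clip(ratings), bundle.movement)
print(
    f"\nmovement vs lie perception: rs = {assoc.statistic:.2f}, "
    f"n = {assoc.extra['n']}, p = {assoc.p_value:.2g}"
    "\n(positive rs: the more a child moves in a clip, the more judges call it a lie)"
)
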