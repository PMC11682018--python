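"""Score raw trials into block indicators and screen careless responding.

Each answered prompt yields two blocks per task; the four scores are the
incongruent error rate and congruent/incongruent RT difference (Stroop)
and the no-go commission rate and mean correct go RT (go/no-go).  A 5%
careless fraction is planted (sub-second item times, hammered responses,
extreme error rates) and the screening rules are expected to remove
exactly those prompts plus any 3-SD outliers.
"""

import warnings

from lstema import (GeneratorConfig, generate_trial_level, score_blocks,
                    apply_exclusions)

cfg = GeneratorConfig(n_subjects=10, n_days=7, seed=2,
                      careless_fraction=0.05)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    data = generate_trial_level(cfg)
    blocks = score_blocks(data.trials)
    clean, report = apply_exclusions(blocks, data.questionnaire, data.trials)

print(blocks[["subject_id", "occasion_index", "block", "stroop_er",
              "stroop_rtdiff", "gng_er", "gng_rt"]].head(4).to_string(
    index=False))
print()
planted = int(data.context["careless"].sum())
print(f"planted careless prompts:          {planted}")
print(f"flagged by <1 s item-time rule:    "
      f"{report.n_prompts_flagged_itemtime}")
print(f"Stroop blocks over longstring cut: "
      f"{report.n_blocks_flagged_longstring}")
print(f"occasions over the 3-SD error cut: {report.n_occasions_excluded}")
print(f"subjects retained (>= 5 complete): {report.n_subjects_retained}")
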