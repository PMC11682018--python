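"""Reliability of change (R_c) versus test length and study day.

R_c = sigma2_pt / (sigma2_pt + sigma2_e / m) asks how reliably the m = 2
parallel blocks track shared within-person ups and downs.  Rescoring
blocks from the first n trials per condition shows how many trials a
protocol needs; estimating R_c per study day checks that reliability does
not drift over the two weeks.
"""

import warnings

from lstema import (GeneratorConfig, generate_trial_level, score_blocks,
                    rc_by_trialcount, rc_by_day)

cfg = GeneratorConfig(n_subjects=25, n_days=7, seed=4, compliance_rate=0.8)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    data = generate_trial_level(cfg)
    curve = rc_by_trialcount(data.trials, step=4,
                             scores=("gng_er", "gng_rt"))
    daily = rc_by_day(score_blocks(data.trials), scores=("gng_rt",))

print("R_c by trials per block and condition:")
print(curve.pivot(index="n_per_condition", columns="score", values="rc")
      .round(3).to_string())
print()
print("R_c of the go/no-go RT per study day (expected: flat):")
print(daily[["day", "rc"]].round(3).to_string(index=False))
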