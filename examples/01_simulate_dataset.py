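"""Generate a synthetic EMA dataset of smartphone Stroop and go/no-go tasks.

Builds a small study (10 subjects, 7 days, 4 prompts/day, ~51% compliance)
and prints what the four output streams contain.  Trial rows carry raw
reaction times and correctness; the latent table records the trait and
occasion-factor values each block aggregate tracks, which is what makes
parameter-recovery experiments possible.
"""

from lstema import GeneratorConfig, generate_trial_level

cfg = GeneratorConfig(n_subjects=10, n_days=7, seed=1)
data = generate_trial_level(cfg)

print(f"trials:        {len(data.trials):>7} rows "
      f"(one per presented Stroop/go-no-go trial)")
print(f"questionnaire: {len(data.questionnaire):>7} rows "
      f"(one per item per answered prompt)")
print(f"context:       {len(data.context):>7} rows (one per answered prompt)")
print(f"latents:       {len(data.latents):>7} rows "
      f"(subject x occasion x score)")
print()
print(data.trials.head(5).to_string(index=False))
print()
answered = data.context.groupby("subject_id").size()
print(f"answered prompts per subject: mean {answered.mean():.1f} "
      f"of {cfg.n_occasions} scheduled "
      f"(compliance target {cfg.compliance_rate:.0%})")
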