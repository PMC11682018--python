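"""Fit the AR(1) latent state-trait model and decompose the variance.

Score-level data are generated exactly under the model
Y_itn = xi_n + OCC_tn + beta*time_t + eps_itn with a known parameter set,
then re-estimated by maximum marginal likelihood.  The printed indices
answer: how much of an observed block score is stable trait (consistency),
systematic situational fluctuation (occasion specificity), and noise —
and how reliably the two blocks track within-person change (within-
subject reliability).
"""

from lstema import (DSEMParams, GeneratorConfig, generate_score_level,
                    blocks_to_wide, fit_dsem)

truth = DSEMParams(mu_trait=0.0, var_trait=1.0, beta=-0.005, phi=0.3,
                   var_state=0.5, var_error=0.5)
cfg = GeneratorConfig(n_subjects=70, n_days=14, prompts_per_day=4,
                      compliance_rate=1.0, seed=3, scores={"y": truth})
blocks, _ = generate_score_level(cfg)
fit = fit_dsem(blocks_to_wide(blocks, "y"))

print(f"{'parameter':<12}{'truth':>8}{'estimate':>10}{'SE':>8}")
for name in ("mu_trait", "var_trait", "beta", "phi", "var_state",
             "var_error"):
    print(f"{name:<12}{getattr(truth, name):>8.3f}"
          f"{getattr(fit.params, name):>10.3f}{fit.se[name]:>8.3f}")
ix = fit.indices
print()
print(f"reliability            Rel  = {ix.rel:.3f}")
print(f"common consistency     Con  = {ix.con:.3f}")
print(f"occasion specificity   Spe  = {ix.spe:.3f}")
print(f"within-subject rel.    Relw = {ix.rel_within:.3f}")
print()
print("Rel - Con exceeds Spe because the occasion factor accumulates "
      "autoregressive carry-over\nfrom earlier innovations "
      f"(Var(OCC) = {ix.var_occ:.3f} vs Var(zeta) = "
      f"{fit.params.var_state:.3f}).")
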