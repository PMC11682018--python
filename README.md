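# lstema

Latent state–trait reliability analysis of cognitive-control tasks in
ecological momentary assessment (EMA).

When a Stroop or go/no-go task is administered on smartphones several
times a day for two weeks, every block score mixes three things: a stable
person trait, a systematic situational state, and measurement noise. For
anyone who wants to use moment-to-moment fluctuations of cognitive control
as a predictor or outcome — in health psychology, psychiatry or cognitive
science — the binding question is whether those fluctuations are measured
reliably at all. `lstema` answers it end to end: it scores raw trials into
parallel block indicators, screens careless responding, fits a dynamic
structural equation model (DSEM) with an AR(1) latent occasion process,
and reports the revised latent state–trait (LST-R) variance decomposition
together with generalizability-theory reliability-of-change curves and
within/between validity analyses. A synthetic-data generator reproduces
the statistical structure of such a protocol, so every estimator in the
package can be validated by parameter recovery.

## Model

Each task score is measured by two parallel block indicators per scheduled
occasion. For indicator *i*, occasion *t* and person *n*:

```
Y_itn  = ξ_1n + OCC_tn + β·time_t + ε_itn
OCC_1n = ζ_1n,   OCC_tn = φ·OCC_{t−1,n} + ζ_tn   (t = 2,…,T)
```

with trait ξ_1n ~ N(μ_ξ, Var(ξ)), i.i.d. innovations ζ_tn ~ N(0, Var(ζ)),
errors ε_itn ~ N(0, Var(ε)) and |φ| < 1. The model is estimated by maximum
marginal likelihood (Kalman filter over the scheduled occasion grid;
missing prompts are marginalized, not imputed). With the occasion-factor
variance approximated over the previous four occasions,
Var(OCC) ≈ Var(ζ)·(1 + φ² + φ⁴ + φ⁶ + φ⁸), the indices are

| index | formula | meaning |
|---|---|---|
| Rel | (Var(ξ) + Var(OCC)) / Var(Y) | overall reliability |
| Con | Var(ξ) / Var(Y) | common consistency (trait share) |
| Spe | Var(ζ) / Var(Y) | occasion specificity (state-residual share) |
| Rel_within | Var(OCC) / (Var(OCC) + Var(ε)) | within-subject reliability |

The reliability of change over the m = 2 blocks is the
generalizability-theory index R_c = σ²_{p·t} / (σ²_{p·t} + σ²_ε/m), with
components estimated by REML from the person × occasion × block layout.

## Worked example

`examples/03_fit_state_trait_model.py` simulates 70 subjects × 56
occasions under known parameters and re-estimates them:

```
parameter      truth  estimate      SE
mu_trait       0.000     0.041   0.124
var_trait      1.000     0.997   0.172
beta          -0.005    -0.005   0.001
phi            0.300     0.285   0.023
var_state      0.500     0.503   0.018
var_error      0.500     0.494   0.011

reliability            Rel  = 0.758
common consistency     Con  = 0.489
occasion specificity   Spe  = 0.247
within-subject rel.    Relw = 0.525
```

All six parameters are recovered within one standard error. The indices
say that 75.8% of an observed block score is systematic, 48.9% of it
stable trait; 24.7% comes from fresh situational innovations, and the two
blocks track within-person fluctuation with reliability 0.525. Rel − Con
(= 0.269) exceeds Spe because the AR(1) occasion factor carries over part
of earlier innovations.

The other examples cover simulation (`01`), scoring and
careless-responding screening (`02`), reliability-of-change curves against
trials per block and per study day (`04`), and within/between validity
plus contextual mixed models (`05`).

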