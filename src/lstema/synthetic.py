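"""Synthetic EMA datasets for smartphone Stroop and go/no-go protocols.

Two generation modes share one latent model per task score:

* **score level** — emits the two parallel block indicators per scheduled
  occasion directly from the latent state-trait equations
  ``Y_itn = xi_n + OCC_tn + beta*time_t + eps_itn`` (the exact structure the
  estimator assumes), together with the latent values for recovery tests.
* **trial level** — emits raw trials whose block aggregates follow that
  structure approximately: error probabilities are inverse-logit of the
  latent state (trait + occasion factor + trend, on the logit scale) and
  correct-trial reaction times are drawn so the expected block aggregate
  equals the latent state in milliseconds.  Questionnaire and context
  streams (item values, per-item completion times, beep number, social and
  location context, tiredness) are emitted alongside, with an optional
  planted fraction of careless prompts to exercise the screening rules.

Defaults emulate the main-study protocol: 70 subjects, 4 prompts/day for
14 days (T=56), ~51% compliance, Stroop blocks of 24 congruent + 24
incongruent trials, go/no-go blocks of 80 go + 20 no-go trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .dsem import DSEMParams

__all__ = ["GeneratorConfig", "ScoreLevelData", "TrialLevelData",
           "generate_score_level", "generate_trial_level"]

SCORES = ("stroop_er", "stroop_rtdiff", "gng_er", "gng_rt")


def _default_scores() -> dict:
    # Block-level variance decompositions implied by the main-study index
    # pattern (consistency >> specificity for Stroop, sizeable specificity
    # for go/no-go) and the observed between-person spread of each score;
    # error-rate latents live on the logit scale, RT latents in ms.  See
    # docs/methods.md for the derivation.
    return {
        "stroop_er": DSEMParams(mu_trait=-1.45, var_trait=0.148, beta=0.0,
                                phi=0.16, var_state=0.032, var_error=0.108),
        "stroop_rtdiff": DSEMParams(mu_trait=55.8, var_trait=1282.0,
                                    beta=-0.2, phi=0.76, var_state=48.0,
                                    var_error=2022.0),
        "gng_er": DSEMParams(mu_trait=-0.65, var_trait=0.498, beta=0.002,
                             phi=0.05, var_state=0.117, var_error=0.112),
        "gng_rt": DSEMParams(mu_trait=287.6, var_trait=420.0, beta=0.1,
                             phi=0.05, var_state=314.0, var_error=111.0),
    }


@dataclass
class GeneratorConfig:
    """Design, latent-model and nuisance parameters of the generator."""

    n_subjects: int = 70
    n_days: int = 14
    prompts_per_day: int = 4
    compliance_rate: float = 0.51
    seed: int = 0
    scores: dict = field(default_factory=_default_scores)
    # trial design (main study)
    stroop_congruent: int = 24
    stroop_incongruent: int = 24
    gng_go: int = 80
    gng_nogo: int = 20
    stroop_max_rt_ms: float = 1200.0
    gng_max_rt_ms: float = 650.0
    # trial-level nuisance parameters
    stroop_congruent_p_error: float = 0.02
    stroop_base_rt_ms: float = 650.0
    stroop_base_rt_between_sd: float = 50.0
    stroop_rt_sigma: float = 0.22       # lognormal shape of congruent RTs
    gng_rt_trial_sd: float = 40.0       # within-block SD of go RTs
    gng_go_omission_p: float = 0.01
    # questionnaire
    n_items: int = 15
    item_time_mean_s: float = 3.0
    item_time_sigma: float = 0.5
    # context coupling: per-score coefficient on each standardized covariate,
    # added to the emitted occasion state (latent units)
    context_effects: dict = field(default_factory=lambda: {
        "stroop_er": {"tiredness": -0.05, "alone": 0.13},
        "stroop_rtdiff": {"tiredness": 3.0},
        "gng_er": {"beep3": 0.20, "beep4": 0.14, "tiredness": 0.04},
        "gng_rt": {"beep3": -9.0, "tiredness": 2.0},
    })
    # cross-task convergent validity: correlation between the Stroop and
    # go/no-go error-rate latents (traits, and AR innovations)
    er_trait_corr: float = 0.57
    er_state_corr: float = 0.40
    # self-report composite coupling with the gng_er latent
    selfreport_between_corr: float = 0.30
    selfreport_within_corr: float = 0.05
    # careless responding
    careless_fraction: float = 0.0
    careless_item_time_s: float = 0.5
    careless_p_error: float = 0.95
    # trial-level mode: add per-block latent noise of variance
    # max(var_error - expected trial-sampling variance, 0) so block
    # aggregates carry (approximately) the configured error variance; with
    # False, block-level error is trial-sampling noise only
    trial_noise_adjustment: bool = True

    @property
    def n_occasions(self) -> int:
        return self.n_days * self.prompts_per_day

    def validate(self) -> "GeneratorConfig":
        for name in ("n_subjects", "n_days", "prompts_per_day"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.compliance_rate <= 1.0:
            raise ValueError(
                f"compliance_rate must be in [0, 1], got {self.compliance_rate!r}")
        if not 0.0 <= self.careless_fraction <= 1.0:
            raise ValueError("careless_fraction must be in [0, 1]")
        for score, p in self.scores.items():
            try:
                p.validate()
            except ValueError as exc:
                raise ValueError(f"scores[{score!r}]: {exc}") from exc
        return self

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scores = raw.pop("scores", None)
        cfg = cls(**raw)
        if scores is not None:
            cfg.scores = {k: DSEMParams(**v) for k, v in scores.items()}
        return cfg.validate()

    def to_yaml(self, path) -> None:
        raw = {k: v for k, v in self.__dict__.items() if k != "scores"}
        raw["scores"] = {k: p.as_dict() for k, p in self.scores.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


class ScoreLevelData(NamedTuple):
    blocks: pd.DataFrame
    latents: pd.DataFrame


class TrialLevelData(NamedTuple):
    trials: pd.DataFrame
    questionnaire: pd.DataFrame
    context: pd.DataFrame
    latents: pd.DataFrame


def _subject_rng(seed: int, subject: int) -> np.random.Generator:
    # sub-stream per subject so adding subjects never perturbs earlier ones
    return np.random.default_rng([seed, subject])


def _simulate_latents(cfg: GeneratorConfig, rng_of) -> pd.DataFrame:
    """Latent trait/occasion draws per subject, occasion and score.

    The two error-rate latents are coupled (trait and innovation
    correlations ``er_trait_corr`` / ``er_state_corr``) so the tasks show
    convergent validity; other scores are independent.
    """
    T = cfg.n_occasions
    couple = {"stroop_er", "gng_er"} <= set(cfg.scores)
    rows = []
    for n in range(cfg.n_subjects):
        rng = rng_of(n)
        z_xi = {s: rng.standard_normal() for s in cfg.scores}
        z_zeta = {s: rng.standard_normal(T) for s in cfg.scores}
        if couple:
            rt, rs = cfg.er_trait_corr, cfg.er_state_corr
            z_xi["gng_er"] = rt * z_xi["stroop_er"] + \
                np.sqrt(1 - rt ** 2) * z_xi["gng_er"]
            z_zeta["gng_er"] = rs * z_zeta["stroop_er"] + \
                np.sqrt(1 - rs ** 2) * z_zeta["gng_er"]
        for score, p in cfg.scores.items():
            xi = p.mu_trait + np.sqrt(p.var_trait) * z_xi[score]
            zeta = np.sqrt(p.var_state) * z_zeta[score]
            occ = np.empty(T)
            occ[0] = zeta[0]
            for t in range(1, T):
                occ[t] = p.phi * occ[t - 1] + zeta[t]
            rows.append(pd.DataFrame({
                "subject_id": n + 1,
                "occasion_index": np.arange(1, T + 1),
                "score": score,
                "xi": xi,
                "occ": occ,
                "zeta": zeta,
                # emitted state: what block aggregates track at occasion t
                "state": xi + occ + p.beta * np.arange(T),
            }))
    return pd.concat(rows, ignore_index=True)


def _schedule(cfg: GeneratorConfig) -> pd.DataFrame:
    T = cfg.n_occasions
    t = np.arange(1, T + 1)
    return pd.DataFrame({
        "occasion_index": t,
        "day": (t - 1) // cfg.prompts_per_day + 1,
        "beep": (t - 1) % cfg.prompts_per_day + 1,
    })


def generate_score_level(config: GeneratorConfig) -> ScoreLevelData:
    """Emit the two block indicators per occasion from the exact model.

    Non-complied prompts keep their row with missing indicators; latent
    values are returned for parameter-recovery tests.  With the seed fixed
    the output is byte-identical across runs.
    """
    cfg = config.validate()
    T = cfg.n_occasions
    latents = _simulate_latents(cfg, lambda n: _subject_rng(cfg.seed, n))
    sched = _schedule(cfg)
    rows = []
    for n in range(cfg.n_subjects):
        rng = _subject_rng(cfg.seed, n).spawn(1)[0]
        answered = rng.random(T) < cfg.compliance_rate
        lat = latents[latents["subject_id"] == n + 1]
        state = {s: lat.loc[lat["score"] == s, "state"].to_numpy()
                 for s in cfg.scores}
        for block in (1, 2):
            df = sched.copy()
            df.insert(0, "subject_id", n + 1)
            df["block"] = block
            for s, p in cfg.scores.items():
                eps = np.sqrt(p.var_error) * rng.standard_normal(T)
                y = state[s] + eps
                df[s] = np.where(answered, y, np.nan)
            df["answered"] = answered.astype(int)
            rows.append(df)
    blocks = (pd.concat(rows, ignore_index=True)
              .sort_values(["subject_id", "occasion_index", "block"])
              .reset_index(drop=True))
    if any(s.startswith("stroop") for s in cfg.scores):
        blocks["valid_stroop"] = blocks["answered"]
    if any(s.startswith("gng") for s in cfg.scores):
        blocks["valid_gng"] = blocks["answered"]
    return ScoreLevelData(blocks=blocks, latents=latents)


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


_STROOP_COLORS = ("red", "blue", "green", "yellow")


def _block_noise_sd(cfg: GeneratorConfig) -> dict:
    """Per-block latent noise SD so block aggregates approximately carry
    the configured error variance on top of trial-sampling noise."""
    out = {}
    p_er = _invlogit(cfg.scores["stroop_er"].mu_trait)
    for s, p in cfg.scores.items():
        if not cfg.trial_noise_adjustment:
            out[s] = 0.0
            continue
        if s == "stroop_er":
            tn = 1.0 / (p_er * (1 - p_er) * cfg.stroop_incongruent)
        elif s == "gng_er":
            pbar = _invlogit(p.mu_trait)
            tn = 1.0 / (pbar * (1 - pbar) * cfg.gng_nogo)
        elif s == "stroop_rtdiff":
            var_trial = (cfg.stroop_base_rt_ms * cfg.stroop_rt_sigma) ** 2
            tn = var_trial * (1.0 / (cfg.stroop_incongruent * (1 - p_er))
                              + 1.0 / (cfg.stroop_congruent
                                       * (1 - cfg.stroop_congruent_p_error)))
        elif s == "gng_rt":
            tn = cfg.gng_rt_trial_sd ** 2 / (
                cfg.gng_go * (1 - cfg.gng_go_omission_p))
        else:
            tn = 0.0
        out[s] = float(np.sqrt(max(p.var_error - tn, 0.0)))
    return out


def _stroop_block(rng, cfg, p_err_incong, rtdiff, base_rt, careless):
    n_c, n_i = cfg.stroop_congruent, cfg.stroop_incongruent
    cond = np.array(["congruent"] * n_c + ["incongruent"] * n_i)
    rng.shuffle(cond)
    n = len(cond)
    correct_color = rng.integers(0, 4, size=n)
    p_err = np.where(cond == "incongruent",
                     cfg.careless_p_error if careless else p_err_incong,
                     cfg.stroop_congruent_p_error)
    err = rng.random(n) < p_err
    # congruent RT lognormal around the subject base; incongruent adds the
    # occasion's latent interference in ms so E[block RT-Diff] = latent
    sigma = cfg.stroop_rt_sigma
    rt = base_rt * np.exp(sigma * rng.standard_normal(n) - sigma ** 2 / 2)
    rt = rt + np.where(cond == "incongruent", rtdiff, 0.0)
    rt = np.clip(rt, 160.0, cfg.stroop_max_rt_ms)
    if careless:
        resp = np.zeros(n, dtype=int)  # one button hammered
        rt = rng.uniform(200, 400, size=n)
        err = resp != correct_color
    else:
        wrong = (correct_color + rng.integers(1, 4, size=n)) % 4
        resp = np.where(err, wrong, correct_color)
    return pd.DataFrame({
        "trial_index": np.arange(1, n + 1),
        "task": "stroop",
        "condition": cond,
        "rt_ms": np.round(rt, 1),
        "correct": (~err).astype(int),
        "response_code": np.array(_STROOP_COLORS)[resp],
    })


def _gng_block(rng, cfg, p_commission, go_rt, careless):
    n_g, n_n = cfg.gng_go, cfg.gng_nogo
    cond = np.array(["go"] * n_g + ["nogo"] * n_n)
    rng.shuffle(cond)
    n = len(cond)
    is_go = cond == "go"
    p_err = np.where(is_go, cfg.gng_go_omission_p,
                     cfg.careless_p_error if careless else p_commission)
    err = rng.random(n) < p_err
    rt = go_rt + cfg.gng_rt_trial_sd * rng.standard_normal(n)
    rt = np.clip(rt, 160.0, cfg.gng_max_rt_ms)
    responded = (is_go & ~err) | (~is_go & err)  # tap on go-correct / commission
    correct = (is_go & ~err) | (~is_go & ~err)
    return pd.DataFrame({
        "trial_index": np.arange(1, n + 1),
        "task": "gng",
        "condition": cond,
        "rt_ms": np.where(responded, np.round(rt, 1), np.nan),
        "correct": correct.astype(int),
        "response_code": np.where(responded, "tap", "none"),
    })


def generate_trial_level(config: GeneratorConfig) -> TrialLevelData:
    """Emit raw trials plus questionnaire and context streams.

    Block aggregates are unbiased for the latent states at the configured
    trial counts; a ``careless_fraction`` of answered prompts is planted
    with sub-second item times, hammered identical Stroop responses and
    extreme error rates (flagged in the context table's ``careless``
    column) to exercise the screening rules.
    """
    cfg = config.validate()
    missing = [s for s in SCORES if s not in cfg.scores]
    if missing:
        raise ValueError(f"trial-level generation needs DSEM parameters for "
                         f"all task scores; missing {missing}")
    T = cfg.n_occasions
    latents = _simulate_latents(cfg, lambda n: _subject_rng(cfg.seed, n))
    sched = _schedule(cfg)
    p_sr = cfg.scores["gng_er"]
    noise_sd = _block_noise_sd(cfg)

    trial_rows, q_rows, ctx_rows = [], [], []
    for n in range(cfg.n_subjects):
        rng = _subject_rng(cfg.seed, n).spawn(1)[0]
        answered = rng.random(T) < cfg.compliance_rate
        base_rt = cfg.stroop_base_rt_ms + \
            cfg.stroop_base_rt_between_sd * rng.standard_normal()
        lat = latents[latents["subject_id"] == n + 1]
        state = {s: lat.loc[lat["score"] == s, "state"].to_numpy()
                 for s in cfg.scores}
        answered_idx = np.flatnonzero(answered)
        n_careless = int(round(cfg.careless_fraction * len(answered_idx)))
        careless_set = set(rng.choice(answered_idx, size=n_careless,
                                      replace=False).tolist()) if n_careless else set()

        # context draws for every answered prompt
        alone = rng.random(T) < 0.45
        outdoors = rng.random(T) < 0.10
        tired = np.clip(47.5 + 20.0 * rng.standard_normal(T), 0, 100)
        beep = sched["beep"].to_numpy()
        cov = {
            "tiredness": (tired - 47.5) / 20.0,
            "alone": alone.astype(float),
            "outdoors": outdoors.astype(float),
            "beep3": (beep == 3).astype(float),
            "beep4": (beep == 4).astype(float),
        }
        eff_state = {s: state[s].copy() for s in cfg.scores}
        for s, effects in cfg.context_effects.items():
            if s in eff_state:
                for name, coef in effects.items():
                    eff_state[s] = eff_state[s] + coef * cov[name]

        # self-report composite coupled to the gng_er latent (standardized
        # trait between subjects, occasion factor within)
        xi_sr = lat.loc[lat["score"] == "gng_er", "xi"].iloc[0]
        occ_sr = lat.loc[lat["score"] == "gng_er", "occ"].to_numpy()
        zb = (xi_sr - p_sr.mu_trait) / np.sqrt(max(p_sr.var_trait, 1e-12))
        occ_sd = np.sqrt(max(p_sr.var_state / max(1 - p_sr.phi ** 2, 1e-9), 1e-12))
        zw = occ_sr / occ_sd
        rb, rw = cfg.selfreport_between_corr, cfg.selfreport_within_corr
        sr_noise_b = np.sqrt(max(1 - rb ** 2, 0.0)) * rng.standard_normal()
        sr = 150.0 + 95.0 * (rb * zb + sr_noise_b) \
            + 40.0 * (rw * zw + np.sqrt(max(1 - rw ** 2, 0.0))
                      * rng.standard_normal(T))
        sr = np.clip(sr, 0, 600)

        for t in answered_idx:
            careless = t in careless_set
            occ_row = sched.iloc[t]
            key = {"subject_id": n + 1,
                   "occasion_index": int(occ_row["occasion_index"]),
                   "day": int(occ_row["day"]), "beep": int(occ_row["beep"])}
            for block in (1, 2):
                eb = {s: noise_sd[s] * rng.standard_normal()
                      for s in cfg.scores}
                sb = _stroop_block(
                    rng, cfg,
                    _invlogit(eff_state["stroop_er"][t] + eb["stroop_er"]),
                    eff_state["stroop_rtdiff"][t] + eb["stroop_rtdiff"],
                    base_rt, careless)
                gb = _gng_block(
                    rng, cfg,
                    _invlogit(eff_state["gng_er"][t] + eb["gng_er"]),
                    eff_state["gng_rt"][t] + eb["gng_rt"], careless)
                for tb in (sb, gb):
                    tb = tb.assign(**key, block=block)
                    trial_rows.append(tb)
            if careless:
                item_t = np.maximum(
                    cfg.careless_item_time_s
                    + 0.05 * rng.standard_normal(cfg.n_items), 0.1)
                values = np.full(cfg.n_items, float(rng.integers(0, 101)))
            else:
                item_t = cfg.item_time_mean_s * np.exp(
                    cfg.item_time_sigma * rng.standard_normal(cfg.n_items)
                    - cfg.item_time_sigma ** 2 / 2)
                values = np.clip(sr[t] / cfg.n_items
                                 + 15.0 * rng.standard_normal(cfg.n_items),
                                 0, 100)
            q_rows.append(pd.DataFrame({
                **key, "item": np.arange(1, cfg.n_items + 1),
                "item_value": np.round(values, 1),
                "item_time_s": np.round(item_t, 3),
            }))
            ctx_rows.append({**key, "alone": int(alone[t]),
                             "outdoors": int(outdoors[t]),
                             "tiredness": round(float(tired[t]), 1),
                             "selfreport": round(float(sr[t]), 1),
                             "careless": int(careless)})

    cols = ["subject_id", "occasion_index", "day", "beep", "block",
            "trial_index", "task", "condition", "rt_ms", "correct",
            "response_code"]
    trials = (pd.concat(trial_rows, ignore_index=True)[cols]
              if trial_rows else pd.DataFrame(columns=cols))
    questionnaire = (pd.concat(q_rows, ignore_index=True) if q_rows
                     else pd.DataFrame(columns=["subject_id", "occasion_index",
                                                "day", "beep", "item",
                                                "item_value", "item_time_s"]))
    context = pd.DataFrame(ctx_rows)
    return TrialLevelData(trials=trials, questionnaire=questionnaire,
                          context=context, latents=latents)
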