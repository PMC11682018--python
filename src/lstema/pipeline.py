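"""End-to-end pipeline: simulate/load -> score -> screen -> fit -> curves
-> validity/context, with every artifact written to CSV/JSON plus a
manifest.  Re-running with the same configuration reproduces identical
numerical outputs."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import GeneratorConfig, generate_trial_level
from .scoring import score_blocks, MIN_RT_MS, MIN_TRIALS
from .screening import apply_exclusions
from .dsem import fit_dsem, blocks_to_wide
from .gtheory import rc_by_trialcount, rc_by_day
from .validity import within_between_corr, fit_context_model

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

SCORES = ("stroop_er", "stroop_rtdiff", "gng_er", "gng_rt")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and model options for one pipeline run."""

    trials_path: str | None = None
    questionnaire_path: str | None = None
    context_path: str | None = None
    generator: GeneratorConfig | None = None  # used when paths are None
    out_dir: str = "lstema_out"
    min_rt_ms: float = MIN_RT_MS
    min_trials: int = MIN_TRIALS
    itemtime_threshold_s: float = 1.0
    sd_multiplier: float = 3.0
    min_assessments: int = 5
    stationary_init: bool = False
    curve_step: int = 2
    scores: tuple = SCORES
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("min_rt_ms", "min_trials", "itemtime_threshold_s",
                     "sd_multiplier", "min_assessments", "curve_step"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for p in (self.trials_path, self.questionnaire_path,
                  self.context_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            from .dsem import DSEMParams
            scores = gen.pop("scores", None)
            g = GeneratorConfig(**gen)
            if scores is not None:
                g.scores = {k: DSEMParams(**v) for k, v in scores.items()}
            cfg.generator = g
        if isinstance(cfg.scores, list):
            cfg.scores = tuple(cfg.scores)
        return cfg.validate()


@dataclass
class PipelineResult:
    blocks: pd.DataFrame
    blocks_clean: pd.DataFrame
    screening: dict
    fits: dict
    rc_curve: pd.DataFrame
    rc_daily: pd.DataFrame
    validity: pd.DataFrame
    context_models: dict
    manifest: dict
    out_dir: Path = field(default=Path("."))


def _occasion_scores(blocks: pd.DataFrame, scores) -> pd.DataFrame:
    keep = ["subject_id", "occasion_index"] + \
        [c for c in ("day", "beep") if c in blocks.columns]
    agg = {c: "mean" for c in scores if c in blocks.columns}
    return blocks.groupby(keep, as_index=False).agg(agg)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the artifact bundle."""
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"lstema_version": __version__, "seed": cfg.seed,
                "thresholds": {"min_rt_ms": cfg.min_rt_ms,
                               "min_trials": cfg.min_trials,
                               "itemtime_threshold_s": cfg.itemtime_threshold_s,
                               "sd_multiplier": cfg.sd_multiplier,
                               "min_assessments": cfg.min_assessments},
                "stages": {}}

    def record(stage, **artifacts):
        manifest["stages"][stage] = {k: str(v) for k, v in artifacts.items()}

    # ---- input ----
    try:
        if cfg.trials_path is not None:
            trials = pd.read_csv(cfg.trials_path)
            questionnaire = (pd.read_csv(cfg.questionnaire_path)
                             if cfg.questionnaire_path else None)
            context = (pd.read_csv(cfg.context_path)
                       if cfg.context_path else None)
            record("input", trials=cfg.trials_path)
        else:
            gen = cfg.generator or GeneratorConfig(seed=cfg.seed)
            data = generate_trial_level(gen)
            trials, questionnaire, context = \
                data.trials, data.questionnaire, data.context
            data.latents.to_csv(out / "latents.csv", index=False)
            trials.to_csv(out / "trials.csv", index=False)
            questionnaire.to_csv(out / "questionnaire.csv", index=False)
            context.to_csv(out / "context.csv", index=False)
            record("simulate", trials=out / "trials.csv",
                   questionnaire=out / "questionnaire.csv",
                   context=out / "context.csv", latents=out / "latents.csv")
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    # ---- score ----
    try:
        blocks = score_blocks(trials, min_trials=cfg.min_trials,
                              min_rt_ms=cfg.min_rt_ms)
        blocks.to_csv(out / "blocks.csv", index=False)
        record("score", blocks=out / "blocks.csv")
    except Exception as exc:
        raise PipelineError("score", exc) from exc

    # ---- screen ----
    try:
        blocks_clean, report = apply_exclusions(
            blocks, questionnaire, trials,
            itemtime_threshold_s=cfg.itemtime_threshold_s,
            sd_multiplier=cfg.sd_multiplier,
            min_assessments=cfg.min_assessments)
        blocks_clean.to_csv(out / "blocks_clean.csv", index=False)
        screening = report.as_dict()
        (out / "screening.json").write_text(json.dumps(screening, indent=2))
        record("screen", blocks_clean=out / "blocks_clean.csv",
               report=out / "screening.json")
    except Exception as exc:
        raise PipelineError("screen", exc) from exc

    # ---- fit ----
    fits = {}
    try:
        model_blocks = blocks_clean[
            ~blocks_clean["subject_id"].isin(report.flagged_subjects)]
        T = int(blocks_clean["occasion_index"].max())
        for score in cfg.scores:
            y = blocks_to_wide(model_blocks, score, n_occasions=T)
            fit = fit_dsem(y, stationary_init=cfg.stationary_init,
                           min_complete=cfg.min_assessments)
            fits[score] = fit
            (out / f"fit_{score}.json").write_text(
                json.dumps(fit.as_dict(), indent=2))
        record("fit", **{s: out / f"fit_{s}.json" for s in cfg.scores})
    except Exception as exc:
        raise PipelineError("fit", exc) from exc

    # ---- curves ----
    try:
        # restrict trials to the prompts and tasks that survived screening
        prompt_key = ["subject_id", "occasion_index"]
        kept = pd.MultiIndex.from_frame(
            blocks_clean[prompt_key].drop_duplicates())
        t_clean = trials[pd.MultiIndex.from_frame(
            trials[prompt_key]).isin(kept)]
        task_bad = {"stroop": set(map(tuple,
                                      report.flagged_prompts_longstring)),
                    "gng": set()}
        for task, pairs in report.flagged_occasions_er.items():
            task_bad.setdefault(task, set()).update(map(tuple, pairs))
        for task, bad in task_bad.items():
            if bad:
                hit = (t_clean["task"] == task) & pd.MultiIndex.from_frame(
                    t_clean[prompt_key]).isin(bad)
                t_clean = t_clean[~hit]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rc_curve = rc_by_trialcount(t_clean, step=cfg.curve_step,
                                        scores=cfg.scores)
            rc_daily = rc_by_day(blocks_clean, scores=cfg.scores)
        rc_curve.to_csv(out / "rc_curve.csv", index=False)
        rc_daily.to_csv(out / "rc_daily.csv", index=False)
        record("curves", rc_curve=out / "rc_curve.csv",
               rc_daily=out / "rc_daily.csv")
    except Exception as exc:
        raise PipelineError("curves", exc) from exc

    # ---- validity / context ----
    try:
        occ = _occasion_scores(blocks_clean, cfg.scores)
        if context is not None and "selfreport" in getattr(
                context, "columns", []):
            occ = occ.merge(context[["subject_id", "occasion_index",
                                     "selfreport"]],
                            on=["subject_id", "occasion_index"], how="left")
        streams = [c for c in list(cfg.scores) + ["selfreport"]
                   if c in occ.columns]
        vrows = []
        for i, a in enumerate(streams):
            for b in streams[i + 1:]:
                pair = occ[[a, b, "subject_id"]].dropna()
                if pair["subject_id"].nunique() < 3:
                    continue
                cp = within_between_corr(pair[a], pair[b],
                                         pair["subject_id"])
                vrows.append({"x": a, "y": b, **cp.as_dict()})
        validity = pd.DataFrame(vrows)
        validity.to_csv(out / "validity.csv", index=False)

        context_models = {}
        if context is not None:
            merged = occ.merge(
                context[["subject_id", "occasion_index", "alone",
                         "outdoors", "tiredness"]],
                on=["subject_id", "occasion_index"], how="inner")
            for score in cfg.scores:
                sub = merged.dropna(
                    subset=[score, "alone", "outdoors", "tiredness"])
                if sub["subject_id"].nunique() < 3 or len(sub) < 20:
                    continue
                res = fit_context_model(
                    sub[score],
                    sub[["beep", "alone", "outdoors", "tiredness"]],
                    sub["subject_id"])
                context_models[score] = res.as_dict()
            (out / "context_models.json").write_text(
                json.dumps(context_models, indent=2))
        record("validity", validity=out / "validity.csv",
               context_models=out / "context_models.json")
    except Exception as exc:
        raise PipelineError("validity", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return PipelineResult(blocks=blocks, blocks_clean=blocks_clean,
                          screening=screening, fits=fits,
                          rc_curve=rc_curve, rc_daily=rc_daily,
                          validity=validity, context_models=context_models,
                          manifest=manifest, out_dir=out)
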