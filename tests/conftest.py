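import warnings

import numpy as np
import pandas as pd
import pytest

from lstema.synthetic import GeneratorConfig, generate_trial_level
from lstema.dsem import DSEMParams


@pytest.fixture(scope="session")
def small_trial_data():
    """Small but complete trial-level dataset shared across tests."""
    cfg = GeneratorConfig(n_subjects=6, n_days=4, prompts_per_day=3,
                          compliance_rate=0.8, seed=42)
    return generate_trial_level(cfg)


@pytest.fixture(scope="session")
def careless_trial_data():
    """Dataset with a planted fraction of careless prompts."""
    cfg = GeneratorConfig(n_subjects=6, n_days=4, prompts_per_day=3,
                          compliance_rate=0.9, seed=7,
                          careless_fraction=0.1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_trial_level(cfg)


def make_block_trials(subject=1, occasion=1, block=1, *,
                      congruent_rts=(), incongruent_rts=(),
                      congruent_correct=None, incongruent_correct=None,
                      go_rts=(), nogo_commissions=()):
    """Hand-built trial table for one block.

    ``nogo_commissions`` is a boolean sequence: True = commission error
    (tap with an RT), False = correctly withheld response (no RT).
    """
    rows = []
    idx = 1
    for cond, rts, correct in (("congruent", congruent_rts,
                                congruent_correct),
                               ("incongruent", incongruent_rts,
                                incongruent_correct)):
        for i, rt in enumerate(rts):
            ok = 1 if correct is None else int(correct[i])
            rows.append(dict(subject_id=subject, occasion_index=occasion,
                             block=block, trial_index=idx, task="stroop",
                             condition=cond, rt_ms=rt, correct=ok,
                             response_code="red" if ok else "blue"))
            idx += 1
    idx = 1
    for rt in go_rts:
        rows.append(dict(subject_id=subject, occasion_index=occasion,
                         block=block, trial_index=idx, task="gng",
                         condition="go", rt_ms=rt, correct=1,
                         response_code="tap"))
        idx += 1
    for hit in nogo_commissions:
        rows.append(dict(subject_id=subject, occasion_index=occasion,
                         block=block, trial_index=idx, task="gng",
                         condition="nogo",
                         rt_ms=300.0 if hit else np.nan,
                         correct=0 if hit else 1,
                         response_code="tap" if hit else "none"))
        idx += 1
    return pd.DataFrame(rows)


@pytest.fixture()
def recovery_params():
    """Ground-truth parameters used in estimator-recovery checks."""
    return DSEMParams(mu_trait=0.0, var_trait=1.0, beta=-0.005, phi=0.3,
                      var_state=0.5, var_error=0.5)
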