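"""Variance components and the reliability-of-change index."""

import warnings

import numpy as np
import pandas as pd
import pytest

from lstema.gtheory import (VarianceComponents, estimate_components, rc,
                            rc_by_trialcount, rc_by_day)
from lstema.synthetic import GeneratorConfig, generate_score_level
from lstema.dsem import DSEMParams


def simulate_two_way(N, T, m, sp2, spt2, se2, seed=0, exact_moments=False):
    """Balanced person + person-by-occasion + residual data."""
    rng = np.random.default_rng(seed)

    def draw(n, var):
        x = rng.standard_normal(n)
        if exact_moments and var > 0:
            x = (x - x.mean()) / x.std(ddof=1)
        return x * np.sqrt(var)

    p = draw(N, sp2)
    pt = draw(N * T, spt2).reshape(N, T)
    if exact_moments:
        pt = pt - pt.mean(axis=1, keepdims=True)  # orthogonal to person
        pt *= np.sqrt(spt2) / pt.std(ddof=1) if spt2 > 0 else 0.0
    e = draw(N * T * m, se2).reshape(N, T, m)
    y = p[:, None, None] + pt[:, :, None] + e
    return pd.DataFrame({
        "subject": np.repeat(np.arange(N), T * m),
        "occasion": np.tile(np.repeat(np.arange(T), m), N),
        "value": y.ravel()})


class TestRcFormula:
    @pytest.mark.parametrize("spt,se,m,expected", [
        (1.0, 1.0, 2, 2 / 3),
        (0.0, 1.0, 2, 0.0),
        (1.0, 0.0, 2, 1.0),
        (0.5, 1.0, 4, 0.5 / (0.5 + 0.25)),
    ])
    def test_printed_formula(self, spt, se, m, expected):
        comp = VarianceComponents(0.0, spt, se, m=m)
        assert rc(comp) == pytest.approx(expected)

    def test_zero_denominator_is_missing(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(rc(VarianceComponents(1.0, 0.0, 0.0, m=2)))

    def test_monotonicity(self):
        base = rc(VarianceComponents(0, 1.0, 1.0, m=2))
        assert rc(VarianceComponents(0, 2.0, 1.0, m=2)) > base
        assert rc(VarianceComponents(0, 1.0, 2.0, m=2)) < base
        assert rc(VarianceComponents(0, 1.0, 1.0, m=4)) > base


class TestEstimateComponents:
    def test_matches_hand_computed_mean_squares(self):
        # independent oracle: expected-mean-squares algebra written out
        d = simulate_two_way(3, 3, 2, 1.0, 0.5, 0.3, seed=5)
        y = d["value"].to_numpy().reshape(3, 3, 2)
        cell = y.mean(axis=2)
        person = cell.mean(axis=1)
        grand = person.mean()
        ms_e = ((y - cell[:, :, None]) ** 2).sum() / (3 * 3 * (2 - 1))
        ms_pt = 2 * ((cell - person[:, None]) ** 2).sum() / (3 * (3 - 1))
        ms_p = 3 * 2 * ((person - grand) ** 2).sum() / (3 - 1)
        comp = estimate_components(d, method="mom")
        assert comp.sigma2_error == pytest.approx(ms_e)
        assert comp.sigma2_person_time == pytest.approx(
            max((ms_pt - ms_e) / 2, 0))
        assert comp.sigma2_person == pytest.approx(
            max((ms_p - ms_pt) / 6, 0))

    def test_reml_agrees_with_mom_on_balanced_data(self):
        d = simulate_two_way(40, 8, 2, 1.0, 0.5, 0.5, seed=3)
        a = estimate_components(d, method="mom")
        b = estimate_components(d, method="reml")
        assert b.sigma2_person == pytest.approx(a.sigma2_person, rel=1e-3)
        assert b.sigma2_person_time == pytest.approx(a.sigma2_person_time,
                                                     rel=1e-3)
        assert b.sigma2_error == pytest.approx(a.sigma2_error, rel=1e-3)

    def test_reml_agrees_with_statsmodels_on_unbalanced_data(self):
        import statsmodels.formula.api as smf
        d = simulate_two_way(25, 6, 2, 0.8, 0.4, 0.6, seed=11)
        d = d.sample(frac=0.8, random_state=1)
        comp = estimate_components(d, method="reml")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm("value ~ 1", d, groups="subject",
                                 re_formula="1",
                                 vc_formula={"occ": "0 + C(occasion)"}
                                 ).fit(reml=True)
        assert comp.sigma2_person == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), abs=2e-3)
        assert comp.sigma2_person_time == pytest.approx(
            float(sm_fit.vcomp[0]), abs=2e-3)
        assert comp.sigma2_error == pytest.approx(float(sm_fit.scale),
                                                  abs=2e-3)

    def test_recovery_on_balanced_synthetic_data(self):
        d = simulate_two_way(200, 20, 2, 1.0, 0.5, 0.5, seed=2,
                             exact_moments=True)
        comp = estimate_components(d)
        assert comp.sigma2_person == pytest.approx(1.0, rel=0.1)
        assert comp.sigma2_person_time == pytest.approx(0.5, rel=0.1)
        assert comp.sigma2_error == pytest.approx(0.5, rel=0.1)

    def test_duplicated_block_gives_zero_error_variance(self):
        d = simulate_two_way(10, 5, 1, 1.0, 0.5, 0.0, seed=4)
        dup = pd.concat([d, d])
        comp = estimate_components(dup)
        assert comp.sigma2_error == pytest.approx(0.0, abs=1e-6)

    def test_occasion_label_permutation_invariance(self):
        d = simulate_two_way(12, 6, 2, 1.0, 0.5, 0.5, seed=9)
        rng = np.random.default_rng(0)
        perm = d.copy()
        for s in perm["subject"].unique():
            mask = perm["subject"] == s
            labels = perm.loc[mask, "occasion"]
            mapping = dict(zip(np.unique(labels),
                               rng.permutation(np.unique(labels))))
            perm.loc[mask, "occasion"] = labels.map(mapping)
        a = estimate_components(d, method="mom")
        b = estimate_components(perm, method="mom")
        assert b.sigma2_person_time == pytest.approx(a.sigma2_person_time)
        assert b.sigma2_error == pytest.approx(a.sigma2_error)

    def test_errors_on_degenerate_layouts(self):
        one_subject = simulate_two_way(1, 5, 2, 0, 1, 1)
        with pytest.raises(ValueError, match="2 subjects"):
            estimate_components(one_subject)
        singleton = simulate_two_way(5, 4, 1, 1, 1, 1)
        with pytest.raises(ValueError, match="single block"):
            estimate_components(singleton)


class TestCurves:
    def test_full_subset_reproduces_all_trials_rc(self, small_trial_data):
        trials = small_trial_data.trials
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = rc_by_trialcount(trials, step=10, scores=("gng_rt",))
        full_n = curve["n_per_condition"].max()
        from lstema.scoring import score_blocks
        blocks = score_blocks(trials)
        comp = estimate_components(
            blocks.rename(columns={"subject_id": "subject",
                                   "occasion_index": "occasion",
                                   "gng_rt": "value"}))
        row = curve[curve["n_per_condition"] == full_n].iloc[0]
        assert row["rc"] == pytest.approx(rc(comp), abs=1e-6)

    def test_curve_increases_with_state_variance(self):
        # trial-noise-only data stays near zero; strong state variance
        # pushes the curve up with the number of trials
        rng = np.random.default_rng(6)
        N, T = 30, 8

        def blocks_from(p_state_sd):
            rows = []
            for s in range(N):
                for t in range(T):
                    state = p_state_sd * rng.standard_normal()
                    for b in (1, 2):
                        for i in range(20):
                            rows.append(dict(
                                subject_id=s, occasion_index=t + 1,
                                block=b, trial_index=i + 1, task="gng",
                                condition="nogo" if i < 10 else "go",
                                rt_ms=300.0 if i >= 10 else np.nan,
                                correct=int(not (
                                    i < 10 and rng.random()
                                    < 1 / (1 + np.exp(-(-1 + state))))),
                                response_code="tap"))
            return pd.DataFrame(rows)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flat = rc_by_trialcount(blocks_from(0.0), step=5,
                                    scores=("gng_er",))
            rich = rc_by_trialcount(blocks_from(1.5), step=5,
                                    scores=("gng_er",))
        assert flat["rc"].max() < 0.25
        assert rich["rc"].iloc[-1] > rich["rc"].iloc[0]
        assert rich["rc"].iloc[-1] > 0.5

    def test_step_must_be_positive(self, small_trial_data):
        with pytest.raises(ValueError, match="step"):
            rc_by_trialcount(small_trial_data.trials, step=0)

    def test_by_day_skips_single_occasion_days(self):
        p = DSEMParams(var_trait=1, var_state=0.5, var_error=0.5, phi=0.0)
        cfg = GeneratorConfig(n_subjects=20, n_days=3, prompts_per_day=1,
                              compliance_rate=1.0, seed=5,
                              scores={"gng_rt": p})
        blocks, _ = generate_score_level(cfg)
        with pytest.warns(UserWarning, match="fewer than 2 occasions"):
            out = rc_by_day(blocks, scores=("gng_rt",))
        assert len(out) == 0

    def test_by_day_flat_for_stationary_generator(self):
        p = DSEMParams(var_trait=1, var_state=0.5, var_error=0.5, phi=0.0)
        cfg = GeneratorConfig(n_subjects=60, n_days=7, prompts_per_day=4,
                              compliance_rate=1.0, seed=8,
                              scores={"gng_rt": p})
        blocks, _ = generate_score_level(cfg)
        out = rc_by_day(blocks, scores=("gng_rt",), method="mom")
        assert len(out) == 7
        # every day estimates the same truth: rc = 0.5/(0.5+0.25) = 2/3
        assert out["rc"].std() < 0.15
        assert out["rc"].mean() == pytest.approx(2 / 3, abs=0.1)
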