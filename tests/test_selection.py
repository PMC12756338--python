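"""Backward stepwise AIC: trace properties, exhaustive oracle, secondary rerun."""

import itertools

import numpy as np
import pandas as pd
import pytest

import clustmed as cm
from clustmed.mediation import estimate_mediation
from clustmed.selection import (
    backward_stepwise_aic, gaussian_aic, secondary_analysis,
)

CONF = list(cm.synthetic.CONFOUNDERS)


def _prepared(seed, n_families=150, n_mediators=5, **kw):
    cfg = cm.default_config(seed=seed, n_families=n_families,
                            n_mediators=n_mediators, **kw)
    cohort, truth = cm.simulate_cohort(cfg)
    sample, _ = cm.build_analysis_sample(cohort, cfg.mediator_names)
    sample, _ = cm.preprocess_mediators(sample, cfg.mediator_names)
    return cfg, sample, truth


def _exhaustive_best_aic(df, outcome, mediators, forced):
    """Independent oracle: enumerate every mediator subset."""
    y = df[outcome].to_numpy(float)
    n = y.size
    best = np.inf
    for r in range(len(mediators) + 1):
        for subset in itertools.combinations(mediators, r):
            x = np.column_stack(
                [np.ones(n)] + [df[c].to_numpy(float) for c in forced]
                + [df[m].to_numpy(float) for m in subset])
            resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
            best = min(best, gaussian_aic(float(resid @ resid), n, x.shape[1]))
    return best


def test_strong_single_candidate_retained():
    cfg, sample, _ = _prepared(3, n_mediators=1,
                               beta_think=np.array([-3.0]),
                               alpha=np.array([0.5]))
    trace = backward_stepwise_aic(sample, "think_time", cfg.mediator_names,
                                  ["apoe2", *CONF])
    assert trace.retained == cfg.mediator_names
    assert trace.steps == []
    assert trace.final_aic == trace.initial_aic


def test_trace_aic_strictly_decreasing():
    cfg, sample, _ = _prepared(5, n_mediators=6)
    trace = backward_stepwise_aic(sample, "ink_time", cfg.mediator_names,
                                  ["apoe2", *CONF])
    seq = [trace.initial_aic] + [s.aic_after for s in trace.steps]
    assert all(b < a for a, b in zip(seq, seq[1:]))
    assert trace.final_aic == seq[-1]
    for step in trace.steps:
        assert step.removed not in trace.retained


def test_forced_terms_never_removed():
    cfg, sample, _ = _prepared(7, n_mediators=4)
    trace = backward_stepwise_aic(sample, "think_time", cfg.mediator_names,
                                  ["apoe2", *CONF])
    removed = {s.removed for s in trace.steps}
    assert removed <= set(cfg.mediator_names)
    assert set(trace.retained) <= set(cfg.mediator_names)


def test_deterministic_given_data():
    cfg, sample, _ = _prepared(9, n_mediators=5)
    a = backward_stepwise_aic(sample, "total_time", cfg.mediator_names,
                              ["apoe2", *CONF])
    b = backward_stepwise_aic(sample, "total_time", cfg.mediator_names,
                              ["apoe2", *CONF])
    assert a == b


def test_backward_path_bounded_by_exhaustive_oracle():
    """For few candidates, exhaustive enumeration bounds the backward
    search: the greedy final AIC can never beat the best subset."""
    cfg, sample, _ = _prepared(11, n_mediators=6)
    forced = ["apoe2", *CONF]
    trace = backward_stepwise_aic(sample, "think_time", cfg.mediator_names,
                                  forced)
    best = _exhaustive_best_aic(sample, "think_time", cfg.mediator_names, forced)
    assert trace.final_aic >= best - 1e-9


def test_zero_coefficient_mediator_removal_leaves_rss():
    """A mediator orthogonal to everything (coefficient exactly 0) does
    not change RSS when dropped, so AIC strictly prefers dropping it."""
    rng = np.random.default_rng(2)
    n = 300
    a = rng.integers(0, 2, n).astype(float)
    y = 1.0 - 2.0 * a + rng.normal(size=n)
    x = np.column_stack([np.ones(n), a, y])
    m = rng.normal(size=n)
    m -= x @ np.linalg.lstsq(x, m, rcond=None)[0]  # β̂ = 0 by construction
    df = pd.DataFrame({"apoe2": a, "y": y, "m": m, "family_id": "F"})
    trace = backward_stepwise_aic(df, "y", ["m"], ["apoe2"])
    assert trace.retained == []
    assert trace.final_aic < trace.initial_aic


def test_signal_mediators_retained_more_often_than_noise():
    keep_signal = keep_noise = 0
    n_sim = 30
    for s in range(n_sim):
        k = 6
        cfg = cm.default_config(
            seed=70_000 + s, n_families=200, n_mediators=k,
            alpha=np.full(k, 0.5),
            beta_think=np.array([3.0, -3.0, 0.0, 0.0, 0.0, 0.0]),
            beta_ink=np.zeros(k),
        )
        cohort, _ = cm.simulate_cohort(cfg)
        sample, _ = cm.build_analysis_sample(cohort, cfg.mediator_names)
        sample, _ = cm.preprocess_mediators(sample, cfg.mediator_names)
        trace = backward_stepwise_aic(sample, "think_time", cfg.mediator_names,
                                      ["apoe2", *CONF])
        retained = set(trace.retained)
        keep_signal += sum(m in retained for m in cfg.mediator_names[:2])
        keep_noise += sum(m in retained for m in cfg.mediator_names[2:])
    signal_rate = keep_signal / (2 * n_sim)
    noise_rate = keep_noise / (4 * n_sim)
    assert signal_rate > 0.9
    assert signal_rate > noise_rate + 0.3


class TestSecondary:
    def test_empty_retained_set_reduces_to_direct(self, analysis_sample):
        cfg, sample, _ = analysis_sample
        dec, _, _ = estimate_mediation(sample, "think_time", [], CONF)
        assert dec.combined_indirect == 0.0
        assert dec.total == dec.direct
        assert dec.mediated_proportion == 0.0

    def test_published_secondary_identities(self):
        total, pm, _ = cm.combine_effects(-3.16, -0.81)
        assert total == pytest.approx(-3.97, abs=1e-12)
        assert round(100 * pm) == 20

    def test_secondary_totals_close_to_primary(self):
        """After selection, the total effect should barely move."""
        cfg, sample, truth = _prepared(13, n_families=250, n_mediators=4)
        primary, _, _ = estimate_mediation(
            sample, "think_time", cfg.mediator_names, CONF, engine="ols")
        sec = secondary_analysis(
            sample, ["think_time"], cfg.mediator_names, CONF,
            engine="ols", reps=30, seed=1)
        assert sec["think_time"].decomposition.total == pytest.approx(
            primary.total, abs=0.5)

    def test_secondary_structure_and_bootstrap(self):
        cfg, sample, _ = _prepared(15, n_families=120, n_mediators=3)
        sec = secondary_analysis(
            sample, ["think_time", "ink_time"], cfg.mediator_names, CONF,
            engine="ols", reps=40, seed=2)
        for outcome, res in sec.items():
            assert set(res.trace.retained) <= set(cfg.mediator_names)
            assert set(res.decomposition.indirect) == set(res.trace.retained)
            assert "total" in res.bootstrap
            b = res.bootstrap["total"]
            assert b.ci_low <= b.ci_high

    def test_reselect_in_replicates_mode_runs(self):
        cfg, sample, _ = _prepared(17, n_families=80, n_mediators=3)
        sec = secondary_analysis(
            sample, ["ink_time"], cfg.mediator_names, CONF,
            engine="ols", reps=20, seed=3, reselect_in_replicates=True)
        assert sec["ink_time"].bootstrap["direct"].n_failed == 0
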