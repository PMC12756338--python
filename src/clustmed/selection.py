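"""Backward stepwise AIC selection of mediators in the outcome model.

Starting from the outcome model containing the exposure, every
candidate mediator, and all confounders, single-mediator deletions are
evaluated and the one giving the largest AIC decrease is removed; the
procedure stops when no deletion lowers the AIC. Only mediator terms
are eligible — the intercept, exposure and confounders are forced.

AIC is computed under the independence Gaussian (OLS) likelihood,

    AIC = n·log(RSS/n) + 2(p + 1),

with p mean parameters plus one variance parameter (additive constants
cancel in comparisons). GEE has no likelihood, so selection runs on the
ordinary linear model and the final retained set is then refit with the
requested engine for effect estimation. Ties in AIC are broken toward
the candidate earliest in the configured mediator order, making the
procedure fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SelectionError
from .gee import GEEFit
from .inference import BootstrapResult, cluster_bootstrap
from .mediation import (
    DEFAULT_TOTAL_THRESHOLD,
    MediationDecomposition,
    estimate_mediation,
    make_estimator,
)

__all__ = [
    "SelectionStep",
    "SelectionTrace",
    "gaussian_aic",
    "backward_stepwise_aic",
    "SecondaryOutcome",
    "secondary_analysis",
]


def gaussian_aic(rss: float, n: int, p: int) -> float:
    """AIC of an OLS fit with residual sum of squares ``rss`` and ``p``
    mean parameters (the +1 counts the error variance)."""
    if rss <= 0.0:  # perfect fit: AIC unbounded below
        return -np.inf
    return n * np.log(rss / n) + 2.0 * (p + 1)


@dataclass
class SelectionStep:
    removed: str
    aic_before: float
    aic_after: float


@dataclass
class SelectionTrace:
    """Audit record of one backward stepwise run."""

    outcome: str
    steps: list[SelectionStep]
    retained: list[str]
    initial_aic: float
    final_aic: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome,
                    "step": i + 1,
                    "removed": s.removed,
                    "aic_before": s.aic_before,
                    "aic_after": s.aic_after,
                }
                for i, s in enumerate(self.steps)
            ]
        )


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    coef, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise SelectionError("candidate model is rank deficient")
    if res.size:
        return float(res[0])
    r = y - x @ coef
    return float(r @ r)


def backward_stepwise_aic(
    data: pd.DataFrame,
    outcome: str,
    mediators: Sequence[str],
    forced: Sequence[str],
) -> SelectionTrace:
    """Backward-delete mediators from the outcome model by AIC.

    ``forced`` terms (exposure and confounders; the intercept is
    implicit) are always kept. The trace's AIC sequence is strictly
    decreasing across accepted steps.
    """
    mediators = list(mediators)
    forced = list(forced)
    y = data[outcome].to_numpy(dtype=float)
    n = y.size
    ones = np.ones((n, 1))
    fmat = data[forced].to_numpy(dtype=float) if forced else np.empty((n, 0))
    mmat = {m: data[m].to_numpy(dtype=float) for m in mediators}

    def aic_for(subset: list[str]) -> float:
        cols = [ones, fmat] + [mmat[m][:, None] for m in subset]
        x = np.hstack(cols)
        return gaussian_aic(_rss(x, y), n, x.shape[1])

    current = list(mediators)
    current_aic = aic_for(current)
    initial_aic = current_aic
    steps: list[SelectionStep] = []
    while current:
        best_name = None
        best_aic = current_aic
        for m in current:  # configured order; strict < keeps the earliest tie
            candidate = [x for x in current if x != m]
            a = aic_for(candidate)
            if a < best_aic:
                best_aic, best_name = a, m
        if best_name is None:
            break
        steps.append(SelectionStep(best_name, current_aic, best_aic))
        current.remove(best_name)
        current_aic = best_aic
    return SelectionTrace(
        outcome=outcome,
        steps=steps,
        retained=current,
        initial_aic=initial_aic,
        final_aic=current_aic,
    )


@dataclass
class SecondaryOutcome:
    """Selection trace plus the rerun mediation analysis for one outcome."""

    trace: SelectionTrace
    decomposition: MediationDecomposition
    mediator_fits: dict[str, GEEFit]
    outcome_fit: GEEFit
    bootstrap: dict[str, BootstrapResult]


def secondary_analysis(
    cohort: pd.DataFrame,
    outcomes: Sequence[str],
    mediators: Sequence[str],
    confounders: Sequence[str],
    exposure: str = "apoe2",
    cluster: str = "family_id",
    engine: str = "gee",
    reps: int = 1500,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    reselect_in_replicates: bool = False,
    total_threshold: float = DEFAULT_TOTAL_THRESHOLD,
) -> dict[str, SecondaryOutcome]:
    """Select mediators per outcome, then rerun the full mediation analysis.

    Each outcome may retain a different mediator set. By default the
    retained set is selected once on the observed sample and held fixed
    across bootstrap replicates; ``reselect_in_replicates=True`` repeats
    the selection inside every replicate instead (more conservative).
    An empty retained set is legal: the decomposition then reduces to
    direct = total with zero combined indirect effect.
    """
    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    out: dict[str, SecondaryOutcome] = {}
    for outcome, child in zip(outcomes, master.spawn(len(outcomes))):
        trace = backward_stepwise_aic(
            cohort, outcome, mediators, [exposure, *confounders]
        )
        retained = trace.retained
        dec, med_fits, out_fit = estimate_mediation(
            cohort, outcome, retained, confounders, exposure, cluster,
            engine=engine, total_threshold=total_threshold,
        )
        if reselect_in_replicates:
            def analysis(df: pd.DataFrame, _outcome: str = outcome
                         ) -> dict[str, float]:
                t = backward_stepwise_aic(
                    df, _outcome, mediators, [exposure, *confounders]
                )
                d, _, _ = estimate_mediation(
                    df, _outcome, t.retained, confounders, exposure, cluster,
                    engine=engine, compute_se=False,
                    total_threshold=total_threshold,
                )
                # replicates retain different sets; a dropped mediator
                # carries a zero indirect effect so quantities line up
                q = d.quantities()
                for m in mediators:
                    q.setdefault(f"indirect:{m}", 0.0)
                return q
        else:
            analysis = make_estimator(
                outcome, retained, confounders, exposure, cluster, engine,
                total_threshold,
            )
        boot = cluster_bootstrap(
            cohort, analysis, cluster=cluster, reps=reps, level=level, seed=child,
        )
        out[outcome] = SecondaryOutcome(trace, dec, med_fits, out_fit, boot)
    return out
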