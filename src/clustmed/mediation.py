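"""Product-method effect decomposition for multiple continuous mediators.

With linear mediator models M_k ~ exposure + confounders (exposure
coefficient α̂_k) and a linear outcome model Y ~ exposure + all M_k +
confounders (exposure coefficient θ̂, mediator coefficients β̂_k), and no
exposure–mediator interactions, the regression-based decomposition is

    indirect through M_k:   δ̂_k = α̂_k · β̂_k
    combined indirect:      Δ̂  = Σ_k δ̂_k
    direct:                 θ̂
    total:                  τ̂  = θ̂ + Δ̂
    mediated proportion:    P̂M = Δ̂ / τ̂          (τ̂ ≠ 0)

A negative indirect effect is *protective* here (the pathway shortens
the clock-drawing time); a positive one is deleterious.

Under OLS on a common sample the product method coincides exactly with
the difference method (exposure coefficient without mediators minus
with mediators); :func:`difference_method_oracle` exposes that identity
as an independent check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MediationError, RankDeficiencyError
from .gee import GEEFit, ModelSpec, fit_gee

__all__ = [
    "MediationDecomposition",
    "combine_effects",
    "decompose",
    "estimate_mediation",
    "make_estimator",
    "difference_method_oracle",
]

#: |total| below this (seconds) flags the mediated proportion as unstable.
DEFAULT_TOTAL_THRESHOLD = 0.1


@dataclass
class MediationDecomposition:
    """Effect decomposition for one outcome (all effects in seconds)."""

    outcome: str
    direct: float
    indirect: dict[str, float]
    combined_indirect: float
    total: float
    mediated_proportion: float  # Δ̂/τ̂, unitless; NaN when τ̂ == 0
    unstable: bool              # |total| below the instability threshold
    total_threshold: float = DEFAULT_TOTAL_THRESHOLD

    def quantities(self) -> dict[str, float]:
        """Flat name → value map of every reported quantity."""
        out = {
            "direct": self.direct,
            "combined_indirect": self.combined_indirect,
            "total": self.total,
            "mediated_proportion": self.mediated_proportion,
        }
        for name, value in self.indirect.items():
            out[f"indirect:{name}"] = value
        return out


def combine_effects(
    direct: float, combined_indirect: float,
    total_threshold: float = DEFAULT_TOTAL_THRESHOLD,
) -> tuple[float, float, bool]:
    """(total, mediated proportion, instability flag) from the identities.

    The mediated proportion is NaN for a vanishing total effect unless
    the combined indirect effect also vanishes (then 0 by convention,
    e.g. a null model with no mediation at all).
    """
    total = direct + combined_indirect
    if total != 0.0:
        proportion = combined_indirect / total
    else:
        proportion = 0.0 if combined_indirect == 0.0 else float("nan")
    return total, proportion, abs(total) < total_threshold


def decompose(
    mediator_fits: Sequence[GEEFit] | Mapping[str, GEEFit],
    outcome_fit: GEEFit,
    exposure: str,
    mediators: Sequence[str],
    total_threshold: float = DEFAULT_TOTAL_THRESHOLD,
) -> MediationDecomposition:
    """Combine mediator-model and outcome-model estimates.

    ``mediator_fits`` may be a list (matched to ``mediators`` by each
    fit's response) or a mapping keyed by mediator name. Every mediator
    in the outcome model must have a mediator fit and vice versa.
    """
    if isinstance(mediator_fits, Mapping):
        fits = dict(mediator_fits)
    else:
        fits = {f.spec.response: f for f in mediator_fits}
    missing = [m for m in mediators if m not in fits]
    extra = [m for m in fits if m not in mediators]
    if missing or extra:
        raise MediationError(
            f"mediator fits do not match mediator list (missing={missing}, "
            f"unexpected={extra})"
        )
    for m in mediators:
        if exposure not in fits[m].params.index:
            raise MediationError(f"mediator fit for {m!r} lacks {exposure!r}")
        if m not in outcome_fit.params.index:
            raise MediationError(f"outcome fit lacks mediator coefficient {m!r}")
    if exposure not in outcome_fit.params.index:
        raise MediationError(f"outcome fit lacks exposure coefficient {exposure!r}")

    indirect = {
        m: float(fits[m].params[exposure] * outcome_fit.params[m]) for m in mediators
    }
    direct = float(outcome_fit.params[exposure])
    combined = float(sum(indirect.values()))
    total, proportion, unstable = combine_effects(direct, combined, total_threshold)
    return MediationDecomposition(
        outcome=outcome_fit.spec.response,
        direct=direct,
        indirect=indirect,
        combined_indirect=combined,
        total=total,
        mediated_proportion=proportion,
        unstable=unstable,
        total_threshold=total_threshold,
    )


def estimate_mediation(
    data: pd.DataFrame,
    outcome: str,
    mediators: Sequence[str],
    confounders: Sequence[str],
    exposure: str = "apoe2",
    cluster: str = "family_id",
    engine: str = "gee",
    compute_se: bool = True,
    total_threshold: float = DEFAULT_TOTAL_THRESHOLD,
) -> tuple[MediationDecomposition, dict[str, GEEFit], GEEFit]:
    """Fit all mediator models and the outcome model, then decompose.

    ``engine`` selects the working correlation of every fit: ``"gee"``
    (exchangeable, the default) or ``"ols"`` (independence, i.e. OLS
    point estimates with cluster-robust standard errors).
    """
    working = {"gee": "exchangeable", "ols": "independence"}.get(engine)
    if working is None:
        raise ValueError(f"unknown engine {engine!r}")
    mediator_fits = {
        m: fit_gee(
            data,
            ModelSpec(m, (exposure, *confounders), cluster),
            working=working,
            compute_se=compute_se,
        )
        for m in mediators
    }
    outcome_fit = fit_gee(
        data,
        ModelSpec(outcome, (exposure, *mediators, *confounders), cluster),
        working=working,
        compute_se=compute_se,
    )
    dec = decompose(mediator_fits, outcome_fit, exposure, mediators, total_threshold)
    return dec, mediator_fits, outcome_fit


def _ols_point_decomposition(
    data: pd.DataFrame,
    outcome: str,
    mediators: Sequence[str],
    confounders: Sequence[str],
    exposure: str,
    total_threshold: float,
) -> MediationDecomposition:
    """Fast OLS point estimates only (single multi-RHS solve for all
    mediator models, which share one design matrix); used inside the
    bootstrap where no standard errors are needed."""
    n = len(data)
    a = data[exposure].to_numpy(dtype=float)
    cmat = data[list(confounders)].to_numpy(dtype=float) if confounders else \
        np.empty((n, 0))
    mmat = data[list(mediators)].to_numpy(dtype=float) if mediators else \
        np.empty((n, 0))
    y = data[outcome].to_numpy(dtype=float)

    xm = np.column_stack([np.ones(n), a, cmat])
    coefs, _, rank, _ = np.linalg.lstsq(xm, mmat, rcond=None) if mediators else \
        (np.zeros((xm.shape[1], 0)), None, xm.shape[1], None)
    if rank < xm.shape[1]:
        raise RankDeficiencyError("mediator-model design is rank deficient")
    alpha = coefs[1] if mediators else np.empty(0)

    xo = np.column_stack([np.ones(n), a, mmat, cmat])
    coef, _, rank, _ = np.linalg.lstsq(xo, y, rcond=None)
    if rank < xo.shape[1]:
        raise RankDeficiencyError("outcome-model design is rank deficient")
    direct = float(coef[1])
    beta = coef[2:2 + len(mediators)]

    indirect = {m: float(al * be) for m, al, be in zip(mediators, alpha, beta)}
    combined = float(sum(indirect.values()))
    total, proportion, unstable = combine_effects(direct, combined, total_threshold)
    return MediationDecomposition(
        outcome=outcome,
        direct=direct,
        indirect=indirect,
        combined_indirect=combined,
        total=total,
        mediated_proportion=proportion,
        unstable=unstable,
        total_threshold=total_threshold,
    )


def make_estimator(
    outcome: str,
    mediators: Sequence[str],
    confounders: Sequence[str],
    exposure: str = "apoe2",
    cluster: str = "family_id",
    engine: str = "gee",
    total_threshold: float = DEFAULT_TOTAL_THRESHOLD,
) -> Callable[[pd.DataFrame], MediationDecomposition]:
    """Closure re-running the whole estimation on any (re)sampled table.

    This is the unit the cluster bootstrap replays. The OLS engine uses
    a point-estimate fast path (identical estimates to
    :func:`estimate_mediation` with ``engine="ols"``, no SEs).
    """
    mediators = list(mediators)
    confounders = list(confounders)

    if engine == "ols":
        def estimator(df: pd.DataFrame) -> MediationDecomposition:
            return _ols_point_decomposition(
                df, outcome, mediators, confounders, exposure, total_threshold
            )
    else:
        def estimator(df: pd.DataFrame) -> MediationDecomposition:
            dec, _, _ = estimate_mediation(
                df, outcome, mediators, confounders, exposure, cluster,
                engine=engine, compute_se=False, total_threshold=total_threshold,
            )
            return dec

    return estimator


def difference_method_oracle(
    data: pd.DataFrame,
    outcome: str,
    mediators: Sequence[str],
    confounders: Sequence[str],
    exposure: str = "apoe2",
) -> float:
    """Combined indirect effect by the difference method, under OLS.

    Fits Y ~ exposure + confounders and Y ~ exposure + mediators +
    confounders by OLS on the identical sample and returns the drop in
    the exposure coefficient. For linear models without interaction
    this equals Σ α̂_k·β̂_k exactly; it is deliberately computed through
    a separate code path so it can serve as an independent oracle for
    :func:`decompose`.
    """
    n = len(data)
    a = data[exposure].to_numpy(dtype=float)
    cmat = data[list(confounders)].to_numpy(dtype=float) if confounders else \
        np.empty((n, 0))
    mmat = data[list(mediators)].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)

    x_without = np.column_stack([np.ones(n), a, cmat])
    x_with = np.column_stack([np.ones(n), a, mmat, cmat])
    for x in (x_without, x_with):
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise RankDeficiencyError("oracle design is rank deficient")
    coef_without, *_ = np.linalg.lstsq(x_without, y, rcond=None)
    coef_with, *_ = np.linalg.lstsq(x_with, y, rcond=None)
    return float(coef_without[1] - coef_with[1])
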