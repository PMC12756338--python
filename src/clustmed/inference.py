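"""Cluster-bootstrap percentile confidence intervals.

Families (clusters) are resampled with replacement — the same number of
families as observed — and the entire estimation (all model fits plus
the effect decomposition) is re-run on each replicate. A family drawn
twice enters the replicate as two distinct clusters. Intervals are
Efron percentile intervals: the empirical 2.5% and 97.5% quantiles of
the successful replicate estimates, computed by linear interpolation of
the empirical CDF (the "type 7" convention).

Significance is "the 95% CI excludes zero"; by convention it is not
assessed for the mediated proportion, which is a ratio with wide,
possibly sign-crossing intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import BootstrapError, EstimationError
from .mediation import MediationDecomposition

__all__ = ["BootstrapResult", "percentile_ci", "cluster_bootstrap"]


@dataclass
class BootstrapResult:
    """Replicate distribution and percentile CI for one quantity."""

    name: str
    estimate: float
    replicates: np.ndarray  # length = replicates attempted; NaN where failed
    n_failed: int
    ci_low: float
    ci_high: float
    significant: bool | None  # None when significance is not assessed


def percentile_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Efron percentile interval of a replicate sample.

    Quantiles use linear interpolation of the order statistics
    (numpy's default, R type 7): for n values, quantile q sits at
    position 1 + (n−1)q.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot form a percentile interval from no values")
    lo, hi = np.quantile(values, [(1.0 - level) / 2.0, (1.0 + level) / 2.0])
    return float(lo), float(hi)


def _as_quantities(result: Mapping[str, float] | MediationDecomposition
                   ) -> dict[str, float]:
    if isinstance(result, MediationDecomposition):
        return result.quantities()
    return dict(result)


def cluster_bootstrap(
    cohort: pd.DataFrame,
    analysis: Callable[[pd.DataFrame], Mapping[str, float] | MediationDecomposition],
    cluster: str = "family_id",
    reps: int = 1500,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    resample_unit: str = "family",
    max_failure_rate: float = 0.01,
    skip_significance: Iterable[str] = ("mediated_proportion",),
) -> dict[str, BootstrapResult]:
    """Percentile bootstrap over every quantity ``analysis`` reports.

    ``analysis`` maps a cohort table to a name → estimate mapping (a
    :class:`MediationDecomposition` is accepted and flattened). Each
    replicate draws families with replacement, relabels them 0..F−1 so
    repeated families stay distinct clusters, and replays ``analysis``.
    Replicates raising an estimation error are recorded as failures and
    excluded from the quantiles; more than ``max_failure_rate`` failures
    is a hard :class:`BootstrapError`.

    Per-replicate random streams are spawned from one master seed, so
    results are reproducible and independent of evaluation order.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if resample_unit not in ("family", "individual"):
        raise ValueError(f"unknown resample unit {resample_unit!r}")

    codes, _ = pd.factorize(cohort[cluster])
    group_rows = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    n_groups = len(group_rows)
    if n_groups < 2:
        raise ValueError("need at least two families to bootstrap")

    point = _as_quantities(analysis(cohort))
    names = list(point)
    group_sizes = np.array([g.size for g in group_rows])
    n_rows = len(cohort)

    master = (seed if isinstance(seed, np.random.SeedSequence)
              else np.random.SeedSequence(seed))
    children = master.spawn(reps)

    draws = np.full((reps, len(names)), np.nan)
    n_failed = 0
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        if resample_unit == "family":
            fams = rng.integers(0, n_groups, n_groups)
            rows = np.concatenate([group_rows[f] for f in fams])
            new_cluster = np.repeat(np.arange(n_groups), group_sizes[fams])
        else:
            rows = rng.integers(0, n_rows, n_rows)
            new_cluster = np.arange(n_rows)  # each draw its own cluster
        rep = cohort.take(rows)
        rep[cluster] = new_cluster
        try:
            q = _as_quantities(analysis(rep))
        except EstimationError:
            n_failed += 1
            continue
        draws[r] = [q[name] for name in names]

    if n_failed > max_failure_rate * reps:
        raise BootstrapError(
            f"{n_failed}/{reps} bootstrap replicates failed to estimate "
            f"(limit {max_failure_rate:.0%})"
        )

    skip = set(skip_significance)
    results: dict[str, BootstrapResult] = {}
    for j, name in enumerate(names):
        col = draws[:, j]
        ok = col[np.isfinite(col)]
        lo, hi = percentile_ci(ok, level)
        significant = None if name in skip else bool(lo > 0.0 or hi < 0.0)
        results[name] = BootstrapResult(
            name=name,
            estimate=float(point[name]),
            replicates=col,
            n_failed=n_failed,
            ci_low=lo,
            ci_high=hi,
            significant=significant,
        )
    return results
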