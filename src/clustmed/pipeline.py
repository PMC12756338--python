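"""End-to-end orchestration: read → genotype → preprocess → estimate →
bootstrap → report, with primary / secondary / sensitivity modes.

The three clock-drawing outcomes are analysed independently (separate
outcome regressions). Mediator models do not involve the outcome, so in
primary mode they are shared across outcomes. Sensitivity mode drops
the configured confounders (by default lipid-lowering medication use)
from *both* the mediator and the outcome models. Mediator
standardization constants are computed once on the analysis sample and
held fixed inside bootstrap replicates (preprocessing is treated as a
fixed upstream step; ``standardize_in_replicates`` reverses that).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    build_analysis_sample,
    detect_mediators,
    preprocess_mediators,
    read_cohort,
)
from .errors import ConfigError
from .inference import BootstrapResult, cluster_bootstrap
from .mediation import (
    DEFAULT_TOTAL_THRESHOLD,
    MediationDecomposition,
    estimate_mediation,
    make_estimator,
)
from .selection import SecondaryOutcome, secondary_analysis
from .synthetic import CONFOUNDERS

__all__ = ["RunConfig", "run", "RunResult", "analyze_cohort"]

OUTCOMES = ["total_time", "think_time", "ink_time"]
MODES = ("primary", "secondary", "sensitivity")

log = logging.getLogger("clustmed")


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    input: str | Path | None = None
    mediators: list[str] | None = None      # None: auto-detect from columns
    confounders: list[str] = field(default_factory=lambda: list(CONFOUNDERS))
    outcomes: list[str] = field(default_factory=lambda: list(OUTCOMES))
    mode: str = "primary"
    engine: str = "gee"
    reps: int = 1500
    level: float = 0.95
    seed: int = 0
    resample_unit: str = "family"
    sensitivity_drop: list[str] = field(default_factory=lambda: ["lipid_med"])
    standardize_in_replicates: bool = False
    reselect_in_replicates: bool = False
    total_threshold: float = DEFAULT_TOTAL_THRESHOLD
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.reps < 1:
            raise ConfigError("reps must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ConfigError("level must lie in (0, 1)")
        if self.engine not in ("gee", "ols"):
            raise ConfigError(f"engine must be 'gee' or 'ols', got {self.engine!r}")


@dataclass
class RunResult:
    """In-memory results of one run (also serialized to the run directory)."""

    config: RunConfig
    decompositions: dict[str, MediationDecomposition]
    bootstrap: dict[str, dict[str, BootstrapResult]]
    secondary: dict[str, SecondaryOutcome] | None
    transforms: dict[str, tuple[float, float]]
    drop_log: dict
    n_obs: int
    n_families: int
    out_dir: Path | None = None


def _bootstrap_outcome(
    df: pd.DataFrame,
    raw_df: pd.DataFrame,
    outcome: str,
    mediators: Sequence[str],
    config: RunConfig,
    seed: np.random.SeedSequence,
) -> dict[str, BootstrapResult]:
    estimator = make_estimator(
        outcome, mediators, config.confounders_effective, "apoe2", "family_id",
        config.engine, config.total_threshold,
    )
    if config.standardize_in_replicates:
        med_list = list(mediators)

        def analysis(rep: pd.DataFrame) -> MediationDecomposition:
            rep, _ = preprocess_mediators(rep, med_list)
            return estimator(rep)

        source = raw_df
    else:
        analysis = estimator
        source = df
    return cluster_bootstrap(
        source, analysis, cluster="family_id", reps=config.reps,
        level=config.level, seed=seed, resample_unit=config.resample_unit,
    )


def analyze_cohort(cohort: pd.DataFrame, config: RunConfig) -> RunResult:
    """Run the configured analysis on an already-loaded cohort table."""
    mediators = (config.mediators if config.mediators is not None
                 else detect_mediators(cohort))
    if not mediators:
        raise ConfigError("no mediator columns found or configured")
    confounders = list(config.confounders)
    if config.mode == "sensitivity":
        confounders = [c for c in confounders if c not in config.sensitivity_drop]
        log.info("sensitivity mode: dropped %s from mediator and outcome models",
                 config.sensitivity_drop)
    config.confounders_effective = confounders  # used by bootstrap closures

    sample, drop_log = build_analysis_sample(cohort, mediators, confounders)
    log.info("analysis sample: %d of %d rows (dropped genotype=%d missing=%d)",
             len(sample), len(cohort), drop_log.genotype, drop_log.missing)
    raw_sample = sample
    sample, transforms = preprocess_mediators(sample, mediators)

    master = np.random.SeedSequence(config.seed)
    outcome_seeds = master.spawn(len(config.outcomes) + 1)

    decs: dict[str, MediationDecomposition] = {}
    boots: dict[str, dict[str, BootstrapResult]] = {}
    secondary = None

    analysis_mediators = mediators
    if config.mode == "secondary":
        secondary = secondary_analysis(
            sample, config.outcomes, mediators, confounders,
            engine=config.engine, reps=config.reps, level=config.level,
            seed=outcome_seeds[-1],
            reselect_in_replicates=config.reselect_in_replicates,
            total_threshold=config.total_threshold,
        )
        for outcome in config.outcomes:
            sec = secondary[outcome]
            decs[outcome] = sec.decomposition
            boots[outcome] = sec.bootstrap
            log.info("secondary %s: retained %d/%d mediators", outcome,
                     len(sec.trace.retained), len(mediators))
    else:
        for outcome, oseed in zip(config.outcomes, outcome_seeds):
            dec, _, _ = estimate_mediation(
                sample, outcome, analysis_mediators, confounders,
                engine=config.engine, total_threshold=config.total_threshold,
            )
            decs[outcome] = dec
            boots[outcome] = _bootstrap_outcome(
                sample, raw_sample, outcome, analysis_mediators, config, oseed
            )
            log.info("%s: direct=%.3f combined_indirect=%.3f total=%.3f",
                     outcome, dec.direct, dec.combined_indirect, dec.total)

    _check_identities(decs)
    return RunResult(
        config=config,
        decompositions=decs,
        bootstrap=boots,
        secondary=secondary,
        transforms=transforms,
        drop_log={
            "genotype": drop_log.genotype,
            "ambiguous": drop_log.ambiguous,
            "missing": drop_log.missing,
            "missing_by_column": drop_log.missing_by_column,
        },
        n_obs=len(sample),
        n_families=sample["family_id"].nunique(),
    )


def _check_identities(decs: dict[str, MediationDecomposition]) -> None:
    """Machine-check τ̂ = θ̂ + Δ̂ and P̂M·τ̂ = Δ̂ on every run."""
    for outcome, d in decs.items():
        assert d.total == d.direct + d.combined_indirect, outcome
        if d.total != 0.0 and np.isfinite(d.mediated_proportion):
            assert abs(d.mediated_proportion * d.total - d.combined_indirect) < 1e-10


def _effects_frame(result: RunResult) -> pd.DataFrame:
    rows = []
    for outcome, boot in result.bootstrap.items():
        for name in ("direct", "combined_indirect", "total", "mediated_proportion"):
            b = boot[name]
            rows.append({
                "outcome": outcome, "quantity": name, "estimate": b.estimate,
                "ci_low": b.ci_low, "ci_high": b.ci_high,
                "significant": b.significant,
            })
    return pd.DataFrame(rows)


def _indirect_frame(result: RunResult) -> pd.DataFrame:
    rows = []
    for outcome, boot in result.bootstrap.items():
        for name, b in boot.items():
            if not name.startswith("indirect:"):
                continue
            rows.append({
                "outcome": outcome, "mediator": name.split(":", 1)[1],
                "estimate": b.estimate, "ci_low": b.ci_low, "ci_high": b.ci_high,
                "significant": b.significant,
            })
    return pd.DataFrame(rows)


def _summary_dict(result: RunResult) -> dict:
    cfg = asdict(result.config)
    cfg.pop("confounders_effective", None)
    cfg["input"] = str(cfg["input"]) if cfg["input"] is not None else None
    cfg["out_dir"] = str(cfg["out_dir"]) if cfg["out_dir"] is not None else None
    summary = {
        "clustmed_version": __version__,
        "config": cfg,
        "n_obs": result.n_obs,
        "n_families": result.n_families,
        "drop_log": result.drop_log,
        "outcomes": {},
    }
    for outcome, dec in result.decompositions.items():
        boot = result.bootstrap[outcome]
        entry = {
            "direct": dec.direct,
            "combined_indirect": dec.combined_indirect,
            "total": dec.total,
            "mediated_proportion": dec.mediated_proportion,
            "mediated_proportion_pct": (
                None if not np.isfinite(dec.mediated_proportion)
                else round(100.0 * dec.mediated_proportion)
            ),
            "unstable_total": dec.unstable,
            "ci": {
                name: [boot[name].ci_low, boot[name].ci_high]
                for name in ("direct", "combined_indirect", "total",
                             "mediated_proportion")
            },
            "indirect": dec.indirect,
        }
        if result.secondary is not None:
            entry["retained_mediators"] = result.secondary[outcome].trace.retained
        summary["outcomes"][outcome] = entry
    return summary


def run(config: RunConfig, cohort: pd.DataFrame | None = None) -> RunResult:
    """Execute a full run; write tables, summary and log when
    ``config.out_dir`` is set."""
    t0 = time.time()
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    handler = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    try:
        log.info("clustmed %s | numpy %s | pandas %s | seed=%d mode=%s engine=%s",
                 __version__, np.__version__, pd.__version__,
                 config.seed, config.mode, config.engine)
        if cohort is None:
            if config.input is None:
                raise ConfigError("either config.input or a cohort table is required")
            cohort = read_cohort(config.input)
            log.info("read %d rows from %s", len(cohort), config.input)
        result = analyze_cohort(cohort, config)
        result.out_dir = out_dir
        if out_dir is not None:
            _effects_frame(result).to_csv(out_dir / "effects.csv", index=False)
            _indirect_frame(result).to_csv(out_dir / "indirect_effects.csv",
                                           index=False)
            if result.secondary is not None:
                traces = pd.concat(
                    [s.trace.to_frame() for s in result.secondary.values()],
                    ignore_index=True,
                )
                traces.to_csv(out_dir / "selection_trace.csv", index=False)
            (out_dir / "summary.json").write_text(
                json.dumps(_summary_dict(result), indent=2, allow_nan=True)
            )
            log.info("run complete in %.1f s", time.time() - t0)
        return result
    finally:
        if handler is not None:
            log.removeHandler(handler)
            handler.close()
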