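"""Cohort table I/O, APOE genotype-group derivation, and mediator preprocessing.

APOE alleles are called from the two coding SNPs rs7412 and rs429358:
on one haplotype, rs7412=T with rs429358=T defines e2, rs7412=C with
rs429358=T defines e3, and rs7412=C with rs429358=C defines e4. The
combination rs7412=T with rs429358=C has no defined allele and, because
genotypes are unphased, a double-heterozygote cannot be resolved into a
diplotype at all; both cases raise :class:`AmbiguousHaplotypeError`
rather than guessing (the e4 exclusion makes a wrong guess consequential).

Genotype groups: APOE3 = e3/e3 (reference), APOE2 = e2/e2 or e2/e3;
any carrier of an e4 allele is excluded from analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousHaplotypeError,
    EmptySampleError,
    GenotypeError,
    MediatorValueError,
)
from .synthetic import CONFOUNDERS

__all__ = [
    "APOE2", "APOE3", "EXCLUDED",
    "call_apoe_alleles", "assign_group", "derive_apoe_groups",
    "read_cohort", "preprocess_mediators", "build_analysis_sample",
    "detect_mediators", "DropLog",
]

APOE2 = "APOE2"
APOE3 = "APOE3"
EXCLUDED = "EXCLUDED"

#: Haplotype → allele map for (rs7412, rs429358); (T, C) is undefined.
_HAPLOTYPE_ALLELE = {("T", "T"): "e2", ("C", "T"): "e3", ("C", "C"): "e4"}

_VALID_ALLELES = {"rs7412": {"C", "T"}, "rs429358": {"C", "T"}}

#: Columns that are never treated as mediators during auto-detection.
RESERVED_COLUMNS = {
    "participant_id", "family_id", "rs7412", "rs429358", "apoe_group", "apoe2",
    "birth_year", "think_time", "ink_time", "total_time", *CONFOUNDERS,
}


def _parse_genotype(genotype: str, snp: str) -> tuple[str, str]:
    if not isinstance(genotype, str):
        raise GenotypeError(f"{snp}: genotype must be a string like 'C/T'")
    raw = genotype.replace("/", "").replace("|", "").upper()
    if len(raw) != 2:
        raise GenotypeError(f"{snp}: expected a biallelic genotype, got {genotype!r}")
    alleles = (raw[0], raw[1])
    bad = set(alleles) - _VALID_ALLELES[snp]
    if bad:
        raise GenotypeError(f"{snp}: invalid allele(s) {sorted(bad)} in {genotype!r}")
    return alleles


def call_apoe_alleles(rs7412: str, rs429358: str) -> tuple[str, str]:
    """Resolve two unphased SNP genotypes into a pair of APOE alleles.

    Raises :class:`AmbiguousHaplotypeError` when both SNPs are
    heterozygous (phase unknown: e2/e4 versus an undefined haplotype
    with e3 are indistinguishable) or when any implied haplotype is the
    undefined rs7412=T / rs429358=C combination.
    """
    a = _parse_genotype(rs7412, "rs7412")
    b = _parse_genotype(rs429358, "rs429358")
    het_a, het_b = a[0] != a[1], b[0] != b[1]
    if het_a and het_b:
        raise AmbiguousHaplotypeError(
            f"unphased double heterozygote rs7412={rs7412!r}, rs429358={rs429358!r}: "
            "diplotype cannot be resolved"
        )
    # At most one SNP is heterozygous, so haplotype pairing is forced.
    pairs = ((a[0], b[0]), (a[1], b[1]))
    alleles = []
    for pair in pairs:
        if pair == ("T", "C"):
            raise AmbiguousHaplotypeError(
                f"haplotype rs7412=T/rs429358=C (from rs7412={rs7412!r}, "
                f"rs429358={rs429358!r}) has no defined APOE allele"
            )
        alleles.append(_HAPLOTYPE_ALLELE[pair])
    return (alleles[0], alleles[1])


def assign_group(alleles: tuple[str, str]) -> str:
    """Map an allele pair to the APOE2 / APOE3 / EXCLUDED genotype group."""
    pair = frozenset(alleles) if alleles[0] != alleles[1] else frozenset({alleles[0]})
    if not pair <= {"e2", "e3", "e4"}:
        raise GenotypeError(f"invalid allele pair {alleles!r}")
    if "e4" in pair:
        return EXCLUDED
    if pair == {"e3"}:
        return APOE3
    return APOE2  # e2/e2 or e2/e3


def derive_apoe_groups(df: pd.DataFrame) -> tuple[pd.Series, int]:
    """Vector version of allele calling + group assignment.

    Unresolvable genotypes are assigned EXCLUDED (they cannot enter
    either analysis group); the second return value counts them.
    """
    groups = []
    n_ambiguous = 0
    for g1, g2 in zip(df["rs7412"], df["rs429358"]):
        if pd.isna(g1) or pd.isna(g2):
            groups.append(np.nan)
            continue
        try:
            groups.append(assign_group(call_apoe_alleles(g1, g2)))
        except AmbiguousHaplotypeError:
            n_ambiguous += 1
            groups.append(EXCLUDED)
    return pd.Series(groups, index=df.index, name="apoe_group"), n_ambiguous


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become missing values."""
    df = pd.read_csv(path, dtype={"participant_id": str, "family_id": str},
                     float_precision="round_trip")
    for col in ("participant_id", "family_id"):
        if col not in df.columns:
            raise ValueError(f"cohort file lacks required column {col!r}")
    if "apoe_group" not in df.columns and not {"rs7412", "rs429358"} <= set(df.columns):
        raise ValueError("cohort needs either apoe_group or rs7412 + rs429358")
    if df["family_id"].isna().any():
        raise ValueError("family_id must be nonmissing for every participant")
    return df


def detect_mediators(df: pd.DataFrame) -> list[str]:
    """All non-reserved columns, in file order, treated as mediators."""
    return [c for c in df.columns if c not in RESERVED_COLUMNS]


def preprocess_mediators(
    cohort: pd.DataFrame, mediator_names: list[str]
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Replace each raw mediator by the z-score of its natural log.

    Returns the transformed table and the per-mediator (mean, SD) of
    the logs, computed with the n−1 denominator on the rows given —
    call this *after* exclusions so the constants describe the analysis
    sample. Standardization makes the log base irrelevant to every
    downstream estimate.
    """
    out = cohort.copy()
    transforms: dict[str, tuple[float, float]] = {}
    for name in mediator_names:
        x = out[name].to_numpy(dtype=float)
        if np.any(x <= 0):
            raise MediatorValueError(f"mediator {name!r} has nonpositive values")
        logged = np.log(x)
        mu = float(logged.mean())
        sd = float(logged.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise MediatorValueError(f"mediator {name!r} has zero variance")
        out[name] = (logged - mu) / sd
        transforms[name] = (mu, sd)
    return out, transforms


@dataclass
class DropLog:
    """Per-reason counts of rows removed by :func:`build_analysis_sample`."""

    genotype: int = 0      # EXCLUDED group (e4 carriers + unresolvable genotypes)
    ambiguous: int = 0     # subset of `genotype` that was unresolvable
    missing: int = 0       # complete-case removal
    missing_by_column: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.genotype + self.missing


def build_analysis_sample(
    cohort: pd.DataFrame,
    mediator_names: list[str],
    confounders: list[str] | None = None,
) -> tuple[pd.DataFrame, DropLog]:
    """Derive genotype groups, apply exclusions, and complete-case filter.

    Adds the numeric exposure column ``apoe2`` (1 = APOE2, 0 = APOE3),
    derives ``generation`` from ``birth_year`` (> 1935) when absent, and
    recomputes ``total_time`` as think + ink so the identity holds
    exactly. Raises :class:`EmptySampleError` if nothing survives.
    """
    confounders = list(CONFOUNDERS) if confounders is None else list(confounders)
    df = cohort.copy()
    log = DropLog()

    if "apoe_group" not in df.columns:
        df["apoe_group"], log.ambiguous = derive_apoe_groups(df)

    keep = df["apoe_group"].isin([APOE2, APOE3])
    log.genotype = int((~keep & df["apoe_group"].notna()).sum())
    df = df.loc[keep | df["apoe_group"].isna()]

    if "generation" not in df.columns or df["generation"].isna().all():
        if "birth_year" not in df.columns:
            raise ValueError("need either a generation or a birth_year column")
        df = df.assign(generation=(df["birth_year"] > 1935).astype(float))
        df.loc[df["birth_year"].isna(), "generation"] = np.nan

    required = ["apoe_group", *confounders, *mediator_names, "think_time", "ink_time"]
    present = df[required].notna()
    complete = present.all(axis=1)
    log.missing = int((~complete).sum())
    log.missing_by_column = {
        c: int(n) for c, n in (~present).sum().items() if n > 0
    }
    df = df.loc[complete].copy()
    if df.empty:
        raise EmptySampleError("analysis sample is empty after exclusions")

    if (df[["think_time", "ink_time"]].to_numpy() < 0).any():
        warnings.warn("negative clock-drawing times in analysis sample", stacklevel=2)
    df["total_time"] = df["think_time"] + df["ink_time"]
    df["apoe2"] = (df["apoe_group"] == APOE2).astype(float)
    return df, log
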