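"""Genotype-group derivation, mediator preprocessing, sample construction."""

import numpy as np
import pandas as pd
import pytest

import clustmed as cm
from clustmed.cohort import (
    APOE2, APOE3, EXCLUDED,
    assign_group, build_analysis_sample, call_apoe_alleles, derive_apoe_groups,
    preprocess_mediators,
)
from clustmed.errors import (
    AmbiguousHaplotypeError, EmptySampleError, GenotypeError, MediatorValueError,
)

# All 9 unordered genotype combinations for (rs7412, rs429358).
RESOLVABLE = {
    ("C/C", "T/T"): (("e3", "e3"), APOE3),
    ("C/C", "C/T"): (("e3", "e4"), EXCLUDED),
    ("C/C", "C/C"): (("e4", "e4"), EXCLUDED),
    ("C/T", "T/T"): (("e3", "e2"), APOE2),
    ("T/T", "T/T"): (("e2", "e2"), APOE2),
}
UNRESOLVABLE = [("T/T", "C/C"), ("T/T", "C/T"), ("C/T", "C/C"), ("C/T", "C/T")]


@pytest.mark.parametrize("geno,expected", list(RESOLVABLE.items()))
def test_allele_calling_enumeration(geno, expected):
    alleles, group = expected
    called = call_apoe_alleles(*geno)
    assert sorted(called) == sorted(alleles)
    assert assign_group(called) == group


@pytest.mark.parametrize("geno", UNRESOLVABLE)
def test_undefined_or_phase_ambiguous_genotypes_raise(geno):
    with pytest.raises(AmbiguousHaplotypeError):
        call_apoe_alleles(*geno)


@pytest.mark.parametrize("geno", [("A/T", "T/T"), ("T", "T/T"), ("T/T", "G/G")])
def test_malformed_genotypes_raise(geno):
    with pytest.raises(GenotypeError):
        call_apoe_alleles(*geno)


def test_separator_variants_accepted():
    assert call_apoe_alleles("TT", "T|T") == ("e2", "e2")


@pytest.mark.parametrize(
    "alleles,group",
    [(("e2", "e3"), APOE2), (("e3", "e4"), EXCLUDED), (("e3", "e3"), APOE3),
     (("e2", "e2"), APOE2), (("e2", "e4"), EXCLUDED), (("e4", "e4"), EXCLUDED)],
)
def test_group_assignment(alleles, group):
    assert assign_group(alleles) == group


def test_group_assignment_rejects_invalid_allele():
    with pytest.raises(GenotypeError):
        assign_group(("e2", "e5"))


def test_derive_groups_counts_ambiguous():
    df = pd.DataFrame({"rs7412": ["C/C", "C/T", "T/T"],
                       "rs429358": ["T/T", "C/T", "T/T"]})
    groups, n_ambiguous = derive_apoe_groups(df)
    assert list(groups) == [APOE3, EXCLUDED, APOE2]
    assert n_ambiguous == 1


class TestPreprocess:
    def test_processed_mean_zero_sd_one(self, small_cohort):
        cfg, cohort, _ = small_cohort
        out, _ = preprocess_mediators(cohort, cfg.mediator_names)
        for m in cfg.mediator_names:
            assert out[m].mean() == pytest.approx(0.0, abs=1e-8)
            assert out[m].std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_two_point_sample_hand_computed(self):
        # logs are {1, 3}: mean 2, SD (n−1 denominator) √2 → z = ∓1/√2
        df = pd.DataFrame({"m": [np.e ** 1.0, np.e ** 3.0]})
        out, transforms = preprocess_mediators(df, ["m"])
        assert out["m"].to_numpy() == pytest.approx(
            [-0.7071067811865475, 0.7071067811865475])
        assert transforms["m"] == pytest.approx((2.0, np.sqrt(2.0)))

    def test_scale_invariance(self, small_cohort):
        cfg, cohort, _ = small_cohort
        m = cfg.mediator_names[0]
        a, _ = preprocess_mediators(cohort, [m])
        b, _ = preprocess_mediators(cohort.assign(**{m: cohort[m] * 7.3}), [m])
        assert a[m].to_numpy() == pytest.approx(b[m].to_numpy(), abs=1e-10)

    def test_log_base_irrelevant_after_standardization(self, small_cohort):
        cfg, cohort, _ = small_cohort
        m = cfg.mediator_names[0]
        out, _ = preprocess_mediators(cohort, [m])
        log10 = np.log10(cohort[m].to_numpy())
        z10 = (log10 - log10.mean()) / log10.std(ddof=1)
        assert out[m].to_numpy() == pytest.approx(z10, abs=1e-10)

    def test_nonpositive_and_constant_mediators_raise(self):
        with pytest.raises(MediatorValueError):
            preprocess_mediators(pd.DataFrame({"m": [1.0, -2.0]}), ["m"])
        with pytest.raises(MediatorValueError):
            preprocess_mediators(pd.DataFrame({"m": [3.0, 3.0, 3.0]}), ["m"])


def _toy_cohort():
    return pd.DataFrame({
        "participant_id": [f"P{i}" for i in range(5)],
        "family_id": ["F1", "F1", "F2", "F2", "F3"],
        "rs7412": ["C/C", "C/C", "C/C", "C/T", "T/T"],
        "rs429358": ["T/T", "C/T", "T/T", "T/T", "T/T"],  # row 1 is e3/e4
        "age_enroll": [60.0] * 5,
        "sex": [0, 1, 0, 1, 0],
        "education": [12] * 5,
        "bmi": [25.0, 26.0, np.nan, 27.0, 28.0],  # row 2 missing BMI
        "lipid_med": [0, 0, 1, 0, 1],
        "birth_year": [1930, 1940, 1932, 1945, 1938],
        "lipidA": [1.0, 2.0, 3.0, 4.0, 5.0],
        "think_time": [20.0, 21.0, 22.0, 23.0, 24.0],
        "ink_time": [10.0, 11.0, 12.0, 13.0, 14.0],
    })


class TestAnalysisSample:
    def test_drop_counts_by_reason(self):
        sample, log = build_analysis_sample(_toy_cohort(), ["lipidA"])
        assert len(sample) == 3
        assert log.genotype == 1 and log.missing == 1
        assert log.missing_by_column == {"bmi": 1}

    def test_generation_derived_from_birth_year(self):
        sample, _ = build_analysis_sample(_toy_cohort(), ["lipidA"])
        assert list(sample["generation"]) == [0.0, 1.0, 1.0]

    def test_exposure_coding(self):
        sample, _ = build_analysis_sample(_toy_cohort(), ["lipidA"])
        # APOE3 reference = 0, APOE2 = 1
        assert list(sample["apoe2"]) == [0.0, 1.0, 1.0]

    def test_total_time_recomputed(self):
        df = _toy_cohort()
        df["total_time"] = 0.0  # stale column must be overwritten
        sample, _ = build_analysis_sample(df, ["lipidA"])
        assert (sample["total_time"]
                == sample["think_time"] + sample["ink_time"]).all()

    def test_complete_synthetic_cohort_drops_nothing(self, small_cohort):
        cfg, cohort, _ = small_cohort
        sample, log = build_analysis_sample(cohort, cfg.mediator_names)
        assert len(sample) == len(cohort) and log.total == 0

    def test_e4_carriers_excluded_from_simulated_cohort(self):
        cfg = cm.default_config(seed=21, n_families=200, n_mediators=2, p_e4=0.1)
        cohort, _ = cm.simulate_cohort(cfg)
        sample, log = build_analysis_sample(cohort, cfg.mediator_names)
        assert log.genotype > 0
        assert len(sample) == len(cohort) - log.genotype

    def test_empty_sample_raises(self):
        df = _toy_cohort()
        df["rs429358"] = "C/C"  # everyone an e4 carrier or unresolvable
        with pytest.raises((EmptySampleError,)):
            build_analysis_sample(df, ["lipidA"])

    def test_standardization_statistics_from_analysis_sample(self):
        """Subset first, then standardize: the processed mediator is
        centred on the retained rows, not on the full cohort."""
        cfg = cm.default_config(seed=21, n_families=200, n_mediators=2, p_e4=0.1)
        cohort, _ = cm.simulate_cohort(cfg)
        sample, _ = build_analysis_sample(cohort, cfg.mediator_names)
        processed, _ = preprocess_mediators(sample, cfg.mediator_names)
        full, _ = preprocess_mediators(cohort, cfg.mediator_names)
        m = cfg.mediator_names[0]
        assert processed[m].mean() == pytest.approx(0.0, abs=1e-8)
        # standardizing before subsetting does NOT leave the subset centred
        assert abs(full.loc[sample.index, m].mean()) > 1e-8
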