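"""ROC/AUC, clustered resampling, optimism correction and comparison."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pzlesion import (
    DEFINITIONS,
    Cohort,
    DegenerateOutcomeError,
    GeneratorParams,
    auc,
    cluster_resample,
    compare,
    generate_cohort,
    likert_baseline,
    validate,
)
from pzlesion.battery import ModelSpec, build_battery
from pzlesion.validation import analysis_frame

from conftest import make_record

DEF_A = DEFINITIONS["A"]
SPECS_A = {s.name: s for s in build_battery(seq_variant="a")}


def brute_force_auc(scores, labels):
    """Exhaustive pairwise enumeration oracle."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_six_point_mixed_example_matches_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.7]
        labels = [0, 0, 1, 1, 0, 1]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-15
        )

    def test_single_class_raises(self):
        with pytest.raises(DegenerateOutcomeError):
            auc([1, 2, 3], [1, 1, 1])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 6), st.booleans()), min_size=2, max_size=50
        ).filter(lambda d: len({l for _, l in d}) == 2)
    )
    def test_matches_brute_force_with_ties(self, data):
        scores = [float(s) for s, _ in data]
        labels = [l for _, l in data]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.floats(-5, 5, allow_nan=False), st.booleans()),
            min_size=2, max_size=30,
        ).filter(lambda d: len({l for _, l in d}) == 2)
    )
    def test_reflection_identity(self, data):
        scores = [s for s, _ in data]
        labels = [l for _, l in data]
        assert auc(scores, labels) + auc([-s for s in scores], labels) == (
            pytest.approx(1.0, abs=1e-12)
        )


class TestClusterResample:
    def test_single_patient_cohort_resamples_to_itself(self):
        cohort = Cohort((make_record(), make_record(likert=3)))
        rep = cluster_resample(cohort, np.random.default_rng(0))
        assert len(rep) == 2
        assert len(rep.patients) == 1

    def test_fixed_rng_state_gives_identical_replicate(self, default_cohort):
        a = cluster_resample(default_cohort, np.random.default_rng(5))
        b = cluster_resample(default_cohort, np.random.default_rng(5))
        assert a.records == b.records

    def test_patient_count_preserved_lesions_variable(self, default_cohort):
        rep = cluster_resample(default_cohort, np.random.default_rng(1))
        assert len(rep.patients) == len(default_cohort.patients)

    def test_expected_lesion_count_matches_original(self):
        cohort = generate_cohort(GeneratorParams(n_patients=50, seed=6))
        rng = np.random.default_rng(2)
        counts = [len(cluster_resample(cohort, rng)) for _ in range(1000)]
        # lesion count is a sum over patient draws; 3-SE Monte-Carlo band
        sizes = {}
        for rec in cohort:
            sizes[rec.patient_id] = sizes.get(rec.patient_id, 0) + 1
        sizes = np.array(list(sizes.values()))
        n_pat = len(sizes)
        se_one = math.sqrt(n_pat * sizes.var())
        se_mean = se_one / math.sqrt(len(counts))
        assert abs(np.mean(counts) - len(cohort)) < 3 * se_mean

    def test_replicate_patients_get_distinct_cluster_ids(self, default_cohort):
        rep = cluster_resample(default_cohort, np.random.default_rng(3))
        # every synthetic id maps back to one source patient
        assert all("#" in p for p in rep.patients)


class TestValidate:
    def test_b_zero_corrected_equals_apparent(self, default_cohort):
        res = validate(default_cohort, SPECS_A["Signal1"], DEF_A, B=0, seed=0)
        assert res.corrected_auc == res.apparent_auc
        assert res.mean_optimism == 0.0
        assert math.isnan(res.ci_low)

    def test_replicate_accounting(self, default_cohort):
        res = validate(default_cohort, SPECS_A["Signal1"], DEF_A, B=50, seed=1)
        assert res.n_boot_used + res.n_boot_degenerate == 50
        assert res.corrected_auc == pytest.approx(
            res.apparent_auc - res.mean_optimism
        )

    def test_seeded_determinism(self, default_cohort):
        a = validate(default_cohort, SPECS_A["Signal1"], DEF_A, B=30, seed=9)
        b = validate(default_cohort, SPECS_A["Signal1"], DEF_A, B=30, seed=9)
        assert a == b

    def test_invariant_to_lesion_order(self, default_cohort):
        shuffled = Cohort(tuple(reversed(default_cohort.records)))
        a = validate(default_cohort, SPECS_A["Signal1+ECE"], DEF_A, B=30, seed=4)
        b = validate(shuffled, SPECS_A["Signal1+ECE"], DEF_A, B=30, seed=4)
        assert a.apparent_auc == b.apparent_auc
        assert a.corrected_auc == pytest.approx(b.corrected_auc, abs=1e-9)

    def test_optimism_nonnegative_in_expectation_small_cohorts(self):
        """Over-parameterized fits on small cohorts show positive optimism."""
        spec = SPECS_A["Signal1+Shape+ECE+Vmax+dPSA"]
        opts = []
        for seed in range(20):
            cohort = generate_cohort(GeneratorParams(n_patients=60, seed=400 + seed))
            res = validate(cohort, spec, DEF_A, B=100, seed=seed)
            opts.append(res.mean_optimism)
        assert np.mean(opts) >= -0.01

    def test_basic_ci_method_switch(self, default_cohort):
        res = validate(default_cohort, SPECS_A["Signal1"], DEF_A, B=50, seed=2,
                       ci_method="basic")
        assert res.ci_low < res.ci_high


class TestCompare:
    def test_self_comparison_is_exactly_null(self, default_cohort):
        res = compare(default_cohort, SPECS_A["Signal1"], SPECS_A["Signal1"],
                      DEF_A, B=40, seed=3)
        assert res.delta_auc == 0.0
        assert res.p_value == 1.0

    def test_signal_model_beats_intercept_only(self):
        intercept_only = ModelSpec("Intercept", (), "a", ())
        wins = 0
        for seed in range(10):
            cohort = generate_cohort(GeneratorParams(n_patients=150, seed=600 + seed))
            res = compare(cohort, SPECS_A["Signal1"], intercept_only, DEF_A,
                          B=200, seed=seed)
            wins += res.p_value < 0.05
        assert wins >= 9

    def test_likert_comparison_route(self, default_cohort):
        res = compare(default_cohort, SPECS_A["Signal1"], "Likert", DEF_A,
                      B=50, seed=5)
        assert res.model_b == "Likert"
        assert math.isfinite(res.p_value)


class TestLikertBaseline:
    def test_likert_equal_to_outcome_gives_perfect_auc(self):
        records = tuple(
            make_record(patient_id=f"P{i}", gleason_group=(3 if i % 2 else 0),
                        likert=(4 if i % 2 else 2))
            for i in range(20)
        )
        res = likert_baseline(Cohort(records), DEF_A, B=20, seed=0)
        assert res.apparent_auc == 1.0
        assert res.mean_optimism == 0.0

    def test_constant_likert_gives_half(self):
        records = tuple(
            make_record(patient_id=f"P{i}", gleason_group=(2 if i % 2 else 0),
                        likert=3)
            for i in range(10)
        )
        res = likert_baseline(Cohort(records), DEF_A, B=10, seed=0)
        assert res.apparent_auc == 0.5

    def test_baseline_tracks_generator_likert_auc(self):
        """The small-cohort baseline sits within Monte-Carlo error of the
        generator's large-sample Likert AUC."""
        from pzlesion.validation import _labels

        big = analysis_frame(generate_cohort(GeneratorParams(n_patients=20000,
                                                             seed=77)))
        target = auc(big["likert"], _labels(big, DEF_A))
        cohort = generate_cohort(GeneratorParams(n_patients=400, seed=78))
        res = likert_baseline(cohort, DEF_A, B=0, seed=0)
        frame = analysis_frame(cohort)
        n_pos = int(_labels(frame, DEF_A).sum())
        n_neg = len(frame) - n_pos
        se = math.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg))
        assert abs(res.apparent_auc - target) < 3 * se


def test_multireader_frame_rejected(default_cohort):
    import dataclasses as dc

    mixed = Cohort(
        default_cohort.records
        + tuple(dc.replace(r, reader_id="R2") for r in default_cohort.records[:5])
    )
    with pytest.raises(ValueError, match="single-reader"):
        analysis_frame(mixed)
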