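"""Synthetic cohort generator: determinism, internal consistency, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from qrsqtc.intervals import audit_qtc_consistency
from qrsqtc.stats import pooled_t_test
from qrsqtc.synthetic import (
    SyntheticCohortSpec,
    generate_cohort,
    power_simulation,
    recover_parameters,
)


def null_spec(**kwargs):
    """Both outcome groups drawn from the same pooled distribution."""
    base = dict(
        qrs_mean_yes=108, qrs_sd_yes=25, qtc_mean_yes=551, qtc_sd_yes=82,
        qrs_mean_no=108, qrs_sd_no=25, qtc_mean_no=551, qtc_sd_no=82,
    )
    base.update(kwargs)
    return SyntheticCohortSpec(**base)


class TestGenerate:
    def test_determinism_identical_spec_and_seed(self):
        spec = SyntheticCohortSpec()
        a = generate_cohort(spec, 1)
        b = generate_cohort(spec, 1)
        assert a == b

    def test_different_seeds_differ(self):
        spec = SyntheticCohortSpec()
        assert generate_cohort(spec, 1) != generate_cohort(spec, 2)

    def test_records_satisfy_interval_invariants(self):
        cohort = generate_cohort(SyntheticCohortSpec(), 1)
        assert len(cohort) == 16
        for _, ecg in cohort:
            assert 40 <= ecg.qrs_ms <= 300
            assert 200 <= ecg.qtc_ms <= 800
            assert 200 <= ecg.qt_ms <= 800
            assert ecg.qrs_ms < ecg.qt_ms
            assert 0 < ecg.ratio < 1

    def test_bazett_inversion_makes_records_self_consistent(self):
        # QT is back-computed from QTc and HR, so a Bazett audit at a
        # 1 ms tolerance finds nothing to flag.
        cohort = generate_cohort(SyntheticCohortSpec(n_yes=50, n_no=50), 3)
        flags = audit_qtc_consistency(cohort, "bazett", 1.0)
        assert not any(f.flagged for f in flags)

    def test_group_labels_follow_group_sizes(self):
        cohort = generate_cohort(SyntheticCohortSpec(n_yes=4, n_no=11), 5)
        yes, no = cohort.split_by_outcome()
        assert (len(yes), len(no)) == (4, 11)

    def test_logistic_labels_enriched_at_low_ratio(self):
        spec = null_spec(n_yes=300, n_no=300, label_model="logistic")
        cohort = generate_cohort(spec, 9)
        ratios = np.array(cohort.values("ratio"))
        labels = np.array([c.vt_vf for c, _ in cohort])
        assert labels.any() and not labels.all()
        assert ratios[labels].mean() < ratios[~labels].mean()

    def test_pathological_spec_raises(self):
        # QRS pinned near 290 ms with QTc near 210 at HR 60 forces QT < QRS
        # on every draw, so rejection sampling can never terminate.
        spec = SyntheticCohortSpec(qrs_mean_yes=290.0, qrs_sd_yes=1e-6,
                                   qtc_mean_yes=210.0, qtc_sd_yes=1e-6,
                                   hr_mean=60.0, hr_sd=1e-6)
        with pytest.raises(RuntimeError, match="rejection"):
            generate_cohort(spec, 1)

    def test_invalid_spec_fields(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n_yes=-1)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(qrs_sd_yes=-2)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(label_model="tree")

    def test_spec_json_round_trip(self, tmp_path):
        spec = SyntheticCohortSpec(n_yes=12, hr_sd=10.0, label_model="logistic")
        path = tmp_path / "spec.json"
        spec.to_json(path)
        assert SyntheticCohortSpec.from_json(path) == spec


class TestCalibration:
    def test_effect_size_detected_in_at_least_95pct_of_seeds(self):
        # at the case-series effect size (pooled d ~ 2.4), n = 7 vs 9 has
        # near-total power
        spec = SyntheticCohortSpec()
        hits = 0
        for seed in range(200):
            cohort = generate_cohort(spec, seed)
            yes, no = cohort.split_by_outcome()
            _, _, p = pooled_t_test(yes.values("ratio"), no.values("ratio"))
            hits += p < 0.05
        assert hits >= 190

    def test_null_p_values_are_uniform(self):
        # type-I calibration of the whole generate -> t-test pipeline
        spec = null_spec()
        pvals = []
        for seed in range(2000):
            cohort = generate_cohort(spec, seed)
            yes, no = cohort.split_by_outcome()
            _, _, p = pooled_t_test(yes.values("ratio"), no.values("ratio"))
            pvals.append(p)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        rate = np.mean(np.asarray(pvals) < 0.05)
        # 99% binomial band around alpha = 0.05 at n = 2000
        assert 0.037 <= rate <= 0.063


class TestRecovery:
    def test_recovered_means_within_3_se_at_n_500(self):
        spec = SyntheticCohortSpec(n_yes=500, n_no=500)
        rec = recover_parameters(generate_cohort(spec, 7))
        checks = [
            ("yes", "qtc_ms", spec.qtc_mean_yes, spec.qtc_sd_yes),
            ("yes", "qrs_ms", spec.qrs_mean_yes, spec.qrs_sd_yes),
            ("no", "qtc_ms", spec.qtc_mean_no, spec.qtc_sd_no),
            ("no", "qrs_ms", spec.qrs_mean_no, spec.qrs_sd_no),
        ]
        for group, var, mean, sd in checks:
            se = sd / np.sqrt(500)
            assert abs(rec[group][var].mean - mean) < 3 * se, (group, var)

    def test_recovered_sds_within_5pct_at_n_1e4(self):
        spec = SyntheticCohortSpec(n_yes=10_000, n_no=10_000)
        rec = recover_parameters(generate_cohort(spec, 21))
        assert rec["yes"]["qtc_ms"].sd == pytest.approx(spec.qtc_sd_yes, rel=0.05)
        assert rec["no"]["qrs_ms"].sd == pytest.approx(spec.qrs_sd_no, rel=0.05)

    def test_fixture_recovery_reproduces_printed_descriptives(self, cohort):
        rec = recover_parameters(cohort)
        assert rec["yes"]["qtc_ms"].mean == pytest.approx(606, abs=0.5)
        assert rec["yes"]["qtc_ms"].sd == pytest.approx(78, abs=0.5)
        assert rec["no"]["qrs_ms"].mean == pytest.approx(122, abs=0.5)
        assert rec["no"]["hr_bpm"].sd == pytest.approx(25, abs=0.5)

    def test_small_group_rejected(self):
        cohort = generate_cohort(SyntheticCohortSpec(n_yes=2, n_no=9), 1)
        with pytest.raises(ValueError):
            recover_parameters(cohort)


class TestPower:
    def test_power_above_95pct_at_case_series_sizes(self):
        power = power_simulation(SyntheticCohortSpec(), 7, 9, reps=1000, seed=11)
        assert power > 0.95

    def test_null_power_matches_alpha(self):
        power = power_simulation(null_spec(), 7, 9, alpha=0.05, reps=1000, seed=13)
        # 99% binomial band around 0.05 at 1000 reps
        assert 0.032 <= power <= 0.068

    def test_alpha_zero_gives_zero_power(self):
        assert power_simulation(SyntheticCohortSpec(), 7, 9, alpha=0.0,
                                reps=100, seed=1) == 0.0

    def test_reproducible_under_fixed_seed(self):
        a = power_simulation(SyntheticCohortSpec(), 7, 9, reps=100, seed=5)
        b = power_simulation(SyntheticCohortSpec(), 7, 9, reps=100, seed=5)
        assert a == b

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(SyntheticCohortSpec(), 7, 9, reps=50, seed=1)
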