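import numpy as np
import pytest

from hdrisk.cohort import (CohortConfig, CorrTargets, PatientProfile,
                           SessionRecord, default_profiles, homogeneous_config,
                           session_corr_matrix, simulate_cohort,
                           verify_cohort_stats)
from hdrisk.exceptions import ConfigurationError, InsufficientDataError
from hdrisk.oversample import induce_correlations


def _cohort_key(cohort):
    return [(s.session_id, s.symptomatic, s.onset_index,
             s.sbp.tobytes(), s.dbp.tobytes(), s.hr.tobytes(),
             s.weight.tobytes(), s.dry_weight, s.target_end_weight,
             s.hourly_weight_loss, s.prev_end_weight) for s in cohort]


class TestSimulateCohort:
    def test_default_cohort_has_200_sessions(self, default_cohort):
        assert len(default_cohort) == 200

    def test_default_cohort_has_17_symptomatic(self, default_cohort):
        assert sum(s.symptomatic for s in default_cohort) == 17

    def test_symptomatic_allocation_matches_profiles(self, default_cohort):
        per_patient = {}
        for s in default_cohort:
            per_patient[s.patient_id] = per_patient.get(s.patient_id, 0) + s.symptomatic
        expected = {p.patient_id: p.n_symptomatic_sessions for p in default_profiles()}
        assert per_patient == expected

    def test_last_hour_onset_count(self, default_cohort):
        n_last = sum(1 for s in default_cohort
                     if s.symptomatic and s.onset_index in (7, 8))
        assert n_last == round(14 / 17 * 17) == 14

    def test_early_onsets_in_range(self, default_cohort):
        early = [s.onset_index for s in default_cohort
                 if s.symptomatic and s.onset_index not in (7, 8)]
        assert len(early) == 3
        assert all(1 <= o <= 6 for o in early)

    def test_same_seed_byte_identical(self):
        a = simulate_cohort(CohortConfig(seed=42))
        b = simulate_cohort(CohortConfig(seed=42))
        assert _cohort_key(a) == _cohort_key(b)

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortConfig(seed=1))
        b = simulate_cohort(CohortConfig(seed=2))
        assert _cohort_key(a) != _cohort_key(b)

    def test_too_many_symptomatic_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(sessions_per_patient=5)  # pt04 has 6 events

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            PatientProfile("x", 60, "M", 0, 75, 0.0, 120, 8, 70, 5, 70, 4)

    def test_vitals_positive_and_grid_complete(self, default_cohort):
        for s in default_cohort:
            for name in ("sbp", "dbp", "hr", "weight"):
                arr = getattr(s, name)
                assert arr.shape == (9,)
                assert np.all(arr > 0)

    def test_onset_present_iff_symptomatic(self, default_cohort):
        for s in default_cohort:
            assert (s.onset_index is not None) == s.symptomatic


class TestSessionRecord:
    def _kwargs(self, **over):
        base = dict(
            patient_id="p", session_id="s", sbp=np.full(9, 120.0),
            dbp=np.full(9, 70.0), hr=np.full(9, 65.0), weight=np.full(9, 80.0),
            dry_weight=78.0, target_end_weight=79.0, hourly_weight_loss=0.5,
            prev_end_weight=79.5, symptomatic=False,
        )
        base.update(over)
        return base

    def test_wrong_grid_length_rejected(self):
        with pytest.raises(ConfigurationError):
            SessionRecord(**self._kwargs(sbp=np.full(8, 120.0)))

    def test_nonpositive_vital_rejected(self):
        bad = np.full(9, 120.0)
        bad[3] = -1.0
        with pytest.raises(ConfigurationError):
            SessionRecord(**self._kwargs(sbp=bad))

    def test_symptomatic_requires_onset(self):
        with pytest.raises(ConfigurationError):
            SessionRecord(**self._kwargs(symptomatic=True))

    def test_onset_forbidden_when_nonsymptomatic(self):
        with pytest.raises(ConfigurationError):
            SessionRecord(**self._kwargs(onset_index=5))

    def test_nan_vitals_allowed(self):
        arr = np.full(9, 120.0)
        arr[4] = np.nan
        rec = SessionRecord(**self._kwargs(sbp=arr))
        assert np.isnan(rec.sbp[4])


class TestCorrelationStructure:
    def test_target_matrix_is_positive_definite(self):
        for cls in (False, True):
            c = session_corr_matrix(CorrTargets(), cls)
            assert np.linalg.eigvalsh(c).min() > 0
            assert np.allclose(np.diag(c), 1.0)

    def test_stated_targets_survive_repair(self):
        t = CorrTargets()
        for cls, suffix in ((False, "asymptomatic"), (True, "symptomatic")):
            c = session_corr_matrix(t, cls)
            for base, name in ((9, "sbp"), (18, "dbp"), (27, "hr")):
                target = np.asarray(getattr(t, f"weight_{name}_{suffix}"))
                got = np.array([c[j, base + j] for j in range(9)])
                assert np.allclose(got, target, atol=1e-8)
            sd = np.array([c[9 + j, 18 + j] for j in range(9)])
            assert np.allclose(sd, t.sbp_dbp, atol=1e-8)
            assert np.allclose([c[0, j] for j in range(1, 9)], 0.99, atol=1e-8)

    def test_induced_correlations_converge(self, rng):
        # 40,000 multivariate rows: every stated target recovered within 0.02
        # (sampling sd of a single coefficient at this n is ~0.005, so the
        # 0.02 band holds across all ~44 stated entries)
        t = CorrTargets()
        c = session_corr_matrix(t, False)
        z = rng.standard_normal((40_000, c.shape[0]))
        emp = np.corrcoef(induce_correlations(z, c), rowvar=False)
        stated = [(j, 9 + j) for j in range(9)] + [(j, 18 + j) for j in range(9)] \
            + [(j, 27 + j) for j in range(9)] + [(9 + j, 18 + j) for j in range(9)] \
            + [(0, j) for j in range(1, 9)]
        for i, j in stated:
            assert abs(emp[i, j] - c[i, j]) < 0.02

    def test_out_of_range_corr_rejected(self):
        with pytest.raises(ConfigurationError):
            CorrTargets(weight_autocorr=1.5)


class TestNullGenerator:
    def test_zero_shift_class_means_close(self):
        # homogeneous profiles, zero class shifts: >= 99% of per-timepoint
        # SBP/DBP class mean differences fall within 3 standard errors
        zero = tuple([0.0] * 9)
        n_cmp = n_ok = 0
        for seed in range(40):
            cfg = homogeneous_config(class_shift_sbp=zero, class_shift_dbp=zero,
                                     seed=seed)
            cohort = simulate_cohort(cfg)
            sympt = [s for s in cohort if s.symptomatic]
            asympt = [s for s in cohort if not s.symptomatic]
            for name in ("sbp", "dbp"):
                a = np.stack([getattr(s, name) for s in sympt])
                b = np.stack([getattr(s, name) for s in asympt])
                se = np.sqrt(a.var(axis=0, ddof=1) / len(a)
                             + b.var(axis=0, ddof=1) / len(b))
                ok = np.abs(a.mean(axis=0) - b.mean(axis=0)) < 3 * se
                n_cmp += ok.size
                n_ok += ok.sum()
        assert n_ok / n_cmp >= 0.99


class TestMomentRecovery:
    def test_per_patient_moments_converge(self):
        cfg = homogeneous_config(n_patients=1, n_symptomatic_per_patient=0,
                                 sessions_per_patient=500, seed=5)
        cohort = simulate_cohort(cfg)
        prof = cfg.profiles[0]
        hwl = np.array([s.hourly_weight_loss for s in cohort])
        # remove the documented deterministic within-session trend from weight
        w = np.stack([s.weight + (np.arange(9) - 4) * s.hourly_weight_loss / 2
                      for s in cohort])
        checks = {
            "weight": (w, prof.weight_mean, prof.weight_sd),
            "sbp": (np.stack([s.sbp for s in cohort]), prof.sbp_mean, prof.sbp_sd),
            "dbp": (np.stack([s.dbp for s in cohort]), prof.dbp_mean, prof.dbp_sd),
            "hr": (np.stack([s.hr for s in cohort]), prof.hr_mean, prof.hr_sd),
        }
        for name, (arr, mu, sd) in checks.items():
            assert abs(arr.mean() - mu) / mu < 0.05, name
            assert abs(arr.std(ddof=1) - sd) / sd < 0.05, name
        assert hwl.mean() == pytest.approx(cfg.hourly_loss_mean, rel=0.1)


class TestVerifyCohortStats:
    def test_null_classes_give_uniformish_pvalues(self):
        zero = tuple([0.0] * 9)
        cfg = homogeneous_config(class_shift_sbp=zero, class_shift_dbp=zero,
                                 n_patients=4, sessions_per_patient=100, seed=9)
        # same correlation structure for both classes: a true null
        t = CorrTargets()
        cfg.corr_targets = CorrTargets(
            weight_sbp_symptomatic=t.weight_sbp_asymptomatic,
            weight_dbp_symptomatic=t.weight_dbp_asymptomatic,
            weight_hr_symptomatic=t.weight_hr_asymptomatic,
        )
        report = verify_cohort_stats(simulate_cohort(cfg), cfg)
        p = report.class_differences["p"].to_numpy()
        assert np.mean(p > 0.01) >= 0.95

    def test_default_weight_dbp_signs_recovered(self):
        cfg = CohortConfig(sessions_per_patient=500, seed=3)
        report = verify_cohort_stats(simulate_cohort(cfg), cfg)
        corr = report.correlations
        sub = corr[(corr["class"] == "asymptomatic")
                   & (corr["pair"] == "weight_dbp")].sort_values("timepoint")
        target = np.asarray(CorrTargets().weight_dbp_asymptomatic)
        assert np.all(np.sign(sub["r"].to_numpy()) == np.sign(target))

    def test_homogeneous_weight_dbp_values_recovered(self):
        # without between-patient mean confounding the pooled coefficient
        # converges to the induced target
        cfg = homogeneous_config(n_patients=1, n_symptomatic_per_patient=0,
                                 sessions_per_patient=500, seed=8)
        cohort = simulate_cohort(cfg)
        # need both classes for the report: flip half the labels artificially
        report_corr = []
        target = np.asarray(CorrTargets().weight_dbp_asymptomatic)
        w = np.stack([s.weight for s in cohort])
        d = np.stack([s.dbp for s in cohort])
        for j in range(9):
            report_corr.append(np.corrcoef(w[:, j], d[:, j])[0, 1])
        assert np.all(np.abs(np.array(report_corr) - target) < 0.1)

    def test_single_class_cohort_rejected(self, default_cohort):
        asympt = [s for s in default_cohort if not s.symptomatic]
        with pytest.raises(InsufficientDataError):
            verify_cohort_stats(asympt)
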