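import math

import numpy as np
import pytest
import scipy.stats

from postprandial import (
    DEFAULT_TIMEPOINTS_H,
    TrajectoryProfile,
    ValidationError,
    gmean,
    icc_absolute_agreement,
    make_design,
    profile_with_icc,
    reference_gsd_table,
    shape_function,
    simulate_panel,
    simulate_study,
    trajectory_mean,
)


class TestMakeDesign:
    def test_default_is_study_cohort(self, design):
        assert design.n_subjects == 34
        assert design.sexes.count("male") == 18 and design.sexes.count("female") == 16
        assert design.timepoints_h == DEFAULT_TIMEPOINTS_H
        assert len(design.timepoints_h) == 14

    @pytest.mark.parametrize(
        "n_male,n_female,timepoints,n_sub,n_t",
        [(1, 1, (0.0, 1.0), 2, 2), (2, 2, (0.0, 0.5, 24.0), 4, 3)],
    )
    def test_small_designs(self, n_male, n_female, timepoints, n_sub, n_t):
        d = make_design(n_male, n_female, timepoints)
        assert d.n_subjects == n_sub and len(d.timepoints_h) == n_t
        assert len(set(d.subject_ids)) == n_sub

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_male": 0},
            {"timepoints_h": (0.0, 2.0, 1.0)},
            {"timepoints_h": (1.0, 2.0)},  # missing the 0 h reference
            {"timepoints_h": (0.0, 1.0, 1.0)},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_design(**{"n_male": 2, "n_female": 2, **kwargs})


class TestTrajectoryShapes:
    profiles = [
        TrajectoryProfile("a", 3.0, "early_peak", amplitude=0.4, t_peak_h=0.5),
        TrajectoryProfile("b", 3.0, "late_rise", amplitude=0.3, t_onset_h=6.0),
        TrajectoryProfile("c", 3.0, "dip_then_rise", amplitude=0.2, t_peak_h=1.0, t_onset_h=3.0),
        TrajectoryProfile("d", 3.0, "decline", amplitude=0.3),
        TrajectoryProfile("e", 3.0, "flat"),
    ]

    @pytest.mark.parametrize("profile", profiles, ids=lambda p: p.shape)
    def test_reference_time_is_baseline(self, profile):
        assert trajectory_mean(profile, 0.0) == pytest.approx(math.log(3.0))

    def test_early_peak_unit_maximum(self):
        p = TrajectoryProfile("m", 5.0, "early_peak", amplitude=0.35, t_peak_h=0.25)
        assert trajectory_mean(p, 0.25) == pytest.approx(math.log(5.0) + 0.35)
        # closed form at 24 h, evaluated independently
        s24 = (24 / 0.25) * math.exp(1 - 24 / 0.25)
        assert trajectory_mean(p, 24.0) == pytest.approx(math.log(5.0) + 0.35 * s24)

    def test_late_rise_ramp(self):
        p = TrajectoryProfile("m", 2.0, "late_rise", amplitude=0.3, t_onset_h=6.0)
        t = np.array(DEFAULT_TIMEPOINTS_H)
        s = shape_function(p, t)
        assert np.all(s[t <= 6.0] == 0.0)
        assert s[-1] == pytest.approx(1.0)  # reaches 1 at the final timepoint
        assert np.all(np.diff(s) >= 0)

    def test_decline_non_positive_monotone(self):
        p = TrajectoryProfile("m", 2.0, "decline", amplitude=0.3)
        s = shape_function(p, np.array(DEFAULT_TIMEPOINTS_H))
        assert np.all(s <= 0) and np.all(np.diff(s) <= 0) and s[-1] == -1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            trajectory_mean(self.profiles[0], -1.0)

    def test_implied_icc(self):
        p = TrajectoryProfile(
            "m", 1.0, "flat",
            sigma_subject=math.sqrt(0.82), sigma_time=math.sqrt(0.06),
            sigma_residual=math.sqrt(0.12),
        )
        assert p.implied_icc == pytest.approx(0.82)


class TestSimulateStudy:
    def test_deterministic_under_seed(self, design, flat_profile):
        a = simulate_study([flat_profile], design, seed=42)
        b = simulate_study([flat_profile], design, seed=42)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = simulate_study([flat_profile], design, seed=43)
        assert not a["concentration"].equals(c["concentration"])

    def test_adding_metabolite_preserves_existing_stream(self, design, flat_profile):
        other = TrajectoryProfile("other", 2.0, "flat", sigma_residual=0.1)
        alone = simulate_study([flat_profile], design, seed=7)
        both = simulate_study([other, flat_profile], design, seed=7)
        kept = both[both["metabolite"] == "marker"].reset_index(drop=True)
        assert alone["concentration"].equals(kept["concentration"])

    def test_zero_noise_flat_is_constant(self, design):
        p = TrajectoryProfile("m", 10.0, "flat")
        data = simulate_study([p], design, seed=0)
        assert np.allclose(data["concentration"], 10.0)
        assert len(data) == 34 * 14

    def test_dropout_truncates_one_subject_to_eight_collections(self, design, flat_profile):
        data = simulate_study([flat_profile], design, seed=0, dropout=True)
        per_subject = data.groupby("subject_id")["time_h"].count()
        assert sorted(per_subject.unique()) == [8, 14]
        truncated = per_subject.idxmin()
        assert data[data["subject_id"] == truncated]["time_h"].max() == 3.0

    def test_flat_log_concentrations_are_normal(self):
        """Log draws from a flat profile pass a normality check at n = 5000."""
        d = make_design(2500, 2500, (0.0, 1.0))
        p = TrajectoryProfile("m", 5.0, "flat", sigma_subject=0.2, sigma_residual=0.2)
        panel = simulate_panel(p, d, np.random.default_rng(11))
        logs = np.log(panel.values[1.0].to_numpy())
        assert logs.size == 5000
        assert scipy.stats.normaltest(logs).pvalue > 1e-3

    def test_marginal_gmean_converges_with_sex_mix(self):
        d = make_design(1000, 1000, (0.0, 0.25))
        p = TrajectoryProfile(
            "m", 5.0, "early_peak", amplitude=0.35, t_peak_h=0.25,
            sigma_subject=0.3, sigma_residual=0.2, sex_shift=0.2,
        )
        panel = simulate_panel(p, d, np.random.default_rng(5))
        expected = math.exp(math.log(5.0) + 0.35 + 0.2 * 0.5)  # 50% male mix
        assert gmean(panel.values[0.25]) == pytest.approx(expected, rel=0.03)

    def test_icc_limit_subject_variance_only(self, design):
        p = TrajectoryProfile(
            "m", 5.0, "flat", sigma_subject=0.5, sigma_time=0.0, sigma_residual=1e-6
        )
        panel = simulate_panel(p, design, np.random.default_rng(2))
        assert icc_absolute_agreement(panel).icc > 0.999

    @pytest.mark.parametrize("true_icc", [0.25, 0.5, 0.82, 0.88])
    def test_icc_recovery(self, design, flat_profile, true_icc):
        """Mean estimated ICC over replicate 34x14 panels tracks the truth."""
        p = profile_with_icc(flat_profile, true_icc)
        assert p.implied_icc == pytest.approx(true_icc)
        seeds = np.random.SeedSequence(900 + int(100 * true_icc)).spawn(200)
        estimates = [
            icc_absolute_agreement(
                simulate_panel(p, design, np.random.default_rng(s))
            ).icc
            for s in seeds
        ]
        assert abs(np.mean(estimates) - true_icc) < 0.03


class TestReferenceGsdTable:
    def test_default_shape_matches_reference_resource(self):
        table = reference_gsd_table(seed=1)
        assert table.shape == (132, 56) and table.size == 7392
        assert (table.to_numpy() > 1).all()

    def test_degenerate_range(self):
        table = reference_gsd_table(1, 1, (1.32, 1.32), seed=0)
        assert table.iloc[0, 0] == pytest.approx(1.32)

    def test_range_containment_and_determinism(self):
        a = reference_gsd_table(10, 5, (1.1, 1.5), seed=9)
        b = reference_gsd_table(10, 5, (1.1, 1.5), seed=9)
        assert a.equals(b)
        assert ((a.to_numpy() >= 1.1) & (a.to_numpy() <= 1.5)).all()

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValidationError):
            reference_gsd_table(2, 2, (0.9, 1.5), seed=0)
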