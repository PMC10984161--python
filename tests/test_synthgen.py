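"""Generator behaviour: determinism, schedule structure, calibration."""

import dataclasses

import numpy as np
import pytest

from judoba.accelio import summarize_trace
from judoba.synthgen import (
    generate_cohort,
    generate_contest_trace,
    generate_physiology,
    sample_effort_pause_schedule,
    truncnorm_mean,
)
from judoba.types import RPE_MAX, ConfigurationError, ContestDesign

from conftest import make_spec


class TestSchedule:
    def test_length_conservation(self, default_design, rng):
        labels = sample_effort_pause_schedule(default_design, rng)
        assert len(labels) == 100  # 300 s / 3 s epochs
        assert set(labels) <= {"effort", "break"}

    def test_deterministic_tiling_when_bout_fixed(self, rng):
        design = ContestDesign(effort_min_s=30, effort_max_s=30)
        labels = sample_effort_pause_schedule(design, rng)
        # 30 s effort (10 epochs) then 10 s break (3 or 4 epochs -> 3)
        cycle = ["effort"] * 10 + ["break"] * 3
        expected = (cycle * 10)[:100]
        assert list(labels) == expected

    def test_mean_bout_length_matches_uniform_oracle(self, default_design):
        # complete (untruncated) bouts should average 25 s for U(20, 30)
        rng = np.random.default_rng(99)
        lengths = []
        for _ in range(10_000):
            labels = sample_effort_pause_schedule(default_design, rng)
            runs = np.split(
                np.arange(len(labels)),
                np.flatnonzero(np.diff(labels != "effort")) + 1,
            )
            bouts = [r for r in runs if labels[r[0]] == "effort"]
            if labels[-1] == "effort":  # final bout truncated by contest end
                bouts = bouts[:-1]
            lengths.extend(len(b) * default_design.epoch_seconds for b in bouts)
        assert abs(np.mean(lengths) - 25.0) < 0.5

    def test_infeasible_design_rejected(self, rng):
        design = ContestDesign(effort_min_s=400, effort_max_s=500)
        with pytest.raises(ConfigurationError, match="effort_min_s"):
            sample_effort_pause_schedule(design, rng)


class TestPhysiology:
    def test_zero_sd_returns_means_exactly(self, rng):
        spec = make_spec(hr_sd=0, bla_sd=0, rpe_sd=0, age_sd=0)
        rec = generate_physiology(spec, rng)
        assert (rec.hr_max_contest, rec.bla, rec.rpe, rec.age) == (
            spec.hr_mean, spec.bla_mean, spec.rpe_mean, spec.age_mean,
        )

    def test_rpe_clamped_to_borg_scale(self, rng):
        spec = dataclasses.replace(make_spec(), rpe_mean=25.0)  # bypass validate
        draws = [generate_physiology(spec, rng).rpe for _ in range(200)]
        assert max(draws) <= RPE_MAX

    def test_sample_mean_matches_truncation_corrected_oracle(self):
        # heavy-weight female HR targets; truncation at 0 is negligible so
        # the truncated-normal mean is the right oracle either way
        spec = make_spec(hr_mean=182.0, hr_sd=5.0)
        rng = np.random.default_rng(4)
        draws = np.array(
            [generate_physiology(spec, rng).hr_max_contest for _ in range(10_000)]
        )
        expected = truncnorm_mean(182.0, 5.0, lower=0.0)
        assert abs(draws.mean() - expected) < 0.2

    def test_pct_hrmax_uses_age_prediction(self, rng):
        rec = generate_physiology(make_spec(), rng)
        assert rec.hr_max_predicted == pytest.approx(208 - 0.7 * rec.age)
        assert rec.pct_hrmax == pytest.approx(
            100 * rec.hr_max_contest / (208 - 0.7 * rec.age)
        )


class TestCohort:
    def test_same_seed_bit_identical(self, default_design):
        specs = [make_spec(n_athletes=3)]
        a = generate_cohort(specs, default_design, seed=11)
        b = generate_cohort(specs, default_design, seed=11)
        for (pa, ta, fa), (pb, tb, fb) in zip(a, b):
            assert pa == pb and fa == fb
            assert np.array_equal(ta.counts, tb.counts)
            assert np.array_equal(ta.t_start, tb.t_start)

    def test_adding_athletes_does_not_perturb_existing(self, default_design):
        small = generate_cohort([make_spec(n_athletes=3)], default_design, seed=11)
        large = generate_cohort([make_spec(n_athletes=5)], default_design, seed=11)
        for (_, ta, _), (_, tb, _) in zip(small, large):
            assert np.array_equal(ta.counts, tb.counts)

    def test_degenerate_noise_recovers_vm_mean(self):
        # no between-athlete spread and no effort/break contrast: every
        # contest VM equals the target up to count discretisation
        design = ContestDesign(break_intensity_fraction=1.0)
        spec = make_spec(vm_sd=0, axis_share_sds=(0, 0, 0))
        cohort = generate_cohort([spec], design, seed=2)
        for _, trace, _ in cohort:
            s = summarize_trace(trace)
            assert s.vm_cpm == pytest.approx(spec.vm_mean, rel=1e-3)

    def test_break_epochs_quieter_than_effort(self, default_design):
        cohort = generate_cohort([make_spec(n_athletes=2)], default_design, seed=3)
        for _, trace, _ in cohort:
            vm = np.sqrt((trace.counts.astype(float) ** 2).sum(axis=1))
            eff = vm[trace.phase_labels == "effort"].mean()
            brk = vm[trace.phase_labels == "break"].mean()
            assert brk < eff

    def test_calibration_recovery_at_n200(self, default_design):
        # law-of-large-numbers check against the configured cell targets
        spec = make_spec(n_athletes=200)
        cohort = generate_cohort([spec], default_design, seed=5)
        sums = [summarize_trace(t) for _, t, _ in cohort]
        vm = np.mean([s.vm_cpm for s in sums])
        shares = np.mean([s.axis_pct for s in sums], axis=0)
        assert abs(vm - spec.vm_mean) / spec.vm_mean < 0.02
        for got, want in zip(shares, spec.axis_share_means):
            assert abs(got - want) < 1.0

    @pytest.mark.parametrize(
        "overrides, field",
        [
            (dict(vm_sd=-1), "vm_sd"),
            (dict(axis_share_means=(50.0, 30.0, 30.0)), "axis_share_means"),
            (dict(n_athletes=1), "n_athletes"),
            (dict(rpe_mean=25.0), "rpe_mean"),
        ],
    )
    def test_invalid_spec_names_field(self, default_design, overrides, field):
        spec = dataclasses.replace(make_spec(), **overrides)
        with pytest.raises(ConfigurationError, match=field):
            generate_cohort([spec], default_design, seed=1)

    def test_seed_required(self, default_design):
        with pytest.raises(ConfigurationError, match="seed"):
            generate_cohort([make_spec()], default_design, seed=None)


def test_trace_shares_follow_drawn_composition(default_design):
    rng = np.random.default_rng(8)
    trace = generate_contest_trace("x", 9000.0, [0.5, 0.3, 0.2], default_design, rng)
    s = summarize_trace(trace)
    assert abs(s.axis_pct[0] - 50) < 2 and abs(s.axis_pct[2] - 20) < 2
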