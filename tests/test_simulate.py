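"""Synthetic cohort generator: determinism, scaling, structure."""

import numpy as np
import pandas as pd
import pytest

from ctsib_sway import (
    CohortConfig,
    Condition,
    SwaySimConfig,
    simulate_cohort,
    simulate_participant,
    simulate_pbs,
    simulate_trace,
    spearman_correlation,
    write_fixture,
)
from ctsib_sway.errors import InputError, ParameterError, StabilityError
from ctsib_sway.simulate import (
    cohort_index_table,
    pbs_items_from_total,
    simulate_condition_paths,
)
from ctsib_sway.traces import path_length_cm


class TestSimulateTrace:
    def test_zero_noise_gives_constant_zero_trace(self):
        cfg = SwaySimConfig(baseline_sigma_cm=0.0)
        tr = simulate_trace(cfg, Condition.C1, 1.0, seed=1)
        assert path_length_cm(tr.ap_cm) == 0.0

    def test_same_seed_is_bitwise_identical(self):
        cfg = SwaySimConfig()
        a = simulate_trace(cfg, Condition.C3, 1.2, seed=99)
        b = simulate_trace(cfg, Condition.C3, 1.2, seed=99)
        np.testing.assert_array_equal(a.ap_cm, b.ap_cm)

    def test_expected_length_and_rate(self):
        tr = simulate_trace(SwaySimConfig(), Condition.C1, 1.0, seed=0)
        assert tr.n_samples == 500  # 25 Hz x 20 s
        assert tr.sampling_rate_hz == 25.0

    def test_unstable_recursion_rejected(self):
        cfg = SwaySimConfig(reversion_rate_per_s=30.0, sampling_rate_hz=25.0)
        with pytest.raises(StabilityError):
            simulate_trace(cfg, Condition.C1, 1.0, seed=0)

    def test_doubling_sigma_doubles_mean_path_length(self):
        cfg1 = SwaySimConfig(baseline_sigma_cm=0.05)
        cfg2 = SwaySimConfig(baseline_sigma_cm=0.10)
        p1 = simulate_condition_paths(cfg1, Condition.C1, 500, seed=11)
        p2 = simulate_condition_paths(cfg2, Condition.C1, 500, seed=12)
        assert p2.mean() / p1.mean() == pytest.approx(2.0, rel=0.03)


class TestSimulateParticipant:
    def test_exactly_36_traces(self):
        traces, scales, sway = simulate_participant(
            SwaySimConfig(), CohortConfig(), "P01", 0, root_seed=5
        )
        assert len(traces) == 36  # 2 markers x 6 conditions x 3 trials
        assert len(sway) == 36
        assert set(scales) == {*scales}  # both markers present
        assert all(s > 0 for s in scales.values())

    def test_zero_marker_noise_gives_near_perfect_agreement(self):
        # without marker-specific condition deviations, both markers
        # share the same latent condition response; only trial noise
        # keeps cross-marker index agreement below 1
        cohort = simulate_cohort(
            SwaySimConfig(), CohortConfig(n_participants=27, marker_noise_sd_log=0.0, seed=17)
        )
        idx = cohort_index_table(cohort.sway)
        wide = idx.pivot(index="participant_id", columns="marker", values="vest")
        res = spearman_correlation(
            wide["lateral_malleolus"].to_numpy(), wide["mastoid_process"].to_numpy()
        )
        assert res.rho > 0.9


class TestCohortStructure:
    def test_identical_multipliers_give_unit_indexes(self):
        # null generator: every condition has the same noise scale and
        # latent heterogeneity is off, so all four ratio indexes
        # concentrate around 1 up to trial noise
        cfg = SwaySimConfig(
            condition_multipliers={c: 1.0 for c in Condition}, condition_sd_log=0.0
        )
        cohort = simulate_cohort(cfg, CohortConfig(n_participants=20, marker_noise_sd_log=0.0, seed=3))
        idx = cohort_index_table(cohort.sway)
        for name in ("som", "vis", "vest", "vp"):
            assert idx[name].median() == pytest.approx(1.0, abs=0.05)

    def test_cohort_reproducible_from_seed(self):
        a = simulate_cohort(SwaySimConfig(), CohortConfig(n_participants=4, seed=11))
        b = simulate_cohort(SwaySimConfig(), CohortConfig(n_participants=4, seed=11))
        pd.testing.assert_frame_equal(a.sway, b.sway)
        pd.testing.assert_frame_equal(a.pbs, b.pbs)

    def test_cross_marker_agreement_positive(self, default_index_table):
        wide = default_index_table.pivot(
            index="participant_id", columns="marker", values="vest"
        )
        res = spearman_correlation(
            wide["lateral_malleolus"].to_numpy(), wide["mastoid_process"].to_numpy()
        )
        assert res.rho > 0


class TestMultiplierRecovery:
    def test_pairwise_ratio_recovers_multipliers(self):
        # median of paired path-length ratios converges to the
        # multiplier ratio; 500 trials should land within 5%
        cfg = SwaySimConfig()
        m = cfg.condition_multipliers
        pa = simulate_condition_paths(cfg, Condition.C2, 500, seed=21)
        pb = simulate_condition_paths(cfg, Condition.C1, 500, seed=22)
        est = float(np.median(pa / pb))
        assert est == pytest.approx(m[Condition.C2] / m[Condition.C1], rel=0.05)


class TestSimulatePbs:
    def test_zero_noise_negative_slope_gives_perfect_negative_spearman(self):
        vest = np.random.default_rng(1).uniform(0.5, 5.0, size=27)
        totals = simulate_pbs(
            CohortConfig(pbs_sd=5.0, pbs_vest_rho_target=-0.999999, pbs_mean=28.0), vest, seed=2
        )
        # noise sd ~ pbs_sd*sqrt(1-rho^2) ~ 0: monotone decreasing in vest
        assert spearman_correlation(vest, totals).rho == pytest.approx(-1.0)

    def test_rho_target_at_least_one_rejected(self):
        with pytest.raises(ParameterError):
            CohortConfig(pbs_vest_rho_target=1.0)

    def test_totals_clamped_to_scale_range(self, caplog):
        vest = np.linspace(0.5, 5.0, 27)
        cfg = CohortConfig(pbs_mean=55.0, pbs_sd=10.0, pbs_vest_rho_target=-0.2)
        with caplog.at_level("WARNING"):
            totals = simulate_pbs(cfg, vest, seed=4)
        assert totals.min() >= 0.0 and totals.max() <= 56.0


class TestPbsItemDecomposition:
    @pytest.mark.parametrize("total", [0.0, 56.0, 50.44, 1 / 3, 55.9, 23.7])
    def test_records_score_to_quantized_total(self, total):
        from ctsib_sway import score_pbs

        items = pbs_items_from_total(total)
        expected = round(min(max(total, 0.0), 56.0) * 3) / 3
        assert score_pbs(items).total == pytest.approx(expected, abs=1e-9)


class TestWriteFixture:
    def test_manifest_has_one_row_per_trace(self, small_fixture_dir):
        d, cohort = small_fixture_dir
        manifest = pd.read_csv(d / "manifest.csv")
        assert len(manifest) == 108  # 3 participants x 36 traces
        assert all((d / f).exists() for f in manifest["file"])

    def test_round_trip_reproduces_sway_scalars(self, small_fixture_dir):
        from ctsib_sway import compute_sway, read_trace_csv, trim_trace

        d, cohort = small_fixture_dir
        manifest = pd.read_csv(d / "manifest.csv")
        mem = cohort.sway.set_index(
            ["participant_id", "marker", "condition", "trial_number"]
        )["sway_cm"]
        for rec in manifest.sample(12, random_state=0).to_dict("records"):
            tr = trim_trace(read_trace_csv(d / rec["file"], rec))
            key = (rec["participant_id"], rec["marker"], rec["condition"], rec["trial_number"])
            assert compute_sway(tr).value_cm == pytest.approx(mem.loc[key], abs=1e-12)

    def test_empty_cohort_rejected(self, tmp_path, default_cohort):
        with pytest.raises(InputError):
            write_fixture(default_cohort, tmp_path)  # simulated without traces
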