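"""Trial measures, %-scores, trimming and condition means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from liftforce import (
    ExtractionConfig,
    ForceTrace,
    HEAVY_CUBE,
    LIGHT_CUBE,
    InvalidArgumentError,
    MissingCellError,
    SimulationConfig,
    condition_means,
    extract_measures,
    percent_scores,
    platform_reduction,
    simulate_trial,
    trim_outliers,
)

FS = 400.0


def noise_free_config(**kwargs) -> SimulationConfig:
    base = dict(
        noise_sd=0.0, participant_sd=0.0, trial_jitter_sd=0.0, rating_noise_sd=0.0
    )
    base.update(kwargs)
    return SimulationConfig(**base)


def make_trace(load, platform, gate, fs=FS) -> ForceTrace:
    load = np.asarray(load, dtype=float)
    return ForceTrace(fs, 0.5 * load, load / 2.0, np.asarray(platform, float), gate)


class TestPlatformReduction:
    def test_reduction_is_zero_at_rest_and_weight_after_a_full_lift(self):
        cfg = noise_free_config()
        trace = simulate_trial(HEAVY_CUBE, 518.0, cfg, np.random.default_rng(0))
        red = platform_reduction(trace)
        n_rest = int(0.2 * FS)
        # the zero-phase filter leaks ~1e-5 N of the upcoming ramp into the
        # late rest samples; anything far below the 0.4 N threshold is rest
        assert np.allclose(red[:n_rest], 0.0, atol=1e-3)
        assert red[-1] == pytest.approx(HEAVY_CUBE.weight_force, abs=1e-3)

    def test_noisy_reduction_matches_a_naive_loop(self, rng):
        cfg = SimulationConfig(noise_sd=0.05)
        trace = simulate_trial(HEAVY_CUBE, 518.0, cfg, rng)
        econf = ExtractionConfig()
        red = platform_reduction(trace, econf)
        from liftforce.signal import lowpass_zero_phase

        filtered = lowpass_zero_phase(trace.platform, FS, econf.filter)
        baseline = float(np.median(filtered[: int(round(econf.baseline_window * FS))]))
        expected = np.array([baseline - v for v in filtered])
        assert np.allclose(red, expected)

    def test_insufficient_baseline_samples_is_an_error(self):
        trace = make_trace(np.zeros(40), np.ones(40), np.zeros(40, dtype=bool))
        with pytest.raises(InvalidArgumentError):
            platform_reduction(trace, ExtractionConfig(baseline_window=0.5))


class TestExtractMeasures:
    def test_anticipated_heavy_lift_exceeds_its_weight_force(self):
        cfg = noise_free_config()
        trace = simulate_trial(HEAVY_CUBE, 518.0, cfg, np.random.default_rng(0))
        m = extract_measures(trace)
        assert m.PLF >= HEAVY_CUBE.weight_force
        assert m.LPD1 > 0

    def test_truncation_case_keeps_lf1st_but_loses_pf1st(self):
        # large overestimate of a light object: lift-off precedes the rate
        # peak, so the platform never records a first peak while the handle,
        # which records through the hold phase, still does
        cfg = noise_free_config()
        assert cfg.overshoot * 518.0 >= 2 * 125.0
        trace = simulate_trial(LIGHT_CUBE, 518.0, cfg, np.random.default_rng(0))
        m = extract_measures(trace)
        assert m.LF1st is not None
        assert m.PF1st is None
        assert "PF1st" in m.absent

    def test_missing_liftoff_keeps_handle_peaks_only(self):
        cfg = noise_free_config(trial_duration=1.0, correction_rate=1e-3)
        trace = simulate_trial(HEAVY_CUBE, 130.0, cfg, np.random.default_rng(0))
        assert not trace.lifted_off
        m = extract_measures(trace)
        assert m.PLF is not None and m.PLFR is not None
        assert m.LPD1 is None and m.LPD2 is None and m.PPFR is None
        assert "LPD1" in m.absent and "PPFR" in m.absent

    def test_triangular_ramp_load_phase_matches_the_closed_form(self):
        # 0 -> 6 N over 1 s after a 0.5 s rest: the 0.2 N and weight-force
        # crossings are straight-line arithmetic; filtering perturbs the
        # corners by less than ~10 ms.
        W = HEAVY_CUBE.weight_force
        slope = 6.0
        lead = 0.5
        t = np.arange(int(4 * FS)) / FS
        load = np.clip((t - lead) * slope, 0.0, 6.0)
        platform = np.maximum(W - load, 0.0)
        gate = load >= W
        platform[int(np.argmax(gate)) :] = 0.0
        m = extract_measures(make_trace(load, platform, gate))
        expected = (W - 0.2) / slope
        assert m.LPD1 == pytest.approx(expected, abs=0.01)

    def test_truncation_worsens_monotonically_with_overshoot(self):
        # same seed throughout: raising the overshoot only shrinks the
        # platform's recording window for the light object
        from liftforce.simulate import simulate_cohort

        fractions = []
        for alpha in (1.05, 1.3, 1.8):
            cfg = SimulationConfig(
                n_participants=3, n_per_transition=3, overshoot=alpha, seed=21
            )
            records = simulate_cohort(cfg)
            light = [
                extract_measures(r)
                for r in records
                if r.condition.cube == "light" and r.condition.analyzable
            ]
            fractions.append(
                np.mean([m.PF1st is not None for m in light])
            )
        assert fractions[0] >= fractions[1] >= fractions[2]

    def test_heavy_trials_platform_and_handle_rate_peaks_agree(self):
        cfg = noise_free_config()
        for expected in (518.0, 125.0):
            trace = simulate_trial(HEAVY_CUBE, expected, cfg, np.random.default_rng(2))
            m = extract_measures(trace)
            assert m.PPFR == pytest.approx(m.PLFR, rel=0.05)


class TestPercentScores:
    def test_two_symmetric_estimates(self):
        assert percent_scores([100.0, 300.0]) == pytest.approx([-50.0, 50.0])

    def test_equal_estimates_all_zero(self):
        assert percent_scores([7.0, 7.0, 7.0]) == pytest.approx([0.0, 0.0, 0.0])

    def test_ideal_rater_of_the_two_cubes(self):
        s = percent_scores([125.0, 518.0])
        assert s[1] - s[0] == pytest.approx(393.0 / 321.5 * 100.0)

    def test_literal_sign_convention_flips_scores(self):
        assert percent_scores([100.0, 300.0], literal_sign=True) == pytest.approx(
            [50.0, -50.0]
        )

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.1, max_value=1e4, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_scores_always_average_to_zero(self, estimates):
        assert abs(percent_scores(estimates).mean()) < 1e-9

    def test_empty_input_is_rejected(self):
        with pytest.raises(InvalidArgumentError):
            percent_scores([])


class TestTrimOutliers:
    def test_degenerate_spread_retains_everything(self):
        assert trim_outliers([3.0] * 8).all()

    def test_hand_computed_borderline_case_is_retained(self):
        # mean 10, SD ~31.6: |100 - 10| = 90 < 3 x 31.6 = 94.9
        values = [0.0] * 9 + [100.0]
        assert trim_outliers(values).all()

    def test_a_true_outlier_is_excluded(self):
        values = [0.0] * 19 + [100.0]  # SD ~22.9, 3 SD ~68.8 < 95
        mask = trim_outliers(values)
        assert not mask[-1]
        assert mask[:-1].all()

    def test_normal_sample_exclusion_rate_is_near_the_3_sd_tail(self):
        x = np.random.default_rng(123).standard_normal(10_000)
        excluded = 1.0 - trim_outliers(x).mean()
        assert 0.001 <= excluded <= 0.006

    def test_fewer_than_two_values_is_an_error(self):
        with pytest.raises(InvalidArgumentError):
            trim_outliers([1.0])


def small_measures_frame() -> pd.DataFrame:
    rows = []
    rng = np.random.default_rng(8)
    for pid in ("P01", "P02"):
        for cube in ("light", "heavy"):
            for switch in ("switch", "no_switch"):
                for k in range(3):
                    rows.append(
                        {
                            "participant_id": pid,
                            "trial_index": len(rows),
                            "cube": cube,
                            "switch": switch,
                            "PLF": rng.normal(5.0, 1.0),
                            "PPFR": rng.normal(10.0, 2.0)
                            if rng.random() > 0.2
                            else np.nan,
                        }
                    )
    rows.append(
        {
            "participant_id": "P01",
            "trial_index": 999,
            "cube": "light",
            "switch": "discard",
            "PLF": 1e6,
            "PPFR": 1e6,
        }
    )
    return pd.DataFrame(rows)


class TestConditionMeans:
    def test_single_trial_per_cell_returns_the_raw_values(self):
        df = small_measures_frame()
        df = df.groupby(
            ["participant_id", "cube", "switch"], as_index=False
        ).first()  # one trial per cell
        cells = condition_means(df, measure_columns=["PLF"], strict=False)
        merged = cells.merge(
            df, on=["participant_id", "cube", "switch"], how="left"
        )
        merged = merged[merged["switch"] != "discard"]
        assert np.allclose(merged["value"], merged["PLF"])

    def test_duplicating_trials_leaves_means_unchanged(self):
        df = small_measures_frame()
        once = condition_means(df, measure_columns=["PLF"], strict=False)
        twice = condition_means(
            pd.concat([df, df], ignore_index=True),
            measure_columns=["PLF"],
            strict=False,
        )
        assert np.allclose(once["value"], twice["value"], equal_nan=True)

    def test_discard_trials_are_excluded_from_means(self):
        df = small_measures_frame()
        cells = condition_means(df, measure_columns=["PLF"], strict=False)
        assert cells["value"].max() < 1e5

    def test_matches_a_naive_group_by_loop(self):
        df = small_measures_frame()
        cells = condition_means(df, measure_columns=["PLF", "PPFR"], strict=False)
        data = df[df["switch"] != "discard"]
        for _, row in cells.iterrows():
            sub = data[
                (data["participant_id"] == row["participant_id"])
                & (data["cube"] == row["cube"])
                & (data["switch"] == row["switch"])
            ][row["measure"]]
            vals = [v for v in sub if np.isfinite(v)]
            expected = sum(vals) / len(vals) if vals else np.nan
            if np.isnan(expected):
                assert np.isnan(row["value"])
            else:
                assert row["value"] == pytest.approx(expected)

    def test_strict_mode_names_the_empty_cell(self):
        df = small_measures_frame()
        df.loc[
            (df["participant_id"] == "P02") & (df["cube"] == "heavy"), "PLF"
        ] = np.nan
        with pytest.raises(MissingCellError, match="P02.*PLF|PLF.*P02"):
            condition_means(df, measure_columns=["PLF"], strict=True)
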