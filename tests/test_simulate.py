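"""Tests for the synthetic-cohort generator and SNIRF round-tripping."""

import numpy as np
import pytest

from nirsprune import (
    CohortDesign,
    MotionConfig,
    QTConfig,
    SimulationConfig,
    clean_window_indices,
    detect_motion_by_channel,
    evaluate_channel,
    generate_cohort,
    generate_recording,
    percent_motion,
    read_snirf,
    window_bounds,
    write_snirf,
)
from nirsprune.io_snirf import SnirfParseError
from nirsprune.motion import detect_motion
from nirsprune.quality import sci


class TestGenerateRecording:
    def test_default_study_conditions(self):
        rec, _ = generate_recording(SimulationConfig(duration=30.0))
        assert rec.n_channels == 34
        assert rec.sampling_rate == 10.0
        assert set(rec.wavelengths) == {780.0, 850.0}

    def test_perfect_coupling_noise_free_gives_unit_sci(self):
        cfg = SimulationConfig(
            n_channels=3, duration=30.0, coupling_quality=(1.0, 1.0, 1.0),
            motion_rate=0.0, cse_probability=0.0, noise_sd=0.0,
            instability_scale=0.0, response_amplitude=0.0, trc_indices=(), seed=1,
        )
        rec, _ = generate_recording(cfg)
        bounds = window_bounds(rec.n_samples, rec.sampling_rate)
        for c in range(3):
            for a, b in bounds:
                assert sci(rec.intensity[c, 0, a:b], rec.intensity[c, 1, a:b]) == pytest.approx(
                    1.0, abs=1e-9
                )

    def test_scheduled_motion_events_are_detectable(self):
        # rate chosen so exactly 4 events are scheduled in 120 s
        cfg = SimulationConfig(
            n_channels=2, duration=120.0, motion_rate=2.0, cse_probability=0.0,
            motion_amplitude_range=(0.8, 1.2),  # well above amp_thresh = 0.4
            coupling_quality=(0.9, 0.9), trc_indices=(), seed=9,
        )
        rec, truth = generate_recording(cfg)
        assert len(truth.motion_events) == 4
        flags = detect_motion_by_channel(rec, 0, MotionConfig())
        bounds = window_bounds(rec.n_samples, rec.sampling_rate)
        dirty = [k for k, (a, b) in enumerate(bounds) if flags[a:b].any()]
        assert len(dirty) >= 4  # brute-force window scan flags every event

    def test_no_motion_no_flags(self):
        cfg = SimulationConfig(
            n_channels=4, duration=60.0, motion_rate=0.0, cse_probability=0.0,
            coupling_quality=(0.8,) * 4, instability_scale=0.0, trc_indices=(), seed=2,
        )
        rec, truth = generate_recording(cfg)
        assert truth.motion_events == []
        mask = detect_motion(rec)
        assert not mask.flags.any()

    def test_cse_channels_below_floor(self):
        cfg = SimulationConfig(n_channels=40, duration=10.0, cse_probability=0.5, seed=3)
        rec, truth = generate_recording(cfg)
        assert truth.cse_channels  # with p = 0.5 over 40 channels
        for c in truth.cse_channels:
            assert rec.intensity[c].min() < 3e-4

    def test_cardiac_frequency_within_band(self):
        _, truth = generate_recording(SimulationConfig(n_channels=2, duration=10.0, trc_indices=(), seed=4))
        lo, hi = SimulationConfig().cardiac_band
        assert lo <= truth.cardiac_frequency <= hi

    def test_fixed_seed_bit_identical(self):
        cfg = SimulationConfig(n_channels=6, duration=30.0, trc_indices=(), seed=11)
        rec1, _ = generate_recording(cfg)
        rec2, _ = generate_recording(cfg)
        assert np.array_equal(rec1.intensity, rec2.intensity)

    def test_coupling_monotonically_increases_sci_and_psp(self):
        # >= 50 replicate channels per coupling level, fixed seed
        means = []
        for level, c in enumerate((0.2, 0.5, 0.8)):
            cfg = SimulationConfig(
                n_channels=50, duration=30.0, coupling_quality=(c,) * 50,
                motion_rate=0.0, cse_probability=0.0, trc_indices=(), seed=100 + level,
            )
            rec, _ = generate_recording(cfg)
            scis, psps = [], []
            for ch in range(50):
                q = evaluate_channel(rec, ch, QTConfig())
                scis.append(np.nanmean(q.sci))
                psps.append(np.nanmean(q.psp))
            means.append((np.mean(scis), np.mean(psps)))
        assert means[0][0] < means[1][0] < means[2][0]
        assert means[0][1] < means[1][1] < means[2][1]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_channels=0)
        with pytest.raises(ValueError):
            SimulationConfig(cardiac_band=(1.3, 6.0))
        with pytest.raises(ValueError):
            SimulationConfig(n_channels=4, trc_indices=(7,))


class TestGenerateCohort:
    def test_participant_table_size(self):
        design = CohortDesign(ages=(5, 8), cohorts=("Gambia", "UK"), tasks=("HaND",),
                              n_participants=5)
        cfg = SimulationConfig(n_channels=2, duration=6.0, trc_indices=(), seed=0)
        recs, table = generate_cohort(design, cfg)
        assert len(recs) == len(table) == 20
        assert set(table.columns) >= {"id", "age_months", "cohort", "task"}

    def test_null_design_cells_similar(self):
        design = CohortDesign(ages=(5, 24), cohorts=("UK",), tasks=("HaND",),
                              n_participants=12, effects={})
        cfg = SimulationConfig(n_channels=2, duration=6.0, trc_indices=(), seed=42)
        _, table = generate_cohort(design, cfg)
        by_age = table.groupby("age_months")["mean_coupling"].mean()
        # only sampling error separates the cells (scatter sd 0.6 on the logit)
        assert abs(by_age.loc[5] - by_age.loc[24]) < 0.25

    def test_injected_age_effect_shifts_cells(self):
        design = CohortDesign(ages=(5, 24), cohorts=("UK",), tasks=("HaND",),
                              n_participants=12, effects={"age_coupling": 2.0})
        cfg = SimulationConfig(n_channels=2, duration=6.0, trc_indices=(), seed=42)
        recs, table = generate_cohort(design, cfg)
        by_age = table.groupby("age_months")["mean_coupling"].mean()
        assert by_age.loc[24] > by_age.loc[5] + 0.1
        assert recs[0][1].injected_effects["age_coupling"] == 2.0

    def test_negative_motion_effect_gives_negative_pom_sci_correlation(self):
        design = CohortDesign(ages=(8,), cohorts=("UK",), tasks=("HaND",),
                              n_participants=10, effects={"motion_coupling": -1.5})
        cfg = SimulationConfig(n_channels=8, duration=60.0, seed=7, cse_probability=0.0,
                               trc_indices=())
        recs, _ = generate_cohort(design, cfg)
        poms, mean_scis = [], []
        for rec, truth in recs:
            mask = detect_motion(rec)
            bounds = window_bounds(rec.n_samples, rec.sampling_rate)
            poms.append(percent_motion(mask))
            scis = []
            for c in range(rec.n_channels):
                clean = clean_window_indices(mask.flags[c], bounds)
                if clean:
                    scis.append(np.nanmean(evaluate_channel(rec, c, QTConfig(), clean).sci))
            mean_scis.append(np.mean(scis))
        r = np.corrcoef(poms, mean_scis)[0, 1]
        assert r < 0

    def test_reproducible_under_subsetting(self):
        cfg = SimulationConfig(n_channels=2, duration=6.0, trc_indices=(), seed=5)
        full = CohortDesign(ages=(5, 8), cohorts=("UK",), tasks=("HaND",), n_participants=2)
        sub = CohortDesign(ages=(8,), cohorts=("UK",), tasks=("HaND",), n_participants=2)
        recs_full, tbl_full = generate_cohort(full, cfg)
        recs_sub, tbl_sub = generate_cohort(sub, cfg)
        full_by_cell = {
            (row.age_months, row.cohort, row.task, i % 2): recs_full[i][0].intensity
            for i, row in enumerate(tbl_full.itertuples())
        }
        for i, row in enumerate(tbl_sub.itertuples()):
            key = (row.age_months, row.cohort, row.task, i % 2)
            assert np.array_equal(recs_sub[i][0].intensity, full_by_cell[key])

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            CohortDesign(ages=())
        with pytest.raises(ValueError):
            CohortDesign(n_participants=0)


class TestSnirfRoundTrip:
    def test_round_trip_lossless(self, tmp_path):
        cfg = SimulationConfig(n_channels=5, duration=12.0, trc_indices=(1,), seed=13)
        rec, _ = generate_recording(cfg)
        rec.participant.update({"id": "P007", "age_months": 12, "cohort": "UK",
                                "task": "SNS"})
        path = tmp_path / "rec.snirf"
        write_snirf(rec, path)
        back = read_snirf(path)
        assert np.allclose(back.intensity, rec.intensity, rtol=0, atol=1e-12)
        assert back.sampling_rate == pytest.approx(rec.sampling_rate)
        assert back.wavelengths == rec.wavelengths
        assert back.participant["id"] == "P007"
        assert back.participant["age_months"] == 12

    def test_measurement_layout(self, tmp_path):
        import h5py

        cfg = SimulationConfig(n_channels=34, duration=60.0, seed=1)
        rec, _ = generate_recording(cfg)
        path = tmp_path / "rec.snirf"
        write_snirf(rec, path)
        with h5py.File(path) as f:
            data = f["nirs/data1"]
            mls = [k for k in data if k.startswith("measurementList")]
            assert len(mls) == 34 * 2
            assert data["dataTimeSeries"].shape == (600, 68)

    def test_missing_wavelengths_is_parse_error(self, tmp_path):
        import h5py

        cfg = SimulationConfig(n_channels=2, duration=6.0, trc_indices=(), seed=1)
        rec, _ = generate_recording(cfg)
        path = tmp_path / "bad.snirf"
        write_snirf(rec, path)
        with h5py.File(path, "a") as f:
            del f["nirs/probe/wavelengths"]
        with pytest.raises(SnirfParseError, match="wavelengths"):
            read_snirf(path)
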