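"""Tests for the threshold sweep, CV matching, and the trade-off tool."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nirsprune import (
    CohortDesign,
    SimulationConfig,
    SweepGrid,
    exclusion_rule,
    generate_cohort,
    match_to_cv,
    run_sweep,
    tradeoff_trend,
    trc_snr,
)
from nirsprune.pruning import PRUNED_QT, RETAINED, PruningResult

from conftest import FS, make_recording


@pytest.fixture(scope="module")
def small_sweep():
    design = CohortDesign(ages=(5, 24), cohorts=("UK",), tasks=("HaND",),
                          n_participants=2, base_coupling=0.6, coupling_sd=0.8)
    cfg = SimulationConfig(duration=90.0, seed=33)
    recs, _ = generate_cohort(design, cfg)
    grid = SweepGrid(sci_values=(0.2, 0.5, 0.8), psp_values=(0.01, 0.05, 0.09))
    return run_sweep(recs, cfg.trc_indices, grid), grid, recs, cfg


class TestSweepGrid:
    def test_default_grid_has_360_combinations(self):
        grid = SweepGrid()
        assert len(grid.sci_values) == 18
        assert len(grid.psp_values) == 20
        assert grid.n_points == 360
        assert grid.sci_values[0] == pytest.approx(0.05)
        assert grid.sci_values[-1] == pytest.approx(0.90)
        assert grid.psp_values[0] == pytest.approx(0.005)
        assert grid.psp_values[-1] == pytest.approx(0.10)

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError):
            SweepGrid(sci_values=(0.5, 0.3))


class TestTrcSnr:
    def _snr_recording(self, snr_db_targets):
        """One channel per target with mean 1 and sd chosen to hit the SNR."""
        n = 300
        chans = []
        for target in snr_db_targets:
            sd = 10 ** (-target / 20.0)
            x = np.ones(n)
            x[0::2] += sd
            x[1::2] -= sd
            chans.append(np.stack([x, x]))
        return make_recording(np.stack(chans))

    def test_single_retained_trc(self):
        rec = self._snr_recording([20.0])
        result = PruningResult({0: RETAINED}, method="qt")
        assert trc_snr(rec, result, {0}) == pytest.approx(20.0, abs=1e-9)

    def test_mean_of_two_trcs(self):
        rec = self._snr_recording([20.0, 40.0])
        result = PruningResult({0: RETAINED, 1: RETAINED}, method="qt")
        assert trc_snr(rec, result, {0, 1}) == pytest.approx(30.0, abs=1e-9)

    def test_all_pruned_is_nan(self):
        rec = self._snr_recording([20.0])
        result = PruningResult({0: PRUNED_QT}, method="qt")
        assert np.isnan(trc_snr(rec, result, {0}))

    def test_empty_trc_set_rejected(self):
        rec = self._snr_recording([20.0])
        with pytest.raises(ValueError):
            trc_snr(rec, PruningResult({0: RETAINED}, method="qt"), set())


class TestExclusionRule:
    @pytest.mark.parametrize(
        "cr, acceptable, expected",
        [(21, 34, False), (20, 34, True), (34, 34, False), (0, 0, True)],
    )
    def test_sixty_percent_cut(self, cr, acceptable, expected):
        assert exclusion_rule(cr, acceptable) is expected


class TestRunSweep:
    def test_row_counts(self, small_sweep):
        df, grid, recs, _ = small_sweep
        n_participants = len(recs)
        per_participant = 1 + len(grid.sci_values) * (1 + len(grid.psp_values))
        assert len(df) == n_participants * per_participant
        assert set(df["method"]) == {"cv", "sci", "qt"}

    def test_doubling_participants_doubles_rows(self, small_sweep):
        df, grid, recs, cfg = small_sweep
        df2 = run_sweep(recs + recs, cfg.trc_indices, grid)
        assert len(df2) == 2 * len(df)

    def test_mean_cr_non_increasing_along_axes(self, small_sweep):
        df, grid, _, _ = small_sweep
        qt = df[df["method"] == "qt"]
        table = qt.groupby(["sci_thr", "psp_thr"])["cr"].mean().unstack()
        assert (table.diff(axis=0).dropna(how="all") <= 1e-12).all().all()
        assert (table.diff(axis=1).T.dropna(how="all") <= 1e-12).all().all()

    def test_deterministic(self, small_sweep):
        df, grid, recs, cfg = small_sweep
        again = run_sweep(recs, cfg.trc_indices, grid)
        pd.testing.assert_frame_equal(df, again)


class TestMatchToCv:
    def _toy_table(self):
        """3 grid points, 2 participants, hand-computable distances."""
        rows = []
        cv_crs = {"a": 30, "b": 20}
        for pid, cr in cv_crs.items():
            rows.append({"id": pid, "method": "cv", "sci_thr": np.nan, "psp_thr": np.nan,
                         "cr": cr, "trc_snr": 20.0, "excluded": cr < 0.6 * 34})
        # CV mean CR = 25, one participant excluded (20 < 20.4)
        grid_crs = {
            (0.2, 0.01): (31, 21),  # mean 26, d1 = 1; excl 0 -> d2 = 1
            (0.5, 0.05): (25, 25),  # mean 25, d1 = 0; excl 0 -> d2 = 1
            (0.8, 0.09): (18, 12),  # mean 15, d1 = 10; excl 2 -> d2 = 1
        }
        for (s, p), (cr1, cr2) in grid_crs.items():
            for pid, cr in zip(("a", "b"), (cr1, cr2)):
                rows.append({"id": pid, "method": "qt", "sci_thr": s, "psp_thr": p,
                             "cr": cr, "trc_snr": 22.0, "excluded": cr < 0.6 * 34})
        return pd.DataFrame(rows)

    def test_hand_computed_selection_matches_enumeration(self):
        df = self._toy_table()
        m = match_to_cv(df, "qt")
        # brute force over grid points: combined rank minimal at (0.5, 0.05)
        cv_mean = df[df.method == "cv"].cr.mean()
        cv_excl = df[df.method == "cv"].excluded.sum()
        best, best_key = None, None
        for (s, p), sub in df[df.method == "qt"].groupby(["sci_thr", "psp_thr"]):
            d1, d2 = abs(sub.cr.mean() - cv_mean), abs(sub.excluded.sum() - cv_excl)
            key = (d1, d2)
            if best is None or key < best:
                best, best_key = key, (s, p)
        assert m.selected == best_key == (0.5, 0.05)

    def test_exact_match_selected(self):
        df = self._toy_table()
        extra = []
        for pid, cr in (("a", 30), ("b", 20)):  # identical to CV rows
            extra.append({"id": pid, "method": "qt", "sci_thr": 0.3, "psp_thr": 0.02,
                          "cr": cr, "trc_snr": 21.0, "excluded": cr < 0.6 * 34})
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
        assert match_to_cv(df, "qt").selected == (0.3, 0.02)

    def test_order_invariance(self):
        df = self._toy_table()
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert match_to_cv(df, "qt").selected == match_to_cv(shuffled, "qt").selected

    def test_ties_broken_toward_lower_thresholds(self):
        rows = []
        rows.append({"id": "a", "method": "cv", "sci_thr": np.nan, "psp_thr": np.nan,
                     "cr": 25, "trc_snr": 20.0, "excluded": False})
        for s, p in ((0.2, 0.01), (0.8, 0.09)):  # identical distances
            rows.append({"id": "a", "method": "qt", "sci_thr": s, "psp_thr": p,
                         "cr": 24, "trc_snr": 21.0, "excluded": False})
        assert match_to_cv(pd.DataFrame(rows), "qt").selected == (0.2, 0.01)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            match_to_cv(pd.DataFrame(columns=["method", "cr", "excluded"]))

    def test_matches_exhaustive_enumeration_on_real_sweep(self, small_sweep):
        df, _, _, _ = small_sweep
        m = match_to_cv(df, "qt")
        cv_mean = df[df.method == "cv"].cr.mean()
        cv_excl = df[df.method == "cv"].excluded.sum()
        from scipy.stats import rankdata

        pts = df[df.method == "qt"].groupby(["sci_thr", "psp_thr"]).agg(
            mean_cr=("cr", "mean"), excl=("excluded", "sum")
        )
        d1 = (pts.mean_cr - cv_mean).abs().to_numpy()
        d2 = (pts.excl - cv_excl).abs().to_numpy()
        combined = rankdata(d1) + rankdata(d2)
        winners = [pts.index[i] for i in np.flatnonzero(combined == combined.min())]
        assert m.selected == min(winners)


class TestTradeoffTrend:
    def _grid_rows(self, snr_by_point):
        rows = []
        for (s, p), (cr, snr) in snr_by_point.items():
            rows.append({"id": "a", "method": "qt", "sci_thr": s, "psp_thr": p,
                         "cr": cr, "trc_snr": snr, "excluded": False})
        return pd.DataFrame(rows)

    def test_collinear_points_tiebreak_prefers_retention(self):
        pts = {(0.1 * k, 0.01 * k): (30 - k, 20.0 + k) for k in range(1, 6)}
        out = tradeoff_trend(self._grid_rows(pts), "qt")
        assert np.allclose(out["residual"], 0.0, atol=1e-9)
        assert out.iloc[0]["mean_cr"] == out["mean_cr"].max()

    def test_displaced_point_recommended(self):
        pts = {(0.1 * k, 0.01 * k): (30 - k, 20.0 + k) for k in range(1, 7)}
        pts[(0.35, 0.035)] = (26.5, 26.5)  # ~+3 dB above the linear cloud
        out = tradeoff_trend(self._grid_rows(pts), "qt")
        top = out[out["recommended"]].iloc[0]
        assert (top["sci_thr"], top["psp_thr"]) == (0.35, 0.035)
        assert top["residual"] > 1.0

    def test_row_order_invariance(self):
        pts = {(0.1 * k, 0.01 * k): (30 - k, 20.0 + k + (k == 3)) for k in range(1, 7)}
        df = self._grid_rows(pts)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = tradeoff_trend(df, "qt")
        b = tradeoff_trend(shuffled, "qt")
        assert a.iloc[0][["sci_thr", "psp_thr"]].tolist() == b.iloc[0][["sci_thr", "psp_thr"]].tolist()

    def test_too_few_points_rejected(self):
        pts = {(0.1, 0.01): (30, 20.0), (0.2, 0.02): (29, 21.0)}
        with pytest.raises(ValueError):
            tradeoff_trend(self._grid_rows(pts), "qt")
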