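"""Marker screens, group trajectories, QC and morphology fractions."""

import numpy as np
import pytest
from scipy import stats

from replidyn import SynthParams, TimeGrid
from replidyn.cohort import CellTrajectory, Cohort
from replidyn.exceptions import ValidationError
from replidyn.markers import (
    correlation_series,
    dividing_at,
    group_series,
    majority_state_compare,
    mean_series,
    qc_filter,
    size_ratio_series,
    state_fractions,
)
from replidyn.simulate import gen_cohort, state_targets


def _cell(cell_id, n, divisions, state=None, area0=100.0, rls_value=None):
    t = np.arange(n, dtype=float)
    return CellTrajectory(
        cell_id=cell_id,
        frames=np.arange(n),
        cell_area=area0 + 2.0 * t,
        nuc_area=15.0 + 0.3 * t,
        i_nuc=np.full(n, 1.0) if rls_value is None else np.full(n, float(rls_value)),
        i_cyt=np.full(n, 10.0),
        division_frames=np.asarray(divisions, dtype=int),
        state=state,
    )


class TestDividingAt:
    def test_boundary_inclusive(self):
        grid = TimeGrid(n_frames=120)
        c = _cell("a", 101, [100])
        cohort = Cohort(grid=grid, cells=[c])
        assert c in dividing_at(cohort, 90)
        assert c in dividing_at(cohort, 100)
        assert dividing_at(cohort, 101) == []

    def test_matches_brute_force_counts(self, default_cohort):
        cohort, _ = default_cohort
        arrests = cohort.arrest_frames()
        for frame in (0, 30, 60, 93, 150):
            expected = int((arrests >= frame).sum())
            assert len(dividing_at(cohort, frame)) == expected


class TestCorrelationSeries:
    def test_perfect_correlation_when_channel_equals_rls(self):
        grid = TimeGrid(n_frames=30)
        cells = [
            _cell(f"c{i}", 21, divisions=list(range(1, i + 2)), rls_value=i + 1)
            for i in range(6)
        ]
        cohort = Cohort(grid=grid, cells=cells)
        cs = correlation_series(cohort, "i_nuc", log10_transform=False, min_cells=3)
        ok = cs.n_dividing >= 3
        np.testing.assert_allclose(cs.r[ok], 1.0, atol=1e-12)

    def test_agrees_with_brute_force(self, default_cohort):
        """Frame-by-frame Pearson r and p match a direct recomputation."""
        cohort, _ = default_cohort
        cs = correlation_series(cohort, "i_nuc", log10_transform=True, min_cells=25)
        rls = cohort.rls_values().astype(float)
        vals = cohort.channel_matrix("i_nuc")
        alive = cohort.alive_matrix()
        for t in (10, 47, 80, 120):
            sel = alive[:, t] & np.isfinite(vals[:, t]) & (vals[:, t] > 0)
            x = np.log10(vals[sel, t])
            r, p = stats.pearsonr(x, rls[sel])
            assert cs.r[t] == pytest.approx(r, abs=1e-12)
            assert cs.p[t] == pytest.approx(p, abs=1e-12)

    def test_independent_channel_stays_near_zero(self, default_cohort):
        cohort, _ = default_cohort
        cs = correlation_series(cohort, "i_cyt", log10_transform=False)
        full = cs.n_dividing >= int(0.9 * cohort.n_cells)
        assert np.nanmax(np.abs(cs.r[full])) < 0.15

    def test_planted_signals_recovered(self, default_cohort):
        """Nuclear intensity correlates positively with lifespan at mid-life;
        nuclear area negatively (the planted screen signals)."""
        cohort, _ = default_cohort
        nuc = correlation_series(cohort, "i_nuc", log10_transform=True)
        frame, r, p = nuc.peak
        assert r > 0.3
        assert 30 <= frame <= 150  # mid-life, not at either end
        area = correlation_series(cohort, "nuc_area", log10_transform=False)
        _, r_area, _ = area.peak
        assert r_area < 0.0

    def test_n_dividing_non_increasing(self, default_cohort):
        cohort, _ = default_cohort
        cs = correlation_series(cohort, "i_nuc")
        assert np.all(np.diff(cs.n_dividing) <= 0)

    def test_min_cells_validated(self, default_cohort):
        cohort, _ = default_cohort
        with pytest.raises(ValidationError):
            correlation_series(cohort, "i_nuc", min_cells=2)


class TestGroupSeries:
    def test_threshold_assignment(self):
        grid = TimeGrid(n_frames=200)
        c14 = _cell("s", 80, divisions=list(range(1, 15)))
        c15 = _cell("l", 90, divisions=list(range(1, 16)))
        cohort = Cohort(grid=grid, cells=[c14, c15])
        short, long_ = group_series(cohort, "i_nuc", min_alive=1)
        assert short.n[0] == 1 and long_.n[0] == 1
        assert c14.rls == 14 and c15.rls == 15

    def test_normalized_series_max_is_one(self, default_cohort):
        cohort, _ = default_cohort
        sub = Cohort(grid=cohort.grid, cells=cohort.cells[:30])
        alive = sub.alive_matrix()
        mat = sub.channel_matrix("i_nuc")
        mx = np.nanmax(np.where(alive, mat, np.nan), axis=1)
        normed = mat / mx[:, None]
        assert np.nanmax(normed) == pytest.approx(1.0)

    def test_groups_reconstruct_overall_mean(self, default_cohort):
        """n-weighted short/long means equal the all-cells mean per frame."""
        cohort, _ = default_cohort
        short, long_ = group_series(cohort, "i_nuc", min_alive=1)
        overall = mean_series(cohort, "i_nuc", min_alive=1)
        k = min(len(short.frames), len(long_.frames), len(overall.frames))
        num = short.mean[:k] * short.n[:k] + long_.mean[:k] * long_.n[:k]
        den = short.n[:k] + long_.n[:k]
        np.testing.assert_allclose(num / den, overall.mean[:k], rtol=1e-10)

    def test_short_lived_nuclear_intensity_declines_faster(self, default_cohort):
        cohort, _ = default_cohort
        short, long_ = group_series(cohort, "i_nuc", normalize=True, min_alive=25)
        k = len(short.frames)
        assert k > 40
        assert short.mean[k - 1] < long_.mean[k - 1]

    def test_truncation_at_min_alive(self, default_cohort):
        cohort, _ = default_cohort
        short, _ = group_series(cohort, "i_nuc", min_alive=25)
        assert np.all(short.n >= 25)


class TestSizeRatio:
    def test_isometric_cohort_has_constant_ratio(self, noiseless_params):
        from dataclasses import replace

        p = replace(noiseless_params, accel_delta0=0.0, nuc_ratio=0.2, n_cells=10)
        cohort, _ = gen_cohort(p)
        ratio, short, long_ = size_ratio_series(cohort, min_alive=1)
        np.testing.assert_allclose(ratio[np.isfinite(ratio)], 0.2, rtol=1e-12)

    def test_short_lived_ratio_rises_after_bend(self, default_cohort):
        cohort, _ = default_cohort
        _, short, long_ = size_ratio_series(cohort)
        k = len(short.frames)
        # early ratio comparable; late short-lived ratio clearly higher
        assert short.mean[5] == pytest.approx(long_.mean[5], rel=0.05)
        assert short.mean[k - 1] > long_.mean[k - 1] * 1.05

    def test_single_frame_cells(self):
        grid = TimeGrid(n_frames=5)
        c = CellTrajectory(
            cell_id="one",
            frames=np.array([0]),
            cell_area=np.array([100.0]),
            nuc_area=np.array([20.0]),
            i_nuc=np.array([1.0]),
            i_cyt=np.array([1.0]),
            division_frames=np.array([0]),
        )
        cohort = Cohort(grid=grid, cells=[c])
        ratio, _, _ = size_ratio_series(cohort, min_alive=1)
        assert ratio[0, 0] == pytest.approx(0.2)


class TestQcFilter:
    def test_linear_growth_kept_constant_rejected(self):
        grid = TimeGrid(n_frames=120)
        linear = _cell("lin", 100, [99])
        flat = CellTrajectory(
            cell_id="flat",
            frames=np.arange(100),
            cell_area=np.full(100, 100.0),
            nuc_area=np.full(100, 15.0),
            i_nuc=np.full(100, 1.0),
            i_cyt=np.full(100, 1.0),
            division_frames=np.array([99]),
        )
        cohort = Cohort(grid=grid, cells=[linear, flat])
        kept, report = qc_filter(cohort)
        assert kept.cell_ids == ["lin"]
        row = report.set_index("cell_id").loc["flat"]
        assert not row["kept"] and row["reason"] == "zero variance"

    def test_white_noise_area_rejected(self):
        rng = np.random.default_rng(0)
        grid = TimeGrid(n_frames=120)
        noise = CellTrajectory(
            cell_id="noise",
            frames=np.arange(100),
            cell_area=100.0 + rng.standard_normal(100),
            nuc_area=np.full(100, 15.0),
            i_nuc=np.full(100, 1.0),
            i_cyt=np.full(100, 1.0),
            division_frames=np.array([99]),
        )
        _, report = qc_filter(Cohort(grid=grid, cells=[noise]))
        assert not report.iloc[0]["kept"]


class TestStateFractions:
    def test_direct_count(self):
        grid = TimeGrid(n_frames=4)
        states = ["circular", "circular", "aggregate", "other"]
        cells = [
            _cell(f"c{i}", 2, [1], state=np.array([s, s], dtype=object))
            for i, s in enumerate(states)
        ]
        cohort = Cohort(grid=grid, cells=cells)
        sf = state_fractions(cohort)
        np.testing.assert_allclose(
            sf.fractions.iloc[0].to_numpy(), [0.5, 0.0, 0.25, 0.25]
        )

    def test_fractions_sum_to_one(self):
        p = SynthParams(seed=6, n_cells=50, with_states=True)
        cohort, _ = gen_cohort(p)
        sf = state_fractions(cohort)
        alive = sf.n_alive > 0
        np.testing.assert_allclose(sf.fractions[alive].sum(axis=1), 1.0, atol=1e-12)

    def test_unknown_label_rejected(self):
        grid = TimeGrid(n_frames=4)
        c = _cell("c0", 2, [1], state=np.array(["circular", "spiral"], dtype=object))
        with pytest.raises(ValidationError, match="spiral"):
            state_fractions(Cohort(grid=grid, cells=[c]))

    def test_matches_propagated_chain_marginals(self):
        """Observed fractions track the sticky chain's analytic marginals
        m(t+1) = h m(t) + (1-h) π(t+1)."""
        p = SynthParams(seed=8, n_cells=400, with_states=True)
        cohort, _ = gen_cohort(p)
        sf = state_fractions(cohort)
        h = p.state_persistence
        u = cohort.grid.frames / (cohort.grid.n_frames - 1)
        pis = state_targets(u)
        m = np.empty_like(pis)
        m[0] = pis[0]
        for t in range(1, len(u)):
            m[t] = h * m[t - 1] + (1 - h) * pis[t]
        check = sf.n_alive >= 200
        err = np.abs(sf.fractions.to_numpy()[check] - m[check])
        # per-entry sampling se <= sqrt(0.25/200) ~ 0.035; the chain's
        # stickiness correlates errors across frames, so bound the mean
        # tightly and the worst entry loosely
        assert err.mean() < 0.025
        assert err.max() < 0.12


class TestMajorityState:
    def _state_cell(self, cell_id, labels, rls_count):
        n = len(labels)
        return _cell(
            cell_id, n, divisions=list(range(1, rls_count + 1)),
            state=np.array(labels, dtype=object),
        )

    def test_plurality_assignment_and_tie(self):
        grid = TimeGrid(n_frames=30)
        mostly_circ = self._state_cell("a", ["circular"] * 6 + ["aggregate"] * 4, 9)
        tie = self._state_cell("b", ["circular"] * 5 + ["aggregate"] * 5, 9)
        cohort = Cohort(grid=grid, cells=[mostly_circ, tie])
        out = majority_state_compare(cohort)
        assert out["groups"]["circular"]["n"] == 1
        assert out["unassigned"] == ["b"]

    def test_planted_lifespan_difference_detected(self):
        rng = np.random.default_rng(3)
        grid = TimeGrid(n_frames=216)
        cells = []
        for i in range(50):
            r = max(2, int(round(rng.normal(20, 4))))
            cells.append(self._state_cell(f"circ{i}", ["circular"] * (r + 1), r))
        for i in range(50):
            r = max(2, int(round(rng.normal(10, 4))))
            cells.append(self._state_cell(f"agg{i}", ["aggregate"] * (r + 1), r))
        out = majority_state_compare(Cohort(grid=grid, cells=cells))
        assert out["groups"]["circular"]["mean_rls"] > out["groups"]["aggregate"]["mean_rls"]
        assert out["rls_ranksum_p"] < 0.01

    def test_small_group_comparison_skipped(self):
        grid = TimeGrid(n_frames=30)
        c = self._state_cell("only", ["circular"] * 8, 5)
        with pytest.warns(UserWarning, match="skipped"):
            out = majority_state_compare(Cohort(grid=grid, cells=[c]))
        assert np.isnan(out["rls_ranksum_p"])
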