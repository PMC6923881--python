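import numpy as np
import pandas as pd
import pytest

from oracles import brute_fuzzy_predict, brute_kde
from protpred.data_io import ValidationError
from protpred.fuzzy_predictor import (DensityGrid, FuzzyParams,
                                      fuzzy_predict_one, gaussian_kde_on_grid,
                                      intersect_densities, local_density,
                                      protein_grid, tune_fuzzy)
from protpred.preprocess import TranscriptSelection


def _params(**kwargs):
    defaults = dict(tau=1.0, alpha=0.1, min_window_samples=10)
    defaults.update(kwargs)
    return FuzzyParams(**defaults)


class TestLocalDensity:
    def test_point_mass_window_peaks_at_zero(self, rng):
        # protein constant 0 in the window -> density maximized nearest 0
        y = np.concatenate([np.zeros(15), np.array([2.0, 3.0, 4.0])])
        x = np.concatenate([np.zeros(15), np.array([5.0, 5.0, 5.0])])
        dg = local_density(y, x, query_value=0.0, params=_params())
        assert dg is not None
        peak = dg.grid[np.argmax(dg.density)]
        nearest = dg.grid[np.argmin(np.abs(dg.grid))]
        assert peak == nearest

    def test_window_below_minimum_discarded(self, rng):
        x = np.concatenate([np.zeros(9), np.full(20, 100.0)])
        y = rng.standard_normal(29)
        assert local_density(y, x, 0.0, _params()) is None
        # exactly at the minimum is retained
        x10 = np.concatenate([np.zeros(10), np.full(20, 100.0)])
        assert local_density(np.r_[y, 0.0], x10, 0.0, _params()) is not None

    def test_identity_relation_argmax_near_query(self, rng):
        # y = x exactly: the window around the query holds only nearby y
        # values, so the density argmax must land next to the query
        x = rng.standard_normal(500)
        sd = x.std(ddof=1)
        dg = local_density(x, x, query_value=0.0, params=_params(tau=0.25))
        peak = dg.grid[np.argmax(dg.density)]
        # every windowed value is within 0.25 sd, argmax stays in their hull
        assert abs(peak) <= 0.3 * sd

    def test_kde_matches_bruteforce(self, rng):
        vals = rng.standard_normal(30)
        grid = protein_grid(vals)
        got = gaussian_kde_on_grid(vals, grid)
        expect = brute_kde(vals, grid)
        assert np.allclose(got, expect, atol=1e-9)

    def test_missing_query_discarded(self, rng):
        x = rng.standard_normal(30)
        assert local_density(x, x, np.nan, _params()) is None


class TestGrid:
    def test_uniform_increasing_midpoints(self, rng):
        y = rng.standard_normal(40)
        grid = protein_grid(y, 0.1)
        steps = np.diff(grid)
        assert np.allclose(steps, 0.1 * y.std(ddof=1))
        assert grid[0] == pytest.approx(y.min() + 0.05 * y.std(ddof=1))

    def test_degenerate_protein_single_point(self):
        assert np.array_equal(protein_grid(np.full(5, 2.0)), [2.0])


class TestFuzzyPredictOne:
    def _frame(self, cols):
        return pd.DataFrame(cols)

    def test_single_transcript_reduces_to_thresholded_argmax(self, rng):
        y = rng.standard_normal(60)
        x = y + 0.1 * rng.standard_normal(60)
        X = self._frame({"t1": x})
        sel = TranscriptSelection("p", ("t1",), (0.9,))
        params = _params()
        pred = fuzzy_predict_one(sel, X, y, {"t1": 0.5}, params)
        dg = local_density(y, x, 0.5, params)
        above = np.nonzero(dg.density > params.alpha)[0]
        seg = dg.density[above[0]:above[-1] + 1]
        expected = dg.grid[above[0] + int(np.argmax(seg))]
        assert pred.status == "ok"
        assert pred.value == pytest.approx(expected, abs=1e-12)

    def test_disjoint_supports_fall_back_to_mean(self, rng):
        # two transcripts whose windows see opposite tails of the protein
        n = 40
        y = np.concatenate([np.full(n, -5.0), np.full(n, 5.0)])
        y += 0.05 * rng.standard_normal(2 * n)
        t1 = np.concatenate([np.zeros(n), np.full(n, 50.0)])   # window at 0 -> low tail
        t2 = np.concatenate([np.full(n, 50.0), np.zeros(n)])   # window at 0 -> high tail
        X = self._frame({"t1": t1, "t2": t2})
        sel = TranscriptSelection("p", ("t1", "t2"), (0.5, 0.5))
        pred = fuzzy_predict_one(sel, X, y, {"t1": 0.0, "t2": 0.0},
                                 _params(tau=0.5))
        assert pred.status == "fallback_mean"
        assert pred.value == pytest.approx(np.mean(y))

    def test_all_windows_empty_falls_back(self, rng):
        y = rng.standard_normal(30)
        x = rng.standard_normal(30)
        X = self._frame({"t1": x})
        sel = TranscriptSelection("p", ("t1",), (0.5,))
        pred = fuzzy_predict_one(sel, X, y, {"t1": 100.0}, _params())
        assert pred.status == "fallback_mean"
        assert pred.value == pytest.approx(y.mean())

    def test_matches_bruteforce_reimplementation(self, rng):
        # <=3 transcripts, <=100 samples: bit-compatible with explicit loops
        for trial in range(5):
            n = 60
            y = rng.standard_normal(n)
            cols = {f"t{j}": y * (0.5 + 0.2 * j) + 0.4 * rng.standard_normal(n)
                    for j in range(3)}
            X = self._frame(cols)
            sel = TranscriptSelection("p", tuple(cols), (0.9, 0.8, 0.7))
            query = {t: float(rng.standard_normal()) * 0.5 for t in cols}
            for tau, alpha in [(0.5, 0.1), (1.0, 0.1), (1.0, 0.3), (2.0, 0.3)]:
                params = _params(tau=tau, alpha=alpha)
                got = fuzzy_predict_one(sel, X, y, query, params)
                expect_val, expect_status = brute_fuzzy_predict(
                    [cols[t] for t in cols], y, [query[t] for t in cols],
                    tau, alpha)
                assert got.status == expect_status
                assert got.value == pytest.approx(expect_val, abs=1e-9)

    def test_order_invariance(self, rng):
        n = 80
        y = rng.standard_normal(n)
        cols = {f"t{j}": y + 0.5 * rng.standard_normal(n) for j in range(3)}
        X = self._frame(cols)
        query = {t: 0.2 for t in cols}
        ids = tuple(cols)
        a = fuzzy_predict_one(TranscriptSelection("p", ids, (0.9, 0.8, 0.7)),
                              X, y, query, _params())
        b = fuzzy_predict_one(TranscriptSelection("p", ids[::-1], (0.9, 0.8, 0.7)),
                              X, y, query, _params())
        assert a.value == b.value

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValidationError):
            fuzzy_predict_one(TranscriptSelection("p", (), ()),
                              self._frame({}), np.ones(5), {}, _params())


class TestIntersection:
    def test_adding_transcript_never_raises_min(self, rng):
        grid = np.linspace(-2, 2, 30)
        grids = [DensityGrid(f"t{i}", grid, np.abs(rng.standard_normal(30)), 20)
                 for i in range(4)]
        lo, hi = 5, 25
        m3 = np.min([g.density[lo:hi] for g in grids[:3]], axis=0)
        m4 = np.min([g.density[lo:hi] for g in grids], axis=0)
        assert (m4 <= m3 + 1e-15).all()

    def test_argmax_tie_takes_smallest_grid_value(self):
        grid = np.array([0.0, 1.0, 2.0])
        flat = DensityGrid("t", grid, np.array([0.5, 0.5, 0.5]), 20)
        value, _ = intersect_densities([flat], alpha=0.1)
        assert value == 0.0


class TestTuneFuzzy:
    def _data(self, rng, n=80):
        y = rng.standard_normal(n)
        X = pd.DataFrame({
            "t1": y + 0.3 * rng.standard_normal(n),
            "t2": y + 0.5 * rng.standard_normal(n),
        }, index=[f"s{i}" for i in range(n)])
        Y = pd.DataFrame({"p": y}, index=X.index)
        sels = {"p": TranscriptSelection("p", ("t1", "t2"), (0.9, 0.8))}
        return X, Y, sels

    def test_default_grids_enumerate_six_combinations(self, rng):
        X, Y, sels = self._data(rng)
        _, trace = tune_fuzzy(X, Y, sels, (0.5, 1.0, 2.0), (0.1, 0.3), seed=1)
        assert len(trace) == 6
        assert set(zip(trace["tau"], trace["alpha"])) == {
            (0.5, 0.1), (0.5, 0.3), (1.0, 0.1), (1.0, 0.3),
            (2.0, 0.1), (2.0, 0.3)}

    def test_returns_argmax_combination(self, rng):
        X, Y, sels = self._data(rng)
        params, trace = tune_fuzzy(X, Y, sels, (0.5, 1.0, 2.0), (0.1, 0.3),
                                   seed=2)
        best = trace.loc[trace["median_corr"].idxmax()]
        assert (params.tau, params.alpha) == (best["tau"], best["alpha"])

    def test_deterministic_given_seed(self, rng):
        X, Y, sels = self._data(rng)
        p1, t1 = tune_fuzzy(X, Y, sels, (0.5, 1.0), (0.1, 0.3), seed=3)
        p2, t2 = tune_fuzzy(X, Y, sels, (0.5, 1.0), (0.1, 0.3), seed=3)
        assert p1 == p2
        pd.testing.assert_frame_equal(t1, t2)

    def test_degenerate_data_falls_back_to_default_optimum(self):
        X = pd.DataFrame({"t1": np.zeros(30)},
                         index=[f"s{i}" for i in range(30)])
        Y = pd.DataFrame({"p": np.zeros(30)}, index=X.index)
        sels = {"p": TranscriptSelection("p", ("t1",), (0.0,))}
        params, _ = tune_fuzzy(X, Y, sels, (0.5, 1.0, 2.0), (0.1, 0.3), seed=4)
        assert (params.tau, params.alpha) == (1.0, 0.1)
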