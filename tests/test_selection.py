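"""Wavelength selection: stepwise MLR, interval PLS, simulated annealing."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from nirproline import (
    AnnealConfig,
    RetentionVector,
    acceptance_probability,
    anneal,
    fit_pls,
    ipls,
    make_grid,
    metropolis_accept,
    propose,
    r_coefficient,
    sa_objective,
    smlr,
)
from nirproline.selection import _best_forward_candidate

from .conftest import noiseless_config
from nirproline import simulate


class TestSmlr:
    def test_recovers_single_true_predictor(self, rng):
        grid = make_grid(100.0, 0.0, 30)
        X = rng.normal(size=(50, 30))
        y = 2.0 * X[:, 12]
        model = smlr(X, y, grid)
        assert model.selected.tolist() == [12]
        assert model.coef[0] == pytest.approx(2.0, abs=1e-8)
        assert r_coefficient(model.predict(X), y) == pytest.approx(1.0)

    def test_null_response_selects_almost_nothing(self):
        grid = make_grid(100.0, 0.0, 10)
        counts = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(50, 10))
            y = r.normal(size=50)
            counts.append(smlr(X, y, grid).selected.size)
        assert np.median(counts) <= 1

    def test_window_excludes_true_predictor(self, rng):
        grid = make_grid(100.0, 0.0, 30)  # column 12 sits at ~58.6 cm^-1
        X = rng.normal(size=(50, 30))
        y = 2.0 * X[:, 12] + 0.01 * rng.normal(size=50)
        model = smlr(X, y, grid, window=(30.0, 0.0))
        assert 12 not in model.selected.tolist()
        assert r_coefficient(model.predict(X), y) < 0.9

    def test_empty_window_rejected(self, rng):
        grid = make_grid(100.0, 0.0, 10)
        with pytest.raises(ValueError):
            smlr(rng.normal(size=(20, 10)), rng.normal(size=20), grid, window=(300.0, 200.0))

    def test_forward_step_matches_statsmodels_pvalues(self, rng):
        # the vectorized partial-correlation entry test must agree with a
        # per-candidate OLS refit
        X = rng.normal(size=(40, 8))
        y = X[:, 2] + rng.normal(size=40)
        selected = [2, 5]
        cands = np.array([0, 1, 3, 4, 6, 7])
        best_j, best_p = _best_forward_candidate(X, y, selected, cands)
        ref = {}
        for j in cands:
            fit = sm.OLS(y, sm.add_constant(X[:, selected + [j]])).fit()
            ref[j] = float(fit.pvalues[-1])
        assert best_j == min(ref, key=ref.get)
        assert best_p == pytest.approx(ref[best_j], abs=1e-10)

    def test_greedy_matches_best_subset_on_strong_signal(self, rng):
        # strong orthogonal-ish signal: greedy and exhaustive best subset agree
        grid = make_grid(10.0, 0.0, 8)
        X = rng.normal(size=(60, 8))
        y = 3.0 * X[:, 1] - 2.0 * X[:, 6] + 0.05 * rng.normal(size=60)
        model = smlr(X, y, grid)
        assert sorted(model.selected.tolist()) == [1, 6]


class TestIpls:
    def test_partition_widths_for_study_grid(self):
        grid = make_grid(10000.0, 4000.0, 1557)
        edges = np.linspace(0, 1557, 10).astype(int)
        widths = np.diff(edges)
        assert widths.tolist() == [173] * 9

    def test_single_interval_reduces_to_full_spectrum(self, rng):
        cfg = noiseless_config(n_samples=30, n_points=60)
        spectra, truth = simulate(cfg)
        result = ipls(
            spectra.absorbance, truth.true_concentrations, spectra.grid,
            n_intervals=1, max_lv=3, n_folds=5,
        )
        assert result.best_index == 0
        np.testing.assert_allclose(result.best_model.coef, result.full_model.coef, atol=1e-10)

    def test_band_interval_wins_on_clean_data(self):
        cfg = noiseless_config(n_samples=45, n_points=90, analyte_bands=[(7660.0, 60.0, 4.0)])
        spectra, truth = simulate(cfg)
        result = ipls(
            spectra.absorbance, truth.true_concentrations, spectra.grid,
            n_intervals=9, max_lv=3, n_folds=5,
        )
        lo, hi = result.best_range
        assert lo <= 7660.0 <= hi

    def test_narrow_intervals_rejected(self, rng):
        grid = make_grid(100.0, 0.0, 10)
        with pytest.raises(ValueError):
            ipls(rng.normal(size=(20, 10)), rng.normal(size=20), grid, n_intervals=8)


class TestMetropolis:
    def test_improvements_always_accepted(self):
        assert acceptance_probability(-0.01, 1.0) == 1.0
        assert acceptance_probability(0.0, 1.0) == 1.0
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-0.5, t, rng) for t in (1e-6, 1.0, 100.0))

    def test_worsening_acceptance_matches_boltzmann(self):
        rng = np.random.default_rng(42)
        draws = np.array([metropolis_accept(0.1, 0.1, rng) for _ in range(20000)])
        assert draws.mean() == pytest.approx(np.exp(-1.0), abs=0.01)

    def test_probability_monotone_in_delta_and_temperature(self):
        des = [0.05, 0.1, 0.2]
        ts = [0.05, 0.1, 0.2]
        for t in ts:
            ps = [acceptance_probability(de, t) for de in des]
            assert ps == sorted(ps, reverse=True)
        for de in des:
            ps = [acceptance_probability(de, t) for t in ts]
            assert ps == sorted(ps)
        # seeded Monte-Carlo confirmation on the 3x3 grid
        for i, de in enumerate(des):
            freqs = []
            for j, t in enumerate(ts):
                rng = np.random.default_rng(1000 + 10 * i + j)
                freqs.append(np.mean([metropolis_accept(de, t, rng) for _ in range(5000)]))
            assert all(b >= a - 0.03 for a, b in zip(freqs, freqs[1:]))

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            acceptance_probability(0.1, 0.0)


class TestPropose:
    def test_full_and_single_retention(self):
        rng = np.random.default_rng(0)
        v = RetentionVector(np.ones(10, dtype=bool))
        assert propose(v, 10, rng).m == 10
        assert propose(v, 1, rng).m == 1

    def test_masks_uniform_over_combinations(self):
        rng = np.random.default_rng(7)
        v = RetentionVector(np.ones(6, dtype=bool))
        counts: dict[tuple, int] = {}
        for _ in range(10000):
            key = tuple(propose(v, 3, rng).indices.tolist())
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 20
        freqs = np.array(list(counts.values())) / 10000
        assert np.all(np.abs(freqs - 0.05) <= 0.01)

    @given(st.integers(2, 40), st.integers(1, 40))
    def test_mask_size_contract(self, length, m):
        rng = np.random.default_rng(3)
        v = RetentionVector(np.ones(length, dtype=bool))
        if m > length:
            with pytest.raises(ValueError):
                propose(v, m, rng)
        else:
            assert propose(v, m, rng).m == m


def small_sparse_problem(seed, n=60, p=120, n_informative=10, noise=0.5):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=n)
    X = rng.normal(size=(n, p))
    info = rng.choice(p, size=n_informative, replace=False)
    X[:, info] += np.outer(y, rng.uniform(0.5, 1.5, size=n_informative))
    X += noise * rng.normal(size=(n, p))
    return X[: n // 2], y[: n // 2], X[n // 2 :], y[n // 2 :], info


class TestSaObjective:
    def test_all_ones_mask_equals_full_spectrum(self):
        Xc, yc, Xv, yv, _ = small_sparse_problem(0)
        v = RetentionVector(np.ones(Xc.shape[1], dtype=bool))
        direct = fit_pls(Xc, yc, 5)
        assert sa_objective(v, Xc, yc, Xv, yv, 5) == pytest.approx(
            r_coefficient(direct.predict(Xv), yv)
        )

    def test_informative_mask_beats_noise_mask(self):
        Xc, yc, Xv, yv, info = small_sparse_problem(1)
        p = Xc.shape[1]
        good = np.zeros(p, dtype=bool)
        good[info] = True
        noise_cols = np.zeros(p, dtype=bool)
        noise_cols[[j for j in range(p) if j not in set(info.tolist())][:10]] = True
        r_good = sa_objective(RetentionVector(good), Xc, yc, Xv, yv, 5)
        r_noise = sa_objective(RetentionVector(noise_cols), Xc, yc, Xv, yv, 5)
        assert r_good > r_noise

    def test_clean_informative_mask_is_near_perfect(self):
        cfg = noiseless_config(n_samples=40, n_points=100)
        spectra, truth = simulate(cfg)
        v = RetentionVector(truth.informative_mask)
        r = sa_objective(
            v, spectra.absorbance[:25], truth.true_concentrations[:25],
            spectra.absorbance[25:], truth.true_concentrations[25:], 5,
        )
        assert r > 0.999


class TestAnneal:
    def test_single_iteration_returns_initial_state(self):
        Xc, yc, Xv, yv, _ = small_sparse_problem(2)
        cfg = AnnealConfig(max_iterations=1, t0=0.1, seed=0)
        mask, model, trace = anneal(Xc, yc, Xv, yv, cfg)
        assert len(trace) == 1
        assert mask.m == model.variable_subset.size

    def test_greedy_mode_accepts_only_improvements(self):
        Xc, yc, Xv, yv, _ = small_sparse_problem(3)
        cfg = AnnealConfig(max_iterations=120, t0=1e-9, seed=1)
        _, _, trace = anneal(Xc, yc, Xv, yv, cfg)
        worsening_accepted = [
            a and de > 0 for a, de in zip(trace.accepted[1:], trace.delta_e[1:])
        ]
        assert not any(worsening_accepted)

    def test_global_best_monotone_nondecreasing(self):
        Xc, yc, Xv, yv, _ = small_sparse_problem(4)
        cfg = AnnealConfig(max_iterations=150, seed=2)
        _, _, trace = anneal(Xc, yc, Xv, yv, cfg)
        best = np.asarray(trace.best_objective)
        assert np.all(np.diff(best) >= 0)

    def test_full_mask_greedy_never_below_full_spectrum(self):
        Xc, yc, Xv, yv, _ = small_sparse_problem(5)
        p = Xc.shape[1]
        cfg = AnnealConfig(max_iterations=60, t0=1e-9, shrink=1.0, initial_m=p, seed=3)
        _, _, trace = anneal(Xc, yc, Xv, yv, cfg)
        full = fit_pls(Xc, yc, 5)
        full_rp = r_coefficient(full.predict(Xv), yv)
        assert trace.best_objective[-1] >= full_rp - 1e-12

    def test_sparse_signal_benchmark(self):
        final_m, sa_rp, full_rp = [], [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, p, k = 60, 400, 20
            y = rng.normal(size=n)
            X = rng.normal(size=(n, p))
            info = rng.choice(p, size=k, replace=False)
            X[:, info] += np.outer(y, rng.uniform(0.5, 1.5, size=k))
            Xc, yc, Xv, yv = X[:30], y[:30], X[30:], y[30:]
            cfg = AnnealConfig(max_iterations=150, seed=seed)
            mask, _, trace = anneal(Xc, yc, Xv, yv, cfg)
            final_m.append(mask.m)
            sa_rp.append(trace.best_objective[-1])
            full = fit_pls(Xc, yc, 5)
            full_rp.append(r_coefficient(full.predict(Xv), yv))
        assert np.median(final_m) < 400
        assert np.median(sa_rp) >= np.median(full_rp)

    def test_infeasible_initial_m_rejected(self):
        Xc, yc, Xv, yv, _ = small_sparse_problem(6)
        with pytest.raises(ValueError):
            anneal(Xc, yc, Xv, yv, AnnealConfig(initial_m=10_000, max_iterations=5))
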