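import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielmet import rhythm
from dielmet.rhythm import (
    PhaseGroupedSeries,
    bh_fdr,
    classify_signals,
    cosinor_fit,
    daily_fold_change,
    umbrella_rank_test,
)
from dielmet.synthetic import SignalTruth, diel_signal


def brute_force_umbrella_p(classes, w):
    """Independent oracle: enumerate every distinct assignment of the
    pooled (possibly tied) values to the class sizes."""
    sizes = [len(c) for c in classes]
    pooled = np.concatenate(classes)

    def stat(split):
        total = 0.0
        for i in range(len(split)):
            for j in range(len(split)):
                if w[i, j]:
                    xi = split[i][:, None]
                    xj = split[j][None, :]
                    total += np.sum(xi < xj) + 0.5 * np.sum(xi == xj)
        return total

    obs = stat(classes)
    seen = set()
    ge = tot = 0
    for perm in itertools.permutations(pooled.tolist()):
        if perm in seen:
            continue
        seen.add(perm)
        split, pos = [], 0
        for s in sizes:
            split.append(np.array(perm[pos:pos + s]))
            pos += s
        tot += 1
        if stat(split) >= obs - 1e-9:
            ge += 1
    return ge / tot


class TestUmbrellaTest:
    def test_perfect_umbrella_small_p(self):
        hours = [2.0, 6.0, 10.0, 14.0, 18.0, 22.0]
        means = {2: 1.0, 6: 2.0, 10: 3.0, 14: 4.0, 18: 3.0, 22: 2.0}
        classes = [means[h] + np.array([0.0, 0.001, -0.001]) for h in (2, 6, 10, 14, 18, 22)]
        pg = PhaseGroupedSeries("x", hours, classes)
        p, details = umbrella_rank_test(pg, return_details=True)
        assert p < 0.001
        assert min(details, key=details.get) == 14.0

    def test_constant_series_p_one(self):
        pg = PhaseGroupedSeries("x", [0, 8, 16], [np.ones(3)] * 3)
        assert umbrella_rank_test(pg) == 1.0

    def test_insufficient_data_errors(self):
        with pytest.raises(ValueError):
            umbrella_rank_test(PhaseGroupedSeries("x", [0, 12], [np.ones(3)] * 2))
        with pytest.raises(ValueError):
            umbrella_rank_test(
                PhaseGroupedSeries("x", [0, 8, 16], [np.ones(3), np.ones(1), np.ones(3)])
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_dp_equals_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 5))
        classes = [rng.normal(size=2) for _ in range(k)]
        for peak in range(k):
            w = rhythm._umbrella_weights(k, peak)
            assert rhythm._exact_p(classes, w) == pytest.approx(
                brute_force_umbrella_p(classes, w), abs=1e-12
            )

    def test_exact_with_ties_equals_enumeration(self):
        # tied data route through conditional enumeration
        classes = [np.array([1.0, 1.0]), np.array([2.0, 3.0]),
                   np.array([3.0, 2.0]), np.array([1.0, 2.0])]
        for peak in range(4):
            w = rhythm._umbrella_weights(4, peak)
            assert rhythm._single_phase_p(classes, w) == pytest.approx(
                brute_force_umbrella_p(classes, w), abs=1e-12
            )

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(8)
        sizes = (5, 4, 4, 4, 4, 4)
        classes = [rng.normal(size=s) for s in sizes]
        w = rhythm._umbrella_weights(6, 2)
        pe = rhythm._exact_p(classes, w)
        pn = rhythm._normal_p(classes, w)
        assert pn == pytest.approx(pe, abs=0.02)

    def test_phase_equivariance(self):
        """Rotating the class labels by one slot rotates the per-phase
        p-values and leaves the combined p unchanged."""
        rng = np.random.default_rng(4)
        hours = [2.0, 6.0, 10.0, 14.0, 18.0, 22.0]
        classes = [rng.lognormal(0, 0.3, 3) * m for m in (1, 2, 4, 3, 2, 1)]
        p1, d1 = umbrella_rank_test(PhaseGroupedSeries("x", hours, classes),
                                    return_details=True)
        rolled = classes[-1:] + classes[:-1]
        p2, d2 = umbrella_rank_test(PhaseGroupedSeries("x", hours, rolled),
                                    return_details=True)
        assert p1 == pytest.approx(p2)
        assert d1[14.0] == pytest.approx(d2[18.0])

    def test_power_monotone_in_fold_change(self, one_period_design):
        design = one_period_design
        t = np.arange(25) * 4.0
        clock = (6 + t) % 24
        hours = sorted(set(clock))
        rejections = []
        for f in (1.5, 2.0, 4.0, 8.0):
            rng = np.random.default_rng(100)
            truth = SignalTruth("x", 1.0, True, f, 16.0, 0.0)
            exp = diel_signal(t, truth, design)
            hits = 0
            for _ in range(40):
                med = np.median(
                    exp[:, None] * rng.lognormal(-0.02, 0.2, size=(25, 3)), axis=1
                )
                classes = [med[clock == h] for h in hours]
                p = umbrella_rank_test(PhaseGroupedSeries("x", hours, classes))
                hits += p < 0.05
            rejections.append(hits)
        assert all(b >= a for a, b in zip(rejections, rejections[1:]))


class TestBhFdr:
    def test_closed_form_example(self):
        q = bh_fdr([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == 0.2

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(50)
            q = bh_fdr(p)
            _, q_ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(q, q_ref)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, np.nan])
        with pytest.raises(ValueError):
            bh_fdr([1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_q_geq_p_and_permutation_invariant(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ps))
        q_perm = bh_fdr(np.asarray(ps)[perm])
        assert np.allclose(q_perm, q[perm])


class TestCosinor:
    def test_noiseless_recovery(self):
        t = np.arange(0, 96, 4.0)
        y = 5 + 2 * np.cos(2 * np.pi * (t - 12.0) / 24)  # peak at t=12 -> clock 18 if start 6
        fit = cosinor_fit(t, y)
        assert fit["peak_time"] == pytest.approx(12.0, abs=0.05)
        assert fit["amplitude"] == pytest.approx(2.0, rel=1e-9)
        assert fit["mesor"] == pytest.approx(5.0, rel=1e-9)

    def test_harmonics_two_grid_search(self):
        t = np.arange(0, 96, 4.0)
        y = 5 + 2 * np.cos(2 * np.pi * (t - 12.0) / 24) + 0.5 * np.cos(4 * np.pi * t / 24)
        fit = cosinor_fit(t, y, harmonics=2)
        assert fit["peak_time"] == pytest.approx(12.0, abs=0.2)

    def test_constant_flagged(self):
        t = np.arange(0, 96, 4.0)
        fit = cosinor_fit(t, np.full_like(t, 3.0))
        assert fit["amplitude"] == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(fit["peak_time"])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cosinor_fit(np.array([0, 4, 8, 8]), np.array([1, 2, 3, 3.0]))

    def test_rank_deficient(self):
        # period 24 sampled every 12 h: second harmonic is aliased
        t = np.arange(0, 120, 12.0)
        with pytest.raises(ValueError):
            cosinor_fit(t, np.sin(t), harmonics=2)

    def test_simulated_peak_error_within_half_interval(self, one_period_design):
        rng = np.random.default_rng(6)
        design = one_period_design
        t = np.arange(25) * 4.0
        errs = []
        for _ in range(60):
            peak = rng.uniform(0, 24)
            truth = SignalTruth("x", 10.0, True, 4.0, peak, 0.0)
            exp = diel_signal(t, truth, design)
            med = np.median(exp[:, None] * rng.lognormal(-0.02, 0.2, size=(25, 3)), axis=1)
            fit = cosinor_fit(t, med)
            est = (design.start_clock_hour + fit["peak_time"]) % 24
            errs.append(min(abs(est - peak), 24 - abs(est - peak)))
        assert np.median(errs) <= 2.0


class TestDailyFoldChange:
    def test_two_day_example(self):
        t = np.arange(0, 48, 4.0)
        y = np.ones_like(t)
        y[t < 24] = 4.0
        y[0], y[7] = 10.0, 4.0
        y[:6] = [10, 8, 6, 5, 4, 7]       # day 1: max 10 min 4
        y[6:12] = [12, 9, 8, 7, 6, 10]    # day 2: max 12 min 6
        fold, n, _ = daily_fold_change(t, y, samples_per_window=6)
        assert fold == pytest.approx((2.5 + 2.0) / 2)
        assert n == 2

    def test_constant_series(self):
        t = np.arange(0, 24, 4.0)
        fold, _, _ = daily_fold_change(t, np.full_like(t, 5.0), 6)
        assert fold == 1.0

    def test_noiseless_cosine_hits_extremes(self, one_period_design):
        truth = SignalTruth("x", 1.0, True, 4.0, 18.0, 0.0)
        t = np.arange(25) * 4.0
        y = diel_signal(t, truth, one_period_design)
        fold, n, _ = daily_fold_change(t, y, 6)
        assert fold == pytest.approx(4.0, abs=1e-9)
        assert n == 4

    def test_zero_minimum_windows_excluded(self):
        t = np.arange(0, 48, 4.0)
        y = np.ones_like(t)
        y[2] = 0.0  # first window has a zero minimum
        fold, n, n_zero = daily_fold_change(t, y, 6)
        assert n == 1 and n_zero == 1

    def test_no_complete_window(self):
        with pytest.raises(ValueError):
            daily_fold_change(np.array([0.0, 4.0]), np.array([1.0, 2.0]), 6)


class TestClassifySignals:
    def _study_values(self, design, truths, seed):
        rng = np.random.default_rng(seed)
        tp = design.time_points()
        rows, meta = [], []
        for _, cast in tp.iterrows():
            for rep in range(3):
                sid = f"t{cast['t_hours']}_r{rep}"
                meta.append({"sample_id": sid, "t_hours": cast["t_hours"],
                             "clock_hour": cast["clock_hour"], "period": cast["period"],
                             "replicate": rep})
                for tr in truths:
                    v = diel_signal(cast["t_hours"], tr, design)
                    noise = rng.lognormal(-0.011, 0.15) if tr.noise_cv else 1.0
                    rows.append({"signal_id": tr.signal_id, "sample_id": sid,
                                 "value": v * noise})
        return pd.DataFrame(rows), pd.DataFrame(meta)

    def test_empty_input(self):
        values = pd.DataFrame(columns=["signal_id", "sample_id", "value"])
        samples = pd.DataFrame(
            columns=["sample_id", "t_hours", "clock_hour", "period", "replicate"]
        )
        out = classify_signals(values, samples)
        assert out.empty

    def test_scopes_and_detection(self, design):
        truths = [SignalTruth("diel", 10.0, True, 6.0, 15.0, 0.15),
                  SignalTruth("flat", 10.0, False, 1.0, 0.0, 0.15)]
        values, samples = self._study_values(design, truths, seed=3)
        res = classify_signals(values, samples)
        assert set(res["scope"]) == {"1", "2", "both"}
        r1 = res[(res.scope == "1")].set_index("signal_id")
        assert bool(r1.loc["diel", "is_diel"])
        assert not bool(r1.loc["flat", "is_diel"])
        assert r1.loc["diel", "peak_hour"] == pytest.approx(15.0, abs=2.0)

    def test_timestamp_shift_equivariance(self, one_period_design):
        truths = [SignalTruth("diel", 10.0, True, 6.0, 15.0, 0.15)]
        values, samples = self._study_values(one_period_design, truths, seed=4)
        res1 = classify_signals(values, samples, scopes=["1"])
        shifted = samples.assign(clock_hour=(samples["clock_hour"] + 4) % 24)
        res2 = classify_signals(values, shifted, scopes=["1"])
        assert res1.loc[0, "p_raw"] == pytest.approx(res2.loc[0, "p_raw"])
        assert (res1.loc[0, "peak_hour"] + 4) % 24 == pytest.approx(
            res2.loc[0, "peak_hour"], abs=1e-6
        )

    def test_interval_must_divide_24(self):
        values = pd.DataFrame(columns=["signal_id", "sample_id", "value"])
        samples = pd.DataFrame(columns=["sample_id", "t_hours", "clock_hour",
                                        "period", "replicate"])
        with pytest.raises(ValueError):
            classify_signals(values, samples, interval=5.0)
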