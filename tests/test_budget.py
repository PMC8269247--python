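import numpy as np
import pandas as pd
import pytest

from dielmet.budget import (
    QuotaProfile,
    StoichiometryParams,
    composition_fraction,
    n2_fixation_fraction,
    net_turnover,
    o2_drawdown_adjust,
    quota_attribution,
    type2_regression,
)
from dielmet.quantify import CompoundInfo


class TestCompositionFraction:
    def test_worked_example(self):
        c = CompoundInfo("x", 12)
        pct_poc, pct_pn = composition_fraction(1000.0, c, poc_umol=3.5)
        assert pct_poc == pytest.approx(12e3 / 3.5e6 * 100)  # 0.3429%
        assert pct_pn == 0.0

    def test_nitrogen_free_pn_zero(self):
        c = CompoundInfo("x", 6, n_nitrogen=0)
        _, pct_pn = composition_fraction(500.0, c, poc_umol=3.5, pn_umol=0.44)
        assert pct_pn == 0.0

    def test_additivity(self):
        rng = np.random.default_rng(0)
        poc = 3.5
        compounds = [CompoundInfo(f"c{i}", int(rng.integers(1, 20))) for i in range(10)]
        concs = rng.lognormal(3, 1, 10)
        parts = sum(
            composition_fraction(cc, c, poc)[0] for cc, c in zip(concs, compounds)
        )
        pooled_c = sum(cc * c.n_carbon for cc, c in zip(concs, compounds))
        whole = composition_fraction(pooled_c, CompoundInfo("pool", 1), poc)[0]
        assert parts == pytest.approx(whole)

    def test_nonpositive_poc_rejected(self):
        with pytest.raises(ValueError):
            composition_fraction(1.0, CompoundInfo("x", 1), 0.0)
        with pytest.raises(ValueError):
            composition_fraction(1.0, CompoundInfo("x", 1, n_nitrogen=1), 3.5, 0.0)

    def test_linearity_in_concentration(self):
        c = CompoundInfo("x", 7, n_nitrogen=2)
        a = composition_fraction(100.0, c, 3.5, 0.44)
        b = composition_fraction(300.0, c, 3.5, 0.44)
        assert b[0] == pytest.approx(3 * a[0]) and b[1] == pytest.approx(3 * a[1])


def _median_table(series: dict[str, np.ndarray], times: np.ndarray) -> pd.DataFrame:
    rows = []
    for name, vals in series.items():
        for t, v in zip(times, vals):
            rows.append({"compound": name, "t_hours": t, "value": v})
    return pd.DataFrame(rows)


class TestNetTurnover:
    def test_trehalose_example(self):
        t = np.arange(0, 48, 4.0)
        y = np.ones_like(t) * 4.0
        y[3], y[9] = 10.0, 10.0  # daily swings 6 and 6
        med = _median_table({"trehalose": y}, t)
        info = {"trehalose": CompoundInfo("trehalose", 12)}
        table, totals = net_turnover(med, info, samples_per_window=6)
        row = table.iloc[0]
        assert row["swing_pmol"] == pytest.approx(6.0)
        assert row["carbon_flux_pmol"] == pytest.approx(72.0)
        assert totals["total_carbon_nmol"] == pytest.approx(0.072)

    def test_constant_zero_flux(self):
        t = np.arange(0, 24, 4.0)
        med = _median_table({"c": np.full_like(t, 5.0)}, t)
        table, _ = net_turnover(med, {"c": CompoundInfo("c", 3)}, 6)
        assert table.iloc[0]["swing_pmol"] == 0.0

    def test_total_equals_sum_of_parts(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 96, 4.0)
        series, infos = {}, {}
        for i in range(10):
            name = f"c{i}"
            series[name] = rng.lognormal(2, 0.5, len(t))
            infos[name] = CompoundInfo(name, int(rng.integers(1, 25)),
                                       n_nitrogen=int(rng.integers(0, 4)))
        table, totals = net_turnover(_median_table(series, t), infos, 6)
        assert totals["total_carbon_nmol"] == pytest.approx(
            table["carbon_flux_pmol"].sum() / 1e3
        )
        assert totals["total_nitrogen_nmol"] == pytest.approx(
            table["nitrogen_flux_pmol"].sum() / 1e3
        )

    def test_include_subset(self):
        t = np.arange(0, 24, 4.0)
        series = {"a": np.array([1, 2, 3, 2, 1, 1.0]), "b": np.array([5, 6, 5, 5, 6, 5.0])}
        infos = {"a": CompoundInfo("a", 10), "b": CompoundInfo("b", 10)}
        table, totals = net_turnover(_median_table(series, t), infos, 6, include=["a"])
        assert totals["total_carbon_nmol"] == pytest.approx(2 * 10 / 1e3)
        assert set(table.loc[table["included"], "compound"]) == {"a"}

    def test_incomplete_window_skipped(self):
        t = np.arange(0, 12, 4.0)
        med = _median_table({"c": np.array([1, 2, 3.0])}, t)
        table, _ = net_turnover(med, {"c": CompoundInfo("c", 1)}, 6)
        assert table.empty

    def test_scaling_linearity(self):
        t = np.arange(0, 48, 4.0)
        rng = np.random.default_rng(2)
        y = rng.lognormal(1, 0.5, len(t))
        infos = {"c": CompoundInfo("c", 5)}
        _, t1 = net_turnover(_median_table({"c": y}, t), infos, 6)
        _, t3 = net_turnover(_median_table({"c": 3 * y}, t), infos, 6)
        assert t3["total_carbon_nmol"] == pytest.approx(3 * t1["total_carbon_nmol"])


class TestQuotaAttribution:
    def test_printed_inputs_product(self):
        # 0.8 fmol/cell x 0.16e6 cells/L = 128 pmol/L
        prof = QuotaProfile("croco", 0.8, 0.07, np.array([0.16e6]))
        out = quota_attribution(np.array([100.0]), prof)
        assert out["predicted_high"][0] == pytest.approx(128.0)
        assert out["predicted_low"][0] == pytest.approx(0.07 * 0.16e6 * 1e-3)

    def test_zero_pool_zero_quota(self):
        prof = QuotaProfile("croco", 0.8, 0.07, np.array([1e6]))
        out = quota_attribution(np.array([0.0]), prof)
        assert out["field_quota_fmol"][0] == 0.0

    def test_zero_abundance_flagged_nan(self):
        prof = QuotaProfile("croco", 0.8, 0.07, np.array([0.0]))
        out = quota_attribution(np.array([10.0]), prof)
        assert np.isnan(out["field_quota_fmol"][0])

    def test_round_trip(self):
        rng = np.random.default_rng(3)
        cells = rng.lognormal(12, 0.3, 25)
        quota = 0.42  # fmol/cell
        pool = cells * quota * 1e-3
        prof = QuotaProfile("croco", 0.8, 0.07, cells)
        out = quota_attribution(pool, prof)
        assert np.allclose(out["field_quota_fmol"], quota)

    def test_per_carbon_units(self):
        # 100 pmol/L of a 342.3 g/mol compound in 1 ugC/L biomass
        prof = QuotaProfile("croco", 0.8, 0.07, np.array([1e6]),
                            ugC_per_L=np.array([1.0]))
        out = quota_attribution(np.array([100.0]), prof, molar_mass=342.3)
        # 100 pmol * 342.3 g/mol = 34.23 ng = 3.423e-5 mg; / 1e-6 gC = 34.23 mg/gC
        assert out["per_carbon_mg_gC"][0] == pytest.approx(34.23)


class TestN2FixationFraction:
    def test_paper_adjustment_pair(self):
        # 9% unadjusted with 60% O2 drawdown -> 3.6% exactly; 28% -> 11.2% (~printed 11)
        assert o2_drawdown_adjust(9.0, 0.60) == pytest.approx(3.6)
        adj = o2_drawdown_adjust(28.0, 0.60)
        assert adj == pytest.approx(11.2)
        assert round(adj) == 11

    def test_zero_drawdown_identity(self):
        params = StoichiometryParams(f_o2_drawdown=0.0)
        un, adj = n2_fixation_fraction(1e-12, 1e-10, params)
        assert adj == un

    def test_min_of_constraints_hand_computed(self):
        params = StoichiometryParams(atp_per_glucose=30.0, electrons_per_glucose=24.0,
                                     f_o2_drawdown=0.0)
        swing, rate = 2.0e-12, 5.0e-11
        glucose = swing * 2.0
        by_atp = glucose * 30.0 / 16.0
        by_e = glucose * 24.0 / 8.0
        expect = 100 * min(by_atp, by_e) / rate
        un, _ = n2_fixation_fraction(swing, rate, params)
        assert un == pytest.approx(expect)
        assert by_atp < by_e  # ATP is binding with these defaults

    def test_monotonicity_and_adjustment_bound(self):
        params = StoichiometryParams()
        u1, a1 = n2_fixation_fraction(1e-12, 1e-10, params)
        u2, a2 = n2_fixation_fraction(2e-12, 1e-10, params)
        u3, _ = n2_fixation_fraction(1e-12, 2e-10, params)
        assert u2 > u1 > u3
        assert a1 <= u1 and a2 <= u2
        assert a1 / u1 == pytest.approx(0.4)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            n2_fixation_fraction(1e-12, 0.0)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            StoichiometryParams(f_o2_drawdown=1.0)
        with pytest.raises(ValueError):
            StoichiometryParams(atp_per_n2=-1)


class TestType2Regression:
    def test_exact_line(self):
        x = np.array([0, 1, 2, 3, 4.0])
        slope, intercept, r = type2_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_swap_inverts_slope(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        y = 1.5 * x + rng.normal(0, 0.3, 30)
        s_xy, _, _ = type2_regression(x, y)
        s_yx, _, _ = type2_regression(y, x)
        assert s_xy == pytest.approx(1 / s_yx)

    def test_matches_geometric_mean_regression(self):
        rng = np.random.default_rng(5)
        x = rng.normal(2, 1, 50)
        y = -0.8 * x + rng.normal(0, 0.5, 50)
        slope, intercept, r = type2_regression(x, y)
        # GMR slope = sign(r) * sqrt(Syy/Sxx)
        expect = np.sign(np.corrcoef(x, y)[0, 1]) * np.sqrt(np.var(y, ddof=1) / np.var(x, ddof=1))
        assert slope == pytest.approx(expect)
        assert intercept == pytest.approx(y.mean() - expect * x.mean())

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            type2_regression([1, 1, 1], [1, 2, 3])
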