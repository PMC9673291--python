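"""Partitioned-survival engine: occupancy, accounting, incremental results.

The heavy checks run against ``_brute_force``, a deliberately naive
cycle-by-cycle pure-Python re-implementation of the accounting conventions,
kept independent of the vectorised engine code path.
"""

import math

import numpy as np
import pytest

from psmcea.engine import (
    AdverseEvent,
    EconSettings,
    RegimenComponent,
    StrategyDefinition,
    StrategyTotals,
    annual_to_cycle_probability,
    cea_from_totals,
    compare,
    drug_cost_per_cycle,
    per_cycle_discount,
    run_trace,
)


class SeqModel:
    """Survival stub returning tabulated values at the cycle grid."""

    def __init__(self, values, cycle_months):
        self.values = np.asarray(values, dtype=float)
        self.cycle_months = cycle_months

    def survival_at(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.rint(t / self.cycle_months).astype(int)
        return self.values[np.clip(idx, 0, len(self.values) - 1)]


def _strategy(s_pfs, s_os, settings, **kw):
    base = dict(
        name="toy",
        pfs_model=SeqModel(s_pfs, settings.cycle_months),
        os_model=SeqModel(s_os, settings.cycle_months),
        drug_cost_per_cycle=0.0,
        admin_cost_per_cycle=0.0,
        followup_cost_per_cycle=0.0,
        subsequent_cost_per_cycle=0.0,
        treatment_cap_cycles=None,
        ae_profile=(),
    )
    base.update(kw)
    return StrategyDefinition(**base)


def _brute_force(s_pfs, s_os, settings, strategy):
    """Naive per-cycle accumulation of every discounted flow."""
    r = settings.discount_per_cycle
    cost = 0.0
    qaly = 0.0
    ly = 0.0
    for k in range(1, settings.horizon_cycles + 1):
        def occ(i):
            pfs = min(s_pfs[i], s_os[i])
            return pfs, s_os[i] - pfs
        pfs_k, pp_k = occ(k)
        if settings.half_cycle_correction:
            pfs_prev, pp_prev = occ(k - 1)
            pfs_i = 0.5 * (pfs_prev + pfs_k)
            pp_i = 0.5 * (pp_prev + pp_k)
        else:
            pfs_i, pp_i = pfs_k, pp_k
        alive_i = pfs_i + pp_i
        new_d = (1 - s_os[k]) - (1 - s_os[k - 1])
        disc = (1.0 + r) ** (-k)
        on = 1.0
        if strategy.treatment_cap_cycles is not None and k > strategy.treatment_cap_cycles:
            on = 0.0
        w = min(max(settings.ae_window_cycles - (k - 1), 0.0), 1.0)
        ae_cost = sum(a.per_cycle_probability * a.cost_per_event for a in strategy.ae_profile)
        ae_du = sum(a.per_cycle_probability * (-a.disutility) for a in strategy.ae_profile)
        cost += (
            (strategy.drug_cost_per_cycle + strategy.admin_cost_per_cycle) * pfs_i * on
            + strategy.followup_cost_per_cycle * alive_i
            + strategy.subsequent_cost_per_cycle * pp_i
            + ae_cost * pfs_i * w
            + settings.end_of_life_cost * new_d
        ) * disc
        qaly += (
            (settings.utility_pfs * pfs_i + settings.utility_pp * pp_i - ae_du * pfs_i * w)
            * settings.cycle_years * disc
        )
        ly += alive_i * settings.cycle_years * disc
    return cost, qaly, ly


class TestConversions:
    def test_published_discount_conversion(self):
        """5%/yr at a 3-week cycle is 0.28% per cycle after rounding."""
        rate = per_cycle_discount(0.05, 3.0)
        assert rate == pytest.approx((1.05) ** (3 / 52) - 1, rel=1e-12)
        assert round(rate * 100, 2) == 0.28

    def test_zero_rate(self):
        assert per_cycle_discount(0.0, 3.0) == 0.0

    def test_identity_at_one_year(self):
        assert per_cycle_discount(0.05, 52.0) == pytest.approx(0.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            per_cycle_discount(-0.01, 3.0)

    @pytest.mark.parametrize(
        "annual, expected",
        [(0.23, 0.0132), (0.125, 0.0072), (0.0, 0.0)],
    )
    def test_ae_probability_conversion(self, annual, expected):
        cycles_per_year = 365.0 / 21.0  # 17.38 three-week cycles
        assert round(
            annual_to_cycle_probability(annual, cycles_per_year), 4
        ) == pytest.approx(expected)

    def test_incidence_above_one_rejected(self):
        with pytest.raises(ValueError):
            annual_to_cycle_probability(1.2, 17.38)


class TestDrugCost:
    def test_flat_iv_whole_vials(self):
        comp = RegimenComponent(
            drug="sintilimab", kind="flat_iv", unit_mg=100, unit_price=166.92,
            dose_mg=200,
        )
        assert drug_cost_per_cycle([comp]) == pytest.approx(333.84)

    def test_oral_daily(self):
        comp = RegimenComponent(
            drug="lenvatinib", kind="oral_daily", unit_mg=4, unit_price=16.69,
            mg_per_day=12,
        )
        assert drug_cost_per_cycle([comp], days_per_cycle=21) == pytest.approx(
            3 * 21 * 16.69
        )

    def test_weight_based_with_wastage(self):
        comp = RegimenComponent(
            drug="bevacizumab_biosimilar", kind="weight_iv", unit_mg=100,
            unit_price=177.13, mg_per_kg=15,
        )
        # 65 kg * 15 mg/kg = 975 mg -> 10 whole vials
        assert drug_cost_per_cycle([comp], body_weight_kg=65) == pytest.approx(
            10 * 177.13
        )

    def test_halved_dose_scenario(self):
        comp = RegimenComponent(
            drug="bevacizumab_biosimilar", kind="weight_iv", unit_mg=100,
            unit_price=177.13, mg_per_kg=7.5,
        )
        # 487.5 mg -> 5 vials
        assert drug_cost_per_cycle([comp], body_weight_kg=65) == pytest.approx(
            5 * 177.13
        )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            RegimenComponent(
                drug="x", kind="weekly", unit_mg=100, unit_price=1.0
            )


class TestTrace:
    def test_unit_utilities_no_discount_qaly_equals_ly(self):
        settings = EconSettings(
            horizon_cycles=10, annual_discount=0.0, utility_pfs=1.0,
            utility_pp=1.0, end_of_life_cost=0.0,
        )
        s_os = np.linspace(1, 0.3, 11)
        s_pfs = s_os * np.linspace(1, 0.5, 11)
        trace = run_trace(_strategy(s_pfs, s_os, settings), settings)
        assert trace.total_qaly == pytest.approx(trace.total_ly, abs=1e-12)

    def test_identical_curves_no_post_progression(self):
        settings = EconSettings(horizon_cycles=8, end_of_life_cost=0.0)
        s = np.linspace(1, 0.2, 9)
        trace = run_trace(
            _strategy(s, s, settings, subsequent_cost_per_cycle=500.0), settings
        )
        assert np.all(trace.pp_occupancy == 0)
        assert trace.cost_by_category["subsequent"].sum() == 0.0

    def test_two_cycle_toy_hand_computed(self):
        """S_PFS = {1, .5, .25}, S_OS = {1, .8, .5}, u = (0.745, 0.678),
        no discounting: per-cycle QALY matches the hand calculation."""
        settings = EconSettings(
            horizon_cycles=2, annual_discount=0.0, end_of_life_cost=0.0,
        )
        trace = run_trace(
            _strategy([1, 0.5, 0.25], [1, 0.8, 0.5], settings), settings
        )
        cy = settings.cycle_years
        expected = [
            0.0,
            (0.745 * 0.5 + 0.678 * 0.3) * cy,
            (0.745 * 0.25 + 0.678 * 0.25) * cy,
        ]
        assert np.allclose(trace.qaly, expected, atol=1e-15)
        assert np.allclose(trace.pp_occupancy, [0.0, 0.3, 0.25])

    def test_occupancy_conservation(self, fitted_model, config):
        from psmcea.config import build_settings, build_strategies

        settings = build_settings(config)
        for strat in build_strategies(config, fitted_model["selected"]):
            tr = run_trace(strat, settings)
            total = tr.pfs_occupancy + tr.pp_occupancy + tr.dead_occupancy
            assert np.max(np.abs(total - 1.0)) <= 1e-12
            assert np.all(np.diff(tr.dead_occupancy) >= -1e-15)
            assert np.all(tr.pp_occupancy >= 0)

    def test_pfs_above_os_capped_and_flagged(self):
        settings = EconSettings(horizon_cycles=3, end_of_life_cost=0.0)
        trace = run_trace(
            _strategy([1, 0.9, 0.8, 0.7], [1, 0.7, 0.6, 0.5], settings), settings
        )
        assert trace.warnings  # excess 0.2 > 0.05 tolerance
        total = trace.pfs_occupancy + trace.pp_occupancy + trace.dead_occupancy
        assert np.max(np.abs(total - 1.0)) <= 1e-12

    def test_brute_force_oracle_agreement(self):
        """Vectorised engine totals match a naive per-cycle loop to 1e-9 on a
        toy strategy exercising every flow (cap, AE window, end-of-life,
        discounting), with and without half-cycle correction."""
        h = 40
        s_os = np.exp(-0.05 * np.arange(h + 1))
        s_pfs = np.exp(-0.12 * np.arange(h + 1))
        for hcc in (False, True):
            settings = EconSettings(
                horizon_cycles=h, annual_discount=0.05, end_of_life_cost=2132.67,
                half_cycle_correction=hcc,
            )
            strategy = _strategy(
                s_pfs, s_os, settings,
                drug_cost_per_cycle=2105.14,
                admin_cost_per_cycle=10.18,
                followup_cost_per_cycle=125.26,
                subsequent_cost_per_cycle=442.29,
                treatment_cap_cycles=12,
                ae_profile=(
                    AdverseEvent("hypertension", 0.0072, 3.42, -0.12),
                    AdverseEvent("platelets", 0.0033, 176.55, 0.0),
                ),
            )
            trace = run_trace(strategy, settings)
            cost, qaly, ly = _brute_force(s_pfs, s_os, settings, strategy)
            assert trace.total_cost == pytest.approx(cost, abs=1e-9)
            assert trace.total_qaly == pytest.approx(qaly, abs=1e-9)
            assert trace.total_ly == pytest.approx(ly, abs=1e-9)

    def test_qaly_bounded_by_ly(self, fitted_model, config):
        from psmcea.config import build_settings, build_strategies

        settings = build_settings(config)
        strat, _ = build_strategies(config, fitted_model["selected"])
        tr = run_trace(strat, settings)
        assert tr.total_qaly < tr.total_ly

    def test_discount_monotonicity(self, fitted_model, config):
        from psmcea.config import build_settings, build_strategies

        strat, _ = build_strategies(config, fitted_model["selected"])
        totals = []
        for annual in (0.0, 0.03, 0.05, 0.08):
            settings = EconSettings(horizon_cycles=300, annual_discount=annual)
            tr = run_trace(strat, settings)
            totals.append((tr.total_cost, tr.total_qaly))
        costs, qalys = zip(*totals)
        assert list(costs) == sorted(costs, reverse=True)
        assert list(qalys) == sorted(qalys, reverse=True)

    def test_horizon_convergence(self, fitted_model, config):
        """Totals move by < 0.1% under a horizon extension once alive
        occupancy is below 0.1% — the operational meaning of 'lifetime'.
        The heavy log-normal tail keeps a sliver of the cohort alive past
        the default horizon, so the qualifying horizon is located first."""
        from psmcea.config import build_settings, build_strategies

        base = build_settings(config)
        strat, _ = build_strategies(config, fitted_model["selected"])
        h = base.horizon_cycles
        while True:
            t_h = h * base.cycle_months
            if strat.os_model.survival_at(t_h) < 0.001:
                break
            h += 100
        tr = run_trace(strat, EconSettings(horizon_cycles=h))
        assert tr.pfs_occupancy[-1] + tr.pp_occupancy[-1] < 0.001
        tr2 = run_trace(strat, EconSettings(horizon_cycles=h + 200))
        assert abs(tr2.total_cost - tr.total_cost) / tr.total_cost < 0.001
        assert abs(tr2.total_qaly - tr.total_qaly) / tr.total_qaly < 0.001


class TestIncremental:
    def test_published_totals_arithmetic(self):
        """Increments recomputed from the printed per-arm totals."""
        res = cea_from_totals(
            StrategyTotals("sintilimab_bevacizumab", 33102.0, 1.431, 2.04),
            StrategyTotals("lenvatinib", 21037.0, 0.938, 1.32),
        )
        assert res.delta_cost == pytest.approx(12065.0)
        assert res.delta_qaly == pytest.approx(0.493)
        assert res.icer == pytest.approx(24462.0, rel=1e-3)

    def test_identical_traces_undefined(self):
        a = StrategyTotals("a", 100.0, 1.0, 1.2)
        b = StrategyTotals("b", 100.0, 1.0, 1.2)
        res = cea_from_totals(a, b)
        assert res.icer is None and res.label == "undefined"

    def test_dominance_labels(self):
        res = cea_from_totals(
            StrategyTotals("a", 90.0, 1.2, 1.4), StrategyTotals("b", 100.0, 1.0, 1.2)
        )
        assert res.label == "dominant"
        res = cea_from_totals(
            StrategyTotals("a", 110.0, 0.9, 1.0), StrategyTotals("b", 100.0, 1.0, 1.2)
        )
        assert res.label == "dominated"

    def test_compare_wraps_traces(self):
        settings = EconSettings(horizon_cycles=5, end_of_life_cost=0.0)
        s_os = np.linspace(1, 0.5, 6)
        s_pfs = np.linspace(1, 0.25, 6)
        t1 = run_trace(
            _strategy(s_pfs, s_os, settings, name="a", drug_cost_per_cycle=100.0),
            settings,
        )
        t2 = run_trace(_strategy(s_pfs, s_os, settings, name="b"), settings)
        res = compare(t1, t2)
        assert res.delta_qaly == 0.0
        assert res.label == "undefined"
        assert res.delta_cost > 0
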