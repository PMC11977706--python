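"""Adjacent-system surplus changes, attribution, shares, boundary counts."""

import numpy as np
import pytest

from cafebudget.budget_engine import (
    BudgetContractError,
    SurplusRate,
    SystemBudget,
    system_budget,
)
from cafebudget.cross_system import (
    PBThresholds,
    county_share_metrics,
    largest_change_system,
    pb_exceedance,
    surplus_change,
)
from cafebudget.flow_model import CafeSystem, Nutrient
from cafebudget.synthetic_data import SyntheticConfig, generate


def _budget(inputs, outputs, system=CafeSystem.Cropping, unit="X", nutrient=Nutrient.N):
    return SystemBudget(unit_id=unit, year=2019, nutrient=nutrient, system=system,
                        inputs=inputs, productive_outputs=outputs)


class TestSurplusChange:
    def test_food_to_ecosystem_2019(self, fixture_table):
        eco = system_budget(fixture_table, "WATERSHED", 2019, "N", CafeSystem.Ecosystem)
        food = system_budget(fixture_table, "WATERSHED", 2019, "N", CafeSystem.Food)
        assert surplus_change(eco, food).delta == pytest.approx(185e6)

    def test_identical_budgets_zero(self):
        a = _budget(10.0, 5.0, CafeSystem.Cropping)
        b = _budget(10.0, 5.0, CafeSystem.AnimalCrop)
        assert surplus_change(b, a).delta == 0.0

    def test_non_adjacent_rejected(self):
        a = _budget(10.0, 5.0, CafeSystem.Cropping)
        b = _budget(10.0, 5.0, CafeSystem.Food)
        with pytest.raises(BudgetContractError):
            surplus_change(b, a)

    def test_temporal_change_ecosystem(self, fixture_table):
        # same system, different periods: 477 - 410 = +67 Gg
        s19 = system_budget(fixture_table, "WATERSHED", 2019, "N", CafeSystem.Ecosystem).surplus
        s85 = system_budget(fixture_table, "WATERSHED", 1985, "N", CafeSystem.Ecosystem).surplus
        assert (s19 - s85) / 1e6 == pytest.approx(67.0)


class TestLargestChange:
    def test_watershed_2019_n_attribution(self, fixture_table):
        budgets = {
            s: system_budget(fixture_table, "WATERSHED", 2019, "N", s) for s in CafeSystem
        }
        # candidates are {92, 138, 62, 185} Gg -> Ecosystem
        assert largest_change_system(budgets) is CafeSystem.Ecosystem

    def test_no_positive_candidate(self):
        budgets = {s: _budget(0.0, 10.0, s) for s in CafeSystem}
        assert largest_change_system(budgets) is None

    def test_tie_breaks_upstream(self):
        # Cropping surplus 5 and an equal +5 jump at Food -> Cropping wins
        budgets = {
            CafeSystem.Cropping: _budget(10.0, 5.0, CafeSystem.Cropping),
            CafeSystem.AnimalCrop: _budget(10.0, 5.0, CafeSystem.AnimalCrop),
            CafeSystem.Food: _budget(15.0, 5.0, CafeSystem.Food),
            CafeSystem.Ecosystem: _budget(15.0, 5.0, CafeSystem.Ecosystem),
        }
        assert largest_change_system(budgets) is CafeSystem.Cropping

    def test_missing_system_rejected(self):
        budgets = {CafeSystem.Cropping: _budget(1.0, 0.0)}
        with pytest.raises(BudgetContractError):
            largest_change_system(budgets)

    def test_matches_bruteforce_argmax_on_random_cohorts(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            surpluses = rng.normal(0.0, 10.0, size=4)
            budgets = {
                s: _budget(float(v), 0.0, s) for s, v in zip(CafeSystem, surpluses)
            }
            # independent oracle: explicit candidate enumeration
            cands = [
                (CafeSystem.Cropping, surpluses[0]),
                (CafeSystem.AnimalCrop, surpluses[1] - surpluses[0]),
                (CafeSystem.Food, surpluses[2] - surpluses[1]),
                (CafeSystem.Ecosystem, surpluses[3] - surpluses[2]),
            ]
            pos = [(s, d) for s, d in cands if d > 0]
            expected = max(pos, key=lambda t: t[1])[0] if pos else None
            assert largest_change_system(budgets) is expected


class TestCountyShares:
    def test_hand_enumerated_three_quarters(self):
        budgets = []
        for i, (sc, sa) in enumerate(zip([1.0, 1.0, 1.0, 10.0], [4.0, 4.0, 4.0, 4.0])):
            budgets.append(_budget(sc, 0.0, CafeSystem.Cropping, unit=f"c{i}"))
            budgets.append(_budget(sa, 0.0, CafeSystem.AnimalCrop, unit=f"c{i}"))
        out = county_share_metrics(budgets)
        row = out[out.downstream_system == "Animal-crop"].iloc[0]
        assert row.pct_surplus_lt_half == pytest.approx(75.0)

    def test_identical_systems_zero_share(self):
        budgets = []
        for i in range(5):
            for s in (CafeSystem.Cropping, CafeSystem.AnimalCrop):
                budgets.append(_budget(3.0, 1.0, s, unit=f"c{i}"))
        out = county_share_metrics(budgets)
        assert out.pct_surplus_lt_half.iloc[0] == 0.0

    def test_invariance_to_order_and_scale(self):
        rng = np.random.default_rng(3)
        budgets = []
        for i in range(12):
            for s in CafeSystem:
                budgets.append(
                    _budget(float(rng.uniform(1, 10)), float(rng.uniform(0, 5)), s, unit=f"c{i}")
                )
        base = county_share_metrics(budgets)
        shuffled = list(budgets)
        rng.shuffle(shuffled)
        scaled = [
            SystemBudget(b.unit_id, b.year, b.nutrient, b.system,
                         b.inputs * 7.5, b.productive_outputs * 7.5)
            for b in shuffled
        ]
        again = county_share_metrics(scaled)
        for col in ("pct_surplus_lt_half", "pct_efficiency_gt"):
            assert np.allclose(base[col].values, again[col].values)

    def test_matches_bruteforce_on_small_cohorts(self):
        for seed in range(100):
            table = generate(SyntheticConfig(n_counties=6, years=(2019, 2019), seed=seed,
                                             noise_cv=0.1))
            budgets = [
                system_budget(table, c, 2019, n, s)
                for c in table.county_ids
                for n in Nutrient
                for s in CafeSystem
            ]
            out = county_share_metrics(budgets)
            # brute force for the N / Animal-crop cell
            sc = {c: system_budget(table, c, 2019, "N", CafeSystem.Cropping).surplus
                  for c in table.county_ids}
            sa = {c: system_budget(table, c, 2019, "N", CafeSystem.AnimalCrop).surplus
                  for c in table.county_ids}
            brute = 100.0 * sum(sc[c] < 0.5 * sa[c] for c in sc) / len(sc)
            row = out[(out.nutrient == "N") & (out.downstream_system == "Animal-crop")]
            assert row.pct_surplus_lt_half.iloc[0] == pytest.approx(brute)


class TestPBExceedance:
    def _rate(self, v, nutrient=Nutrient.N, unit="X"):
        return SurplusRate(unit, 2019, nutrient, CafeSystem.Cropping, v, v / 5.0)

    def test_direct_counts(self):
        rates = [self._rate(v) for v in (10.0, 16.0, 30.0)]
        out = pb_exceedance(rates)
        assert out["n_exceed_us"] == 2
        assert out["n_exceed_global"] == 1

    def test_boundary_is_strict(self):
        out = pb_exceedance([self._rate(24.0)])
        assert out["n_exceed_global"] == 0

    def test_p_within_upper_bound(self):
        rates = [self._rate(v, Nutrient.P) for v in (1.0, 7.0, 3.0)]
        assert pb_exceedance(rates)["p_within_upper"] == 2

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            PBThresholds(n_global=10.0, n_us=15.0)


def test_telescoping_deltas(fixture_table):
    # Cropping surplus plus the three adjacent deltas equals Ecosystem surplus
    for year in (1985, 2019):
        for nutrient in Nutrient:
            b = {s: system_budget(fixture_table, "WATERSHED", year, nutrient, s)
                 for s in CafeSystem}
            total = b[CafeSystem.Cropping].surplus + sum(
                surplus_change(b[hi], b[lo]).delta
                for lo, hi in zip(list(CafeSystem)[:-1], list(CafeSystem)[1:])
            )
            assert total == pytest.approx(b[CafeSystem.Ecosystem].surplus, rel=1e-12)
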