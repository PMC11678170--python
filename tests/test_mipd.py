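"""Regimen grid, clone simulation, decision rules, cost, exposure window."""

import numpy as np
import pytest

from sckmipd.errors import InsufficientDataError, InvalidInputError
from sckmipd.estimation import ConditionalSample
from sckmipd.mipd import (
    ProbabilityEntry,
    ProbabilityTable,
    Regimen,
    annual_cost,
    candidate_regimens,
    classify,
    exposure_response_window,
    optimization_rank,
    probability_target,
    recommend_patient,
    regimen_doses,
    select_regimen,
    simulate_clones,
)
from sckmipd.model import simulate
from sckmipd.population import individual_from_etas


def clone_set(pop, etas_list, pasi_obs0=11.6, tolerance=False):
    draws = [individual_from_etas(pop, 70.0, pasi_obs0, e, tolerance) for e in etas_list]
    etas = np.zeros((len(draws), 1))
    return ConditionalSample(draws, etas, ("kout",), 1.0, None, {})


class TestRegimen:
    def test_label_roundtrip(self):
        for reg in candidate_regimens():
            assert Regimen.from_label(reg.label) == reg

    def test_validation(self):
        with pytest.raises(InvalidInputError):
            Regimen(200.0, 4)
        with pytest.raises(InvalidInputError):
            Regimen(300.0, 3)
        with pytest.raises(InvalidInputError):
            Regimen(150.0, 2)
        with pytest.raises(InvalidInputError):
            Regimen.from_label("junk")

    def test_derived_quantities(self):
        r = Regimen(300.0, 5)
        assert r.tau_days == 35.0
        assert r.label == "300 q5w"
        assert r.annualized_dose == pytest.approx(300.0 * 365.0 / 35.0)

    def test_grid(self):
        grid = candidate_regimens()
        assert len(grid) == 7
        labels = [r.label for r in grid]
        assert "150 q2w" not in labels
        assert labels[0] == "300 q2w"
        ann = [r.annualized_dose for r in grid]
        assert ann == sorted(ann, reverse=True)

    def test_optimization_rank_ordering(self):
        # fewer mg/year is more optimized; ties go to the longer interval
        assert optimization_rank(Regimen(150.0, 6)) < optimization_rank(Regimen(150.0, 4))
        assert optimization_rank(Regimen(150.0, 4)) < optimization_rank(Regimen(300.0, 6))
        assert optimization_rank(Regimen(300.0, 4)) < optimization_rank(Regimen(300.0, 2))

    def test_regimen_doses(self):
        doses = regimen_doses(Regimen(300.0, 4), 3, start=10.0)
        assert [d.time for d in doses] == [10.0, 38.0, 66.0]
        assert all(d.amount == 300.0 for d in doses)


class TestProbabilityTarget:
    def test_inclusive_threshold(self):
        assert probability_target([0.5, 1.0, 1.5, 2.0]) == 50.0

    def test_empty(self):
        with pytest.raises(InvalidInputError):
            probability_target([])


class TestSimulateClones:
    def test_degenerate_clones_match_direct_simulation(self, pop):
        clones = clone_set(pop, [{} for _ in range(5)])
        cur, cand = Regimen(300.0, 4), Regimen(300.0, 5)
        out = simulate_clones(clones, cur, cand, n_cycles_each=10, dt_max=0.25)
        assert out.n_failed == 0
        assert np.all(out.pasi_c20 == out.pasi_c20[0])
        t_switch = 10 * cur.tau_days
        t_end = t_switch + 10 * cand.tau_days
        doses = regimen_doses(cur, 10) + regimen_doses(cand, 10, start=t_switch)
        ref = simulate(clones.draws[0], doses, np.array([t_switch, t_end]), dt_max=0.25)
        assert out.pasi_c10[0] == pytest.approx(ref.pasi[0], rel=1e-9)
        assert out.pasi_c20[0] == pytest.approx(ref.pasi[1], rel=1e-9)
        assert out.ctrough_c20[0] == pytest.approx(ref.conc[1], rel=1e-9)

    def test_empty_clone_set(self, pop):
        with pytest.raises(InvalidInputError):
            simulate_clones(clone_set(pop, []), Regimen(300.0, 4), Regimen(300.0, 5))


def table_for(qualifying, current="300 q4w", p_hi=95.0, p_lo=50.0):
    entries = [
        ProbabilityEntry(
            regimen=r,
            p_cycle10=p_lo,
            p_cycle20=p_hi if r.label in qualifying else p_lo,
            median_pasi=1.0,
            median_ctrough=30.0,
        )
        for r in candidate_regimens()
    ]
    return ProbabilityTable("x", entries), Regimen.from_label(current)


class TestDecisionRules:
    def test_classify(self):
        cur = Regimen(300.0, 4)
        assert classify(cur, None) == "no_target"
        assert classify(cur, cur) == "maintained"
        assert classify(cur, Regimen(300.0, 5)) == "optimized"
        assert classify(cur, Regimen(300.0, 2)) == "intensified"
        assert classify(cur, Regimen(150.0, 4)) == "optimized"

    def test_none_qualifying(self):
        table, cur = table_for(set())
        rec = select_regimen(table, cur)
        assert rec.classification == "no_target"
        assert rec.selected is None and rec.probability is None

    def test_most_optimized_wins(self):
        table, cur = table_for({"300 q4w", "300 q5w"})
        rec = select_regimen(table, cur)
        assert rec.selected == Regimen(300.0, 5)
        assert rec.classification == "optimized"

    def test_interval_tie_break_via_rank(self):
        # 150 q6w is the most optimized candidate overall
        table, cur = table_for({lab.label for lab in candidate_regimens()})
        rec = select_regimen(table, cur)
        assert rec.selected == Regimen(150.0, 6)

    def test_intensification(self):
        table, cur = table_for({"300 q2w"})
        rec = select_regimen(table, cur)
        assert rec.selected == Regimen(300.0, 2)
        assert rec.classification == "intensified"

    def test_incomplete_table(self):
        table, cur = table_for({"300 q4w"})
        table.entries = table.entries[:-1]
        with pytest.raises(InvalidInputError):
            select_regimen(table, cur)

    def test_probability_rule_boundary(self):
        table, cur = table_for({"300 q4w"}, p_hi=90.0)
        assert select_regimen(table, cur, prob_rule=90.0).selected == Regimen(300.0, 4)
        table, cur = table_for({"300 q4w"}, p_hi=89.99)
        assert select_regimen(table, cur, prob_rule=90.0).selected is None


class TestRecommendPatient:
    def test_strong_responder_is_optimized(self, pop):
        clones = clone_set(pop, [{"kout": 0.5} for _ in range(20)], pasi_obs0=5.0)
        table, rec, outcomes = recommend_patient(clones, Regimen(300.0, 4))
        assert len(table.entries) == 7
        assert len(outcomes) == 7
        assert rec.classification in ("optimized", "maintained")
        if rec.selected is not None:
            assert optimization_rank(rec.selected) <= optimization_rank(Regimen(300.0, 4))


class TestAnnualCost:
    @pytest.mark.parametrize(
        "interval,doses", [(2, 28), (4, 14), (5, 11), (6, 9)]
    )
    def test_dose_counts(self, interval, doses):
        reg = Regimen(300.0, interval)
        d, eur, sav = annual_cost(reg)
        assert d == doses
        assert eur == int(np.floor(doses * 1246.98 + 0.5))
        assert sav == int(np.floor((1 - doses / 14) * 100 + 0.5))

    def test_invalid_price(self):
        with pytest.raises(InvalidInputError):
            annual_cost(Regimen(300.0, 4), unit_cost_eur=0.0)


class TestExposureResponseWindow:
    def test_insufficient_pairs(self):
        with pytest.raises(InsufficientDataError):
            exposure_response_window([(10.0, 0.5)] * 50)

    def test_all_respond_gives_full_range(self):
        troughs = np.linspace(10.0, 90.0, 500)
        pairs = np.column_stack([troughs, np.full(500, 0.2)])
        lo, hi = exposure_response_window(pairs)
        assert lo == pytest.approx(10.0, abs=0.2)
        assert hi == pytest.approx(90.0, abs=0.2)

    def test_none_respond(self):
        troughs = np.linspace(10.0, 90.0, 500)
        pairs = np.column_stack([troughs, np.full(500, 5.0)])
        assert exposure_response_window(pairs) is None

    def test_threshold_edge_location(self):
        # response iff trough >= 50: the >=90% region starts where 90% of
        # the +/-2.5 neighbourhood is above 50, i.e. near 52
        troughs = np.linspace(0.0, 100.0, 4001)
        pasi = np.where(troughs >= 50.0, 0.5, 3.0)
        lo, hi = exposure_response_window(np.column_stack([troughs, pasi]))
        assert lo == pytest.approx(52.0, abs=0.2)
        assert hi == pytest.approx(100.0, abs=0.2)
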