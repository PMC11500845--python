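"""OWSA tornado, PSA draws, CEAC, cost-effectiveness plane."""

import numpy as np
import pandas as pd
import pytest

from bpscreen.parameters import DistributionSpec
from bpscreen.sensitivity import (PsaResult, ceac, ce_plane_points,
                                  default_wtp_grid, draw_psa_parameters,
                                  one_way_sensitivity, run_psa)
from bpscreen.screening import get_strategy
from bpscreen.markov_engine import run_cohort
from bpscreen.economics import accrue


def _fix_all(ps):
    out = ps.copy()
    out.psa = {name: DistributionSpec("fixed", spec.mean)
               for name, spec in out.psa.items()}
    return out


# ----------------------------------------------------------------- OWSA

def test_owsa_degenerate_range_has_zero_swing(ps_short):
    ps = ps_short.copy()
    base = ps.get("cost_ht_controlled")
    ps.owsa_range["cost_ht_controlled"] = (base, base)
    [entry] = one_way_sensitivity(ps, ("Serial1", "CBPM"),
                                  parameters=["cost_ht_controlled"])
    assert entry.swing == 0.0


def test_owsa_inert_parameter_has_zero_swing(ps_short):
    """A parameter the cohort never touches (the under-45 CVD fatality in
    a cohort starting at 45) cannot move the ICER."""
    ps = ps_short.copy()
    ps.start_age = 45
    entries = one_way_sensitivity(ps, ("Serial1", "CBPM"),
                                  parameters=["p_cvd_death_young",
                                              "cost_ht_controlled"])
    by_name = {e.parameter: e for e in entries}
    assert by_name["p_cvd_death_young"].swing == 0.0
    assert by_name["cost_ht_controlled"].swing > 0.0
    # sorted by descending swing
    assert entries[0].parameter == "cost_ht_controlled"


def test_owsa_matches_independent_rerun(ps_short):
    """Tornado entries equal ICERs recomputed by hand at each bound."""
    name = "se_hbpm"
    lo, hi = 0.7, 0.95
    ps = ps_short.copy()
    ps.owsa_range[name] = (lo, hi)
    [entry] = one_way_sensitivity(ps, ("HBPM", "CBPM"), parameters=[name])

    def icer_at(value):
        probe = ps.copy()
        probe.set(name, value)
        res = {}
        for sname in ("HBPM", "CBPM"):
            strat = get_strategy(sname, probe)
            res[sname] = accrue(run_cohort(probe, strat), probe, strat)
        d_cost = res["HBPM"].total_cost - res["CBPM"].total_cost
        d_qaly = res["HBPM"].total_qaly - res["CBPM"].total_qaly
        return d_cost / d_qaly

    assert entry.icer_at_low == pytest.approx(icer_at(lo))
    assert entry.icer_at_high == pytest.approx(icer_at(hi))
    assert entry.swing == pytest.approx(abs(icer_at(hi) - icer_at(lo)))


def test_owsa_rejects_invalid_range_before_running(ps_short):
    ps = ps_short.copy()
    ps.owsa_range["se_cbpm"] = (0.5, 1.5)
    with pytest.raises(ValueError, match="se_cbpm"):
        one_way_sensitivity(ps, ("HBPM", "CBPM"), parameters=["se_cbpm"])


# ----------------------------------------------------------------- PSA draws

def test_all_fixed_distributions_reproduce_base(ps_short):
    ps = _fix_all(ps_short)
    draw = draw_psa_parameters(ps, rng_seed=7, replication=0)
    for name in ps.parameter_names():
        assert draw.get(name) == ps.get(name), name


def test_draw_is_deterministic_and_valid(ps_short):
    d1 = draw_psa_parameters(ps_short, rng_seed=11, replication=3)
    d2 = draw_psa_parameters(ps_short, rng_seed=11, replication=3)
    d3 = draw_psa_parameters(ps_short, rng_seed=11, replication=4)
    for name in ps_short.parameter_names():
        assert d1.get(name) == d2.get(name)
    assert any(d1.get(n) != d3.get(n) for n in ps_short.parameter_names())
    assert d1.validate() == []
    # complementary fractions stay closed in every draw
    assert d1.prop_stroke + d1.prop_cad == pytest.approx(1.0)
    assert d1.prop_hemorrhagic + d1.prop_ischemic == pytest.approx(1.0)


def test_degenerate_beta_converges_to_mean(ps_short):
    ps = ps_short.copy()
    ps.psa["se_cbpm"] = DistributionSpec("beta", 0.74, 1e-6)
    draw = draw_psa_parameters(ps, rng_seed=5, replication=0)
    assert draw.se_cbpm == pytest.approx(0.74, abs=1e-3)


def test_gamma_draw_sample_mean_matches_configured_mean(ps_short):
    """Law of large numbers on the method-of-moments gamma conversion."""
    name, n = "cost_cvd_acute", 1500
    spec = ps_short.psa[name]
    vals = np.array([draw_psa_parameters(ps_short, 123, rep).get(name)
                     for rep in range(n)])
    se_mean = spec.se / np.sqrt(n)
    assert abs(vals.mean() - spec.mean) < 3 * se_mean
    assert vals.std() == pytest.approx(spec.se, rel=0.15)


def test_infeasible_beta_se_names_parameter(ps_short):
    ps = ps_short.copy()
    ps.psa["se_cbpm"] = DistributionSpec("beta", 0.74, 0.6)
    with pytest.raises(ValueError, match="se_cbpm"):
        draw_psa_parameters(ps, rng_seed=1, replication=0)


# ----------------------------------------------------------------- run_psa

def test_single_fixed_replication_equals_base_case(ps_short):
    ps = _fix_all(ps_short)
    psa = run_psa(ps, replications=1, rng_seed=3)
    strat = get_strategy("CBPM", ps)
    base = accrue(run_cohort(ps, strat), ps, strat)
    row = psa.table[(psa.table.strategy == "CBPM")].iloc[0]
    assert row.total_cost == pytest.approx(base.total_cost)
    assert row.total_qaly == pytest.approx(base.total_qaly)


def test_run_psa_reproducible(ps_short):
    p1 = run_psa(ps_short, replications=4, rng_seed=42)
    p2 = run_psa(ps_short, replications=4, rng_seed=42)
    pd.testing.assert_frame_equal(p1.table, p2.table, check_exact=True)
    with pytest.raises(ValueError):
        run_psa(ps_short, replications=0, rng_seed=1)


# ----------------------------------------------------------------- CEAC

def _toy_psa(records):
    return PsaResult(table=pd.DataFrame(records), seed=0,
                     replications=len({r["replication"] for r in records}))


def test_ceac_single_replication_winner_takes_all():
    psa = _toy_psa([
        {"replication": 0, "strategy": "A", "total_cost": 10.0,
         "total_qaly": 1.0, "total_ly": 1.0},
        {"replication": 0, "strategy": "B", "total_cost": 20.0,
         "total_qaly": 1.5, "total_ly": 1.5},
    ])
    curve = ceac(psa, wtp_grid=[0.0, 100.0])
    # at WTP 0 the cheaper strategy wins; at 100 the extra QALY pays off
    assert curve.probability.loc[0].to_dict() == {"A": 1.0, "B": 0.0}
    assert curve.probability.loc[1].to_dict() == {"A": 0.0, "B": 1.0}


def test_ceac_hand_enumerated_three_replications():
    # B wins replications 0 and 1 at WTP 50; tie at replication 2
    records = []
    data = {0: {"A": (10, 1.0), "B": (10, 1.2)},
            1: {"A": (30, 1.0), "B": (10, 1.0)},
            2: {"A": (10, 1.0), "B": (10, 1.0)}}
    for rep, by_strat in data.items():
        for s, (c, q) in by_strat.items():
            records.append({"replication": rep, "strategy": s,
                            "total_cost": float(c), "total_qaly": q,
                            "total_ly": q})
    curve = ceac(_toy_psa(records), wtp_grid=[50.0])
    # hand count: B wins 2 of 3; the tie splits 0.5/0.5
    assert curve.probability.loc[0, "B"] == pytest.approx((2 + 0.5) / 3)
    assert curve.probability.loc[0, "A"] == pytest.approx(0.5 / 3)


def test_ceac_probabilities_sum_to_one(ps_short):
    psa = run_psa(ps_short, replications=8, rng_seed=2)
    curve = ceac(psa)
    sums = curve.probability.sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)
    assert ((curve.probability >= 0) & (curve.probability <= 1)).all().all()
    assert 160_000.0 in default_wtp_grid()
    with pytest.raises(ValueError):
        ceac(psa, wtp_grid=[])


def test_ceac_degenerate_distributions_concentrate_on_best(ps_short):
    ps = _fix_all(ps_short)
    psa = run_psa(ps, replications=2, rng_seed=9)
    curve = ceac(psa, wtp_grid=[160_000.0])
    top = curve.probability.loc[0]
    assert top.max() == 1.0 and top.sum() == pytest.approx(1.0)


# ----------------------------------------------------------------- CE plane

def test_ce_plane_comparator_differences():
    psa = _toy_psa([
        {"replication": 0, "strategy": "A", "total_cost": 10.0,
         "total_qaly": 1.0, "total_ly": 1.0},
        {"replication": 0, "strategy": "B", "total_cost": 25.0,
         "total_qaly": 1.4, "total_ly": 1.4},
    ])
    pts = ce_plane_points(psa, "A")
    assert len(pts) == 1
    assert pts.iloc[0].delta_cost == pytest.approx(15.0)
    assert pts.iloc[0].delta_qaly == pytest.approx(0.4)
    with pytest.raises(KeyError):
        ce_plane_points(psa, "Z")


def test_ce_plane_dominant_strategy_fills_one_quadrant(ps_short):
    """A strategy made strictly cheaper and healthier lands every PSA
    point in the dominant (SE) quadrant."""
    psa = run_psa(ps_short, replications=6, rng_seed=13,
                  strategies=("CBPM", "Serial1"))
    # Serial1 vs CBPM under the defaults: cheaper in every replication
    pts = ce_plane_points(psa, "CBPM")
    assert (pts.delta_cost < 0).all()


def test_ce_plane_fixed_psa_gives_single_base_point(ps_short):
    ps = _fix_all(ps_short)
    psa = run_psa(ps, replications=3, rng_seed=1,
                  strategies=("CBPM", "HBPM"))
    pts = ce_plane_points(psa, "CBPM")
    assert pts.delta_cost.nunique() == 1 and pts.delta_qaly.nunique() == 1
    res = {}
    for name in ("CBPM", "HBPM"):
        strat = get_strategy(name, ps)
        res[name] = accrue(run_cohort(ps, strat), ps, strat)
    assert pts.delta_cost.iloc[0] == pytest.approx(
        res["HBPM"].total_cost - res["CBPM"].total_cost)
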