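"""Discounted cost/QALY accrual, ICERs, dominance, net monetary benefit.

Costs are 2021 Thai baht from the societal perspective (direct medical
plus direct non-medical; productivity losses excluded).  Costs and QALYs
are discounted at ``discount_rate`` per year with cycle 0 (the start
age) undiscounted.  Life years are reported both discounted and
undiscounted; the report table prints the undiscounted total.

State value mapping per cycle:

* screening cost — screened mass x expected per-person strategy cost at
  that cycle's true-hypertension fraction;
* treated hypertension (controlled, and transient WCHT which is managed
  as controlled) — annual controlled-HT drug/visit cost plus 4 clinic
  visits; uncontrolled — its own annual cost plus 8 visits; undiagnosed
  hypertension is untreated and accrues no treatment cost;
* CVD — incident events pay the acute admission (medical cost plus
  9.83 inpatient days of non-medical cost); prevalent survivors pay the
  chronic annual cost plus 8 visits;
* utilities — healthy and transient WCHT 1, any hypertension state
  u_ht, CVD the stroke/CAD-mix-weighted utility, death 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .markov_engine import CohortTrace
from .parameters import ParameterSet
from .screening import Strategy, expected_screening_cost

__all__ = [
    "EconomicResult",
    "IcerRow",
    "discount_factor",
    "cvd_utility",
    "accrue",
    "icer_table",
    "incremental_row",
    "net_monetary_benefit",
    "format_report",
]


@dataclass(frozen=True)
class EconomicResult:
    """Discounted lifetime totals for one strategy (per cohort member)."""

    strategy: str
    screening_cost: float
    direct_medical_cost: float
    direct_nonmedical_cost: float
    total_cost: float
    total_ly: float
    total_qaly: float
    total_ly_undisc: float


@dataclass(frozen=True)
class IcerRow:
    """One strategy-vs-comparator comparison.

    ``icer_qaly`` is delta cost / delta QALY (baht per QALY), signed;
    ``dominance_class`` says how to read it: ``dominant`` (cheaper, more
    QALYs), ``dominated`` (dearer, fewer QALYs), ``trade_off_NE`` (more
    cost, more QALYs: cost per QALY gained), ``trade_off_SW`` (less
    cost, fewer QALYs: cost saved per QALY lost).
    """

    label: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_qaly: Optional[float]
    dominance_class: str
    icer_ly: Optional[float] = None
    delta_ly_undisc: Optional[float] = None


def discount_factor(rate: float, cycle_index: int) -> float:
    """1/(1+rate)^t; cycle 0 is undiscounted."""
    if cycle_index < 0:
        raise ValueError(f"cycle_index={cycle_index} must be >= 0")
    if rate < 0:
        raise ValueError(f"rate={rate} must be >= 0")
    return 1.0 / (1.0 + rate) ** cycle_index


def cvd_utility(ps: ParameterSet) -> float:
    """Utility of the CVD state: stroke/CAD utilities weighted by case mix."""
    return ps.prop_stroke * ps.u_stroke + ps.prop_cad * ps.u_cad


def accrue(trace: CohortTrace, ps: ParameterSet,
           strategy: Strategy) -> EconomicResult:
    """Accumulate discounted costs, LYs and QALYs over a cohort trace."""
    t = trace.table
    n = len(t)
    df = np.array([discount_factor(ps.discount_rate, i) for i in range(n)])

    screened = t["screened"].to_numpy()
    true_ht = t["screened_true_ht"].to_numpy()
    with np.errstate(invalid="ignore"):
        pi = np.where(screened > 0, true_ht / np.maximum(screened, 1e-300), 0.0)
    unit_screen = np.array([
        expected_screening_cost(strategy, float(p), ps) for p in pi])
    screening = screened * unit_screen

    treated_ctrl = t["ht_controlled"].to_numpy() + t["wcht_transient"].to_numpy()
    unctrl = t["ht_uncontrolled"].to_numpy()
    cvd_all = t["cvd"].to_numpy()
    cvd_new = t["new_cvd"].to_numpy()
    cvd_new_alive = t["cvd_new_alive"].to_numpy()
    cvd_prev = np.clip(cvd_all - cvd_new_alive, 0.0, None)

    medical = (treated_ctrl * ps.cost_ht_controlled
               + unctrl * ps.cost_ht_uncontrolled
               + cvd_new * ps.cost_cvd_acute
               + cvd_prev * ps.cost_cvd_chronic)
    nonmedical = (treated_ctrl * ps.visits_controlled * ps.nonmed_visit_cost
                  + unctrl * ps.visits_uncontrolled * ps.nonmed_visit_cost
                  + cvd_prev * ps.visits_cvd_chronic * ps.nonmed_visit_cost
                  + cvd_new * ps.acute_admission_days
                  * ps.nonmed_inpatient_cost_per_day)

    alive = 1.0 - t["dead"].to_numpy()
    u_cvd = cvd_utility(ps)
    utility = (t["no_ht"].to_numpy() * ps.u_healthy
               + t["wcht_transient"].to_numpy() * ps.u_healthy
               + (t["undiagnosed_ht"].to_numpy()
                  + t["ht_controlled"].to_numpy() + unctrl) * ps.u_ht
               + cvd_all * u_cvd
               + t["dead"].to_numpy() * ps.u_death)

    sc = float((screening * df).sum())
    med = float((medical * df).sum())
    nonmed = float((nonmedical * df).sum())
    return EconomicResult(
        strategy=strategy.name,
        screening_cost=sc,
        direct_medical_cost=med,
        direct_nonmedical_cost=nonmed,
        total_cost=sc + med + nonmed,
        total_ly=float((alive * df).sum()),
        total_qaly=float((utility * df).sum()),
        total_ly_undisc=float(alive.sum()),
    )


def _dominance(delta_cost: float, delta_qaly: float) -> str:
    if delta_cost > 0 and delta_qaly < 0:
        return "dominated"
    if delta_cost < 0 and delta_qaly > 0:
        return "dominant"
    if delta_qaly >= 0:
        return "trade_off_NE"
    return "trade_off_SW"


def incremental_row(label: str, delta_cost: float, delta_ly: float,
                    delta_qaly: float,
                    delta_ly_undisc: Optional[float] = None) -> IcerRow:
    """Build an IcerRow from raw increments (also usable on printed values)."""
    icer = None if delta_qaly == 0 else delta_cost / delta_qaly
    ly_for_icer = delta_ly_undisc if delta_ly_undisc is not None else delta_ly
    icer_ly = None if ly_for_icer == 0 else delta_cost / ly_for_icer
    return IcerRow(
        label=label,
        delta_cost=delta_cost,
        delta_ly=delta_ly,
        delta_qaly=delta_qaly,
        icer_qaly=icer,
        dominance_class=_dominance(delta_cost, delta_qaly),
        icer_ly=icer_ly,
        delta_ly_undisc=delta_ly_undisc,
    )


def icer_table(results: Dict[str, EconomicResult],
               comparator: str) -> List[IcerRow]:
    """Pairwise comparison of every strategy against the comparator."""
    if comparator not in results:
        raise KeyError(f"comparator {comparator!r} not among results")
    base = results[comparator]
    rows = []
    for name, res in results.items():
        if name == comparator:
            continue
        rows.append(incremental_row(
            f"{name} vs {comparator}",
            res.total_cost - base.total_cost,
            res.total_ly - base.total_ly,
            res.total_qaly - base.total_qaly,
            delta_ly_undisc=res.total_ly_undisc - base.total_ly_undisc,
        ))
    return rows


def net_monetary_benefit(result: EconomicResult, wtp: float) -> float:
    """NMB = WTP x QALYs - cost; the decision statistic behind CEACs."""
    if wtp < 0:
        raise ValueError(f"wtp={wtp} must be >= 0")
    return wtp * result.total_qaly - result.total_cost


def format_report(results: Dict[str, EconomicResult],
                  outcomes: Dict[str, Dict[str, float]],
                  comparator: str) -> pd.DataFrame:
    """Report table: costs (with category %), outcomes and increments.

    Costs and ICERs are rounded to whole baht, LYs/QALYs to 4 decimals
    (internal arithmetic is full precision); life years are printed
    undiscounted.
    """
    strategies = list(results)
    rows: Dict[str, Dict[str, object]] = {}

    def pct(part: float, total: float) -> str:
        return f"{part:,.0f} ({100 * part / total:.2f})" if total else "0"

    for label in ("screening_cost", "direct_medical_cost",
                  "direct_nonmedical_cost"):
        rows[label] = {s: pct(getattr(results[s], label),
                              results[s].total_cost) for s in strategies}
    rows["total_cost"] = {s: f"{results[s].total_cost:,.0f}"
                          for s in strategies}
    for label, key in (("ht_prevalence_pct", "ht_prevalence_timeavg"),
                       ("cvd_incidence_pct", "cvd_incidence"),
                       ("cvd_mortality_pct", "cvd_mortality")):
        rows[label] = {s: f"{100 * outcomes[s][key]:.2f}" for s in strategies}
    for label, key in (("wcht_incidence", "wcht_incidence"),
                       ("p_undiagnosed", "p_undiagnosed")):
        rows[label] = {s: f"{outcomes[s][key]:.3f}" for s in strategies}
    rows["total_ly"] = {s: f"{results[s].total_ly_undisc:.4f}"
                        for s in strategies}
    rows["total_qaly"] = {s: f"{results[s].total_qaly:.4f}"
                          for s in strategies}

    quadrant_codes = {"dominated": "c", "trade_off_SW": "d",
                      "trade_off_NE": "", "dominant": ""}
    for row in icer_table(results, comparator):
        name = row.label.split(" vs ")[0]
        rows.setdefault("delta_cost", {})[name] = f"{row.delta_cost:,.0f}"
        rows.setdefault("delta_qaly", {})[name] = f"{row.delta_qaly:.4f}"
        icer = ("undefined" if row.icer_qaly is None
                else f"{row.icer_qaly:,.0f}{quadrant_codes[row.dominance_class]}")
        rows.setdefault("icer_qaly", {})[name] = icer
    return pd.DataFrame(rows).T[strategies].fillna("")
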