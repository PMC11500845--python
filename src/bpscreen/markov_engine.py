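"""Annual-cycle Markov cohort model of hypertension screening.

The cohort starts at ``start_age`` entirely free of diagnosed
hypertension and CVD and is stepped one year at a time.  Seven state
occupancies are recorded per cycle::

    no_ht, undiagnosed_ht, wcht_transient, ht_controlled,
    ht_uncontrolled, cvd, dead

Two further states of the clinical model — "new HT diagnosis" and
"temporary WCHT" — are within-cycle tunnels: a positive screen routes a
person through them into ``ht_uncontrolled`` or ``wcht_transient``
before the cycle's vector is recorded.

Event order within a cycle (the narrative gives no explicit ordering;
this one lets screening detect both prevalent and incident cases and
resolves tunnels in-cycle):

1. hypertension incidence moves part of ``no_ht`` into the latent pool;
2. the ``no_ht`` + latent + ``undiagnosed_ht`` pool is screened;
   true positives enter ``ht_uncontrolled``, false positives enter
   ``wcht_transient`` (people already diagnosed, including WCHT, are
   never re-screened);
3. control-status switching between controlled and uncontrolled
   (including the cycle's new diagnoses);
4. first CVD events from undiagnosed (at uncontrolled-group risk),
   uncontrolled, and controlled hypertension;
5. mortality: CVD case fatality first, then background non-CVD
   mortality applied to every alive state (sequential competing risks,
   the later probability conditional on surviving the earlier).

No half-cycle correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .parameters import AgeBand, ParameterSet
from .screening import Strategy, classify_screened

__all__ = [
    "STATES",
    "FLOWS",
    "CohortTrace",
    "cvd_death_probability",
    "step_cycle",
    "run_cohort",
    "summarize_outcomes",
    "prevalence_by_age_band",
]

STATES = ("no_ht", "undiagnosed_ht", "wcht_transient", "ht_controlled",
          "ht_uncontrolled", "cvd", "dead")
FLOWS = ("screened", "new_diagnoses", "new_wcht", "new_cvd",
         "cvd_deaths", "other_deaths")
# auxiliary columns used by economics (not part of the exported flow set)
_AUX = ("screened_true_ht", "cvd_new_alive")

_SUM_TOL = 1e-12


class CycleOverflowError(RuntimeError):
    """Competing risks pushed a state occupancy negative."""


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and event flows for one strategy.

    ``table`` has one row per model cycle; the ``age`` column is the age
    lived during that cycle and the state columns hold end-of-cycle
    occupancy fractions.
    """

    strategy: str
    table: pd.DataFrame

    def export(self, path) -> None:
        """Write the age + states + flows table as CSV."""
        cols = ["age", *STATES, *FLOWS]
        self.table[cols].to_csv(path, index=False)


def cvd_death_probability(age: int, ps: ParameterSet) -> float:
    """Annual CVD case-fatality probability; ages 45+ use the older stratum."""
    return ps.p_cvd_death_young if age < 45 else ps.p_cvd_death_old


def step_cycle(state: np.ndarray, age: int, ps: ParameterSet,
               strategy: Strategy) -> tuple[np.ndarray, Dict[str, float]]:
    """Advance the occupancy vector one annual cycle.

    Returns the end-of-cycle vector and the cycle's event flows.
    """
    no_ht, undiag, wcht, ctrl, unctrl, cvd, dead = state
    inc = ps.band_value("ht_incidence", age)

    # (1) incidence: part of the healthy pool develops true hypertension
    latent = no_ht * inc
    healthy = no_ht - latent

    # (2) screening of everyone not yet carrying a diagnosis
    pool = healthy + latent + undiag
    true_ht = latent + undiag
    pi = true_ht / pool if pool > 0.0 else 0.0
    split = classify_screened(pi, strategy.performance)
    new_dx = pool * split.to_new_diagnosis
    undiag2 = pool * split.to_undiagnosed
    new_wcht = pool * split.to_wcht
    no_ht2 = pool * split.to_no_ht
    unctrl = unctrl + new_dx  # tunnel: new diagnosis -> uncontrolled

    # WCHT transient occupants develop true HT at the general incidence
    # and move to controlled HT; the cycle's new entrants start next year.
    wcht_progress = wcht * inc
    ctrl = ctrl + wcht_progress
    wcht2 = wcht - wcht_progress + new_wcht

    # (3) control-status switching
    c2u = ctrl * ps.p_controlled_to_uncontrolled
    u2c = unctrl * ps.p_uncontrolled_to_controlled
    ctrl2 = ctrl - c2u + u2c
    unctrl2 = unctrl + c2u - u2c

    # (4) first CVD events (undiagnosed at uncontrolled-group risk)
    p_cvd_u = ps.band_value("p_cvd_given_uncontrolled", age)
    p_cvd_c = ps.band_value("p_cvd_given_controlled", age)
    ev_undiag = undiag2 * p_cvd_u
    ev_unctrl = unctrl2 * p_cvd_u
    ev_ctrl = ctrl2 * p_cvd_c
    new_cvd = ev_undiag + ev_unctrl + ev_ctrl
    undiag3 = undiag2 - ev_undiag
    unctrl3 = unctrl2 - ev_unctrl
    ctrl3 = ctrl2 - ev_ctrl
    cvd_pool = cvd + new_cvd

    # (5) mortality: CVD fatality, then background mortality on survivors
    p_fatal = cvd_death_probability(age, ps)
    p_bg = ps.band_value("p_death_other", age)
    cvd_deaths = cvd_pool * p_fatal
    cvd_alive = cvd_pool - cvd_deaths
    alive_states = np.array(
        [no_ht2, undiag3, wcht2, ctrl3, unctrl3, cvd_alive])
    other_deaths = float(alive_states.sum() * p_bg)
    alive_states = alive_states * (1.0 - p_bg)
    dead2 = dead + cvd_deaths + other_deaths

    nxt = np.array([*alive_states, dead2])
    if np.any(nxt < -1e-15):
        idx = int(np.argmin(nxt))
        raise CycleOverflowError(
            f"negative occupancy in state {([*STATES])[idx]!r} at age {age}")
    nxt = np.clip(nxt, 0.0, None)
    if abs(nxt.sum() - state.sum()) > 1e-9:
        raise CycleOverflowError(f"mass not conserved at age {age}")

    flows = {
        "screened": pool,
        "new_diagnoses": new_dx,
        "new_wcht": new_wcht,
        "new_cvd": new_cvd,
        "cvd_deaths": cvd_deaths,
        "other_deaths": other_deaths,
        "screened_true_ht": true_ht,
        "cvd_new_alive": new_cvd * (1.0 - p_fatal) * (1.0 - p_bg),
    }
    return nxt, flows


def run_cohort(ps: ParameterSet, strategy: Strategy) -> CohortTrace:
    """Run the cohort from start_age to end_age (one row per year lived).

    The initial vector is 100% ``no_ht``; the run is fully deterministic.
    """
    state = np.zeros(len(STATES))
    state[0] = 1.0
    rows: List[Dict[str, float]] = []
    for age in range(ps.start_age, ps.end_age):
        state, flows = step_cycle(state, age, ps, strategy)
        row = {"age": age}
        row.update(dict(zip(STATES, state)))
        row.update(flows)
        rows.append(row)
    table = pd.DataFrame(rows, columns=["age", *STATES, *FLOWS, *_AUX])
    return CohortTrace(strategy=strategy.name, table=table)


def summarize_outcomes(trace: CohortTrace) -> Dict[str, float]:
    """Lifetime outcome summary for one strategy's trace.

    * ``cvd_incidence`` / ``cvd_mortality``: cumulative first-event and
      CVD-death probability per cohort member (fractions).
    * ``wcht_incidence``: cumulative white-coat diagnoses per person.
    * ``ht_prevalence_timeavg``: person-year-weighted prevalence of true
      hypertension (undiagnosed + controlled + uncontrolled) among the
      alive — the headline prevalence figure.
    * ``ht_prevalence_terminal``: the same ratio in the final cycle.
    * ``p_undiagnosed``: person-year-weighted probability of being alive
      with undiagnosed hypertension.
    """
    t = trace.table
    alive = 1.0 - t["dead"]
    ht = t["undiagnosed_ht"] + t["ht_controlled"] + t["ht_uncontrolled"]
    alive_py = float(alive.sum())
    out = {
        "cvd_incidence": float(t["new_cvd"].sum()),
        "cvd_mortality": float(t["cvd_deaths"].sum()),
        "wcht_incidence": float(t["new_wcht"].sum()),
        "ht_prevalence_timeavg": (float((ht).sum()) / alive_py
                                  if alive_py > 0 else 0.0),
        "ht_prevalence_terminal": (
            float(ht.iloc[-1] / alive.iloc[-1]) if alive.iloc[-1] > 0 else 0.0),
        "p_undiagnosed": (float(t["undiagnosed_ht"].sum()) / alive_py
                          if alive_py > 0 else 0.0),
    }
    return out


def prevalence_by_age_band(trace: CohortTrace,
                           bands: Sequence[AgeBand]) -> Dict[AgeBand, float]:
    """Hypertension prevalence among the alive, averaged over each band.

    Prevalence counts true hypertension: undiagnosed + controlled +
    uncontrolled occupancy (transient WCHT is not truly hypertensive).
    A band whose cycles hold no alive mass gets ``nan`` rather than a
    silent zero.
    """
    t = trace.table
    out: Dict[AgeBand, float] = {}
    for band in bands:
        rows = t[(t["age"] >= band.lower) & (t["age"] <= band.upper)]
        if rows.empty:
            raise ValueError(f"band {band.label} outside the model horizon")
        alive = (1.0 - rows["dead"]).sum()
        if alive <= 0:
            out[band] = float("nan")
            continue
        ht = (rows["undiagnosed_ht"] + rows["ht_controlled"]
              + rows["ht_uncontrolled"]).sum()
        out[band] = float(ht / alive)
    return out
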