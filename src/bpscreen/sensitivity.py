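"""One-way and probabilistic sensitivity analysis.

OWSA reruns the full model with a single parameter at its low/high
bound and records the resulting ICER swing (tornado ordering).  PSA
draws every uncertain parameter jointly — beta for probabilities and
utilities, gamma for costs, by method-of-moments from (mean, SE) — and
propagates each draw through all strategies with common random
parameters.  CEACs report, per willingness-to-pay value, the fraction
of draws in which each strategy attains the maximum net monetary
benefit (ties split evenly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import economics
from .markov_engine import run_cohort
from .parameters import DistributionSpec, ParameterSet
from .screening import STRATEGY_NAMES, get_strategy

__all__ = [
    "TornadoEntry",
    "PsaResult",
    "CeacCurve",
    "default_wtp_grid",
    "one_way_sensitivity",
    "draw_psa_parameters",
    "run_psa",
    "ceac",
    "ce_plane_points",
]

# parameters whose PSA draw fixes a complementary fraction
_COMPLEMENTS = {"prop_stroke": "prop_cad", "prop_hemorrhagic": "prop_ischemic"}


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: Optional[float]
    icer_at_high: Optional[float]
    swing: float


@dataclass
class PsaResult:
    """Per-replication discounted cost/QALY for every strategy.

    ``table`` columns: replication, strategy, total_cost, total_qaly,
    total_ly.
    """

    table: pd.DataFrame
    seed: int
    replications: int

    def pivot(self, value: str) -> pd.DataFrame:
        return self.table.pivot(index="replication", columns="strategy",
                                values=value)


@dataclass
class CeacCurve:
    """Probability each strategy is cost-effective along a WTP grid."""

    wtp: np.ndarray
    probability: pd.DataFrame  # index aligned with wtp, one column/strategy

    def export(self, path) -> None:
        out = self.probability.copy()
        out.insert(0, "wtp", self.wtp)
        out.to_csv(path, index=False)


def default_wtp_grid() -> np.ndarray:
    """0..500,000 baht/QALY in 10,000-baht steps (includes 160,000)."""
    return np.arange(0, 500_001, 10_000, dtype=float)


def _evaluate(ps: ParameterSet,
              strategies: Sequence[str]) -> Dict[str, economics.EconomicResult]:
    out = {}
    for name in strategies:
        strat = get_strategy(name, ps)
        out[name] = economics.accrue(run_cohort(ps, strat), ps, strat)
    return out


def _icer(ps: ParameterSet, intervention: str,
          comparator: str) -> Optional[float]:
    res = _evaluate(ps, (intervention, comparator))
    row = economics.icer_table(res, comparator)[0]
    return row.icer_qaly


def one_way_sensitivity(ps: ParameterSet,
                        comparison: Tuple[str, str],
                        parameters: Optional[Sequence[str]] = None
                        ) -> List[TornadoEntry]:
    """Tornado entries for ICER(intervention vs comparator), sorted by swing.

    Each listed parameter is set to its configured (low, high) bound in
    turn, all others held at base, and the model fully rerun.  Ranges
    violating a parameter invariant abort before any model run.
    """
    intervention, comparator = comparison
    names = list(parameters) if parameters is not None else list(ps.owsa_range)
    for name in names:
        if name not in ps.owsa_range:
            raise KeyError(f"no OWSA range for parameter {name!r}")
        for bound in ps.owsa_range[name]:
            probe = ps.copy()
            probe.set(name, bound)
            _rebalance_complements(probe, name)
            violations = probe.validate()
            if violations:
                raise ValueError(
                    f"OWSA range for {name!r} violates invariants: {violations}")

    entries = []
    for name in names:
        lo, hi = ps.owsa_range[name]
        icers = []
        for bound in (lo, hi):
            probe = ps.copy()
            probe.set(name, bound)
            _rebalance_complements(probe, name)
            icers.append(_icer(probe, intervention, comparator))
        swing = (abs(icers[1] - icers[0])
                 if None not in icers else float("inf"))
        entries.append(TornadoEntry(name, icers[0], icers[1], swing))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def _rebalance_complements(ps: ParameterSet, name: str) -> None:
    # keep complementary fraction pairs summing to 1 whichever member moved
    if name in _COMPLEMENTS:
        ps.set(_COMPLEMENTS[name], 1.0 - ps.get(name))
    else:
        for a, b in _COMPLEMENTS.items():
            if name == b:
                ps.set(a, 1.0 - ps.get(name))


def _beta_params(mean: float, se: float, name: str) -> Tuple[float, float]:
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"{name}: SE {se} too large for beta with mean {mean}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def draw_psa_parameters(ps: ParameterSet, rng_seed: int,
                        replication: int) -> ParameterSet:
    """One joint PSA draw; deterministic given (seed, replication).

    Probabilities/utilities draw beta, costs draw gamma (both
    method-of-moments from the configured mean and SE); ``fixed``
    entries keep their base value.  Complementary fraction pairs
    (stroke/CAD, hemorrhagic/ischemic) are drawn once and closed so
    every draw is itself a valid ParameterSet.
    """
    rng = np.random.default_rng([int(rng_seed), int(replication)])
    draw = ps.copy()
    for name in sorted(ps.psa):
        spec = ps.psa[name]
        if spec.family == "fixed":
            continue
        base = name.split("[")[0]
        if base in _COMPLEMENTS.values():
            continue  # set by its complement below
        if spec.family == "beta":
            if spec.mean in (0.0, 1.0) or spec.se == 0.0:
                value = spec.mean
            else:
                a, b = _beta_params(spec.mean, spec.se, name)
                value = float(rng.beta(a, b))
        elif spec.family == "gamma":
            if spec.se == 0.0:
                value = spec.mean
            else:
                shape = (spec.mean / spec.se) ** 2
                scale = spec.se ** 2 / spec.mean
                value = float(rng.gamma(shape, scale))
        else:  # pragma: no cover - families are closed in DistributionSpec
            raise ValueError(f"{name}: unknown family {spec.family!r}")
        draw.set(name, value)
        _rebalance_complements(draw, name)
    violations = draw.validate()
    if violations:
        raise ValueError(f"PSA draw invalid (seed={rng_seed}, "
                         f"replication={replication}): {violations}")
    return draw


def run_psa(ps: ParameterSet, replications: int, rng_seed: int,
            strategies: Sequence[str] = STRATEGY_NAMES) -> PsaResult:
    """Monte Carlo PSA: one joint draw per replication, all strategies
    evaluated on the same draw (common random parameters)."""
    if replications < 1:
        raise ValueError("replications must be >= 1")
    records = []
    for rep in range(replications):
        try:
            draw = draw_psa_parameters(ps, rng_seed, rep)
            results = _evaluate(draw, strategies)
        except Exception as exc:
            raise RuntimeError(f"PSA replication {rep} failed: {exc}") from exc
        for name, res in results.items():
            records.append({"replication": rep, "strategy": name,
                            "total_cost": res.total_cost,
                            "total_qaly": res.total_qaly,
                            "total_ly": res.total_ly})
    return PsaResult(table=pd.DataFrame(records), seed=int(rng_seed),
                     replications=replications)


def ceac(psa: PsaResult, wtp_grid: Optional[Sequence[float]] = None
         ) -> CeacCurve:
    """Cost-effectiveness acceptability curves over a WTP grid.

    At each WTP a strategy scores the fraction of replications in which
    it attains the maximum NMB; exact ties share the point's mass
    equally, so columns sum to 1 at every WTP.
    """
    grid = np.asarray(default_wtp_grid() if wtp_grid is None else wtp_grid,
                      dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    cost = psa.pivot("total_cost")
    qaly = psa.pivot("total_qaly")
    strategies = list(cost.columns)
    probs = np.zeros((grid.size, len(strategies)))
    for i, wtp in enumerate(grid):
        nmb = wtp * qaly.to_numpy() - cost.to_numpy()
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        probs[i] = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
    return CeacCurve(wtp=grid,
                     probability=pd.DataFrame(probs, columns=strategies))


def ce_plane_points(psa: PsaResult, comparator: str) -> pd.DataFrame:
    """Per-replication (delta_cost, delta_qaly) pairs vs the comparator."""
    cost = psa.pivot("total_cost")
    qaly = psa.pivot("total_qaly")
    if comparator not in cost.columns:
        raise KeyError(f"comparator {comparator!r} not in PSA result")
    frames = []
    for name in cost.columns:
        if name == comparator:
            continue
        frames.append(pd.DataFrame({
            "replication": cost.index,
            "strategy": name,
            "delta_cost": cost[name] - cost[comparator],
            "delta_qaly": qaly[name] - qaly[comparator],
        }))
    return pd.concat(frames, ignore_index=True)
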