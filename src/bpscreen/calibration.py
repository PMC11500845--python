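"""Calibration of age-specific inputs to hypertension-prevalence targets.

Age-specific hypertension incidence (and optionally background non-CVD
mortality) carry the most uncertainty, so they are the calibration
handles: each age band overlapping a target band gets a multiplicative
scalar, chosen by deterministic coordinate-wise bounded search
(derivative-free) to minimise the sum of squared differences between
modelled and target prevalence.  Scalars are bounded so no probability
leaves [0, 1]; any binding bound is reported as clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from scipy import optimize

from .markov_engine import prevalence_by_age_band, run_cohort
from .parameters import AgeBand, ParameterSet
from .screening import get_strategy

__all__ = [
    "CalibrationTarget",
    "FitReport",
    "calibrate",
    "validation_report",
    "load_targets",
]

_SCALAR_CAP = 20.0  # generous upper bound for incidence multipliers


@dataclass(frozen=True)
class CalibrationTarget:
    band: AgeBand
    target_prevalence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_prevalence <= 1.0):
            raise ValueError(
                f"target prevalence {self.target_prevalence} outside [0, 1]")


@dataclass
class FitReport:
    """Outcome of one calibration run."""

    scalars: Dict[str, float]
    objective: float
    converged: bool
    iterations: int
    clipped: List[str] = field(default_factory=list)
    comparison: Optional[pd.DataFrame] = None


def _model_prevalence(ps: ParameterSet,
                      bands: Sequence[AgeBand]) -> Dict[AgeBand, float]:
    strat = get_strategy("CBPM", ps)  # true prevalence is test-invariant
    return prevalence_by_age_band(run_cohort(ps, strat), bands)


def _adjustable_bands(ps: ParameterSet, targets: Sequence[CalibrationTarget],
                      table_name: str) -> List[AgeBand]:
    table = getattr(ps, table_name)
    out = []
    for band in sorted(table):
        if any(band.lower <= t.band.upper and t.band.lower <= band.upper
               for t in targets):
            out.append(band)
    return out


def calibrate(ps: ParameterSet, targets: Sequence[CalibrationTarget],
              max_iter: int = 25, tol: float = 1e-8,
              adjust_mortality: bool = False
              ) -> Tuple[ParameterSet, FitReport]:
    """Fit band-wise incidence multipliers to prevalence targets.

    Coordinate sweeps over the scalars, each coordinate solved by
    bounded scalar minimisation of the full-model SSE.  Stops when the
    objective falls below ``tol`` or improves by less than ``tol``
    between sweeps; hitting ``max_iter`` sweeps returns the best-found
    set flagged unconverged.  The adjusted set always satisfies all
    ParameterSet invariants.
    """
    for t in targets:
        if t.band.lower < ps.start_age or t.band.upper >= ps.end_age:
            raise ValueError(f"target band {t.band.label} outside horizon")

    handles: List[Tuple[str, AgeBand]] = [
        ("ht_incidence", b)
        for b in _adjustable_bands(ps, targets, "ht_incidence")]
    if adjust_mortality:
        handles += [("p_death_other", b)
                    for b in _adjustable_bands(ps, targets, "p_death_other")]
    if not handles:
        raise ValueError("no adjustable bands overlap the targets")

    base_values = {h: getattr(ps, h[0])[h[1]] for h in handles}
    target_bands = [t.band for t in targets]
    target_vec = [t.target_prevalence for t in targets]
    clipped: List[str] = []

    def apply(scalars: Dict[Tuple[str, AgeBand], float]) -> ParameterSet:
        trial = ps.copy()
        for h, s in scalars.items():
            getattr(trial, h[0])[h[1]] = min(base_values[h] * s, 1.0)
        return trial

    def objective(scalars) -> float:
        prev = _model_prevalence(apply(scalars), target_bands)
        return sum((prev[b] - t) ** 2 for b, t in zip(target_bands, target_vec))

    scalars = {h: 1.0 for h in handles}
    best = objective(scalars)
    converged = best <= tol
    sweeps = 0
    while not converged and sweeps < max_iter:
        sweeps += 1
        before = best
        for h in handles:
            upper = min(_SCALAR_CAP,
                        1.0 / base_values[h] if base_values[h] > 0
                        else _SCALAR_CAP)

            def f(s: float, h=h) -> float:
                trial = dict(scalars)
                trial[h] = s
                return objective(trial)

            res = optimize.minimize_scalar(
                f, bounds=(0.0, upper), method="bounded",
                options={"xatol": 1e-5})
            # accept only non-worsening moves: objective is non-increasing
            if res.fun <= best:
                scalars[h] = float(res.x)
                best = float(res.fun)
                if res.x >= upper - 1e-4:
                    clipped.append(f"{h[0]}[{h[1].label}]")
        if best <= tol:
            converged = True
        elif before - best < tol:
            break  # stalled above tolerance: return best found, flagged

    adjusted = apply(scalars)
    prev = _model_prevalence(adjusted, target_bands)
    comparison = pd.DataFrame({
        "band": [b.label for b in target_bands],
        "modeled": [prev[b] for b in target_bands],
        "target": target_vec,
    })
    comparison["residual"] = comparison["modeled"] - comparison["target"]
    report = FitReport(
        scalars={f"{h[0]}[{h[1].label}]": s for h, s in scalars.items()},
        objective=best, converged=converged, iterations=sweeps,
        clipped=sorted(set(clipped)), comparison=comparison)
    return adjusted, report


def validation_report(ps: ParameterSet,
                      targets: Sequence[CalibrationTarget]) -> pd.DataFrame:
    """Modeled vs target prevalence per band, without any fitting."""
    bands = [t.band for t in targets]
    prev = _model_prevalence(ps, bands)
    df = pd.DataFrame({
        "band": [b.label for b in bands],
        "modeled": [prev[b] for b in bands],
        "target": [t.target_prevalence for t in targets],
    })
    df["abs_deviation"] = (df["modeled"] - df["target"]).abs()
    df["rel_deviation"] = df["abs_deviation"] / df["target"].where(
        df["target"] != 0)
    return df


def load_targets(path) -> List[CalibrationTarget]:
    """Read a targets table: age_lower, age_upper, prevalence (CSV)."""
    df = pd.read_csv(path)
    return [CalibrationTarget(AgeBand(int(r.age_lower), int(r.age_upper)),
                              float(r.prevalence))
            for r in df.itertuples(index=False)]
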