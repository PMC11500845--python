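"""Screening strategies and serial-test diagnostic performance.

Four annual blood-pressure screening strategies are modelled:

* ``CBPM``   — clinic measurement alone (the comparator).
* ``HBPM``   — home measurement alone.
* ``Serial1`` — CBPM first, HBPM confirmation only for clinic-positive
  subjects (clinic BP >= 140/90 mmHg); positive requires both tests
  positive.
* ``Serial2`` — CBPM first, HBPM offered to clinic-negative subjects;
  positive if CBPM is positive or, failing that, HBPM is positive.

Serial performance assumes the two tests err conditionally independently
given true hypertension status, the only assumption under which a serial
sensitivity/specificity is determined by the component values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "DiagnosticPerformance",
    "Strategy",
    "ClassificationSplit",
    "STRATEGY_NAMES",
    "compose_serial1",
    "compose_serial2",
    "get_strategy",
    "classify_screened",
    "expected_screening_cost",
]

STRATEGY_NAMES = ("CBPM", "HBPM", "Serial1", "Serial2")


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for label, v in (("sensitivity", self.sensitivity),
                         ("specificity", self.specificity)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{label}={v} outside [0, 1]")


@dataclass(frozen=True)
class Strategy:
    """A named screening strategy with its combined test performance."""

    name: str
    performance: DiagnosticPerformance

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy {self.name!r}; "
                             f"expected one of {STRATEGY_NAMES}")


@dataclass(frozen=True)
class ClassificationSplit:
    """Fractions of one screened cohort by outcome; sums to 1."""

    to_new_diagnosis: float
    to_undiagnosed: float
    to_wcht: float
    to_no_ht: float


def compose_serial1(cbpm: DiagnosticPerformance,
                    hbpm: DiagnosticPerformance) -> DiagnosticPerformance:
    """Serial confirmation of clinic positives: positive iff CBPM+ and HBPM+.

    Se = Se_C * Se_H;  Sp = Sp_C + (1 - Sp_C) * Sp_H.
    """
    se = cbpm.sensitivity * hbpm.sensitivity
    sp = cbpm.specificity + (1.0 - cbpm.specificity) * hbpm.specificity
    return DiagnosticPerformance(se, sp)


def compose_serial2(cbpm: DiagnosticPerformance,
                    hbpm: DiagnosticPerformance) -> DiagnosticPerformance:
    """HBPM offered to clinic negatives: positive iff CBPM+ or HBPM+.

    Se = Se_C + (1 - Se_C) * Se_H;  Sp = Sp_C * Sp_H.
    """
    se = cbpm.sensitivity + (1.0 - cbpm.sensitivity) * hbpm.sensitivity
    sp = cbpm.specificity * hbpm.specificity
    return DiagnosticPerformance(se, sp)


def get_strategy(name: str, ps: ParameterSet) -> Strategy:
    """Build a Strategy from the parameter set's component test values."""
    cbpm = DiagnosticPerformance(ps.se_cbpm, ps.sp_cbpm)
    hbpm = DiagnosticPerformance(ps.se_hbpm, ps.sp_hbpm)
    if name == "CBPM":
        perf = cbpm
    elif name == "HBPM":
        perf = hbpm
    elif name == "Serial1":
        perf = compose_serial1(cbpm, hbpm)
    elif name == "Serial2":
        perf = compose_serial2(cbpm, hbpm)
    else:
        raise ValueError(f"unknown strategy {name!r}; "
                         f"expected one of {STRATEGY_NAMES}")
    return Strategy(name, perf)


def classify_screened(true_ht_fraction: float,
                      perf: DiagnosticPerformance) -> ClassificationSplit:
    """Split a screened group by true status x test result.

    True hypertensives testing positive are newly diagnosed; those
    testing negative stay undiagnosed (masked hypertension).  Healthy
    subjects testing positive become white-coat hypertension; negatives
    remain disease-free.
    """
    pi = true_ht_fraction
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"true_ht_fraction={pi} outside [0, 1]")
    se, sp = perf.sensitivity, perf.specificity
    return ClassificationSplit(
        to_new_diagnosis=pi * se,
        to_undiagnosed=pi * (1.0 - se),
        to_wcht=(1.0 - pi) * (1.0 - sp),
        to_no_ht=(1.0 - pi) * sp,
    )


def expected_screening_cost(strategy: Strategy, true_ht_fraction: float,
                            ps: ParameterSet) -> float:
    """Expected screening cost per screened person (baht).

    Serial strategies pay for CBPM on everyone and HBPM only for the
    subgroup routed to confirmation: first-stage positives (Serial1) or
    first-stage negatives (Serial2), evaluated at the screened group's
    current true-hypertension fraction.
    """
    pi = true_ht_fraction
    if not (0.0 <= pi <= 1.0):
        raise ValueError(f"true_ht_fraction={pi} outside [0, 1]")
    c_c, c_h = ps.cost_screen_cbpm, ps.cost_screen_hbpm
    if strategy.name == "CBPM":
        return c_c
    if strategy.name == "HBPM":
        return c_h
    if strategy.name == "Serial1":
        first_positive = pi * ps.se_cbpm + (1.0 - pi) * (1.0 - ps.sp_cbpm)
        return c_c + c_h * first_positive
    if strategy.name == "Serial2":
        first_negative = pi * (1.0 - ps.se_cbpm) + (1.0 - pi) * ps.sp_cbpm
        return c_c + c_h * first_negative
    raise ValueError(f"unknown strategy {strategy.name!r}")
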