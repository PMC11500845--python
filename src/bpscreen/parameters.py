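"""Model parameter definitions, validation, and (de)serialization.

The parameter file is a single UTF-8 text document: a small ``key: value``
scalar-config header (structural settings) followed by a ``[parameters]``
marker and a comma-separated table with columns::

    parameter, age_lower, age_upper, value, dist_family, dist_se,
    owsa_low, owsa_high, provenance

Age-banded parameters repeat the parameter name with the band columns
filled; scalar parameters leave them blank.  ``dist_family`` drives the
probabilistic sensitivity analysis (beta / gamma / fixed) and
``owsa_low``/``owsa_high`` the one-way ranges; blank ranges are filled
with +/-25% of the base value at load time (clipped to [0, 1] for
probabilities and utilities).
"""

from __future__ import annotations

import copy
import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd
import yaml

__all__ = [
    "AgeBand",
    "DistributionSpec",
    "ParameterSet",
    "SchemaError",
    "ValidationError",
    "load_parameter_set",
    "save_parameter_set",
    "validate_parameter_set",
]


class SchemaError(ValueError):
    """Raised when a parameter file does not follow the documented schema."""


class ValidationError(ValueError):
    """Raised when a ParameterSet violates its invariants.

    Carries the full list of violations, not just the first.
    """

    def __init__(self, violations: List[str]):
        self.violations = list(violations)
        super().__init__("invalid parameter set:\n  " + "\n  ".join(self.violations))


@dataclass(frozen=True, order=True)
class AgeBand:
    """Closed age interval [lower, upper] in whole years."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"AgeBand lower {self.lower} > upper {self.upper}")

    def contains(self, age: int) -> bool:
        return self.lower <= age <= self.upper

    @property
    def label(self) -> str:
        return f"{self.lower}-{self.upper}"

    @classmethod
    def parse(cls, text: str) -> "AgeBand":
        m = re.fullmatch(r"\s*(\d+)\s*-\s*(\d+)\s*", str(text))
        if not m:
            raise SchemaError(f"cannot parse age band {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class DistributionSpec:
    """PSA sampling distribution: family plus (mean, SE) on the natural scale.

    ``beta`` for probabilities/utilities, ``gamma`` for costs, ``fixed``
    for parameters held at their base value.
    """

    family: str  # beta | gamma | fixed
    mean: float
    se: float = 0.0

    FAMILIES = ("beta", "gamma", "fixed")

    def __post_init__(self) -> None:
        if self.family not in self.FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ValueError("dispersion (SE) must be >= 0")
        if self.family == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ValueError(f"beta mean {self.mean} outside [0, 1]")
        if self.family == "gamma" and self.mean <= 0:
            raise ValueError(f"gamma mean {self.mean} must be > 0")


BandTable = Dict[AgeBand, float]

# scalar parameter name -> validation kind
SCALAR_KINDS: Dict[str, str] = {
    "discount_rate": "rate",
    "p_controlled_to_uncontrolled": "probability",
    "p_uncontrolled_to_controlled": "probability",
    "p_cvd_death_young": "probability",
    "p_cvd_death_old": "probability",
    "prop_stroke": "probability",
    "prop_cad": "probability",
    "prop_hemorrhagic": "probability",
    "prop_ischemic": "probability",
    "se_cbpm": "probability",
    "sp_cbpm": "probability",
    "se_hbpm": "probability",
    "sp_hbpm": "probability",
    "cost_screen_cbpm": "cost",
    "cost_screen_hbpm": "cost",
    "cost_ht_controlled": "cost",
    "cost_ht_uncontrolled": "cost",
    "cost_cvd_acute": "cost",
    "cost_cvd_chronic": "cost",
    "nonmed_visit_cost": "cost",
    "nonmed_inpatient_cost_per_day": "cost",
    "visits_controlled": "count",
    "visits_uncontrolled": "count",
    "visits_cvd_chronic": "count",
    "acute_admission_days": "count",
    "u_healthy": "utility",
    "u_ht": "utility",
    "u_stroke": "utility",
    "u_cad": "utility",
    "u_death": "utility",
}

BANDED_KINDS: Dict[str, str] = {
    "ht_incidence": "probability",
    "p_cvd_given_uncontrolled": "probability",
    "p_cvd_given_controlled": "probability",
    "p_death_other": "probability",
}

_BANDED_NAME_RE = re.compile(r"^(\w+)\[(\d+)-(\d+)\]$")


@dataclass
class ParameterSet:
    """Complete input set for the screening cost-utility model.

    Banded entries map :class:`AgeBand` to an annual probability; ``psa``
    and ``owsa_range`` are keyed by parameter name, with banded entries
    written ``name[lo-hi]``.  Costs are 2021 Thai baht; the model cycle is
    one year.
    """

    start_age: int = 35
    end_age: int = 100
    wtp: float = 160_000.0

    discount_rate: float = 0.03

    ht_incidence: BandTable = field(default_factory=dict)
    p_cvd_given_uncontrolled: BandTable = field(default_factory=dict)
    p_cvd_given_controlled: BandTable = field(default_factory=dict)
    p_death_other: BandTable = field(default_factory=dict)

    p_controlled_to_uncontrolled: float = 0.0
    p_uncontrolled_to_controlled: float = 0.0
    p_cvd_death_young: float = 0.00699
    p_cvd_death_old: float = 0.0853

    prop_stroke: float = 0.64
    prop_cad: float = 0.36
    prop_hemorrhagic: float = 0.35
    prop_ischemic: float = 0.65

    se_cbpm: float = 1.0
    sp_cbpm: float = 1.0
    se_hbpm: float = 1.0
    sp_hbpm: float = 1.0

    cost_screen_cbpm: float = 0.0
    cost_screen_hbpm: float = 0.0
    cost_ht_controlled: float = 0.0
    cost_ht_uncontrolled: float = 0.0
    cost_cvd_acute: float = 0.0
    cost_cvd_chronic: float = 0.0
    nonmed_visit_cost: float = 0.0
    nonmed_inpatient_cost_per_day: float = 0.0

    visits_controlled: float = 4.0
    visits_uncontrolled: float = 8.0
    visits_cvd_chronic: float = 8.0
    acute_admission_days: float = 9.83

    u_healthy: float = 1.0
    u_ht: float = 0.95
    u_stroke: float = 0.55
    u_cad: float = 0.75
    u_death: float = 0.0

    psa: Dict[str, DistributionSpec] = field(default_factory=dict)
    owsa_range: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    # ---- generic access by name -------------------------------------
    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def get(self, name: str) -> float:
        """Value of a parameter by name (``name`` or ``name[lo-hi]``)."""
        m = _BANDED_NAME_RE.match(name)
        if m:
            table: BandTable = getattr(self, m.group(1))
            return table[AgeBand(int(m.group(2)), int(m.group(3)))]
        if name in SCALAR_KINDS or name in ("start_age", "end_age", "wtp"):
            return getattr(self, name)
        raise KeyError(name)

    def set(self, name: str, value: float) -> None:
        m = _BANDED_NAME_RE.match(name)
        if m:
            if m.group(1) not in BANDED_KINDS:
                raise KeyError(name)
            table: BandTable = getattr(self, m.group(1))
            table[AgeBand(int(m.group(2)), int(m.group(3)))] = value
            return
        if name in SCALAR_KINDS or name in ("start_age", "end_age", "wtp"):
            setattr(self, name, value)
            return
        raise KeyError(name)

    def band_value(self, table_name: str, age: int) -> float:
        """Look up a banded parameter at a given age."""
        table: BandTable = getattr(self, table_name)
        for band, value in table.items():
            if band.contains(age):
                return value
        raise KeyError(f"{table_name} has no band covering age {age}")

    def parameter_names(self) -> List[str]:
        """All varied-parameter names (scalars plus expanded banded names)."""
        names = list(SCALAR_KINDS)
        for tname in BANDED_KINDS:
            table: BandTable = getattr(self, tname)
            names.extend(f"{tname}[{b.label}]" for b in sorted(table))
        return names

    def validate(self) -> List[str]:
        return validate_parameter_set(self)


def _check_kind(name: str, value: float, kind: str, out: List[str]) -> None:
    if not math.isfinite(value):
        out.append(f"{name}={value}: must be finite")
        return
    if kind == "probability" and not (0.0 <= value <= 1.0):
        out.append(f"{name}={value}: probability outside [0, 1]")
    elif kind == "utility" and not (0.0 <= value <= 1.0):
        out.append(f"{name}={value}: utility outside [0, 1]")
    elif kind in ("cost", "count") and value < 0:
        out.append(f"{name}={value}: must be >= 0")
    elif kind == "rate" and value < 0:
        out.append(f"{name}={value}: rate must be >= 0")


def _check_band_coverage(name: str, table: BandTable, lo: int, hi: int,
                         out: List[str]) -> None:
    if not table:
        out.append(f"{name}: no age bands defined")
        return
    bands = sorted(table)
    for a, b in zip(bands, bands[1:]):
        if b.lower <= a.upper:
            out.append(f"{name}: bands {a.label} and {b.label} overlap")
    if bands[0].lower > lo:
        out.append(f"{name}: no band covers age {lo}")
    cursor = bands[0].lower
    for band in bands:
        if band.lower > cursor:
            out.append(f"{name}: gap between ages {cursor} and {band.lower}")
        cursor = max(cursor, band.upper + 1)
    if cursor <= hi:
        out.append(f"{name}: no band covers ages {cursor}..{hi}")


def validate_parameter_set(ps: ParameterSet) -> List[str]:
    """Return all invariant violations (empty list == valid)."""
    out: List[str] = []
    if ps.start_age >= ps.end_age:
        out.append(f"start_age={ps.start_age} must be < end_age={ps.end_age}")
    for name, kind in SCALAR_KINDS.items():
        _check_kind(name, getattr(ps, name), kind, out)
    for tname, kind in BANDED_KINDS.items():
        table: BandTable = getattr(ps, tname)
        for band, value in table.items():
            _check_kind(f"{tname}[{band.label}]", value, kind, out)
        _check_band_coverage(tname, table, ps.start_age, ps.end_age - 1, out)
    if abs(ps.prop_stroke + ps.prop_cad - 1.0) > 1e-9:
        out.append(
            f"prop_stroke={ps.prop_stroke} + prop_cad={ps.prop_cad} must sum to 1")
    if abs(ps.prop_hemorrhagic + ps.prop_ischemic - 1.0) > 1e-9:
        out.append(
            f"prop_hemorrhagic={ps.prop_hemorrhagic} + "
            f"prop_ischemic={ps.prop_ischemic} must sum to 1")
    if ps.wtp < 0:
        out.append(f"wtp={ps.wtp} must be >= 0")
    return out


# ---------------------------------------------------------------------------
# serialization

_TABLE_MARKER = "[parameters]"
_TABLE_COLUMNS = ["parameter", "age_lower", "age_upper", "value",
                  "dist_family", "dist_se", "owsa_low", "owsa_high",
                  "provenance"]


def _default_owsa(name: str, value: float, kind: str) -> Tuple[float, float]:
    """+/-25% of base, clipped into the parameter's legal range."""
    lo, hi = 0.75 * value, 1.25 * value
    if kind in ("probability", "utility"):
        hi = min(hi, 1.0)
    return lo, hi


def _kind_of(name: str) -> str:
    m = _BANDED_NAME_RE.match(name)
    if m:
        return BANDED_KINDS[m.group(1)]
    return SCALAR_KINDS[name]


def load_parameter_set(path) -> ParameterSet:
    """Load and validate a parameter file.

    Raises :class:`SchemaError` for structural problems (missing fields,
    unknown parameters) and :class:`ValidationError` listing every
    invariant violation.
    """
    text = Path(path).read_text(encoding="utf-8")
    if _TABLE_MARKER not in text:
        raise SchemaError(f"missing {_TABLE_MARKER} section")
    head, _, tail = text.partition(_TABLE_MARKER)
    try:
        scalars = yaml.safe_load(head) or {}
    except yaml.YAMLError as exc:
        raise SchemaError(f"malformed scalar-config header: {exc}") from exc
    for key in ("start_age", "end_age", "wtp"):
        if key not in scalars:
            raise SchemaError(f"missing required scalar-config field {key!r}")

    table = pd.read_csv(io.StringIO(tail.lstrip("\n")),
                        dtype={"parameter": str}, skipinitialspace=True,
                        float_precision="round_trip")
    missing_cols = [c for c in _TABLE_COLUMNS[:4] if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"parameter table missing columns {missing_cols}")

    ps = ParameterSet(start_age=int(scalars["start_age"]),
                      end_age=int(scalars["end_age"]),
                      wtp=float(scalars["wtp"]))
    ps.ht_incidence = {}
    ps.p_cvd_given_uncontrolled = {}
    ps.p_cvd_given_controlled = {}
    ps.p_death_other = {}

    seen = set()
    for row in table.itertuples(index=False):
        pname = row.parameter.strip()
        banded = pname in BANDED_KINDS
        if not banded and pname not in SCALAR_KINDS:
            raise SchemaError(f"unknown parameter {pname!r}")
        value = float(row.value)
        if banded:
            if pd.isna(row.age_lower) or pd.isna(row.age_upper):
                raise SchemaError(f"{pname}: banded parameter needs age bounds")
            band = AgeBand(int(row.age_lower), int(row.age_upper))
            getattr(ps, pname)[band] = value
            full = f"{pname}[{band.label}]"
        else:
            setattr(ps, pname, value)
            full = pname
        if full in seen:
            raise SchemaError(f"duplicate parameter row {full!r}")
        seen.add(full)

        fam = getattr(row, "dist_family", None)
        fam = "fixed" if (fam is None or pd.isna(fam)) else str(fam).strip()
        se = getattr(row, "dist_se", None)
        se = 0.0 if (se is None or pd.isna(se)) else float(se)
        try:
            ps.psa[full] = DistributionSpec(fam, value, se)
        except ValueError as exc:
            # a mean outside the family's domain is a value problem, not a
            # file-structure problem: let final validation report it by name
            probe: List[str] = []
            _check_kind(full, value, _kind_of(full), probe)
            if probe:
                ps.psa[full] = DistributionSpec("fixed", 0.0)
            else:
                raise SchemaError(
                    f"{full}: bad distribution spec: {exc}") from exc

        lo = getattr(row, "owsa_low", None)
        hi = getattr(row, "owsa_high", None)
        if lo is None or hi is None or pd.isna(lo) or pd.isna(hi):
            ps.owsa_range[full] = _default_owsa(full, value, _kind_of(full))
        else:
            ps.owsa_range[full] = (float(lo), float(hi))

        prov = getattr(row, "provenance", None)
        ps.provenance[full] = ("" if prov is None or pd.isna(prov)
                               else str(prov).strip())

    required = set(SCALAR_KINDS)
    present = {n for n in seen if "[" not in n}
    absent = sorted(required - present)
    if absent:
        raise SchemaError(f"missing required parameters: {absent}")

    violations = validate_parameter_set(ps)
    if violations:
        raise ValidationError(violations)
    return ps


def save_parameter_set(ps: ParameterSet, path) -> None:
    """Write a ParameterSet in the load_parameter_set file format."""
    lines = [
        "# bpscreen parameter file",
        "schema: bpscreen-params-v1",
        f"start_age: {ps.start_age}",
        f"end_age: {ps.end_age}",
        f"wtp: {ps.wtp!r}",
        "",
        _TABLE_MARKER,
        ",".join(_TABLE_COLUMNS),
    ]

    def row(full: str, lo, hi, value: float) -> str:
        spec = ps.psa.get(full, DistributionSpec("fixed", value))
        olo, ohi = ps.owsa_range.get(
            full, _default_owsa(full, value, _kind_of(full)))
        prov = ps.provenance.get(full, "")
        base = full.split("[")[0]
        return (f"{base},{lo},{hi},{value!r},{spec.family},"
                f"{spec.se!r},{olo!r},{ohi!r},{prov}")

    for name in SCALAR_KINDS:
        lines.append(row(name, "", "", getattr(ps, name)))
    for tname in BANDED_KINDS:
        table: BandTable = getattr(ps, tname)
        for band in sorted(table):
            lines.append(row(f"{tname}[{band.label}]",
                             band.lower, band.upper, table[band]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
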