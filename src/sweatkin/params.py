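"""Physical parameters of the blood → ISF → sweat-gland urea transport model.

Units follow a single internal convention:

* concentrations in mol m⁻³ — numerically identical to mmol L⁻¹, so clinical
  values can be used unchanged;
* pressures in mmHg as tabulated; they are converted to Pa (1 mmHg =
  133.322 Pa) only where hydraulic resistance (Pa s m⁻³) enters the flow
  balance;
* everything else in SI.

The default values are the literature constants of the transport model; the
active-transport rate ``S`` defaults to 0 (purely passive transport) because
no literature reference value exists, and the normalized sweat velocity
``u_sweat_n`` defaults to 1 (passive sweating).
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
from dataclasses import dataclass
from typing import Iterator

MMHG_TO_PA = 133.322
"""Pressure conversion factor, Pa per mmHg."""


@dataclass(frozen=True)
class ModelParameters:
    """Constants of the three-compartment urea transport model.

    Attributes
    ----------
    Pc : float
        Capillary hydrostatic pressure (mmHg).
    PISF : float
        Interstitial hydrostatic pressure (mmHg).
    Lpc : float
        Capillary hydraulic conductivity (m s⁻¹ mmHg⁻¹).
    kDE : float
        Dermal clearance rate of urea, capillary → ISF (s⁻¹).
    Dsg_wall : float
        Urea diffusivity across the gland wall (m² s⁻¹).
    DISF : float
        Urea diffusivity in interstitial fluid (m² s⁻¹).
    Dsw : float
        Urea diffusivity in sweat, inside the gland lumen (m² s⁻¹).
    Asg : float
        Luminal cross-sectional area of the sweat gland (m²).
    Ac : float
        Capillary exchange surface area (m²).
    AISF : float
        ISF cross-sectional area (m²).
    Vp : float
        Effective plasma (capillary) volume per gland (m³).
    VISF : float
        Effective ISF volume per gland (m³).
    d : float
        Gland luminal diameter (m).
    L : float
        Gland length (m).
    Kwu : float
        Dimensionless water/urea volumetric flow ratio (dilution strength).
    hsg : float
        Gland-wall thickness (m).
    mu : float
        Water viscosity (Pa s).
    S : float
        Active urea transport rate into the gland lumen (mol m⁻³ s⁻¹,
        numerically mmol L⁻¹ s⁻¹).
    u_sweat_n : float
        Measured sweat velocity normalized to the passive reference velocity
        (dimensionless).
    u_passive : float
        Reference passive sweat velocity (m s⁻¹).
    """

    Pc: float = 30.0
    PISF: float = -3.0
    Lpc: float = 6.5e-10
    kDE: float = 1.2e-3
    Dsg_wall: float = 3.01e-10
    DISF: float = 9.29e-10
    Dsw: float = 1.38e-9
    Asg: float = 1.96e-11
    Ac: float = 1.5e-8
    AISF: float = 2.2e-8
    Vp: float = 3.02e-13
    VISF: float = 6.0e-13
    d: float = 5e-6
    L: float = 4e-3
    Kwu: float = 2.5
    hsg: float = 5e-5
    mu: float = 1e-3
    S: float = 0.0
    u_sweat_n: float = 1.0
    u_passive: float = 3e-4

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))


# Fields that must be strictly positive for the model to be well posed.
_STRICTLY_POSITIVE = (
    "Lpc",
    "kDE",
    "Dsg_wall",
    "DISF",
    "Dsw",
    "Asg",
    "Ac",
    "AISF",
    "Vp",
    "VISF",
    "d",
    "L",
    "hsg",
    "mu",
    "u_passive",
)
# Fields that must be non-negative.
_NON_NEGATIVE = ("Kwu", "S")


def default_parameters() -> ModelParameters:
    """Return the literature default parameter set.

    ``S = 0`` (no reference value exists for the active-transport rate, so
    the default model is purely passive) and ``u_sweat_n = 1`` (passive
    sweating).
    """
    return ModelParameters()


def validate(params: ModelParameters) -> list[str]:
    """Check type invariants; return a list of human-readable violations.

    An empty list means the parameter set is valid.  This reports rather than
    raises so callers can aggregate problems across a configuration file.
    """
    violations: list[str] = []
    for name in _STRICTLY_POSITIVE:
        value = getattr(params, name)
        if not value > 0:
            violations.append(f"{name} must be strictly positive, got {value!r}")
    for name in _NON_NEGATIVE:
        value = getattr(params, name)
        if not value >= 0:
            violations.append(f"{name} must be non-negative, got {value!r}")
    if not params.u_sweat_n > 0:
        violations.append(
            f"u_sweat_n must be strictly positive, got {params.u_sweat_n!r}"
        )
    return violations


def perturb(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a copy of *params* with field *name* set to *value*.

    The input is never mutated (``ModelParameters`` is frozen).  Unknown
    names raise ``KeyError`` naming the offending field.
    """
    if name not in ModelParameters.field_names():
        raise KeyError(f"unknown model parameter: {name!r}")
    return params.replace(**{name: value})


# ---------------------------------------------------------------------------
# Parameter file I/O: flat JSON keyed by symbol name, or CSV (symbol,value,unit)
# ---------------------------------------------------------------------------

_UNITS: dict[str, str] = {
    "Pc": "mmHg",
    "PISF": "mmHg",
    "Lpc": "m s-1 mmHg-1",
    "kDE": "s-1",
    "Dsg_wall": "m2 s-1",
    "DISF": "m2 s-1",
    "Dsw": "m2 s-1",
    "Asg": "m2",
    "Ac": "m2",
    "AISF": "m2",
    "Vp": "m3",
    "VISF": "m3",
    "d": "m",
    "L": "m",
    "Kwu": "-",
    "hsg": "m",
    "mu": "Pa s",
    "S": "mol m-3 s-1",
    "u_sweat_n": "-",
    "u_passive": "m s-1",
}


def to_json(params: ModelParameters) -> str:
    """Serialize to a flat JSON object keyed by symbol name (lossless)."""
    return json.dumps(params.to_dict(), indent=2)


def from_json(text: str) -> ModelParameters:
    """Parse a flat JSON parameter object; missing keys take defaults."""
    data = json.loads(text)
    unknown = set(data) - set(ModelParameters.field_names())
    if unknown:
        raise KeyError(f"unknown model parameters in JSON: {sorted(unknown)}")
    return ModelParameters(**{k: float(v) for k, v in data.items()})


def to_csv(params: ModelParameters) -> str:
    """Serialize to ``symbol,value,unit`` CSV (repr-roundtrip floats)."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["symbol", "value", "unit"])
    for name, value in params.to_dict().items():
        writer.writerow([name, repr(value), _UNITS[name]])
    return buf.getvalue()


def from_csv(text: str) -> ModelParameters:
    """Parse the ``symbol,value,unit`` CSV dialect written by :func:`to_csv`."""
    reader = csv.DictReader(io.StringIO(text))
    values: dict[str, float] = {}
    for row in reader:
        name = row["symbol"]
        if name not in ModelParameters.field_names():
            raise KeyError(f"unknown model parameter in CSV: {name!r}")
        values[name] = float(row["value"])
    return ModelParameters(**values)


def iter_physical_fields() -> Iterator[str]:
    """Names of parameters that are physical constants (everything but the
    operating inputs ``S``, ``u_sweat_n``)."""
    for name in ModelParameters.field_names():
        if name not in ("S", "u_sweat_n"):
            yield name
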