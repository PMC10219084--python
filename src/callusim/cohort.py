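"""Synthetic patient cohort and fracture/fixation scenario generation.

The clinical cohort this package emulates consists of adults (inclusion
window 16-65 years) with closed diaphyseal femoral shaft fractures treated
by intramedullary nailing.  Anthropometrics are drawn from truncated normal
distributions whose parent moments match the target population summary
(age 30.4 +/- 14.5 y, height 173.4 +/- 12.8 cm, weight 80.4 +/- 18.3 kg);
BMI is derived from height and weight, never sampled independently.

Because no per-case fracture geometry is available, scenarios are a mixture
of two artifact classes: "favorable" (small gap, adequately sized nail) and
"compromised" (large gap and undersized nail), at a configurable fraction.
The compromised class is constructed to violate the strain windows of the
healing module, so that both union and non-union outcomes occur in a
synthetic cohort.

All sampling is driven by a single integer seed threaded through
``numpy.random.default_rng``; identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PatientCase",
    "FractureConfig",
    "NailConfig",
    "CohortParams",
    "Scenario",
    "ConfigurationError",
    "sample_patient",
    "sample_scenario",
    "sample_cohort",
    "write_cohort",
    "read_cohort",
]

AGE_MIN = 16.0
AGE_MAX = 65.0

SCHEMA_VERSION = 1


class ConfigurationError(ValueError):
    """Invalid configuration value; the message names the offending field."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {msg}")


@dataclass(frozen=True)
class PatientCase:
    """Anthropometrics and laterality for one simulated patient."""

    id: str
    age: float  # years, inside the clinical inclusion window [16, 65]
    height: float  # cm
    weight: float  # kg
    sex: str  # "F" or "M"
    side: str  # "left" or "right"

    def __post_init__(self) -> None:
        _require(AGE_MIN <= self.age <= AGE_MAX, "age",
                 f"{self.age} outside inclusion window [{AGE_MIN:g}, {AGE_MAX:g}]")
        _require(self.height > 0, "height", "must be positive")
        _require(self.weight > 0, "weight", "must be positive")
        _require(self.sex in ("F", "M"), "sex", f"unknown value {self.sex!r}")
        _require(self.side in ("left", "right"), "side", f"unknown value {self.side!r}")

    @property
    def bmi(self) -> float:
        """Body-mass index in kg/m^2, derived from height and weight."""
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class FractureConfig:
    """Idealized diaphyseal fracture geometry.

    The gap is a planar slab of thickness ``gap_size`` whose normal is
    tilted by ``obliquity`` degrees from the transverse plane; the distal
    fragment may be translated by ``translational_offset`` (malalignment).
    ``callus_envelope_thickness`` is the radial extent of the periosteal
    healing envelope in which callus may form.
    """

    gap_size: float  # mm
    obliquity: float = 0.0  # degrees from transverse
    translational_offset: float = 0.0  # mm
    callus_envelope_thickness: float = 4.0  # mm

    def __post_init__(self) -> None:
        _require(self.gap_size >= 0, "gap_size", "must be >= 0")
        _require(0 <= self.obliquity < 90, "obliquity", "must be in [0, 90)")
        _require(self.translational_offset >= 0, "translational_offset", "must be >= 0")
        _require(self.callus_envelope_thickness > 0,
                 "callus_envelope_thickness", "must be > 0")


@dataclass(frozen=True)
class NailConfig:
    """Parametric cylindrical intramedullary nail with locking screws."""

    diameter: float  # mm; must be smaller than the medullary canal
    elastic_modulus: float = 110_000.0  # MPa (titanium alloy)
    locking: str = "static"  # "static" or "dynamic"
    screw_positions: tuple[float, ...] = (-25.0, 25.0)  # axial offsets, mm

    def __post_init__(self) -> None:
        _require(self.diameter > 0, "diameter", "must be > 0")
        _require(self.elastic_modulus > 0, "elastic_modulus", "must be > 0")
        _require(self.locking in ("static", "dynamic"), "locking",
                 f"unknown value {self.locking!r}")


@dataclass(frozen=True)
class CohortParams:
    """Moments and mixture settings for synthetic cohort generation.

    Defaults reproduce the target population's summary statistics; the
    compromised fraction defaults to the clinical non-union prevalence
    (6 of 27 cases).
    """

    age_mean: float = 30.4
    age_sd: float = 14.5
    height_mean: float = 173.4
    height_sd: float = 12.8
    weight_mean: float = 80.4
    weight_sd: float = 18.3
    male_fraction: float = 20.0 / 27.0
    left_fraction: float = 17.0 / 27.0
    fraction_compromised: float = 6.0 / 27.0
    # favorable scenarios: small gap, adequately sized nail
    favorable_gap_range: tuple[float, float] = (1.0, 3.0)
    favorable_nail_range: tuple[float, float] = (12.5, 14.0)
    # compromised scenarios: large gap and undersized nail
    compromised_gap_range: tuple[float, float] = (6.0, 10.0)
    compromised_nail_range: tuple[float, float] = (8.5, 9.5)
    obliquity_max: float = 25.0  # degrees
    offset_max: float = 1.0  # mm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("age_sd", "height_sd", "weight_sd"):
            _require(getattr(self, name) >= 0, name, "standard deviation must be >= 0")
        for name in ("age_mean", "height_mean", "weight_mean"):
            _require(getattr(self, name) > 0, name, "mean must be > 0")
        for name in ("male_fraction", "left_fraction", "fraction_compromised"):
            v = getattr(self, name)
            _require(0 <= v <= 1, name, "fraction must be in [0, 1]")
        for name in ("favorable_gap_range", "favorable_nail_range",
                     "compromised_gap_range", "compromised_nail_range"):
            lo, hi = getattr(self, name)
            _require(0 < lo <= hi, name, "range must satisfy 0 < lo <= hi")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Scenario:
    """One simulated case: a patient plus fracture and fixation parameters.

    ``compromised`` records the generative class and serves as ground truth
    for cohort-level confusion-matrix evaluation (compromised -> expected
    non-union).
    """

    patient: PatientCase
    fracture: FractureConfig
    nail: NailConfig
    compromised: bool


def _truncnorm_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float, n: int | None = None):
    """Draw from a normal with parent moments (mean, sd), truncated to [lo, hi]."""
    if sd == 0:
        return mean if n is None else np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.rvs(size=n, random_state=rng)


def sample_patient(params: CohortParams, rng: np.random.Generator,
                   case_id: str = "case-0") -> PatientCase:
    """Sample one patient from truncated normal anthropometric distributions.

    Age is truncated to the clinical inclusion window [16, 65]; height and
    weight to parent mean +/- 4 SD (floored at a small positive value) so
    no non-physical quantity can be drawn.  Note that hard truncation of the
    age window shifts the realized mean above the parent mean; see the
    methods note.
    """
    age = float(_truncnorm_draw(rng, params.age_mean, params.age_sd, AGE_MIN, AGE_MAX))
    height = float(_truncnorm_draw(
        rng, params.height_mean, params.height_sd,
        max(1.0, params.height_mean - 4 * params.height_sd),
        params.height_mean + 4 * params.height_sd))
    weight = float(_truncnorm_draw(
        rng, params.weight_mean, params.weight_sd,
        max(1.0, params.weight_mean - 4 * params.weight_sd),
        params.weight_mean + 4 * params.weight_sd))
    sex = "M" if rng.random() < params.male_fraction else "F"
    side = "left" if rng.random() < params.left_fraction else "right"
    return PatientCase(id=case_id, age=age, height=height, weight=weight,
                       sex=sex, side=side)


def sample_scenario(patient: PatientCase, params: CohortParams,
                    rng: np.random.Generator,
                    compromised: bool | None = None) -> Scenario:
    """Sample fracture and nail parameters for one patient.

    If ``compromised`` is None the class is drawn Bernoulli with
    ``params.fraction_compromised``.  Favorable scenarios draw a small gap
    and an adequately sized nail; compromised scenarios draw a large gap and
    an undersized nail.
    """
    if compromised is None:
        compromised = bool(rng.random() < params.fraction_compromised)
    gap_lo, gap_hi = (params.compromised_gap_range if compromised
                      else params.favorable_gap_range)
    nail_lo, nail_hi = (params.compromised_nail_range if compromised
                        else params.favorable_nail_range)
    nail_d = _feasible_nail(float(rng.uniform(nail_lo, nail_hi)),
                            patient.height)
    frac = FractureConfig(
        gap_size=float(rng.uniform(gap_lo, gap_hi)),
        obliquity=float(rng.uniform(0.0, params.obliquity_max)),
        translational_offset=_feasible_offset(
            float(rng.uniform(0.0, params.offset_max)), nail_d,
            patient.height),
    )
    return Scenario(patient=patient, fracture=frac,
                    nail=NailConfig(diameter=nail_d),
                    compromised=compromised)


def _feasible_nail(diameter: float, height_cm: float) -> float:
    """Cap the nail diameter at 88% of the height-implied canal diameter
    (a surgeon would not implant a nail that does not fit the canal)."""
    from .grid import canal_diameter_for_height
    return min(diameter, 0.88 * canal_diameter_for_height(height_cm))


def _feasible_offset(offset: float, nail_diameter: float,
                     height_cm: float) -> float:
    """Cap fragment malalignment at the residual canal slack around the
    nail (the nail physically limits translational displacement)."""
    from .grid import canal_diameter_for_height
    slack = (canal_diameter_for_height(height_cm) - nail_diameter) / 2
    return max(0.0, min(offset, 0.9 * slack))


def sample_cohort(params: CohortParams, n: int) -> list[Scenario]:
    """Sample ``n`` scenarios (vectorized draws); deterministic for a given
    ``params.seed``."""
    rng = params.rng()
    ages = np.atleast_1d(_truncnorm_draw(rng, params.age_mean, params.age_sd,
                                         AGE_MIN, AGE_MAX, n))
    heights = np.atleast_1d(_truncnorm_draw(
        rng, params.height_mean, params.height_sd,
        max(1.0, params.height_mean - 4 * params.height_sd),
        params.height_mean + 4 * params.height_sd, n))
    weights = np.atleast_1d(_truncnorm_draw(
        rng, params.weight_mean, params.weight_sd,
        max(1.0, params.weight_mean - 4 * params.weight_sd),
        params.weight_mean + 4 * params.weight_sd, n))
    males = rng.random(n) < params.male_fraction
    lefts = rng.random(n) < params.left_fraction
    compromised = rng.random(n) < params.fraction_compromised
    glo = np.where(compromised, params.compromised_gap_range[0],
                   params.favorable_gap_range[0])
    ghi = np.where(compromised, params.compromised_gap_range[1],
                   params.favorable_gap_range[1])
    nlo = np.where(compromised, params.compromised_nail_range[0],
                   params.favorable_nail_range[0])
    nhi = np.where(compromised, params.compromised_nail_range[1],
                   params.favorable_nail_range[1])
    gaps = rng.uniform(glo, ghi)
    nails = np.array([_feasible_nail(d, h)
                      for d, h in zip(rng.uniform(nlo, nhi), heights)])
    obliquities = rng.uniform(0.0, params.obliquity_max, n)
    offsets = np.array([_feasible_offset(o, d, h) for o, d, h
                        in zip(rng.uniform(0.0, params.offset_max, n),
                               nails, heights)])
    cohort = []
    for i in range(n):
        patient = PatientCase(
            id=f"case-{i:05d}", age=float(ages[i]), height=float(heights[i]),
            weight=float(weights[i]), sex="M" if males[i] else "F",
            side="left" if lefts[i] else "right")
        frac = FractureConfig(gap_size=float(gaps[i]),
                              obliquity=float(obliquities[i]),
                              translational_offset=float(offsets[i]))
        nail = NailConfig(diameter=float(nails[i]))
        cohort.append(Scenario(patient=patient, fracture=frac, nail=nail,
                               compromised=bool(compromised[i])))
    return cohort


# ---------------------------------------------------------------------------
# JSON round trip


def _scenario_to_dict(s: Scenario) -> dict:
    d = {
        "patient": asdict(s.patient),
        "fracture": asdict(s.fracture),
        "nail": asdict(s.nail),
        "compromised": s.compromised,
    }
    d["nail"]["screw_positions"] = list(s.nail.screw_positions)
    return d


def _scenario_from_dict(d: dict, index: int) -> Scenario:
    try:
        nail_kw = dict(d["nail"])
        nail_kw["screw_positions"] = tuple(nail_kw.get("screw_positions", (-25.0, 25.0)))
        return Scenario(
            patient=PatientCase(**d["patient"]),
            fracture=FractureConfig(**d["fracture"]),
            nail=NailConfig(**nail_kw),
            compromised=bool(d["compromised"]),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"scenario #{index}: malformed record ({exc})") from exc


def write_cohort(cohort: Sequence[Scenario], path) -> None:
    """Write a cohort to a schema-versioned JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "scenarios": [_scenario_to_dict(s) for s in cohort],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_cohort(path) -> list[Scenario]:
    """Read and validate a cohort JSON document (lossless round trip)."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(
                f"{path}: not valid JSON (line {exc.lineno}, col {exc.colno}): "
                f"{exc.msg}") from exc
    if not isinstance(doc, dict) or "scenarios" not in doc:
        raise ConfigurationError(f"{path}: missing 'scenarios' key")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"{path}: unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    return [_scenario_from_dict(d, i) for i, d in enumerate(doc["scenarios"])]
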