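"""Mechanoregulated tissue differentiation: the daily healing loop.

Each simulated day the current tissue distribution is homogenized, the
strain state under body-weight-scaled loading is solved by the voxel FE
model, each healing-region voxel is classified by its mechanical and
biological stimuli (distortional and dilatational strain, vascularity,
neighboring tissue composition), and the tissue concentrations and the
vascular front are advanced.

The rule set is a crisp strain-window scheme in the Claes-Heigele
tradition: low strain with adequate vascularity drives intramembranous
ossification (connective -> woven bone), moderate distortional strain
drives chondrogenesis (connective -> fibrocartilage), distortional strain
above the destruction cutoff (default 0.17, configurable up to 1.0)
destroys formed tissue.  Endochondral ossification (cartilage -> woven)
requires arriving vascularity; remodeling (woven -> lamellar) requires low
strain and near-full vascularity.  Bone-formation rates are scaled by the
mineralized content of the 6-neighborhood (osteoconduction), so ossification
advances as a front from existing bone surfaces and healing time grows with
gap size.

There are no stochastic terms; trajectories are fully deterministic
functions of the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import ConfigurationError, NailConfig, PatientCase
from .grid import Domain, Region, QUADRANT_NAMES, initial_state
from .mechanics import (LoadCoefficients, MaterialTable, StrainField,
                        assemble_and_solve, body_weight_load, homogenize,
                        make_fem)
from .outcome import quadrant_bridged
from .state import StateCorruptionError, TissueState

__all__ = [
    "Signal",
    "RuleSet",
    "HealingTrajectory",
    "classify_stimulus",
    "update_vascularity",
    "update_tissues",
    "simulate_healing",
]


class Signal:
    """Differentiation signal codes."""

    CONNECTIVE = 0
    INTRAMEMBRANOUS = 1
    CHONDROGENIC = 2
    DESTRUCTIVE = 3


@dataclass(frozen=True)
class RuleSet:
    """Strain windows, transition rates and vascular parameters.

    Windows are dimensionless strains; rates are fractions per day in
    [0, 1]; ``vascular_rate`` is the front speed in mm/day.  The defaults
    are calibration constants of this package (the strain-window tradition
    fixes their order of magnitude, not their exact values), chosen so that
    the favorable default scenario consolidates within the predicted-range
    envelope of 120-280 days while the compromised default does not bridge.
    """

    im_distortional_max: float = 0.05
    im_dilatational_max: float = 0.05  # absolute value bound
    chondro_distortional_min: float = 0.05
    destruction_cutoff: float = 0.17  # configurable up to 1.0
    v_min_ossification: float = 0.5
    v_min_remodeling: float = 0.9
    remodel_distortional_max: float = 0.05
    rate_intramembranous: float = 0.2
    rate_chondrogenesis: float = 0.1
    rate_endochondral: float = 0.15
    rate_remodeling: float = 0.008
    rate_destruction: float = 0.5
    vascular_rate: float = 0.1  # mm/day
    osteoconduction: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.destruction_cutoff <= 1.0):
            raise ConfigurationError("destruction_cutoff: must be in (0, 1]")
        if self.im_distortional_max > self.destruction_cutoff:
            raise ConfigurationError(
                "im_distortional_max: must not exceed the destruction cutoff")
        if self.chondro_distortional_min > self.destruction_cutoff:
            raise ConfigurationError(
                "chondro_distortional_min: must not exceed the destruction cutoff")
        for name in ("rate_intramembranous", "rate_chondrogenesis",
                     "rate_endochondral", "rate_remodeling", "rate_destruction"):
            r = getattr(self, name)
            if not (0 <= r <= 1):
                raise ConfigurationError(f"{name}: rate must be in [0, 1]")
        if self.vascular_rate < 0:
            raise ConfigurationError("vascular_rate: must be >= 0")
        for name in ("v_min_ossification", "v_min_remodeling"):
            if not (0 <= getattr(self, name) <= 1):
                raise ConfigurationError(f"{name}: must be in [0, 1]")


def classify_stimulus(distortional, dilatational, vascularity,
                      rules: RuleSet):
    """Classify the local stimulus into a differentiation signal.

    Returns ``(signal, weight)`` arrays (crisp memberships, weight 1).
    Destruction wins above the cutoff; intramembranous ossification
    requires both strain invariants inside the low window and vascularity
    at or above the ossification threshold; moderate distortional strain is
    chondrogenic; anything else leaves connective tissue unchanged.
    """
    dist = np.asarray(distortional, dtype=float)
    dil = np.asarray(dilatational, dtype=float)
    v = np.asarray(vascularity, dtype=float)
    signal = np.full(np.broadcast(dist, dil, v).shape, Signal.CONNECTIVE,
                     dtype=np.int8)
    destructive = dist > rules.destruction_cutoff
    intramem = (~destructive
                & (dist < rules.im_distortional_max)
                & (np.abs(dil) < rules.im_dilatational_max)
                & (v >= rules.v_min_ossification))
    chondro = ~destructive & ~intramem & (dist >= rules.chondro_distortional_min)
    signal[chondro] = Signal.CHONDROGENIC
    signal[intramem] = Signal.INTRAMEMBRANOUS
    signal[destructive] = Signal.DESTRUCTIVE
    weight = np.ones_like(signal, dtype=float)
    return signal, weight


def _neighbor_max(a: np.ndarray) -> np.ndarray:
    """Max of a over the 6-neighborhood (excluding the voxel itself)."""
    out = np.zeros_like(a)
    np.maximum(out[1:], a[:-1], out=out[1:])
    np.maximum(out[:-1], a[1:], out=out[:-1])
    np.maximum(out[:, 1:], a[:, :-1], out=out[:, 1:])
    np.maximum(out[:, :-1], a[:, 1:], out=out[:, :-1])
    np.maximum(out[:, :, 1:], a[:, :, :-1], out=out[:, :, 1:])
    np.maximum(out[:, :, :-1], a[:, :, 1:], out=out[:, :, :-1])
    return out


def update_vascularity(state: TissueState, strain_field: StrainField,
                       rules: RuleSet, voxel_size: float,
                       domain: Domain) -> TissueState:
    """Advance the vascular front by one day.

    Vascularity grows in healing-region voxels fed by vascularized
    neighbors at ``vascular_rate`` converted to voxel fractions per day; it
    never decreases, except that voxels under destructive strain are reset
    to 0 (vascular disruption), which also blocks ingrowth there.
    """
    v = state.vascularity.copy()
    healing = domain.healing_mask
    destructive = strain_field.distortional > rules.destruction_cutoff
    feed = _neighbor_max(state.vascularity)
    growth = (rules.vascular_rate / voxel_size) * feed
    v[healing] = np.minimum(1.0, v[healing] + growth[healing])
    v[healing & destructive] = 0.0
    new = state.copy()
    new.vascularity = v
    return new


def update_tissues(state: TissueState, signal: np.ndarray, weight: np.ndarray,
                   strain_field: StrainField, rules: RuleSet,
                   domain: Domain) -> TissueState:
    """Apply one day of tissue transitions on the healing region.

    Allowed transitions: connective -> woven (intramembranous), connective
    -> cartilage (chondrogenic), cartilage -> woven (endochondral, gated by
    vascularity), woven -> lamellar (remodeling at low strain and near-full
    vascularity), and any formed tissue -> connective (destructive).  The
    transferred fraction per transition is rate x membership weight
    (formation additionally scaled by the neighborhood mineral content when
    osteoconduction is enabled); concentrations are renormalized to unit
    sum and the day counter advances.
    """
    state.check_normalized(atol=1e-6)
    healing = domain.healing_mask
    new = state.copy()
    c_con, c_car = new.connective, new.cartilage
    c_wov, c_lam = new.woven, new.lamellar
    v = state.vascularity
    dist = strain_field.distortional

    if rules.osteoconduction:
        g_bone = np.minimum(1.0, _neighbor_max(state.mineral()))
    else:
        g_bone = np.ones(state.shape)

    destructive = healing & (signal == Signal.DESTRUCTIVE)
    intramem = healing & (signal == Signal.INTRAMEMBRANOUS)
    chondro = healing & (signal == Signal.CHONDROGENIC)
    not_destr = healing & (signal != Signal.DESTRUCTIVE)
    endo = not_destr & (v >= rules.v_min_ossification)
    remodel = (not_destr & (dist < rules.remodel_distortional_max)
               & (v >= rules.v_min_remodeling))

    # All transfers are computed from the start-of-day pools and applied
    # simultaneously, so a single intramembranous day moves exactly
    # rate x weight of the connective pool into woven bone.
    con0, car0 = state.connective, state.cartilage
    wov0, lam0 = state.woven, state.lamellar
    d = rules.rate_destruction * weight
    # destructive: all formed tissue decays toward connective
    for pool0, pool in ((car0, c_car), (wov0, c_wov), (lam0, c_lam)):
        moved = np.where(destructive, d * pool0, 0.0)
        pool -= moved
        c_con += moved
    # intramembranous ossification: connective -> woven at the bone front
    moved = np.where(intramem,
                     rules.rate_intramembranous * weight * g_bone * con0, 0.0)
    c_con -= moved
    c_wov += moved
    # chondrogenesis: connective -> cartilage
    moved = np.where(chondro, rules.rate_chondrogenesis * weight * con0, 0.0)
    c_con -= moved
    c_car += moved
    # endochondral ossification: cartilage -> woven where vascularized
    moved = np.where(endo, rules.rate_endochondral * g_bone * car0, 0.0)
    c_car -= moved
    c_wov += moved
    # remodeling: woven -> lamellar at low strain, full vascularity
    moved = np.where(remodel, rules.rate_remodeling * wov0, 0.0)
    c_wov -= moved
    c_lam += moved

    total = c_con + c_car + c_wov + c_lam
    if np.any(total[healing] <= 0):
        raise StateCorruptionError("tissue concentrations vanished in a voxel")
    for pool in (c_con, c_car, c_wov, c_lam):
        pool[healing] /= total[healing]
    new.day = state.day + 1
    return new


@dataclass
class HealingTrajectory:
    """Record of one healing simulation.

    ``bridge_days`` maps quadrant names to the first day a continuous
    lamellar column spanned the healing region in that quadrant (None if
    never); ``snapshots`` holds (day, TissueState) pairs at the configured
    cadence plus one at every bridging event; ``summary`` holds per-day
    scalar series.
    """

    domain: Domain
    snapshots: list = field(default_factory=list)
    strain_snapshots: list = field(default_factory=list)  # (day, StrainField)
    bridge_days: dict = field(default_factory=dict)
    summary: dict = field(default_factory=lambda: {
        "day": [], "mean_gap_distortional": [], "mean_gap_dilatational": [],
        "bridged_count": [], "mass_error": []})
    final_state: TissueState | None = None
    max_mass_error: float = 0.0

    @property
    def days_simulated(self) -> int:
        return 0 if self.final_state is None else self.final_state.day

    def summary_frame(self):
        """Per-day scalar series (mean gap strains, bridged-quadrant count,
        mass error) as a pandas DataFrame indexed by day."""
        import pandas as pd
        return pd.DataFrame(self.summary).set_index("day")


def simulate_healing(domain: Domain, patient: PatientCase, nail: NailConfig,
                     rules: RuleSet = RuleSet(),
                     materials: MaterialTable = MaterialTable(),
                     load_coefficients: LoadCoefficients = LoadCoefficients(),
                     max_days: int = 280,
                     snapshot_every: int | None = None,
                     bridge_threshold: float = 0.70,
                     stop_after_bridged: int | None = None,
                     solver: str = "auto",
                     rtol: float = 1e-8,
                     mechanics_interval: int = 1) -> HealingTrajectory:
    """Run the daily healing loop and record the trajectory.

    Each day: homogenize -> elastic solve (warm-started) -> stimulus
    classification -> vascular update -> tissue update -> bridging check.
    ``stop_after_bridged`` ends the run early once that many quadrants have
    bridged (saves time when only the consolidation day is needed).
    ``mechanics_interval`` > 1 re-solves the elastic problem only every
    that many days, reusing the last strain field in between (a quasi-static
    coarsening appropriate when tissue moduli change by a few percent per
    day).  Deterministic for identical inputs.
    """
    materials = replace(materials, nail_modulus=nail.elastic_modulus)
    state = initial_state(domain)
    traj = HealingTrajectory(domain=domain)
    traj.snapshots.append((0, state.copy()))
    traj.bridge_days = {name: None for name in QUADRANT_NAMES.values()}
    traj.final_state = state
    if max_days <= 0:
        return traj

    fem = make_fem(domain, materials)
    gap = domain.region == Region.GAP
    if not gap.any():
        gap = domain.healing_mask  # degenerate zero-gap scenario
    u = None
    strain = None
    load = body_weight_load(patient, load_coefficients)
    for day in range(1, max_days + 1):
        if strain is None or (day - 1) % mechanics_interval == 0:
            E = homogenize(state, materials, domain)
            try:
                strain, u = assemble_and_solve(domain, E, load, fem=fem,
                                               x0=u, rtol=rtol, solver=solver)
            except Exception as exc:
                raise RuntimeError(
                    f"elastic solve failed at day {day}: {exc}") from exc
        signal, weight = classify_stimulus(
            strain.distortional, strain.dilatational, state.vascularity, rules)
        state = update_vascularity(state, strain, rules, domain.voxel_size, domain)
        state = update_tissues(state, signal, weight, strain, rules, domain)
        traj.max_mass_error = max(traj.max_mass_error, state.max_mass_error())

        newly_bridged = False
        for code, name in QUADRANT_NAMES.items():
            if traj.bridge_days[name] is None and quadrant_bridged(
                    state, domain, code, threshold=bridge_threshold):
                traj.bridge_days[name] = day
                newly_bridged = True
        n_bridged = sum(d is not None for d in traj.bridge_days.values())

        take_snapshot = newly_bridged or (
            snapshot_every is not None and day % snapshot_every == 0)
        if take_snapshot:
            traj.snapshots.append((day, state.copy()))
            traj.strain_snapshots.append((day, strain))
        traj.summary["day"].append(day)
        traj.summary["mean_gap_distortional"].append(
            float(strain.distortional[gap].mean()))
        traj.summary["mean_gap_dilatational"].append(
            float(strain.dilatational[gap].mean()))
        traj.summary["bridged_count"].append(n_bridged)
        traj.summary["mass_error"].append(state.max_mass_error())
        traj.final_state = state
        if stop_after_bridged is not None and n_bridged >= stop_after_bridged:
            break
    return traj
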