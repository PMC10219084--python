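"""Labeled voxel domain for an idealized nailed femoral diaphysis.

The femoral shaft segment around the fracture is modeled as a straight
hollow cylinder (cortex around a medullary canal) with a cylindrical
intramedullary nail, a planar fracture-gap slab of configurable thickness
and obliquity, and an annular periosteal callus envelope in which healing
tissue may form.  Locking screws are stiff chords through the canal at
configured axial offsets and provide the nail-to-bone load path.

Coordinate convention (fixed, 0-based voxel indexing, half-open extents):
  z -- shaft axis, proximal at high z; the gap slab is centered axially;
  x -- anterior direction;
  y -- lateral for a right femur (medial for a left one).
The shaft axis passes through the transverse grid center.

Region labels partition the grid; the four anatomical quadrant labels
(anterior, posterior, medial, lateral) are 90-degree angular sectors about
the shaft axis with boundaries on the diagonals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import ConfigurationError, FractureConfig, NailConfig, PatientCase
from .state import TissueState

__all__ = [
    "Region",
    "Quadrant",
    "GeometryParams",
    "Domain",
    "InfeasibleScenarioError",
    "build_domain",
    "assign_quadrants",
    "initial_state",
    "QUADRANT_NAMES",
]


class Region:
    """Region label codes (mutually exclusive, exhaustive)."""

    OUTSIDE = 0
    CORTEX = 1
    CANAL = 2
    NAIL = 3
    GAP = 4
    ENVELOPE = 5


class Quadrant:
    """Quadrant label codes."""

    NONE = 0
    ANTERIOR = 1
    POSTERIOR = 2
    MEDIAL = 3
    LATERAL = 4


QUADRANT_NAMES = {
    Quadrant.ANTERIOR: "anterior",
    Quadrant.POSTERIOR: "posterior",
    Quadrant.MEDIAL: "medial",
    Quadrant.LATERAL: "lateral",
}


class InfeasibleScenarioError(ValueError):
    """Scenario geometry cannot be realized (e.g. nail exceeds the canal)."""


# Reference femoral diaphysis dimensions at the cohort's mean height; the
# linear scaling rule below adapts them to patient stature.
_REF_HEIGHT_CM = 173.4
_REF_OUTER_DIAMETER = 28.0  # mm
_REF_CORTICAL_THICKNESS = 6.0  # mm


@dataclass(frozen=True)
class GeometryParams:
    """Idealized diaphysis segment dimensions (mm)."""

    outer_diameter: float = _REF_OUTER_DIAMETER
    cortical_thickness: float = _REF_CORTICAL_THICKNESS
    segment_length: float = 72.0

    def __post_init__(self) -> None:
        if not (0 < self.cortical_thickness < self.outer_diameter / 2):
            raise ConfigurationError(
                "cortical_thickness: must be positive and below the outer radius")
        if self.segment_length <= 0:
            raise ConfigurationError("segment_length: must be > 0")

    @classmethod
    def from_patient(cls, patient: PatientCase,
                     segment_length: float = 72.0) -> "GeometryParams":
        """Scale the reference diaphysis linearly with patient height."""
        s = patient.height / _REF_HEIGHT_CM
        return cls(outer_diameter=_REF_OUTER_DIAMETER * s,
                   cortical_thickness=_REF_CORTICAL_THICKNESS * s,
                   segment_length=segment_length)

    @property
    def outer_radius(self) -> float:
        return self.outer_diameter / 2

    @property
    def canal_radius(self) -> float:
        return self.outer_radius - self.cortical_thickness

    @property
    def canal_diameter(self) -> float:
        return 2 * self.canal_radius


def canal_diameter_for_height(height_cm: float) -> float:
    """Medullary canal diameter (mm) implied by the height scaling rule."""
    s = height_cm / _REF_HEIGHT_CM
    return (_REF_OUTER_DIAMETER - 2 * _REF_CORTICAL_THICKNESS) * s


@dataclass
class Domain:
    """Labeled voxel grid with quadrant partition."""

    voxel_size: float
    region: np.ndarray  # uint8, shape (nx, ny, nz)
    quadrant: np.ndarray  # uint8, shape (nx, ny, nz)
    side: str
    geom: GeometryParams
    fracture: FractureConfig
    nail: NailConfig
    envelope_axial_margin: float

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.region.shape

    def coords(self):
        """Voxel-center coordinates (1D arrays x, y, z) in mm.

        The shaft axis is at x = y = 0; z runs from 0 (distal) upward; the
        gap is centered at z = z_mid.
        """
        nx, ny, nz = self.region.shape
        h = self.voxel_size
        x = (np.arange(nx) + 0.5) * h - nx * h / 2
        y = (np.arange(ny) + 0.5) * h - ny * h / 2
        z = (np.arange(nz) + 0.5) * h
        return x, y, z

    @property
    def z_mid(self) -> float:
        return self.region.shape[2] * self.voxel_size / 2

    @property
    def healing_mask(self) -> np.ndarray:
        return (self.region == Region.GAP) | (self.region == Region.ENVELOPE)

    def healing_z_slices(self) -> tuple[int, int]:
        """Lowest and highest z-indices containing healing-region voxels."""
        ks = np.nonzero(self.healing_mask.any(axis=(0, 1)))[0]
        if ks.size == 0:
            raise ValueError("domain has no healing region (gap size 0 and no envelope)")
        return int(ks[0]), int(ks[-1])


def build_domain(geom: GeometryParams, frac: FractureConfig, nail: NailConfig,
                 voxel_size: float, side: str = "right",
                 envelope_axial_margin: float = 10.0,
                 screw_radius: float = 2.0) -> Domain:
    """Build and label the voxel domain for one scenario.

    The gap is a slab of thickness ``frac.gap_size`` normal to a plane
    tilted by ``frac.obliquity`` degrees (about the y axis) from the
    transverse plane, centered at mid-segment.  The callus envelope is an
    annulus of thickness ``frac.callus_envelope_thickness`` outside the
    cortex extending ``envelope_axial_margin`` beyond the gap on both
    sides.  The distal fragment may be translated in +x by
    ``frac.translational_offset``.
    """
    h = voxel_size
    if h <= 0:
        raise ConfigurationError("voxel_size: must be > 0")
    if h > geom.cortical_thickness / 2:
        raise ConfigurationError(
            f"voxel_size: {h} mm does not resolve the cortical thickness "
            f"({geom.cortical_thickness} mm) with >= 2 voxels")
    if nail.diameter >= geom.canal_diameter:
        raise InfeasibleScenarioError(
            f"nail diameter {nail.diameter:.1f} mm >= medullary canal diameter "
            f"{geom.canal_diameter:.1f} mm")
    r_nail = nail.diameter / 2
    if frac.translational_offset + r_nail > geom.canal_radius:
        raise InfeasibleScenarioError(
            f"translational offset {frac.translational_offset:.1f} mm leaves no room "
            f"for the nail in the distal canal")

    r_out = geom.outer_radius
    r_can = geom.canal_radius
    r_env = r_out + frac.callus_envelope_thickness
    off = frac.translational_offset

    half_nx = math.ceil((r_env + off) / h) + 1
    nx = ny = 2 * half_nx
    nz = 2 * math.ceil(geom.segment_length / (2 * h))  # even: gap center on a boundary

    x = (np.arange(nx) + 0.5) * h - nx * h / 2
    y = (np.arange(ny) + 0.5) * h - ny * h / 2
    z = (np.arange(nz) + 0.5) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    z0 = nz * h / 2

    th = math.radians(frac.obliquity)
    # signed normal distance from the (tilted) fracture mid-plane
    s = math.cos(th) * (Z - z0) - math.sin(th) * X
    distal = s < 0
    xs = X - off * distal  # fragment-local x (distal fragment shifted by the offset)
    r2 = xs**2 + Y**2

    region = np.full((nx, ny, nz), Region.OUTSIDE, dtype=np.uint8)
    region[r2 <= r_can**2] = Region.CANAL
    region[(r2 > r_can**2) & (r2 <= r_out**2)] = Region.CORTEX

    # fracture-gap slab: all bone-section voxels within half a gap of the
    # plane.  The effective half-thickness is floored at half a voxel so a
    # thin gap always severs the cortex (otherwise a gap thinner than the
    # grid pitch would vanish and the fracture would be spuriously intact);
    # with face (6-neighbor) connectivity this also guarantees that no
    # voxel path can cross the slab without entering it.
    if frac.gap_size > 0:
        slab = np.abs(s) <= max(frac.gap_size / 2, h / 2)
        r2_prox = X**2 + Y**2
        r2_dist = (X - off) ** 2 + Y**2
        in_section = (r2_prox <= r_out**2) | (r2_dist <= r_out**2)
        region[slab & in_section] = Region.GAP

    # periosteal callus envelope around the gap
    envelope = ((r2 > r_out**2) & (r2 <= r_env**2)
                & (np.abs(Z - z0) <= frac.gap_size / 2 + envelope_axial_margin))
    region[envelope & (region == Region.OUTSIDE)] = Region.ENVELOPE

    # straight nail along the global axis, crossing the gap
    nail_mask = (X**2 + Y**2 <= r_nail**2) & (region != Region.OUTSIDE) \
        & (region != Region.CORTEX)
    region[nail_mask] = Region.NAIL

    # locking screws: stiff chords through the canal along y
    half_len = nz * h / 2
    for z_off in nail.screw_positions:
        if abs(z_off) + screw_radius > half_len:
            raise ConfigurationError(
                f"screw_positions: offset {z_off} mm falls outside the "
                f"{geom.segment_length} mm segment")
        screw = ((np.abs(Z - (z0 + z_off)) <= screw_radius)
                 & (np.abs(X) <= screw_radius)
                 & (region == Region.CANAL))
        region[screw] = Region.NAIL

    domain = Domain(voxel_size=h, region=region,
                    quadrant=np.zeros_like(region), side=side,
                    geom=geom, fracture=frac, nail=nail,
                    envelope_axial_margin=envelope_axial_margin)
    return assign_quadrants(domain)


def assign_quadrants(domain: Domain) -> Domain:
    """Label every non-outside voxel with its 90-degree anatomical sector.

    Sector boundaries lie on the diagonals (half-open, rotationally
    symmetric): anterior is centered on +x, posterior on -x; +y is lateral
    for a right femur and medial for a left one.
    """
    x, y, _ = domain.coords()
    theta = np.degrees(np.arctan2(y[None, :], x[:, None]))  # (nx, ny)
    sector = np.floor((theta + 45.0) / 90.0).astype(int) % 4  # 0:+x 1:+y 2:-x 3:-y
    plus_y = Quadrant.LATERAL if domain.side == "right" else Quadrant.MEDIAL
    minus_y = Quadrant.MEDIAL if domain.side == "right" else Quadrant.LATERAL
    lut = np.array([Quadrant.ANTERIOR, plus_y, Quadrant.POSTERIOR, minus_y],
                   dtype=np.uint8)
    quad2d = lut[sector]
    quadrant = np.repeat(quad2d[:, :, None], domain.region.shape[2], axis=2)
    quadrant = quadrant.copy()
    quadrant[domain.region == Region.OUTSIDE] = Quadrant.NONE
    domain.quadrant = quadrant
    return domain


def _neighbor_any(mask: np.ndarray) -> np.ndarray:
    """True where any 6-neighbor of a voxel is in ``mask``."""
    out = np.zeros_like(mask)
    out[1:, :, :] |= mask[:-1, :, :]
    out[:-1, :, :] |= mask[1:, :, :]
    out[:, 1:, :] |= mask[:, :-1, :]
    out[:, :-1, :] |= mask[:, 1:, :]
    out[:, :, 1:] |= mask[:, :, :-1]
    out[:, :, :-1] |= mask[:, :, 1:]
    return out


def initial_state(domain: Domain) -> TissueState:
    """Day-0 tissue state.

    Cortex voxels are 100% lamellar bone; every other voxel (gap, envelope,
    canal, nail, outside) is 100% fibrous connective tissue, so all
    concentrations sum to one everywhere.  Vascularity is 1 in the cortex,
    in healing-region voxels adjacent to the cortex, and on the outer
    (periosteal) surface of the envelope; 0 elsewhere in the healing region
    (the reamed canal is avascular).
    """
    shape = domain.grid_shape
    region = domain.region
    cortex = region == Region.CORTEX

    connective = np.ones(shape)
    lamellar = np.zeros(shape)
    connective[cortex] = 0.0
    lamellar[cortex] = 1.0

    healing = domain.healing_mask
    vascularity = np.zeros(shape)
    vascularity[cortex] = 1.0
    vascularity[healing & _neighbor_any(cortex)] = 1.0
    vascularity[(region == Region.ENVELOPE) & _neighbor_any(region == Region.OUTSIDE)] = 1.0

    return TissueState(connective=connective, cartilage=np.zeros(shape),
                       woven=np.zeros(shape), lamellar=lamellar,
                       vascularity=vascularity, day=0)
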