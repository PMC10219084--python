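"""Outcome layer: cortical bridging detection, union/non-union
classification, virtual radiographs, and mRUST scoring.

Bridging follows the radiographic convention: a quadrant is bridged when a
face-connected column of voxels with lamellar-bone concentration at or
above 70% spans the healing region from its proximal to its distal
boundary plane, staying inside the quadrant's angular sector (the intact
cortex, itself lamellar, participates in the column; the fracture slab
must be crossed by newly formed lamellar bone).  A case is a union when at
least 3 of the 4 quadrants bridge within the 280-day window, and the
consolidation day is the day the third quadrant bridges.

The mRUST score rates each of the four cortices (two per view on AP and
lateral projections) from 1 (no callus) to 4 (bridging callus without a
visible fracture line); the total ranges 4-16 and a total of at least 9 is
defined as consolidated.  Scoring is operationalized on the simulated 3D
state per cortex sector; the virtual radiographs are parallel projections
kept for qualitative comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import Domain, Region, QUADRANT_NAMES
from .state import TissueState

__all__ = [
    "BridgingReport",
    "MRUSTAssessment",
    "VirtualRadiograph",
    "quadrant_bridged",
    "bridging_dates",
    "classify_outcome",
    "project_radiograph",
    "score_mrust",
]

BRIDGE_THRESHOLD = 0.70  # lamellar concentration defining a bridged column
UNION_WINDOW_DAYS = 280
MIN_BRIDGED_QUADRANTS = 3
MRUST_CONSOLIDATED = 9

_NAME_TO_CODE = {v: k for k, v in QUADRANT_NAMES.items()}

# cortices visible per radiographic view
VIEW_CORTICES = {
    "AP": ("medial", "lateral"),
    "lateral": ("anterior", "posterior"),
}


@dataclass(frozen=True)
class BridgingReport:
    """Per-quadrant bridging days and the union/non-union call."""

    per_quadrant: dict  # quadrant name -> first bridged day or None
    consolidation_day: int | None  # day the min_quadrants-th quadrant bridged
    outcome: str  # "union" or "non_union"
    window: int = UNION_WINDOW_DAYS
    min_quadrants: int = MIN_BRIDGED_QUADRANTS


@dataclass(frozen=True)
class MRUSTAssessment:
    """Per-cortex scores (1-4), total (4-16) and the consolidation flag."""

    cortex_scores: dict  # cortex (quadrant) name -> score in {1,2,3,4}
    total: int
    consolidated: bool


@dataclass(frozen=True)
class VirtualRadiograph:
    """Parallel-projection line integral of mineral density."""

    image: np.ndarray  # 2D, non-negative
    view: str  # "AP" or "lateral"
    pixel_size: float  # mm


def _resolve_quadrant(quadrant) -> int:
    if isinstance(quadrant, str):
        try:
            return _NAME_TO_CODE[quadrant]
        except KeyError:
            raise ValueError(f"unknown quadrant {quadrant!r}; expected one of "
                             f"{sorted(_NAME_TO_CODE)}") from None
    if quadrant in QUADRANT_NAMES:
        return int(quadrant)
    raise ValueError(f"unknown quadrant code {quadrant!r}")


def _spans_healing_region(field: np.ndarray, domain: Domain, qcode: int,
                          threshold: float, connectivity: int = 6) -> bool:
    """True iff a connected column with field >= threshold spans the healing
    region axially inside the quadrant's sector (bone regions included)."""
    zlo, zhi = domain.healing_z_slices()
    sub = slice(zlo, zhi + 1)
    allowed = ((domain.region == Region.CORTEX) | (domain.region == Region.GAP)
               | (domain.region == Region.ENVELOPE))
    mask = (field[:, :, sub] >= threshold) \
        & allowed[:, :, sub] & (domain.quadrant[:, :, sub] == qcode)
    if not mask.any():
        return False
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, _ = ndimage.label(mask, structure=structure)
    bottom = np.unique(labels[:, :, 0])
    top = np.unique(labels[:, :, -1])
    common = np.intersect1d(bottom, top)
    return bool(np.any(common > 0))


def quadrant_bridged(state: TissueState, domain: Domain, quadrant,
                     threshold: float = BRIDGE_THRESHOLD,
                     connectivity: int = 6) -> bool:
    """Is there a continuous lamellar column (>= threshold) spanning the
    healing region within the quadrant's sector?

    Connectivity is 6-neighbor (face) by default; 26 selects full
    neighborhood connectivity.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    qcode = _resolve_quadrant(quadrant)
    return _spans_healing_region(state.lamellar, domain, qcode, threshold,
                                 connectivity)


def bridging_dates(trajectory, domain: Domain | None = None,
                   threshold: float = BRIDGE_THRESHOLD) -> dict:
    """First bridged day per quadrant.

    Accepts a :class:`~callusim.healing.HealingTrajectory` (whose daily
    bridging record is returned directly) or a list of ``(day, state)``
    snapshots, which are re-scanned in day order against ``domain``.
    """
    if hasattr(trajectory, "bridge_days"):
        return dict(trajectory.bridge_days)
    if domain is None:
        raise ValueError("domain is required when passing raw snapshots")
    snapshots = sorted(trajectory, key=lambda pair: pair[0])
    if not snapshots:
        raise ValueError("empty trajectory")
    dates: dict = {name: None for name in QUADRANT_NAMES.values()}
    for day, state in snapshots:
        for code, name in QUADRANT_NAMES.items():
            if dates[name] is None and quadrant_bridged(state, domain, code,
                                                        threshold=threshold):
                dates[name] = day
    return dates


def classify_outcome(dates: dict, window: int = UNION_WINDOW_DAYS,
                     min_quadrants: int = MIN_BRIDGED_QUADRANTS) -> BridgingReport:
    """Union/non-union call from per-quadrant bridging days.

    Union iff at least ``min_quadrants`` quadrants bridged on or before
    ``window`` (inclusive); the consolidation day is the
    ``min_quadrants``-th smallest qualifying date.
    """
    qualifying = sorted(d for d in dates.values() if d is not None and d <= window)
    if len(qualifying) >= min_quadrants:
        return BridgingReport(per_quadrant=dict(dates),
                              consolidation_day=qualifying[min_quadrants - 1],
                              outcome="union", window=window,
                              min_quadrants=min_quadrants)
    return BridgingReport(per_quadrant=dict(dates), consolidation_day=None,
                          outcome="non_union", window=window,
                          min_quadrants=min_quadrants)


def project_radiograph(state: TissueState, domain: Domain, view: str,
                       w_woven: float = 0.5, w_lamellar: float = 1.0,
                       nail_density: float = 3.0) -> VirtualRadiograph:
    """Parallel-ray projection of mineral density.

    Density per voxel is ``w_woven*c_woven + w_lamellar*c_lamellar`` (the
    intact cortex contributes through its lamellar concentration); nail
    voxels are rendered at a fixed high density.  The AP view integrates
    along the anterior axis (x), the lateral view along y; pixel values are
    density times path length, in density-mm.
    """
    if view not in VIEW_CORTICES:
        raise ValueError(f"unknown view {view!r}; expected 'AP' or 'lateral'")
    density = w_woven * state.woven + w_lamellar * state.lamellar
    density = np.where(domain.region == Region.NAIL, nail_density, density)
    axis = 0 if view == "AP" else 1
    image = density.sum(axis=axis) * domain.voxel_size
    return VirtualRadiograph(image=image, view=view, pixel_size=domain.voxel_size)


def score_mrust(state: TissueState, domain: Domain,
                views: tuple[str, ...] = ("AP", "lateral"),
                callus_threshold: float = 0.1,
                bridge_threshold: float = 0.5,
                line_threshold: float = 0.5,
                line_fraction: float = 0.05) -> MRUSTAssessment:
    """mRUST assessment of the simulated state.

    Each cortex (the two cortical margins per view) is scored on its
    quadrant sector of the 3D state: 1 -- no callus (no healing-region
    voxel with mineral fraction >= ``callus_threshold``); 2 -- callus
    present but no spanning mineralized column; 3 -- bridging callus with a
    still-detectable fracture line (at least ``line_fraction`` of the gap
    voxels in the sector below ``line_threshold`` mineral); 4 -- bridging
    callus without a visible fracture line.  The total over the four
    cortices spans 4-16; a total >= 9 is consolidated.
    """
    missing = [v for v in views if v not in VIEW_CORTICES]
    if missing:
        raise ValueError(f"unknown views {missing}; expected 'AP'/'lateral'")
    mineral = state.mineral()
    healing = domain.healing_mask
    gap = domain.region == Region.GAP
    scores: dict = {}
    for view in views:
        for name in VIEW_CORTICES[view]:
            qcode = _NAME_TO_CODE[name]
            in_q = domain.quadrant == qcode
            callus = bool((mineral[healing & in_q] >= callus_threshold).any())
            if not callus:
                scores[name] = 1
                continue
            bridged = _spans_healing_region(mineral, domain, qcode,
                                            bridge_threshold)
            if not bridged:
                scores[name] = 2
                continue
            gap_q = gap & in_q
            if gap_q.any():
                frac_lucent = float((mineral[gap_q] < line_threshold).mean())
                line_visible = frac_lucent >= line_fraction
            else:
                line_visible = False
            scores[name] = 3 if line_visible else 4
    total = int(sum(scores.values()))
    return MRUSTAssessment(cortex_scores=scores, total=total,
                           consolidated=total >= MRUST_CONSOLIDATED)
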