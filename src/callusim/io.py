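"""Serialization: HDF5 state files, JSON reports, PNG renders.

The HDF5 layout stores the domain labels once (datasets ``region`` and
``quadrant`` with the voxel size and axis convention as attributes) and
each recorded snapshot under ``states/day_<n>`` with one dataset per
tissue concentration plus vascularity.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .grid import Domain
from .outcome import VirtualRadiograph
from .state import TISSUES, TissueState

AXIS_CONVENTION = ("z: shaft axis, proximal at high z; x: anterior; "
                   "y: lateral for a right femur")


def write_trajectory_h5(domain: Domain, trajectory, path) -> None:
    """Write domain labels and all recorded snapshots to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["voxel_size_mm"] = domain.voxel_size
        f.attrs["axis_convention"] = AXIS_CONVENTION
        f.attrs["side"] = domain.side
        f.create_dataset("region", data=domain.region, compression="gzip")
        f.create_dataset("quadrant", data=domain.quadrant, compression="gzip")
        grp = f.create_group("states")
        for day, state in trajectory.snapshots:
            g = grp.create_group(f"day_{day:04d}")
            g.attrs["day"] = day
            for tissue in TISSUES:
                g.create_dataset(tissue, data=state.concentration(tissue),
                                 compression="gzip", shuffle=True)
            g.create_dataset("vascularity", data=state.vascularity,
                             compression="gzip", shuffle=True)
        for day, strain in getattr(trajectory, "strain_snapshots", []):
            g = f[f"states/day_{day:04d}"]
            g.create_dataset("distortional", data=strain.distortional,
                             compression="gzip", shuffle=True)
            g.create_dataset("dilatational", data=strain.dilatational,
                             compression="gzip", shuffle=True)


def read_state_h5(path, day: int) -> TissueState:
    """Read one snapshot back from an HDF5 state file."""
    with h5py.File(path, "r") as f:
        key = f"states/day_{day:04d}"
        if key not in f:
            days = sorted(int(k.split("_")[1]) for k in f["states"])
            raise KeyError(f"day {day} not stored; available: {days}")
        g = f[key]
        return TissueState(
            connective=g["connective"][()],
            cartilage=g["cartilage"][()],
            woven=g["woven"][()],
            lamellar=g["lamellar"][()],
            vascularity=g["vascularity"][()],
            day=day,
        )


def stored_days(path) -> list[int]:
    with h5py.File(path, "r") as f:
        return sorted(int(k.split("_")[1]) for k in f["states"])


def write_report_json(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)


def read_report_json(path):
    from .pipeline import OutcomeReport
    with open(path) as fh:
        return OutcomeReport.from_dict(json.load(fh))


def write_radiograph_png(radiograph: VirtualRadiograph, path) -> None:
    """Write a 16-bit grayscale PNG (image transposed so z runs upward)."""
    from PIL import Image
    img = radiograph.image.T[::-1]  # (z up, transverse across)
    peak = float(img.max())
    scaled = np.zeros_like(img) if peak == 0 else img / peak
    arr = (scaled * 65535).astype(np.uint16)
    Image.fromarray(arr).save(Path(path))
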