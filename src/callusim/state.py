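"""Per-voxel tissue composition state.

The healing model tracks four tissue phases -- fibrous connective tissue,
fibrocartilage, woven bone, lamellar bone -- as volume concentrations that
sum to one in every voxel, plus a scalar vascularity in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

TISSUES = ("connective", "cartilage", "woven", "lamellar")


class StateCorruptionError(RuntimeError):
    """Concentration normalization violated."""


@dataclass
class TissueState:
    """Tissue concentrations and vascularity on the voxel grid at one day.

    Arrays share the domain's grid shape.  Concentrations are volume
    fractions in [0, 1] summing to 1 per voxel; ``vascularity`` is 1 in
    fully vascularized voxels and 0 in avascular ones.
    """

    connective: np.ndarray
    cartilage: np.ndarray
    woven: np.ndarray
    lamellar: np.ndarray
    vascularity: np.ndarray
    day: int = 0

    @property
    def shape(self) -> tuple[int, ...]:
        return self.connective.shape

    def concentration(self, tissue: str) -> np.ndarray:
        if tissue not in TISSUES:
            raise KeyError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
        return getattr(self, tissue)

    def concentration_sum(self) -> np.ndarray:
        return self.connective + self.cartilage + self.woven + self.lamellar

    def mineral(self) -> np.ndarray:
        """Mineralized-bone fraction (woven + lamellar)."""
        return self.woven + self.lamellar

    def max_mass_error(self) -> float:
        """Largest per-voxel deviation of the concentration sum from 1."""
        return float(np.abs(self.concentration_sum() - 1.0).max())

    def check_normalized(self, atol: float = 1e-8) -> None:
        err = self.max_mass_error()
        if err > atol:
            raise StateCorruptionError(
                f"concentrations deviate from unit sum by {err:.3e} at day {self.day}")

    def copy(self) -> "TissueState":
        return replace(
            self,
            connective=self.connective.copy(),
            cartilage=self.cartilage.copy(),
            woven=self.woven.copy(),
            lamellar=self.lamellar.copy(),
            vascularity=self.vascularity.copy(),
        )
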