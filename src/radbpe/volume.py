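"""Core in-memory containers for 4-D DCE-MRI data and derived products.

A DCE acquisition here is always four T1-weighted volumes: one pre-contrast
baseline (t1) and three post-contrast phases (t2, t3 early; t4 late).  Arrays
are index-space (x, y, z[, t]), 0-based; world orientation lives in the NIfTI
headers handled by :mod:`radbpe.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import RadbpeError

#: default acquisition times in minutes for t1..t4
DEFAULT_TIMES = (0.0, 1.0, 2.0, 6.0)


@dataclass
class DceVolume:
    """A 4-timepoint dynamic contrast-enhanced volume.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz, 4)``, non-negative signal in arbitrary
        units.  Only signal ratios and differences matter downstream.
    spacing
        Voxel edge lengths in mm per axis.
    times
        Acquisition time of each volume in minutes; t1 is the pre-contrast
        baseline.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    times: tuple[float, float, float, float] = DEFAULT_TIMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 4:
            raise RadbpeError(
                f"expected a (nx, ny, nz, 4) array, got shape {self.data.shape}"
            )
        if len(self.times) != 4:
            raise RadbpeError("exactly 4 acquisition times required")
        if any(s <= 0 for s in self.spacing):
            raise RadbpeError("voxel spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise RadbpeError("signal must be finite")
        if np.any(self.data < 0):
            raise RadbpeError("signal must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def timepoint(self, index: int) -> np.ndarray:
        """The 3-D volume acquired at timepoint ``index`` (0-based)."""
        return self.data[..., index]


@dataclass
class CompartmentMasks:
    """Aligned binary masks for the breast and its tissue compartments.

    Invariants: ``tumor ⊆ breast``; ``parenchyma ⊆ breast \\ tumor``;
    ``adipose = breast \\ (tumor ∪ parenchyma)``.
    """

    breast: np.ndarray
    tumor: np.ndarray
    parenchyma: np.ndarray
    adipose: np.ndarray

    def __post_init__(self) -> None:
        for name in ("breast", "tumor", "parenchyma", "adipose"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shapes = {getattr(self, n).shape for n in ("breast", "tumor", "parenchyma", "adipose")}
        if len(shapes) != 1:
            raise RadbpeError(f"mask shapes differ: {shapes}")

    def validate(self) -> None:
        """Raise if the compartment algebra is violated."""
        if np.any(self.tumor & ~self.breast):
            raise RadbpeError("tumor extends outside the breast")
        if np.any(self.parenchyma & (self.tumor | ~self.breast)):
            raise RadbpeError("parenchyma overlaps tumor or exits the breast")
        expected_adipose = self.breast & ~self.tumor & ~self.parenchyma
        if np.any(self.adipose != expected_adipose):
            raise RadbpeError("adipose is not breast minus (tumor ∪ parenchyma)")


@dataclass
class ParametricMaps:
    """Per-voxel pharmacokinetic maps over the breast.

    ``maps`` holds the three enhancement maps keyed ``"rate in"``, ``"PE"``,
    ``"SER"``; ``valid`` holds a boolean mask per map marking voxels where the
    quantity is defined (e.g. SER is undefined where the late-phase change is
    below the denominator floor).  Values outside ``valid`` are NaN.
    """

    maps: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # region the maps were computed on

    MAP_NAMES = ("rate in", "PE", "SER")

    def __post_init__(self) -> None:
        if set(self.maps) != set(self.valid):
            raise RadbpeError("maps and validity masks must share keys")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(a & b) / denom
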