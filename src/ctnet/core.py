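"""Shared containers: voxel spacing, labeled 3D volumes, homolog ids, nucleus records.

Conventions used throughout the package:

* Arrays are indexed ``(z, y, x)``; physical coordinates are in micrometres.
* Binary masks are boolean arrays.  A mask's *boundary* is the set of mask
  voxels with at least one face neighbour (6-connectivity) outside the mask;
  connected-component labeling of masks uses 26-connectivity.
* The default voxel pitch is 0.07 µm in x/y and 0.5 µm in z, so the 0.28 µm
  interaction threshold corresponds to 4 in-plane pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, NamedTuple, Optional

import numpy as np
from scipy import ndimage

#: Chromosomes labeled in the study design this package models.
CHROMOSOME_PANEL = (1, 4, 11, 12, 16, 17, 18)

#: Structuring elements: faces only (boundary) and full 26-neighbourhood (labeling).
STRUCT_6 = ndimage.generate_binary_structure(3, 1)
STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class VoxelSpacing:
    """Anisotropic physical voxel pitch in µm per voxel."""

    dx: float = 0.07
    dy: float = 0.07
    dz: float = 0.5

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def sampling(self) -> tuple:
        """Per-axis pitch in array order (z, y, x), as scipy expects."""
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dx * self.dy * self.dz


class HomologID(NamedTuple):
    """One chromosome copy; within a nucleus tag 'a' is the larger-volume copy."""

    chromosome: int
    tag: str  # 'a' or 'b'

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chromosome}{self.tag}"


@dataclass
class LabeledVolume:
    """A 3D raster with physical spacing; binary masks use boolean data."""

    data: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabeledVolume requires a 3D array (z, y, x)")

    # -- binary-mask helpers -------------------------------------------------
    @property
    def mask(self) -> np.ndarray:
        return self.data.astype(bool)

    def volume_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    def volume_um3(self) -> float:
        return self.volume_voxels() * self.spacing.voxel_volume

    def coords_um(self) -> np.ndarray:
        """Physical (z, y, x) coordinates of nonzero voxels, shape (n, 3)."""
        idx = np.argwhere(self.mask)
        return idx * np.asarray(self.spacing.sampling)

    def centroid_um(self) -> np.ndarray:
        c = self.coords_um()
        if c.shape[0] == 0:
            raise ValueError("centroid of an empty mask is undefined")
        return c.mean(axis=0)

    def boundary(self) -> np.ndarray:
        """Boundary voxels: in the mask, with a face neighbour outside it."""
        m = self.mask
        eroded = ndimage.binary_erosion(m, structure=STRUCT_6, border_value=0)
        return m & ~eroded

    def boundary_coords_um(self) -> np.ndarray:
        idx = np.argwhere(self.boundary())
        return idx * np.asarray(self.spacing.sampling)

    def n_components(self) -> int:
        _, n = ndimage.label(self.mask, structure=STRUCT_26)
        return int(n)

    def is_subset_of(self, other: "LabeledVolume") -> bool:
        return bool(np.all(~self.mask | other.mask))


@dataclass
class NucleusRecord:
    """One cell: nucleus mask, 14 homolog territory masks, condition metadata."""

    nucleus: LabeledVolume
    territories: Dict[HomologID, LabeledVolume]
    condition: str = ""
    truth: Optional[object] = None  # InteractionMatrix planted by the generator
    meta: dict = field(default_factory=dict)

    @property
    def spacing(self) -> VoxelSpacing:
        return self.nucleus.spacing

    @property
    def chromosomes(self) -> tuple:
        return tuple(sorted({h.chromosome for h in self.territories}))

    def validate(self) -> None:
        """Check containment and single-connectedness of every territory."""
        for hid, vol in self.territories.items():
            if not vol.is_subset_of(self.nucleus):
                raise ValueError(f"territory {hid} is not contained in the nucleus")
            if vol.n_components() != 1:
                raise ValueError(f"territory {hid} is not a single connected component")
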