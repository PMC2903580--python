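"""Gridded displacement-field container shared by all pipeline stages.

A :class:`DisplacementField` holds per-pixel 3D Lagrangian displacement
vectors sampled on a regular 2D grid of material (reference) positions,
together with a myocardial mask, the pixel spacing and the slice normal.
Positions are in mm, times in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

__all__ = ["DisplacementField"]


@dataclass
class DisplacementField:
    """3D Lagrangian displacement sampled on one image slice.

    Attributes
    ----------
    ref_positions : (nr, nc, 3) float array
        Reference (material, end-diastolic) position of each grid point, mm.
    displacements : (nt, nr, nc, 3) float array
        Displacement vector of each grid point at each time, mm. Values
        outside the mask may be NaN.
    mask : (nr, nc) bool array
        True where the grid point lies inside the myocardium.
    spacing : float
        In-plane pixel size, mm.
    slice_normal : (3,) float array
        Unit normal of the imaging plane.
    times : (nt,) float array
        Acquisition times, ms.
    metadata : dict
        Free-form provenance (phantom parameters, noise level, seed, ...).
    """

    ref_positions: np.ndarray
    displacements: np.ndarray
    mask: np.ndarray
    spacing: float
    slice_normal: np.ndarray
    times: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_positions = np.asarray(self.ref_positions, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.slice_normal = np.asarray(self.slice_normal, dtype=float)
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if self.spacing <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        n = np.linalg.norm(self.slice_normal)
        if not np.isclose(n, 1.0, atol=1e-8):
            raise ValueError("slice_normal must have unit norm")
        if self.ref_positions.shape[:2] != self.mask.shape:
            raise ValueError("ref_positions and mask grids disagree")
        if self.displacements.shape != (len(self.times), *self.mask.shape, 3):
            raise ValueError(
                "displacements must have shape (nt, nr, nc, 3); got "
                f"{self.displacements.shape}"
            )
        if self.mask.any() and not np.isfinite(
            self.displacements[:, self.mask, :]
        ).all():
            raise ValueError("displacements must be finite inside the mask")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.mask.shape

    def masked_positions(self) -> np.ndarray:
        """Reference positions of in-mask points, shape (P, 3)."""
        return self.ref_positions[self.mask]

    def masked_displacements(self, t_index: int) -> np.ndarray:
        """Displacements of in-mask points at one time frame, shape (P, 3)."""
        return self.displacements[t_index][self.mask]

    def time_index(self, t_ms: float) -> int:
        """Index of the frame closest to ``t_ms`` (exact match expected)."""
        i = int(np.argmin(np.abs(self.times - t_ms)))
        return i

    def copy(self) -> "DisplacementField":
        return replace(
            self,
            ref_positions=self.ref_positions.copy(),
            displacements=self.displacements.copy(),
            mask=self.mask.copy(),
            slice_normal=self.slice_normal.copy(),
            times=self.times.copy(),
            metadata=dict(self.metadata),
        )
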