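"""Core data containers shared by all stages of the pipeline.

Conventions used throughout the package:

* Image arrays are indexed ``[x, y, z]`` (in-plane axes first, slice axis
  last); 4D sequences append a cardiac-phase axis: ``[x, y, z, phase]``.
* Voxel indices are 0-based; the slice axis is ordered apex -> base.
* Displacement and flow vectors are stored in *voxel units per axis*.
  Conversion to millimetres (multiplying each component by the voxel
  spacing) happens only in reporting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VolumeSequence",
    "FlowField",
    "DisplacementField",
    "as_spacing",
]


def as_spacing(spacing: Sequence[float]) -> tuple[float, ...]:
    """Validate and normalize a voxel-spacing tuple (mm/voxel per axis)."""
    sp = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in sp):
        raise ValueError(f"voxel spacing must be positive, got {sp}")
    return sp


@dataclass
class VolumeSequence:
    """A 4D grayscale image sequence: ``data[x, y, z, phase]``.

    Parameters
    ----------
    data:
        Float array of shape ``(nx, ny, nz, n_phases)``.
    spacing:
        Voxel size in mm per axis, ``(sx, sy, sz)``.
    phase_times:
        Acquisition time of each phase in ms measured from tag
        application; strictly increasing.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    phase_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 3:
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError(f"expected 3D or 4D data, got shape {self.data.shape}")
        self.spacing = as_spacing(self.spacing)  # type: ignore[assignment]
        if self.phase_times is None:
            self.phase_times = np.arange(self.n_phases, dtype=float)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        if self.phase_times.shape != (self.n_phases,):
            raise ValueError("phase_times length must match the number of phases")
        if self.n_phases > 1 and not np.all(np.diff(self.phase_times) > 0):
            raise ValueError("phase_times must be strictly increasing")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_phases(self) -> int:
        return self.data.shape[3]

    def phase(self, p: int) -> np.ndarray:
        """The 3D volume of phase ``p`` (a view, not a copy)."""
        return self.data[..., p]


@dataclass
class FlowField:
    """Eulerian incremental motion between two adjacent phases.

    ``u[..., a]`` is the voxel-unit displacement along axis ``a`` taking a
    point observed in the earlier phase to its position in the later
    phase. ``valid`` flags voxels where the estimate is trustworthy (e.g.
    enough local image structure and in-bounds sampling).
    """

    u: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim < 2:
            raise ValueError("flow array must have a trailing component axis")
        if self.valid is None:
            self.valid = np.ones(self.u.shape[:-1], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.u.shape[:-1]:
            raise ValueError("valid mask shape must match the flow grid")

    @property
    def ndim_vec(self) -> int:
        return self.u.shape[-1]


@dataclass
class DisplacementField:
    """Lagrangian displacement from the reference phase to a later phase.

    ``U`` lives on the *reference* (material) grid: the material point at
    voxel ``X`` of the reference phase sits at ``X + U[X]`` in the target
    phase. Components are in voxel units per axis; for in-plane (2D)
    tracking the trailing axis has length 2 and the through-plane
    component is simply absent.
    """

    U: np.ndarray
    reference_phase: int = 0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=np.float64)
        if self.valid is None:
            self.valid = np.ones(self.U.shape[:-1], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.U.shape[:-1]:
            raise ValueError("valid mask shape must match the displacement grid")

    @property
    def ndim_vec(self) -> int:
        return self.U.shape[-1]

    @classmethod
    def zero(cls, grid_shape: Sequence[int], ndim_vec: int = 3,
             reference_phase: int = 0) -> "DisplacementField":
        return cls(np.zeros(tuple(grid_shape) + (ndim_vec,)), reference_phase)
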