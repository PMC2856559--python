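"""Lagrangian strain from integrated displacement fields.

Given the material displacement u(X) of every reference-phase voxel (in
mm after scaling by the voxel spacing), the deformation gradient is
F = I + du/dX, the Green-Lagrange tensor E = (F^T F - I) / 2, and the
principal strains are the eigenvalues of E: eps1 (greatest stretch,
radial wall thickening when positive) >= eps2 >= eps3 (greatest
shortening, the combined circumferential-longitudinal contraction). The
alpha angle locates the eps1 eigenvector relative to the local radial
direction from the endocardial centre.

E vanishes identically for rigid motion, which makes it suitable for the
large rotations and deformations of the systolic LV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import DisplacementField, as_spacing

__all__ = [
    "StrainField",
    "PrincipalStrainField",
    "deformation_gradient",
    "green_lagrange",
    "principal_strains",
    "alpha_angle",
    "strain_pipeline",
]


@dataclass
class StrainField:
    """Per-voxel deformation gradient F and Green-Lagrange tensor E."""

    F: np.ndarray                      # (..., 3, 3)
    E: np.ndarray | None = None        # (..., 3, 3), symmetric
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(self.F.shape[:-2], dtype=bool)


@dataclass
class PrincipalStrainField:
    """Eigen-decomposition of E: sorted principal strains and directions."""

    eps1: np.ndarray
    eps2: np.ndarray
    eps3: np.ndarray
    v1: np.ndarray                     # (..., 3) unit eigenvector of eps1
    v3: np.ndarray                     # (..., 3) unit eigenvector of eps3
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    alpha_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(np.shape(self.eps1), dtype=bool)


def _masked_gradient(f: np.ndarray, mask: np.ndarray, h: float,
                     axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference derivative restricted to a mask.

    Central differences where both axis neighbours are inside the mask,
    one-sided differences where only one is, undefined (and flagged)
    where neither is. ``h`` is the physical step along the axis.
    """
    fwd = np.roll(f, -1, axis=axis)
    bwd = np.roll(f, 1, axis=axis)
    m_fwd = np.roll(mask, -1, axis=axis)
    m_bwd = np.roll(mask, 1, axis=axis)
    # rolled-over borders are not real neighbours
    idx_last = [slice(None)] * f.ndim
    idx_last[axis] = -1
    idx_first = [slice(None)] * f.ndim
    idx_first[axis] = 0
    m_fwd[tuple(idx_last)] = False
    m_bwd[tuple(idx_first)] = False

    grad = np.zeros_like(f)
    defined = mask & (m_fwd | m_bwd)
    both = mask & m_fwd & m_bwd
    only_f = mask & m_fwd & ~m_bwd
    only_b = mask & m_bwd & ~m_fwd
    grad[both] = (fwd[both] - bwd[both]) / (2.0 * h)
    grad[only_f] = (fwd[only_f] - f[only_f]) / h
    grad[only_b] = (f[only_b] - bwd[only_b]) / h
    return grad, defined


def deformation_gradient(U: DisplacementField | np.ndarray,
                         spacing: Sequence[float],
                         mask: np.ndarray | None = None,
                         presmooth_sigma: float = 0.0) -> StrainField:
    """Deformation gradient F = I + du/dX on the reference grid.

    ``U`` is the Lagrangian displacement in voxel units; displacements
    and material coordinates are converted to mm via ``spacing`` before
    differentiation, so F is dimensionless and refers to physical space.
    Derivatives use central differences in the mask interior and
    one-sided differences at mask boundaries; voxels with no valid
    neighbour along some axis are flagged out of the output mask.
    ``presmooth_sigma > 0`` Gaussian-smooths the displacement (voxels)
    before differentiation.
    """
    u = U.U if isinstance(U, DisplacementField) else np.asarray(U, dtype=float)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("expected a (nx, ny, nz, 3) displacement array")
    sp = as_spacing(spacing)
    if mask is None:
        mask = np.ones(u.shape[:-1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")

    u_mm = u * np.asarray(sp)
    if presmooth_sigma > 0:
        u_mm = np.stack([ndimage.gaussian_filter(u_mm[..., j], presmooth_sigma)
                         for j in range(3)], axis=-1)

    F = np.zeros(u.shape[:-1] + (3, 3))
    defined = mask.copy()
    for j in range(3):          # displacement component
        for a in range(3):      # material axis
            g, ok = _masked_gradient(u_mm[..., j], mask, sp[a], axis=a)
            F[..., j, a] = g
            defined &= ok
    F += np.eye(3)
    return StrainField(F, mask=defined)


def green_lagrange(F: StrainField | np.ndarray) -> np.ndarray:
    """Green-Lagrange strain tensor E = (F^T F - I) / 2.

    Exactly zero for any rigid motion (F orthogonal).
    """
    Fa = F.F if isinstance(F, StrainField) else np.asarray(F, dtype=float)
    E = 0.5 * (np.swapaxes(Fa, -1, -2) @ Fa - np.eye(Fa.shape[-1]))
    if isinstance(F, StrainField):
        F.E = E
    return E


def principal_strains(E: np.ndarray, mask: np.ndarray | None = None,
                      positions: np.ndarray | None = None,
                      endo_center: Sequence[float] | None = None,
                      symmetry_tol: float = 1e-8) -> PrincipalStrainField:
    """Principal strains and directions of a symmetric tensor field.

    Eigenvalues are sorted descending (eps1 >= eps2 >= eps3); positive
    values indicate lengthening/thickening, negative values shortening.
    The eps1 eigenvector sign is fixed to have non-negative dot product
    with the outward in-plane radial direction when voxel ``positions``
    and an ``endo_center`` are supplied (otherwise: non-negative x
    component, falling back to y then z for ties). When a centre is given
    the alpha angle (degrees in [0, 90] between v1 and the in-plane
    radial direction) is also computed.
    """
    E = np.asarray(E, dtype=np.float64)
    if E.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) tensors")
    asym = np.max(np.abs(E - np.swapaxes(E, -1, -2)))
    if asym > symmetry_tol:
        raise ValueError(f"tensor field not symmetric (max asymmetry {asym:.2e})")

    vals, vecs = np.linalg.eigh(E)              # ascending
    eps1, eps2, eps3 = vals[..., 2], vals[..., 1], vals[..., 0]
    v1 = vecs[..., :, 2]
    v3 = vecs[..., :, 0]

    if positions is not None and endo_center is not None:
        radial = np.zeros_like(v1)
        radial[..., :2] = np.asarray(positions, dtype=float)[..., :2] \
            - np.asarray(endo_center, dtype=float)[:2]
        sign = np.sum(v1 * radial, axis=-1)
    else:
        sign = v1[..., 0]
        sign = np.where(sign == 0, v1[..., 1], sign)
        sign = np.where(sign == 0, v1[..., 2], sign)
    flip = np.where(sign < 0, -1.0, 1.0)
    v1 = v1 * flip[..., None]

    alpha = None
    if positions is not None and endo_center is not None:
        alpha = alpha_angle(v1, positions, endo_center)

    return PrincipalStrainField(eps1, eps2, eps3, v1, v3,
                                mask=mask, alpha_deg=alpha)


def alpha_angle(v1: np.ndarray, voxel_position: np.ndarray,
                endo_center: Sequence[float]) -> np.ndarray:
    """Angle between the greatest-stretch direction and the radial line.

    The radial line runs from the endocardial-contour centre to the voxel
    (in-plane). The result is the absolute angle in degrees, folded into
    [0, 90] — v1 and -v1 give the same answer. Raises if the voxel sits
    at the centre (zero radial vector).
    """
    v1 = np.asarray(v1, dtype=np.float64)
    pos = np.asarray(voxel_position, dtype=np.float64)
    ctr = np.asarray(endo_center, dtype=np.float64)
    radial = pos[..., :2] - ctr[:2]
    rnorm = np.linalg.norm(radial, axis=-1)
    if np.any(rnorm == 0):
        raise ValueError("voxel at the endocardial centre: radial direction undefined")
    rhat = np.zeros(v1.shape)
    rhat[..., 0] = radial[..., 0] / rnorm
    rhat[..., 1] = radial[..., 1] / rnorm
    v1n = v1 / np.linalg.norm(v1, axis=-1, keepdims=True)
    cosang = np.abs(np.sum(v1n * rhat, axis=-1))
    # |v1 . rhat| <= |v1 in-plane| <= 1; angle to the radial *line*
    return np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))


def strain_pipeline(U: DisplacementField | np.ndarray,
                    spacing: Sequence[float],
                    mask: np.ndarray | None = None,
                    endo_center: Sequence[float] | None = None,
                    presmooth_sigma: float = 0.0) -> tuple[StrainField,
                                                           PrincipalStrainField]:
    """Displacement -> F -> E -> principal strains in one call.

    ``endo_center`` (voxel coordinates, in-plane) enables the radial sign
    convention and the alpha angle. Positions passed to the eigen step
    are voxel indices scaled to mm.
    """
    sf = deformation_gradient(U, spacing, mask, presmooth_sigma)
    E = green_lagrange(sf)
    positions = None
    center_mm = None
    if endo_center is not None:
        shape = sf.F.shape[:-2]
        grid = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                           indexing="ij")
        positions = np.stack(grid, axis=-1) * np.asarray(spacing)
        ec = np.asarray(endo_center, dtype=float)
        center_mm = ec[:2] * np.asarray(spacing[:2])
    ps = principal_strains(E, mask=sf.mask, positions=positions,
                           endo_center=center_mm)
    return sf, ps
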