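"""Hierarchical 3D optical flow for tagged MR volumes.

The estimator follows the classic coarse-to-fine SSD-minimization scheme:

1. **Global stage** — a parametric transform (translation + small-angle
   rotation about the volume centre) is fit between a volume pair by
   Gauss-Newton iterations over a Gaussian pyramid, coarse to fine.
2. **Local stage** — initialized from the global motion, a dense
   per-voxel flow vector is refined by Gauss-Newton on a small inspection
   window (3x3x3 by default) around each voxel, on band-pass
   (Laplacian-filtered) data so that tag fading between phases does not
   bias the match.

Pair-wise flow over a multi-phase sequence is vector-integrated along the
tracked (Lagrangian) trajectories to give the total displacement of every
material point of the reference phase, maintained at sub-voxel precision.

All motion is estimated and stored in voxel units per axis; conversion to
mm is left to the reporting layer. The same machinery runs in 2D
(slice-by-slice, 2-vector flow) for comparison with purely in-plane
tracking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import VolumeSequence, FlowField, DisplacementField
from .pyramid import build_pyramid, laplacian3d

__all__ = [
    "OFMConfig",
    "GlobalTransform",
    "ssd",
    "gauss_newton_step",
    "estimate_global",
    "estimate_local",
    "estimate_flow",
    "track_sequence",
    "estimate_flow_2d",
]


@dataclass
class OFMConfig:
    """Estimator settings.

    The defaults are the optimized configuration for tagged LV data:
    3 coarse-to-fine levels with 8 Gauss-Newton iterations each and
    Gaussian filtering for the global stage; a single level with
    8 iterations and Laplacian (band-pass) filtering for the local
    stage. The local inspection window defaults to 7 x 7 x 3 voxels
    (slice axis last), chosen by phantom optimization for tag patterns
    of ~6-pixel spacing on anisotropic grids: a 3-voxel window holds too
    few independent samples to constrain three motion components, a
    window spanning about one tag period stabilizes the estimate, and
    with slices ~2x thicker than the in-plane pixels a 7 x 7 x 3 window
    is roughly isotropic in mm. ``window`` may be a single odd int or a
    per-axis tuple; in 2D mode the leading two entries are used.
    """

    global_levels: int = 3
    global_iters: int = 8
    global_filter: str = "gaussian"
    local_levels: int = 1
    local_iters: int = 8
    local_filter: str = "laplacian"
    window: int | tuple[int, ...] = (7, 7, 3)
    filter_sigma: float = 1.0
    #: relative diagonal loading for near-singular normal equations
    regularization: float = 1e-6
    #: relative eigenvalue threshold of the windowed structure matrix
    #: below which a motion direction is considered unobservable (the
    #: aperture problem) and its update suppressed
    structure_gate: float = 0.25
    #: absolute floor: voxels whose strongest structure eigenvalue is
    #: below this fraction of the volume's strongest are left at their
    #: initialization (e.g. empty background, or slices whose content
    #: moved through-plane out of view)
    structure_floor: float = 1e-2
    #: per-iteration trust region: max |du| per axis, voxels
    step_clamp: float = 1.0
    #: condition-number limit above which a voxel inherits the global motion
    cond_limit: float = 1e6
    mode: str = "3d"

    def __post_init__(self) -> None:
        win = (self.window,) if np.isscalar(self.window) else tuple(self.window)
        if any(w < 3 or w % 2 == 0 for w in win):
            raise ValueError("window extents must be odd and >= 3")
        if min(self.global_iters, self.local_iters,
               self.global_levels, self.local_levels) < 1:
            raise ValueError("iteration and level counts must be >= 1")
        if self.mode not in ("3d", "2d"):
            raise ValueError("mode must be '3d' or '2d'")


# ---------------------------------------------------------------------------
# global parametric transform
# ---------------------------------------------------------------------------

def _rotation_generators(d: int) -> list[np.ndarray]:
    """Skew-symmetric generators of small rotations in d dimensions."""
    if d == 2:
        return [np.array([[0.0, -1.0], [1.0, 0.0]])]
    if d == 3:
        gx = np.array([[0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        gy = np.array([[0, 0, 1.0], [0, 0, 0], [-1.0, 0, 0]])
        gz = np.array([[0, -1.0, 0], [1.0, 0, 0], [0, 0, 0]])
        return [gx, gy, gz]
    raise ValueError("only 2D and 3D are supported")


@dataclass
class GlobalTransform:
    """Translation + small-angle rotation about a fixed centre.

    The motion of a point at voxel position x is
    ``u(x) = translation + Omega @ (x - center)`` with ``Omega`` the
    skew-symmetric small-angle matrix built from ``rotation`` (radians;
    one parameter in 2D, three in 3D). Identity = all-zero parameters.
    """

    translation: np.ndarray
    rotation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=np.float64)
        self.rotation = np.atleast_1d(np.asarray(self.rotation, dtype=np.float64))
        self.center = np.asarray(self.center, dtype=np.float64)

    @classmethod
    def identity(cls, shape: Sequence[int]) -> "GlobalTransform":
        d = len(shape)
        n_rot = 1 if d == 2 else 3
        center = (np.asarray(shape, dtype=float) - 1) / 2.0
        return cls(np.zeros(d), np.zeros(n_rot), center)

    @property
    def omega(self) -> np.ndarray:
        gens = _rotation_generators(len(self.translation))
        return sum(w * g for w, g in zip(self.rotation, gens))

    def motion_field(self, shape: Sequence[int]) -> np.ndarray:
        """Dense per-voxel motion ``u(x)`` on a grid of the given shape."""
        grid = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                           indexing="ij")
        disp = np.stack(grid, axis=-1) - self.center
        u = disp @ self.omega.T + self.translation
        return u


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _coords_and_inbounds(shape: Sequence[int], u: np.ndarray
                         ) -> tuple[list[np.ndarray], np.ndarray]:
    """Sample positions ``x - u(x)`` and their in-grid mask."""
    grid = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                       indexing="ij")
    coords = [g - u[..., a] for a, g in enumerate(grid)]
    inb = np.ones(tuple(shape), dtype=bool)
    for a, c in enumerate(coords):
        inb &= (c >= 0) & (c <= shape[a] - 1)
    return coords, inb


def _sample(vol: np.ndarray, coords: list[np.ndarray],
            mode: str = "constant") -> np.ndarray:
    return ndimage.map_coordinates(vol, coords, order=1, mode=mode, cval=0.0)


def _as_motion_array(shape: tuple[int, ...], u) -> np.ndarray:
    """Normalize a motion argument (vector, transform or field) to a field."""
    if isinstance(u, GlobalTransform):
        return u.motion_field(shape)
    u = np.asarray(u, dtype=np.float64)
    d = len(shape)
    if u.shape == (d,):
        return np.broadcast_to(u, shape + (d,))
    if u.shape == shape + (d,):
        return u
    raise ValueError(f"motion shape {u.shape} incompatible with grid {shape}")


# ---------------------------------------------------------------------------
# SSD and single Gauss-Newton steps
# ---------------------------------------------------------------------------

def ssd(La: np.ndarray, Lb: np.ndarray, u, region: np.ndarray | None = None
        ) -> float:
    """Sum of squared differences ``sum [Lb(x) - La(x - u(x))]^2``.

    ``u`` may be a uniform d-vector, a :class:`GlobalTransform`, or a
    dense per-voxel field. The sum runs over ``region`` (default: the
    whole grid); voxels whose sample position falls outside the grid are
    excluded.
    """
    La = np.asarray(La, dtype=np.float64)
    Lb = np.asarray(Lb, dtype=np.float64)
    if La.shape != Lb.shape:
        raise ValueError("volume pair must share a shape")
    shape = La.shape
    uf = _as_motion_array(shape, u)
    coords, inb = _coords_and_inbounds(shape, uf)
    sel = inb if region is None else (inb & np.asarray(region, dtype=bool))
    if not sel.any():
        raise ValueError("empty region: no in-bounds voxels to compare")
    res = Lb - _sample(La, coords)
    return float(np.sum(res[sel] ** 2))


def gauss_newton_step(La: np.ndarray, Lb: np.ndarray, u_current,
                      region: np.ndarray | None = None,
                      regularization: float = 1e-6,
                      max_halvings: int = 4) -> np.ndarray:
    """One safeguarded Gauss-Newton increment for a region's translation.

    Linearizes the SSD residual around the current uniform motion
    ``u_current`` using central-difference spatial gradients (forward and
    backward differences averaged), solves the (diagonally loaded) normal
    equations for the increment, and enforces descent: if the full step
    increases the SSD it is halved up to ``max_halvings`` times and
    rejected (zero increment) if the SSD still does not decrease.
    Near-singular systems return a zero increment.
    """
    La = np.asarray(La, dtype=np.float64)
    Lb = np.asarray(Lb, dtype=np.float64)
    shape = La.shape
    d = La.ndim
    u0 = np.asarray(u_current, dtype=np.float64)
    uf = _as_motion_array(shape, u0)
    coords, inb = _coords_and_inbounds(shape, uf)
    sel = inb if region is None else (inb & np.asarray(region, dtype=bool))
    if not sel.any():
        raise ValueError("empty region")

    grads = np.gradient(La)
    if d == 1:
        grads = [grads]
    g = np.stack([_sample(gr, coords)[sel] for gr in grads], axis=-1)
    res = (Lb - _sample(La, coords))[sel]

    A = g.T @ g
    b = g.T @ res
    tr = np.trace(A)
    if tr <= 0:
        return np.zeros(d)
    A = A + regularization * tr * np.eye(d)
    try:
        du = -np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.zeros(d)

    ssd0 = ssd(La, Lb, u0, region)
    scale = 1.0
    for _ in range(max_halvings + 1):
        if ssd(La, Lb, u0 + scale * du, region) <= ssd0:
            return scale * du
        scale *= 0.5
    return np.zeros(d)


# ---------------------------------------------------------------------------
# global stage
# ---------------------------------------------------------------------------

def estimate_global(volA: np.ndarray, volB: np.ndarray,
                    config: OFMConfig | None = None) -> GlobalTransform:
    """Fit translation + rotation between a volume pair, coarse to fine.

    The pair is band-pass pre-filtered (offset elimination — tag fading
    changes the overall brightness between phases, and matching raw
    intensities would reward transforms that merely blur the brighter
    image), then Gauss-Newton runs on the pose parameters at each level
    of a Gaussian pyramid, starting at the coarsest; iterations stop
    early at a level once the SSD no longer decreases. Parameters are
    expressed on the full-resolution grid (voxel units / radians about
    the volume centre).
    """
    if config is None:
        config = OFMConfig()
    volA = laplacian3d(np.asarray(volA, dtype=np.float64), config.filter_sigma)
    volB = laplacian3d(np.asarray(volB, dtype=np.float64), config.filter_sigma)
    if volA.shape != volB.shape:
        raise ValueError("volume pair must share a shape")
    d = volA.ndim
    gens = _rotation_generators(d)
    n_rot = len(gens)
    shape_fine = volA.shape
    center = (np.asarray(shape_fine, dtype=float) - 1) / 2.0

    n_levels = min(config.global_levels,
                   1 + int(np.log2(max(min(shape_fine), 2))) - 1)
    n_levels = max(n_levels, 1)
    pyrA = build_pyramid(volA, n_levels, config.global_filter, config.filter_sigma)
    pyrB = build_pyramid(volB, n_levels, config.global_filter, config.filter_sigma)

    t = np.zeros(d)
    w = np.zeros(n_rot)

    for lev in reversed(range(n_levels)):
        La, Lb = pyrA[lev].data, pyrB[lev].data
        factors = np.asarray(pyrA[lev].factors, dtype=float)
        shape = La.shape
        grads = np.gradient(La)
        grads_b = np.gradient(Lb)
        if d == 1:
            grads = [grads]
            grads_b = [grads_b]
        grid = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                           indexing="ij")
        # fine-grid offsets from the rotation centre, one array per axis
        d_fine = [grid[a] * factors[a] - center[a] for a in range(d)]

        def level_motion(t_p: np.ndarray, w_p: np.ndarray) -> np.ndarray:
            om = sum(wk * gk for wk, gk in zip(w_p, gens))
            u = np.empty(shape + (d,))
            for j in range(d):
                rot_j = sum(om[j, a] * d_fine[a] for a in range(d))
                u[..., j] = (t_p[j] + rot_j) / factors[j]
            return u

        # Fixed interior region: border voxels are excluded from the SSD
        # and the normal equations. Because the region does not depend on
        # the candidate motion, the cost is continuous in the parameters
        # (voxels cannot "leave" the sum as samples cross the grid edge)
        # for motions up to the margin, and pushing content out of view
        # brings no spurious cost reduction.
        margin = [min(2, max((s - 1) // 4, 0)) for s in shape]
        interior = np.zeros(shape, dtype=bool)
        interior[tuple(slice(m, s - m if m else None)
                       for m, s in zip(margin, shape))] = True
        interior_f = interior.ravel()

        def level_cost(t_p: np.ndarray, w_p: np.ndarray) -> float:
            u = level_motion(t_p, w_p)
            coords, _ = _coords_and_inbounds(shape, u)
            res = (Lb - _sample(La, coords, mode="nearest"))[interior]
            return float(np.sum(res ** 2))

        ssd_prev = level_cost(t, w)
        if lev < n_levels - 1:
            # Coarse levels of band-passed tagged data can carry almost no
            # energy (decimation wipes the tag pattern); an estimate
            # inherited from such a level may be arbitrary. Keep it only
            # if it actually beats the identity on this level's data.
            ssd_id = level_cost(np.zeros(d), np.zeros(n_rot))
            if ssd_id < ssd_prev:
                t, w, ssd_prev = np.zeros(d), np.zeros(n_rot), ssd_id
        for _ in range(config.global_iters):
            u = level_motion(t, w)
            coords, _ = _coords_and_inbounds(shape, u)
            res = (Lb - _sample(La, coords, mode="nearest")).ravel()[interior_f]
            # symmetric gradient (template gradient at the warped position
            # averaged with the target gradient): cancels the first-order
            # interpolation bias of one-sided gradients at sub-voxel offsets
            g = [0.5 * (_sample(gr, coords, mode="nearest")
                        + gb).ravel()[interior_f]
                 for gr, gb in zip(grads, grads_b)]
            # Jacobian columns: translations then rotation parameters
            J = np.empty((res.size, d + n_rot))
            for j in range(d):
                J[:, j] = g[j] / factors[j]
            for k, gk in enumerate(gens):
                col = np.zeros(res.size)
                for j in range(d):
                    rot_j = sum(gk[j, a] * d_fine[a] for a in range(d))
                    col += g[j] * rot_j.ravel()[interior_f] / factors[j]
                J[:, d + k] = col
            A = J.T @ J
            tr = np.trace(A)
            if tr <= 0:
                break
            A += config.regularization * tr * np.eye(d + n_rot)
            try:
                dp = -np.linalg.solve(A, J.T @ res)
            except np.linalg.LinAlgError:
                break
            # trust region per iteration: along directions the data barely
            # constrain (e.g. rotating a near-symmetric ring) the normal
            # equations produce arbitrarily large steps; a bounded step
            # plus strict descent keeps the estimate from wandering there
            np.clip(dp[:d], -2.0, 2.0, out=dp[:d])
            np.clip(dp[d:], -0.1, 0.1, out=dp[d:])

            # translation-only fallback step: in a near-degenerate joint
            # system the rotation columns can absorb (and misdirect) the
            # weakest translation component
            At = J[:, :d].T @ J[:, :d]
            At += config.regularization * np.trace(At) * np.eye(d)
            dp_t = np.zeros(d + n_rot)
            dp_t[:d] = np.clip(-np.linalg.solve(At, J[:, :d].T @ res),
                               -2.0, 2.0)

            accepted = False
            for cand in (dp, dp_t):
                scale = 1.0
                for _ in range(5):
                    t_c = t + scale * cand[:d]
                    w_c = w + scale * cand[d:]
                    # the transform models small bulk motion between
                    # adjacent phases; stay in the small-angle regime
                    t_c = np.clip(t_c, -0.5 * np.asarray(shape_fine),
                                  0.5 * np.asarray(shape_fine))
                    w_c = np.clip(w_c, -0.5, 0.5)
                    ssd_c = level_cost(t_c, w_c)
                    if ssd_c < ssd_prev * (1.0 - 1e-9):
                        t, w, ssd_prev, accepted = t_c, w_c, ssd_c, True
                        break
                    scale *= 0.5
                if accepted:
                    break
            if not accepted:
                break

    return GlobalTransform(t, w, center)


# ---------------------------------------------------------------------------
# local stage
# ---------------------------------------------------------------------------

def _window_size(window, ndim: int) -> tuple[int, ...]:
    if np.isscalar(window):
        return (int(window),) * ndim
    window = tuple(int(w) for w in window)
    if len(window) < ndim:
        raise ValueError(f"window {window} has fewer extents than {ndim} axes")
    return window[:ndim]


def _window_sum(vol: np.ndarray, window) -> np.ndarray:
    size = _window_size(window, vol.ndim)
    return ndimage.uniform_filter(vol, size=size, mode="constant") \
        * float(np.prod(size))


def _dense_gauss_newton(La: np.ndarray, Lb: np.ndarray, u: np.ndarray,
                        config: OFMConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel windowed Gauss-Newton refinement of a dense flow field.

    Returns the refined field and the final per-voxel structure matrix
    (for conditioning diagnostics). Each voxel minimizes the SSD over a
    ``window``-wide neighbourhood. Three safeguards keep the iteration
    honest where the data are weak:

    * the normal equations are solved in the eigenbasis of the windowed
      structure matrix, and update components along directions whose
      eigenvalue is below ``structure_gate`` times the largest are
      suppressed — the aperture problem makes those motion components
      unobservable in the window, so the voxel keeps its initialization
      (the global-stage motion) along them;
    * each component of the increment is clamped to ``step_clamp``
      voxels (a window this small cannot evidence larger motion);
    * a per-voxel descent check halves the step up to four times and
      rejects it if the windowed SSD still increases, so the accepted
      windowed SSD sequence is non-increasing by construction.
    """
    shape = La.shape
    d = La.ndim
    win = config.window
    grads = np.gradient(La)
    if d == 1:
        grads = [grads]

    # Samples that fall outside the grid read as 0 — on band-pass data the
    # empty background. They are *not* excluded: excluding them would make
    # "move everything out of view" a descent direction for the windowed
    # SSD, and the slice-wise 2D tracker does exactly that on slices whose
    # material leaves the plane.
    def residual(uf: np.ndarray) -> np.ndarray:
        coords, _ = _coords_and_inbounds(shape, uf)
        return Lb - _sample(La, coords)

    A_last = np.zeros(shape + (d, d))
    res = residual(u)
    total_prev = float(np.sum(res ** 2))
    for _ in range(config.local_iters):
        coords, _ = _coords_and_inbounds(shape, u)
        g = [_sample(gr, coords) for gr in grads]
        res = Lb - _sample(La, coords)

        A = np.empty(shape + (d, d))
        b = np.empty(shape + (d,))
        for j in range(d):
            for k in range(j, d):
                A[..., j, k] = A[..., k, j] = _window_sum(g[j] * g[k], win)
            b[..., j] = _window_sum(g[j] * res, win)
        A_last = A

        lam, V = np.linalg.eigh(A)
        lam_max = lam[..., -1:]
        gate = np.maximum(config.structure_gate * lam_max, 1e-30)
        inv = np.where(lam > gate, 1.0 / np.maximum(lam, 1e-30), 0.0)
        b_eig = np.einsum("...ij,...i->...j", V, b)
        du = -np.einsum("...ij,...j->...i", V, inv * b_eig)
        du[lam_max[..., 0] < config.structure_floor * lam_max.max()] = 0.0
        np.clip(du, -config.step_clamp, config.step_clamp, out=du)

        # per-voxel descent safeguard on the windowed SSD
        wssd0 = _window_sum(res ** 2, win)
        scale = np.ones(shape)
        for attempt in range(5):
            cand = u + scale[..., None] * du
            wssd_c = _window_sum(residual(cand) ** 2, win)
            bad = wssd_c > wssd0 * (1.0 + 1e-12) + 1e-30
            if not bad.any():
                break
            if attempt < 4:
                scale[bad] *= 0.5
            else:
                scale[bad] = 0.0
        u = u + scale[..., None] * du

        total = float(np.sum(residual(u) ** 2))
        if total >= total_prev:
            break
        total_prev = total

    return u, A_last


def estimate_local(volA: np.ndarray, volB: np.ndarray,
                   init: GlobalTransform | None,
                   config: OFMConfig | None = None) -> FlowField:
    """Dense per-voxel flow refinement on band-pass-filtered data.

    The flow is initialized from the global transform's local motion
    (identity if ``init`` is None) and refined level-by-level on a
    Laplacian pyramid (``config.local_levels``, default a single level at
    full resolution). Voxels whose windowed structure matrix is too
    ill-conditioned to constrain the motion keep the global-transform
    motion and are flagged invalid.
    """
    if config is None:
        config = OFMConfig()
    volA = np.asarray(volA, dtype=np.float64)
    volB = np.asarray(volB, dtype=np.float64)
    if volA.shape != volB.shape:
        raise ValueError("volume pair must share a shape")
    d = volA.ndim
    if init is None:
        init = GlobalTransform.identity(volA.shape)

    pyrA = build_pyramid(volA, config.local_levels, config.local_filter,
                         config.filter_sigma)
    pyrB = build_pyramid(volB, config.local_levels, config.local_filter,
                         config.filter_sigma)

    u = None
    A = None
    for lev in reversed(range(config.local_levels)):
        La, Lb = pyrA[lev].data, pyrB[lev].data
        factors = np.asarray(pyrA[lev].factors, dtype=float)
        if u is None:
            # express the fine-grid transform motion in level voxels
            grid = np.meshgrid(*(np.arange(n, dtype=float) for n in La.shape),
                               indexing="ij")
            pos_fine = np.stack([grid[a] * factors[a] for a in range(d)], -1)
            u_fine = (pos_fine - init.center) @ init.omega.T + init.translation
            u_level = u_fine / factors
        else:
            zoom = [La.shape[a] / prev_shape[a] for a in range(d)]
            u_level = np.stack(
                [ndimage.zoom(u[..., a], zoom, order=1, mode="nearest",
                              grid_mode=False) * zoom[a] for a in range(d)],
                axis=-1)
        u, A = _dense_gauss_newton(La, Lb, u_level, config)
        prev_shape = La.shape

    eig = np.linalg.eigvalsh(A)
    cond = eig[..., -1] / np.maximum(eig[..., 0], 1e-30)
    degenerate = (cond > config.cond_limit) | (eig[..., -1] <= 0) \
        | (eig[..., -1] < config.structure_floor * eig[..., -1].max())
    if degenerate.any():
        u_global = init.motion_field(volA.shape)
        u[degenerate] = u_global[degenerate]
    return FlowField(u, valid=~degenerate)


def estimate_flow(volA: np.ndarray, volB: np.ndarray,
                  config: OFMConfig | None = None) -> FlowField:
    """Full two-stage flow estimate between a volume pair.

    Global parametric alignment on Gaussian-filtered pyramids followed by
    dense local refinement on Laplacian-filtered data. Deterministic:
    identical inputs and config give bit-identical output.
    """
    if config is None:
        config = OFMConfig()
    g = estimate_global(volA, volB, config)
    return estimate_local(volA, volB, g, config)


# ---------------------------------------------------------------------------
# temporal integration
# ---------------------------------------------------------------------------

def _sample_field(f: np.ndarray, coords: list[np.ndarray]) -> np.ndarray:
    return np.stack(
        [ndimage.map_coordinates(f[..., a], coords, order=1, mode="nearest")
         for a in range(f.shape[-1])], axis=-1)


def track_sequence(seq: VolumeSequence, config: OFMConfig | None = None
                   ) -> list[DisplacementField]:
    """Track every reference-phase voxel through the whole sequence.

    Adjacent phases are pair-wise compared to obtain incremental flow
    fields, which are vector-integrated along each material trajectory:
    ``U_{p+1}(X) = U_p(X) + flow_{p->p+1}(X + U_p(X))``, with the
    incremental flow sampled (trilinearly) at the tracked sub-voxel
    position. Returns one Lagrangian :class:`DisplacementField` per
    phase; the reference (phase 0) field is identically zero.
    """
    if config is None:
        config = OFMConfig()
    if seq.n_phases < 2:
        raise ValueError("need at least two phases to track")
    shape = seq.grid_shape
    grid = np.meshgrid(*(np.arange(n, dtype=float) for n in shape),
                       indexing="ij")

    fields = [DisplacementField.zero(shape, 3, 0)]
    U = fields[0].U.copy()
    valid = np.ones(shape, dtype=bool)
    for p in range(seq.n_phases - 1):
        flow = estimate_flow(seq.phase(p), seq.phase(p + 1), config)
        coords = [grid[a] + U[..., a] for a in range(3)]
        U = U + _sample_field(flow.u, coords)
        valid = valid & (ndimage.map_coordinates(
            flow.valid.astype(np.float64), coords, order=0, mode="nearest") > 0.5)
        fields.append(DisplacementField(U.copy(), 0, valid.copy()))
    return fields


def estimate_flow_2d(seq: VolumeSequence, config: OFMConfig | None = None
                     ) -> list[DisplacementField]:
    """Slice-by-slice 2D tracking of a 3D sequence (in-plane flow only).

    Runs the identical two-stage algorithm independently on every z-slice
    with 2-vector flow and 2D pyramids/windows, then integrates pair-wise
    flow per slice exactly as in :func:`track_sequence`. Output fields
    carry 2 components (x, y); the through-plane component is absent by
    construction. This is the in-plane projection a conventional 2D
    tagged acquisition would measure.
    """
    if config is None:
        config = OFMConfig(mode="2d")
    nx, ny, nz = seq.grid_shape
    n = seq.n_phases
    if n < 2:
        raise ValueError("need at least two phases to track")
    gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")

    U_all = np.zeros((nx, ny, nz, 2, n))
    valid_all = np.ones((nx, ny, nz, n), dtype=bool)
    for z in range(nz):
        U = np.zeros((nx, ny, 2))
        valid = np.ones((nx, ny), dtype=bool)
        for p in range(n - 1):
            a = seq.data[:, :, z, p]
            b = seq.data[:, :, z, p + 1]
            flow = estimate_flow(a, b, config)
            coords = [gx + U[..., 0], gy + U[..., 1]]
            U = U + _sample_field(flow.u, coords)
            valid = valid & (ndimage.map_coordinates(
                flow.valid.astype(np.float64), coords, order=0,
                mode="nearest") > 0.5)
            U_all[:, :, z, :, p + 1] = U
            valid_all[:, :, z, p + 1] = valid

    return [DisplacementField(U_all[..., p], 0, valid_all[..., p])
            for p in range(n)]
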