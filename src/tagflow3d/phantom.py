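"""Synthetic 3D tagged left-ventricle phantom with known ground-truth motion.

The phantom emulates a SPAMM-tagged short-axis acquisition of an LV:

* an annular, bright myocardial wall with smooth random texture on a dark
  cavity/background (the "untagged base" volume);
* three families of parallel tag planes imprinted as dark stripes — two
  orthogonal in-plane sets (normals along x and y) and a third oblique set
  whose angle to the slice axis (beta) controls through-plane sensitivity;
* T1 tag fading, SI = M0 * (1 - exp(-t/T1)) inside the stripes;
* a smooth, analytic systolic deformation (torsion + radial contraction +
  linear longitudinal shortening) with an exactly known displacement field,
  so any tracker can be scored against ground truth;
* optional additive zero-mean Gaussian noise.

All displacements are stored in voxel units per axis (see ``core``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .core import VolumeSequence, DisplacementField, as_spacing

__all__ = [
    "PhantomConfig",
    "TagSpec",
    "DeformationModel",
    "make_lv_phantom",
    "tag_field",
    "apply_tags",
    "third_tag_normal",
    "default_tag_specs",
    "synth_displacement",
    "invert_displacement",
    "warp_volume",
    "add_noise",
    "make_tagged_sequence",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry, intensity and timing parameters of the synthetic LV.

    Defaults describe a short-axis stack at 0.70 x 0.70 mm in-plane
    resolution and 1.5 mm slice thickness, with tag-fading time constant
    T1 = 900 ms and phases spanning systole (~50-350 ms after tagging).
    """

    grid_shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (0.70, 0.70, 1.5)
    n_phases: int = 10
    phase_times: np.ndarray | None = None      # ms from tag application
    endo_radius_mm: float = 8.0
    epi_radius_mm: float = 14.0
    wall_extent_mm: float = 30.0               # long-axis extent of the wall
    myo_intensity: float = 0.85                # mean wall intensity / M0
    cavity_intensity: float = 0.05             # blood pool intensity / M0
    background_intensity: float = 0.0
    texture_amplitude: float = 0.15            # relative texture modulation
    texture_sigma_vox: float = 1.5             # texture smoothness
    psf_sigma_vox: float = 0.6                 # acquisition point-spread blur
    texture_seed: int = 0
    T1: float = 900.0                          # ms
    M0: float = 1.0                            # max signal intensity

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)  # type: ignore
        if len(self.grid_shape) != 3 or any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be three dimensions, each >= 8")
        self.spacing = as_spacing(self.spacing)  # type: ignore[assignment]
        if self.phase_times is None:
            self.phase_times = np.linspace(50.0, 350.0, self.n_phases)
        self.phase_times = np.asarray(self.phase_times, dtype=float)
        if self.phase_times.shape != (self.n_phases,):
            raise ValueError("phase_times length must equal n_phases")
        if self.phase_times[0] < 0 or not np.all(np.diff(self.phase_times) > 0):
            raise ValueError("phase_times must be non-negative and strictly increasing")
        if self.T1 <= 0:
            raise ValueError("T1 must be positive")
        if self.M0 <= 0:
            raise ValueError("M0 must be positive")
        nx, ny, nz = self.grid_shape
        sx, sy, sz = self.spacing
        if 2 * self.epi_radius_mm > min(nx * sx, ny * sy):
            raise ValueError(
                f"epicardial diameter {2 * self.epi_radius_mm} mm exceeds the "
                f"in-plane grid extent ({nx * sx:.1f} x {ny * sy:.1f} mm)")
        if self.wall_extent_mm > nz * sz:
            raise ValueError(
                f"wall extent {self.wall_extent_mm} mm exceeds the long-axis "
                f"grid extent ({nz * sz:.1f} mm)")
        if not 0 < self.endo_radius_mm < self.epi_radius_mm:
            raise ValueError("need 0 < endo_radius_mm < epi_radius_mm")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_times"] = [float(t) for t in self.phase_times]
        return d


@dataclass
class TagSpec:
    """One family of parallel tag planes.

    The planes are the level sets ``r . normal = k * spacing`` in
    *physical* (mm) space — a tagging pulse saturates planes of tissue
    regardless of how the voxel grid samples them. ``normal`` is the unit
    plane normal in physical coordinates; ``spacing`` and ``width`` are
    expressed in in-plane pixel units (the field's usual way of quoting
    tag geometry, e.g. "width 2 px, spacing 6 px") and converted to mm
    with the in-plane pixel size when the field is rasterized. A point is inside a stripe when its distance
    along the normal to the nearest plane is at most ``width / 2``.
    ``beta_deg``/``azimuth_deg`` record the oblique third-plane geometry
    when built via :func:`third_tag_normal`.
    """

    normal: tuple[float, float, float]
    spacing: float = 6.0                       # in-plane pixels along the normal
    width: float = 2.0                         # in-plane pixels along the normal
    beta_deg: float | None = None
    azimuth_deg: float | None = None

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = float(np.linalg.norm(n))
        if norm == 0:
            raise ValueError("tag normal must be non-zero")
        self.normal = tuple(n / norm)  # type: ignore[assignment]
        if not 0 < self.width < self.spacing:
            raise ValueError("need 0 < width < spacing")
        if self.beta_deg is not None and not 0 <= self.beta_deg <= 90:
            raise ValueError("beta_deg must lie in [0, 90]")


@dataclass
class DeformationModel:
    """Analytic systolic deformation: torsion + radial contraction +
    linear longitudinal shortening.

    * ``torsion_deg``: peak apex-base counter-rotation. The rotation angle
      varies linearly along z from ``-torsion_deg/2`` at the apex (slice 0)
      to ``+torsion_deg/2`` at the base — the systolic "wringing" motion.
    * ``radial_contraction``: peak fractional inward radial displacement;
      a material point at in-plane radius r moves inward by
      ``radial_contraction * r`` (so the endocardium moves by that
      fraction of the endocardial radius).
    * ``longitudinal_shortening_mm``: peak base-toward-apex displacement;
      varies linearly in z, zero at the apex.
    * ``temporal_profile``: monotone ramp from 0 (reference phase) to 1
      (end-systole); ``"linear"``, ``"smoothstep"`` or a callable.

    The defaults give a peak in-plane displacement of about 3 voxels
    (2 mm at 0.7 mm pixels) and a peak through-plane displacement of
    2 slices (3 mm at 1.5 mm slices) — a realistic systolic excursion for
    an ovine LV at this resolution.
    """

    torsion_deg: float = 12.0
    radial_contraction: float = 0.12
    longitudinal_shortening_mm: float = 3.0
    temporal_profile: str | Callable[[float], float] = "linear"

    def profile(self, s: float) -> float:
        """Temporal ramp value for normalized phase position s in [0, 1]."""
        if callable(self.temporal_profile):
            return float(self.temporal_profile(s))
        if self.temporal_profile == "linear":
            return float(s)
        if self.temporal_profile == "smoothstep":
            return float(s * s * (3.0 - 2.0 * s))
        raise ValueError(f"unknown temporal profile {self.temporal_profile!r}")


# ---------------------------------------------------------------------------
# base anatomy
# ---------------------------------------------------------------------------

def make_lv_phantom(config: PhantomConfig) -> tuple[VolumeSequence, np.ndarray]:
    """Build the untagged base volume and its myocardial mask.

    Returns a single-frame :class:`VolumeSequence` replicated over
    ``config.n_phases`` (the anatomy itself is static; motion is applied
    later by warping) and a boolean mask of the annular myocardial wall.

    The wall is an annulus between the endo- and epicardial radii,
    spanning ``wall_extent_mm`` along the slice axis (centred), filled
    with a bright, smoothly varying random texture; the cavity and
    background are dark. The texture is reproducible from
    ``config.texture_seed``.
    """
    nx, ny, nz = config.grid_shape
    sx, sy, sz = config.spacing
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    x = (np.arange(nx) - cx) * sx
    y = (np.arange(ny) - cy) * sy
    r_mm = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)

    z_mm = np.arange(nz) * sz
    z_lo = (nz * sz - config.wall_extent_mm) / 2.0
    z_hi = z_lo + config.wall_extent_mm
    in_z = (z_mm >= z_lo) & (z_mm < z_hi)

    annulus = (r_mm >= config.endo_radius_mm) & (r_mm <= config.epi_radius_mm)
    mask = annulus[:, :, None] & in_z[None, None, :]
    cavity = (r_mm < config.endo_radius_mm)[:, :, None] & in_z[None, None, :]

    rng = np.random.default_rng(config.texture_seed)
    noise = rng.standard_normal((nx, ny, nz))
    noise = ndimage.gaussian_filter(noise, config.texture_sigma_vox, mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise /= sd

    vol = np.full((nx, ny, nz), config.background_intensity * config.M0)
    myo = config.M0 * config.myo_intensity * (1.0 + config.texture_amplitude * noise)
    # keep the wall strictly inside (0, M0]
    myo = np.clip(myo, 0.05 * config.M0, config.M0)
    vol[mask] = myo[mask]
    vol[cavity] = config.cavity_intensity * config.M0
    if config.psf_sigma_vox > 0:
        # acquisition point-spread: a real scan is band-limited, it never
        # contains the aliased hard edges of the raw geometric model
        vol = ndimage.gaussian_filter(vol, config.psf_sigma_vox, mode="reflect")

    data = np.repeat(vol[..., None], config.n_phases, axis=3)
    seq = VolumeSequence(data, config.spacing, config.phase_times)
    return seq, mask


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------

def third_tag_normal(beta_deg: float, azimuth_deg: float = 45.0) -> np.ndarray:
    """Unit normal of the oblique third tag-plane family.

    ``beta_deg`` is the angle between the slice (z) axis and the tag
    plane: beta = 0 gives planes parallel to the z-axis whose normal lies
    in-plane at ``azimuth_deg`` from the x-axis (45 degrees by default,
    bisecting the two in-plane tag normals); beta = 90 gives planes
    perpendicular to the z-axis (normal = z), which saturate whole slices.
    """
    if not 0 <= beta_deg <= 90:
        raise ValueError(f"beta must lie in [0, 90] degrees, got {beta_deg}")
    b = np.deg2rad(beta_deg)
    a = np.deg2rad(azimuth_deg)
    n = np.array([np.cos(b) * np.cos(a), np.cos(b) * np.sin(a), np.sin(b)])
    return n / np.linalg.norm(n)


def default_tag_specs(beta_deg: float = 30.0, spacing: float = 6.0,
                      width: float = 2.0, azimuth_deg: float = 45.0) -> list[TagSpec]:
    """The standard three tag-plane families: x, y, and the oblique set.

    Defaults are the optimized acquisition parameters: tag width 2 px,
    spacing 6 px, third plane at beta = 30 degrees.
    """
    return [
        TagSpec(normal=(1.0, 0.0, 0.0), spacing=spacing, width=width),
        TagSpec(normal=(0.0, 1.0, 0.0), spacing=spacing, width=width),
        TagSpec(normal=tuple(third_tag_normal(beta_deg, azimuth_deg)),
                spacing=spacing, width=width,
                beta_deg=beta_deg, azimuth_deg=azimuth_deg),
    ]


def tag_field(spec: TagSpec, grid_shape: Sequence[int], t_ms: float,
              t1_ms: float = 900.0, edge_sigma: float = 0.0,
              spacing: Sequence[float] | None = None) -> np.ndarray:
    """Multiplicative tag intensity field in [0, 1] at time ``t_ms``.

    Inside a stripe the value is the T1-recovery factor
    ``f(t) = 1 - exp(-t/T1)`` (0 at t = 0: full saturation; -> 1 as the
    magnetization recovers); outside the stripes the value is exactly 1.
    ``spacing`` is the voxel size in mm used to place the (physically
    defined) tag planes on the grid; ``None`` treats voxels as isotropic
    unit cells, which matches the mm definition up to a global scale.
    ``edge_sigma > 0`` softens the stripe edges with a Gaussian of that
    width (voxels) to mimic a finite tag profile; the default is a
    hard-edged stripe.
    """
    if t_ms < 0:
        raise ValueError("t_ms must be non-negative")
    nx, ny, nz = grid_shape
    sx, sy, sz = (1.0, 1.0, 1.0) if spacing is None else as_spacing(spacing)
    if abs(sx - sy) > 1e-9:
        raise ValueError("in-plane pixel size must be isotropic")
    n = np.asarray(spec.normal, dtype=float)
    X, Y, Z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij", sparse=True)
    s = X * (sx * n[0]) + Y * (sy * n[1]) + Z * (sz * n[2])
    period = spec.spacing * sx                 # in-plane pixels -> mm
    half_width = spec.width * sx / 2.0
    phase = np.mod(s, period)
    dist = np.minimum(phase, period - phase)
    stripe = (dist <= half_width).astype(np.float64)
    if edge_sigma > 0:
        stripe = ndimage.gaussian_filter(stripe, edge_sigma, mode="wrap")
        np.clip(stripe, 0.0, 1.0, out=stripe)
    f = 1.0 - np.exp(-t_ms / t1_ms)
    return 1.0 - stripe * (1.0 - f)


def apply_tags(base: VolumeSequence, specs: Sequence[TagSpec],
               t1_ms: float = 900.0, edge_sigma: float = 0.0) -> VolumeSequence:
    """Imprint tag stripes on every phase of ``base``, with T1 fading.

    Each phase ``p`` is multiplied element-wise by the product of the tag
    fields of all families evaluated at that phase's time — saturated
    stripes are dark at early times and recover toward the background as
    the magnetization relaxes. With no specs the input is returned
    unchanged (bit-exact copy).
    """
    out = base.data.copy()
    for p in range(base.n_phases):
        t = float(base.phase_times[p])
        for spec in specs:
            out[..., p] *= tag_field(spec, base.grid_shape, t, t1_ms,
                                     edge_sigma, base.spacing)
    return VolumeSequence(out, base.spacing, base.phase_times)


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

def synth_displacement(model: DeformationModel, grid_shape: Sequence[int],
                       phase_fraction: float,
                       spacing: Sequence[float] = (0.70, 0.70, 1.5)
                       ) -> DisplacementField:
    """Ground-truth Lagrangian displacement at a given phase fraction.

    The field is evaluated on the reference (phase-0) grid and scales
    *exactly linearly* with ``phase_fraction``:
    ``u(lambda) = lambda * u(1)`` per component, so the peak-deformation
    field fully determines the trajectory. At fraction 0 it is
    identically zero. Components are in voxel units per axis. The
    in-plane rotation is a true rotation in mm space at peak (isotropic
    in-plane spacing required); the z-component is linear in z with the
    apex (slice 0) fixed.
    """
    if not 0 <= phase_fraction <= 1:
        raise ValueError("phase_fraction must lie in [0, 1]")
    nx, ny, nz = (int(n) for n in grid_shape)
    sx, sy, sz = as_spacing(spacing)
    if abs(sx - sy) > 1e-9:
        raise ValueError("in-plane spacing must be isotropic for the torsion model")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0

    X, Y, Z = np.meshgrid(np.arange(nx, dtype=float),
                          np.arange(ny, dtype=float),
                          np.arange(nz, dtype=float), indexing="ij")
    dx = X - cx
    dy = Y - cy
    zfrac = Z / (nz - 1)                     # 0 at apex, 1 at base

    U = np.zeros((nx, ny, nz, 3))

    # torsion at peak: rotation angle linear in z, opposite at apex/base
    theta = np.deg2rad(model.torsion_deg) * (zfrac - 0.5)
    c, s = np.cos(theta), np.sin(theta)
    U[..., 0] += c * dx - s * dy - dx
    U[..., 1] += s * dx + c * dy - dy

    # radial contraction: linear inward scaling of the in-plane position
    k = model.radial_contraction
    U[..., 0] += -k * dx
    U[..., 1] += -k * dy

    # longitudinal shortening: linear in z, apex fixed, base moves down
    U[..., 2] += -(model.longitudinal_shortening_mm / sz) * zfrac

    return DisplacementField(phase_fraction * U, reference_phase=0)


def invert_displacement(U: np.ndarray, n_iter: int = 20,
                        tol: float = 1e-4) -> np.ndarray:
    """Invert a forward Lagrangian displacement field by fixed point.

    Given ``U`` with material points mapped ``X -> X + U(X)``, returns the
    backward field ``v`` with ``v(r) = U(r - v(r))``, so that sampling an
    image at ``r - v(r)`` realizes the forward motion exactly. Converges
    for smooth fields with displacement gradients below 1 (true for the
    phantom's systolic motion).
    """
    U = np.asarray(U, dtype=np.float64)
    grid = np.meshgrid(*(np.arange(n, dtype=float) for n in U.shape[:-1]),
                       indexing="ij")
    v = U.copy()
    for _ in range(n_iter):
        coords = [g - v[..., a] for a, g in enumerate(grid)]
        v_new = np.stack(
            [ndimage.map_coordinates(U[..., a], coords, order=1, mode="nearest")
             for a in range(U.shape[-1])], axis=-1)
        delta = np.max(np.abs(v_new - v))
        v = v_new
        if delta < tol:
            break
    return v


def warp_volume(volume: np.ndarray, displacement: DisplacementField | np.ndarray,
                background: float = 0.0) -> np.ndarray:
    """Backward-warp a 3D volume: ``out(r) = volume(r - u(r))``.

    Trilinear interpolation; samples falling outside the grid take the
    ``background`` intensity. To apply a *forward* motion (material point
    X moves to X + U(X)), pass the inverted field from
    :func:`invert_displacement`.
    """
    u = displacement.U if isinstance(displacement, DisplacementField) else displacement
    u = np.asarray(u, dtype=np.float64)
    volume = np.asarray(volume, dtype=np.float64)
    if u.shape[:-1] != volume.shape or u.shape[-1] != volume.ndim:
        raise ValueError(
            f"displacement grid {u.shape} does not match volume {volume.shape}")
    grid = np.meshgrid(*(np.arange(n, dtype=float) for n in volume.shape),
                       indexing="ij")
    coords = [g - u[..., a] for a, g in enumerate(grid)]
    return ndimage.map_coordinates(volume, coords, order=1,
                                   mode="constant", cval=background)


def add_noise(volume: np.ndarray, percent: float, seed: int) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise at ``percent`` % of the global max.

    The noise standard deviation is ``percent/100`` times the maximum
    intensity of the noiseless input (the whole array, all phases);
    reproducible from ``seed``.
    """
    if percent < 0:
        raise ValueError("percent must be non-negative")
    volume = np.asarray(volume, dtype=np.float64)
    if percent == 0:
        return volume.copy()
    sigma = percent / 100.0 * float(volume.max())
    rng = np.random.default_rng(seed)
    return volume + rng.normal(0.0, sigma, size=volume.shape)


# ---------------------------------------------------------------------------
# full phantom sequence
# ---------------------------------------------------------------------------

def make_tagged_sequence(
    config: PhantomConfig,
    tag_specs: Sequence[TagSpec] | None = None,
    motion: DeformationModel | None = None,
    noise_percent: float = 0.0,
    noise_seed: int = 0,
    edge_sigma: float = 0.5,
) -> tuple[VolumeSequence, list[DisplacementField], np.ndarray]:
    """Generate a complete tagged, deforming, optionally noisy sequence.

    ``edge_sigma`` (voxels) softens the tag-stripe edges to emulate the
    finite, band-limited tag profile of a real acquisition (an imaged tag
    is never a perfect step); set 0 for ideal hard-edged stripes.

    Per phase ``p`` the pipeline is: imprint the (faded) tag stripes on
    the base anatomy at that phase's time, then warp the tagged reference
    image by the ground-truth displacement for that phase. The warp uses
    the *inverted* field so that the exported ground truth is exact at
    material (reference-grid) points: a material point at reference voxel
    X appears at ``X + U_p(X)`` in phase p.

    Returns ``(sequence, truth, mask)`` where ``truth[p]`` is the
    ground-truth :class:`DisplacementField` of phase ``p`` on the
    reference grid and ``mask`` is the reference-phase myocardial mask.
    """
    if tag_specs is None:
        tag_specs = default_tag_specs()
    if motion is None:
        motion = DeformationModel()

    base, mask = make_lv_phantom(config)
    base_vol = base.phase(0)
    n = config.n_phases
    background = config.background_intensity * config.M0

    data = np.empty(config.grid_shape + (n,))
    truth: list[DisplacementField] = []
    for p in range(n):
        t = float(config.phase_times[p])
        tagged = base_vol.copy()
        for spec in tag_specs:
            tagged *= tag_field(spec, config.grid_shape, t, config.T1,
                                edge_sigma, config.spacing)
        frac = motion.profile(p / (n - 1)) if n > 1 else 0.0
        U = synth_displacement(motion, config.grid_shape, frac, config.spacing)
        truth.append(U)
        if frac == 0.0:
            data[..., p] = tagged
        else:
            v = invert_displacement(U.U)
            data[..., p] = warp_volume(tagged, v, background=background)

    if noise_percent > 0:
        data = add_noise(data, noise_percent, noise_seed)

    seq = VolumeSequence(data, config.spacing, config.phase_times)
    return seq, truth, mask
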