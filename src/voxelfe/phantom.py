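"""Synthetic distal radius/tibia phantoms and paired repeat scans.

A phantom is a tapered, slightly irregular cortical tube enclosing a
regular lattice of trabecular struts, voxelised at the scanner's 82 um
isotropic resolution.  Densities are in mg HA/cm^3 and span roughly
0-1200, so the standard 400 mg HA/cm^3 bone threshold and the
density-modulus power law both behave as they do on real scans.

Repeat ("follow-up") scans differ from baseline by an axial slice shift,
a small in-plane rigid motion, additive scanner noise and a motion-
artifact blur.  The axial convention throughout: slice index 0 is the
distal end, and a positive slice shift means the captured region moved
proximally, i.e. ``follow[z] = base[z + shift]``.

All randomness flows from explicit integer seeds through
``numpy.random.SeedSequence`` spawning; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import CORT, TRAB, VOID, DEFAULT_VOXEL_SIZE, DensityVolume


# --------------------------------------------------------------------------
# Specifications

@dataclass
class PhantomSpec:
    """Geometry and composition of one synthetic bone.

    Lengths in mm, densities in mg HA/cm^3.  The tube tapers (metaphyseal
    flare) at ``flare_rate`` toward the distal end and its outer radius is
    modulated by a smooth seeded wobble so that the per-slice bone-area
    profile is unique along the axis -- without this, axial registration
    of shifted repeat scans would be degenerate.
    """

    outer_radius: float = 0.95
    cortical_thickness: float = 0.25
    cortical_density: float = 900.0
    trabecular_strut_density: float = 600.0
    trabecular_spacing: float = 0.6
    strut_thickness: float = 0.164
    background_noise_sd: float = 0.0
    flare_rate: float = 0.04           # mm of extra radius per mm toward distal
    wobble_amplitude: float = 0.04     # mm, smooth random radius modulation
    wobble_sigma: float = 4.0          # slices, smoothness of the wobble
    grid_shape: tuple[int, int] = (48, 48)
    n_slices: int = 110
    voxel_size: float = DEFAULT_VOXEL_SIZE
    lattice: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not self.cortical_thickness < self.outer_radius:
            raise ValueError("cortical_thickness must be < outer_radius")
        if min(self.cortical_density, self.trabecular_strut_density,
               self.background_noise_sd) < 0:
            raise ValueError("densities and noise SD must be non-negative")
        if not self.trabecular_spacing > self.strut_thickness:
            raise ValueError("trabecular_spacing must exceed strut_thickness")
        if self.cortical_thickness < self.voxel_size:
            raise ValueError("unresolvable cortex: shell thinner than one voxel")


@dataclass
class RescanSpec:
    """Between-scan differences for a simulated follow-up acquisition."""

    slice_shift: float = 0.0           # slices; positive = region moved proximally
    in_plane_rotation: float = 0.0     # degrees about the axial axis
    in_plane_translation: float = 0.0  # mm, applied along +x
    noise_sd: float = 0.0              # mg HA/cm^3 additive Gaussian noise
    motion_amplitude: float = 0.0      # unitless in [0, 1]; movement-artifact proxy
    interval_days: int = 10
    seed: int = 0

    def validate(self, n_slices: int | None = None) -> None:
        if not 0.0 <= self.motion_amplitude <= 1.0:
            raise ValueError("motion_amplitude must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if n_slices is not None and abs(self.slice_shift) >= n_slices:
            raise ValueError("no overlap: |slice_shift| >= n_slices")


@dataclass
class RegistrationResult:
    slice_shift_est: int
    common_region_pct: float
    score: float = 1.0


@dataclass
class ScanPair:
    """Baseline/follow-up pair plus acquisition metadata for one participant."""

    participant_id: str
    site: str
    baseline: DensityVolume
    followup: DensityVolume
    interval_days: int
    true_shift: float
    motion_amplitude: float
    seed: int


# --------------------------------------------------------------------------
# Phantom construction

def _outer_radius_profile(spec: PhantomSpec, n_slices: int,
                          slice_offset: float = 0.0) -> np.ndarray:
    """Outer radius (mm) per slice: flare + smooth seeded wobble.

    ``slice_offset`` shifts the axial coordinate so that overlapping
    windows cut from a longer master volume agree slice-for-slice.
    """
    z = (np.arange(n_slices) + slice_offset) * spec.voxel_size
    z_mid = 0.5 * (spec.n_slices - 1) * spec.voxel_size
    r = spec.outer_radius - spec.flare_rate * (z - z_mid)  # distal (z=0) wider
    if spec.wobble_amplitude > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xB0B]))
        # Draw on a long fixed axis so windows at different offsets agree.
        n_master = 4 * spec.n_slices
        raw = rng.standard_normal(n_master)
        smooth = ndimage.gaussian_filter1d(raw, spec.wobble_sigma, mode="wrap")
        smooth /= max(np.abs(smooth).max(), 1e-12)
        idx = np.rint(np.arange(n_slices) + slice_offset).astype(int) % n_master
        r = r + spec.wobble_amplitude * smooth[idx]
    return r


def _geometry_masks(spec: PhantomSpec, n_slices: int, slice_offset: float = 0.0,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (shell, strut) masks for the voxel grid; struts clipped to
    the endosteal cavity and shell/strut overlap resolved in favour of shell."""
    nx, ny = spec.grid_shape
    h = spec.voxel_size
    # Voxel-centre coordinates relative to the tube axis.
    x = (np.arange(nx) - (nx - 1) / 2.0) * h
    y = (np.arange(ny) - (ny - 1) / 2.0) * h
    rr = np.sqrt(x[:, None] ** 2 + y[None, :] ** 2)  # (nx, ny)

    r_out = _outer_radius_profile(spec, n_slices, slice_offset)  # (nz,)
    r_in = r_out - spec.cortical_thickness

    shell = (rr[:, :, None] <= r_out[None, None, :]) & \
            (rr[:, :, None] > r_in[None, None, :])
    # Struts stop one voxel short of the endosteal surface: rods running
    # tangent along the shell would otherwise be inseparable from cortex
    # for any contour algorithm (and are not an anatomical feature).
    cavity = rr[:, :, None] <= (r_in[None, None, :] - h)

    if spec.lattice:
        s, w = spec.trabecular_spacing, spec.strut_thickness
        z = (np.arange(n_slices) + slice_offset) * h
        # Distance of each coordinate from its nearest lattice plane.
        def near(c: np.ndarray) -> np.ndarray:
            m = np.mod(c + w / 2.0, s)
            return m < w
        fx, fy, fz = near(x), near(y), near(z)
        rods_z = fx[:, None, None] & fy[None, :, None]
        rods_x = fy[None, :, None] & fz[None, None, :]
        rods_y = fx[:, None, None] & fz[None, None, :]
        struts = (rods_z | rods_x | rods_y) & cavity
    else:
        struts = np.zeros_like(shell)
    return shell, struts & ~shell


def generate_phantom(spec: PhantomSpec, *, n_slices: int | None = None,
                     slice_offset: float = 0.0, scan_id: str = "phantom",
                     ) -> DensityVolume:
    """Voxelise the phantom described by ``spec``.

    Deterministic given ``spec.seed``.  ``n_slices``/``slice_offset`` allow
    cutting an axially extended master volume (used by cohort generation);
    by default the standard ``spec.n_slices`` region is produced.
    """
    spec.validate()
    nz = spec.n_slices if n_slices is None else n_slices
    half_width = (min(spec.grid_shape) / 2.0 - 1.0) * spec.voxel_size
    r_max = spec.outer_radius + spec.wobble_amplitude + \
        abs(spec.flare_rate) * 0.5 * spec.n_slices * spec.voxel_size
    if r_max > half_width:
        raise ValueError(f"phantom does not fit the grid: outer radius up to "
                         f"{r_max:.2f} mm vs half-width {half_width:.2f} mm")
    shell, struts = _geometry_masks(spec, nz, slice_offset)
    data = np.zeros(shell.shape, dtype=np.float32)
    data[shell] = spec.cortical_density
    data[struts] = spec.trabecular_strut_density
    if spec.background_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xBA]))
        noise = rng.normal(0.0, spec.background_noise_sd, size=data.shape)
        bg = ~(shell | struts)
        data[bg] = np.maximum(noise[bg], 0.0)
    return DensityVolume(data=data, voxel_size=spec.voxel_size,
                         site="phantom", scan_id=scan_id)


def phantom_truth_labels(spec: PhantomSpec, *, n_slices: int | None = None,
                         slice_offset: float = 0.0) -> np.ndarray:
    """Construction ground-truth labels (VOID/TRAB/CORT) for ``spec``."""
    spec.validate()
    nz = spec.n_slices if n_slices is None else n_slices
    shell, struts = _geometry_masks(spec, nz, slice_offset)
    labels = np.zeros(shell.shape, dtype=np.uint8)
    labels[struts] = TRAB
    labels[shell] = CORT
    return labels


# --------------------------------------------------------------------------
# Rescanning

def _axial_shift(data: np.ndarray, shift: float, fill: np.ndarray) -> np.ndarray:
    """``out[z] = data[z + shift]`` with linear interpolation for fractional
    shifts; slices sampled outside the field of view come from ``fill``."""
    nz = data.shape[2]
    out = fill
    lo = int(np.floor(shift))
    frac = shift - lo
    if frac == 0.0:
        src0, src1 = max(lo, 0), min(nz + lo, nz)
        if src1 > src0:
            out[:, :, src0 - lo:src1 - lo] = data[:, :, src0:src1]
    else:
        z_src = np.arange(nz) + shift
        valid = (z_src >= 0) & (z_src <= nz - 1)
        zi = np.clip(np.floor(z_src[valid]).astype(int), 0, nz - 2)
        t = (z_src[valid] - zi).astype(data.dtype)
        out[:, :, valid] = (data[:, :, zi] * (1 - t) + data[:, :, zi + 1] * t)
    return out


def _inplane_motion(data: np.ndarray, rotation_deg: float, translation_mm: float,
                    voxel_size: float) -> np.ndarray:
    if rotation_deg == 0.0 and translation_mm == 0.0:
        return data
    theta = np.deg2rad(rotation_deg)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    centre = (np.array(data.shape[:2]) - 1) / 2.0
    # output coords -> input coords: x_in = R^T (x_out - c) + c - t
    matrix = np.eye(3)
    matrix[:2, :2] = rot.T
    offset = np.zeros(3)
    offset[:2] = centre - rot.T @ centre
    offset[0] -= translation_mm / voxel_size
    return ndimage.affine_transform(data, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def rescan(base: DensityVolume, spec: RescanSpec) -> DensityVolume:
    """Simulate a follow-up acquisition of ``base``.

    Order of effects: axial shift (out-of-view slices filled with
    background noise), in-plane rigid motion, motion-artifact blur,
    additive scanner noise.  Deterministic given ``spec.seed``.
    """
    spec.validate(base.n_slices)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5CA7]))
    data = base.data.astype(np.float32)

    if spec.noise_sd > 0:
        fill = rng.normal(0.0, spec.noise_sd, size=data.shape)
        fill = np.maximum(fill, 0.0).astype(np.float32)
    else:
        fill = np.zeros_like(data)
    if spec.slice_shift != 0.0:
        data = _axial_shift(data, spec.slice_shift, fill.copy())
    data = _inplane_motion(data, spec.in_plane_rotation,
                           spec.in_plane_translation, base.voxel_size)
    if spec.motion_amplitude > 0:
        # Directional (x) blur whose width scales with the motion proxy;
        # 1.0 corresponds to a 2-voxel-sigma streak.
        data = ndimage.gaussian_filter1d(data, 2.0 * spec.motion_amplitude,
                                         axis=0, mode="nearest")
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
        data = np.maximum(data, 0.0)
    return DensityVolume(data=data.astype(np.float32), voxel_size=base.voxel_size,
                         site=base.site, scan_id=base.scan_id + "+rescan")


# --------------------------------------------------------------------------
# Common-region registration

def bone_area_profile(vol: DensityVolume, threshold: float = 400.0) -> np.ndarray:
    """Per-slice bone cross-sectional area in voxels (density >= threshold)."""
    return (vol.data >= threshold).sum(axis=(0, 1)).astype(float)


def register_common_region(a: DensityVolume, b: DensityVolume, *,
                           threshold: float = 400.0, max_shift: int | None = None,
                           min_overlap: int = 8, score_floor: float = 0.2,
                           ) -> RegistrationResult:
    """Estimate the integer axial shift between two scans of one limb.

    Maximises the normalised cross-correlation of the per-slice bone-area
    profiles over integer shifts ``s`` (comparing ``a[z + s]`` with
    ``b[z]``), mirroring the scanner's cross-sectional-area registration.
    ``common_region_pct = 100 * (n_slices - |s|) / n_slices``.
    """
    if a.shape != b.shape or a.voxel_size != b.voxel_size:
        raise ValueError("volumes must share grid dimensions and voxel size")
    nz = a.n_slices
    pa, pb = bone_area_profile(a, threshold), bone_area_profile(b, threshold)
    limit = nz - min_overlap if max_shift is None else max_shift
    best_s, best_score = 0, -np.inf
    for s in range(-limit, limit + 1):
        if s >= 0:
            xa, xb = pa[s:], pb[:nz - s]
        else:
            xa, xb = pa[:nz + s], pb[-s:]
        da, db = xa - xa.mean(), xb - xb.mean()
        denom = np.sqrt((da ** 2).sum() * (db ** 2).sum())
        if denom <= 0:
            continue
        score = float((da * db).sum() / denom)
        # Prefer the smaller displacement on (near-)ties.
        if score > best_score + 1e-12 or \
                (abs(score - best_score) <= 1e-12 and abs(s) < abs(best_s)):
            best_s, best_score = s, score
    if not np.isfinite(best_score) or best_score < score_floor:
        raise ValueError("registration failed: no plausible overlap "
                         f"(best score {best_score:.3f})")
    pct = 100.0 * (nz - abs(best_s)) / nz
    return RegistrationResult(slice_shift_est=best_s,
                              common_region_pct=pct, score=best_score)


# --------------------------------------------------------------------------
# Cohort generation

DEFAULT_PHANTOM_VARIABILITY: dict[str, tuple[float, float]] = {
    # mean, SD of per-participant draws (truncated two SD below the mean)
    "outer_radius": (0.95, 0.06),
    "cortical_thickness": (0.28, 0.03),
    "cortical_density": (900.0, 60.0),
    "trabecular_strut_density": (600.0, 50.0),
}

DEFAULT_RESCAN_DISTRIBUTION: dict[str, object] = {
    # Integer axial shift drawn uniformly over the observed per-scan range.
    "shift_range": (-19, 17),
    "rotation_sd": 0.0,        # degrees
    "translation_sd": 0.0,     # mm
    "noise_sd": 0.0,           # mg HA/cm^3
    "motion_amplitude_max": 0.0,
    "interval": (10.0, 4.0),   # days: mean, SD
}


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd < 0:
        raise ValueError("distribution SD must be non-negative")
    lo = mean - 2.0 * sd
    return float(np.clip(rng.normal(mean, sd), lo, mean + 2.0 * sd)) if sd > 0 \
        else float(mean)


def generate_cohort(n_participants: int,
                    phantom_variability: dict | None = None,
                    rescan_distribution: dict | None = None,
                    seed: int = 0, *,
                    grid_shape: tuple[int, int] = (48, 48),
                    n_slices: int = 110,
                    site: str = "radius",
                    base_spec: PhantomSpec | None = None,
                    ) -> list[ScanPair]:
    """Draw a cohort of baseline/follow-up scan pairs.

    Each participant gets an individual phantom (parameters drawn from
    ``phantom_variability``) voxelised as an axially extended master
    volume; the baseline is the central ``n_slices`` window and the
    follow-up is the window displaced by the drawn slice shift, so that a
    shifted follow-up captures genuinely new anatomy (flared/wobbled
    cross-sections) instead of empty padding -- as in real repositioning
    error.  In-plane motion, blur and scanner noise are then applied to
    the follow-up.  Deterministic given ``seed``.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    pv = dict(DEFAULT_PHANTOM_VARIABILITY, **(phantom_variability or {}))
    rd = dict(DEFAULT_RESCAN_DISTRIBUTION, **(rescan_distribution or {}))
    for key in ("rotation_sd", "translation_sd", "noise_sd"):
        if rd[key] < 0:
            raise ValueError(f"{key} must be non-negative")
    if rd["interval"][1] < 0:
        raise ValueError("interval SD must be non-negative")

    shift_lo, shift_hi = rd["shift_range"]
    margin = int(max(abs(shift_lo), abs(shift_hi))) + 1
    template = base_spec or PhantomSpec()

    pairs: list[ScanPair] = []
    children = np.random.SeedSequence(seed).spawn(n_participants)
    for i, child in enumerate(children):
        sub = child.generate_state(4)
        rng = np.random.default_rng(child)
        spec = PhantomSpec(
            outer_radius=_draw_truncated(rng, *pv["outer_radius"]),
            cortical_thickness=_draw_truncated(rng, *pv["cortical_thickness"]),
            cortical_density=_draw_truncated(rng, *pv["cortical_density"]),
            trabecular_strut_density=_draw_truncated(
                rng, *pv["trabecular_strut_density"]),
            trabecular_spacing=template.trabecular_spacing,
            strut_thickness=template.strut_thickness,
            background_noise_sd=template.background_noise_sd,
            flare_rate=template.flare_rate,
            wobble_amplitude=template.wobble_amplitude,
            grid_shape=grid_shape, n_slices=n_slices,
            voxel_size=template.voxel_size, lattice=template.lattice,
            seed=int(sub[0] % (2 ** 31)),
        )
        true_shift = int(rng.integers(shift_lo, shift_hi + 1))
        motion = float(rng.uniform(0.0, rd["motion_amplitude_max"])) \
            if rd["motion_amplitude_max"] > 0 else 0.0
        interval = max(1, int(round(rng.normal(*rd["interval"]))))
        pid = f"P{i + 1:03d}"

        baseline = generate_phantom(spec, n_slices=n_slices, slice_offset=0.0,
                                    scan_id=f"{pid}-t0")
        follow = generate_phantom(spec, n_slices=n_slices,
                                  slice_offset=float(true_shift),
                                  scan_id=f"{pid}-t1")
        motion_spec = RescanSpec(
            slice_shift=0.0,
            in_plane_rotation=float(rng.normal(0.0, rd["rotation_sd"]))
            if rd["rotation_sd"] > 0 else 0.0,
            in_plane_translation=float(rng.normal(0.0, rd["translation_sd"]))
            if rd["translation_sd"] > 0 else 0.0,
            noise_sd=float(rd["noise_sd"]),
            motion_amplitude=motion,
            interval_days=interval,
            seed=int(sub[1] % (2 ** 31)),
        )
        if (motion_spec.in_plane_rotation or motion_spec.in_plane_translation
                or motion_spec.noise_sd or motion_spec.motion_amplitude):
            follow = rescan(follow, motion_spec)
            follow.scan_id = f"{pid}-t1"
        follow.site = baseline.site = site
        pairs.append(ScanPair(participant_id=pid, site=site,
                              baseline=baseline, followup=follow,
                              interval_days=interval, true_shift=true_shift,
                              motion_amplitude=motion,
                              seed=int(sub[0] % (2 ** 31))))
    return pairs


def cohort_metadata(pairs: Sequence[ScanPair]) -> pd.DataFrame:
    """Cohort metadata table (one row per participant)."""
    return pd.DataFrame(
        [{"participant_id": p.participant_id, "site": p.site,
          "interval_days": p.interval_days, "true_shift": p.true_shift,
          "motion_amplitude": p.motion_amplitude, "seed": p.seed}
         for p in pairs]
    )
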