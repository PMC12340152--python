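"""Virtual microscope: synthetic phantoms, tilt projections, hydration model.

Stands in for the instrument so the acquisition stack (eucentric
calibration, drift control, dose accounting) and the 3D quantification
stack can be exercised end to end with known ground truth.

Conventions, used everywhere in this package:

* volumes are numpy arrays in (z, y, x) axis order, 0-based indexing,
  image origin at array index (0, 0) top-left;
* the tilt axis is the image y axis; tilting rotates the volume in the
  (z, x) plane (right-hand rule about y);
* a projection is the parallel-beam line integral along z.  Voxel values
  are attenuation per voxel of path, so a noise-free projection is the
  plain z-sum of the density grid;
* dose-limited noise draws pixel counts from Poisson with mean
  N₀·exp(−line integral), N₀ = beam_current·dwell/e electrons per pixel
  (Beer–Lambert attenuation, detector gain 1 count/electron; bright/dark
  field contrast inversion is not modelled);
* sample hydration follows the dew curve of water: holding the chamber
  pressure at/above the saturation vapor pressure at the sample
  temperature (100% relative humidity) keeps the specimen wet.  The guard
  here only gates acquisition — water-layer thickness physics is out of
  scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from . import dosimetry
from .drift_control import DriftControllerState, DriftProcess, controller_update, estimate_shift
from .stage_geometry import EucentricModel, TiltPlan, predict_displacement

logger = logging.getLogger(__name__)

__all__ = [
    "Phantom",
    "BeamConfig",
    "EnvironmentState",
    "Frame",
    "TiltSeries",
    "AcquisitionAborted",
    "make_bead_phantom",
    "make_gel_phantom",
    "make_bacterium_phantom",
    "project_volume",
    "render_projection",
    "acquire_series",
    "saturation_vapor_pressure",
    "hydration_state",
]

_MAX_PLACEMENT_RETRIES = 1000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """3D density grid (attenuation per voxel) with ground-truth annotations.

    ``ground_truth`` holds kind-specific annotations with all coordinates
    in nm, (z, y, x) order: bead/pore/magnetosome centers and radii, the
    bacterial backbone polyline, etc.
    """

    density: np.ndarray
    voxel_size_nm: float
    ground_truth: dict
    kind: str

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape


@dataclass(frozen=True)
class BeamConfig:
    beam_current_a: float = 8.72e-12
    dwell_time_s: float = 5e-6
    pixel_size_nm: float = 5.5
    frame_shape: tuple[int, int] = (1024, 1536)
    accel_voltage_kv: float = 30.0

    def __post_init__(self) -> None:
        if min(self.beam_current_a, self.dwell_time_s, self.pixel_size_nm) <= 0:
            raise ValueError("beam parameters must be strictly positive")
        if min(self.frame_shape) <= 0:
            raise ValueError("frame shape must be positive")

    @property
    def electrons_per_pixel(self) -> float:
        return self.beam_current_a * self.dwell_time_s / dosimetry.ELEMENTARY_CHARGE

    @property
    def dose_per_image(self) -> float:
        return dosimetry.dose_per_image(
            self.beam_current_a, self.dwell_time_s, self.pixel_size_nm
        )


@dataclass(frozen=True)
class EnvironmentState:
    """Chamber condition; the regime follows from pressure vs saturation pressure."""

    temperature_c: float = 1.0
    pressure_hpa: float = 8.0
    tol_hpa: float = 0.1

    @property
    def regime(self) -> str:
        return hydration_state(self.pressure_hpa, self.temperature_c, self.tol_hpa)


@dataclass
class Frame:
    pixels: np.ndarray
    angle_deg: float
    beam: BeamConfig
    dose_e_per_nm2: float
    index: int
    is_counts: bool = False
    clipped: bool = False


@dataclass
class TiltSeries:
    frames: list[Frame]
    plan: TiltPlan
    log: dict = field(default_factory=dict)

    @property
    def angles_deg(self) -> np.ndarray:
        return np.array([f.angle_deg for f in self.frames])

    def stack(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])

    @property
    def total_dose(self) -> float:
        return float(sum(f.dose_e_per_nm2 for f in self.frames))

    def __len__(self) -> int:
        return len(self.frames)


class AcquisitionAborted(RuntimeError):
    """Acquisition stopped by a guard; carries the partial series."""

    def __init__(self, message: str, partial_series: TiltSeries):
        super().__init__(message)
        self.partial_series = partial_series


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _paint_sphere(grid: np.ndarray, center_vox: np.ndarray, radius_vox: float,
                  value: float, mode: str = "max") -> None:
    lo = np.maximum(np.floor(center_vox - radius_vox).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(center_vox + radius_vox).astype(int) + 2,
                    np.asarray(grid.shape))
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    inside = ((zz - center_vox[0]) ** 2 + (yy - center_vox[1]) ** 2
              + (xx - center_vox[2]) ** 2) <= radius_vox**2
    sub = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if mode == "max":
        sub[inside] = np.maximum(sub[inside], value)
    else:
        sub[inside] = value


def _box_to_grid(box_nm: tuple[float, float, float] | float, voxel_size_nm: float):
    box = np.broadcast_to(np.asarray(box_nm, dtype=float), (3,)).copy()
    shape = np.maximum(np.round(box / voxel_size_nm).astype(int), 1)
    return box, tuple(shape)


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def _sample_csr(n: int, lo: np.ndarray, hi: np.ndarray, rng) -> np.ndarray:
    return rng.uniform(lo, hi, size=(n, 3))


def _sample_thomas(n: int, lo: np.ndarray, hi: np.ndarray, params: dict, rng) -> np.ndarray:
    """Thomas cluster process: Poisson parents, Gaussian-scattered children."""
    parent_rate = float(params.get("parent_rate", 5e-7))  # parents per nm^3
    sigma = float(params.get("cluster_sigma", 30.0))
    mean_children = float(params.get("mean_children", 8.0))
    volume = float(np.prod(hi - lo))
    points: list[np.ndarray] = []
    for _ in range(_MAX_PLACEMENT_RETRIES):
        n_parents = max(int(rng.poisson(parent_rate * volume)), 1)
        parents = rng.uniform(lo, hi, size=(n_parents, 3))
        for p in parents:
            k = rng.poisson(mean_children)
            if k == 0:
                continue
            kids = p + rng.normal(0.0, sigma, size=(k, 3))
            keep = np.all((kids >= lo) & (kids <= hi), axis=1)
            points.extend(kids[keep])
        if len(points) >= n:
            pts = np.asarray(points)
            return pts[rng.permutation(len(pts))[:n]]
    raise RuntimeError("Thomas process failed to produce enough points")


def make_calibration_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_nm: float = 5.5,
    seed: int = 0,
    smooth_sigma: float = 1.0,
) -> Phantom:
    """Axisymmetric calibration scene for eucentric round-trip tests.

    The density depends only on (y, radius in the z–x plane about the grid
    center), so tilting about the y axis leaves the projection unchanged —
    the only image motion is the displacement a(θ) imposed by the eucentric
    offset.  A textured random field in (y, r) gives phase correlation
    plenty of contrast.  Real calibration scenes add parallax from the
    tracked feature's own offset; that offset is precisely what the
    calibration measures, so this phantom isolates the imposed part.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    n_r = int(np.ceil(np.hypot(nz, nx) / 2)) + 2
    field = ndi.gaussian_filter(rng.normal(size=(ny, n_r)), smooth_sigma)
    field -= field.min()
    zz, xx = np.meshgrid(np.arange(nz) - (nz - 1) / 2,
                         np.arange(nx) - (nx - 1) / 2, indexing="ij")
    r = np.hypot(zz, xx)
    r0 = np.minimum(np.floor(r).astype(int), n_r - 2)
    frac = r - r0
    density = np.empty(shape, dtype=np.float32)
    for iy in range(ny):
        density[:, iy, :] = field[iy, r0] * (1 - frac) + field[iy, r0 + 1] * frac
    return Phantom(density=density, voxel_size_nm=voxel_size_nm,
                   ground_truth={"axisymmetric": True}, kind="calibration")


def make_bead_phantom(
    n_beads: int,
    box_nm: tuple[float, float, float] | float = (300.0, 300.0, 300.0),
    bead_radius_nm: float = 5.0,
    clustering: str | dict = "csr",
    seed: int = 0,
    voxel_size_nm: float = 2.0,
    bead_density: float = 1.0,
    background: float = 0.0,
    slab_thickness_nm: float = 0.0,
    slab_density: float = 0.05,
    thickness_nm: float | None = None,
    allow_overlap: bool = False,
) -> Phantom:
    """Gold-bead phantom: solid spheres on an optional support slab.

    Bead centers follow either complete spatial randomness (``"csr"``) or a
    Thomas cluster process (``{"kind": "thomas", "parent_rate": …,
    "cluster_sigma": …, "mean_children": …}``), emulating nanoparticles
    dispersed (or weakly clustered) on a support.  Centers and the common
    radius are recorded as ground truth in nm.

    ``thickness_nm`` confines bead centers to a slab of that thickness
    around the mid-plane in z — the membrane-supported geometry that keeps
    the specimen near the eucentric plane, where tilt-induced parallax of
    the tracked content stays small.
    """
    if n_beads < 0:
        raise ValueError("n_beads must be >= 0")
    rng = np.random.default_rng(seed)
    box, shape = _box_to_grid(box_nm, voxel_size_nm)
    margin = bead_radius_nm
    lo = np.full(3, margin)
    hi = box - margin
    if thickness_nm is not None:
        half = max(thickness_nm / 2.0, bead_radius_nm)
        lo[0] = max(box[0] / 2.0 - half + bead_radius_nm, margin)
        hi[0] = min(box[0] / 2.0 + half - bead_radius_nm, box[0] - margin)
        if hi[0] < lo[0]:
            hi[0] = lo[0] = box[0] / 2.0
    if n_beads > 0 and np.any(hi <= lo):
        raise ValueError("box too small for the requested bead radius")

    centers = np.empty((0, 3))
    if n_beads > 0:
        if isinstance(clustering, dict) and clustering.get("kind") == "thomas":
            candidates = _sample_thomas(max(4 * n_beads, n_beads + 32), lo, hi,
                                        clustering, rng)
        elif clustering == "csr":
            candidates = None
        else:
            raise ValueError(f"unknown clustering {clustering!r}")
        accepted: list[np.ndarray] = []
        tries = 0
        idx = 0
        while len(accepted) < n_beads:
            if candidates is not None:
                if idx >= len(candidates):
                    candidates = _sample_thomas(4 * n_beads, lo, hi, clustering, rng)
                    idx = 0
                c = candidates[idx]
                idx += 1
            else:
                c = rng.uniform(lo, hi)
            if not allow_overlap and accepted:
                d2 = np.sum((np.asarray(accepted) - c) ** 2, axis=1)
                if np.min(d2) < (2 * bead_radius_nm) ** 2:
                    tries += 1
                    if tries > _MAX_PLACEMENT_RETRIES:
                        raise RuntimeError(
                            f"could not place {n_beads} non-overlapping beads"
                        )
                    continue
            accepted.append(c)
        centers = np.asarray(accepted)

    density = np.full(shape, background, dtype=np.float32)
    if slab_thickness_nm > 0:
        n_slab = max(int(round(slab_thickness_nm / voxel_size_nm)), 1)
        density[-n_slab:, :, :] = np.maximum(density[-n_slab:, :, :], slab_density)
    for c in centers:
        _paint_sphere(density, c / voxel_size_nm, bead_radius_nm / voxel_size_nm,
                      bead_density)
    return Phantom(
        density=density, voxel_size_nm=voxel_size_nm,
        ground_truth={"bead_centers_nm": centers,
                      "bead_radius_nm": bead_radius_nm,
                      "box_nm": box},
        kind="beads",
    )


def make_gel_phantom(
    box_nm: tuple[float, float, float] | float = (200.0, 200.0, 200.0),
    porosity_target: float = 0.2,
    pore_radius_range_nm: tuple[float, float] = (2.5, 15.0),
    seed: int = 0,
    voxel_size_nm: float = 2.0,
    matrix_density: float = 1.0,
) -> Phantom:
    """Porous-gel phantom: a solid matrix minus non-overlapping spherical pores.

    Emulates a hydrogel whose substructure carries pores in the 5–30 nm
    diameter range.  Pores are added until the analytic pore-volume
    fraction reaches the target; the achieved voxelized porosity must land
    within 20% relative of the target or the construction fails.
    """
    if not 0.0 <= porosity_target < 1.0:
        raise ValueError("porosity_target must lie in [0, 1)")
    r_lo, r_hi = pore_radius_range_nm
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError("pore radii must be positive with lo <= hi")
    rng = np.random.default_rng(seed)
    box, shape = _box_to_grid(box_nm, voxel_size_nm)
    volume = float(np.prod(box))

    density = np.full(shape, matrix_density, dtype=np.float32)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    pore_vol = 0.0
    fails = 0
    while porosity_target > 0 and pore_vol / volume < porosity_target:
        r = rng.uniform(r_lo, r_hi)
        lo_c, hi_c = np.full(3, r), box - r
        if np.any(hi_c <= lo_c):
            raise ValueError("box too small for the requested pore radii")
        c = rng.uniform(lo_c, hi_c)
        if centers:
            d = np.sqrt(np.sum((np.asarray(centers) - c) ** 2, axis=1))
            if np.min(d - np.asarray(radii)) < r:  # would overlap an existing pore
                fails += 1
                if fails > _MAX_PLACEMENT_RETRIES:
                    raise RuntimeError(
                        f"unachievable porosity {porosity_target} with non-overlapping pores"
                    )
                continue
        fails = 0
        centers.append(c)
        radii.append(r)
        pore_vol += 4.0 / 3.0 * np.pi * r**3
        _paint_sphere(density, c / voxel_size_nm, r / voxel_size_nm, 0.0, mode="set")

    achieved = float(np.mean(density < 0.5 * matrix_density)) if porosity_target > 0 else 0.0
    if porosity_target > 0 and abs(achieved - porosity_target) > 0.2 * porosity_target:
        raise RuntimeError(
            f"achieved porosity {achieved:.3f} outside 20% of target {porosity_target}"
        )
    return Phantom(
        density=density, voxel_size_nm=voxel_size_nm,
        ground_truth={"pore_centers_nm": np.asarray(centers).reshape(-1, 3),
                      "pore_radii_nm": np.asarray(radii),
                      "porosity": achieved, "box_nm": box,
                      "matrix_density": matrix_density},
        kind="gel",
    )


def gel_pore_mask(phantom: Phantom) -> np.ndarray:
    """Boolean pore mask of a gel phantom (True inside pores)."""
    if phantom.kind != "gel":
        raise ValueError("pore mask is defined for gel phantoms")
    return phantom.density < 0.5 * phantom.ground_truth["matrix_density"]


def make_bacterium_phantom(
    length_nm: float = 1000.0,
    helix_radius_nm: float = 40.0,
    helix_pitch_nm: float = 300.0,
    body_radius_nm: float = 60.0,
    n_magnetosomes: int = 10,
    magnetosome_diam_nm: float = 50.0,
    n_inclusions: int = 3,
    inclusion_diam_nm: float = 80.0,
    seed: int = 0,
    voxel_size_nm: float = 5.0,
) -> Phantom:
    """Spirillum phantom: helical cell body, magnetosome chain, storage granules.

    Emulates a magnetotactic spirillum — a low-density helical body, a chain
    of dense magnetite nanoparticles (magnetosomes) strung along the cell
    axis, and medium-density spherical inclusions (PHA-like granules).
    Densities are ordered magnetosome (1.0) > inclusion (0.6) >
    cytoplasm (0.3).
    """
    rng = np.random.default_rng(seed)
    margin = body_radius_nm + helix_radius_nm + voxel_size_nm
    box = np.array([2 * margin + 2 * helix_radius_nm,
                    2 * margin + 2 * helix_radius_nm,
                    length_nm + 2 * margin])
    box, shape = _box_to_grid(box, voxel_size_nm)
    zc, yc = box[0] / 2, box[1] / 2

    xs = np.linspace(margin, margin + length_nm, max(int(length_nm / voxel_size_nm) * 2, 16))
    backbone = np.column_stack([
        zc + helix_radius_nm * np.sin(2 * np.pi * xs / helix_pitch_nm),
        yc + helix_radius_nm * np.cos(2 * np.pi * xs / helix_pitch_nm),
        xs,
    ])

    density = np.zeros(shape, dtype=np.float32)
    for p in backbone:
        _paint_sphere(density, p / voxel_size_nm, body_radius_nm / voxel_size_nm, 0.3)

    # magnetosome chain along the central stretch of the backbone
    mag_centers = np.empty((0, 3))
    if n_magnetosomes > 0:
        spacing = 1.2 * magnetosome_diam_nm
        chain_len = (n_magnetosomes - 1) * spacing
        if chain_len > length_nm:
            raise ValueError("magnetosome chain does not fit inside the body")
        x0 = margin + (length_nm - chain_len) / 2
        mx = x0 + spacing * np.arange(n_magnetosomes)
        mag_centers = np.column_stack([
            np.interp(mx, backbone[:, 2], backbone[:, 0]),
            np.interp(mx, backbone[:, 2], backbone[:, 1]),
            mx,
        ])

    # inclusions: offset perpendicular to the backbone, clear of the chain
    incl_centers: list[np.ndarray] = []
    incl_r = inclusion_diam_nm / 2
    offset = max(body_radius_nm - incl_r, 0.0) * 0.7
    tries = 0
    while len(incl_centers) < n_inclusions:
        i = rng.integers(len(backbone))
        phi = rng.uniform(0, 2 * np.pi)
        c = backbone[i] + np.array([offset * np.sin(phi), offset * np.cos(phi), 0.0])
        clear = True
        if len(mag_centers):
            dmin = np.min(np.linalg.norm(mag_centers - c, axis=1))
            clear = dmin > incl_r + magnetosome_diam_nm / 2
        if clear and all(np.linalg.norm(np.asarray(e) - c) > 2 * incl_r for e in incl_centers):
            incl_centers.append(c)
        else:
            tries += 1
            if tries > _MAX_PLACEMENT_RETRIES:
                raise RuntimeError("could not place inclusions clear of the chain")
    incl_centers = np.asarray(incl_centers).reshape(-1, 3)

    for c in incl_centers:
        _paint_sphere(density, c / voxel_size_nm, incl_r / voxel_size_nm, 0.6)
    for c in mag_centers:
        _paint_sphere(density, c / voxel_size_nm,
                      magnetosome_diam_nm / 2 / voxel_size_nm, 1.0)

    return Phantom(
        density=density, voxel_size_nm=voxel_size_nm,
        ground_truth={"backbone_nm": backbone,
                      "magnetosome_centers_nm": mag_centers,
                      "magnetosome_diam_nm": magnetosome_diam_nm,
                      "inclusion_centers_nm": incl_centers,
                      "inclusion_diam_nm": inclusion_diam_nm,
                      "box_nm": box},
        kind="bacterium",
    )


# ---------------------------------------------------------------------------
# projection rendering
# ---------------------------------------------------------------------------

def project_volume(density: np.ndarray, theta_deg: float) -> np.ndarray:
    """Parallel-beam line integral of a (z, y, x) volume tilted by θ about y.

    The volume is rotated in the (z, x) plane by −θ (right-hand rule about
    the image y axis: the beam direction stays fixed along z while the
    specimen tilts) and summed along z.  Linear interpolation; the result
    has shape (ny, nx).  This exact routine is also the forward projector
    of the SART reconstruction, so renderer and reconstruction share one
    geometry.
    """
    if density.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    if theta_deg == 0.0:
        return density.sum(axis=0)
    rot = ndi.rotate(density, -theta_deg, axes=(0, 2), reshape=False, order=1,
                     mode="constant", cval=0.0)
    return rot.sum(axis=0)


def backproject_image(image: np.ndarray, theta_deg: float, n_z: int) -> np.ndarray:
    """Adjoint-style backprojection: smear a (y, x) image along z and untilt."""
    vol = np.broadcast_to(image, (n_z,) + image.shape).astype(float).copy()
    if theta_deg == 0.0:
        return vol
    return ndi.rotate(vol, theta_deg, axes=(0, 2), reshape=False, order=1,
                      mode="constant", cval=0.0)


def render_projection(
    phantom: Phantom,
    theta_deg: float,
    eucentric_offset_nm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    drift_offset_px: tuple[float, float] = (0.0, 0.0),
    beam: BeamConfig | None = None,
    noise: bool = False,
    seed: int = 0,
    index: int = 0,
) -> Frame:
    """Render one tilt frame with stage error, drift, and optional shot noise.

    ``eucentric_offset_nm`` is (y_A, z_A, R) of the calibration model; the
    resulting image-plane displacement a(θ) shifts the projection along x
    (perpendicular to the tilt axis) by a(θ)/pixel_size pixels, on top of
    ``drift_offset_px`` (row, col).  With ``noise`` the pixel values are
    Poisson counts under Beer–Lambert attenuation; otherwise they are the
    line integrals themselves.
    """
    if abs(theta_deg) >= 90.0:
        raise ValueError("tilt angle must lie strictly inside (-90, 90) degrees")
    if beam is None:
        ny, nx = phantom.density.shape[1:]
        beam = BeamConfig(pixel_size_nm=phantom.voxel_size_nm, frame_shape=(ny, nx))
    if not np.isclose(beam.pixel_size_nm, phantom.voxel_size_nm):
        raise ValueError("beam pixel size must match the phantom voxel size")

    proj = project_volume(phantom.density, theta_deg)
    y_a, z_a, r = eucentric_offset_nm
    model = EucentricModel(y_a=y_a, z_a=z_a, r=r)
    a_nm = predict_displacement(model, theta_deg)
    shift_vec = np.array([drift_offset_px[0],
                          drift_offset_px[1] + a_nm / beam.pixel_size_nm])
    if np.any(shift_vec != 0.0):
        proj = ndi.shift(proj, shift_vec, order=1, mode="constant", cval=0.0)

    clipped = False
    ny, nx = beam.frame_shape
    if proj.shape != (ny, nx):
        out = np.zeros((ny, nx), dtype=proj.dtype)
        sy, sx = proj.shape
        oy, ox = max((ny - sy) // 2, 0), max((nx - sx) // 2, 0)
        iy, ix = max((sy - ny) // 2, 0), max((sx - nx) // 2, 0)
        cy, cx = min(sy, ny), min(sx, nx)
        out[oy:oy + cy, ox:ox + cx] = proj[iy:iy + cy, ix:ix + cx]
        clipped = proj.shape[0] > ny or proj.shape[1] > nx
        proj = out

    if noise:
        rng = np.random.default_rng(seed)
        mean = beam.electrons_per_pixel * np.exp(-np.clip(proj, 0.0, 700.0))
        pixels = rng.poisson(mean).astype(np.float32)
    else:
        pixels = proj.astype(np.float32)

    return Frame(pixels=pixels, angle_deg=float(theta_deg), beam=beam,
                 dose_e_per_nm2=beam.dose_per_image, index=index,
                 is_counts=noise, clipped=clipped)


# ---------------------------------------------------------------------------
# acquisition loop
# ---------------------------------------------------------------------------

def acquire_series(
    phantom: Phantom,
    plan: TiltPlan,
    controller: str | None = "full",
    eucentric_offset_nm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    drift_process: DriftProcess | None = None,
    beam: BeamConfig | None = None,
    env: EnvironmentState | None = None,
    noise: bool = False,
    seed: int = 0,
    shift_method: str = "phase_correlation",
) -> TiltSeries:
    """Simulated automatic tilt-series acquisition with in-loop drift control.

    Frames are rendered in plan order.  After each frame the shift against
    the previous frame is measured, fed to the predictive controller
    (variant ``controller``; None/"off" disables correction), and the
    emitted beam shift is applied before the next frame.  Per-frame dose,
    applied corrections and the environment regime are logged; the
    hydration guard aborts (with the partial series attached) if the
    chamber is in the evaporation regime.
    """
    if controller in ("off", None):
        controller = None
    elif controller not in ("correction_only", "correction_memory", "full"):
        raise ValueError(f"unknown controller variant {controller!r}")
    if beam is None:
        ny, nx = phantom.density.shape[1:]
        beam = BeamConfig(pixel_size_nm=phantom.voxel_size_nm, frame_shape=(ny, nx))
    angles = plan.angles
    rng = np.random.default_rng(seed)

    drift_cum = (drift_process.cumulative(len(angles)) if drift_process is not None
                 else np.zeros((len(angles), 2)))

    frames: list[Frame] = []
    corrections: list[np.ndarray] = []
    doses: list[float] = []
    regimes: list[str] = []
    series = TiltSeries(frames=frames, plan=plan, log={})
    state = DriftControllerState()
    b_applied = np.zeros(2)
    prev_pixels = None
    total = 0.0

    for n, theta in enumerate(angles):
        if env is not None and env.regime == "evaporation":
            series.log.update(_series_log(corrections, doses, regimes, controller, seed))
            raise AcquisitionAborted(
                f"hydration guard: evaporation regime at frame {n} "
                f"(P={env.pressure_hpa} hPa, T={env.temperature_c} C)",
                partial_series=series,
            )
        frame = render_projection(
            phantom, theta,
            eucentric_offset_nm=eucentric_offset_nm,
            drift_offset_px=tuple(drift_cum[n] + b_applied),
            beam=beam, noise=noise,
            seed=int(rng.integers(2**31)), index=n,
        )
        frames.append(frame)
        total += frame.dose_e_per_nm2
        doses.append(frame.dose_e_per_nm2)
        regimes.append(env.regime if env is not None else "stable")
        logger.debug("frame %d at %.2f deg, dose %.3g e/nm2", n, theta, frame.dose_e_per_nm2)

        if controller is not None and prev_pixels is not None:
            d_n = estimate_shift(prev_pixels, frame.pixels, method=shift_method)
            state, r_n = controller_update(state, d_n, variant=controller)
            b_applied = b_applied + r_n
        corrections.append(b_applied.copy())
        prev_pixels = frame.pixels

    series.log.update(_series_log(corrections, doses, regimes, controller, seed))
    logger.info("acquired %d frames, total dose %.4g e/nm2", len(frames), total)
    return series


def _series_log(corrections, doses, regimes, controller, seed) -> dict:
    return {
        "applied_corrections_px": np.asarray(corrections).reshape(-1, 2),
        "doses_e_per_nm2": list(doses),
        "total_dose_e_per_nm2": float(np.sum(doses)),
        "environment_regimes": list(regimes),
        "controller_variant": controller or "off",
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# hydration (dew curve)
# ---------------------------------------------------------------------------

#: Magnus coefficients for saturation vapor pressure over liquid water.
MAGNUS_A_HPA = 6.1094
MAGNUS_B = 17.625
MAGNUS_C = 243.04


def saturation_vapor_pressure(temperature_c: float) -> float:
    """Saturation vapor pressure over liquid water, hPa (Magnus formula).

    Valid for −40 °C ≤ T ≤ 60 °C; this P(T) locus is the dew curve along
    which the chamber is operated to hold 100% relative humidity.
    """
    if not -40.0 <= temperature_c <= 60.0:
        raise ValueError("temperature outside the Magnus validity range [-40, 60] C")
    return MAGNUS_A_HPA * np.exp(MAGNUS_B * temperature_c / (temperature_c + MAGNUS_C))


def hydration_state(pressure_hpa: float, temperature_c: float, tol_hpa: float = 0.1) -> str:
    """Hydration regime from chamber pressure vs the dew curve.

    ``condensation`` (wet, P above saturation by more than tol),
    ``evaporation`` (drying), or ``stable`` within ±tol of saturation.
    """
    p_sat = saturation_vapor_pressure(temperature_c)
    if pressure_hpa > p_sat + tol_hpa:
        return "condensation"
    if pressure_hpa < p_sat - tol_hpa:
        return "evaporation"
    return "stable"
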