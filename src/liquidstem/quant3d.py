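"""Post-acquisition 3D quantification.

Five analyses, in the order a tomography study runs them:

* **SART reconstruction** — simultaneous algebraic reconstruction with
  per-angle updates, non-negativity, and optional FISTA-style (Nesterov)
  momentum.  The forward projector is the exact routine the virtual
  microscope renders with, so reconstruction tests isolate algorithmic
  error from geometry mismatch.
* **Fourier shell correlation (FSC)** — normalized correlation of two
  volumes' Fourier coefficients per radial shell; resolution is quoted at
  the 0.5 or 0.143 crossing (half-map convention), linearly interpolated
  between shells.
* **Bead detection** — band-pass (Laplacian-of-Gaussian) blob detection
  with centroid refinement, returning sub-voxel centers in nm.
* **Pair correlation g(r)** — density of point pairs at separation r
  relative to complete spatial randomness (CSR) at equal intensity, with
  translational edge correction (or periodic boundaries for synthetic
  exactness), plus a pointwise Monte Carlo CSR envelope: g above the upper
  envelope at small r indicates significant clustering.
* **Pore-size distribution** — local thickness: every pore voxel is
  assigned the diameter of the largest inscribed sphere that contains it;
  the histogram is weighted by pore volume.  Volume change between two
  segmented masks is reported as a percentage (negative = shrinkage), with
  the linear-equivalent change alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import blob_log

from .virtual_scope import TiltSeries, backproject_image, project_volume

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "FSCCurve",
    "ResolutionEstimate",
    "PCFResult",
    "PoreSizeDistribution",
    "VolumeChange",
    "reconstruct_sart",
    "fsc",
    "resolution_at",
    "detect_beads",
    "pair_correlation",
    "csr_envelope",
    "local_thickness",
    "pore_size_distribution",
    "volume_change",
]


@dataclass
class Volume:
    grid: np.ndarray
    voxel_size_nm: float

    def __post_init__(self) -> None:
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def shape(self):
        return self.grid.shape


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def _series_line_integrals(series: TiltSeries) -> tuple[np.ndarray, np.ndarray]:
    shapes = {f.pixels.shape for f in series.frames}
    if len(shapes) != 1:
        raise ValueError("frames have mismatched shapes")
    projs = []
    for f in series.frames:
        if f.is_counts:
            n0 = f.beam.electrons_per_pixel
            projs.append(-np.log(np.clip(f.pixels, 1.0, None) / n0))
        else:
            projs.append(np.asarray(f.pixels, dtype=float))
    return np.stack(projs), series.angles_deg


def reconstruct_sart(
    series: TiltSeries,
    n_iter: int = 15,
    relax: float = 0.25,
    momentum: bool = False,
) -> Volume:
    """SART reconstruction of a tilt series.

    One iteration sweeps the angles in acquisition order; for each angle θ
    the projection residual is ray-normalized, backprojected, and applied
    with relaxation ``relax``, then the volume is clipped to be
    non-negative.  ``momentum`` adds a FISTA (Nesterov) extrapolation
    between full sweeps.  Frames holding Poisson counts are converted to
    line integrals by −log(counts/N₀) first.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 projections")
    projs, angles = _series_line_integrals(series)
    ny, nx = projs.shape[1:]
    nz = nx  # reconstruct a cube along the beam axis
    voxel = series.frames[0].beam.pixel_size_nm

    recon = np.zeros((nz, ny, nx))
    prev = recon.copy()
    t_k = 1.0
    ones_vol = np.ones_like(recon)
    for it in range(n_iter):
        for theta, p_obs in zip(angles, projs):
            ray = project_volume(ones_vol, theta)
            p_est = project_volume(recon, theta)
            resid = (p_obs - p_est) / np.clip(ray, 1.0, None)
            recon += relax * backproject_image(resid, theta, nz)
            np.clip(recon, 0.0, None, out=recon)
        if momentum:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k**2))
            recon, prev = recon + ((t_k - 1.0) / t_next) * (recon - prev), recon.copy()
            np.clip(recon, 0.0, None, out=recon)
            t_k = t_next
        logger.debug("SART iteration %d/%d done", it + 1, n_iter)
    return Volume(grid=recon, voxel_size_nm=voxel)


def projection_residual_norm(volume: Volume, series: TiltSeries) -> float:
    """RMS mismatch between a volume's reprojections and the series."""
    projs, angles = _series_line_integrals(series)
    sq = 0.0
    for theta, p_obs in zip(angles, projs):
        sq += float(np.sum((project_volume(volume.grid, theta) - p_obs) ** 2))
    return np.sqrt(sq / projs.size)


# ---------------------------------------------------------------------------
# Fourier shell correlation
# ---------------------------------------------------------------------------

@dataclass
class FSCCurve:
    shell_freq: np.ndarray  # cycles per nm, shell centers
    correlation: np.ndarray
    shell_counts: np.ndarray
    nyquist: float  # cycles per nm


def fsc(vol_a: Volume, vol_b: Volume, shell_width: float = 1.0) -> FSCCurve:
    """Fourier shell correlation between two volumes of identical geometry.

    Shells are ``shell_width`` voxel-frequency units wide (1/(N·voxel) in
    physical frequency); the correlation in each shell is
    Re⟨A·B*⟩ / √(⟨|A|²⟩⟨|B|²⟩).
    """
    if vol_a.shape != vol_b.shape:
        raise ValueError("volumes must share the same shape")
    if not np.isclose(vol_a.voxel_size_nm, vol_b.voxel_size_nm):
        raise ValueError("volumes must share the same voxel size")
    fa = np.fft.fftn(vol_a.grid)
    fb = np.fft.fftn(vol_b.grid)
    shape = np.asarray(vol_a.shape)
    n_ref = int(shape.min())
    grids = np.meshgrid(*[np.fft.fftfreq(n) * n_ref for n in shape], indexing="ij")
    radius = np.sqrt(sum(g**2 for g in grids))  # in reference-voxel frequency units
    n_shells = int(np.floor(n_ref / 2 / shell_width)) + 1
    idx = np.minimum((radius / shell_width).astype(int), n_shells)  # last bin = overflow

    cross = np.bincount(idx.ravel(), weights=(fa * np.conj(fb)).real.ravel(),
                        minlength=n_shells + 1)[:n_shells]
    pa = np.bincount(idx.ravel(), weights=(np.abs(fa) ** 2).ravel(),
                     minlength=n_shells + 1)[:n_shells]
    pb = np.bincount(idx.ravel(), weights=(np.abs(fb) ** 2).ravel(),
                     minlength=n_shells + 1)[:n_shells]
    counts = np.bincount(idx.ravel(), minlength=n_shells + 1)[:n_shells]

    denom = np.sqrt(pa * pb)
    corr = np.divide(cross, denom, out=np.zeros_like(cross), where=denom > 0)
    freq_per_unit = 1.0 / (n_ref * vol_a.voxel_size_nm)
    centers = (np.arange(n_shells) + 0.5) * shell_width * freq_per_unit
    centers[0] = 0.0  # DC shell
    return FSCCurve(shell_freq=centers, correlation=corr, shell_counts=counts,
                    nyquist=0.5 / vol_a.voxel_size_nm)


@dataclass(frozen=True)
class ResolutionEstimate:
    resolution_nm: float
    crossing_freq: float  # cycles per nm
    criterion: float
    nyquist_limited: bool


def resolution_at(curve: FSCCurve, criterion: float = 0.143) -> ResolutionEstimate:
    """Resolution at an FSC criterion (conventionally 0.5 or 0.143).

    Returns the reciprocal of the first frequency at which the curve drops
    below the criterion, linearly interpolated between shell centers.  If
    the curve never crosses, the estimate is Nyquist-limited and flagged.
    """
    freq = np.asarray(curve.shell_freq)
    corr = np.asarray(curve.correlation)
    keep = curve.shell_counts > 0
    freq, corr = freq[keep], corr[keep]
    if len(freq) == 0:
        raise ValueError("empty FSC curve")
    below = np.flatnonzero(corr < criterion)
    below = below[below > 0]  # ignore the DC shell
    if len(below) == 0:
        return ResolutionEstimate(resolution_nm=1.0 / curve.nyquist,
                                  crossing_freq=curve.nyquist,
                                  criterion=criterion, nyquist_limited=True)
    i = int(below[0])
    f0, f1 = freq[i - 1], freq[i]
    c0, c1 = corr[i - 1], corr[i]
    f_cross = f0 + (c0 - criterion) * (f1 - f0) / (c0 - c1) if c0 != c1 else f1
    return ResolutionEstimate(resolution_nm=float(1.0 / f_cross),
                              crossing_freq=float(f_cross),
                              criterion=criterion, nyquist_limited=False)


# ---------------------------------------------------------------------------
# bead detection
# ---------------------------------------------------------------------------

def detect_beads(
    vol: Volume,
    diameter_nm: float,
    threshold: float = 0.1,
    refine_window_vox: int | None = None,
) -> np.ndarray:
    """Detect spherical beads; returns (n, 3) centers in nm, (z, y, x) order.

    Band-pass blob detection (Laplacian of Gaussian at scales bracketing
    the bead radius) followed by intensity-centroid refinement in a local
    window.  ``threshold`` is the LoG response floor relative to the volume
    maximum.
    """
    r_vox = diameter_nm / 2.0 / vol.voxel_size_nm
    if r_vox < 1.0:
        raise ValueError("bead diameter must span at least 2 voxels")
    grid = np.asarray(vol.grid, dtype=float)
    vmax = grid.max()
    if vmax <= 0:
        return np.empty((0, 3))
    norm = grid / vmax
    sigma = r_vox / np.sqrt(3.0)
    blobs = blob_log(norm, min_sigma=0.7 * sigma, max_sigma=1.4 * sigma,
                     num_sigma=5, threshold=threshold)
    if len(blobs) == 0:
        return np.empty((0, 3))
    centers = blobs[:, :3]
    win = refine_window_vox if refine_window_vox is not None else max(int(round(r_vox)), 1)
    refined = []
    for c in centers:
        lo = np.maximum(np.round(c).astype(int) - win, 0)
        hi = np.minimum(np.round(c).astype(int) + win + 1, grid.shape)
        sub = norm[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        w = np.clip(sub - sub.min(), 0, None)
        if w.sum() == 0:
            refined.append(c)
            continue
        com = np.array(ndi.center_of_mass(w))
        refined.append(lo + com)
    return np.asarray(refined) * vol.voxel_size_nm


# ---------------------------------------------------------------------------
# pair correlation
# ---------------------------------------------------------------------------

@dataclass
class PCFResult:
    r_bins: np.ndarray  # bin centers, nm
    g: np.ndarray
    env_lo: np.ndarray | None
    env_hi: np.ndarray | None
    n_points: int
    n_sims: int


def pair_correlation(
    points: np.ndarray,
    box: tuple[float, float, float],
    r_max: float,
    n_bins: int = 25,
    edge_correction: str = "translational",
) -> PCFResult:
    """Pair correlation function g(r) of a 3D point pattern in a box.

    ``translational`` weights each pair by V/∏(Lᵢ−|Δᵢ|) (intersection
    volume of the window with its shifted copy); ``periodic`` uses
    minimum-image distances with unit weights.  Normalization uses
    intensity λ² → n(n−1)/V², so g → 1 for CSR.  ``r_max`` must not exceed
    half the shortest box edge (edge-correction validity).
    """
    pts = np.asarray(points, dtype=float)
    box = np.asarray(box, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    if r_max > 0.5 * box.min():
        raise ValueError("r_max exceeds half the shortest box edge")
    if edge_correction not in ("translational", "periodic"):
        raise ValueError(f"unknown edge correction {edge_correction!r}")

    volume = float(np.prod(box))
    delta = pts[:, None, :] - pts[None, :, :]
    iu = np.triu_indices(n, k=1)
    delta = delta[iu]
    if edge_correction == "periodic":
        delta = delta - box * np.round(delta / box)
        weights = np.ones(len(delta))
    else:
        weights = volume / np.prod(box - np.abs(delta), axis=1)
    dist = np.linalg.norm(delta, axis=1)

    edges = np.linspace(0.0, r_max, n_bins + 1)
    which = np.digitize(dist, edges) - 1
    ok = (which >= 0) & (which < n_bins)
    pair_sum = np.bincount(which[ok], weights=weights[ok], minlength=n_bins)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    lam2 = n * (n - 1) / volume**2
    # factor 2: unordered pairs counted once above, estimator sums ordered pairs
    g = 2.0 * pair_sum / (lam2 * volume * shell_vol)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PCFResult(r_bins=centers, g=g, env_lo=None, env_hi=None,
                     n_points=n, n_sims=0)


def csr_envelope(
    n_points: int,
    box: tuple[float, float, float],
    r_max: float,
    n_bins: int = 25,
    n_sims: int = 99,
    seed: int = 0,
    edge_correction: str = "translational",
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise min/max envelope of g(r) over CSR simulations.

    Simulates ``n_sims`` uniform patterns of the same intensity in the same
    box and records the per-bin extremes; a measured g(r) above ``env_hi``
    marks significant clustering at that distance.  At least 19
    realizations are required (5% pointwise level of a one-sided max test).
    """
    if n_sims < 19:
        raise ValueError("need at least 19 CSR realizations for an envelope")
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    gs = np.empty((n_sims, n_bins))
    for s in range(n_sims):
        pts = rng.uniform(0.0, box_arr, size=(n_points, 3))
        gs[s] = pair_correlation(pts, box, r_max, n_bins, edge_correction).g
    return gs.min(axis=0), gs.max(axis=0)


# ---------------------------------------------------------------------------
# pore-size distribution (local thickness)
# ---------------------------------------------------------------------------

def local_thickness(mask: np.ndarray, radius_step_vox: float = 0.5) -> np.ndarray:
    """Local thickness map of a binary structure, in voxels (diameter units).

    Each foreground voxel is assigned the diameter of the largest inscribed
    sphere containing it.  Computed exactly on radii quantized to
    ``radius_step_vox``: for each candidate radius r (descending), the set
    of voxels covered by some sphere of radius r is the binary dilation of
    {EDT ≥ r} by a ball of radius r; voxels first covered at level r get
    thickness 2r.  Quantizing radii downward makes the map monotone under
    dilation of the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    lt = np.zeros(mask.shape, dtype=float)
    if not mask.any():
        return lt
    dt = ndi.distance_transform_edt(mask)
    # quantize down to the step grid
    levels = np.unique(np.floor(dt[mask] / radius_step_vox)) * radius_step_vox
    levels = levels[levels > 0][::-1]
    assigned = np.zeros(mask.shape, dtype=bool)
    for r in levels:
        centers = dt >= r
        # exact Euclidean dilation of the centers by a ball of radius r
        covered = ndi.distance_transform_edt(~centers) <= r
        covered &= mask
        new = covered & ~assigned
        lt[new] = 2.0 * r
        assigned |= new
        if assigned[mask].all():
            break
    # voxels with 0 < dt < first level (thin slivers) get their own diameter
    rest = mask & ~assigned
    lt[rest] = 2.0 * dt[rest]
    return lt


@dataclass
class PoreSizeDistribution:
    diameter_bins_nm: np.ndarray  # bin centers
    volume_fraction: np.ndarray
    total_porosity: float


def pore_size_distribution(
    pore_mask: np.ndarray,
    voxel_size_nm: float,
    bin_width_nm: float | None = None,
) -> PoreSizeDistribution:
    """Pore-volume-weighted histogram of local-thickness diameters.

    Every pore voxel contributes its volume to the bin of its assigned
    inscribed-sphere diameter; fractions sum to 1 when pores exist.
    ``total_porosity`` is the pore-voxel fraction of the whole grid.
    """
    mask = np.asarray(pore_mask, dtype=bool)
    porosity = float(mask.mean())
    if not mask.any():
        return PoreSizeDistribution(diameter_bins_nm=np.empty(0),
                                    volume_fraction=np.empty(0),
                                    total_porosity=0.0)
    lt_nm = local_thickness(mask)[mask] * voxel_size_nm
    width = bin_width_nm if bin_width_nm is not None else voxel_size_nm
    edges = np.arange(0.0, lt_nm.max() + width, width)
    if len(edges) < 2:
        edges = np.array([0.0, lt_nm.max() + width])
    hist, edges = np.histogram(lt_nm, bins=edges)
    frac = hist / hist.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = hist > 0
    return PoreSizeDistribution(diameter_bins_nm=centers[keep],
                                volume_fraction=frac[keep],
                                total_porosity=porosity)


# ---------------------------------------------------------------------------
# volume change
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeChange:
    percent: float         # volumetric change, negative = shrinkage
    linear_percent: float  # equivalent isotropic linear change


def volume_change(mask_a: np.ndarray, mask_b: np.ndarray) -> VolumeChange:
    """Relative volume change between two segmented masks, in percent.

    100·(V_b − V_a)/V_a by voxel count; the linear-equivalent change
    assumes isotropic scaling, 100·((V_b/V_a)^(1/3) − 1).
    """
    va = int(np.count_nonzero(mask_a))
    vb = int(np.count_nonzero(mask_b))
    if va == 0:
        raise ValueError("reference mask is empty")
    ratio = vb / va
    return VolumeChange(percent=100.0 * (ratio - 1.0),
                        linear_percent=100.0 * (ratio ** (1.0 / 3.0) - 1.0))
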