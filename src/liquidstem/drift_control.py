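"""Predictive in situ drift correction and image-quality metrics.

The controller avoids the dose-costly validation image of classical
drift-correction loops.  After frame n the inter-frame shift d_n is
measured and three accumulators are updated:

    c_n = c_{n−1} − d_n          (correction, with memory of past moves)
    a_n = a_{n−1} + c_n          (anticipation of the next move)
    r_n = a_n + c_n              (relative beam shift actually applied)

with c_0 = a_0 = 0.  ``r_n`` is an *incremental* beam shift, accumulated
into the applied correction B_n = B_{n−1} + r_n; frame n+1 is acquired at
position p_{n+1} = D_{n+1} + B_n where D is the true cumulative drift.
Under this reading the full controller cancels a constant-rate drift
exactly from the second frame on, a correction-only loop (r_n = −d_n) lags
and diverges, and correction+memory (r_n = c_n) tracks with a constant lag
— the three behaviours the closed-loop simulations below reproduce.

Shift vectors follow numpy array order (row, col); the controller is
axis-separable, so each component runs the scalar recurrence independently.
All recurrences run in pixels; conversion to physical units is a single
multiplication by the pixel size at the controller boundary.

The module also provides the two focus/astigmatism quality metrics used to
monitor defocus drift along z: the variance of a Laplacian-of-Gaussian
filtered image (sharpness) and the ellipticity of the power-spectrum
half-power contour (astigmatism).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import SIFT, match_descriptors
from skimage.registration import phase_cross_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "DriftControllerState",
    "DriftProcess",
    "ControllerTrace",
    "estimate_shift",
    "controller_update",
    "simulate_closed_loop",
    "trace_summary",
    "focus_metric",
    "astigmatism_metric",
]

CONTROLLER_VARIANTS = ("correction_only", "correction_memory", "full")


# ---------------------------------------------------------------------------
# shift estimation
# ---------------------------------------------------------------------------

def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def estimate_shift(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    method: str = "phase_correlation",
    upsample_factor: int = 50,
) -> np.ndarray:
    """Subpixel shift of ``frame_b`` relative to ``frame_a``, in (row, col).

    Returns s such that translating ``frame_b`` by −s best aligns it with
    ``frame_a`` (i.e. the content of b sits at +s relative to a).

    ``phase_correlation`` (default) Hann-windows both frames and refines to
    subpixel precision by upsampled cross-correlation; it is robust on
    low-dose noisy frames and returns (0, 0) for featureless constant
    images.  ``feature_matching`` detects SIFT keypoints, matches them with
    a cross-checked ratio test, and aggregates per-match displacements by
    the median; it raises on images with too few features.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share the same shape")
    if method == "phase_correlation":
        if a.std() == 0 or b.std() == 0:
            logger.debug("constant frame(s): phase correlation confidence 0")
            return np.zeros(2)
        win = _hann2d(a.shape)
        # demean before windowing: the DC term otherwise swamps the
        # correlation peak on smooth low-contrast frames
        shift, _err, _ = phase_cross_correlation(
            (a - a.mean()) * win, (b - b.mean()) * win,
            upsample_factor=upsample_factor, normalization="phase",
        )
        return -np.asarray(shift, dtype=float)
    if method == "feature_matching":
        if a.std() == 0 or b.std() == 0:
            raise ValueError("featureless frame: feature matching impossible")
        det_a, det_b = SIFT(), SIFT()
        try:
            det_a.detect_and_extract(a)
            det_b.detect_and_extract(b)
        except RuntimeError as exc:  # no keypoints found
            raise ValueError(f"feature detection failed: {exc}") from exc
        matches = match_descriptors(
            det_a.descriptors, det_b.descriptors, cross_check=True, max_ratio=0.8
        )
        if len(matches) < 3:
            raise ValueError(f"only {len(matches)} feature matches; shift unreliable")
        disp = det_b.keypoints[matches[:, 1]] - det_a.keypoints[matches[:, 0]]
        return np.median(disp, axis=0)
    raise ValueError(f"unknown shift-estimation method {method!r}")


# ---------------------------------------------------------------------------
# controller recurrence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftControllerState:
    """Accumulators of the correction–memory–anticipation recurrence."""

    c: np.ndarray = field(default_factory=lambda: np.zeros(2))
    a: np.ndarray = field(default_factory=lambda: np.zeros(2))
    last_d: np.ndarray = field(default_factory=lambda: np.zeros(2))
    n: int = 0


def controller_update(
    state: DriftControllerState,
    d_n: np.ndarray,
    variant: str = "full",
) -> tuple[DriftControllerState, np.ndarray]:
    """One controller step: ingest the measured shift, emit the beam move.

    The accumulators always follow the full recurrence; ``variant`` only
    selects which correction is emitted (``correction_only``: −d_n,
    ``correction_memory``: c_n, ``full``: a_n + c_n).
    """
    if variant not in CONTROLLER_VARIANTS:
        raise ValueError(f"unknown controller variant {variant!r}")
    d = np.asarray(d_n, dtype=float)
    c = state.c - d
    a = state.a + c
    if variant == "correction_only":
        r = -d
    elif variant == "correction_memory":
        r = c
    else:
        r = a + c
    new_state = DriftControllerState(c=c, a=a, last_d=d, n=state.n + 1)
    return new_state, r


# ---------------------------------------------------------------------------
# drift processes and closed-loop simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DriftProcess:
    """Synthetic stage-drift model, in pixels per frame.

    kinds
    -----
    ``linear``        constant slope; params ``{"slope": s}`` (scalar or 2-vector).
    ``segmentwise``   piecewise-linear; params ``{"slopes": [...], "breakpoints": [...]}``
                      where breakpoints are the frame indices at which the
                      next slope takes over.
    ``quadratic``     D_n = coeff·n²; params ``{"coeff": c}``.
    ``constant_zero`` no drift.

    ``noise_halfwidth`` adds i.i.d. uniform noise on [−h, +h] to each
    per-frame drift increment (the regime probed by the noisy simulation
    rows: h = 0.5 px).
    """

    kind: str = "linear"
    params: dict = field(default_factory=lambda: {"slope": 2.0})
    noise_halfwidth: float = 0.0
    seed: int = 0

    def _slope_at(self, n: int) -> np.ndarray:
        if self.kind == "linear":
            return np.broadcast_to(np.asarray(self.params["slope"], float), (2,)).copy()
        if self.kind == "segmentwise":
            slopes = self.params["slopes"]
            breaks = self.params.get("breakpoints", [])
            seg = int(np.searchsorted(np.asarray(breaks), n, side="right"))
            return np.broadcast_to(np.asarray(slopes[min(seg, len(slopes) - 1)], float), (2,)).copy()
        raise ValueError(f"no slope for kind {self.kind!r}")

    def increments(self, n_frames: int) -> np.ndarray:
        """Per-frame drift increments ΔD_n for n = 1..n_frames−1, shape (n_frames, 2).

        Row 0 is zero: the first frame defines the reference position.
        """
        rng = np.random.default_rng(self.seed)
        inc = np.zeros((n_frames, 2))
        for n in range(1, n_frames):
            if self.kind == "constant_zero":
                step = np.zeros(2)
            elif self.kind == "quadratic":
                coeff = float(self.params["coeff"])
                step = np.full(2, coeff * (n**2 - (n - 1) ** 2))
            else:
                step = self._slope_at(n)
            if self.noise_halfwidth > 0:
                step = step + rng.uniform(-self.noise_halfwidth, self.noise_halfwidth, size=2)
            inc[n] = step
        return inc

    def cumulative(self, n_frames: int) -> np.ndarray:
        return np.cumsum(self.increments(n_frames), axis=0)


@dataclass
class ControllerTrace:
    """Per-frame record of a closed-loop drift-correction run.

    Arrays have shape (n_frames, 2) in (row, col) pixels: true cumulative
    drift D, applied cumulative correction B, observed position
    p_n = D_n + B_{n−1}, measured shift d, emitted correction r.
    """

    d_true: np.ndarray
    b_applied: np.ndarray
    positions: np.ndarray
    d_measured: np.ndarray
    r_emitted: np.ndarray
    controller_variant: str

    def __len__(self) -> int:
        return len(self.positions)

    def to_dataframe(self):
        import pandas as pd

        n = len(self)
        cols = {"frame": np.arange(n)}
        for name, arr in (
            ("D", self.d_true), ("B", self.b_applied), ("p", self.positions),
            ("d", self.d_measured), ("r", self.r_emitted),
        ):
            cols[f"{name}_y"] = arr[:, 0]
            cols[f"{name}_x"] = arr[:, 1]
        return pd.DataFrame(cols)


def simulate_closed_loop(
    process: DriftProcess,
    variant: str = "full",
    n_frames: int = 100,
    measurement_noise_halfwidth: float = 0.0,
    measurement_seed: int | None = None,
) -> ControllerTrace:
    """Closed-loop simulation of the drift controller on a synthetic drift.

    Frame n sees position p_n = D_n + B_{n−1}; the measured shift is
    d_n = p_n − p_{n−1} (optionally corrupted by uniform measurement noise),
    the controller emits r_n, and B_n = B_{n−1} + r_n takes effect before
    frame n+1.
    """
    if variant not in CONTROLLER_VARIANTS:
        raise ValueError(f"unknown controller variant {variant!r}")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(
        process.seed + 1 if measurement_seed is None else measurement_seed
    )
    D = process.cumulative(n_frames)
    B = np.zeros((n_frames, 2))
    p = np.zeros((n_frames, 2))
    d = np.zeros((n_frames, 2))
    r = np.zeros((n_frames, 2))
    state = DriftControllerState()
    for n in range(1, n_frames):
        p[n] = D[n] + B[n - 1]
        d[n] = p[n] - p[n - 1]
        if measurement_noise_halfwidth > 0:
            d[n] = d[n] + rng.uniform(
                -measurement_noise_halfwidth, measurement_noise_halfwidth, size=2
            )
        state, r[n] = controller_update(state, d[n], variant=variant)
        B[n] = B[n - 1] + r[n]
    return ControllerTrace(
        d_true=D, b_applied=B, positions=p, d_measured=d, r_emitted=r,
        controller_variant=variant,
    )


def trace_summary(trace: ControllerTrace, zone: float = 1.0) -> dict:
    """Containment statistics of a trace against the ±zone acceptable band.

    A frame is "in zone" when both position components have magnitude
    ≤ ``zone`` (the drift is then invisible at the pixel scale).
    ``settled_after`` is the first frame index from which every later frame
    stays in zone (None if the last frame is outside).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    mag = np.max(np.abs(trace.positions), axis=1)
    in_zone = mag <= zone
    frac = float(np.mean(in_zone))
    max_abs = float(np.max(mag))
    violations = np.flatnonzero(~in_zone)
    settled = 0 if len(violations) == 0 else (
        None if violations[-1] == len(trace) - 1 else int(violations[-1]) + 1
    )
    return {"frac_in_zone": frac, "max_abs_position": max_abs, "settled_after": settled}


# ---------------------------------------------------------------------------
# focus / astigmatism metrics
# ---------------------------------------------------------------------------

def focus_metric(image: np.ndarray, presmooth_sigma: float = 1.0) -> float:
    """Sharpness score: variance of the Laplacian of a Gaussian-filtered image.

    Defocus blurs away high spatial frequencies, which the Laplacian
    emphasizes, so the score decreases monotonically with blur; a constant
    image scores 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("focus metric expects a 2D image")
    if min(img.shape) < 5:
        raise ValueError("image smaller than the filter support")
    smoothed = ndi.gaussian_filter(img, presmooth_sigma)
    lap = ndi.laplace(smoothed)  # 3x3 discrete Laplacian
    return float(np.var(lap))


def astigmatism_metric(image: np.ndarray, smooth_sigma: float = 2.0) -> dict:
    """Ellipticity of the power-spectrum half-power contour.

    Astigmatism blurs the image anisotropically, elongating the FFT power
    spectrum along the less-blurred frequency axis.  The smoothed log power
    spectrum is thresholded halfway between its peak (at DC) and its
    background level; the second moments of the resulting central region
    give the major/minor axis ratio (≥ 1) and the major-axis angle in
    degrees counter-clockwise from the x-frequency axis, in (−90, 90].
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("astigmatism metric expects a 2D image")
    if img.std() == 0:
        raise ValueError("constant image: power spectrum undefined")
    win = _hann2d(img.shape)
    ps = np.abs(np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))) ** 2
    logps = ndi.gaussian_filter(np.log1p(ps), smooth_sigma)
    level = np.median(logps) + 0.5 * (logps.max() - np.median(logps))
    mask = logps >= level
    # keep the connected blob around DC
    labels, _ = ndi.label(mask)
    cy, cx = img.shape[0] // 2, img.shape[1] // 2
    centre_label = labels[cy, cx]
    if centre_label == 0:
        raise ValueError("no half-power region around the spectrum centre")
    ys, xs = np.nonzero(labels == centre_label)
    coords = np.column_stack([ys - cy, xs - cx]).astype(float)
    cov = coords.T @ coords / len(coords)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    minor, major = np.sqrt(np.maximum(evals, 1e-12))
    vec = evecs[:, 1]  # (dy, dx) of the major axis
    angle = np.rad2deg(np.arctan2(vec[0], vec[1]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    return {"ellipticity_ratio": float(major / minor), "major_axis_angle": float(angle)}
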