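"""Eucentric calibration of a tomography stage from displacement-vs-tilt data.

A feature at lateral offset ``y_A`` and height offset ``z_A`` from the tilt
axis sweeps across the image as the specimen tilts.  Its image-plane
displacement perpendicular to the (vertical) tilt axis is

    a(θ) = a0 + R·(1 − sin θ) + y_A·(1 − cos θ) + z_A·sin θ

where ``R`` is the radius of the radial/tilt error motion of the stage and
``a0`` a free baseline absorbing the zero-tilt reference.  With R = a0 = 0
this reduces to the ideal-stage model a(θ) = y_A(1 − cos θ) + z_A sin θ.

The model is linear in the basis {1, 1−cos θ, sin θ}: the fit solves an
ordinary least-squares problem on that basis and maps the coefficients
(a0 + R, y_A, z_A − R) back to physical parameters.  Because the constant
term conflates a0 and R, ``R`` is only identifiable when a0 is pinned to 0
(the default for the error-motion model; a documented limitation).

Calibration protocol: track one feature over a small tilt ramp, fit the
model, then move the stage by (−y_A, −z_A) and restore focus by z_A.  After
the move the feature should stay put over the whole tilt range.

Angles are degrees at every public interface.  Positive tilt follows the
right-hand rule about the image y axis (tilt axis vertical in the image),
and the fitted displacement is the signed image-x component; the measured
y component is carried along for diagnostics but excluded from the fit.
Lengths are unit-agnostic: the fitted parameters come out in whatever unit
the displacements are supplied in (µm in stage practice, nm in the
simulations here).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EucentricModel",
    "DisplacementObservations",
    "EucentricFit",
    "StageMove",
    "TiltPlan",
    "predict_displacement",
    "measure_displacements",
    "fit_eucentric",
    "correction_moves",
    "validate_eucentricity",
    "make_tilt_plan",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EucentricModel:
    """Parameters of the displacement-vs-tilt model (lengths in one common unit)."""

    y_a: float
    z_a: float
    r: float = 0.0
    a0: float = 0.0


@dataclass
class DisplacementObservations:
    """Cumulative image-plane displacements of one tracked feature per tilt angle.

    ``dx_px`` is the component perpendicular to the tilt axis (the fitted
    one); ``dy_px`` the component along it.  ``pixel_size_nm`` converts to
    physical units when known.
    """

    angles_deg: np.ndarray
    dx_px: np.ndarray
    dy_px: np.ndarray
    pixel_size_nm: float | None = None
    dropped_angles: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.dx_px = np.asarray(self.dx_px, dtype=float)
        self.dy_px = np.asarray(self.dy_px, dtype=float)
        if not (len(self.angles_deg) == len(self.dx_px) == len(self.dy_px)):
            raise ValueError("angles and displacements must have equal length")
        if len(self.angles_deg) >= 2 and not np.all(np.diff(self.angles_deg) > 0):
            raise ValueError("angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.angles_deg)

    @property
    def dx_nm(self) -> np.ndarray:
        if self.pixel_size_nm is None:
            raise ValueError("pixel size unknown; cannot convert to nm")
        return self.dx_px * self.pixel_size_nm


@dataclass(frozen=True)
class EucentricFit:
    model: EucentricModel
    residual_rms: float
    covariance: np.ndarray
    n_obs: int
    model_kind: str

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "y_a": self.model.y_a,
            "z_a": self.model.z_a,
            "r": self.model.r,
            "a0": self.model.a0,
            "residual_rms": self.residual_rms,
            "n_obs": self.n_obs,
            "covariance": np.asarray(self.covariance).tolist(),
        }


@dataclass(frozen=True)
class StageMove:
    """Correction move: stage shifts dy, dz and the accompanying focus change."""

    dy: float
    dz: float
    dfocus: float


@dataclass(frozen=True)
class TiltPlan:
    """Angular sampling of a tilt series.

    ``closed`` includes both endpoints (count = (stop−start)/step + 1);
    ``half_open`` excludes ``stop`` (count = (stop−start)/step).
    """

    start: float
    stop: float
    step: float
    convention: str = "closed"
    extra_angles: tuple[float, ...] = ()

    @property
    def angles(self) -> np.ndarray:
        span = self.stop - self.start
        n = int(round(span / self.step))
        if self.convention == "closed":
            base = self.start + self.step * np.arange(n + 1)
        else:
            base = self.start + self.step * np.arange(n)
        return np.sort(np.concatenate([base, np.asarray(self.extra_angles, dtype=float)]))

    def __len__(self) -> int:
        return len(self.angles)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _check_theta(theta_deg: np.ndarray | float) -> np.ndarray:
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(np.abs(theta) >= 90.0):
        raise ValueError("tilt angle must lie strictly inside (-90, 90) degrees")
    return theta


def predict_displacement(model: EucentricModel, theta_deg: float | np.ndarray) -> float | np.ndarray:
    """Predicted image-plane displacement of the feature at tilt ``theta_deg``.

    Evaluates a(θ) = a0 + R(1−sinθ) + y_A(1−cosθ) + z_A sinθ, in the length
    unit of the model parameters.  Vectorized over θ.
    """
    theta = np.deg2rad(_check_theta(theta_deg))
    a = (
        model.a0
        + model.r * (1.0 - np.sin(theta))
        + model.y_a * (1.0 - np.cos(theta))
        + model.z_a * np.sin(theta)
    )
    return float(a) if np.isscalar(theta_deg) else a


def _design_matrix(theta_deg: np.ndarray, model_kind: str) -> np.ndarray:
    theta = np.deg2rad(theta_deg)
    cols = [1.0 - np.cos(theta), np.sin(theta)]
    if model_kind == "error_motion":
        cols.insert(0, np.ones_like(theta))
    return np.column_stack(cols)


def fit_eucentric(
    obs: DisplacementObservations,
    model_kind: str = "simple",
) -> EucentricFit:
    """Least-squares estimate of the eucentric parameters from a tilt ramp.

    ``simple`` fits (y_A, z_A) with R = a0 = 0 and needs ≥ 3 observations;
    ``error_motion`` adds the error-motion radius R (a0 pinned to 0, see
    module docstring) and needs ≥ 4.  Displacements are fitted in physical
    units when the pixel size is known, else in pixels.
    """
    if model_kind not in ("simple", "error_motion"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    n_params = 2 if model_kind == "simple" else 3
    if len(obs) < n_params + 1:
        raise ValueError(f"{model_kind} fit needs at least {n_params + 1} observations")

    a_meas = obs.dx_nm if obs.pixel_size_nm is not None else obs.dx_px
    X = _design_matrix(obs.angles_deg, model_kind)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix: tilt angles do not constrain the model")

    beta, _, _, _ = np.linalg.lstsq(X, a_meas, rcond=None)
    resid = a_meas - X @ beta
    rms = float(np.sqrt(np.mean(resid**2)))
    dof = max(len(obs) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)

    if model_kind == "simple":
        model = EucentricModel(y_a=float(beta[0]), z_a=float(beta[1]))
    else:
        # basis coefficients are (a0 + R, y_A, z_A − R); with a0 := 0,
        # R = beta[0] and z_A = beta[2] + R.
        r = float(beta[0])
        model = EucentricModel(y_a=float(beta[1]), z_a=float(beta[2]) + r, r=r, a0=0.0)
    logger.info(
        "eucentric fit (%s): y_A=%.4g z_A=%.4g R=%.4g rms=%.3g (%d obs)",
        model_kind, model.y_a, model.z_a, model.r, rms, len(obs),
    )
    return EucentricFit(model=model, residual_rms=rms, covariance=cov,
                        n_obs=len(obs), model_kind=model_kind)


def correction_moves(fit: EucentricFit) -> StageMove:
    """Stage move that brings the feature onto the tilt axis.

    Moves the stage by −y_A laterally and −z_A in height; the focus follows
    the height change by +z_A so the feature stays in focus after the move.
    """
    m = fit.model
    return StageMove(dy=-m.y_a, dz=-m.z_a, dfocus=m.z_a)


def validate_eucentricity(obs: DisplacementObservations, tol_px: float) -> dict:
    """Check a post-correction tilt ramp: the feature must stay within ``tol_px``.

    Returns ``{"pass": bool, "max_residual_px": float}`` where the residual
    is the in-plane displacement magnitude.
    """
    if len(obs) == 0:
        raise ValueError("no observations to validate")
    mags = np.hypot(obs.dx_px, obs.dy_px)
    max_resid = float(np.max(mags))
    return {"pass": max_resid <= tol_px, "max_residual_px": max_resid}


def make_tilt_plan(
    start: float,
    stop: float,
    step: float,
    convention: str = "closed",
    extra_angles: list[float] | tuple[float, ...] | None = None,
) -> TiltPlan:
    """Build a tilt plan from start/stop/step (degrees)."""
    if step <= 0:
        raise ValueError("tilt step must be positive")
    if start >= stop:
        raise ValueError("start angle must be below stop angle")
    if convention not in ("closed", "half_open"):
        raise ValueError(f"unknown convention {convention!r}")
    return TiltPlan(start=start, stop=stop, step=step, convention=convention,
                    extra_angles=tuple(extra_angles or ()))


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def measure_displacements(
    frames,
    angles_deg,
    method: str = "phase_correlation",
    pixel_size_nm: float | None = None,
) -> DisplacementObservations:
    """Chain pairwise inter-frame shifts into cumulative feature displacements.

    Consecutive frames are registered with :func:`drift_control.estimate_shift`
    and the shifts accumulated.  The zero-tilt frame is the (0, 0) reference
    (the first frame when no angle equals 0).  Pairs that fail to match are
    dropped with a warning; their angles are listed in ``dropped_angles``.
    """
    from .drift_control import estimate_shift  # local import avoids a cycle

    frames = list(frames)
    angles = np.asarray(angles_deg, dtype=float)
    if len(frames) < 3:
        raise ValueError("need at least 3 frames for a calibration ramp")
    if len(frames) != len(angles):
        raise ValueError("one angle per frame required")

    cum = np.zeros((len(frames), 2))
    ok = np.ones(len(frames), dtype=bool)
    running = np.zeros(2)
    for i in range(1, len(frames)):
        try:
            shift = estimate_shift(frames[i - 1], frames[i], method=method)
        except ValueError as exc:
            warnings.warn(f"shift estimation failed at angle {angles[i]:g} deg: {exc}")
            ok[i] = False
            cum[i] = running  # placeholder; observation dropped below
            continue
        running = running + shift
        cum[i] = running

    dropped = [float(a) for a in angles[~ok]]
    angles, cum = angles[ok], cum[ok]
    # re-reference to the zero-tilt frame when present
    zero = np.flatnonzero(angles == 0.0)
    if len(zero):
        cum = cum - cum[zero[0]]
    # shift vectors are (row, col) = (y, x); the fitted axis is image x
    return DisplacementObservations(
        angles_deg=angles, dx_px=cum[:, 1], dy_px=cum[:, 0],
        pixel_size_nm=pixel_size_nm, dropped_angles=dropped,
    )
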