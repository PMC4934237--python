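"""Minimum-variance estimation (MVE) of the full 19-DOF hand pose.

The glove reads m < 19 joint angles, y = H x + nu, with H a canonical-row
selection matrix and nu zero-mean Gaussian noise of covariance R.  Fusing
the measurement with the synergy prior N(mu_o, P_o) gives the Bayesian
posterior mean and covariance.  Two algebraically equivalent forms exist:

covariance (innovation) form, the default —
    x_hat = mu_o - P_o H^T (H P_o H^T + R)^{-1} (H mu_o - y)
    P_p   = P_o - P_o H^T (H P_o H^T + R)^{-1} H P_o

information form, requiring P_o and R invertible —
    x_hat = (P_o^{-1} + H^T R^{-1} H)^{-1} (H^T R^{-1} y + P_o^{-1} mu_o)
    P_p   = (P_o^{-1} + H^T R^{-1} H)^{-1}

The covariance form is the default because the distal-coupling construction
makes P_o rank-deficient, and because the glove operates with R = 0, where
the information form is undefined.  With R = 0 the estimator interpolates:
H x_hat = y exactly and the measured rows/columns of P_p vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .goniometer import GoniometerCalibration, angle_from_resistance
from .hand_model import N_DOF, SelectionMatrix
from .prior import SynergyPrior

#: Reciprocal-condition-number floor for (H P_o H^T + R); below it the
#: measured subsystem is treated as singular.
RCOND_MIN = 1e-12


class SingularMeasurementError(np.linalg.LinAlgError):
    """(H P_o H^T + R) is numerically singular for the chosen joints.

    With R = 0 this signals a sensor placed on a joint subset whose prior
    covariance block has (numerically) deficient rank, e.g. a zero-variance
    DOF.
    """


@dataclass(frozen=True)
class MeasurementSet:
    """A joint subset (H), measured angles y (degrees), and noise covariance R.

    ``noise_cov=None`` means the noise-free case R = 0.
    """

    sel: SelectionMatrix
    y: np.ndarray = field(repr=False)
    noise_cov: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        m = self.sel.m
        if y.shape != (m,):
            raise ValueError(f"y must have shape ({m},), got {y.shape}")
        R = self.noise_cov
        if R is None:
            R = np.zeros((m, m))
        else:
            R = np.asarray(R, dtype=float)
            if R.shape != (m, m):
                raise ValueError(f"noise_cov must be {m}x{m}, got {R.shape}")
            scale = max(np.abs(R).max(), 1.0)
            if np.abs(R - R.T).max() > 1e-10 * scale:
                raise ValueError("noise_cov must be symmetric")
            if np.linalg.eigvalsh((R + R.T) / 2)[0] < -1e-10 * scale:
                raise ValueError("noise_cov must be positive semidefinite")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "noise_cov", (R + R.T) / 2)


@dataclass(frozen=True)
class PoseEstimate:
    """Posterior mean ``x_hat`` (19, degrees) and covariance ``post_cov``."""

    x_hat: np.ndarray = field(repr=False)
    post_cov: np.ndarray = field(repr=False)

    @property
    def posterior_trace(self) -> float:
        return float(np.trace(self.post_cov))


def _innovation_gram(prior: SynergyPrior, meas: MeasurementSet) -> np.ndarray:
    """S = H P_o H^T + R, symmetrized, with a conditioning gate."""
    idx = meas.sel.indices
    S = prior.cov[np.ix_(idx, idx)] + meas.noise_cov
    S = (S + S.T) / 2
    w = np.linalg.eigvalsh(S)
    if w[-1] <= 0 or w[0] / w[-1] < RCOND_MIN:
        raise SingularMeasurementError(
            "singular measured subsystem H*Po*H^T + R for joints "
            f"{meas.sel.measured_joints}: with R=0 this indicates a sensor on a "
            "(numerically) zero-variance joint subset of the prior"
        )
    return S


def mve_estimate(prior: SynergyPrior, meas: MeasurementSet) -> PoseEstimate:
    """Minimum-variance pose estimate, covariance (innovation) form.

    Valid for singular P_o and for R = 0; only the m x m innovation Gram
    matrix H P_o H^T + R must be well conditioned.  Uses a symmetric linear
    solve, never an explicit inverse.

    Raises
    ------
    SingularMeasurementError
        If the innovation Gram matrix is numerically singular.
    """
    idx = meas.sel.indices
    S = _innovation_gram(prior, meas)
    PHt = prior.cov[:, idx]                      # P_o H^T, 19 x m
    gain = scipy.linalg.solve(S, PHt.T, assume_a="sym")   # S^{-1} H P_o, m x 19
    x_hat = prior.mu + gain.T @ (meas.y - prior.mu[idx])
    post = prior.cov - PHt @ gain
    return PoseEstimate(x_hat=x_hat, post_cov=(post + post.T) / 2)


def mve_estimate_information_form(prior: SynergyPrior, meas: MeasurementSet) -> PoseEstimate:
    """Minimum-variance pose estimate, information form.

    Requires both P_o and R nonsingular; raises otherwise, directing callers
    to :func:`mve_estimate`, which covers the rank-deficient and noise-free
    cases.  Kept primarily as an independent algebraic route for validation.
    """
    for name, M in (("prior covariance P_o", prior.cov), ("noise covariance R", meas.noise_cov)):
        w = np.linalg.eigvalsh((M + M.T) / 2)
        if w[-1] <= 0 or w[0] / w[-1] < RCOND_MIN:
            raise np.linalg.LinAlgError(
                f"{name} is singular; the information form is undefined — "
                "use mve_estimate (covariance form) instead"
            )
    H = meas.sel.matrix
    Po_inv = np.linalg.inv(prior.cov)
    R_inv = np.linalg.inv(meas.noise_cov)
    info = Po_inv + H.T @ R_inv @ H
    post = np.linalg.inv(info)
    x_hat = scipy.linalg.solve(
        info, H.T @ R_inv @ meas.y + Po_inv @ prior.mu, assume_a="sym"
    )
    return PoseEstimate(x_hat=x_hat, post_cov=(post + post.T) / 2)


def average_window(readings) -> float:
    """Arithmetic mean of a window of sensor readings (no outlier rejection)."""
    arr = np.asarray(readings, dtype=float)
    if arr.size == 0:
        raise ValueError("empty reading window")
    return float(arr.mean())


def reconstruct_from_sensors(
    prior: SynergyPrior,
    calibrations: list[GoniometerCalibration],
    dr_windows: list,
    sel: SelectionMatrix,
) -> PoseEstimate:
    """Full pipeline from raw goniometer windows to a 19-DOF pose estimate.

    Each sensor's resistance-difference readings (collected while the pose
    is held) are converted to angles through its two-point calibration and
    averaged into the measurement vector y_bar; the pose is then estimated
    with R = 0, the glove's operating assumption.
    """
    if len(calibrations) != sel.m or len(dr_windows) != sel.m:
        raise ValueError(
            f"need one calibration and one window per measured joint ({sel.m})"
        )
    y_bar = np.array(
        [
            average_window(angle_from_resistance(cal, np.asarray(win, dtype=float)))
            for cal, win in zip(calibrations, dr_windows)
        ]
    )
    return mve_estimate(prior, MeasurementSet(sel=sel, y=y_bar, noise_cov=None))
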