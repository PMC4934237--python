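"""Knitted-piezoresistive-fabric (KPF) goniometer model and calibration.

A double-layer textile goniometer outputs the resistance difference dR
between its two piezoresistive layers, which varies affinely with the
flexion angle theta between the sensor extremities:

    dR = s_theta * theta + dR0

(the ideal identical-layer case dR = k * theta is the special case dR0 = 0).
Inverting for the angle gives theta = alpha1 * dR + alpha2 with
alpha1 = 1 / s_theta and alpha2 = -dR0 / s_theta; the two alphas are found
from sensor outputs in two known angular positions (by default a flat 0
position and a 90-degree bend).

Measurement noise is modelled in the angle domain with a default standard
deviation of 0.8 degrees, the bound observed for these sensors at rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default angle-domain noise level, degrees.
DEFAULT_NOISE_SD = 0.8

#: Default two-point calibration positions, degrees.
CALIBRATION_ANGLES = (0.0, 90.0)


@dataclass(frozen=True)
class GoniometerModel:
    """Forward sensor model: angle (degrees) -> resistance difference.

    ``sensitivity`` is in resistance-difference units per degree (must be
    nonzero), ``offset`` in resistance-difference units, ``noise_sd`` in
    degrees.  Resistance-difference units are arbitrary; only the affine
    relation matters.
    """

    sensitivity: float
    offset: float = 0.0
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self):
        if self.sensitivity == 0:
            raise ValueError("sensitivity must be nonzero")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GoniometerCalibration:
    """Inverse sensor map: angle = alpha1 * dR + alpha2 (degrees)."""

    alpha1: float
    alpha2: float

    def __post_init__(self):
        if not np.isfinite(self.alpha1) or self.alpha1 == 0:
            raise ValueError("alpha1 must be finite and nonzero")


def response(model: GoniometerModel, theta) -> float | np.ndarray:
    """Noise-free resistance difference at flexion angle ``theta`` (degrees)."""
    return model.sensitivity * np.asarray(theta, dtype=float) + model.offset


def calibrate(theta1: float, dr1: float, theta2: float, dr2: float) -> GoniometerCalibration:
    """Two-point calibration from sensor outputs at two known angles.

    Solves the affine relation exactly so that the returned calibration
    round-trips both calibration pairs:
    ``angle_from_resistance(cal, dr_i) == theta_i``.

    Raises
    ------
    ValueError
        If ``dr1 == dr2`` (degenerate: the affine map cannot be inverted).
    """
    if dr1 == dr2:
        raise ValueError(
            "degenerate calibration: identical sensor outputs at both positions"
        )
    alpha1 = (theta2 - theta1) / (dr2 - dr1)
    alpha2 = theta1 - alpha1 * dr1
    return GoniometerCalibration(alpha1=alpha1, alpha2=alpha2)


def calibrate_model(model: GoniometerModel,
                    angles: tuple[float, float] = CALIBRATION_ANGLES) -> GoniometerCalibration:
    """Calibrate from exact responses of ``model`` at two angles (default 0/90)."""
    t1, t2 = angles
    return calibrate(t1, float(response(model, t1)), t2, float(response(model, t2)))


def angle_from_resistance(cal: GoniometerCalibration, dr) -> float | np.ndarray:
    """Angle (degrees) recovered from a resistance difference reading."""
    return cal.alpha1 * np.asarray(dr, dtype=float) + cal.alpha2


def simulate_reading(model: GoniometerModel, theta, seed=None, size=None):
    """Noisy sensor reading(s): response at theta + Normal(0, noise_sd^2) jitter.

    Noise perturbs the angle (the domain in which the sensor noise level is
    specified) before the affine response.  Deterministic given ``seed``;
    ``seed`` may also be an existing :class:`numpy.random.Generator`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta = np.asarray(theta, dtype=float)
    noisy = theta + rng.normal(0.0, model.noise_sd, size=size if size is not None else theta.shape)
    return response(model, noisy)
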