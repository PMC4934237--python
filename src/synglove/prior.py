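"""Synergy prior: Gaussian summary (mu_o, P_o) of an ensemble of grasp poses.

Postural synergies — inter-joint covariation patterns of the grasping hand —
are encoded statistically: a large set of observed poses X (19 x N, one pose
per column, degrees) is summarized by its mean vector mu_o and sample
covariance P_o = (X - x_bar)(X - x_bar)^T / (N - 1).  P_o is the Bayesian
a-priori information fused with sparse glove measurements downstream.

Because DIP joints are slaved to PIP joints (2/3 coupling) in the pose
construction, P_o is typically rank-deficient (rank <= 15).  That is legal
here and handled by the covariance-form estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .hand_model import N_DOF


@dataclass(frozen=True)
class SynergyPrior:
    """Mean ``mu`` (19, degrees) and covariance ``cov`` (19x19, degrees^2)."""

    mu: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    n_samples: int | None = None

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mu.shape != (N_DOF,):
            raise ValueError(f"mu must have shape ({N_DOF},), got {mu.shape}")
        if cov.shape != (N_DOF, N_DOF):
            raise ValueError(f"cov must be {N_DOF}x{N_DOF}, got {cov.shape}")
        scale = np.abs(cov).max()
        if scale > 0 and np.abs(cov - cov.T).max() > 1e-10 * scale:
            raise ValueError("cov must be symmetric")
        w = np.linalg.eigvalsh((cov + cov.T) / 2)
        if w.size and w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError("cov must be positive semidefinite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "cov", (cov + cov.T) / 2)

    def to_json(self) -> str:
        return json.dumps(
            {"mu": self.mu.tolist(), "cov": self.cov.tolist(), "n_samples": self.n_samples}
        )

    @classmethod
    def from_json(cls, text: str) -> "SynergyPrior":
        d = json.loads(text)
        return cls(mu=np.array(d["mu"]), cov=np.array(d["cov"]), n_samples=d.get("n_samples"))


def estimate_prior(X) -> SynergyPrior:
    """Estimate the synergy prior from a 19 x N pose matrix (degrees).

    ``mu`` is the per-joint mean over the N poses and ``cov`` the sample
    covariance with denominator N - 1, symmetrized against round-off.

    Raises
    ------
    ValueError
        If N < 2 (sample covariance undefined) or entries are non-finite.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != N_DOF:
        raise ValueError(f"X must be {N_DOF} x N, got shape {X.shape}")
    N = X.shape[1]
    if N < 2:
        raise ValueError("need at least 2 poses to estimate a covariance")
    if not np.all(np.isfinite(X)):
        raise ValueError("pose matrix contains non-finite entries")
    mu = X.mean(axis=1)
    Xc = X - mu[:, None]
    cov = (Xc @ Xc.T) / (N - 1)
    return SynergyPrior(mu=mu, cov=(cov + cov.T) / 2, n_samples=N)
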