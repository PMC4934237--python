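"""Synergy-structured synthetic grasp data.

No public repository of the original motion-capture grasp ensemble exists,
so this module generates stand-in data with the statistical structure the
reconstruction method relies on: hand poses whose 15 free DOFs concentrate
along a few synergy directions (low-rank covariance) plus a small isotropic
residual, lifted to 19 DOFs through the distal coupling *before* any
estimation — so the resulting prior covariance is rank-deficient exactly as
the real construction implies.

Two generators are provided:

* :func:`sample_prior_set` — a large ensemble of grasp postures emulating
  the a-priori set from which the synergy prior is estimated;
* :func:`sample_grasp_panel` — labeled multi-subject repetitions of a small
  set of grasp types (default 8 types, 5 subjects, 3 repetitions, i.e. 120
  trials) for the unsupervised recognition experiment, with a per-subject
  additive offset modelling inter-individual hand differences.

All sampling is driven by one explicit RNG stream per call; there is no
hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hand_model import FREE_JOINT_ORDER, N_DOF, N_FREE, coupling_matrix
from .prior import SynergyPrior

#: Default synergy-weight standard deviations (degrees), geometrically
#: decaying: most postural variance lives in a handful of directions.
DEFAULT_SYNERGY_SD = (20.0, 12.0, 7.0, 4.0, 2.0)

#: Default isotropic residual standard deviation (degrees).
DEFAULT_RESIDUAL_SD = 1.0

#: Default size of a generated a-priori grasp set.
DEFAULT_PRIOR_SET_SIZE = 2000

#: Within-grasp-type variability for panel generators (degrees).
PANEL_SYNERGY_SD = (2.0, 1.5, 1.0, 0.7, 0.5)
PANEL_RESIDUAL_SD = 0.5

#: Default per-subject offset standard deviation (degrees).
DEFAULT_SUBJECT_JITTER_SD = 1.5


def default_mean_pose15() -> np.ndarray:
    """A mildly flexed rest-like grasp mean over the 15 free DOFs (degrees)."""
    mean_by_code = {"TA": 25.0, "TR": 20.0, "TM": 30.0}
    for f in "IMRL":
        mean_by_code[f + "A"] = 5.0    # abduction
        mean_by_code[f + "M"] = 40.0   # MCP flexion
        mean_by_code[f + "P"] = 30.0   # PIP flexion
    return np.array([mean_by_code[c] for c in FREE_JOINT_ORDER])


@dataclass(frozen=True)
class SynergyGenerator:
    """Gaussian pose generator over the 15 free DOFs.

    A pose is drawn as ``x15 = mu + basis @ w + eps`` with
    ``w ~ N(0, diag(synergy_sd^2))`` and ``eps ~ N(0, residual_sd^2 I)``,
    then lifted to 19 DOFs by the distal coupling.  ``basis`` columns are
    unit-norm synergy directions; k = 0 columns is legal (pure residual).
    """

    mu: np.ndarray = field(repr=False)
    basis: np.ndarray = field(repr=False)
    synergy_sd: np.ndarray = field(repr=False)
    residual_sd: float = DEFAULT_RESIDUAL_SD
    seed: int = 0

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        B = np.asarray(self.basis, dtype=float)
        sd = np.atleast_1d(np.asarray(self.synergy_sd, dtype=float))
        if mu.shape != (N_FREE,):
            raise ValueError(f"mu must have shape ({N_FREE},), got {mu.shape}")
        if B.ndim != 2 or B.shape[0] != N_FREE:
            raise ValueError(f"basis must be {N_FREE} x k, got {B.shape}")
        if sd.shape != (B.shape[1],):
            raise ValueError("synergy_sd length must match basis column count")
        if np.any(sd < 0) or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if B.shape[1]:
            norms = np.linalg.norm(B, axis=0)
            if np.any(np.abs(norms - 1.0) > 1e-8):
                raise ValueError("basis columns must have unit Euclidean norm")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "basis", B)
        object.__setattr__(self, "synergy_sd", sd)

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    def free_covariance(self) -> np.ndarray:
        """Analytic 15x15 covariance B diag(sd^2) B^T + residual_sd^2 I."""
        B, sd = self.basis, self.synergy_sd
        return B @ np.diag(sd**2) @ B.T + self.residual_sd**2 * np.eye(N_FREE)

    def analytic_prior(self) -> SynergyPrior:
        """Exact generating-model prior lifted through the distal coupling."""
        C = coupling_matrix()
        cov = C @ self.free_covariance() @ C.T
        return SynergyPrior(mu=C @ self.mu, cov=(cov + cov.T) / 2)

    def within_spread(self, subject_jitter_sd: float = 0.0) -> float:
        """RMS norm of a pose's deviation from the generator mean (degrees).

        sqrt of the trace of the free-DOF covariance, optionally including a
        per-subject isotropic jitter term — the scale against which grasp-type
        mean separation is expressed.
        """
        tr = float(np.sum(self.synergy_sd**2)) + N_FREE * (
            self.residual_sd**2 + subject_jitter_sd**2
        )
        return float(np.sqrt(tr))


def _orthonormal_basis(rng: np.random.Generator, k: int) -> np.ndarray:
    Q, _ = np.linalg.qr(rng.standard_normal((N_FREE, k)))
    return Q[:, :k]


def default_generator(seed: int = 0,
                      synergy_sd=DEFAULT_SYNERGY_SD,
                      residual_sd: float = DEFAULT_RESIDUAL_SD) -> SynergyGenerator:
    """A 5-synergy generator with a random orthonormal basis and default scales."""
    rng = np.random.default_rng(seed)
    sd = np.asarray(synergy_sd, dtype=float)
    return SynergyGenerator(
        mu=default_mean_pose15(),
        basis=_orthonormal_basis(rng, len(sd)),
        synergy_sd=sd,
        residual_sd=residual_sd,
        seed=seed,
    )


def _sample_free(rng: np.random.Generator, gen: SynergyGenerator, n: int) -> np.ndarray:
    """n columns of 15-DOF poses from the generator's Gaussian model."""
    w = rng.standard_normal((gen.k, n)) * gen.synergy_sd[:, None]
    eps = rng.standard_normal((N_FREE, n)) * gen.residual_sd
    return gen.mu[:, None] + gen.basis @ w + eps


def sample_prior_set(gen: SynergyGenerator, N: int = DEFAULT_PRIOR_SET_SIZE,
                     seed: int | None = None) -> np.ndarray:
    """Draw an a-priori grasp ensemble as a 19 x N pose matrix (degrees).

    Poses are coupling-consistent by construction (distal = 2/3 proximal
    exactly).  Deterministic given the seed (``gen.seed`` unless overridden).
    """
    if N < 2:
        raise ValueError("N must be >= 2 (covariance undefined otherwise)")
    rng = np.random.default_rng(gen.seed if seed is None else seed)
    return coupling_matrix() @ _sample_free(rng, gen, N)


@dataclass(frozen=True)
class GraspPanel:
    """Labeled multi-subject grasp repetitions.

    ``poses`` is n_trials x 19 (degrees); the three parallel integer arrays
    give each trial's subject (1-based), grasp label (1..n_labels) and
    repetition (1-based).
    """

    poses: np.ndarray = field(repr=False)
    subject_id: np.ndarray = field(repr=False)
    grasp_label: np.ndarray = field(repr=False)
    repetition: np.ndarray = field(repr=False)

    def __post_init__(self):
        poses = np.asarray(self.poses, dtype=float)
        subj = np.asarray(self.subject_id, dtype=int)
        lab = np.asarray(self.grasp_label, dtype=int)
        rep = np.asarray(self.repetition, dtype=int)
        n = poses.shape[0]
        if poses.ndim != 2 or poses.shape[1] != N_DOF:
            raise ValueError(f"poses must be n x {N_DOF}, got {poses.shape}")
        if not (subj.shape == lab.shape == rep.shape == (n,)):
            raise ValueError("subject_id, grasp_label, repetition must match pose count")
        triples = set(zip(subj.tolist(), lab.tolist(), rep.tolist()))
        if len(triples) != n:
            raise ValueError("(subject, label, repetition) triples must be distinct")
        object.__setattr__(self, "poses", poses)
        object.__setattr__(self, "subject_id", subj)
        object.__setattr__(self, "grasp_label", lab)
        object.__setattr__(self, "repetition", rep)

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_id)

    @property
    def labels(self) -> np.ndarray:
        return np.unique(self.grasp_label)

    def is_balanced(self) -> bool:
        """True iff every (subject, label) pair has the same repetition count."""
        counts = {
            (s, g): int(np.sum((self.subject_id == s) & (self.grasp_label == g)))
            for s in self.subjects
            for g in self.labels
        }
        return len(set(counts.values())) == 1


def make_grasp_generators(
    seed: int = 0,
    n_labels: int = 8,
    separation: float = 10.0,
    within_synergy_sd=PANEL_SYNERGY_SD,
    within_residual_sd: float = PANEL_RESIDUAL_SD,
    subject_jitter_sd: float = DEFAULT_SUBJECT_JITTER_SD,
    base: SynergyGenerator | None = None,
) -> list[SynergyGenerator]:
    """One generator per grasp type, means drawn from a shared synergy model.

    Label means are sampled from ``base`` (default: the package default
    generator) and then rescaled about the base mean so that the minimum
    pairwise distance between label means equals ``separation`` times the
    total within-label spread (within-grasp variability plus subject
    jitter).  ``separation >= ~10`` gives cleanly separable grasp types;
    ``~3`` gives realistic overlap between similar grasps.
    """
    if n_labels < 1:
        raise ValueError("n_labels must be >= 1")
    base = base if base is not None else default_generator(seed)
    rng = np.random.default_rng(seed)
    means = _sample_free(rng, base, n_labels).T       # n_labels x 15
    template = SynergyGenerator(
        mu=base.mu,
        basis=base.basis[:, : len(np.atleast_1d(within_synergy_sd))],
        synergy_sd=np.asarray(within_synergy_sd, dtype=float),
        residual_sd=within_residual_sd,
        seed=seed,
    )
    if separation is not None and n_labels > 1:
        d_min = min(
            np.linalg.norm(means[i] - means[j])
            for i in range(n_labels)
            for j in range(i + 1, n_labels)
        )
        if d_min == 0:
            raise ValueError("degenerate draw: coincident label means")
        target = separation * template.within_spread(subject_jitter_sd)
        means = base.mu + (means - base.mu) * (target / d_min)
    return [replace(template, mu=means[g]) for g in range(n_labels)]


def sample_grasp_panel(
    gen_per_label: list[SynergyGenerator],
    n_subjects: int = 5,
    n_reps: int = 3,
    subject_jitter_sd: float = DEFAULT_SUBJECT_JITTER_SD,
    seed: int = 0,
) -> GraspPanel:
    """Balanced multi-subject panel: n_subjects x n_labels x n_reps poses.

    Each subject carries one additive offset per experiment, drawn once as
    N(0, subject_jitter_sd^2 I) over the free DOFs and applied to every
    grasp-type mean — a crude model of individual hand geometry and sensor
    placement differences.  Deterministic given ``seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (one to seed, one to cluster)")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    C = coupling_matrix()
    poses, subj, lab, rep = [], [], [], []
    for s in range(1, n_subjects + 1):
        offset = rng.standard_normal(N_FREE) * subject_jitter_sd
        for g, gen in enumerate(gen_per_label, start=1):
            shifted = replace(gen, mu=gen.mu + offset)
            x15 = _sample_free(rng, shifted, n_reps)
            x19 = (C @ x15).T
            for r in range(1, n_reps + 1):
                poses.append(x19[r - 1])
                subj.append(s)
                lab.append(g)
                rep.append(r)
    return GraspPanel(
        poses=np.array(poses),
        subject_id=np.array(subj),
        grasp_label=np.array(lab),
        repetition=np.array(rep),
    )
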