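"""19-DOF kinematic hand model: joint naming, distal coupling, selection matrices.

The hand state is a vector of 19 joint angles in degrees.  The thumb
contributes three DOFs (abduction TA, rotation TR, metacarpal flexion TM);
each finger F in {I (index), M (middle), R (ring), L (little)} contributes
four (abduction FA, metacarpal-phalangeal flexion FM, proximal
interphalangeal flexion FP, distal interphalangeal flexion FD).  Distal
flexions are not independent: they follow the proximal joints through the
kinematic convention theta_D = (2/3) * theta_P, leaving 15 free DOFs.

A measurement device that reads individual joint angles is described by a
selection matrix H whose rows are canonical basis vectors, so that y = H x
extracts the measured joints directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical joint ordering: thumb block, then per finger the
#: (abduction, MCP flexion, PIP flexion, DIP flexion) block.
JOINT_ORDER: tuple[str, ...] = (
    "TA", "TR", "TM",
    "IA", "IM", "IP", "ID",
    "MA", "MM", "MP", "MD",
    "RA", "RM", "RP", "RD",
    "LA", "LM", "LP", "LD",
)

JOINT_INDEX: dict[str, int] = {code: i for i, code in enumerate(JOINT_ORDER)}

#: Distal joint -> proximal partner driving it through the 2/3 coupling.
DISTAL_TO_PROXIMAL: dict[str, str] = {"ID": "IP", "MD": "MP", "RD": "RP", "LD": "LP"}

#: The 15 independent (non-distal) joints, in canonical order.
FREE_JOINT_ORDER: tuple[str, ...] = tuple(
    c for c in JOINT_ORDER if c not in DISTAL_TO_PROXIMAL
)

N_DOF: int = len(JOINT_ORDER)          # 19
N_FREE: int = len(FREE_JOINT_ORDER)    # 15

#: DIP flexion tracks PIP flexion at this fixed ratio.
DISTAL_COUPLING_RATIO: float = 2.0 / 3.0

#: The five-joint set used by the optimally designed glove (reference answer
#: for the original a-priori grasp covariance; a different prior may yield a
#: different optimum).
GLOVE_JOINTS: tuple[str, ...] = ("TA", "MM", "RP", "LA", "LM")


class UnknownJointError(ValueError):
    """A joint code outside the canonical 19-joint set."""


def validate_joints(joints) -> tuple[str, ...]:
    """Validate a list of joint codes: all known, all distinct, nonempty."""
    joints = tuple(joints)
    if not joints:
        raise ValueError("joint list must be nonempty")
    for code in joints:
        if code not in JOINT_INDEX:
            raise UnknownJointError(f"unknown joint code {code!r}")
    if len(set(joints)) != len(joints):
        dupes = sorted({c for c in joints if list(joints).count(c) > 1})
        raise ValueError(f"duplicate joint codes: {dupes}")
    return joints


def joint_indices(joints) -> np.ndarray:
    """Canonical column indices of the given joint codes."""
    return np.array([JOINT_INDEX[c] for c in validate_joints(joints)], dtype=int)


def as_pose(angles) -> np.ndarray:
    """Coerce to a finite 19-vector of joint angles (degrees)."""
    x = np.asarray(angles, dtype=float)
    if x.shape != (N_DOF,):
        raise ValueError(f"pose must have shape ({N_DOF},), got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("pose angles must be finite")
    return x


def coupling_matrix() -> np.ndarray:
    """The 19x15 linear map lifting the free DOFs to the full pose.

    Row for a free joint copies it; row for a distal joint is 2/3 times the
    row of its proximal partner.
    """
    C = np.zeros((N_DOF, N_FREE))
    free_index = {code: j for j, code in enumerate(FREE_JOINT_ORDER)}
    for i, code in enumerate(JOINT_ORDER):
        if code in DISTAL_TO_PROXIMAL:
            C[i, free_index[DISTAL_TO_PROXIMAL[code]]] = DISTAL_COUPLING_RATIO
        else:
            C[i, free_index[code]] = 1.0
    return C


def couple_distal(pose_15) -> np.ndarray:
    """Complete a 15-DOF pose to 19 DOFs via the distal coupling.

    Parameters
    ----------
    pose_15
        Angles (degrees) of the free joints, ordered by ``FREE_JOINT_ORDER``.

    Returns
    -------
    numpy.ndarray
        19-vector in canonical order; each DIP angle equals 2/3 of the
        corresponding PIP angle.
    """
    x15 = np.asarray(pose_15, dtype=float)
    if x15.shape != (N_FREE,):
        raise ValueError(f"expected {N_FREE} free joint angles, got shape {x15.shape}")
    return coupling_matrix() @ x15


def drop_distal(pose) -> np.ndarray:
    """Project a 19-DOF pose down to its 15 free DOFs."""
    x = as_pose(pose)
    return x[[JOINT_INDEX[c] for c in FREE_JOINT_ORDER]]


def is_coupling_consistent(pose, atol: float = 1e-9) -> bool:
    """True iff every DIP angle equals 2/3 of its PIP angle within ``atol``.

    Raw minimum-variance estimates need not satisfy this exactly; it is a
    predicate, not an enforced constraint.
    """
    x = as_pose(pose)
    for d, p in DISTAL_TO_PROXIMAL.items():
        if abs(x[JOINT_INDEX[d]] - DISTAL_COUPLING_RATIO * x[JOINT_INDEX[p]]) > atol:
            return False
    return True


@dataclass(frozen=True)
class SelectionMatrix:
    """Measurement matrix H whose rows are canonical basis vectors.

    ``matrix @ pose`` extracts the measured joints, in order.  Distinct
    joints guarantee full row rank by construction.
    """

    measured_joints: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    @property
    def m(self) -> int:
        return len(self.measured_joints)

    @property
    def indices(self) -> np.ndarray:
        return np.array([JOINT_INDEX[c] for c in self.measured_joints], dtype=int)


def build_selection_matrix(joints) -> SelectionMatrix:
    """Build the m x 19 binary selection matrix for the named joints.

    Raises
    ------
    ValueError
        On duplicate or unknown joint codes, or an empty list.
    """
    joints = validate_joints(joints)
    H = np.zeros((len(joints), N_DOF))
    for row, code in enumerate(joints):
        H[row, JOINT_INDEX[code]] = 1.0
    return SelectionMatrix(measured_joints=joints, matrix=H)


def extract_measurements(pose, sel: SelectionMatrix) -> np.ndarray:
    """Noise-free measurement y = H x: the pose entries at the measured joints."""
    return as_pose(pose)[sel.indices]
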