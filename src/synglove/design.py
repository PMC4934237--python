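"""Optimal sensor placement: which m joints should the glove measure?

The posterior covariance P_p quantifies the pose uncertainty that remains
after reading a joint subset, so its squared Frobenius norm ||P_p||_F^2 is a
scalar information cost.  The design problem is to choose the m canonical
measurement rows minimizing that cost.  With C(19, 5) = 11,628 subsets the
exact exhaustive search is cheap and is the reference method; a greedy
forward selection is provided as a scalable approximation (it is exact for
diagonal priors but in general only an upper bound on the optimum).

Subsets whose innovation Gram matrix H P_o H^T + R is numerically singular
(e.g. a sensor on a zero-variance joint with R = 0) are infeasible and score
+inf, so they can never be selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .hand_model import JOINT_ORDER, build_selection_matrix, validate_joints
from .prior import SynergyPrior
from .reconstruction import MeasurementSet, SingularMeasurementError, mve_estimate

#: Ceiling on the number of subsets the exhaustive search will enumerate.
DEFAULT_ENUMERATION_BUDGET = 200_000


@dataclass(frozen=True)
class DesignResult:
    """Selected joints, their posterior cost, and how the search ran."""

    joints: tuple[str, ...]
    cost: float
    method: str              # "exhaustive" or "greedy"
    evaluated: int           # subsets scored


def _restrict_noise(noise_cov, joints):
    """Noise covariance for a joint subset.

    Accepts None (R = 0), a scalar sigma^2 (isotropic), a k x k matrix for
    the k chosen joints, or a full 19 x 19 per-joint matrix in canonical
    order, restricted to the subset.
    """
    if noise_cov is None:
        return None
    R = np.asarray(noise_cov, dtype=float)
    k = len(joints)
    if R.ndim == 0:
        return float(R) * np.eye(k)
    if R.shape == (len(JOINT_ORDER), len(JOINT_ORDER)) and k != len(JOINT_ORDER):
        idx = [JOINT_ORDER.index(c) for c in joints]
        return R[np.ix_(idx, idx)]
    if R.shape == (k, k):
        return R
    raise ValueError(f"cannot restrict noise covariance of shape {R.shape} to {k} joints")


def design_cost(prior: SynergyPrior, joints, noise_cov=None) -> float:
    """||P_p||_F^2 (degrees^4) after measuring ``joints`` with noise ``R``.

    An empty joint list is allowed and returns the prior cost ||P_o||_F^2
    (no measurement taken).  ``noise_cov`` may be None (R = 0), a scalar
    variance, an m x m matrix, or a full 19 x 19 per-joint matrix.
    """
    joints = tuple(joints)
    if len(joints) == 0:
        return float(np.sum(prior.cov**2))
    sel = build_selection_matrix(joints)
    meas = MeasurementSet(sel=sel, y=np.zeros(sel.m),
                          noise_cov=_restrict_noise(noise_cov, joints))
    est = mve_estimate(prior, meas)
    return float(np.sum(est.post_cov**2))


def _subset_cost_or_inf(prior, joints, noise_cov) -> float:
    try:
        return design_cost(prior, joints, noise_cov)
    except SingularMeasurementError:
        return np.inf


def select_exhaustive(
    prior: SynergyPrior,
    m: int,
    noise_cov=None,
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> DesignResult:
    """Score every m-subset of the 19 joints and return the minimizer.

    Ties are broken lexicographically by canonical joint order (the
    enumeration is lexicographic and only a strictly better cost replaces
    the incumbent).

    Raises
    ------
    ValueError
        If C(19, m) exceeds the enumeration budget; use
        :func:`select_greedy` instead.
    """
    if not 1 <= m <= len(JOINT_ORDER):
        raise ValueError(f"m must be in 1..{len(JOINT_ORDER)}")
    from math import comb

    n_subsets = comb(len(JOINT_ORDER), m)
    if n_subsets > budget:
        raise ValueError(
            f"C({len(JOINT_ORDER)}, {m}) = {n_subsets} exceeds the enumeration "
            f"budget {budget}; use select_greedy"
        )
    best_joints, best_cost = None, np.inf
    for subset in combinations(JOINT_ORDER, m):
        cost = _subset_cost_or_inf(prior, subset, noise_cov)
        if cost < best_cost:
            best_joints, best_cost = subset, cost
    if best_joints is None:
        raise SingularMeasurementError(f"every {m}-subset is infeasible for this prior")
    return DesignResult(joints=best_joints, cost=best_cost, method="exhaustive",
                        evaluated=n_subsets)


def select_greedy(prior: SynergyPrior, m: int, noise_cov=None) -> DesignResult:
    """Greedy forward selection: add the joint with the largest cost decrease.

    Evaluates O(19 m) subsets; optimal for diagonal priors, in general an
    upper bound on the exhaustive optimum.  Ties break toward the earlier
    joint in canonical order.
    """
    if not 1 <= m <= len(JOINT_ORDER):
        raise ValueError(f"m must be in 1..{len(JOINT_ORDER)}")
    chosen: list[str] = []
    evaluated = 0
    for _ in range(m):
        best_joint, best_cost = None, np.inf
        for code in JOINT_ORDER:
            if code in chosen:
                continue
            candidate = chosen + [code]
            # keep canonical ordering inside the subset for determinism
            candidate.sort(key=JOINT_ORDER.index)
            cost = _subset_cost_or_inf(prior, candidate, noise_cov)
            evaluated += 1
            if cost < best_cost:
                best_joint, best_cost = code, cost
        if best_joint is None:
            raise SingularMeasurementError("no feasible joint to add")
        chosen.append(best_joint)
        chosen.sort(key=JOINT_ORDER.index)
    return DesignResult(joints=tuple(chosen), cost=best_cost, method="greedy",
                        evaluated=evaluated)
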