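"""Minimum-variance pose estimation: both algebraic forms and the sensor path."""

import numpy as np
import pytest

from synglove import (
    GoniometerModel,
    MeasurementSet,
    SingularMeasurementError,
    build_selection_matrix,
    calibrate_model,
    default_generator,
    estimate_prior,
    mve_estimate,
    mve_estimate_information_form,
    reconstruct_from_sensors,
    response,
    sample_prior_set,
)
from synglove.hand_model import JOINT_ORDER
from synglove.prior import SynergyPrior
from tests.conftest import random_joint_subset, random_spd, random_spd_prior


def _random_instance(rng, m, noisy=True):
    prior = random_spd_prior(rng)
    joints = random_joint_subset(rng, m)
    sel = build_selection_matrix(joints)
    y = rng.uniform(-30, 60, m)
    R = random_spd(rng, m, scale=0.5) if noisy else None
    return prior, MeasurementSet(sel=sel, y=y, noise_cov=R)


def test_zero_innovation_returns_prior_mean(rng):
    prior = random_spd_prior(rng)
    sel = build_selection_matrix(["TA", "MM", "RP", "LA", "LM"])
    meas = MeasurementSet(sel=sel, y=prior.mu[sel.indices])
    est = mve_estimate(prior, meas)
    np.testing.assert_allclose(est.x_hat, prior.mu, atol=1e-10)
    # posterior still shrinks: measured block of P_p vanishes
    assert np.abs(est.post_cov[np.ix_(sel.indices, sel.indices)]).max() < 1e-8


def test_fully_measured_pose_is_returned_exactly(rng):
    prior = random_spd_prior(rng)
    sel = build_selection_matrix(JOINT_ORDER)
    y = rng.uniform(-30, 60, 19)
    est = mve_estimate(prior, MeasurementSet(sel=sel, y=y))
    np.testing.assert_allclose(est.x_hat, y, atol=1e-8)
    assert np.abs(est.post_cov).max() < 1e-7


def test_covariance_and_information_forms_agree(rng):
    """The innovation form and the information form are algebraically identical."""
    for _ in range(50):
        m = int(rng.integers(1, 9))
        prior, meas = _random_instance(rng, m, noisy=True)
        a = mve_estimate(prior, meas)
        b = mve_estimate_information_form(prior, meas)
        np.testing.assert_allclose(a.x_hat, b.x_hat, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(a.post_cov, b.post_cov, rtol=1e-8, atol=1e-10)


def test_information_form_rejects_singular_inputs(rng):
    # coupling-induced singular prior: covariance form works, information form raises
    X = sample_prior_set(default_generator(1), 500, seed=2)
    prior = estimate_prior(X)
    sel = build_selection_matrix(["TA", "MM", "RP", "LA", "LM"])
    meas = MeasurementSet(sel=sel, y=prior.mu[sel.indices], noise_cov=np.eye(5))
    mve_estimate(prior, meas)  # succeeds
    with pytest.raises(np.linalg.LinAlgError):
        mve_estimate_information_form(prior, meas)
    # R = 0 also only works in covariance form
    spd_prior = random_spd_prior(rng)
    meas0 = MeasurementSet(sel=sel, y=np.zeros(5), noise_cov=None)
    mve_estimate(spd_prior, meas0)
    with pytest.raises(np.linalg.LinAlgError):
        mve_estimate_information_form(spd_prior, meas0)


def test_noise_free_measurements_are_interpolated(rng):
    for _ in range(25):
        m = int(rng.integers(1, 9))
        prior, meas = _random_instance(rng, m, noisy=False)
        est = mve_estimate(prior, meas)
        idx = meas.sel.indices
        assert np.abs(est.x_hat[idx] - meas.y).max() < 1e-8
        assert np.abs(est.post_cov[idx, :]).max() < 1e-7
        assert np.abs(est.post_cov[:, idx]).max() < 1e-7


def test_posterior_never_exceeds_prior_loewner(rng):
    for noisy in (False, True):
        for _ in range(10):
            prior, meas = _random_instance(rng, int(rng.integers(1, 9)), noisy=noisy)
            est = mve_estimate(prior, meas)
            gap = np.linalg.eigvalsh(prior.cov - est.post_cov)
            assert gap.min() > -1e-8 * max(1.0, gap.max())
            assert est.posterior_trace <= np.trace(prior.cov) + 1e-8


def test_adding_a_joint_never_increases_cost(rng):
    for _ in range(10):
        prior = random_spd_prior(rng)
        joints = list(random_joint_subset(rng, 4))
        sub = joints[:3]
        est_sub = mve_estimate(prior, MeasurementSet(
            sel=build_selection_matrix(sub), y=np.zeros(3)))
        est_full = mve_estimate(prior, MeasurementSet(
            sel=build_selection_matrix(joints), y=np.zeros(4)))
        assert (np.sum(est_full.post_cov**2)
                <= np.sum(est_sub.post_cov**2) + 1e-8)


def test_singular_subsystem_raises_with_joint_names():
    cov = np.eye(19)
    cov[0, 0] = 0.0  # zero-variance TA
    prior = SynergyPrior(mu=np.zeros(19), cov=cov)
    sel = build_selection_matrix(["TA"])
    with pytest.raises(SingularMeasurementError, match="TA"):
        mve_estimate(prior, MeasurementSet(sel=sel, y=np.zeros(1)))


def test_reconstruct_from_sensors_matches_direct_estimate(rng):
    prior = random_spd_prior(rng)
    sel = build_selection_matrix(["TA", "MM", "RP", "LA", "LM"])
    angles = rng.uniform(0, 80, 5)
    models = [GoniometerModel(sensitivity=2.0 + j, offset=3.0 * j, noise_sd=0.0)
              for j in range(5)]
    cals = [calibrate_model(m) for m in models]
    windows = [np.full(10, response(models[j], angles[j])) for j in range(5)]
    est = reconstruct_from_sensors(prior, cals, windows, sel)
    direct = mve_estimate(prior, MeasurementSet(sel=sel, y=angles))
    np.testing.assert_allclose(est.x_hat, direct.x_hat, atol=1e-9)

    # two-sample window: the arithmetic mean of the window is used
    win2 = [np.array([response(models[j], angles[j] - 1.0),
                      response(models[j], angles[j] + 1.0)]) for j in range(5)]
    est2 = reconstruct_from_sensors(prior, cals, win2, sel)
    np.testing.assert_allclose(est2.x_hat, direct.x_hat, atol=1e-9)

    with pytest.raises(ValueError):
        reconstruct_from_sensors(prior, cals, [np.array([])] * 5, sel)


def test_noisy_windows_average_out(rng):
    """1000-sample windows at 0.8 deg noise leave <0.1 deg error on measured joints."""
    prior = random_spd_prior(rng)
    sel = build_selection_matrix(["TA", "MM", "RP", "LA", "LM"])
    angles = rng.uniform(0, 80, 5)
    models = [GoniometerModel(sensitivity=1.5 + 0.3 * j, offset=-5.0 + j, noise_sd=0.8)
              for j in range(5)]
    cals = [calibrate_model(m) for m in models]
    windows = [response(models[j], angles[j] + rng.normal(0, 0.8, 1000))
               for j in range(5)]
    noisy = reconstruct_from_sensors(prior, cals, windows, sel)
    clean = mve_estimate(prior, MeasurementSet(sel=sel, y=angles))
    assert np.abs(noisy.x_hat[sel.indices] - clean.x_hat[sel.indices]).max() < 0.1
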