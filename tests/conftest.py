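import numpy as np
import pytest

from gaitload import msk, pipeline, synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_params(**overrides):
    """Cheap envelope-mode cohort parameters for tests."""
    base = dict(
        n_participants=3,
        emg_mode="envelope",
        signal_rate=250.0,
        kin_rate=250.0,
        baseline_steps=20,
        steps_per_trial=60,
        trials_per_session=2,
        step_sd=3.0,
        ar1_rho=0.3,
        seed=11,
    )
    base.update(overrides)
    return synth.CohortParams(**base)


@pytest.fixture(scope="session")
def responder():
    """One participant with a solid 25% reduction and mild compensation."""
    params = small_params(seed=5)
    return synth.generate_participant(
        params, 42, participant_id="P01", reduction=0.25, kappa=0.4
    )


@pytest.fixture(scope="session")
def responder_result(responder):
    return pipeline.run_participant(responder)


@pytest.fixture
def toy_ankle_model():
    """Two ankle plantarflexors on a 3-joint scaffold (other joints get
    filler muscle pairs so the redundancy invariant holds)."""
    muscles = [
        msk.Muscle("gastrocnemius", 2800.0, {"knee": -0.02, "ankle": 0.05},
                   l_opt=0.06, c_knee=0.9),
        msk.Muscle("soleus", 5200.0, {"ankle": 0.04}, l_opt=0.05),
        msk.Muscle("vasti", 8000.0, {"knee": 0.045}, l_opt=0.10, c_knee=0.7),
        msk.Muscle("hamstrings", 3500.0, {"hip": -0.06, "knee": -0.035},
                   l_opt=0.11, c_knee=0.3),
        msk.Muscle("iliopsoas", 2500.0, {"hip": 0.05}, l_opt=0.12),
    ]
    return msk.MskModel(muscles=muscles, body_mass=75.0, height=1.75)


def flat_angles(model, n):
    """Angles pinned at the reference pose: fiber lengths exactly 1."""
    return {j: np.full(n, model.theta_ref.get(j, 0.0)) for j in model.joints}


def qp_oracle(A, b, w, lb, ub, x0=None):
    """Independent box-constrained quadratic solver for one frame:
    min ||a||^2 + w * ||A a - b||^2, lb <= a <= ub (trust-region method
    with analytic gradient and Hessian)."""
    from scipy.optimize import Bounds, minimize

    A = np.asarray(A, float)
    b = np.asarray(b, float)
    n = A.shape[1]
    H = 2.0 * np.eye(n) + 2.0 * w * A.T @ A
    res = minimize(
        lambda a: a @ a + w * (r := b - A @ a) @ r,
        x0 if x0 is not None else np.clip(np.full(n, 0.2), lb, ub),
        jac=lambda a: 2.0 * a + 2.0 * w * A.T @ (A @ a - b),
        hess=lambda a: H,
        bounds=Bounds(np.asarray(lb, float), np.asarray(ub, float)),
        method="trust-constr",
        options={"gtol": 1e-14, "xtol": 1e-14, "maxiter": 5000},
    )
    return res.x
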