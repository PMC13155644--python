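import numpy as np
import pytest

from gaitload import msk

from conftest import flat_angles, qp_oracle


class TestHillCurves:
    def test_active_peak_at_optimal(self):
        assert msk.active_force_length(1.0) == pytest.approx(1.0)
        assert msk.active_force_length(0.7) < 1.0
        assert msk.active_force_length(1.3) < 1.0

    def test_passive_zero_at_or_below_optimal(self):
        assert msk.passive_force(1.0) == 0.0
        assert msk.passive_force(0.8) == 0.0
        # monotone above optimal
        xs = np.linspace(1.0, 1.6, 20)
        fp = msk.passive_force(xs)
        assert np.all(np.diff(fp) > 0)

    def test_muscle_force_closed_forms(self, toy_ankle_model):
        m = toy_ankle_model.muscle("gastrocnemius")
        # a=0.5 at optimal length: F = 0.5 * F_max
        f = msk.muscle_force(toy_ankle_model, m, 0.5, 1.0)
        assert f == pytest.approx(0.5 * m.f_max)
        # passive only
        lt = 1.2
        fp = msk.passive_force(lt, toy_ankle_model.passive_strain,
                               toy_ankle_model.passive_exp_k)
        assert msk.muscle_force(toy_ankle_model, m, 0.0, lt) == pytest.approx(
            m.f_max * fp)

    def test_activation_bounds_enforced(self, toy_ankle_model):
        m = toy_ankle_model.muscle("soleus")
        with pytest.raises(ValueError):
            msk.muscle_force(toy_ankle_model, m, 1.2, 1.0)


class TestModelConstruction:
    def test_default_model_loads(self):
        model = msk.default_model(75.0, 1.75)
        assert len(model.muscles) == 8
        assert model.muscle("gastrocnemius").c_knee == pytest.approx(0.9)
        assert model.body_weight == pytest.approx(75.0 * 9.81)

    def test_redundancy_required(self):
        with pytest.raises(ValueError, match="spanned"):
            msk.MskModel(
                muscles=[msk.Muscle("a", 100.0, {"hip": 0.05})],
                body_mass=70.0, height=1.7,
                joints=("hip",),
            )

    def test_muscle_validation(self):
        with pytest.raises(ValueError):
            msk.Muscle("m", -1.0, {})
        with pytest.raises(ValueError):
            msk.Muscle("m", 100.0, {"knee": 0.5})
        with pytest.raises(ValueError):
            msk.Muscle("m", 100.0, {}, c_knee=1.5)


def solve_one_frame(model, moments, angles=None, constraints=None, w=None):
    angles = angles if angles is not None else flat_angles(model, 1)
    mom = {j: np.array([v]) for j, v in moments.items()}
    return msk.solve_static_optimization(
        model, mom, angles, emg_constraints=constraints, reserve_weight=w)


class TestStaticOptimization:
    def test_single_muscle_closed_form(self, toy_ankle_model):
        # pin everything but the gastrocnemius to zero: a = M / (r * F_max)
        model = toy_ankle_model
        zero = (np.zeros(1), np.zeros(1))
        M = 25.0
        sol = msk.solve_static_optimization(
            model, {"ankle": np.array([M])}, flat_angles(model, 1),
            emg_constraints={n: zero for n in
                             ("soleus", "vasti", "hamstrings", "iliopsoas")},
            reserve_weight=1e12,
        )
        a = sol.activation("gastrocnemius")[0]
        assert a == pytest.approx(M / (0.05 * 2800.0), abs=1e-6)

    def test_two_identical_agonists_split_equally(self):
        muscles = [
            msk.Muscle("a1", 1000.0, {"ankle": 0.05}),
            msk.Muscle("a2", 1000.0, {"ankle": 0.05}),
        ]
        model = msk.MskModel(muscles=muscles, body_mass=70.0, height=1.7,
                             joints=("ankle",))
        sol = solve_one_frame(model, {"ankle": 30.0}, w=1e12)
        a1, a2 = sol.activations[:, 0]
        assert a1 == pytest.approx(a2, abs=1e-9)
        assert a1 == pytest.approx(30.0 / (2 * 0.05 * 1000.0), abs=1e-6)

    def test_constrained_matches_qp_oracle(self, toy_ankle_model):
        """Box-constrained frame vs an independent general-purpose solver."""
        model = toy_ankle_model
        moments = {"hip": 20.0, "knee": -25.0, "ankle": 70.0}
        box = (np.array([0.294]), np.array([0.306]))
        w = 1000.0
        sol = solve_one_frame(model, moments, constraints={"gastrocnemius": box}, w=w)

        names = [m.name for m in model.muscles]
        joints = list(model.joints)
        R = np.array([[m.arm(j) for m in model.muscles] for j in joints])
        fmax = np.array([m.f_max for m in model.muscles])
        A = R * fmax  # fiber length 1 at reference pose -> f_L = 1, f_P = 0
        b = np.array([moments[j] for j in joints])
        lb = np.zeros(len(names))
        ub = np.ones(len(names))
        gi = names.index("gastrocnemius")
        lb[gi], ub[gi] = 0.294, 0.306
        oracle = qp_oracle(A, b, w, lb, ub)
        np.testing.assert_allclose(sol.activations[:, 0], oracle, atol=1e-6)

    def test_matches_brute_force_grid(self):
        """Two-muscle toy vs exhaustive activation grid at 1e-3."""
        muscles = [
            msk.Muscle("m1", 900.0, {"ankle": 0.05}),
            msk.Muscle("m2", 1500.0, {"ankle": 0.03}),
        ]
        model = msk.MskModel(muscles=muscles, body_mass=70.0, height=1.7,
                             joints=("ankle",))
        M, w = 40.0, 1000.0
        sol = solve_one_frame(model, {"ankle": M}, w=w)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-3)
        A = np.array([0.05 * 900.0, 0.03 * 1500.0])
        a1, a2 = np.meshgrid(grid, grid, indexing="ij")
        rho = M - A[0] * a1 - A[1] * a2
        cost = a1**2 + a2**2 + w * rho**2
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        np.testing.assert_allclose(sol.activations[:, 0], [grid[i], grid[j]],
                                   atol=2e-3)

    def test_moment_balance_with_reserves(self, toy_ankle_model):
        model = toy_ankle_model
        rng = np.random.default_rng(0)
        T = 5
        moments = {"hip": rng.uniform(-30, 30, T),
                   "knee": rng.uniform(-30, 40, T),
                   "ankle": rng.uniform(0, 70, T)}
        sol = msk.solve_static_optimization(model, moments, flat_angles(model, T))
        # balance holds exactly by construction of the reserve
        R = np.array([[m.arm(j) for m in model.muscles] for j in model.joints])
        fmax = np.array([m.f_max for m in model.muscles])
        for t in range(T):
            produced = R @ (fmax * sol.activations[:, t]) + sol.reserves[:, t]
            target = np.array([moments[j][t] for j in model.joints])
            np.testing.assert_allclose(produced, target, atol=1e-9)

    def test_reserves_vanish_at_high_weight(self, toy_ankle_model):
        model = toy_ankle_model
        moments = {"hip": np.array([10.0]), "knee": np.array([-20.0]),
                   "ankle": np.array([60.0])}
        sol = msk.solve_static_optimization(
            model, moments, flat_angles(model, 1), reserve_weight=1e12)
        assert np.max(np.abs(sol.reserves)) < 1e-6

    def test_kkt_monotone_in_gastroc_upper_bound(self, toy_ankle_model):
        model = toy_ankle_model
        moments = {"knee": -25.0, "ankle": 70.0, "hip": 15.0}
        prev_force, prev_obj = None, None
        for ub in (0.4, 0.3, 0.2, 0.1, 0.05):
            sol = solve_one_frame(
                model, moments,
                constraints={"gastrocnemius": (np.zeros(1), np.array([ub]))},
                w=1000.0)
            f = sol.force("gastrocnemius")[0]
            obj = sol.objective[0]
            if prev_force is not None:
                assert f <= prev_force + 1e-9
                assert obj >= prev_obj - 1e-9
            prev_force, prev_obj = f, obj

    def test_empty_box_rejected(self, toy_ankle_model):
        with pytest.raises(ValueError, match="frame 0"):
            solve_one_frame(
                toy_ankle_model, {"ankle": 10.0},
                constraints={"soleus": (np.array([0.5]), np.array([0.2]))})

    def test_activations_within_bounds(self, toy_ankle_model):
        sol = solve_one_frame(toy_ankle_model,
                              {"hip": 20.0, "knee": 30.0, "ankle": 50.0})
        assert np.all(sol.activations >= -1e-6)
        assert np.all(sol.activations <= 1 + 1e-6)

    def test_deterministic(self, toy_ankle_model):
        kw = dict(moments={"knee": -25.0, "ankle": 70.0, "hip": 15.0})
        a = solve_one_frame(toy_ankle_model, **kw)
        b = solve_one_frame(toy_ankle_model, **kw)
        np.testing.assert_array_equal(a.activations, b.activations)


class TestScaleFactor:
    def test_mean_of_ratios(self):
        acts = [0.4, 0.5, 0.45, 0.5, 0.4]
        emgs = [0.2, 0.25, 0.225, 0.25, 0.2]
        assert msk.emg_scale_factor(acts, emgs) == pytest.approx(2.0)

    def test_ratio_sequence(self):
        assert msk.emg_scale_factor([1, 2, 3, 4, 5], [1, 1, 1, 1, 1]) == pytest.approx(3.0)

    def test_zero_emg_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            msk.emg_scale_factor([0.4] * 5, [0.2, 0.2, 0.0, 0.2, 0.2])


class TestEmgConstraints:
    def test_two_percent_band(self):
        lo, hi = msk.build_emg_constraints(np.array([0.3]), 1.0)
        assert lo[0] == pytest.approx(0.294)
        assert hi[0] == pytest.approx(0.306)

    def test_zero_emg_forces_off(self):
        lo, hi = msk.build_emg_constraints(np.array([0.0]), 1.0)
        assert lo[0] == 0.0 and hi[0] == 0.0

    def test_overflow_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="ceiling"):
            lo, hi = msk.build_emg_constraints(np.array([1.05]), 1.0)
        assert hi[0] == 1.0
        assert lo[0] <= hi[0]

    def test_bad_factor(self):
        with pytest.raises(ValueError):
            msk.build_emg_constraints(np.array([0.3]), 0.0)


def manual_solution(model, forces_by_name, T=11):
    names = [m.name for m in model.muscles]
    forces = np.zeros((len(names), T))
    for name, f in forces_by_name.items():
        forces[names.index(name)] = f
    return msk.SOSolution(
        muscle_names=names,
        activations=np.zeros_like(forces),
        forces=forces,
        reserves=np.zeros((3, T)),
        objective=np.zeros(T),
    )


class TestContactForce:
    def test_intersegmental_only_is_one_bw(self, toy_ankle_model):
        mass = 71.36
        sol = manual_solution(toy_ankle_model, {})
        curve = msk.knee_contact_force(
            toy_ankle_model, sol, np.full(11, 700.0), mass, 0.6)
        np.testing.assert_allclose(curve.values_bw, 700.0 / (mass * 9.81))
        assert curve.values_bw[0] == pytest.approx(1.0, abs=1e-3)

    def test_muscle_projection_added(self, toy_ankle_model):
        mass = 71.36
        sol = manual_solution(toy_ankle_model, {"gastrocnemius": 500.0})
        curve = msk.knee_contact_force(
            toy_ankle_model, sol, np.full(11, 700.0), mass, 0.6)
        expected = (700.0 + 0.9 * 500.0) / (mass * 9.81)
        np.testing.assert_allclose(curve.values_bw, expected)
        assert curve.values_bw[0] == pytest.approx(1150.0 / 700.0, abs=2e-3)

    def test_non_knee_spanning_ignored(self, toy_ankle_model):
        mass = 70.0
        a = manual_solution(toy_ankle_model, {})
        b = manual_solution(toy_ankle_model, {"soleus": 900.0})
        ca = msk.knee_contact_force(toy_ankle_model, a, np.full(11, 500.0), mass, 0.6)
        cb = msk.knee_contact_force(toy_ankle_model, b, np.full(11, 500.0), mass, 0.6)
        np.testing.assert_allclose(ca.values_bw, cb.values_bw)

    def test_superposition(self, toy_ankle_model):
        mass = 70.0
        inter = np.linspace(400, 800, 11)
        s_g = manual_solution(toy_ankle_model, {"gastrocnemius": 300.0})
        s_v = manual_solution(toy_ankle_model, {"vasti": 700.0})
        s_both = manual_solution(toy_ankle_model,
                                 {"gastrocnemius": 300.0, "vasti": 700.0})
        zero = manual_solution(toy_ankle_model, {})
        c = lambda s, i: msk.knee_contact_force(toy_ankle_model, s, i, mass, 0.6).values_bw
        np.testing.assert_allclose(
            c(s_both, inter),
            c(s_g, inter) + c(s_v, inter) - c(zero, inter),
            rtol=1e-12,
        )

    def test_grid_mismatch(self, toy_ankle_model):
        sol = manual_solution(toy_ankle_model, {})
        with pytest.raises(ValueError, match="grid"):
            msk.knee_contact_force(toy_ankle_model, sol, np.zeros(7), 70.0, 0.6)


class TestMetrics:
    def grid_curve(self, fn):
        pct = np.linspace(0, 100, 101)
        return msk.ContactForceCurve(fn(pct), 0.6)

    def test_two_hump_peaks(self):
        curve = self.grid_curve(
            lambda p: 2.0 * np.exp(-0.5 * ((p - 25) / 8) ** 2)
            + 2.5 * np.exp(-0.5 * ((p - 75) / 8) ** 2))
        early, late = msk.peak_metrics(curve)
        assert early == pytest.approx(2.0, abs=0.01)
        assert late == pytest.approx(2.5, abs=0.01)

    def test_midstance_max_ignored(self):
        curve = self.grid_curve(lambda p: np.exp(-0.5 * ((p - 50) / 3) ** 2))
        early, late = msk.peak_metrics(curve)
        assert early < 0.5 and late < 0.5

    def test_constant_curve(self):
        curve = self.grid_curve(lambda p: np.full_like(p, 2.0))
        assert msk.peak_metrics(curve) == (2.0, 2.0)

    def test_impulse_constant(self):
        curve = msk.ContactForceCurve(np.ones(101), 0.6)
        assert msk.contact_impulse(curve) == pytest.approx(0.6)

    def test_impulse_zero(self):
        curve = msk.ContactForceCurve(np.zeros(101), 0.6)
        assert msk.contact_impulse(curve) == 0.0

    def test_impulse_triangle(self):
        v = np.concatenate([np.linspace(0, 2, 51), np.linspace(2, 0, 51)[1:]])
        curve = msk.ContactForceCurve(v, 0.6)
        assert msk.contact_impulse(curve) == pytest.approx(0.6, abs=1e-9)

    def test_half_extrema_sinusoid(self):
        pct = np.linspace(0, 100, 1001)
        v = np.sin(2 * np.pi * pct / 100.0)
        first, second = msk.stance_half_extrema(v, sense=("max", "min"))
        assert first == pytest.approx(1.0, abs=1e-4)
        assert second == pytest.approx(-1.0, abs=1e-4)

    def test_half_extrema_monotone(self):
        v = np.linspace(0, 1, 101)
        first, second = msk.stance_half_extrema(v, sense=("max", "max"))
        assert first == pytest.approx(0.5)
        assert second == pytest.approx(1.0)

    def test_half_extrema_constant(self):
        v = np.full(101, 1.5)
        assert msk.stance_half_extrema(v, ("max", "min")) == (1.5, 1.5)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            msk.ContactForceCurve(np.array([np.inf]), 0.6)
        with pytest.raises(ValueError):
            msk.ContactForceCurve(np.ones(5), 0.0)
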