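"""Reduced sagittal-plane musculoskeletal model and static optimization.

The model has three sagittal joints (hip, knee, ankle) spanned by eight
lumped muscles with constant moment arms and rigid tendons. Per frame the
muscle redundancy is resolved by

    min  sum_m a_m^2  +  w_res * sum_j rho_j^2
    s.t. sum_m r_{m,j} * F_m(a_m) + rho_j = M_j,    0 <= a_m <= 1,

optionally with per-muscle activation boxes from scaled EMG. Because the
Hill force is affine in activation at fixed fiber length, each frame is a
box-constrained linear least-squares problem, solved exactly with
``scipy.optimize.lsq_linear`` (deterministic, convex).

Knee contact force along the tibia's longitudinal axis is the axial
intersegmental force plus the axial projections ``c_m * F_m`` of the
knee-spanning muscle forces, reported in body weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import lsq_linear

__all__ = [
    "GRAVITY",
    "Muscle",
    "MskModel",
    "SOSolution",
    "ContactForceCurve",
    "load_model",
    "default_model",
    "active_force_length",
    "passive_force",
    "fiber_length",
    "muscle_force",
    "solve_static_optimization",
    "emg_scale_factor",
    "build_emg_constraints",
    "knee_contact_force",
    "peak_metrics",
    "contact_impulse",
    "stance_half_extrema",
]

GRAVITY = 9.81
JOINTS = ("hip", "knee", "ankle")


@dataclass(frozen=True)
class Muscle:
    name: str
    f_max: float  # N
    moment_arms: dict  # joint -> m, signed (hip flex +, knee ext +, ankle pf +)
    l_opt: float = 0.1  # optimal fiber length, m
    c_knee: float = 0.0  # axial projection onto the tibia, [0, 1]

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError(f"{self.name}: f_max must be > 0")
        for j, r in self.moment_arms.items():
            if abs(r) > 0.1:
                raise ValueError(f"{self.name}: |moment arm| at {j} exceeds 0.1 m")
        if not 0.0 <= self.c_knee <= 1.0:
            raise ValueError(f"{self.name}: c_knee must be in [0, 1]")

    def arm(self, joint: str) -> float:
        return self.moment_arms.get(joint, 0.0)


@dataclass
class MskModel:
    muscles: list
    body_mass: float  # kg
    height: float  # m
    reserve_weight: float = 1000.0
    fl_width: float = 0.45
    passive_strain: float = 0.6
    passive_exp_k: float = 10.0
    theta_ref: dict = field(default_factory=lambda: {j: 0.0 for j in JOINTS})
    joints: tuple = JOINTS

    def __post_init__(self) -> None:
        if self.reserve_weight < 100:
            raise ValueError("reserve weight must be >= 100")
        for j in self.joints:
            spanning = sum(1 for m in self.muscles if m.arm(j) != 0.0)
            if spanning < 2:
                raise ValueError(f"joint {j!r} spanned by {spanning} muscle(s); need >= 2")

    def muscle(self, name: str) -> Muscle:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)

    @property
    def body_weight(self) -> float:
        return self.body_mass * GRAVITY


def load_model(path, body_mass: float, height: float) -> MskModel:
    """Build a model from a YAML parameter file."""
    spec = yaml.safe_load(Path(path).read_text())
    muscles = [
        Muscle(
            name=name,
            f_max=float(p["f_max"]),
            moment_arms={j: float(r) for j, r in p["moment_arms"].items()},
            l_opt=float(p.get("l_opt", 0.1)),
            c_knee=float(p.get("c_knee", 0.0)),
        )
        for name, p in spec["muscles"].items()
    ]
    return MskModel(
        muscles=muscles,
        body_mass=body_mass,
        height=height,
        reserve_weight=float(spec.get("reserve_weight", 1000.0)),
        fl_width=float(spec.get("fl_width", 0.45)),
        passive_strain=float(spec.get("passive_strain", 0.6)),
        passive_exp_k=float(spec.get("passive_exp_k", 10.0)),
        theta_ref={j: float(v) for j, v in spec.get("theta_ref", {}).items()},
    )


def default_model(body_mass: float, height: float) -> MskModel:
    """The packaged 8-muscle default parameter set."""
    ref = resources.files("gaitload.data") / "default_model.yaml"
    with resources.as_file(ref) as p:
        return load_model(p, body_mass, height)


# ---------------------------------------------------------------- Hill curves


def active_force_length(l_tilde, width: float = 0.45):
    """Unimodal active force-length curve, f_L(1) = 1."""
    l_tilde = np.asarray(l_tilde, dtype=float)
    return np.exp(-(((l_tilde - 1.0) / width) ** 2))


def passive_force(l_tilde, strain: float = 0.6, k: float = 10.0):
    """Monotone passive curve, zero at or below optimal length, reaching 1
    at strain ``strain`` beyond optimal."""
    l_tilde = np.asarray(l_tilde, dtype=float)
    x = np.maximum(l_tilde - 1.0, 0.0)
    return (np.exp(k * x) - 1.0) / (np.exp(k * strain) - 1.0)


def fiber_length(model: MskModel, muscle: Muscle, angles_deg: dict):
    """Normalized fiber length from joint-angle excursion:
    l = 1 - sum_j r_j * (theta_j - theta_ref_j) / l_opt (theta in rad)."""
    l = None
    for j in model.joints:
        if j not in angles_deg or muscle.arm(j) == 0.0:
            continue
        dtheta = (np.asarray(angles_deg[j], float) - model.theta_ref.get(j, 0.0)) * np.pi / 180.0
        term = muscle.arm(j) * dtheta / muscle.l_opt
        l = term if l is None else l + term
    if l is None:
        l = 0.0
    return 1.0 - l


def muscle_force(model: MskModel, muscle: Muscle, a, l_tilde):
    """Hill-type force F = F_max * (a * f_L + f_P) at fixed fiber length."""
    a = np.asarray(a, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("activation must lie in [0, 1]")
    fl = active_force_length(l_tilde, model.fl_width)
    fp = passive_force(l_tilde, model.passive_strain, model.passive_exp_k)
    return muscle.f_max * (a * fl + fp)


# ------------------------------------------------------- static optimization


@dataclass
class SOSolution:
    """Per-frame static optimization solution on a stance grid."""

    muscle_names: list
    activations: np.ndarray  # (n_muscles, n_frames)
    forces: np.ndarray  # (n_muscles, n_frames), N
    reserves: np.ndarray  # (n_joints, n_frames), N*m
    objective: np.ndarray  # (n_frames,)
    joints: tuple = JOINTS
    high_reserve_frames: list = field(default_factory=list)

    def activation(self, name: str) -> np.ndarray:
        return self.activations[self.muscle_names.index(name)]

    def force(self, name: str) -> np.ndarray:
        return self.forces[self.muscle_names.index(name)]


def solve_static_optimization(
    model: MskModel,
    moments: dict,
    angles: dict,
    emg_constraints: dict | None = None,
    reserve_weight: float | None = None,
) -> SOSolution:
    """Resolve muscle redundancy frame by frame.

    Parameters
    ----------
    moments : dict joint -> (T,) array, N*m on the stance grid.
    angles : dict joint -> (T,) array, degrees on the same grid.
    emg_constraints : optional dict muscle -> (lo, hi) arrays of activation
        bounds per frame, each within [0, 1].
    reserve_weight : overrides the model's reserve cost weight (use a very
        large value to approximate hard moment balance).

    Raises
    ------
    ValueError
        Empty constraint box (lo > hi), grid mismatch, or solver failure
        (reported with the frame index).
    """
    w = model.reserve_weight if reserve_weight is None else float(reserve_weight)
    joints = [j for j in model.joints if j in moments]
    if not joints:
        raise ValueError("no joint moments provided")
    T = len(np.asarray(moments[joints[0]]))
    for j in joints:
        if len(np.asarray(moments[j])) != T:
            raise ValueError("moment arrays must share one grid")
    M = len(model.muscles)
    names = [m.name for m in model.muscles]

    # fiber lengths per muscle per frame
    lt = np.empty((M, T))
    for i, mus in enumerate(model.muscles):
        l = fiber_length(model, mus, angles)
        lt[i] = np.broadcast_to(np.asarray(l, float), (T,))
    fl = active_force_length(lt, model.fl_width)
    fp = passive_force(lt, model.passive_strain, model.passive_exp_k)

    lo = np.zeros((M, T))
    hi = np.ones((M, T))
    if emg_constraints:
        for name, (clo, chi) in emg_constraints.items():
            i = names.index(name)
            clo = np.broadcast_to(np.asarray(clo, float), (T,))
            chi = np.broadcast_to(np.asarray(chi, float), (T,))
            if np.any(clo > chi):
                t = int(np.nonzero(clo > chi)[0][0])
                raise ValueError(f"empty constraint box for {name!r} at frame {t}")
            lo[i] = np.clip(clo, 0.0, 1.0)
            hi[i] = np.clip(chi, 0.0, 1.0)
    if np.any(lo > hi):
        raise ValueError("constraint bounds empty after clipping")

    R = np.array([[mus.arm(j) for mus in model.muscles] for j in joints])  # (J, M)
    sqw = np.sqrt(w)
    acts = np.empty((M, T))
    reserves = np.empty((len(joints), T))
    objective = np.empty(T)
    high = []
    for t in range(T):
        A = R * (_fmax(model) * fl[:, t])  # (J, M)
        b = np.array([moments[j][t] for j in joints]) - R @ (_fmax(model) * fp[:, t])
        # variables with a degenerate box are fixed and eliminated (the BVLS
        # solver requires strictly ordered bounds)
        fixed = hi[:, t] - lo[:, t] <= 1e-12
        a = np.empty(M)
        a[fixed] = lo[fixed, t]
        free = ~fixed
        if free.any():
            b_eff = b - A[:, fixed] @ a[fixed]
            nf = int(free.sum())
            # min ||a||^2 + w * ||A a - b||^2 over box [lo, hi]
            C = np.vstack([sqw * A[:, free], np.eye(nf)])
            d = np.concatenate([sqw * b_eff, np.zeros(nf)])
            res = lsq_linear(C, d, bounds=(lo[free, t], hi[free, t]),
                             method="bvls", tol=1e-14)
            if not res.success and res.status <= 0:
                raise ValueError(
                    f"static optimization failed at frame {t}: {res.message}")
            a[free] = np.clip(res.x, lo[free, t], hi[free, t])
        rho = b - A @ a
        acts[:, t] = a
        reserves[:, t] = rho
        objective[t] = float(a @ a + w * rho @ rho)
        for ji, j in enumerate(joints):
            mj = abs(moments[j][t])
            if mj > 1e-9 and abs(rho[ji]) > 0.05 * mj:
                high.append((t, j))
    forces = _fmax(model)[:, None] * (acts * fl + fp)
    return SOSolution(
        muscle_names=names,
        activations=acts,
        forces=forces,
        reserves=reserves,
        objective=objective,
        joints=tuple(joints),
        high_reserve_frames=high,
    )


def _fmax(model: MskModel) -> np.ndarray:
    return np.array([m.f_max for m in model.muscles])


def emg_scale_factor(activation_means, emg_means) -> float:
    """Activation/EMG scale factor from representative baseline steps.

    Per step, the ratio of the stance-mean static-optimization activation to
    the stance-mean delayed normalized EMG; the factor is the mean ratio.
    """
    activation_means = np.asarray(activation_means, dtype=float)
    emg_means = np.asarray(emg_means, dtype=float)
    if activation_means.shape != emg_means.shape:
        raise ValueError("need one EMG mean per activation mean")
    if np.any(emg_means <= 0):
        raise ValueError("every step must have strictly positive stance-mean EMG")
    return float(np.mean(activation_means / emg_means))


def build_emg_constraints(
    emg: np.ndarray, factor: float, tolerance: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame activation bounds tracking scaled EMG within a relative
    tolerance: [ (1-tol)*f*emg, (1+tol)*f*emg ], intersected with [0, 1]."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    target = factor * np.asarray(emg, dtype=float)
    lo = (1.0 - tolerance) * target
    hi = (1.0 + tolerance) * target
    if np.any(lo > 1.0):
        warnings.warn(
            "scaled EMG target exceeds the activation ceiling; clamping to 1",
            stacklevel=2,
        )
    hi = np.clip(hi, 0.0, 1.0)
    lo = np.clip(np.minimum(lo, hi), 0.0, 1.0)
    return lo, hi


# ------------------------------------------------------------- contact force


@dataclass
class ContactForceCurve:
    """Axial knee contact force on a 0-100% stance grid, in body weights."""

    values_bw: np.ndarray
    stance_duration: float  # s

    def __post_init__(self) -> None:
        self.values_bw = np.asarray(self.values_bw, dtype=float)
        if not np.all(np.isfinite(self.values_bw)):
            raise ValueError("contact force curve must be finite")
        if self.stance_duration <= 0:
            raise ValueError("stance duration must be > 0")

    @property
    def grid_pct(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, self.values_bw.size)


def knee_contact_force(
    model: MskModel,
    sol: SOSolution,
    intersegmental_axial: np.ndarray,
    body_mass: float,
    stance_duration: float = 0.6,
) -> ContactForceCurve:
    """Axial knee force: intersegmental axial force plus c_m-weighted
    knee-spanning muscle forces, normalized to body weight."""
    inter = np.asarray(intersegmental_axial, dtype=float)
    if inter.size != sol.forces.shape[1]:
        raise ValueError(
            f"grid mismatch: intersegmental has {inter.size} frames, "
            f"solution has {sol.forces.shape[1]}"
        )
    c = np.array([model.muscle(n).c_knee for n in sol.muscle_names])
    total = inter + c @ sol.forces
    return ContactForceCurve(total / (body_mass * GRAVITY), stance_duration)


def peak_metrics(
    curve: ContactForceCurve,
    early: tuple = (15.0, 35.0),
    late: tuple = (65.0, 85.0),
) -> tuple[float, float]:
    """Early- and late-stance peaks: maxima over 15-35% and 65-85% stance
    (inclusive endpoints on the grid)."""
    pct = curve.grid_pct
    v = curve.values_bw

    def window_max(lo, hi):
        mask = (pct >= lo - 1e-12) & (pct <= hi + 1e-12)
        return float(v[mask].max())

    return window_max(*early), window_max(*late)


def contact_impulse(curve: ContactForceCurve) -> float:
    """Trapezoidal integral of contact force (BW) over stance time (s)."""
    dt = curve.stance_duration / (curve.values_bw.size - 1)
    return float(np.trapezoid(curve.values_bw, dx=dt))


def stance_half_extrema(
    values: np.ndarray, sense: tuple = ("max", "max")
) -> tuple[float, float]:
    """Extremum of each stance half: [0, 50%] and (50%, 100%] of the grid.

    ``sense`` selects max or min per half (e.g. ("max", "min") for a
    quantity peaking early and dipping late).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    pct = np.linspace(0.0, 100.0, n)
    halves = (pct <= 50.0 + 1e-12, pct > 50.0 + 1e-12)
    out = []
    for mask, s in zip(halves, sense):
        seg = values[mask]
        out.append(float(seg.max() if s == "max" else seg.min()))
    return out[0], out[1]
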