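"""Synthetic gait cohorts with known ground truth.

Each participant gets a baseline trial and several feedback trials. Stance
EMG envelopes are Gaussian bumps on the % stance axis (gastrocnemius
centred near 75% stance, vasti near 25%, soleus near 70%, hamstrings near
10%); the vertical GRF is a double-hump template that crosses the step
detection threshold cleanly. Feedback trials scale the gastrocnemius
envelope by the participant's realized per-step reduction (saturating
within-session learning plus AR(1) step noise), add proportional vasti
compensation, and reduce the late-stance ankle plantarflexion and knee
flexion moments by a coupling fraction of the realized reduction. The
intersegmental axial knee force is held at its baseline shape.

EMG can be emitted as pre-conditioned normalized envelopes (``envelope``
mode, cheap, any rate) or as raw volts (``raw`` mode): band-limited white
carrier noise amplitude-modulated by the envelope so that the full
bandpass-rectify-lowpass chain recovers the envelope in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import TimeSeries, TrialBundle, TrialMeta

__all__ = [
    "CohortParams",
    "ParticipantTruth",
    "ParticipantData",
    "CohortData",
    "generate_participant",
    "generate_cohort",
    "EMG_MUSCLES",
]

EMG_MUSCLES = (
    "medial_gastrocnemius",
    "lateral_gastrocnemius",
    "soleus",
    "vastus_medialis",
    "vastus_lateralis",
    "biceps_femoris",
    "semitendinosus",
    "tibialis_anterior",
    "rectus_femoris",
)

# stance envelope templates: (amplitude, centre % stance, width) per muscle
_TEMPLATES = {
    "medial_gastrocnemius": (0.40, 0.75, 0.10),
    "lateral_gastrocnemius": (0.36, 0.74, 0.11),
    "soleus": (0.45, 0.70, 0.12),
    "vastus_medialis": (0.30, 0.25, 0.10),
    "vastus_lateralis": (0.28, 0.26, 0.10),
    "biceps_femoris": (0.25, 0.10, 0.08),
    "semitendinosus": (0.22, 0.11, 0.09),
    "tibialis_anterior": (0.25, 0.05, 0.07),
    "rectus_femoris": (0.20, 0.30, 0.15),
}

_GASTROCS = ("medial_gastrocnemius", "lateral_gastrocnemius")
_VASTI = ("vastus_medialis", "vastus_lateralis")


@dataclass(frozen=True)
class CohortParams:
    n_participants: int = 13
    baseline_steps: int = 40
    steps_per_trial: int = 70
    trials_per_session: int = 3
    signal_rate: float = 2000.0  # EMG and GRF, Hz
    kin_rate: float = 2000.0  # kinematics/kinetics synthesis grid, Hz
    stance_mean_s: float = 0.60
    stance_sd_s: float = 0.03
    swing_s: float = 0.45
    mean_reduction: float = 25.0  # mu_r, percent
    sd_reduction: float = 15.0  # sigma_r, percent (between participants)
    step_sd: float = 5.0  # within-participant per-step SD, percent points
    ar1_rho: float = 0.7
    kappa_mean: float = 1.52  # vasti compensation per unit gastroc reduction
    kappa_sd: float = 0.5
    gamma: float = 0.8  # fraction of reduction coupled into late-stance moments
    envelope_noise: float = 0.05  # relative (multiplicative) envelope noise
    grf_noise: float = 2.0  # N
    emg_mode: str = "raw"  # raw | envelope
    session: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_reduction", "step_sd", "kappa_sd", "stance_sd_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.emg_mode not in ("raw", "envelope"):
            raise ValueError(f"unknown emg_mode {self.emg_mode!r}")
        if self.emg_mode == "raw" and self.signal_rate <= 1000.0:
            raise ValueError(
                "raw EMG synthesis needs signal_rate > 1000 Hz "
                "(bandpass upper edge below Nyquist)"
            )


@dataclass
class ParticipantTruth:
    participant_id: str
    reduction: float  # r_i as a fraction (0.25 = 25%)
    kappa: float
    amplitude: float
    realized: list = field(default_factory=list)  # per-trial per-step fractions


@dataclass
class ParticipantData:
    participant_id: str
    baseline: TrialBundle
    feedback: list
    truth: ParticipantTruth


@dataclass
class CohortData:
    params: CohortParams
    participants: list

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": p.participant_id,
                "true_reduction_pct": 100.0 * p.truth.reduction,
                "kappa": p.truth.kappa,
                "amplitude": p.truth.amplitude,
            }
            for p in self.participants
        ]
        return pd.DataFrame(rows).set_index("participant_id")


def _gauss(s, c, w):
    return np.exp(-0.5 * ((s - c) / w) ** 2)


def _taper(s):
    return np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 0.25


def _learning(trial_index: int) -> float:
    """Saturating within-session learning; reaches 95% of the participant's
    reduction by the second trial."""
    return 1.0 - np.exp(-(trial_index + 1) * np.log(20.0) / 2.0)


def _vgrf_template(s, bw):
    return bw * (1.10 * _gauss(s, 0.25, 0.14) + 1.15 * _gauss(s, 0.75, 0.14)) * _taper(s)


def _interseg_template(s, bw):
    return bw * (0.25 + 0.85 * _gauss(s, 0.25, 0.15) + 0.95 * _gauss(s, 0.75, 0.15)) * _taper(s)


def _angles(s):
    return {
        "angle_hip": 25.0 * np.cos(np.pi * s),
        "angle_knee": 8.0 + 12.0 * _gauss(s, 0.15, 0.12) + 40.0 * _gauss(s, 1.05, 0.15),
        "angle_ankle": 10.0 * np.sin(np.pi * s) - 20.0 * _gauss(s, 1.0, 0.1),
    }


def _moments(s, mscale, late_factor):
    """Joint moments; the late-stance ankle plantarflexion and knee flexion
    components scale with ``late_factor`` (1 at baseline)."""
    return {
        "moment_ankle": mscale * (85.0 * late_factor * _gauss(s, 0.72, 0.15)
                                  - 8.0 * _gauss(s, 0.05, 0.05)),
        "moment_knee": mscale * (50.0 * _gauss(s, 0.22, 0.10)
                                 - 32.0 * late_factor * _gauss(s, 0.75, 0.10)),
        "moment_hip": mscale * (35.0 * _gauss(s, 0.08, 0.10)
                                - 30.0 * _gauss(s, 0.85, 0.12)),
    }


def _bandlimited_carrier(n, rate, rng):
    sos = sps.butter(4, [30.0, min(500.0, 0.45 * rate)], btype="bandpass",
                     fs=rate, output="sos")
    w = sps.sosfilt(sos, rng.standard_normal(n))
    sd = w.std()
    return w / sd if sd > 0 else w


def _assemble_trial(
    params: CohortParams,
    rng: np.random.Generator,
    n_steps: int,
    amp: float,
    body_mass: float,
    gastroc_scale_per_step: np.ndarray,
    vasti_scale_per_step: np.ndarray,
    moment_factor_per_step: np.ndarray,
) -> TimeSeries:
    rate = params.signal_rate
    bw = body_mass * 9.81
    mscale = body_mass / 75.0
    lead = int(round(0.3 * rate))

    segments: dict[str, list] = {
        **{f"emg_{m}": [np.full(lead, 0.01)] for m in EMG_MUSCLES},
        "vertical_grf": [np.zeros(lead)],
        "knee_axial_force": [np.zeros(lead)],
        **{ch: [np.zeros(lead)] for ch in ("angle_hip", "angle_knee", "angle_ankle",
                                           "moment_hip", "moment_knee", "moment_ankle")},
    }
    swing_n = int(round(params.swing_s * rate))
    for k in range(n_steps):
        dur = max(0.35, rng.normal(params.stance_mean_s, params.stance_sd_s))
        n = int(round(dur * rate))
        s = (np.arange(n) + 0.5) / n
        for m in EMG_MUSCLES:
            a0, c, w = _TEMPLATES[m]
            scale = amp
            if m in _GASTROCS:
                scale *= gastroc_scale_per_step[k]
            elif m in _VASTI:
                scale *= vasti_scale_per_step[k]
            # floor inside the scale and multiplicative noise keep per-step
            # stance means proportional to the scale factor (unbiased ratios)
            env = scale * (a0 * _gauss(s, c, w) + 0.02)
            env *= 1.0 + params.envelope_noise * rng.standard_normal(n)
            segments[f"emg_{m}"].append(np.maximum(env, 0.0))
        segments["vertical_grf"].append(
            np.maximum(_vgrf_template(s, bw) + params.grf_noise * rng.standard_normal(n), 0.0)
        )
        segments["knee_axial_force"].append(_interseg_template(s, bw))
        for ch, vals in _angles(s).items():
            segments[ch].append(vals)
        for ch, vals in _moments(s, mscale, moment_factor_per_step[k]).items():
            segments[ch].append(vals)
        # swing: quiet EMG, zero force, coasting kinematics
        for m in EMG_MUSCLES:
            segments[f"emg_{m}"].append(np.full(swing_n, 0.01))
        segments["vertical_grf"].append(np.zeros(swing_n))
        segments["knee_axial_force"].append(np.zeros(swing_n))
        for ch in ("angle_hip", "angle_knee", "angle_ankle",
                   "moment_hip", "moment_knee", "moment_ankle"):
            segments[ch].append(np.zeros(swing_n))

    channels = {ch: np.concatenate(parts) for ch, parts in segments.items()}

    if params.emg_mode == "raw":
        # modulate a unit-variance band-limited carrier so that
        # lowpass(|carrier * env * sqrt(pi/2)|) ~= env
        for m in EMG_MUSCLES:
            key = f"emg_{m}"
            env = channels[key]
            carrier = _bandlimited_carrier(env.size, rate, rng)
            channels[key] = env * np.sqrt(np.pi / 2.0) * carrier

    if abs(params.kin_rate - rate) > 1e-9:
        # kinematics are synthesized on the signal grid; a distinct kin_rate
        # is honoured by resampling those channels through their own grid
        n = channels["angle_hip"].size
        t_sig = np.arange(n) / rate
        t_kin = np.arange(0.0, t_sig[-1] + 0.5 / params.kin_rate, 1.0 / params.kin_rate)
        for ch in ("angle_hip", "angle_knee", "angle_ankle",
                   "moment_hip", "moment_knee", "moment_ankle", "knee_axial_force"):
            coarse = np.interp(t_kin, t_sig, channels[ch])
            channels[ch] = np.interp(t_sig, t_kin, coarse)

    n = channels["vertical_grf"].size
    return TimeSeries(time=np.arange(n) / rate, channels=channels, rate=rate)


def generate_participant(
    params: CohortParams,
    participant_seed: int,
    participant_id: str = "P00",
    reduction: float | None = None,
    kappa: float | None = None,
) -> ParticipantData:
    """One participant: baseline trial, feedback trials, ground truth.

    ``reduction``/``kappa`` override the participant-level draws (fraction
    and dimensionless, respectively). Same seed, same bytes.
    """
    rng = np.random.default_rng(participant_seed)
    if reduction is None:
        reduction = _truncated_normal(rng, params.mean_reduction, params.sd_reduction) / 100.0
    if kappa is None:
        kappa = max(0.0, rng.normal(params.kappa_mean, params.kappa_sd))
    amp = max(0.5, rng.normal(1.0, 0.1))
    body_mass = max(45.0, rng.normal(78.2, 17.4))
    height = max(1.4, rng.normal(1.75, 0.12))
    speed = max(0.5, rng.normal(0.99, 0.19))
    mvc = {m: 1.0 for m in EMG_MUSCLES}
    truth = ParticipantTruth(participant_id, float(reduction), float(kappa), float(amp))

    def meta(kind):
        return TrialMeta(
            participant_id=participant_id,
            session=params.session,
            trial_kind=kind,
            body_mass=body_mass,
            height=height,
            treadmill_speed=speed,
            mvc_values=mvc,
            emg_is_envelope=params.emg_mode == "envelope",
        )

    ones = np.ones(params.baseline_steps)
    baseline_ts = _assemble_trial(
        params, rng, params.baseline_steps, amp, body_mass, ones, ones, ones
    )
    baseline = TrialBundle(baseline_ts, meta("baseline"))

    feedback = []
    for trial_idx in range(params.trials_per_session):
        n = params.steps_per_trial
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, params.step_sd)
        for k in range(1, n):
            noise[k] = params.ar1_rho * noise[k - 1] + np.sqrt(
                1.0 - params.ar1_rho**2
            ) * rng.normal(0.0, params.step_sd)
        realized = np.clip(
            reduction * _learning(trial_idx) + noise / 100.0, 0.0, 0.95
        )
        truth.realized.append(realized)
        ts = _assemble_trial(
            params,
            rng,
            n,
            amp,
            body_mass,
            gastroc_scale_per_step=1.0 - realized,
            vasti_scale_per_step=1.0 + kappa * realized,
            moment_factor_per_step=1.0 - params.gamma * realized,
        )
        feedback.append(TrialBundle(ts, meta("feedback")))

    return ParticipantData(participant_id, baseline, feedback, truth)


def _truncated_normal(rng, mean, sd, lo: float = 0.0) -> float:
    if sd == 0:
        return max(mean, lo)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lo:
            return x
    return lo


def truncated_normal_mean(mu: float, sigma: float) -> float:
    """Mean of a Normal(mu, sigma^2) truncated below at zero."""
    if sigma == 0:
        return max(mu, 0.0)
    from scipy.stats import norm

    z = mu / sigma
    return mu + sigma * norm.pdf(z) / norm.cdf(z)


def recover_location(measured_mean: float, sigma: float) -> float:
    """Invert the truncated-normal mean: the location mu whose zero-truncated
    Normal(mu, sigma^2) has the given mean (method of moments, sigma known).
    Lets a pipeline estimate of the cohort mean reduction be mapped back to
    the generator's mu_r."""
    if sigma == 0:
        return measured_mean
    from scipy.optimize import brentq

    lo, hi = measured_mean - 10.0 * sigma, measured_mean + 1e-9
    return float(brentq(lambda m: truncated_normal_mean(m, sigma) - measured_mean, lo, hi))


def generate_cohort(params: CohortParams) -> CohortData:
    """Independent participants with r_i ~ Normal(mu_r, sigma_r^2) truncated
    at zero; deterministic for a fixed seed."""
    if params.n_participants < 1:
        raise ValueError("need at least one participant")
    ss = np.random.SeedSequence(params.seed)
    seeds = ss.generate_state(params.n_participants)
    participants = [
        generate_participant(params, int(seeds[i]), participant_id=f"P{i + 1:02d}")
        for i in range(params.n_participants)
    ]
    return CohortData(params=params, participants=participants)
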