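"""Per-participant and cohort orchestration.

``run_participant`` executes, in order: EMG conditioning and normalization,
GRF filtering and step segmentation, per-step stance means and percent
changes, 50-step window selection, representative-step selection,
electromechanical delay, unconstrained baseline static optimization,
gastrocnemius activation/EMG scale-factor calibration, EMG-constrained
feedback static optimization, and knee contact force metrics.

``run_cohort`` aggregates participant results and applies the statistics
layer: primary outcomes uncorrected, exploratory outcomes in one
Benjamini-Hochberg family.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import feedback as fb
from . import msk, signal, stats, windows
from .config import DEFAULTS
from .io import TrialBundle

logger = logging.getLogger(__name__)

__all__ = ["ParticipantResult", "CohortReport", "run_participant", "run_cohort"]


@dataclass
class StepData:
    """One detected step: stance window plus per-group stance means."""

    window: signal.StanceWindow
    record: windows.TrialStepRecord


@dataclass
class ParticipantResult:
    participant_id: str
    qualified: bool
    session_log: fb.SessionLog | None
    baseline_group_means: dict
    selected_window: windows.SelectedWindow
    selected_trial: int
    best_gastroc_window: windows.SelectedWindow
    group_pct: dict  # per-group mean % change over the selected window
    scale_factor: float
    metrics: dict  # condition -> {early_peak_bw, late_peak_bw, impulse_bw_s}
    deltas: dict  # feedback - baseline, BW / BW*s; late_peak_pct from BW values
    emg_means: dict  # condition -> per-group mean stance EMG
    mean_curves: dict  # condition -> mean contact force curve (BW)
    warnings: list = field(default_factory=list)


def _trial_steps(bundle: TrialBundle, cfg: dict) -> list[StepData]:
    """Envelope extraction, step segmentation and per-step group means."""
    ts, meta = bundle.ts, bundle.meta
    rate = ts.rate
    envs: dict[str, np.ndarray] = {}
    for ch, vals in ts.channels.items():
        if not ch.startswith("emg_"):
            continue
        muscle = ch[len("emg_"):]
        mvc = meta.mvc_values.get(muscle, 1.0)
        if meta.emg_is_envelope:
            env = vals
        else:
            env = signal.process_emg(
                vals, rate,
                band=tuple(cfg["emg_band_hz"]), band_order=cfg["emg_band_order"],
                lowpass_cut=cfg["emg_lowpass_hz"], lowpass_order=cfg["emg_lowpass_order"],
            )
        envs[muscle] = signal.normalize_emg(env, mvc, muscle, rate).values

    grf = signal.lowpass_grf(
        ts.channels["vertical_grf"], rate,
        cutoff=cfg["grf_lowpass_hz"], order=cfg["grf_order"],
    )
    wins = signal.segment_steps(
        grf, rate, threshold=cfg["grf_threshold_n"], min_stance=cfg["min_stance_s"]
    )
    steps = []
    for i, w in enumerate(wins):
        per_muscle = {m: signal.stance_mean(v, w) for m, v in envs.items()}
        groups = windows.group_emg(per_muscle)
        steps.append(StepData(w, windows.TrialStepRecord(i, groups, {})))
    return steps


def _with_pct(steps: list[StepData], baseline_means: dict) -> list[StepData]:
    out = []
    for s in steps:
        pct = {
            g: 100.0 * (s.record.group_means[g] - b) / b
            for g, b in baseline_means.items()
            if b > 0 and g in s.record.group_means
        }
        out.append(StepData(s.window, windows.TrialStepRecord(
            s.record.step_index, s.record.group_means, pct)))
    return out


def _model_step(bundle: TrialBundle, w: signal.StanceWindow, cfg: dict) -> dict:
    """Resample one step's modeling channels onto the stance grid."""
    ts = bundle.ts
    n = cfg["stance_grid_n"]
    out = {"angles": {}, "moments": {}}
    for joint in ("hip", "knee", "ankle"):
        ang = signal.lowpass_kinematics(
            ts.channels[f"angle_{joint}"], ts.rate,
            cutoff=cfg["kinematics_lowpass_hz"], order=cfg["kinematics_order"])
        mom = signal.lowpass_kinematics(
            ts.channels[f"moment_{joint}"], ts.rate,
            cutoff=cfg["kinematics_lowpass_hz"], order=cfg["kinematics_order"])
        out["angles"][joint] = signal.resample_stance(ang, w, n)
        out["moments"][joint] = signal.resample_stance(mom, w, n)
    inter = signal.lowpass_grf(
        ts.channels["knee_axial_force"], ts.rate,
        cutoff=cfg["grf_lowpass_hz"], order=cfg["grf_order"])
    out["intersegmental"] = signal.resample_stance(inter, w, n)
    out["duration"] = w.duration
    return out


def _delayed_gastroc_env(bundle: TrialBundle, cfg: dict) -> np.ndarray:
    """Group (medial+lateral mean) normalized gastrocnemius envelope with the
    electromechanical delay applied, on the trial's raw grid."""
    ts, meta = bundle.ts, bundle.meta
    envs = []
    for m in ("medial_gastrocnemius", "lateral_gastrocnemius"):
        ch = f"emg_{m}"
        if ch not in ts.channels:
            continue
        vals = ts.channels[ch]
        if not meta.emg_is_envelope:
            vals = signal.process_emg(
                vals, ts.rate,
                band=tuple(cfg["emg_band_hz"]), band_order=cfg["emg_band_order"],
                lowpass_cut=cfg["emg_lowpass_hz"], lowpass_order=cfg["emg_lowpass_order"])
        envs.append(vals / meta.mvc_values.get(m, 1.0))
    if not envs:
        raise ValueError("no gastrocnemius EMG channel present")
    env = np.mean(envs, axis=0)
    return signal.apply_emg_delay(env, ts.rate, cfg["emg_delay_s"])


def _condition_metrics(curves, cfg):
    early, late, imp = [], [], []
    for c in curves:
        e, l = msk.peak_metrics(c, tuple(cfg["early_peak_window"]),
                                tuple(cfg["late_peak_window"]))
        early.append(e)
        late.append(l)
        imp.append(msk.contact_impulse(c))
    return {
        "early_peak_bw": float(np.mean(early)),
        "late_peak_bw": float(np.mean(late)),
        "impulse_bw_s": float(np.mean(imp)),
    }


def run_participant(pdata, cfg: dict | None = None,
                    model: msk.MskModel | None = None,
                    modeling: bool = True) -> ParticipantResult:
    """Full analysis for one participant's trial bundles.

    ``pdata`` carries ``participant_id``, ``baseline`` (TrialBundle) and
    ``feedback`` (list of TrialBundle). Any stage error is re-raised with
    the stage name and participant id prepended. With ``modeling=False``
    the static-optimization and contact-force stages are skipped (EMG and
    feedback analysis only; metrics come back empty).
    """
    cfg = {**DEFAULTS, **(cfg or {})}
    pid = pdata.participant_id
    t0 = _time.perf_counter()
    stage = "segment"
    try:
        baseline_steps = _trial_steps(pdata.baseline, cfg)
        feedback_steps = [_trial_steps(t, cfg) for t in pdata.feedback]

        stage = "baseline-means"
        if not baseline_steps:
            raise ValueError("no steps detected in baseline trial")
        groups = baseline_steps[0].record.group_means.keys()
        baseline_means = {
            g: float(np.mean([s.record.group_means[g] for s in baseline_steps]))
            for g in groups
        }

        stage = "percent-change"
        baseline_steps = _with_pct(baseline_steps, baseline_means)
        feedback_steps = [_with_pct(ts_, baseline_means) for ts_ in feedback_steps]

        stage = "feedback-replay"
        session = pdata.baseline.meta.session
        rules = fb.SESSION_RULES[session]
        rules = fb.SessionRules(
            session=session, min_trials=rules.min_trials,
            max_trials=rules.max_trials,
            qualification_pct=rules.qualification_pct,
            window=cfg["window_steps"],
        )
        state0 = fb.FeedbackState(baseline_value=baseline_means["gastrocnemius"])
        trial_means = [
            [s.record.group_means["gastrocnemius"] for s in ts_]
            for ts_ in feedback_steps
        ]
        session_log = fb.run_session(trial_means, state0, rules)

        stage = "window-selection"
        w = cfg["window_steps"]
        best_joint = best_gast = None
        sel_trial = gast_trial = 0
        for ti, steps in enumerate(feedback_steps):
            recs = [s.record for s in steps]
            if len(recs) < w:
                continue
            cand = windows.gastroc_vasti_window(recs, w)
            if best_joint is None or cand.objective < best_joint.objective:
                best_joint, sel_trial = cand, ti
            cand_g = windows.best_gastroc_window(recs, w)
            if best_gast is None or cand_g.mean_gastroc_pct < best_gast.mean_gastroc_pct:
                best_gast, gast_trial = cand_g, ti
        if best_joint is None:
            raise ValueError(
                f"no feedback trial contains {w} steps; cannot select a window"
            )
        sel_steps = feedback_steps[sel_trial][best_joint.start:best_joint.stop]
        group_pct = {
            g: float(np.mean([s.record.pct_change[g] for s in sel_steps]))
            for g in sel_steps[0].record.pct_change
        }
        emg_means = {
            "baseline": {f"emg_{g}": baseline_means[g] for g in baseline_means},
            "feedback": {
                f"emg_{g}": float(np.mean([s.record.group_means[g] for s in sel_steps]))
                for g in groups
            },
        }

        stage = "representative-steps"
        k = cfg["representative_k"]
        base_target = baseline_means["gastrocnemius"]
        base_idx = windows.representative_steps(
            [s.record for s in baseline_steps], k, target=base_target)
        win_mean = float(np.mean(
            [s.record.group_means["gastrocnemius"] for s in sel_steps]))
        fb_idx = windows.representative_steps(
            [s.record for s in sel_steps], k, target=win_mean)
        base_rep = [baseline_steps[i] for i in base_idx]
        fb_rep = [s for s in sel_steps if s.record.step_index in fb_idx]

        if not modeling:
            return ParticipantResult(
                participant_id=pid,
                qualified=session_log.qualified,
                session_log=session_log,
                baseline_group_means=baseline_means,
                selected_window=best_joint,
                selected_trial=sel_trial,
                best_gastroc_window=best_gast,
                group_pct=group_pct,
                scale_factor=float("nan"),
                metrics={},
                deltas={},
                emg_means=emg_means,
                mean_curves={},
            )

        stage = "msk-model"
        meta = pdata.baseline.meta
        if meta.body_mass is None or meta.height is None:
            raise ValueError("modeling requires body_mass and height")
        if model is None:
            model = msk.default_model(meta.body_mass, meta.height)

        stage = "baseline-so"
        n_grid = cfg["stance_grid_n"]
        base_env = _delayed_gastroc_env(pdata.baseline, cfg)
        act_means, emg_step_means = [], []
        base_curves = []
        for s in base_rep:
            md = _model_step(pdata.baseline, s.window, cfg)
            sol = msk.solve_static_optimization(
                model, md["moments"], md["angles"],
                reserve_weight=cfg["reserve_weight"])
            act_means.append(float(sol.activation("gastrocnemius").mean()))
            env_grid = signal.resample_stance(base_env, s.window, n_grid)
            emg_step_means.append(float(env_grid.mean()))
            base_curves.append(msk.knee_contact_force(
                model, sol, md["intersegmental"], meta.body_mass, md["duration"]))

        stage = "scale-factor"
        factor = msk.emg_scale_factor(act_means, emg_step_means)

        stage = "feedback-so"
        fb_bundle = pdata.feedback[sel_trial]
        fb_env = _delayed_gastroc_env(fb_bundle, cfg)
        fb_curves = []
        for s in fb_rep:
            md = _model_step(fb_bundle, s.window, cfg)
            constraints = None
            if cfg["constrain_feedback"]:
                env_grid = signal.resample_stance(fb_env, s.window, n_grid)
                constraints = {
                    "gastrocnemius": msk.build_emg_constraints(
                        env_grid, factor, cfg["emg_constraint_tol"])
                }
            sol = msk.solve_static_optimization(
                model, md["moments"], md["angles"],
                emg_constraints=constraints,
                reserve_weight=cfg["reserve_weight"])
            fb_curves.append(msk.knee_contact_force(
                model, sol, md["intersegmental"], meta.body_mass, md["duration"]))

        stage = "metrics"
        metrics = {
            "baseline": _condition_metrics(base_curves, cfg),
            "feedback": _condition_metrics(fb_curves, cfg),
        }
        deltas = {
            key: metrics["feedback"][key] - metrics["baseline"][key]
            for key in metrics["baseline"]
        }
        deltas["late_peak_pct"] = (
            100.0 * deltas["late_peak_bw"] / metrics["baseline"]["late_peak_bw"]
        )
        mean_curves = {
            cond: np.mean([c.values_bw for c in curves], axis=0)
            for cond, curves in (("baseline", base_curves), ("feedback", fb_curves))
        }
    except Exception as exc:
        raise type(exc)(f"[{pid} @ {stage}] {exc}") from exc

    logger.info("participant %s analyzed in %.2f s", pid, _time.perf_counter() - t0)
    return ParticipantResult(
        participant_id=pid,
        qualified=session_log.qualified,
        session_log=session_log,
        baseline_group_means=baseline_means,
        selected_window=best_joint,
        selected_trial=sel_trial,
        best_gastroc_window=best_gast,
        group_pct=group_pct,
        scale_factor=factor,
        metrics=metrics,
        deltas=deltas,
        emg_means=emg_means,
        mean_curves=mean_curves,
    )


@dataclass
class CohortReport:
    n: int
    results: list
    tests: list  # stats.TestResult, primary first
    summary: pd.DataFrame
    mean_gastroc_pct: float
    sd_gastroc_pct: float
    mean_vasti_pct: float
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_gastroc_pct": self.mean_gastroc_pct,
            "sd_gastroc_pct": self.sd_gastroc_pct,
            "mean_vasti_pct": self.mean_vasti_pct,
            "tests": [
                {
                    "outcome": t.outcome, "test": t.test, "statistic": t.statistic,
                    "p": t.p, "p_adj": t.p_adj, "mean_diff": t.mean_diff,
                    "sd_diff": t.sd_diff, "n": t.n,
                }
                for t in self.tests
            ],
            "summary": self.summary.reset_index().to_dict(orient="records"),
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.tests])


def run_cohort(results: list, cfg: dict | None = None) -> CohortReport:
    """Statistics over ParticipantResults.

    With fewer than two participants a descriptive-only report is produced
    (with a warning); otherwise primary outcomes are tested uncorrected and
    exploratory outcomes share one Benjamini-Hochberg family.
    """
    cfg = {**DEFAULTS, **(cfg or {})}
    warnings_list = []
    n = len(results)
    if n < 1:
        raise ValueError("need at least one participant result")

    def paired(outcome):
        if outcome.startswith("emg_"):
            b = [r.emg_means["baseline"][outcome] for r in results]
            f = [r.emg_means["feedback"][outcome] for r in results]
            units = "fraction MVC"
        else:
            b = [r.metrics["baseline"][outcome] for r in results]
            f = [r.metrics["feedback"][outcome] for r in results]
            units = "BW" if outcome.endswith("_bw") else "BW*s"
        return stats.PairedSample(outcome, np.array(b), np.array(f), units)

    tests: list[stats.TestResult] = []
    if n >= 2:
        for outcome in cfg["primary_outcomes"]:
            tests.append(stats.paired_compare(paired(outcome), cfg["alpha"]))
        explor = [
            stats.paired_compare(paired(o), cfg["alpha"])
            for o in cfg["exploratory_outcomes"]
        ]
        valid = [t for t in explor if not np.isnan(t.p)]
        if valid:
            adj = stats.bh_adjust([t.p for t in valid])
            for t, a in zip(valid, adj):
                t.p_adj = float(a)
        tests.extend(explor)
    else:
        warnings_list.append("fewer than 2 participants: descriptive report only")

    changes = pd.DataFrame(
        {
            "late_peak_bw": [r.deltas["late_peak_bw"] for r in results],
            "early_peak_bw": [r.deltas["early_peak_bw"] for r in results],
            "impulse_bw_s": [r.deltas["impulse_bw_s"] for r in results],
            "gastroc_pct": [r.group_pct["gastrocnemius"] for r in results],
            "vasti_pct": [r.group_pct.get("vasti", np.nan) for r in results],
        },
        index=[r.participant_id for r in results],
    )
    summary = stats.cohort_summary(changes)
    g = changes["gastroc_pct"].to_numpy()
    v = changes["vasti_pct"].to_numpy()
    return CohortReport(
        n=n,
        results=results,
        tests=tests,
        summary=summary,
        mean_gastroc_pct=float(g.mean()),
        sd_gastroc_pct=float(g.std(ddof=1)) if n > 1 else float("nan"),
        mean_vasti_pct=float(np.nanmean(v)),
        warnings=warnings_list,
    )
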