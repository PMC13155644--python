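# gaitload

Analysis pipeline for EMG-biofeedback gait retraining aimed at reducing
late-stance knee contact force: raw EMG / ground-reaction processing,
per-step adaptive haptic-feedback logic, 50-step analysis-window selection,
EMG-constrained static optimization on a reduced sagittal-plane
musculoskeletal model, knee contact force metrics (early/late peaks,
impulse), and the paired cohort statistics — plus a synthetic gait-cohort
generator with known ground truth.

## Layout

| module | role |
| --- | --- |
| `gaitload.io` | `.sto/.mot`-dialect and CSV trial time-series I/O, trial bundles |
| `gaitload.signal` | EMG conditioning (bandpass → rectify → low-pass), MVC normalization, GRF/kinematics filtering, step segmentation, stance resampling, electromechanical delay |
| `gaitload.feedback` | per-step vibration coding, adaptive 10→20→30% goal progression, session qualification rules |
| `gaitload.windows` | muscle grouping, best-gastrocnemius / gastrocnemius+vasti 50-step window selection, representative-step picking |
| `gaitload.msk` | reduced 8-muscle sagittal model, per-frame activation-squared static optimization (plain and EMG-constrained), scale-factor calibration, knee contact force and metrics |
| `gaitload.stats` | Shapiro-Wilk-gated paired t / Wilcoxon tests, Benjamini-Hochberg adjustment, noncentral-t power analysis, responder summaries |
| `gaitload.synth` | synthetic cohorts (envelope or raw-EMG mode) with ground-truth reductions |
| `gaitload.pipeline` | per-participant and cohort orchestration |
| `gaitload.cli` | `gaitload` command-line entry point |

## CLI

```bash
# synthesize a cohort of trial bundles (text files + manifest + ground truth)
gaitload simulate --out scratch/cohort --seed 1 --participants 13 --emg-mode envelope

# replay a feedback session from per-step stance means
gaitload feedback steps.csv --baseline 0.2 --session 1 --out log.csv

# analyze one participant / the whole cohort
gaitload analyze scratch/cohort --participant P01 --out p01.json
gaitload cohort scratch/cohort --out report.json

# paired tests on a wide metrics CSV (baseline_*/feedback_* columns)
gaitload stats metrics.csv --out tests.csv
```

Every numeric default (filter orders and cutoffs, 20 N step threshold,
50-step window, 5 representative steps, 40 ms delay, 2% EMG constraint
band, peak windows 15–35% / 65–85%) lives in `gaitload.config.DEFAULTS`
and can be overridden with `--config config.yaml`.

## Notes

- The musculoskeletal model is deliberately reduced (8 lumped muscles,
  constant moment arms, rigid tendons); parameters ship in
  `src/gaitload/data/default_model.yaml`.
- Static optimization solves each frame as a box-constrained linear
  least-squares problem (exact, deterministic); reserve actuators with a
  quadratic penalty guarantee feasibility, and frames where a reserve
  exceeds 5% of the joint moment are flagged.
- Normalized EMG is not clipped at 1 (walking may exceed the MVC reference).
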