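"""Analysis configuration: every numeric default of the pipeline lives here
and can be overridden from a YAML file."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config"]

DEFAULTS: dict = {
    # EMG conditioning
    "emg_band_hz": [30.0, 500.0],  # bandpass edges, 4th-order zero-phase
    "emg_band_order": 4,
    "emg_lowpass_hz": 6.0,  # envelope low-pass, 4th-order zero-phase
    "emg_lowpass_order": 4,
    "emg_delay_s": 0.040,  # electromechanical delay applied before modeling
    # kinematics / GRF filtering (6 Hz zero-phase; orders 6 and 4)
    "kinematics_lowpass_hz": 6.0,
    "kinematics_order": 6,
    "grf_lowpass_hz": 6.0,
    "grf_order": 4,
    # step detection (thresholds are our defaults; not prescribed upstream)
    "grf_threshold_n": 20.0,
    "min_stance_s": 0.3,
    # stance grid and analysis windows
    "stance_grid_n": 101,
    "window_steps": 50,  # moving-average / selection window, steps
    "representative_k": 5,  # steps modeled per condition
    # static optimization
    "emg_constraint_tol": 0.02,  # +/-2% band around scaled gastrocnemius EMG
    "constrain_feedback": True,
    "reserve_weight": 1000.0,
    # contact force metrics: % stance windows for the two peaks
    "early_peak_window": [15.0, 35.0],
    "late_peak_window": [65.0, 85.0],
    # statistics
    "alpha": 0.05,
    "primary_outcomes": ["emg_gastrocnemius", "late_peak_bw"],
    "exploratory_outcomes": [
        "early_peak_bw",
        "impulse_bw_s",
        "emg_soleus",
        "emg_vasti",
        "emg_hamstrings",
        "emg_tibialis_anterior",
        "emg_rectus_femoris",
    ],
}


def load_config(path: str | Path | None = None) -> dict:
    """Deep-copied defaults, optionally overlaid with a YAML file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        overrides = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(overrides, dict):
            raise ValueError("config file must contain a mapping")
        cfg.update(overrides)
    return cfg
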