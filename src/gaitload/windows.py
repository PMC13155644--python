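"""Selection of analyzed 50-step segments and representative steps.

Two window objectives are defined over consecutive-step windows of per-step
percent changes (window mean = arithmetic mean of per-step percent changes):

* greatest gastrocnemius reduction, and
* most negative sum of gastrocnemius and vasti percent changes
  (maximal gastrocnemius reduction while limiting vasti compensation).

Ties break toward the earliest window start; windows never span trial
boundaries (callers select per trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MUSCLE_GROUPS",
    "TrialStepRecord",
    "SelectedWindow",
    "group_emg",
    "best_gastroc_window",
    "gastroc_vasti_window",
    "representative_steps",
]

MUSCLE_GROUPS: dict[str, tuple[str, ...]] = {
    "gastrocnemius": ("medial_gastrocnemius", "lateral_gastrocnemius"),
    "soleus": ("soleus",),
    "vasti": ("vastus_medialis", "vastus_lateralis"),
    "hamstrings": ("biceps_femoris", "semitendinosus"),
    "tibialis_anterior": ("tibialis_anterior",),
    "rectus_femoris": ("rectus_femoris",),
}


@dataclass(frozen=True)
class TrialStepRecord:
    """Per-step stance-mean normalized EMG by muscle group, plus percent
    changes from the baseline-trial group means."""

    step_index: int
    group_means: dict = field(default_factory=dict)
    pct_change: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SelectedWindow:
    """A run of ``size`` consecutive step records, [start, start+size)."""

    start: int  # positional index into the record list
    size: int
    mean_gastroc_pct: float
    mean_vasti_pct: float
    objective: float

    @property
    def stop(self) -> int:
        return self.start + self.size

    def step_indices(self, records) -> list[int]:
        return [records[i].step_index for i in range(self.start, self.stop)]


def group_emg(per_muscle_means: dict, groups: dict | None = None) -> dict:
    """Collapse per-muscle stance means to unweighted per-group means.

    Only groups with at least one member present are returned; requesting a
    group with no members available raises.
    """
    if groups is None:
        groups = {
            g: m for g, m in MUSCLE_GROUPS.items()
            if any(mu in per_muscle_means for mu in m)
        }
    out = {}
    for gname, members in groups.items():
        present = [per_muscle_means[m] for m in members if m in per_muscle_means]
        if not present:
            raise ValueError(f"no member muscles present for group {gname!r}")
        out[gname] = float(np.mean(present))
    return out


def _window_means(values: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(values)))
    return (c[w:] - c[:-w]) / w


def _select(records, w: int, objective_values: np.ndarray) -> SelectedWindow:
    if len(records) < w:
        raise ValueError(f"need at least {w} records, got {len(records)}")
    g = np.array([r.pct_change["gastrocnemius"] for r in records])
    v = np.array([r.pct_change.get("vasti", 0.0) for r in records])
    gm, vm = _window_means(g, w), _window_means(v, w)
    start = int(np.argmin(objective_values))  # argmin -> earliest on ties
    return SelectedWindow(
        start=start,
        size=w,
        mean_gastroc_pct=float(gm[start]),
        mean_vasti_pct=float(vm[start]),
        objective=float(objective_values[start]),
    )


def best_gastroc_window(records, w: int = 50) -> SelectedWindow:
    """Window with the greatest mean gastrocnemius reduction."""
    if len(records) < w:
        raise ValueError(f"need at least {w} records, got {len(records)}")
    g = np.array([r.pct_change["gastrocnemius"] for r in records])
    return _select(records, w, _window_means(g, w))


def gastroc_vasti_window(records, w: int = 50) -> SelectedWindow:
    """Window minimizing mean gastrocnemius %change + mean vasti %change."""
    if len(records) < w:
        raise ValueError(f"need at least {w} records, got {len(records)}")
    g = np.array([r.pct_change["gastrocnemius"] for r in records])
    v = np.array([r.pct_change["vasti"] for r in records])
    return _select(records, w, _window_means(g, w) + _window_means(v, w))


def representative_steps(
    records,
    k: int = 5,
    key: str = "gastrocnemius",
    target: float | None = None,
) -> list[int]:
    """The ``k`` steps whose ``key`` group stance mean is closest to the
    target (default: the mean over the given records), by absolute
    difference; ties break toward the lower step index. Returns step
    indices sorted ascending.
    """
    if k > len(records):
        raise ValueError(f"k={k} exceeds {len(records)} records")
    keys = np.array([r.group_means[key] for r in records])
    idx = np.array([r.step_index for r in records])
    if target is None:
        target = float(keys.mean())
    order = np.lexsort((idx, np.abs(keys - target)))
    return sorted(int(idx[i]) for i in order[:k])
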