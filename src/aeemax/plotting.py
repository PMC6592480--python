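"""Diagnostic plot: per-subject HR vs aEE scatter with the fitted line."""

from __future__ import annotations

import numpy as np

from .features import FeatureSet
from .io import ActivityTrace
from .preprocess import select_activity_minutes


def plot_activity_fit(trace: ActivityTrace, features: FeatureSet, ax=None,
                      smooth_window: int = 5, hr_gate: float = 120.0):
    """Scatter the selected minutes with the regression line and its
    extrapolation to HRmax (the aEEmax construction)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sel, hr_s, aee_s = select_activity_minutes(trace, smooth_window, hr_gate)
    idx = sel.selected_idx
    ax.scatter(hr_s[idx], aee_s[idx], s=8, alpha=0.5, label="selected minutes")
    hr_line = np.linspace(hr_gate, features.hrmax, 50)
    ax.plot(hr_line, features.slope * hr_line + features.intercept,
            color="tab:red", label="fitted line")
    ax.axvline(features.hrmax, ls="--", color="gray", lw=1)
    ax.plot([features.hrmax], [features.aeemax], "k*", ms=12,
            label=f"aEEmax = {features.aeemax:.1f}")
    ax.set_xlabel("heart rate (bpm)")
    ax.set_ylabel("activity energy expenditure (kcal/kg/h)")
    ax.set_title(trace.subject_id)
    ax.legend(fontsize=8)
    return ax
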