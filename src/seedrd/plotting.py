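"""Coverage-profile figures (headless-safe; tables remain the contract).

The per-transcript plot shows the cohort-mean normalized profiles with the
RD areas marked inside the 25-75% analysis window: the area between 100 and
the reference profile (shaded) integrates to RD_ref * L * 100, and the area
between the reference and aged profiles (hatched) to RD_delta * L * 100.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .degradation import analysis_window
from .depth import NormalizedProfile, smooth_moving_window
from .errors import ParameterError

__all__ = ["render_profile_plot"]


def render_profile_plot(
    transcript_id: str,
    profiles: Mapping[str, NormalizedProfile],
    reference_cohort: str,
    aged_cohort: str,
    path: str | Path,
    smoothing_window: int = 100,
    window_fracs: tuple[float, float] = (0.25, 0.75),
) -> Path:
    """Write a per-transcript coverage plot with shaded RD_ref / hatched RD_delta areas."""
    for c in (reference_cohort, aged_cohort):
        if c not in profiles:
            raise ParameterError(
                f"no profile for cohort {c!r} of transcript {transcript_id!r}"
            )
    ref = profiles[reference_cohort].values
    aged = profiles[aged_cohort].values
    L = ref.shape[0]
    win = analysis_window(L, *window_fracs, transcript_id=transcript_id)
    x = np.arange(1, L + 1)
    ref_s = smooth_moving_window(ref, smoothing_window)
    aged_s = smooth_moving_window(aged, smoothing_window)

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(x, ref_s, color="forestgreen", label=reference_cohort)
    ax.plot(x, aged_s, color="darkorange", linestyle="--", label=aged_cohort)
    sel = (x >= win.start) & (x <= win.end)
    ax.fill_between(
        x[sel], ref_s[sel], 100.0, color="forestgreen", alpha=0.2, label="RD_ref area"
    )
    ax.fill_between(
        x[sel],
        aged_s[sel],
        ref_s[sel],
        facecolor="none",
        edgecolor="darkorange",
        hatch="///",
        linewidth=0,
        label="RD_delta area",
    )
    ax.axvline(win.start, color="grey", linewidth=0.5)
    ax.axvline(win.end, color="grey", linewidth=0.5)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("normalized depth")
    ax.set_ylim(0, 105)
    ax.set_title(transcript_id)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
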