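"""Matplotlib conveniences for meta-profiles and footprints."""
from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .footprints import Footprint
from .profiles import MetaProfile

# stage colours in the conventional early-blue / late-red / 8C-brown scheme
STAGE_COLORS = {"early2C": "#2166ac", "late2C": "#b2182b", "8C": "#8c510a"}

__all__ = ["plot_meta_profiles"]


def plot_meta_profiles(
    profiles: Mapping[str, MetaProfile],
    footprints: Sequence[Footprint] = (),
    ax: "plt.Axes | None" = None,
    smooth_window: int = 3,
):
    """Overlay per-stage insertion-frequency curves with footprint shading.

    Returns the axes; callers save or show the figure themselves.
    """
    from .profiles import smooth_profile

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    family = None
    for stage, prof in profiles.items():
        family = prof.family
        y = smooth_profile(prof.per_million, smooth_window)
        ax.plot(y, label=stage, color=STAGE_COLORS.get(stage), lw=1.2)
    for fp in footprints:
        ax.axvspan(fp.start, fp.end, color="0.85", zorder=0)
        ax.annotate(str(fp.index), ((fp.start + fp.end) / 2, 0),
                    ha="center", va="bottom", fontsize=8)
    ax.set_xlabel("consensus position (bp)")
    ax.set_ylabel("insertions per million")
    if family:
        ax.set_title(family)
    ax.legend(frameon=False, fontsize=8)
    return ax
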