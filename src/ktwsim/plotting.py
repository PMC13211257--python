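"""Figure panels: abundance and Hill-number dynamics over time.

Purely presentational — all quantities are read off the trajectory
table.  Active-surveillance windows are drawn as shaded spans.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; figures are written to files
import matplotlib.pyplot as plt
import pandas as pd


def plot_panels(
    trajectories: pd.DataFrame | Sequence[pd.DataFrame],
    path: str | Path,
    windows: Iterable[tuple[int, int]] = (),
    titles: Sequence[str] | None = None,
) -> Path:
    """Plot abundance and Hill-number panels for one or more trajectories.

    Each trajectory gets a row of two panels: per-species counts over
    time, and Hill numbers (q = 0, 1, 2) over time.  ``windows`` are
    shaded as active-surveillance spans on every panel.  Returns the
    written figure path.
    """
    if isinstance(trajectories, pd.DataFrame):
        trajectories = [trajectories]
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("no trajectories to plot")
    for traj in trajectories:
        if len(traj) == 0:
            raise ValueError("trajectory is empty")
    steps0 = trajectories[0]["step"]
    for traj in trajectories[1:]:
        if len(traj) != len(steps0):
            raise ValueError("trajectories must share the same step range")

    n_rows = len(trajectories)
    fig, axes = plt.subplots(
        n_rows, 2, figsize=(10, 3 * n_rows), squeeze=False, sharex=True
    )
    windows = list(windows)
    for r, traj in enumerate(trajectories):
        ax_ab, ax_hill = axes[r]
        count_cols = [c for c in traj.columns if c.startswith("count_")]
        for col in count_cols:
            ax_ab.plot(traj["step"], traj[col], label=f"species {col.split('_')[1]}")
        ax_ab.set_ylabel("cells")
        ax_ab.legend(fontsize="x-small", ncol=2)
        for q in (0, 1, 2):
            col = f"hill_q{q}"
            if col in traj.columns:
                ax_hill.plot(traj["step"], traj[col], label=f"q = {q}")
        ax_hill.set_ylabel("Hill diversity")
        ax_hill.legend(fontsize="x-small")
        if titles is not None:
            ax_ab.set_title(titles[r], fontsize="small", loc="left")
        for ax in (ax_ab, ax_hill):
            for start, end in windows:
                ax.axvspan(start, end, color="0.85", zorder=0)
    axes[-1][0].set_xlabel("step")
    axes[-1][1].set_xlabel("step")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
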