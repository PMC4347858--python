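"""Prevalence-trajectory figures in the style of the published scenarios."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .dynamics import Trajectory

__all__ = ["plot_trajectories", "plot_fig6_panels"]

# no horizontal transmission in blue; low rate dashed orange, moderate solid
_STYLE = {0.0: ("tab:blue", "-"), 0.01: ("tab:orange", "--"), 0.06: ("tab:orange", "-")}


def _line_style(w: float):
    return _STYLE.get(round(w, 6), ("tab:gray", "-"))


def plot_trajectories(trajectories: dict[float, Trajectory], ax=None, title=None):
    """Plot prevalence against generation for one scenario panel."""
    if not trajectories:
        raise ValueError("no trajectories to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    for w, traj in sorted(trajectories.items()):
        color, ls = _line_style(w)
        ax.plot(range(traj.p.size), traj.p, color=color, linestyle=ls,
                label=f"w = {w:g}")
    ax.set_xlabel("generation")
    ax.set_ylabel("prevalence")
    ax.set_ylim(0.0, 1.0)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_fig6_panels(
    panels: dict[str, dict[float, Trajectory]],
    out_stem: str | Path | None = None,
    formats: tuple[str, ...] = ("pdf", "png"),
) -> list[Path]:
    """Multi-panel scenario figure; writes one file per requested format.

    ``panels`` maps a panel label to its w -> Trajectory mapping.  Returns
    the written file paths (empty if ``out_stem`` is None).
    """
    if not panels:
        raise ValueError("no panels to plot")
    n = len(panels)
    fig, axes = plt.subplots(1, n, figsize=(4.0 * n, 3.2), squeeze=False)
    for ax, (label, trajs) in zip(axes[0], sorted(panels.items())):
        plot_trajectories(trajs, ax=ax, title=f"panel {label}")
    fig.tight_layout()
    written: list[Path] = []
    if out_stem is not None:
        out_stem = Path(out_stem)
        for fmt in formats:
            path = out_stem.with_suffix(f".{fmt}")
            fig.savefig(path, dpi=150)
            written.append(path)
    plt.close(fig)
    return written
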