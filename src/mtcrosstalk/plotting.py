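"""Static rendering of runs and device geometries (no live GUI)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np

from .environment import Environment
from .io import read_snapshot, read_track

__all__ = ["draw_environment", "draw_state", "plot_run"]


def draw_environment(env: Environment, ax) -> None:
    """Draw obstacles and walls onto a matplotlib axes."""
    for (cx, cy, R) in env.obstacles:
        ax.add_patch(matplotlib.patches.Circle((cx, cy), R, color="0.75"))
    for (ax1, ay1, bx1, by1, hw) in env.walls:
        ax.plot([ax1, bx1], [ay1, by1], color="0.6", lw=4, alpha=0.8,
                solid_capstyle="round")


def draw_state(state, ax, mt_alpha: float = 0.4) -> None:
    """Draw membrane, nucleus, centrosome and microtubules."""
    mem = np.vstack([state.membrane.pos, state.membrane.pos[:1]])
    nuc = np.vstack([state.nucleus.pos, state.nucleus.pos[:1]])
    ax.plot(mem[:, 0], mem[:, 1], "k-", lw=1.2)
    ax.plot(nuc[:, 0], nuc[:, 1], "b-", lw=1.2)
    for m in range(state.mts.N):
        nb = int(state.mts.n_beads[m])
        chain = state.mts.pos[m, :nb]
        color = "green" if state.mts.state[m] else "red"
        ax.plot(chain[:, 0], chain[:, 1], "-", lw=0.5, color=color,
                alpha=mt_alpha)
    ax.plot(*state.centrosome, "r*", ms=12)


def plot_run(run_dir, out_path=None):
    """Render a run directory (trajectory, final state, geometry) to PNG.

    Returns the matplotlib figure; writes ``<run_dir>/summary.png`` unless
    ``out_path`` is given.
    """
    run_dir = Path(run_dir)
    track = read_track(run_dir / "track.csv")
    env = Environment.from_json((run_dir / "env.json").read_text())
    state = read_snapshot(run_dir / "final_snapshot.json")

    fig, ax = plt.subplots(figsize=(7, 7))
    draw_environment(env, ax)
    draw_state(state, ax)
    ax.plot(track["x"], track["y"], "m-", lw=1.5, label="centroid track")
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.legend(loc="upper right")
    ax.set_title(f"{env.name}: t = {track['t'].iloc[-1]:.0f} s")
    out = Path(out_path) if out_path else run_dir / "summary.png"
    fig.savefig(out, dpi=110, bbox_inches="tight")
    return fig
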