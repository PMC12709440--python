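"""Prepackaged study conditions: free migration, obstacle parks, and
channel-device path choice.

These helpers bundle the environment, start position and run control for
the conditions the model is exercised under, so the same code path serves
the examples, the acceptance script and the test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import fit_msd_exponent, msd
from .engine import Simulation
from .environment import (Environment, build_multichannel,
                          build_obstacle_park, build_y_junction,
                          channel_entry_check)
from .params import Params
from .state import CellState, make_initial_state

__all__ = [
    "free_run", "obstacle_park_run", "channel_run", "y_junction_env",
    "multichannel_env", "averaged_msd_exponent", "central_decade",
    "shift_state",
]


def shift_state(state: CellState, offset) -> CellState:
    """Translate the whole cell (in place) by ``offset``."""
    offset = np.asarray(offset, dtype=float)
    state.membrane.pos += offset
    state.nucleus.pos += offset
    state.centrosome += offset
    state.mts.pos[:, :, :] += offset
    return state


def free_run(lmt: float, Nmt: int, seed: int, t_total: float = 1800.0,
             **overrides) -> pd.DataFrame:
    """Free-space migration at a given mean MT length and count."""
    p = Params(lmt_target=lmt, Nmt=Nmt, seed=seed, t_total=t_total,
               **overrides)
    sim = Simulation(p)
    return sim.run()


def obstacle_park_run(lmt: float, Nmt: int, seed: int, Robs: float = 4.0,
                      spacing: float = 20.0, extent: float = 200.0,
                      t_total: float = 1800.0, **overrides) -> pd.DataFrame:
    """Migration in a square pillar lattice, starting at a lattice-cell
    center far from the park boundary."""
    p = Params(lmt_target=lmt, Nmt=Nmt, seed=seed, t_total=t_total,
               **overrides)
    env = build_obstacle_park(Robs, spacing, extent)
    sim = Simulation(p, env)
    return sim.run()


def y_junction_env(w_left: float = 10.0, w_right: float = 10.0) -> Environment:
    """Y-junction with a 16-um loading stem narrowing into the two arms."""
    return build_y_junction(w_left=w_left, w_right=w_right, stem_w=16.0,
                            stem_len=30.0)


def multichannel_env(widths=(2.0, 4.0, 6.0, 8.0)) -> Environment:
    """Feeder chamber fanning into parallel channels of the given widths."""
    return build_multichannel(widths, feeder_len=30.0, pitch=9.0)


def channel_run(env: Environment, lmt: float, Nmt: int, seed: int,
                t_max: float = 3000.0, v_chemo: float = 0.1,
                start=(-12.0, 0.0), **overrides
                ) -> tuple[str | None, float, pd.DataFrame]:
    """Drive a cell through a channel device under chemotactic bias.

    Runs until the whole-cell entry criterion fires for some channel or
    ``t_max`` is reached.  Returns ``(channel_id_or_None, entry_time,
    track)``; the entry time is NaN for censored runs.
    """
    p = Params(lmt_target=lmt, Nmt=Nmt, seed=seed, v_chemo=v_chemo,
               t_total=t_max, **overrides)
    state = shift_state(make_initial_state(p), start)
    sim = Simulation(p, env, state)
    rows = [sim.record_row()]
    spc = sim.steps_per_chunk
    n_chunks = int(round(t_max / p.record_every))
    entry, t_entry = None, float("nan")
    for _ in range(n_chunks):
        sim.advance(spc)
        rows.append(sim.record_row())
        entry = channel_entry_check(sim.state, env)
        if entry is not None:
            t_entry = sim.state.t
            break
    from .engine import TRACK_COLUMNS
    return entry, t_entry, pd.DataFrame(rows, columns=TRACK_COLUMNS)


def central_decade(tau: np.ndarray) -> tuple[float, float]:
    """One-decade fit window centered (geometrically) in the lag range."""
    lo = float(np.min(tau))
    hi = float(np.max(tau))
    start = lo * (hi / lo) ** 0.25
    return start, min(10.0 * start, hi)


def averaged_msd_exponent(tracks: list[pd.DataFrame]) -> float:
    """Log-log slope of the run-averaged time-averaged MSD over the
    central lag decade."""
    tables = [msd(t) for t in tracks]
    lags = tables[0]["tau"].to_numpy()
    mean_msd = np.mean([t["msd"].to_numpy() for t in tables], axis=0)
    avg = pd.DataFrame({"tau": lags, "msd": mean_msd})
    alpha, _ = fit_msd_exponent(avg, tau_range=central_decade(lags))
    return alpha
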