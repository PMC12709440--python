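"""Synthetic trajectory fixtures with known statistics.

Generators for the analysis tests and the ``fixtures`` CLI subcommand:
ballistic tracks (MSD exponent exactly 2), isotropic random walks
(exponent 1), constant-speed worm-like-chain paths with a prescribed
tangent-correlation persistence length, and piecewise tracks alternating
ballistic and diffusive segments with known labels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ballistic_track", "brownian_track", "wlc_track",
           "piecewise_track"]


def _frame(xy: np.ndarray, dt: float) -> pd.DataFrame:
    t = np.arange(len(xy)) * dt
    return pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1]})


def ballistic_track(n: int = 500, speed: float = 0.05, dt: float = 5.0,
                    direction: float = 0.3) -> pd.DataFrame:
    """Straight constant-velocity path: MSD = (v tau)^2."""
    u = np.array([np.cos(direction), np.sin(direction)])
    xy = np.arange(n)[:, None] * (speed * dt) * u
    return _frame(xy, dt)


def brownian_track(n: int = 2000, step: float = 0.25, dt: float = 5.0,
                   seed: int = 0) -> pd.DataFrame:
    """Isotropic Gaussian random walk: MSD = 2 step^2 (tau/dt)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    inc = rng.normal(0.0, step, size=(n - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(inc, axis=0)])
    return _frame(xy, dt)


def wlc_track(n: int = 10000, step: float = 0.25, lp: float = 30.0,
              dt: float = 5.0, seed: int = 0) -> pd.DataFrame:
    """Constant-speed worm-like-chain path.

    Heading increments are Gaussian with variance ``2 * step / lp`` per
    step, giving a tangent correlation ``<cos dtheta(s)> = exp(-s / lp)``
    with decay length exactly ``lp`` along the contour.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    dth = rng.normal(0.0, np.sqrt(2.0 * step / lp), size=n - 1)
    th = np.concatenate([[0.0], np.cumsum(dth)])[:-1]
    inc = step * np.column_stack([np.cos(th), np.sin(th)])
    xy = np.vstack([[0.0, 0.0], np.cumsum(inc, axis=0)])
    return _frame(xy, dt)


def piecewise_track(n_segments: int = 6, seg_frames: int = 60,
                    speed: float = 0.05, step: float = 0.02, dt: float = 5.0,
                    seed: int = 0) -> tuple[pd.DataFrame, list[bool]]:
    """Alternating ballistic / diffusive segments with known labels.

    Returns ``(track, labels)`` where ``labels[k]`` is True for ballistic
    segments.  Segment length ``seg_frames * dt`` is chosen to match the
    300-s classification window at the default cadence.
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    xy = [np.zeros(2)]
    labels = []
    for k in range(n_segments):
        ballistic = k % 2 == 0
        labels.append(ballistic)
        if ballistic:
            ang = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(ang), np.sin(ang)])
            for _ in range(seg_frames):
                xy.append(xy[-1] + speed * dt * u)
        else:
            for _ in range(seg_frames):
                xy.append(xy[-1] + rng.normal(0.0, step, 2))
    return _frame(np.array(xy), dt), labels
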