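"""Trajectory, polarity, morphology and path-choice statistics.

All estimators are pure functions of the recorded track table (or of a
final state for shape metrics), so any analysis is bit-reproducible from
the run directory.

Conventions: tracks are uniformly sampled; velocities are central
differences at the recording cadence; the anomalous exponent alpha is the
log-log slope of the time-averaged mean-square displacement (MSD) against
lag; a migration window is classified *directed* when ``alpha > 1.7`` and
the circular standard deviation of its velocity angles is below 0.9 rad,
evaluated on non-overlapping 300-s windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SegmentClassification", "msd", "fit_msd_exponent", "local_alpha",
    "persistence_length", "polarity_angle", "morphology",
    "channel_choice_stats", "ALPHA_DIRECTED", "DPHI_DIRECTED",
]

#: directed-migration thresholds on the local MSD exponent and the circular
#: standard deviation of the velocity angle
ALPHA_DIRECTED = 1.7
DPHI_DIRECTED = 0.9


def _xy(track) -> np.ndarray:
    if isinstance(track, pd.DataFrame):
        return track[["x", "y"]].to_numpy(dtype=float)
    return np.asarray(track, dtype=float)


def _dt_of(track) -> float:
    t = track["t"].to_numpy(dtype=float)
    dts = np.diff(t)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6):
        raise ValueError("track is not uniformly sampled")
    return float(dts[0]) if len(dts) else 1.0


def msd(track, lags: np.ndarray | None = None) -> pd.DataFrame:
    """Time-averaged mean-square displacement.

    ``MSD(tau) = < |r(t + tau) - r(t)|^2 >_t`` over all admissible start
    frames.  ``lags`` are integer frame lags (default: 1 .. n/2).
    Returns a DataFrame with columns ``lag`` (frames), ``tau`` (s, if the
    track has a time column) and ``msd``.
    """
    xy = _xy(track)
    n = len(xy)
    if lags is None:
        lags = np.arange(1, max(n // 2, 2))
    lags = np.asarray(lags, dtype=int)
    lags = lags[(lags >= 1) & (lags < n)]
    vals = np.empty(len(lags))
    for k, lag in enumerate(lags):
        d = xy[lag:] - xy[:-lag]
        vals[k] = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
    out = pd.DataFrame({"lag": lags, "msd": vals})
    if isinstance(track, pd.DataFrame) and "t" in track:
        out["tau"] = lags * _dt_of(track)
    return out


def fit_msd_exponent(msd_table: pd.DataFrame,
                     tau_range: tuple[float, float] | None = None
                     ) -> tuple[float, float]:
    """Least-squares log-log slope of MSD vs lag: returns (alpha, log A).

    Zero MSD values are excluded; ``tau_range`` restricts the fit window
    (in the same units as the ``tau``/``lag`` column used).
    """
    tau = (msd_table["tau"] if "tau" in msd_table else msd_table["lag"]
           ).to_numpy(dtype=float)
    m = msd_table["msd"].to_numpy(dtype=float)
    ok = m > 0
    if tau_range is not None:
        ok &= (tau >= tau_range[0]) & (tau <= tau_range[1])
    if ok.sum() < 2:
        return float("nan"), float("nan")
    coeffs = np.polyfit(np.log(tau[ok]), np.log(m[ok]), 1)
    return float(coeffs[0]), float(coeffs[1])


def _circular_std(angles: np.ndarray) -> float:
    """sqrt(-2 ln Rbar): standard directional dispersion, bounded behavior
    at high dispersion."""
    if len(angles) == 0:
        return float("nan")
    rbar = float(np.hypot(np.mean(np.cos(angles)), np.mean(np.sin(angles))))
    rbar = min(max(rbar, 1e-12), 1.0)
    return float(np.sqrt(-2.0 * np.log(rbar)))


@dataclass
class SegmentClassification:
    """Local-MSD classification of one analysis window."""

    t_start: float
    alpha: float
    log_A: float
    dphi: float
    directed: bool
    flagged: bool = False   # zero-displacement window: alpha undefined


def local_alpha(track: pd.DataFrame, window: float = 300.0,
                lag_fraction: float = 1.0 / 3.0
                ) -> list[SegmentClassification]:
    """Local MSD scaling in non-overlapping windows.

    Within each window of length ``window`` seconds the local MSD
    ``dR^2(t_i, tau_k) = A tau_k^alpha`` is fitted over lags from one
    recording interval to ``window * lag_fraction``; ``dphi`` is the
    circular standard deviation of the frame-to-frame velocity angles in
    the window.  A window is *directed* iff ``alpha > 1.7`` and
    ``dphi < 0.9``.
    """
    dt = _dt_of(track)
    xy = _xy(track)
    per = int(round(window / dt))
    if per < 10:
        raise ValueError("window must contain at least 10 samples")
    max_lag = max(int(per * lag_fraction), 2)
    out = []
    for start in range(0, len(xy) - per + 1, per):
        seg = xy[start:start + per]
        sub = pd.DataFrame({"x": seg[:, 0], "y": seg[:, 1],
                            "t": np.arange(per) * dt})
        table = msd(sub, np.arange(1, max_lag + 1))
        v = np.diff(seg, axis=0)
        moving = np.hypot(v[:, 0], v[:, 1]) > 0
        dphi = _circular_std(np.arctan2(v[moving, 1], v[moving, 0]))
        if np.all(table["msd"].to_numpy() == 0.0):
            out.append(SegmentClassification(start * dt, float("nan"),
                                             float("nan"), dphi, False,
                                             flagged=True))
            continue
        alpha, logA = fit_msd_exponent(table)
        directed = bool(alpha > ALPHA_DIRECTED and dphi < DPHI_DIRECTED)
        out.append(SegmentClassification(start * dt, alpha, logA, dphi,
                                         directed))
    return out


def persistence_length(track, min_step: float = 1e-6
                       ) -> tuple[float, bool]:
    """Tangent-correlation persistence length of the centroid path.

    Fits ``<cos dtheta(s)> = exp(-s / Lp)`` against contour distance s
    along the path.  Returns ``(Lp, bounded)``; ``bounded`` is True when
    the correlation does not decay below 1/e within the path, in which case
    Lp is reported as a lower bound equal to the contour length.
    """
    xy = _xy(track)
    seg = np.diff(xy, axis=0)
    ln = np.hypot(seg[:, 0], seg[:, 1])
    keep = ln > min_step
    seg, ln = seg[keep], ln[keep]
    n = len(seg)
    if n < 3:
        return float(np.sum(ln)), True
    th = np.arctan2(seg[:, 1], seg[:, 0])
    mean_step = float(np.mean(ln))
    contour = float(np.sum(ln))
    max_k = n - 1
    ks = np.arange(1, max_k + 1)
    corr = np.empty(len(ks))
    for i, k in enumerate(ks):
        corr[i] = np.mean(np.cos(th[k:] - th[:-k]))
    s = ks * mean_step
    # weighted fit over the initial, well-resolved part of the decay: the
    # contiguous prefix with C > 0.35 (the noisy large-lag tail has few
    # effective samples and can fluctuate back above any threshold);
    # C^2 weights further downweight the decayed end of the window
    below = np.flatnonzero(corr <= 0.35)
    stop = int(below[0]) if len(below) else len(corr)
    if stop < 2:
        return mean_step, False
    sw, cw = s[:stop], corr[:stop]
    slope = np.polyfit(sw, np.log(cw), 1, w=cw ** 2)[0]
    if slope >= 0:
        return contour, True   # non-decaying: report the path length bound
    lp = -1.0 / slope
    if lp > contour:
        return contour, True
    return float(lp), False


def polarity_angle(track: pd.DataFrame, v_floor: float = 1e-3
                   ) -> np.ndarray:
    """Angle theta (degrees) between centroid velocity and the
    nucleus-to-centrosome axis, per admissible frame.

    Velocity is the central difference of the centroid; frames slower than
    ``v_floor`` (um/s) are excluded.  theta < 90 deg means the centrosome
    leads the nucleus in the direction of motion.
    """
    dt = _dt_of(track)
    xy = _xy(track)
    v = (xy[2:] - xy[:-2]) / (2 * dt)
    axis = (track[["cen_x", "cen_y"]].to_numpy()
            - track[["nuc_x", "nuc_y"]].to_numpy())[1:-1]
    speed = np.hypot(v[:, 0], v[:, 1])
    an = np.hypot(axis[:, 0], axis[:, 1])
    ok = (speed > v_floor) & (an > 1e-9)
    cosang = np.clip(np.sum(v[ok] * axis[ok], axis=1)
                     / (speed[ok] * an[ok]), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def morphology(membrane_pos: np.ndarray, nucleus_pos: np.ndarray,
               centrosome: np.ndarray, Rcell: float) -> dict:
    """Shape metrics of a configuration.

    area by the shoelace formula; ``area_ratio`` relative to the initial
    area ``pi Rcell^2``; aspect ratio from the membrane-bead gyration
    tensor; distances of the nucleus center and the centrosome from the
    cell centroid.
    """
    from .engine import gyration_aspect_ratio
    from .state import polygon_area

    centroid = membrane_pos.mean(axis=0)
    nuc_c = nucleus_pos.mean(axis=0)
    return {
        "area": abs(polygon_area(membrane_pos)),
        "area_ratio": abs(polygon_area(membrane_pos)) / (np.pi * Rcell ** 2),
        "aspect_ratio": gyration_aspect_ratio(membrane_pos),
        "d_nuc_center": float(np.hypot(*(nuc_c - centroid))),
        "d_cen_center": float(np.hypot(*(np.asarray(centrosome) - centroid))),
    }


def channel_choice_stats(entries: list[tuple[str | None, float]]
                         ) -> pd.DataFrame:
    """Per-channel entry fractions and entry-time statistics.

    ``entries`` holds one ``(channel_id_or_None, entry_time)`` pair per run
    (time ignored for non-entrants).  Runs that never entered are reported
    under the id ``"censored"``.  Fractions over all rows sum to 1.
    """
    total = len(entries)
    ids = sorted({e[0] for e in entries if e[0] is not None})
    rows = []
    for cid in ids:
        times = np.array([t for c, t in entries if c == cid], dtype=float)
        rows.append({"channel": cid, "n": len(times),
                     "fraction": len(times) / total,
                     "mean_entry_time": float(times.mean()),
                     "sd_entry_time": float(times.std(ddof=1))
                     if len(times) > 1 else float("nan")})
    n_cens = sum(1 for c, _ in entries if c is None)
    rows.append({"channel": "censored", "n": n_cens,
                 "fraction": n_cens / total,
                 "mean_entry_time": float("nan"),
                 "sd_entry_time": float("nan")})
    return pd.DataFrame(rows)
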