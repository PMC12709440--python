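"""Snapshots, track tables, configuration echo, and run directories.

Snapshots are JSON (schema-versioned) and round-trip the full state
bit-exactly: Python's float repr is exact for float64, and the PCG64
bit-generator states are plain integers.  Track tables are CSV with one row
per recorded frame (see :data:`mtcrosstalk.engine.TRACK_COLUMNS`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .environment import Environment
from .engine import Simulation
from .params import DyneinParams, Params, PROVENANCE
from .state import BeadLoop, CellState, MotorState, MTEnsemble

SNAPSHOT_SCHEMA = 1

__all__ = [
    "write_snapshot", "read_snapshot", "write_track", "read_track",
    "params_to_yaml", "params_from_yaml", "run_to_dir",
]


class SnapshotError(RuntimeError):
    pass


def _arr(a: np.ndarray) -> list:
    return a.tolist()


def write_snapshot(state: CellState, path) -> None:
    d = {
        "schema": SNAPSHOT_SCHEMA,
        "t": state.t,
        "membrane": {"pos": _arr(state.membrane.pos),
                     "rest_bond": state.membrane.rest_bond,
                     "rest_angle": state.membrane.rest_angle},
        "nucleus": {"pos": _arr(state.nucleus.pos),
                    "rest_bond": state.nucleus.rest_bond,
                    "rest_angle": state.nucleus.rest_angle},
        "centrosome": _arr(state.centrosome),
        "mts": {"pos": _arr(state.mts.pos),
                "n_beads": _arr(state.mts.n_beads),
                "state": _arr(state.mts.state),
                "partial": _arr(state.mts.partial),
                "direction": _arr(state.mts.direction),
                "era": _arr(state.mts.era)},
        "motors": {"anchor_loop": _arr(state.motors.anchor_loop),
                   "anchor_bead": _arr(state.motors.anchor_bead),
                   "bound": state.motors.bound.astype(int).tolist(),
                   "mt_index": _arr(state.motors.mt_index),
                   "arc_pos": _arr(state.motors.arc_pos)},
        "rng_state": state.rng_state,
        "signal_grow": None if state.signal_grow is None
        else _arr(state.signal_grow),
        "signal_shrink": None if state.signal_shrink is None
        else _arr(state.signal_shrink),
    }
    Path(path).write_text(json.dumps(d))


def read_snapshot(path) -> CellState:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SnapshotError(f"corrupt snapshot file {path}: {e}") from e
    if not isinstance(d, dict) or "schema" not in d:
        raise SnapshotError(f"{path} is not a snapshot file")
    if d["schema"] != SNAPSHOT_SCHEMA:
        raise SnapshotError(
            f"snapshot schema {d['schema']} unsupported "
            f"(expected {SNAPSHOT_SCHEMA})")

    def rng_fix(s):
        # JSON round-trips dict keys and big ints fine; states are nested
        # dicts of ints/strs already
        return s

    mts = d["mts"]
    mo = d["motors"]
    return CellState(
        membrane=BeadLoop(np.array(d["membrane"]["pos"]),
                          d["membrane"]["rest_bond"],
                          d["membrane"]["rest_angle"]),
        nucleus=BeadLoop(np.array(d["nucleus"]["pos"]),
                         d["nucleus"]["rest_bond"],
                         d["nucleus"]["rest_angle"]),
        centrosome=np.array(d["centrosome"]),
        mts=MTEnsemble(np.array(mts["pos"]),
                       np.array(mts["n_beads"], dtype=np.int64),
                       np.array(mts["state"], dtype=np.int64),
                       np.array(mts["partial"]),
                       np.array(mts["direction"]),
                       np.array(mts["era"], dtype=np.int64)),
        motors=MotorState(np.array(mo["anchor_loop"], dtype=np.int64),
                          np.array(mo["anchor_bead"], dtype=np.int64),
                          np.array(mo["bound"], dtype=bool),
                          np.array(mo["mt_index"], dtype=np.int64),
                          np.array(mo["arc_pos"])),
        t=d["t"],
        rng_state=rng_fix(d["rng_state"]),
        signal_grow=None if d["signal_grow"] is None
        else np.array(d["signal_grow"]),
        signal_shrink=None if d["signal_shrink"] is None
        else np.array(d["signal_shrink"]),
    )


def write_track(track: pd.DataFrame, path) -> None:
    track.to_csv(path, index=False)


def read_track(path) -> pd.DataFrame:
    return pd.read_csv(path)


# --------------------------------------------------------------------------
# configuration (key = value structured text via YAML)
# --------------------------------------------------------------------------

def params_to_yaml(params: Params, path=None) -> str:
    text = yaml.safe_dump(params.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_yaml(src) -> Params:
    """Load parameters from YAML text or a file path; omitted keys take
    the registered defaults."""
    text = str(src)
    if "\n" not in text:
        p = Path(text)
        if p.exists():
            text = p.read_text()
    d = yaml.safe_load(text) or {}
    return Params.from_dict(d)


# --------------------------------------------------------------------------
# run directories
# --------------------------------------------------------------------------

def run_to_dir(params: Params, outdir, env: Environment | None = None
               ) -> Path:
    """Run a simulation and write a self-describing run directory.

    Contents: ``track.csv`` (frame table), ``final_snapshot.json``,
    ``env.json`` (geometry, redrawable), ``config.yaml`` (full parameter
    echo for provenance), ``run.log``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    env = env if env is not None else Environment.empty()

    log = logging.getLogger(f"mtcrosstalk.run.{outdir.name}")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        params_to_yaml(params, outdir / "config.yaml")
        (outdir / "env.json").write_text(env.to_json())
        log.info("environment: %s", env.name)
        log.info("parameter provenance: %s",
                 json.dumps(PROVENANCE, indent=0).replace("\n", " "))
        sim = Simulation(params, env)
        log.info("starting run: t_total=%s s, dt=%s s, Nmt=%d",
                 params.t_total, params.dt, params.Nmt)
        track = sim.run()
        write_track(track, outdir / "track.csv")
        write_snapshot(sim.state, outdir / "final_snapshot.json")
        log.info("finished at t=%.1f s, %d frames", sim.state.t, len(track))
    except Exception:
        log.exception("run failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
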