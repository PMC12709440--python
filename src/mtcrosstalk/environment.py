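"""Static confinement geometries and the chemotactic forward bias.

Environments are collections of circular obstacles and thick wall segments.
Both repel beads through the same WCA force family as bead-bead sterics,
applied to the gap between the bead and the surface with the repulsion
onset effectively at the surface (the force vanishes once the gap exceeds
``(2^(1/6) - 1) * sigma_mt`` ~ 0.06 um).

Device builders are pure: the same arguments always produce the same
obstacle/wall sets.  Channel devices carry labeled mouth lines so that
entries can be scored by the whole-cell 5-um rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .params import Params
from .state import CellState

__all__ = [
    "Channel", "Environment", "build_obstacle_park", "build_y_junction",
    "build_multichannel", "channel_entry_check", "chemotactic_bias",
    "signed_distance",
]

#: whole-cell channel-entry depth (um): every membrane bead must be at
#: least this far past the channel mouth.
ENTRY_DEPTH = 5.0


@dataclass
class Channel:
    """Labeled channel: mouth line plus axis frame for entry scoring."""

    id: str
    width: float            # um
    mouth: np.ndarray       # (2,) a point on the mouth line
    axis: np.ndarray        # (2,) unit vector pointing into the channel
    half_width: float       # um, lateral half-extent measured from mouth


@dataclass
class Environment:
    """Static geometry (obstacles, walls) plus the chemotactic direction."""

    obstacles: list = field(default_factory=list)   # [(cx, cy, R), ...]
    walls: list = field(default_factory=list)       # [(ax, ay, bx, by, halfw)]
    channels: list = field(default_factory=list)    # [Channel, ...]
    v_chemo_dir: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0]))
    name: str = "free"

    @classmethod
    def empty(cls) -> "Environment":
        return cls(name="free")

    def obstacle_array(self) -> np.ndarray:
        if not self.obstacles:
            return np.zeros((0, 3))
        return np.asarray(self.obstacles, dtype=float).reshape(-1, 3)

    def wall_array(self) -> np.ndarray:
        if not self.walls:
            return np.zeros((0, 5))
        return np.asarray(self.walls, dtype=float).reshape(-1, 5)

    # -- serialization (structured text, redrawable by plot tools) -------
    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "obstacles": [list(map(float, o)) for o in self.obstacles],
            "walls": [list(map(float, w)) for w in self.walls],
            "channels": [
                {"id": c.id, "width": c.width,
                 "mouth": list(map(float, c.mouth)),
                 "axis": list(map(float, c.axis)),
                 "half_width": c.half_width}
                for c in self.channels],
            "v_chemo_dir": list(map(float, self.v_chemo_dir)),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Environment":
        d = json.loads(text)
        return cls(
            obstacles=[tuple(o) for o in d["obstacles"]],
            walls=[tuple(w) for w in d["walls"]],
            channels=[Channel(c["id"], c["width"], np.array(c["mouth"]),
                              np.array(c["axis"]), c["half_width"])
                      for c in d["channels"]],
            v_chemo_dir=np.array(d["v_chemo_dir"]),
            name=d["name"],
        )


def signed_distance(env: Environment, p) -> float:
    """Signed distance from point p to the nearest surface (negative
    inside an obstacle or wall)."""
    p = np.asarray(p, dtype=float)
    best = np.inf
    for (cx, cy, R) in env.obstacles:
        best = min(best, float(np.hypot(p[0] - cx, p[1] - cy)) - R)
    for (ax, ay, bx, by, hw) in env.walls:
        v = np.array([bx - ax, by - ay])
        w = p - np.array([ax, ay])
        L2 = float(v @ v)
        t = 0.0 if L2 < 1e-24 else float(np.clip((w @ v) / L2, 0.0, 1.0))
        q = np.array([ax, ay]) + t * v
        best = min(best, float(np.hypot(*(p - q))) - hw)
    return best


# ==========================================================================
# builders
# ==========================================================================

def build_obstacle_park(Robs: float, spacing: float, extent: float,
                        lattice: str = "square") -> Environment:
    """Square (default) or hexagonal lattice of circular pillars.

    Pillars of radius ``Robs`` at pitch ``spacing`` covering
    ``[-extent/2, extent/2]^2``, offset so that the origin (the cell start
    position) sits at the center of a lattice cell.
    """
    if spacing <= 2.0 * Robs:
        raise ValueError("obstacle spacing must exceed the obstacle diameter")
    half = extent / 2.0
    # pillars at (k + 1/2) * spacing so the origin (the cell's start
    # position) is always the center of a lattice cell, never a pillar
    kmax = int(np.floor(half / spacing - 0.5))
    coords = (np.arange(-kmax - 1, kmax + 1) + 0.5) * spacing
    coords = coords[np.abs(coords) <= half + 1e-9]
    obstacles = []
    if lattice == "square":
        for x in coords:
            for y in coords:
                obstacles.append((float(x), float(y), Robs))
    elif lattice == "hex":
        dy = spacing * np.sqrt(3.0) / 2.0
        ys = np.arange(-half, half + 1e-9, dy)
        for r, y in enumerate(ys):
            off = 0.0 if r % 2 == 0 else spacing / 2.0
            for x in coords:
                obstacles.append((float(x + off), float(y), Robs))
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    return Environment(obstacles=obstacles, name=f"park_R{Robs}_d{spacing}")


def build_y_junction(w_left: float = 10.0, w_right: float = 10.0,
                     stem_w: float = 10.0, arm_angle: float = 45.0,
                     stem_len: float = 35.0, arm_len: float = 60.0,
                     wall_halfw: float = 0.5) -> Environment:
    """Y-junction: a stem channel along +x bifurcating into two arms.

    Channel widths are measured between wall *surfaces* (wall centerlines
    are offset outward by the wall half-thickness), so a 10-um stem leaves
    exactly 10 um of clear space.  The "left" arm is the upper one (+y
    side).  The chemotactic bias points along the stem axis (+x).  Arm
    mouths sit at the splitter tip on the stem axis, so the whole-cell 5-um
    entry rule measures penetration past the junction.  Wall segments
    overlap at corners so the device is sealed.
    """
    th = np.deg2rad(arm_angle)
    cos_th, sin_th = np.cos(th), np.sin(th)
    uL = np.array([cos_th, sin_th])             # upper arm axis
    uR = np.array([cos_th, -sin_th])            # lower arm axis
    nL = np.array([-uL[1], uL[0]])              # left normal of uL (outward)
    nR = np.array([uR[1], -uR[0]])              # outward normal of lower arm
    h = stem_w / 2.0
    hw = wall_halfw
    walls = []
    # stem side walls (surfaces at y = +-h), overlapping the junction corner
    walls.append((-stem_len - hw, h + hw, hw, h + hw, hw))
    walls.append((-stem_len - hw, -h - hw, hw, -h - hw, hw))
    # back wall behind the start position
    walls.append((-stem_len - hw, -h - 2 * hw, -stem_len - hw, h + 2 * hw, hw))
    # outer arm walls (surfaces through the stem corners), back-extended
    outL_srf = np.array([0.0, h])
    a = outL_srf + hw * nL - 1.0 * uL
    b = outL_srf + hw * nL + arm_len * uL
    walls.append((float(a[0]), float(a[1]), float(b[0]), float(b[1]), hw))
    outR_srf = np.array([0.0, -h])
    a = outR_srf + hw * nR - 1.0 * uR
    b = outR_srf + hw * nR + arm_len * uR
    walls.append((float(a[0]), float(a[1]), float(b[0]), float(b[1]), hw))
    # inner arm walls: surface parallel to the outer surface at the channel
    # width; the surface tip is where it crosses the stem axis (y = 0)
    t_hit_L = (w_left * cos_th - h) / sin_th
    tip_L = outL_srf + t_hit_L * uL - w_left * nL        # surface tip, y = 0
    a = tip_L - hw * nL
    b = outL_srf + (arm_len) * uL - (w_left + hw) * nL
    walls.append((float(a[0]), float(a[1]), float(b[0]), float(b[1]), hw))
    startL = a
    t_hit_R = (w_right * cos_th - h) / sin_th
    tip_R = outR_srf + t_hit_R * uR - w_right * nR
    a = tip_R - hw * nR
    b = outR_srf + (arm_len) * uR - (w_right + hw) * nR
    walls.append((float(a[0]), float(a[1]), float(b[0]), float(b[1]), hw))
    startR = a
    # seal the splitter apex between the two inner-wall starts
    walls.append((float(startL[0]), float(startL[1]),
                  float(startR[0]), float(startR[1]), hw))

    channels = [
        Channel("left", w_left, tip_L.copy(), uL, w_left + 1.0),
        Channel("right", w_right, tip_R.copy(), uR, w_right + 1.0),
    ]
    return Environment(walls=walls, channels=channels,
                       v_chemo_dir=np.array([1.0, 0.0]),
                       name=f"yjunction_{w_left:g}_{w_right:g}")


def build_multichannel(widths=(2.0, 4.0, 6.0, 8.0), feeder_len: float = 30.0,
                       channel_len: float = 50.0, pitch: float | None = None,
                       wall_halfw: float = 0.5) -> Environment:
    """Feeder chamber fanning into parallel channels of the given widths.

    Channels run along +x starting at x = 0, with equal center-to-center
    spacing, centered as a group on y = 0; the feeder chamber spans the
    full group plus clearance.  The chemotactic bias points along +x.
    """
    widths = [float(w) for w in widths]
    if any(w <= 0 for w in widths):
        raise ValueError("channel widths must be positive")
    k = len(widths)
    if pitch is None:
        pitch = max(widths) + 6.0
    span = (k - 1) * pitch
    centers = [-span / 2.0 + i * pitch for i in range(k)]
    top = centers[-1] + widths[-1] / 2.0 + 4.0   # feeder surface above
    bot = centers[0] - widths[0] / 2.0 - 4.0
    hw = wall_halfw
    walls = []
    # feeder chamber (surfaces at y = top/bot, x = -feeder_len), overlapping
    walls.append((-feeder_len - hw, top + hw, hw, top + hw, hw))
    walls.append((-feeder_len - hw, bot - hw, hw, bot - hw, hw))
    walls.append((-feeder_len - hw, bot - 2 * hw, -feeder_len - hw,
                  top + 2 * hw, hw))
    # front wall pieces between channel openings (surface facing the feeder
    # at x = 0, centerline at x = +hw); ends extended to seal the corners
    # with the channel side walls
    edges = [top + 2 * hw]
    for c, w in zip(centers[::-1], widths[::-1]):
        edges.extend([c + w / 2.0, c - w / 2.0])
    edges.append(bot - 2 * hw)
    for lo_i in range(0, len(edges), 2):
        y_hi = edges[lo_i]
        y_lo = edges[lo_i + 1]
        if y_hi - y_lo > 1e-9:
            # end caps (radius hw) overlap the side-wall centerlines, so the
            # corners are sealed without protruding into the channel mouths
            walls.append((hw, y_lo, hw, y_hi, hw))
    # channel side walls (surfaces at c +- w/2)
    channels = []
    for c, w in zip(centers, widths):
        walls.append((0.0, c + w / 2.0 + hw, channel_len, c + w / 2.0 + hw, hw))
        walls.append((0.0, c - w / 2.0 - hw, channel_len, c - w / 2.0 - hw, hw))
        channels.append(Channel(f"w{w:g}", w, np.array([0.0, c]),
                                np.array([1.0, 0.0]), w / 2.0 + 1.0))
    return Environment(walls=walls, channels=channels,
                       v_chemo_dir=np.array([1.0, 0.0]),
                       name="multichannel_" + "_".join(f"{w:g}" for w in widths))


# ==========================================================================
# queries
# ==========================================================================

def channel_entry_check(state: CellState, env: Environment) -> str | None:
    """Channel id if the *entire* cell is >= 5 um past a channel mouth.

    Every membrane bead must be at least ``ENTRY_DEPTH`` past the mouth
    line along the channel axis and within the channel's lateral band;
    otherwise returns None.
    """
    mem = state.membrane.pos
    for ch in env.channels:
        rel = mem - ch.mouth
        xi = rel @ ch.axis
        lat = rel @ np.array([-ch.axis[1], ch.axis[0]])
        if np.all(xi >= ENTRY_DEPTH) and np.all(np.abs(lat) <= ch.half_width):
            return ch.id
    return None


def chemotactic_bias(state: CellState, env: Environment,
                     params: Params) -> np.ndarray:
    """Uniform forward active velocity on every membrane bead.

    ``v_chemo * v_chemo_dir`` replicates the chemotactic gradient that
    drives cells into the channel devices; zero in free space and obstacle
    parks (``v_chemo = 0`` there).
    """
    v = params.v_chemo * env.v_chemo_dir
    return np.tile(v, (state.membrane.n, 1))
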