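"""Microtubule-tip signaling to the actomyosin boundary.

The model's motility engine: growing plus-end tips near a membrane segment
promote local actin polymerization, imposed as an outward *active velocity*
proportional to the local tip count; shrinking tips promote local myosin
contraction, imposed as an inward *force* proportional to the local tip
count.  The asymmetry (velocity vs force) is deliberate and mirrors how the
two pathways act on the cortex in the underlying experiments.  A linear
elastic coupling between nucleus beads and membrane beads represents myosin
contractility across overlapping actin filaments, dragging the nucleus and
the cell rear behind the advancing front.

Both signals use the same uniform hard-disc kernel of radius ``r_signal``
(default ``2 * 1.12 * sigma_mt``, the model's tip-membrane contact
criterion).  Signals are instantaneous counts by default; an optional
exponential memory trace (``signal_tau``) is available and off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import Params
from .state import CellState, GROW, polygon_area

__all__ = [
    "TipSignalField", "compute_tip_signals", "protrusion_velocity",
    "contraction_force", "coupling_forces", "coupling_pairs",
    "outward_normals",
]


@dataclass
class TipSignalField:
    """Per-membrane-bead tip counts and outward unit normals."""

    n_grow: np.ndarray     # (n_mem,) growing-tip counts
    n_shrink: np.ndarray   # (n_mem,) shrinking-tip counts
    normals: np.ndarray    # (n_mem, 2) outward unit normals


def outward_normals(pos: np.ndarray) -> np.ndarray:
    """Outward unit normals of a simple polygon ring.

    The normal at bead i is perpendicular to the chord between neighbors
    i-1 and i+1, oriented outward according to the polygon winding.
    Degenerate (coincident-neighbor) tangents copy the nearest preceding
    valid normal.
    """
    sgn = 1.0 if polygon_area(pos) > 0 else -1.0
    t = np.roll(pos, -1, axis=0) - np.roll(pos, 1, axis=0)
    L = np.hypot(t[:, 0], t[:, 1])
    normals = np.empty_like(pos)
    ok = L > 1e-12
    normals[ok, 0] = sgn * t[ok, 1] / L[ok]
    normals[ok, 1] = -sgn * t[ok, 0] / L[ok]
    if not np.all(ok):
        for i in np.flatnonzero(~ok):
            normals[i] = normals[i - 1]  # copy nearest valid neighbor
    return normals


def compute_tip_signals(state: CellState, params: Params) -> TipSignalField:
    """Count plus-end tips within ``r_signal`` of each membrane bead.

    Counts are per bead (a tip near several beads contributes to each) and
    split by dynamic state.
    """
    mem = state.membrane.pos
    tips = state.mts.tips()
    n_grow = np.zeros(len(mem))
    n_shrink = np.zeros(len(mem))
    if len(tips):
        d2 = ((mem[:, None, :] - tips[None, :, :]) ** 2).sum(axis=2)
        near = d2 < params.r_signal ** 2
        growing = state.mts.state == GROW
        n_grow = (near & growing[None, :]).sum(axis=1).astype(float)
        n_shrink = (near & ~growing[None, :]).sum(axis=1).astype(float)
    return TipSignalField(n_grow=n_grow, n_shrink=n_shrink,
                          normals=outward_normals(mem))


def protrusion_velocity(field: TipSignalField, params: Params) -> np.ndarray:
    """Outward active velocity ``v_prot0 * n_grow`` per membrane bead."""
    return params.v_prot0 * field.n_grow[:, None] * field.normals


def contraction_force(field: TipSignalField, params: Params) -> np.ndarray:
    """Inward force ``f_contr0 * n_shrink`` per membrane bead."""
    return -params.f_contr0 * field.n_shrink[:, None] * field.normals


def coupling_pairs(n_nuc: int, n_mem: int) -> np.ndarray:
    """Membrane partner index for each nucleus bead (fixed at t = 0).

    Nucleus bead j couples to membrane bead ``round(j * n_mem / n_nuc)``;
    the index-proportional pairing is kept for the whole run so the coupling
    can transmit the rear drag that pulls the nucleus after the front.
    """
    return (np.round(np.arange(n_nuc) * n_mem / n_nuc).astype(np.int64)
            % n_mem)


def coupling_forces(state: CellState, params: Params
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Hookean nucleus-membrane coupling forces.

    Returns ``(f_membrane, f_nucleus)``; each nucleus bead pulls its fixed
    membrane partner toward the rest separation ``rest_couple`` and feels
    the opposite force.
    """
    mem, nuc = state.membrane.pos, state.nucleus.pos
    pairs = coupling_pairs(len(nuc), len(mem))
    d = mem[pairs] - nuc
    r = np.hypot(d[:, 0], d[:, 1])
    safe = np.where(r > 1e-12, r, 1.0)
    coef = np.where(r > 1e-12,
                    params.k_couple * (r - params.rest_couple) / safe, 0.0)
    f_on_pair = -coef[:, None] * d       # force on the membrane partner
    f_mem = np.zeros_like(mem)
    np.add.at(f_mem, pairs, f_on_pair)
    return f_mem, -f_on_pair
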