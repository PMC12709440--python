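"""Parameter registry for the crosstalk migration model.

Every model constant lives here, with units and a provenance tag:

* ``"printed"``   -- value printed in the source experimental/modeling study
  (cell and nucleus radii, rescue rate, microtubule lengths and counts,
  device geometries, classification thresholds);
* ``"reconstructed"`` -- value chosen by this package to reproduce the
  study's qualitative regimes, because the original appendix-level constants
  are not available (speeds, stiffnesses, drags, crosstalk gains, motor
  kinetics).

Units are micrometers (length), seconds (time) and piconewtons (force)
throughout; drags are pN*s/um, so a bead with gamma = 1 moves at 1 um/s
under a 1 pN load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "DyneinParams",
    "Params",
    "ParamError",
    "derive_catastrophe_rate",
    "derive_instability_rates",
    "PROVENANCE",
]


class ParamError(ValueError):
    """Raised when a parameter set fails validation."""


@dataclass
class DyneinParams:
    """Cortical / perinuclear dynein kinetics.

    Motors occupy a fixed random subset of loop beads chosen at
    initialization (fractions ``rho_cortex``, ``rho_nuc``); an unoccupied
    motor binds the nearest microtubule point within ``r_capture`` at rate
    ``k_on``, walks minus-end-ward at ``v_motor`` and pulls through a linear
    spring ``k_motor``, detaching at rate ``k_off`` or when the spring load
    exceeds ``f_stall``.
    """

    rho_cortex: float = 0.1   # motors per membrane bead (occupancy fraction)
    rho_nuc: float = 0.2      # motors per nucleus bead
    k_on: float = 1.0         # 1/s
    k_off: float = 0.5        # 1/s
    v_motor: float = 0.3      # um/s toward the minus end
    k_motor: float = 1.5      # pN/um motor-spring stiffness
    r_capture: float = 1.0    # um capture radius
    f_stall: float = 1.5      # pN forced-detachment load


@dataclass
class Params:
    """Full parameter set of the whole-cell model."""

    # --- geometry -------------------------------------------------------
    Rcell: float = 7.0        # um, initial cell radius
    Rnuc: float = 3.0         # um, initial nucleus radius
    n_mem_beads: int = 100
    n_nuc_beads: int = 50

    # --- microtubules ---------------------------------------------------
    Nmt: int = 100            # number of MTs (study range 25-200)
    lmt_target: float = 9.3   # um, target mean MT length
    sigma_mt: float = 0.5     # um, MT bead spacing / steric diameter
    vg: float = 0.1           # um/s growth speed
    vs: float = 0.2           # um/s shrink speed
    fr: float = 0.04          # 1/s rescue rate
    fc: float | None = None   # 1/s catastrophe rate; None -> derived from lmt_target
    mt_length_cap_factor: float = 4.0  # MT length capped at factor*lmt_target

    # --- passive mechanics ---------------------------------------------
    eps_wca: float = 0.05     # pN*um, steric repulsion strength
    kappa_mem: float = 0.2    # pN*um^2 membrane bending stiffness
    kappa_nuc: float = 0.35   # pN*um^2 nucleus bending stiffness
    kappa_mt: float = 1.5     # pN*um^2 MT bending stiffness
    ks_mem: float = 20.0      # pN/um membrane stretching stiffness
    ks_nuc: float = 20.0      # pN/um nucleus stretching stiffness
    ks_mt: float = 20.0       # pN/um MT stretching stiffness
    k_couple: float = 2.0     # pN/um nucleus-membrane elastic coupling
    k_area_nuc: float = 50.0  # pN/um nuclear area pressure (incompressible interior)
    k_area_mem: float = 20.0  # pN/um weak cell-area regulation (osmotic/cortical)
    rest_couple: float = 4.0  # um coupling rest length (= Rcell - Rnuc)
    f_cap: float = 0.75       # pN cap on any single bead-bead steric pair force: bounds bond compression and the contact stiffness 13*f_cap/sigma that limits dt (bead jams can stack many pairs)
    f_cap_wall: float = 6.0   # pN cap for rigid wall/obstacle contacts (at most ~2 surfaces per bead, so a larger cap stays stable)

    # --- crosstalk ------------------------------------------------------
    v_prot0: float = 0.2      # um/s outward velocity per growing tip
    f_contr0: float = 0.12   # pN inward force per shrinking tip
    r_signal: float = 1.12    # um tip-membrane signaling radius (2*1.12*sigma_mt)
    signal_tau: float = 20.0  # s, exponential memory of cortical tip signals (0 disables)

    # --- dynein ---------------------------------------------------------
    dynein: DyneinParams = field(default_factory=DyneinParams)

    # --- drags ----------------------------------------------------------
    gamma_mem: float = 1.0    # pN*s/um per membrane bead
    gamma_nuc: float = 5.0    # nuclear envelope + lamina: more viscous than cortex
    gamma_cen: float = 10.0   # centrosome drags the whole aster: larger than a single bead
    gamma_mt: float = 6.0    # slow transverse relaxation; also stabilizes the stiffest bending mode

    # --- run control ----------------------------------------------------
    dt: float = 0.01         # s integration step
    n_sub: int = 6            # elastic (stretch/bend) substeps per dt
    t_total: float = 1800.0   # s
    record_every: float = 5.0  # s
    v_chemo: float = 0.0      # um/s forward bias on membrane beads
    skin: float = 0.6         # um Verlet-list skin
    seed: int = 0

    # -------------------------------------------------------------------
    def __post_init__(self) -> None:
        if isinstance(self.dynein, dict):
            self.dynein = DyneinParams(**self.dynein)

    def validate(self) -> "Params":
        """Check positivity, the bounded-length regime, and timestep safety.

        Returns self so calls can be chained.  Raises :class:`ParamError`.
        """
        positive = [
            "Rcell", "Rnuc", "sigma_mt", "vg", "vs", "eps_wca",
            "kappa_mem", "kappa_nuc", "kappa_mt", "ks_mem", "ks_nuc",
            "ks_mt", "k_couple", "gamma_mem", "gamma_nuc", "gamma_cen",
            "gamma_mt", "dt", "record_every", "lmt_target", "r_signal",
            "f_cap", "f_cap_wall", "skin",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParamError(f"{name} must be strictly positive")
        for name in ("fr", "v_chemo", "signal_tau", "rest_couple",
                     "t_total", "k_area_nuc", "k_area_mem"):
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be non-negative")
        if self.n_mem_beads < 3 or self.n_nuc_beads < 3:
            raise ParamError("bead loops need at least 3 beads")
        if self.Nmt < 0:
            raise ParamError("Nmt must be non-negative")
        if self.Rnuc >= self.Rcell:
            raise ParamError("nucleus must fit inside the cell")
        d = self.dynein
        for name in ("rho_cortex", "rho_nuc", "k_on", "k_off", "v_motor",
                     "k_motor", "r_capture", "f_stall"):
            if getattr(d, name) < 0:
                raise ParamError(f"dynein.{name} must be non-negative")

        fc = self.catastrophe_rate()
        if self.vg * self.fr >= self.vs * fc:
            raise ParamError(
                "unbounded MT growth: require vg*fr < vs*fc for a finite "
                "mean length"
            )
        # forward-Euler safety.  Local elasticity (stretch + bend) is
        # sub-cycled at dt/n_sub; the remaining forces act at dt.
        if self.n_sub < 1:
            raise ParamError("n_sub must be at least 1")
        dt_sub = self.dt / self.n_sub
        rate = max(
            self.ks_mem / self.gamma_mem,
            self.ks_nuc / self.gamma_nuc,
            self.ks_mt / self.gamma_mt,
        )
        if rate * dt_sub >= 0.1:
            raise ParamError(
                f"dt too large: max spring relaxation rate * dt_sub = "
                f"{rate * dt_sub:.3f} >= 0.1"
            )
        slow = max(self.k_couple / self.gamma_mem,
                   d.k_motor / self.gamma_mem)
        if slow * self.dt >= 0.1:
            raise ParamError("dt too large for coupling/motor springs")
        # stiffest bending (zigzag) mode: kappa pi^4 / (gamma l0^4)
        import math as _math
        pi4 = _math.pi ** 4
        l0m = 2 * self.Rcell * _math.sin(_math.pi / self.n_mem_beads)
        l0n = 2 * self.Rnuc * _math.sin(_math.pi / self.n_nuc_beads)
        bend_rate = max(
            self.kappa_mem * pi4 / (self.gamma_mem * l0m ** 4),
            self.kappa_nuc * pi4 / (self.gamma_nuc * l0n ** 4),
            self.kappa_mt * pi4 / (self.gamma_mt * self.sigma_mt ** 4),
        )
        if bend_rate * dt_sub >= 1.5:
            raise ParamError(
                f"dt too large for bending: stiffest bending rate * dt_sub "
                f"= {bend_rate * dt_sub:.2f} >= 1.5")
        if self.dt * max(fc, self.fr) >= 0.1:
            raise ParamError("dt too large for the MT switching rates")
        # initial containment: centrosome offset + first MT bead inside cell
        if self.Rnuc + 1.0 + self.sigma_mt >= self.Rcell:
            raise ParamError(
                "initial centrosome offset plus MT extent does not fit "
                "inside the cell"
            )
        return self

    def catastrophe_rate(self) -> float:
        """Catastrophe rate: explicit ``fc`` if set, else derived from lmt."""
        if self.fc is not None:
            return self.fc
        return derive_catastrophe_rate(self.vg, self.vs, self.fr, self.lmt_target)

    # convenience -------------------------------------------------------
    def replace(self, **kw: Any) -> "Params":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParamError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)


def derive_catastrophe_rate(vg: float, vs: float, fr: float,
                            lmt_target: float) -> float:
    """Catastrophe rate that yields a prescribed mean free-MT length.

    The unconstrained two-state (grow/shrink) model with bounded dynamics
    has an exponential length distribution with mean

        <L> = vg*vs / (fc*vs - fr*vg),

    so enforcing ``<L> = lmt_target`` gives
    ``fc = (vg*vs/lmt_target + fr*vg) / vs``.  In the ``fr = 0`` limit this
    reduces to ``fc = vg/lmt_target``.
    """
    if lmt_target <= 0:
        raise ParamError("lmt_target must be positive")
    if vg <= 0 or vs <= 0 or fr < 0:
        raise ParamError("need vg, vs > 0 and fr >= 0")
    fc = (vg * vs / lmt_target + fr * vg) / vs
    if fc <= 0:
        raise ParamError("no positive catastrophe rate solves the target length")
    return fc


def derive_instability_rates(params: Params) -> float:
    """Solve the catastrophe rate for ``params.lmt_target`` (see above)."""
    return derive_catastrophe_rate(params.vg, params.vs, params.fr,
                                   params.lmt_target)


#: provenance of every registered constant ("printed" vs "reconstructed")
PROVENANCE: dict[str, str] = {
    "Rcell": "printed",
    "Rnuc": "printed",
    "n_mem_beads": "reconstructed",
    "n_nuc_beads": "reconstructed",
    "Nmt": "printed",
    "lmt_target": "printed",
    "sigma_mt": "printed",
    "vg": "reconstructed",
    "vs": "reconstructed",
    "fr": "printed",
    "fc": "derived from lmt_target",
    "mt_length_cap_factor": "reconstructed",
    "eps_wca": "reconstructed",
    "kappa_mem": "reconstructed",
    "kappa_nuc": "reconstructed",
    "kappa_mt": "reconstructed",
    "ks_mem": "reconstructed",
    "ks_nuc": "reconstructed",
    "ks_mt": "reconstructed",
    "k_couple": "reconstructed",
    "k_area_nuc": "reconstructed",
    "k_area_mem": "reconstructed",
    "rest_couple": "reconstructed",
    "f_cap": "reconstructed",
    "f_cap_wall": "reconstructed",
    "v_prot0": "reconstructed",
    "f_contr0": "reconstructed",
    "r_signal": "printed (2 x 1.12 sigma_mt contact criterion)",
    "signal_tau": "reconstructed (optional, off by default)",
    "dynein.rho_cortex": "reconstructed",
    "dynein.rho_nuc": "reconstructed",
    "dynein.k_on": "reconstructed",
    "dynein.k_off": "reconstructed",
    "dynein.v_motor": "reconstructed",
    "dynein.k_motor": "reconstructed",
    "dynein.r_capture": "reconstructed",
    "dynein.f_stall": "reconstructed",
    "gamma_mem": "reconstructed",
    "gamma_nuc": "reconstructed",
    "gamma_cen": "reconstructed",
    "gamma_mt": "reconstructed",
    "dt": "reconstructed",
    "n_sub": "numerical",
    "t_total": "run control",
    "record_every": "run control",
    "v_chemo": "printed (qualitative: small forward velocity)",
    "skin": "numerical",
    "seed": "run control",
}
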