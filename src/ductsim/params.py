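"""Model parameters for the ductal CPM.

All energies are in the same arbitrary units; lengths are in pixels with
1 pixel = 1 um, so a mammary epithelial cell has a diameter of 10 px.
Defaults reproduce the baseline parameterization of the duct bilayer:
a hierarchy of negative contact energies (LEP-LEP tightest), a 2:1
MEP:LEP volume stiffness ratio reflecting AFM moduli, and contractile
center-of-mass springs whose target length is shorter than the resting
cell spacing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

# agent type codes (index into the adhesion matrix)
MEDIUM = 0
LEP = 1
MEP = 2
NECROTIC = 3
N_TYPES = 4

TYPE_NAMES = {MEDIUM: "medium", LEP: "LEP", MEP: "MEP", NECROTIC: "necrotic"}

CELL_DIAMETER = 10.0  # px; one epithelial cell

# An agent's surface S is its count of 4-neighbor lattice faces adjoining a
# different index.  That taxicab metric overestimates Euclidean arc length by
# 4/pi (Cauchy-Crofton): a digital disk of diameter 10 has ~40 boundary faces
# against a true circumference of 31.4.  Target surfaces are specified as
# Euclidean circumferences and converted to face units on assignment, so a
# round cell at target volume sits at its surface optimum instead of feeling
# a spurious inward tension.
SURFACE_FACE_FACTOR = 4.0 / np.pi


@dataclass
class AdhesionMatrix:
    """Symmetric contact energy per neighboring pixel pair of unlike index.

    Negative values favor contact.  Any pair involving culture medium or a
    necrotic agent is zero: necrotic cells occupy space as debris but no
    longer bind.
    """

    j_lep_lep: float = -20.0
    j_lep_mep: float = -10.0
    j_mep_mep: float = -5.0

    def as_array(self) -> np.ndarray:
        J = np.zeros((N_TYPES, N_TYPES), dtype=np.float64)
        J[LEP, LEP] = self.j_lep_lep
        J[LEP, MEP] = J[MEP, LEP] = self.j_lep_mep
        J[MEP, MEP] = self.j_mep_mep
        return J


@dataclass
class FppParams:
    """Focal-point-plasticity springs between neighboring cells' centers of mass.

    Homotypic springs are 10-fold stiffer than heterotypic ones.  Target
    lengths sit below the ~10 px resting spacing so the springs contract
    the tissue.
    """

    lam_lep_lep: float = 50.0
    lam_lep_mep: float = 5.0
    lam_mep_mep: float = 50.0
    len_lep_lep: float = 8.0
    len_lep_mep: float = 8.0
    len_mep_mep: float = 5.0

    def spring(self, type_a: int, type_b: int) -> tuple[float, float]:
        """Return (lambda, target_length) for an (a, b) type pair; zero spring
        for any pair that is not LEP/MEP."""
        pair = frozenset((type_a, type_b))
        if pair == {LEP}:
            return self.lam_lep_lep, self.len_lep_lep
        if pair == {LEP, MEP}:
            return self.lam_lep_mep, self.len_lep_mep
        if pair == {MEP}:
            return self.lam_mep_mep, self.len_mep_mep
        return 0.0, 0.0


@dataclass
class SimulationParams:
    """Full parameter set for one simulation run."""

    # contact energies
    adhesion: AdhesionMatrix = field(default_factory=AdhesionMatrix)
    # volume constraint
    vt_lep: float = 78.5
    vt_mep: float = 78.5
    lam_v_lep: float = 5.0
    lam_v_mep: float = 10.0
    # surface (membrane elasticity) constraint
    st_lep: float = 31.4
    st_mep: float = 31.4
    lam_s_lep: float = 1.0
    lam_s_mep: float = 1.0
    # center-of-mass springs
    fpp: FppParams = field(default_factory=FppParams)
    # Metropolis temperature: intrinsic agent motility
    temperature: float = 20.0
    # neighborhood order of the contact-energy sum (1: 4 pixel pairs,
    # 2: 8, 3: 12, 4: 20); the surface constraint always uses 1st-order faces
    adhesion_neighbor_order: int = 2

    # --- event layer ---
    mitosis_interval: int = 50          # MCS between mitotic events
    mitotic_fraction: float = 0.25      # fraction of LEP dividing per event
    division_axis: str = "perpendicular"  # 'perpendicular' | 'parallel' | 'random'
    protect_luminal_progeny: bool = False
    apoptosis_probability: float = 0.0  # per overcrowded-LEP per-MCS check
    overcrowding_radius: float = 25.0   # px: 2.5 cell diameters
    overcrowding_threshold: int = 10    # neighbors within radius
    necrosis_distance: float = 100.0    # px from the MEP layer
    preferential_end_proliferation: bool = False
    end_weight_factor: float = 2.0

    # --- run control ---
    run_length: int = 1000  # MCS
    seed: int = 0

    def replace(self, **kwargs) -> "SimulationParams":
        return dataclasses.replace(self, **kwargs)

    def type_params(self) -> dict[int, tuple[float, float, float, float]]:
        """Per-type (V_t, lambda_V, S_t, lambda_S); S_t in lattice face units."""
        f = SURFACE_FACE_FACTOR
        return {
            LEP: (self.vt_lep, self.lam_v_lep, f * self.st_lep, self.lam_s_lep),
            MEP: (self.vt_mep, self.lam_v_mep, f * self.st_mep, self.lam_s_mep),
            # necrotic debris keeps occupying space under the same
            # constraints it had as a live cell
            NECROTIC: (self.vt_lep, self.lam_v_lep, f * self.st_lep,
                       self.lam_s_lep),
        }

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not (0.0 <= self.apoptosis_probability <= 0.01 + 1e-12):
            raise ValueError("apoptosis probability must lie in [0, 0.01]")
        if self.mitosis_interval < 1:
            raise ValueError("mitosis interval must be >= 1 MCS")
        if self.division_axis not in ("perpendicular", "parallel", "random"):
            raise ValueError(f"unknown division axis {self.division_axis!r}")
        for name in ("lam_v_lep", "lam_v_mep", "lam_s_lep", "lam_s_mep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.adhesion_neighbor_order not in (1, 2, 3, 4):
            raise ValueError("adhesion neighbor order must be 1-4")


# Standard cadence pairs (events per 1000 MCS -> interval).  The products
# (975, 1000, 950, 960) all place the last scheduled division at or shortly
# before the 1000 MCS evaluation point.
_INTERVAL_TABLE = {15: 65, 20: 50, 25: 38, 30: 32}


def events_to_interval(n_events: int, run_length: int = 1000) -> int:
    """Mitosis interval (MCS) that yields ``n_events`` divisions over a run.

    Uses the standard cadence pairings (15 events <-> 65 MCS, 20 <-> 50, 25 <-> 38,
    30 <-> 32) when available; other counts follow the same family, with the
    final event ~1 interval before the evaluation point."""
    if n_events < 1:
        raise ValueError("need at least one mitotic event")
    if run_length == 1000 and n_events in _INTERVAL_TABLE:
        return _INTERVAL_TABLE[n_events]
    return max(1, int(0.96 * run_length) // n_events)


# Named parameter presets for the adhesion / contractility experiments.
def preset(name: str) -> SimulationParams:
    """Return a SimulationParams for a named preset.

    ``default``            baseline values above
    ``low_adhesion``       all contact energies and springs zeroed
    ``high_adhesion``      J = (-100, -50, -25)
    ``low_contractility``  lambda_V = (1 LEP, 2 MEP), springs (1 homo, 0.1 hetero)
    ``high_contractility`` lambda_V = (25 LEP, 50 MEP), springs (100 homo, 10 hetero)
    """
    p = SimulationParams()
    if name == "default":
        return p
    if name == "low_adhesion":
        return p.replace(
            adhesion=AdhesionMatrix(0.0, 0.0, 0.0),
            fpp=FppParams(0.0, 0.0, 0.0, 8.0, 8.0, 5.0),
        )
    if name == "high_adhesion":
        return p.replace(adhesion=AdhesionMatrix(-100.0, -50.0, -25.0))
    if name == "low_contractility":
        return p.replace(
            lam_v_lep=1.0, lam_v_mep=2.0,
            fpp=FppParams(1.0, 0.1, 1.0, 8.0, 8.0, 5.0),
        )
    if name == "high_contractility":
        return p.replace(
            lam_v_lep=25.0, lam_v_mep=50.0,
            fpp=FppParams(100.0, 10.0, 100.0, 8.0, 8.0, 5.0),
        )
    raise KeyError(f"unknown preset {name!r}")
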