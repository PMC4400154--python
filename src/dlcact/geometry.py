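"""Nuclear-cycle schedule and compartment geometry for the half-DV-axis array.

The syncytial embryo cross-section is modeled as a linear array of
rectangular-prism compartments, one nucleus per compartment, spanning one half
of the dorsal-ventral (DV) axis from the ventral midline (index 0) to the
dorsal midline (index n-1).  The nucleus count roughly doubles at the start of
each interphase from nuclear cycle (NC) 10 through NC 14; nuclear dimensions
are static within a cycle.  All areas and volumes are nondimensionalized by
the NC14 nuclear surface area and volume respectively, so that
``A_n_tilde = V_n_tilde = 1`` at NC14.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CycleSpec",
    "GeometrySchedule",
    "build_schedule",
    "DEFAULT_NUCLEAR_RADII_UM",
    "DEFAULT_INTERPHASE_MIN",
    "DEFAULT_MITOSIS_MIN",
    "DEFAULT_H_UM",
    "DEFAULT_L_UM",
    "DEFAULT_N14",
]

# Defaults are order-of-magnitude realistic for the NC10-14 blastoderm and are
# fully overridable: radii of the (spherical) nuclei per cycle, compartment
# height H, and the modeled half-axis length L, all in micrometres; phase
# durations in minutes.
DEFAULT_NUCLEAR_RADII_UM = (3.3, 3.7, 4.2, 4.9, 5.5)
DEFAULT_INTERPHASE_MIN = (8.0, 10.0, 12.0, 14.0, 60.0)
DEFAULT_MITOSIS_MIN = (3.0, 3.0, 3.0, 4.0)
DEFAULT_H_UM = 35.0
DEFAULT_L_UM = 280.0
DEFAULT_N14 = 50

CYCLES = (10, 11, 12, 13, 14)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CycleSpec:
    """Geometry and timing of one nuclear cycle.

    Areas/volumes carry a tilde in the model equations: they are scaled by the
    NC14 nuclear surface area (``A_n_tilde``, ``A_m_tilde``) or the NC14
    nuclear volume (``V_n_tilde``, ``V_C_tilde``).
    """

    cycle_id: int
    n_nuclei: int
    interphase_duration: float
    mitosis_duration: float | None  # None for NC14, which ends the simulation
    A_n_tilde: float
    V_n_tilde: float
    V_C_tilde: float
    A_m_tilde: float
    compartment_length: float
    height: float

    @property
    def prism_volume_tilde(self) -> float:
        """Total compartment (nuclear + cytoplasmic) volume, NC14-nucleus units."""
        return self.V_n_tilde + self.V_C_tilde

    def dv_positions(self):
        """Compartment-center DV positions as fractions of the half-axis."""
        import numpy as np

        n = self.n_nuclei
        return (np.arange(n) + 0.5) / n


@dataclass(frozen=True)
class GeometrySchedule:
    """Ordered NC10-NC14 cycle specs plus global geometry constants.

    The time unit is one minute throughout.
    """

    cycles: tuple[CycleSpec, ...]
    L: float
    T_bar: float = 1.0  # minutes

    def __post_init__(self):
        ids = [c.cycle_id for c in self.cycles]
        if ids != list(CYCLES):
            raise ValueError(f"cycles must be contiguous NC10..NC14, got {ids}")

    @property
    def total_time(self) -> float:
        return sum(
            c.interphase_duration + (c.mitosis_duration or 0.0) for c in self.cycles
        )

    def cycle(self, cycle_id: int) -> CycleSpec:
        return self.cycles[cycle_id - 10]

    @property
    def n14(self) -> int:
        return self.cycles[-1].n_nuclei


def nucleus_counts(n14: int) -> list[int]:
    """Per-cycle nucleus counts NC10..NC14 by successive round-half-up halving.

    The count doubles (to the nearest integer) at each interphase start;
    inverting that map from the NC14 count is done by halving with the same
    rounding rule, which reproduces e.g. 50 -> 25 -> 13 -> 7 -> 4.
    """
    counts = [int(n14)]
    for _ in range(4):
        counts.append(_round_half_up(counts[-1] / 2.0))
    counts.reverse()
    if counts[0] < 1:
        raise ValueError(f"n14={n14} halves below one NC10 nucleus")
    if any(b <= a for a, b in zip(counts, counts[1:])):
        raise ValueError(
            f"n14={n14} gives non-increasing nucleus counts {counts}; use n14 >= 16"
        )
    return counts


def build_schedule(
    n14: int = DEFAULT_N14,
    durations: tuple = None,
    nuclear_radii: tuple = DEFAULT_NUCLEAR_RADII_UM,
    H: float = DEFAULT_H_UM,
    L: float = DEFAULT_L_UM,
    mitosis_durations: tuple = DEFAULT_MITOSIS_MIN,
    width_mode: str = "constant",
) -> GeometrySchedule:
    """Build the NC10-NC14 geometry schedule.

    Parameters
    ----------
    n14
        Nucleus count along the half-axis at NC14 (>= 16 so halving stays
        strictly decreasing).
    durations
        Interphase durations in minutes, NC10..NC14.
    nuclear_radii
        Spherical nuclear radii per cycle, same length units as ``H``/``L``.
    H
        Compartment height (apical-basal), constant across cycles.
    L
        Modeled half-axis length.
    mitosis_durations
        Mitosis durations NC10..NC13 (NC14 ends the simulation).
    width_mode
        ``"constant"`` (default): slab depth fixed at ``L / n14``, keeping the
        modeled volume constant across cycles so total dl is conserved through
        divisions.  ``"per_cycle"``: depth equals the compartment length
        ``L / n_i`` (square footprint), in which case the modeled slab thins
        as nuclei multiply.
    """
    if durations is None:
        durations = DEFAULT_INTERPHASE_MIN
    if len(durations) != 5 or len(nuclear_radii) != 5 or len(mitosis_durations) != 4:
        raise ValueError("need 5 interphase durations, 5 radii, 4 mitosis durations")
    if min(durations) <= 0 or min(mitosis_durations) <= 0:
        raise ValueError("durations must be positive")
    if min(nuclear_radii) <= 0 or H <= 0 or L <= 0:
        raise ValueError("lengths must be positive")
    if width_mode not in ("constant", "per_cycle"):
        raise ValueError(f"unknown width_mode {width_mode!r}")

    counts = nucleus_counts(n14)
    r14 = nuclear_radii[-1]
    A_n14 = 4.0 * math.pi * r14**2
    V_n14 = 4.0 / 3.0 * math.pi * r14**3

    specs = []
    for i, cid in enumerate(CYCLES):
        n = counts[i]
        r = nuclear_radii[i]
        length = L / n
        width = L / n14 if width_mode == "constant" else length
        V_n = 4.0 / 3.0 * math.pi * r**3
        V_prism = length * width * H
        V_C = V_prism - V_n
        if V_C <= 0:
            raise ValueError(
                f"NC{cid}: nuclear volume {V_n:.1f} exceeds compartment volume "
                f"{V_prism:.1f}; shrink radii or enlarge L/H"
            )
        A_m = H * width  # shared face between DV neighbors
        specs.append(
            CycleSpec(
                cycle_id=cid,
                n_nuclei=n,
                interphase_duration=float(durations[i]),
                mitosis_duration=float(mitosis_durations[i]) if cid < 14 else None,
                A_n_tilde=4.0 * math.pi * r**2 / A_n14,
                V_n_tilde=V_n / V_n14,
                V_C_tilde=V_C / V_n14,
                A_m_tilde=A_m / A_n14,
                compartment_length=length / L,  # fraction of the half-axis
                height=H,
            )
        )
    return GeometrySchedule(cycles=tuple(specs), L=L)
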