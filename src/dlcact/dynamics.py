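"""Reaction-transport dynamics of dl, Cact and dl/Cact complex over NC10-NC14.

The model tracks three species -- free Dorsal (dl), free Cactus (Cact) and the
dl/Cact complex -- in nuclear and cytoplasmic pools of each compartment of the
half-DV-axis array.  All concentrations are nondimensional: dl-containing
species are scaled by the total dl concentration, Cact by the total Cact
concentration, times by T_bar = 1 min, and geometry by the NC14 nucleus (see
:mod:`dlcact.geometry`).

Processes, each first-order unless noted:

* nuclear import/export of each species (``zeta_s`` / ``xi_s``),
* slow intercompartmental exchange along the DV axis (``lambda_s``), with
  no-flux boundaries at the ventral and dorsal midlines,
* dl/Cact association (``gamma``, bimolecular) and basal dissociation
  (``beta0``),
* Toll-mediated dissociation of *cytoplasmic* complex, with a Gaussian rate
  profile peaked at the ventral midline (amplitude ``beta``, width
  ``phi_prime`` as a fraction of the half-axis),
* Cact turnover in the cytoplasm: first-order degradation ``alpha`` and
  constant nondimensional production (rate 1).

Two model variants are supported.  In the ``"extended"`` variant nascent
nuclei inherit the cytoplasmic concentrations of all three species at each
interphase onset, so Cact and dl/Cact complex can reside in nuclei.  In the
``"classic"`` variant nuclei begin interphase empty and only free dl shuttles
in and out; nuclear Cact and complex are identically zero.

During mitosis nuclei are undefined: nuclear contents are mixed into the
cytoplasm and only the cytoplasmic equations are integrated, with the
cytoplasm occupying the full compartment prism.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, asdict

import numpy as np
from scipy.integrate import odeint

from .geometry import CycleSpec, GeometrySchedule

__all__ = [
    "ModelParameters",
    "EmbryoState",
    "Trajectory",
    "PARAM_NAMES",
    "DAMPED_PARAMS",
    "toll_rate",
    "interphase_rhs",
    "mitosis_rhs",
    "mix_at_mitosis",
    "start_interphase",
    "initial_conditions",
    "simulate",
    "resample_piecewise_constant",
]

# Canonical flat ordering of the 15 free rate constants.
PARAM_NAMES = (
    "zeta_dl", "xi_dl",
    "zeta_dc", "xi_dc",
    "zeta_cact", "xi_cact",
    "lambda_dl", "lambda_dc", "lambda_cact",
    "gamma", "beta0", "beta", "phi_prime", "alpha", "psi",
)

# Parameters whose EA initialization draws are damped 100-fold (exchange
# rates and basal dissociation start unrealistically high otherwise).
DAMPED_PARAMS = ("lambda_dl", "lambda_dc", "lambda_cact", "beta0")

INTERPHASE = "interphase"
MITOSIS = "mitosis"

# State layout during interphase: per compartment, in this order.
SPECIES_6 = ("U_nuc", "U_cyt", "W_nuc", "W_cyt", "Z_nuc", "Z_cyt")
SPECIES_3 = ("U_cyt", "W_cyt", "Z_cyt")


@dataclass(frozen=True)
class ModelParameters:
    """The 15 nondimensional rate constants of the dl/Cact model.

    ``zeta_*``/``xi_*`` are nuclear import/export rates, ``lambda_*``
    intercompartmental exchange rates, ``gamma`` the dl/Cact binding rate,
    ``beta0`` basal and ``beta`` the Toll-mediated (peak) dissociation rate,
    ``phi_prime`` the Toll Gaussian width (fraction of the half-axis),
    ``alpha`` Cact degradation, and ``psi`` the ratio of total dl to total
    Cact concentration.
    """

    zeta_dl: float
    xi_dl: float
    zeta_dc: float
    xi_dc: float
    zeta_cact: float
    xi_cact: float
    lambda_dl: float
    lambda_dc: float
    lambda_cact: float
    gamma: float
    beta0: float
    beta: float
    phi_prime: float
    alpha: float
    psi: float

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v}")
        if self.phi_prime <= 0:
            raise ValueError("phi_prime must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (15,):
            raise ValueError(f"expected 15 parameters, got shape {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelParameters":
        return cls(**json.loads(text))

    def replace(self, **kw) -> "ModelParameters":
        d = asdict(self)
        d.update(kw)
        return ModelParameters(**d)


#: A plausible hand-picked parameter set used by examples and as the ground
#: truth of parameter-recovery experiments: dl import-favored, complex
#: export-favored, slow exchange, Toll width matching a ~0.15 gradient.
DEFAULT_TRUE_PARAMS = ModelParameters(
    zeta_dl=8.0, xi_dl=0.5,
    zeta_dc=0.3, xi_dc=2.5,
    zeta_cact=0.6, xi_cact=0.6,
    lambda_dl=0.05, lambda_dc=0.05, lambda_cact=0.05,
    gamma=1.0, beta0=0.005, beta=5.0, phi_prime=0.12, alpha=0.6, psi=1.0,
)


@dataclass
class EmbryoState:
    """Per-compartment concentrations at one instant.

    dl-containing fields (``U_*``, ``W_*``) are scaled by total dl
    concentration; Cact fields (``Z_*``) by total Cact concentration.  Nuclear
    fields are undefined during mitosis and held as ``None``.
    """

    phase: str
    U_cyt: np.ndarray
    W_cyt: np.ndarray
    Z_cyt: np.ndarray
    U_nuc: np.ndarray | None = None
    W_nuc: np.ndarray | None = None
    Z_nuc: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.U_cyt)

    def copy(self) -> "EmbryoState":
        return EmbryoState(
            phase=self.phase,
            U_cyt=self.U_cyt.copy(), W_cyt=self.W_cyt.copy(),
            Z_cyt=self.Z_cyt.copy(),
            U_nuc=None if self.U_nuc is None else self.U_nuc.copy(),
            W_nuc=None if self.W_nuc is None else self.W_nuc.copy(),
            Z_nuc=None if self.Z_nuc is None else self.Z_nuc.copy(),
        )

    def pack(self) -> np.ndarray:
        """Flatten to the integrator layout: (n, 6) or (n, 3) row-major."""
        if self.phase == INTERPHASE:
            return np.stack(
                [self.U_nuc, self.U_cyt, self.W_nuc, self.W_cyt,
                 self.Z_nuc, self.Z_cyt], axis=1
            ).ravel()
        return np.stack([self.U_cyt, self.W_cyt, self.Z_cyt], axis=1).ravel()

    @classmethod
    def unpack(cls, y: np.ndarray, phase: str) -> "EmbryoState":
        if phase == INTERPHASE:
            m = y.reshape(-1, 6)
            return cls(phase=phase, U_nuc=m[:, 0].copy(), U_cyt=m[:, 1].copy(),
                       W_nuc=m[:, 2].copy(), W_cyt=m[:, 3].copy(),
                       Z_nuc=m[:, 4].copy(), Z_cyt=m[:, 5].copy())
        m = y.reshape(-1, 3)
        return cls(phase=phase, U_cyt=m[:, 0].copy(), W_cyt=m[:, 1].copy(),
                   Z_cyt=m[:, 2].copy())

    def total_dl_mass(self, cyc: CycleSpec) -> float:
        """Volume-weighted total dl (free + complexed), NC14-nucleus units."""
        if self.phase == INTERPHASE:
            return float(
                np.sum(cyc.V_n_tilde * (self.U_nuc + self.W_nuc)
                       + cyc.V_C_tilde * (self.U_cyt + self.W_cyt))
            )
        return float(np.sum(cyc.prism_volume_tilde * (self.U_cyt + self.W_cyt)))


def toll_rate(z, beta: float, phi_prime: float, beta0: float):
    """Dissociation rate of cytoplasmic dl/Cact at DV position ``z``.

    A Gaussian centered on the ventral midline riding on the basal rate:
    ``beta * exp(-z**2 / (2 * phi_prime**2)) + beta0``.
    """
    if phi_prime <= 0:
        raise ValueError("phi_prime must be > 0")
    z = np.asarray(z, dtype=float)
    return beta * np.exp(-0.5 * (z / phi_prime) ** 2) + beta0


def _laplacian(c: np.ndarray) -> np.ndarray:
    """Nearest-neighbor exchange stencil with no-flux midline boundaries."""
    left = np.empty_like(c)
    right = np.empty_like(c)
    left[1:] = c[:-1]
    left[0] = c[0]
    right[:-1] = c[1:]
    right[-1] = c[-1]
    return left - 2.0 * c + right


def interphase_rhs(
    y: np.ndarray,
    p: ModelParameters,
    cyc: CycleSpec,
    z: np.ndarray,
    variant: str = "extended",
    cact_production: float = 1.0,
) -> np.ndarray:
    """Time derivative of the packed interphase state (n compartments x 6).

    Implements the six coupled balances per compartment: nuclear and
    cytoplasmic free dl, dl/Cact complex and Cact, with nuclear exchange
    scaled by the nuclear surface area ``A_n_tilde``, DV exchange by the
    shared face ``A_m_tilde``, and reactions by the pool volumes.  Toll-driven
    dissociation acts on cytoplasmic complex only; nuclear complex dissociates
    at the basal rate.  In the classic variant the nuclear pools of Cact and
    complex do not exist (their derivatives are zero and nuclear binding is
    absent).
    """
    m = y.reshape(-1, 6)
    if len(z) != m.shape[0] or m.shape[0] != cyc.n_nuclei:
        raise ValueError("state/positions/cycle dimension mismatch")
    U_n, U_c, W_n, W_c, Z_n, Z_c = (m[:, i] for i in range(6))
    An, Vn, VC, Am = cyc.A_n_tilde, cyc.V_n_tilde, cyc.V_C_tilde, cyc.A_m_tilde
    bhat = toll_rate(z, p.beta, p.phi_prime, p.beta0)

    diff_U = Am * p.lambda_dl * _laplacian(U_c)
    diff_W = Am * p.lambda_dc * _laplacian(W_c)
    diff_Z = Am * p.lambda_cact * _laplacian(Z_c)

    ex_U = An * (p.zeta_dl * U_c - p.xi_dl * U_n)
    cyt_rx = bhat * W_c - p.gamma * U_c * Z_c

    out = np.empty_like(m)
    if variant == "extended":
        nuc_rx = p.gamma * U_n * Z_n - p.beta0 * W_n
        ex_W = An * (p.zeta_dc * W_c - p.xi_dc * W_n)
        ex_Z = An * (p.zeta_cact * Z_c - p.xi_cact * Z_n)
        out[:, 0] = (ex_U - Vn * nuc_rx) / Vn
        out[:, 1] = (diff_U + VC * cyt_rx - ex_U) / VC
        out[:, 2] = (ex_W + Vn * nuc_rx) / Vn
        out[:, 3] = (diff_W - VC * cyt_rx - ex_W) / VC
        out[:, 4] = (ex_Z - Vn * p.psi * nuc_rx) / Vn
        out[:, 5] = (diff_Z + VC * p.psi * cyt_rx - p.alpha * Z_c
                     - ex_Z + cact_production) / VC
    elif variant == "classic":
        out[:, 0] = ex_U / Vn
        out[:, 1] = (diff_U + VC * cyt_rx - ex_U) / VC
        out[:, 2] = 0.0
        out[:, 3] = (diff_W - VC * cyt_rx) / VC
        out[:, 4] = 0.0
        out[:, 5] = (diff_Z + VC * p.psi * cyt_rx - p.alpha * Z_c
                     + cact_production) / VC
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return out.ravel()


def mitosis_rhs(
    y: np.ndarray,
    p: ModelParameters,
    cyc: CycleSpec,
    z: np.ndarray,
    cact_production: float = 1.0,
) -> np.ndarray:
    """Time derivative of the packed mitosis state (n compartments x 3).

    Cytoplasmic balances only: nuclei are dissolved, so all nuclear-exchange
    terms vanish and the cytoplasm occupies the full compartment prism.
    """
    m = y.reshape(-1, 3)
    if len(z) != m.shape[0] or m.shape[0] != cyc.n_nuclei:
        raise ValueError("state/positions/cycle dimension mismatch")
    U_c, W_c, Z_c = m[:, 0], m[:, 1], m[:, 2]
    V = cyc.prism_volume_tilde
    Am = cyc.A_m_tilde
    bhat = toll_rate(z, p.beta, p.phi_prime, p.beta0)
    cyt_rx = bhat * W_c - p.gamma * U_c * Z_c

    out = np.empty_like(m)
    out[:, 0] = (Am * p.lambda_dl * _laplacian(U_c) + V * cyt_rx) / V
    out[:, 1] = (Am * p.lambda_dc * _laplacian(W_c) - V * cyt_rx) / V
    out[:, 2] = (Am * p.lambda_cact * _laplacian(Z_c) + V * p.psi * cyt_rx
                 - p.alpha * Z_c + cact_production) / V
    return out.ravel()


def mix_at_mitosis(state: EmbryoState, cyc: CycleSpec) -> EmbryoState:
    """Mix each nucleus into its surrounding cytoplasm at mitosis onset.

    The mixed cytoplasmic concentration is the volume-weighted average
    ``(V_n * c_nuc + V_C * c_cyt) / (V_n + V_C)``; per-compartment amounts of
    every species are conserved exactly.
    """
    if state.phase != INTERPHASE:
        raise ValueError("mix_at_mitosis expects an interphase state")
    Vn, VC = cyc.V_n_tilde, cyc.V_C_tilde
    Vt = Vn + VC

    def mix(nuc, cyt):
        return (Vn * nuc + VC * cyt) / Vt

    return EmbryoState(
        phase=MITOSIS,
        U_cyt=mix(state.U_nuc, state.U_cyt),
        W_cyt=mix(state.W_nuc, state.W_cyt),
        Z_cyt=mix(state.Z_nuc, state.Z_cyt),
    )


def resample_piecewise_constant(values: np.ndarray, n_new: int) -> np.ndarray:
    """Cell-average a piecewise-constant profile onto a new uniform grid.

    Treats ``values`` as constant on ``n_old`` equal cells covering [0, 1] and
    returns the exact averages over ``n_new`` equal cells; the integral of the
    profile (hence total mass for equal-depth compartments) is preserved to
    machine precision.  For exact doubling each daughter pair inherits its
    parent's value unchanged.
    """
    values = np.asarray(values, dtype=float)
    n_old = len(values)
    if n_new == 2 * n_old:
        return np.repeat(values, 2)
    # cumulative integral of the old profile at old cell edges
    cum = np.concatenate([[0.0], np.cumsum(values) / n_old])
    edges_old = np.linspace(0.0, 1.0, n_old + 1)
    edges_new = np.linspace(0.0, 1.0, n_new + 1)
    cum_new = np.interp(edges_new, edges_old, cum)
    return np.diff(cum_new) * n_new


def start_interphase(
    cyt_state: EmbryoState, next_cyc: CycleSpec, variant: str = "extended"
) -> EmbryoState:
    """Initialize the next interphase from the cytoplasm-only mitotic state.

    The cytoplasmic profiles are remapped from the parent grid onto the
    roughly-doubled daughter grid by mass-conservative cell averaging.  In the
    extended variant the reforming nuclear envelopes enclose cytoplasm, so
    nuclear concentrations start equal to the cytoplasmic ones for all three
    species; in the classic variant nascent nuclei start empty.
    """
    if cyt_state.phase != MITOSIS:
        raise ValueError("start_interphase expects a cytoplasm-only state")
    n_new = next_cyc.n_nuclei
    U = resample_piecewise_constant(cyt_state.U_cyt, n_new)
    W = resample_piecewise_constant(cyt_state.W_cyt, n_new)
    Z = resample_piecewise_constant(cyt_state.Z_cyt, n_new)
    if variant == "extended":
        return EmbryoState(phase=INTERPHASE, U_cyt=U, W_cyt=W, Z_cyt=Z,
                           U_nuc=U.copy(), W_nuc=W.copy(), Z_nuc=Z.copy())
    if variant == "classic":
        zero = np.zeros(n_new)
        return EmbryoState(phase=INTERPHASE, U_cyt=U, W_cyt=W, Z_cyt=Z,
                           U_nuc=zero.copy(), W_nuc=zero.copy(),
                           Z_nuc=zero.copy())
    raise ValueError(f"unknown variant {variant!r}")


def initial_conditions(
    schedule: GeometrySchedule, p: ModelParameters, variant: str = "extended"
) -> EmbryoState:
    """Spatially uniform state at NC10 interphase onset.

    Free dl is zero, the dl/Cact complex is at unit concentration, and free
    Cact sits at the steady state of its production/degradation/transport
    balance with U = 0 and W = 1 frozen (basal dissociation only).  For the
    extended variant this is the 2x2 linear system coupling nuclear and
    cytoplasmic Cact; for the classic variant nuclear pools are empty and the
    cytoplasmic balance is scalar.
    """
    if p.alpha <= 0:
        raise ValueError("alpha must be > 0: Cact production has no steady state")
    cyc = schedule.cycle(10)
    n = cyc.n_nuclei
    An, Vn, VC = cyc.A_n_tilde, cyc.V_n_tilde, cyc.V_C_tilde
    ones = np.ones(n)
    zeros = np.zeros(n)

    if variant == "extended":
        # nuclear:      0 = An*(zc*Zc - xc*Zn) + Vn*psi*beta0*W_n,  W_n = 1
        # cytoplasmic:  0 = VC*psi*beta0*W_c - alpha*Zc - An*(zc*Zc - xc*Zn) + 1
        # Summing gives Zc; back-substitution gives Zn (xi_cact > 0 required).
        Zc = (p.psi * p.beta0 * (VC + Vn) + 1.0) / p.alpha
        if p.xi_cact > 0:
            Zn = (p.zeta_cact * Zc + Vn * p.psi * p.beta0 / An) / p.xi_cact
        elif p.zeta_cact == 0 and p.beta0 == 0:
            Zn = 0.0
        else:
            raise ValueError(
                "xi_cact = 0 with nuclear Cact influx: no nuclear steady state"
            )
        return EmbryoState(
            phase=INTERPHASE,
            U_cyt=zeros.copy(), W_cyt=ones.copy(), Z_cyt=Zc * ones,
            U_nuc=zeros.copy(), W_nuc=ones.copy(), Z_nuc=Zn * ones,
        )
    if variant == "classic":
        Zc = (VC * p.psi * p.beta0 + 1.0) / p.alpha
        return EmbryoState(
            phase=INTERPHASE,
            U_cyt=zeros.copy(), W_cyt=ones.copy(), Z_cyt=Zc * ones,
            U_nuc=zeros.copy(), W_nuc=zeros.copy(), Z_nuc=zeros.copy(),
        )
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class PhaseBlock:
    """Solution samples of one interphase or mitosis segment."""

    cycle_id: int
    phase: str
    times: np.ndarray  # absolute minutes, strictly increasing
    states: np.ndarray  # (nt, n, 6) interphase / (nt, n, 3) mitosis
    cyc: CycleSpec

    @property
    def dv_positions(self) -> np.ndarray:
        return self.cyc.dv_positions()


@dataclass
class Trajectory:
    """Ordered solution of a full NC10-NC14 simulation.

    Holds per-phase sample blocks (state dimension changes at interphase
    starts) together with the geometry schedule and model variant used.
    Concentrations in reported samples are clipped at zero; the integrator
    state itself is never clipped.
    """

    blocks: list
    schedule: GeometrySchedule
    variant: str

    def interphase_blocks(self):
        return [b for b in self.blocks if b.phase == INTERPHASE]

    def block_for_cycle(self, cycle_id: int, phase: str = INTERPHASE) -> PhaseBlock:
        for b in self.blocks:
            if b.cycle_id == cycle_id and b.phase == phase:
                return b
        raise KeyError(f"no block for NC{cycle_id} {phase}")

    def end_of_cycle_profile(self, cycle_id: int, component: str = "total"):
        """(dv_positions, profile) of nuclear signal at the interphase end."""
        b = self.block_for_cycle(cycle_id)
        m = b.states[-1]
        return b.dv_positions, _nuclear_component(m, component)

    def interphase_times(self) -> np.ndarray:
        return np.concatenate([b.times for b in self.interphase_blocks()])

    def nuclear_signal_on_grid(
        self, dv_positions, times, component: str = "total", atol: float = 1e-6
    ) -> np.ndarray:
        """Sample nuclear signal at (position, time) points of a data grid.

        Each requested DV position is mapped to its containing compartment at
        the relevant cycle (position-proportional), so a fine NC14-resolution
        grid can be compared against coarser early cycles.  Requested times
        must coincide with interphase sample times.
        """
        dv_positions = np.asarray(dv_positions, dtype=float)
        times = np.asarray(times, dtype=float)
        out = np.empty((len(dv_positions), len(times)))
        lookup = {}
        for b in self.interphase_blocks():
            for i, t in enumerate(b.times):
                lookup[round(float(t) / atol)] = (b, i)
        for k, t in enumerate(times):
            key = round(float(t) / atol)
            if key not in lookup:
                raise ValueError(f"time {t} min is not an interphase sample")
            b, i = lookup[key]
            n = b.cyc.n_nuclei
            idx = np.minimum((dv_positions * n).astype(int), n - 1)
            prof = _nuclear_component(b.states[i], component)
            out[:, k] = prof[idx]
        return out

    def to_frame(self):
        """Tidy table: one row per (time, compartment) sample."""
        import pandas as pd

        rows = []
        for b in self.blocks:
            z = b.dv_positions
            for i, t in enumerate(b.times):
                m = b.states[i]
                for h in range(b.cyc.n_nuclei):
                    if b.phase == INTERPHASE:
                        vals = dict(zip(SPECIES_6, m[h]))
                    else:
                        vals = dict(zip(SPECIES_6, [np.nan] * 6))
                        vals.update(dict(zip(SPECIES_3, m[h])))
                    rows.append(
                        dict(time_min=t, cycle=b.cycle_id, phase=b.phase,
                             compartment=h, dv_position=z[h], **vals)
                    )
        return pd.DataFrame(rows)


def _nuclear_component(m: np.ndarray, component: str) -> np.ndarray:
    if component == "total":
        return m[:, 0] + m[:, 2]  # U_nuc + W_nuc
    if component == "free":
        return m[:, 0]
    if component == "complex":
        return m[:, 2]
    raise ValueError(f"unknown component {component!r}")


def _integrate_phase(y0, rhs_args, duration, t0, rtol, atol, n_species,
                     max_steps=100000):
    """Integrate one phase with LSODA on a 1-min output grid (plus endpoint)."""
    n_min = int(np.floor(duration + 1e-9))
    grid = list(np.arange(0.0, n_min + 1.0))
    if grid[-1] < duration - 1e-9:
        grid.append(duration)
    grid = np.asarray(grid)
    rhs, args = rhs_args
    # nearest-neighbor coupling in compartment-major layout; LSODA requires
    # the band to be narrower than the state itself (single-compartment case)
    band = min(n_species, len(y0) - 1)
    sol, info = odeint(
        lambda t, y: rhs(y, *args),
        y0,
        grid,
        tfirst=True,
        rtol=rtol,
        atol=atol,
        ml=band,
        mu=band,
        mxstep=max_steps,
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise RuntimeError(f"integrator failed: {info['message']}")
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("non-finite state during integration")
    return grid + t0, sol


def simulate(
    p: ModelParameters,
    schedule: GeometrySchedule,
    variant: str = "extended",
    rtol: float = 1e-6,
    atol: float = 1e-9,
    cact_production: float = 1.0,
    max_steps: int = 100000,
) -> Trajectory:
    """Run the full NC10-NC14 simulation.

    Alternates interphase integration, nuclear-cytoplasmic mixing, mitosis
    integration and nascent-nucleus initialization, with hard integrator
    restarts at every phase boundary.  Output is sampled on a 1-minute grid
    within each phase.  Reported concentrations are clipped at zero;
    undershoot beyond ``10 * atol`` triggers a warning.

    Raises ``RuntimeError`` with cycle/phase context on integrator failure.
    """
    if variant not in ("extended", "classic"):
        raise ValueError(f"unknown variant {variant!r}")
    state = initial_conditions(schedule, p, variant)
    blocks = []
    t = 0.0
    for cyc in schedule.cycles:
        z = cyc.dv_positions()
        # --- interphase ---
        try:
            times, sol = _integrate_phase(
                state.pack(),
                (interphase_rhs, (p, cyc, z, variant, cact_production)),
                cyc.interphase_duration, t, rtol, atol, 6, max_steps,
            )
        except RuntimeError as e:
            raise RuntimeError(f"NC{cyc.cycle_id} interphase: {e}") from e
        _check_undershoot(sol, atol, cyc.cycle_id, INTERPHASE)
        blocks.append(PhaseBlock(cyc.cycle_id, INTERPHASE, times,
                                 np.clip(sol, 0.0, None).reshape(len(times), -1, 6),
                                 cyc))
        state = EmbryoState.unpack(sol[-1], INTERPHASE)
        t = times[-1]
        if cyc.mitosis_duration is None:
            break
        # --- mitosis ---
        state = mix_at_mitosis(state, cyc)
        try:
            times, sol = _integrate_phase(
                state.pack(),
                (mitosis_rhs, (p, cyc, z, cact_production)),
                cyc.mitosis_duration, t, rtol, atol, 3, max_steps,
            )
        except RuntimeError as e:
            raise RuntimeError(f"NC{cyc.cycle_id} mitosis: {e}") from e
        _check_undershoot(sol, atol, cyc.cycle_id, MITOSIS)
        blocks.append(PhaseBlock(cyc.cycle_id, MITOSIS, times,
                                 np.clip(sol, 0.0, None).reshape(len(times), -1, 3),
                                 cyc))
        state = EmbryoState.unpack(sol[-1], MITOSIS)
        t = times[-1]
        next_cyc = schedule.cycle(cyc.cycle_id + 1)
        state = start_interphase(state, next_cyc, variant)
    return Trajectory(blocks=blocks, schedule=schedule, variant=variant)


def _check_undershoot(sol, atol, cycle_id, phase):
    low = sol.min()
    if low < -10.0 * atol:
        warnings.warn(
            f"NC{cycle_id} {phase}: concentration undershoot to {low:.3e}",
            RuntimeWarning,
            stacklevel=3,
        )
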