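"""Threshold-plus-noise read-out of the nuclear dl gradient into mRNA patterns.

Each target gene follows a linear production-degradation balance
``d[mRNA]_i/dt = (f_i - [mRNA]_i) / tau_i`` in every nucleus, with a
hard-threshold production switch (Hill exponent ``n_H = 100`` by default):
sna turns on above its dl threshold; vnd and sog turn on above theirs but are
repressed when sna exceeds their sna-thresholds; zen turns on only below its
dl threshold (dl-repressed, dorsal domain).  Read-out noise enters as an
effective dl concentration ``U_eff = U_nuc (1 + eta N(0,1))`` clipped at
zero, redrawn independently per nucleus, per gene, at each one-minute step --
emulating the stochastic arrival of dl molecules at enhancer sites rather
than fluctuations of nuclear dl itself.

The dl input is either free nuclear dl (``U_nuc``, the transcriptionally
active pool) or total nuclear dl (``U_nuc + W_nuc``, what fluorescence
reports); contrasting the two is the point of the downstream analyses.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .dynamics import Trajectory
from .ea import EAConfig, FitResult, run_ea
from .synthetic import GENES

__all__ = [
    "GeneParameters",
    "ExpressionProfile",
    "effective_dl",
    "production_rate",
    "simulate_expression",
    "boundary_position",
    "boundary_width",
    "fit_expression",
    "sensitivity_scan",
    "dl_input_from_trajectory",
    "GENE_PARAM_NAMES",
    "DEFAULT_ETA_GRID",
]

# Flat ordering used by the EA: four dl thresholds, four lifetimes, two sna
# repression thresholds.
GENE_PARAM_NAMES = (
    "theta_dl_sna", "theta_dl_vnd", "theta_dl_sog", "theta_dl_zen",
    "tau_sna", "tau_vnd", "tau_sog", "tau_zen",
    "theta_sna_vnd", "theta_sna_sog",
)

#: Nine noise levels spanning the studied range 0.02-0.5, evenly spaced.
DEFAULT_ETA_GRID = (0.02, 0.08, 0.14, 0.20, 0.26, 0.32, 0.38, 0.44, 0.50)


@dataclass(frozen=True)
class GeneParameters:
    """Per-gene thresholds/lifetimes plus the global noise and Hill exponent.

    Thresholds are in scaled dl units, lifetimes in minutes, ``eta`` is the
    multiplicative read-out noise amplitude, and ``n_H`` the Hill exponent of
    the (near-hard) threshold switch.
    """

    theta_dl: dict  # gene -> activation (zen: repression) threshold
    tau: dict  # gene -> mRNA lifetime, minutes
    theta_sna: dict  # vnd/sog -> sna repression threshold
    eta: float = 0.2
    n_H: float = 100.0

    def __post_init__(self):
        for g in GENES:
            if self.theta_dl[g] < 0:
                raise ValueError(f"theta_dl[{g}] must be >= 0")
            if self.tau[g] <= 0:
                raise ValueError(f"tau[{g}] must be > 0")
        for g in ("vnd", "sog"):
            if self.theta_sna[g] < 0:
                raise ValueError(f"theta_sna[{g}] must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.n_H < 1:
            raise ValueError("n_H must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.theta_dl[g] for g in GENES]
            + [self.tau[g] for g in GENES]
            + [self.theta_sna["vnd"], self.theta_sna["sog"]]
        )

    @classmethod
    def from_array(cls, arr, eta: float = 0.2, n_H: float = 100.0):
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (10,):
            raise ValueError(f"expected 10 gene parameters, got {arr.shape}")
        return cls(
            theta_dl=dict(zip(GENES, arr[:4])),
            tau=dict(zip(GENES, arr[4:8])),
            theta_sna={"vnd": arr[8], "sog": arr[9]},
            eta=eta,
            n_H=n_H,
        )


@dataclass
class ExpressionProfile:
    """Replicate-averaged mRNA levels over time and the final spatial profile."""

    dv_positions: np.ndarray
    times: np.ndarray
    mrna: np.ndarray  # (n_nuclei, n_times, 4), gene order as GENES
    replicate_count: int

    @property
    def final(self) -> np.ndarray:
        """Final-time spatial profile, (n_nuclei, 4)."""
        return self.mrna[:, -1, :]

    def final_for(self, gene: str) -> np.ndarray:
        return self.final[:, GENES.index(gene)]


def effective_dl(U_nuc, eta: float, rng: np.random.Generator):
    """Noisy effective dl: ``max(0, U_nuc (1 + eta N(0,1)))`` elementwise."""
    U_nuc = np.asarray(U_nuc, dtype=float)
    if eta == 0:
        return U_nuc.copy()
    draw = rng.standard_normal(U_nuc.shape)
    return np.maximum(U_nuc + eta * draw * U_nuc, 0.0)


def _hill_act(u, theta, n):
    """Activating Hill switch u^n/(u^n + theta^n), computed in log space.

    The identity ``u^n/(u^n+theta^n) = expit(n (ln u - ln theta))`` avoids
    overflow at large Hill exponents; the theta -> 0 limit is a step at zero.
    """
    from scipy.special import expit

    u = np.asarray(u, dtype=float)
    if theta == 0:
        return np.where(u > 0, 1.0, 0.0)
    with np.errstate(divide="ignore"):
        out = expit(n * (np.log(np.maximum(u, 0.0)) - np.log(theta)))
    return out


def _hill_rep(u, theta, n):
    return 1.0 - _hill_act(u, theta, n)


def production_rate(gene: str, U_eff, sna_level, gp: GeneParameters):
    """Production switch ``f`` in [0, 1] for one gene.

    sna: on above its dl threshold.  vnd/sog: on above their dl thresholds
    AND below their sna thresholds (activation x repression).  zen: on below
    its dl threshold.
    """
    n = gp.n_H
    if gene == "sna":
        return _hill_act(U_eff, gp.theta_dl["sna"], n)
    if gene in ("vnd", "sog"):
        return _hill_act(U_eff, gp.theta_dl[gene], n) * _hill_rep(
            sna_level, gp.theta_sna[gene], n
        )
    if gene == "zen":
        return _hill_rep(U_eff, gp.theta_dl["zen"], n)
    raise ValueError(f"unknown gene {gene!r}")


def dl_input_from_trajectory(traj: Trajectory, component: str = "free"):
    """(times, dl matrix (n14, nt)) on the NC14 grid over all interphases.

    Early cycles are mapped position-proportionally onto the NC14 nucleus
    grid, which also encodes daughter inheritance across divisions.
    """
    n14 = traj.schedule.n14
    z = (np.arange(n14) + 0.5) / n14
    times = traj.interphase_times()
    return times, traj.nuclear_signal_on_grid(z, times, component=component)


def simulate_expression(
    dl_times: np.ndarray,
    dl_matrix: np.ndarray,
    gp: GeneParameters,
    rng: np.random.Generator | int = 0,
    replicate_count: int = 10,
    dv_positions: np.ndarray | None = None,
) -> ExpressionProfile:
    """Integrate the four mRNA balances driven by a per-nucleus dl series.

    ``dl_matrix`` is (n_nuclei, nt) sampled at ``dl_times`` (1-minute cadence
    within interphases; larger gaps are mitoses).  Within each step the
    production switch is held at the noisy start-of-step value and the linear
    balance is advanced exactly; sna is updated first and its new level feeds
    the vnd/sog repression within the same step.  Production is off during
    mitosis gaps (nuclei absent) while decay continues.  The returned levels
    are averaged over ``replicate_count`` independent noise histories.
    """
    if replicate_count < 1:
        raise ValueError("replicate_count must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n, nt = dl_matrix.shape
    if dv_positions is None:
        dv_positions = (np.arange(n) + 0.5) / n
    taus = np.array([gp.tau[g] for g in GENES])
    acc = np.zeros((n, nt, 4))
    for _ in range(replicate_count):
        m = np.zeros((n, 4))
        out = np.zeros((n, nt, 4))
        for k in range(1, nt):
            dt = dl_times[k] - dl_times[k - 1]
            decay = np.exp(-dt / taus)
            if dt > 1.0 + 1e-9:  # mitosis gap: decay only
                m = m * decay
                out[:, k, :] = m
                continue
            U = dl_matrix[:, k - 1]
            f = np.empty((n, 4))
            U_eff_sna = effective_dl(U, gp.eta, rng)
            f[:, 0] = production_rate("sna", U_eff_sna, None, gp)
            m_new = np.empty_like(m)
            m_new[:, 0] = f[:, 0] + (m[:, 0] - f[:, 0]) * decay[0]
            sna_now = m_new[:, 0]
            for j, g in enumerate(GENES[1:], start=1):
                U_eff = effective_dl(U, gp.eta, rng)
                f[:, j] = production_rate(g, U_eff, sna_now, gp)
                m_new[:, j] = f[:, j] + (m[:, j] - f[:, j]) * decay[j]
            m = m_new
            out[:, k, :] = m
        acc += out
    return ExpressionProfile(
        dv_positions=np.asarray(dv_positions),
        times=np.asarray(dl_times),
        mrna=acc / replicate_count,
        replicate_count=replicate_count,
    )


def _half_max_crossing(z, prof, start: int, step: int, half: float):
    """March from ``start`` in direction ``step`` to the first drop below half."""
    i = start
    j = i + step
    while 0 <= j < len(prof):
        if prof[j] < half <= prof[i]:
            # linear interpolation between nucleus centers
            frac = (prof[i] - half) / (prof[i] - prof[j])
            return float(z[i] + frac * (z[j] - z[i]))
        i = j
        j += step
    return None


def boundary_position(profile, dv_positions=None, gene: str = "sna"):
    """DV fraction of the half-max expression border, or None if no domain.

    For the ventral/band genes (sna, vnd, sog) the border is the dorsal edge:
    the first half-max crossing dorsal of the profile maximum.  For zen (a
    dorsal domain) it is the ventral edge, sought moving ventrally from the
    maximum.  Crossings are linearly interpolated between nucleus centers.
    """
    prof = np.asarray(profile, dtype=float)
    if dv_positions is None:
        n = len(prof)
        dv_positions = (np.arange(n) + 0.5) / n
    z = np.asarray(dv_positions, dtype=float)
    peak = prof.max()
    if peak <= 1e-9:  # never meaningfully expressed: no domain
        return None
    half = 0.5 * peak
    imax = int(np.argmax(prof))
    step = -1 if gene == "zen" else +1
    return _half_max_crossing(z, prof, imax, step, half)


def boundary_width(profile, dv_positions=None, gene: str = "sna",
                   lo: float = 0.1, hi: float = 0.9):
    """Width of the border: distance between hi- and lo-fraction crossings.

    A crossing that never occurs before the end of the axis (heavy read-out
    noise can keep expression above the low fraction all the way to the
    midline) is clamped to the terminal nucleus position, so the width stays
    defined and grows as borders smear out.
    """
    prof = np.asarray(profile, dtype=float)
    if dv_positions is None:
        n = len(prof)
        dv_positions = (np.arange(n) + 0.5) / n
    z = np.asarray(dv_positions, dtype=float)
    peak = prof.max()
    if peak <= 1e-9:
        return None
    imax = int(np.argmax(prof))
    step = -1 if gene == "zen" else +1
    edge = z[0] if step < 0 else z[-1]
    a = _half_max_crossing(z, prof, imax, step, hi * peak)
    b = _half_max_crossing(z, prof, imax, step, lo * peak)
    a = edge if a is None else a
    b = edge if b is None else b
    return abs(b - a)


def _objective_seed(params: np.ndarray, base_seed: int) -> int:
    """Order-independent, reproducible per-individual noise seed."""
    digest = zlib.crc32(np.round(params, 12).tobytes())
    return (digest ^ (base_seed * 2654435761)) % (2**31 - 1)


def fit_expression(
    dl_times: np.ndarray,
    dl_matrix: np.ndarray,
    fish_z: np.ndarray,
    fish_levels: np.ndarray,
    eta_values=(0.2,),
    ea_cfg: EAConfig | None = None,
    replicate_count: int = 10,
    n_H: float = 100.0,
) -> dict:
    """Fit gene parameters against FISH-like profiles, one EA run per eta.

    The objective is the unweighted sum of squared differences between the
    replicate-averaged simulated final NC14 profiles and the target profiles,
    summed over nuclei and genes.  dl thresholds are initialized uniformly
    over the input gradient's actual range (the point of the initialization
    box is that thresholds start inside the gradient's span), sna thresholds
    over the unit mRNA range, and lifetimes in [0, 3] minutes; lifetimes may
    evolve outside that range.  Returns ``{eta: FitResult}``.
    """
    if ea_cfg is None:
        ea_cfg = EAConfig(
            param_names=GENE_PARAM_NAMES, lam=250, mu=50, generations=25,
            init_mode="uniform", bounds=(0.0, 3.0),
        )
    if dl_matrix.shape[0] != len(fish_z):
        raise ValueError("FISH grid must match the dl input's NC14 nuclei")
    if ea_cfg.bounds_per_param is None:
        import dataclasses

        theta_hi = max(1.05 * float(np.max(dl_matrix)), 1e-6)
        bpp = tuple(
            [(0.0, theta_hi)] * 4          # dl thresholds: gradient range
            + [ea_cfg.bounds] * 4          # lifetimes, minutes
            + [(0.0, 1.0)] * 2             # sna-repression thresholds
        )
        ea_cfg = dataclasses.replace(ea_cfg, bounds_per_param=bpp)
    results = {}
    for eta in eta_values:
        def objective(vec, _eta=eta):
            gp = GeneParameters.from_array(vec, eta=_eta, n_H=n_H)
            seed = _objective_seed(vec, ea_cfg.seed)
            prof = simulate_expression(
                dl_times, dl_matrix, gp,
                rng=np.random.default_rng(seed),
                replicate_count=replicate_count,
            )
            resid = prof.final - fish_levels
            return float(np.sum(resid * resid))

        results[eta] = run_ea(objective, ea_cfg)
    return results


def sensitivity_scan(
    best_gp: GeneParameters,
    dl_times: np.ndarray,
    dl_matrix: np.ndarray,
    params_to_vary=None,
    delta: float = 0.1,
    replicate_count: int = 10,
    seed: int = 0,
) -> dict:
    """Profile discrepancy under +-``delta`` perturbation of each parameter.

    Reruns the expression simulation with each named parameter scaled by
    (1 +- delta) and reports the mean absolute difference of the final
    profiles against the unperturbed run, per gene.  Parameter names follow
    ``GENE_PARAM_NAMES`` plus ``"eta"``.
    """
    if params_to_vary is None:
        params_to_vary = list(GENE_PARAM_NAMES) + ["eta"]
    base_vec = best_gp.as_array()

    def run(vec, eta):
        gp = GeneParameters.from_array(vec, eta=eta, n_H=best_gp.n_H)
        return simulate_expression(
            dl_times, dl_matrix, gp, rng=np.random.default_rng(seed),
            replicate_count=replicate_count,
        ).final

    ref = run(base_vec, best_gp.eta)
    out = {}
    for name in params_to_vary:
        entry = {}
        for sign, factor in (("minus", 1.0 - delta), ("plus", 1.0 + delta)):
            vec = base_vec.copy()
            eta = best_gp.eta
            if name == "eta":
                eta = min(best_gp.eta * factor, 1.0)
            else:
                vec[GENE_PARAM_NAMES.index(name)] *= factor
            prof = run(vec, eta)
            entry[sign] = {
                "mean_abs_diff": float(np.mean(np.abs(prof - ref))),
                "per_gene": {
                    g: float(np.mean(np.abs(prof[:, j] - ref[:, j])))
                    for j, g in enumerate(GENES)
                },
            }
        out[name] = entry
    return out
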