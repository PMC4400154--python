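"""Surrogate datasets with the statistical structure of the study inputs.

Neither the dl-Venus live-imaging dataset nor the FISH gene-expression
profiles this kind of analysis is fit against are publicly deposited, so this
module generates surrogates that encode their documented features:

* a ventral "saw tooth" -- nuclear fluorescence builds within each interphase
  and collapses at mitosis;
* dorsal-most nuclei whose signal slowly declines within interphase and
  recovers at the next cycle start (the declining basal level);
* an approximately Gaussian spatial gradient of constant width
  ``sigma ~= 0.15`` (fraction of the DV half-axis);
* gene-expression borders near 20% (sna), 33% (vnd) and 50% (sog) DV, plus a
  dorsal zen domain.

It also builds model-generated "truth" datasets (simulate, scale, add noise,
remember the generating parameters) for parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import ModelParameters, Trajectory, simulate
from .geometry import GeometrySchedule, build_schedule
from .observable import SpatioTemporalDataset, fluorescence_signal

__all__ = [
    "SurrogateConfig",
    "FishConfig",
    "generate_surrogate_venus",
    "generate_truth_dataset",
    "generate_fish_profiles",
    "GENES",
]

GENES = ("sna", "vnd", "sog", "zen")


@dataclass(frozen=True)
class SurrogateConfig:
    """Shape parameters of the surrogate fluorescence dataset.

    Amplitudes are expressed relative to the NC14 end-of-interphase peak
    amplitude (= 1).  ``amp_end`` sets the ventral Gaussian amplitude reached
    at the end of each interphase NC10..NC14; each interphase starts at
    ``mitotic_drop`` times its own end amplitude and rises linearly.  The
    basal (dorsal plateau) level starts each interphase at ``basal_start`` and
    decays linearly to ``basal_end``, emulating the declining basal levels:
    the NC14 default (0.20 -> 0.115) leaves the end-of-NC14 profile with a
    ~20% drop between 40% DV and the dorsal midline.
    """

    gradient_width: float = 0.15
    amp_end: tuple = (0.25, 0.40, 0.55, 0.75, 1.0)
    mitotic_drop: float = 0.45
    basal_start: tuple = (0.40, 0.35, 0.30, 0.25, 0.20)
    basal_end: tuple = (0.35, 0.30, 0.25, 0.20, 0.115)
    noise_frac: float = 0.05
    dX_floor: float = 0.01
    n14: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.gradient_width <= 0:
            raise ValueError("gradient_width must be > 0")
        if self.noise_frac <= 0:
            raise ValueError("noise_frac must be > 0")


@dataclass(frozen=True)
class FishConfig:
    """Half-max borders and sharpness of the FISH-like target profiles."""

    sna_border: float = 0.20
    vnd_border: float = 0.33
    sog_border: float = 0.50
    zen_border: float = 0.55
    sharpness: float = 0.02  # logistic width, DV fraction
    n14: int = 50

    def __post_init__(self):
        b = (self.sna_border, self.vnd_border, self.sog_border)
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValueError("borders must satisfy 0 < sna < vnd < sog < 1")
        if not 0 < self.zen_border < 1:
            raise ValueError("zen border must lie inside (0, 1)")


def _interphase_grid(schedule: GeometrySchedule):
    """Integer-minute interphase sample times and their cycle labels."""
    times, cycles = [], []
    t = 0.0
    for cyc in schedule.cycles:
        n_min = int(round(cyc.interphase_duration))
        for m in range(n_min + 1):
            times.append(t + m)
            cycles.append(cyc.cycle_id)
        t += cyc.interphase_duration + (cyc.mitosis_duration or 0.0)
    return np.asarray(times), np.asarray(cycles, dtype=int)


def generate_surrogate_venus(
    cfg: SurrogateConfig = SurrogateConfig(),
    schedule: GeometrySchedule | None = None,
) -> SpatioTemporalDataset:
    """Generate the dl-Venus-like surrogate fluorescence dataset.

    ``X_hk = A_i(t) exp(-z^2 / (2 sigma^2)) + b_i(t) + eps`` on the NC14
    nucleus grid at 1-minute cadence during interphases (mitoses are gaps),
    with multiplicative Gaussian measurement noise and ``dX = noise_frac * X``
    floored at ``dX_floor``.
    """
    if schedule is None:
        schedule = build_schedule(n14=cfg.n14)
    rng = np.random.default_rng(cfg.seed)
    times, cycles = _interphase_grid(schedule)
    n = cfg.n14
    z = (np.arange(n) + 0.5) / n
    shape = np.exp(-(z**2) / (2.0 * cfg.gradient_width**2))

    X = np.empty((n, len(times)))
    for k, (t, cid) in enumerate(zip(times, cycles)):
        i = cid - 10
        cyc = schedule.cycle(cid)
        t0 = sum(
            c.interphase_duration + (c.mitosis_duration or 0.0)
            for c in schedule.cycles
            if c.cycle_id < cid
        )
        frac = (t - t0) / cyc.interphase_duration
        A = cfg.amp_end[i] * (cfg.mitotic_drop + (1.0 - cfg.mitotic_drop) * frac)
        b = cfg.basal_start[i] + (cfg.basal_end[i] - cfg.basal_start[i]) * frac
        X[:, k] = A * shape + b
    X_clean = X.copy()
    X = X_clean * (1.0 + cfg.noise_frac * rng.standard_normal(X.shape))
    X = np.clip(X, 1e-6, None)
    dX = np.maximum(cfg.noise_frac * X_clean, cfg.dX_floor)
    return SpatioTemporalDataset(
        X=X, dX=dX, dv_positions=z, times=times, cycles=cycles
    )


@dataclass
class TruthDataset:
    """A model-generated dataset plus its generating ground truth."""

    dataset: SpatioTemporalDataset
    true_params: ModelParameters
    true_scale: float
    trajectory: Trajectory


def generate_truth_dataset(
    p: ModelParameters,
    schedule: GeometrySchedule,
    noise_frac: float = 0.05,
    seed: int = 0,
    scale: float = 100.0,
    variant: str = "extended",
    dX_floor: float | None = None,
) -> TruthDataset:
    """Simulate, scale, and noise a dataset from known parameters.

    Used by parameter-recovery experiments: the generating parameters and
    scale are recorded so fitted populations can be scored against them.
    """
    traj = simulate(p, schedule, variant=variant)
    times, cycles = _interphase_grid(schedule)
    n14 = schedule.n14
    z = (np.arange(n14) + 0.5) / n14
    Y = traj.nuclear_signal_on_grid(z, times, component="total")
    rng = np.random.default_rng(seed)
    clean = scale * Y
    X = clean * (1.0 + noise_frac * rng.standard_normal(clean.shape))
    if dX_floor is None:
        dX_floor = 1e-3 * scale
    dX = np.maximum(noise_frac * clean, dX_floor)
    if noise_frac == 0:
        X = clean
    ds = SpatioTemporalDataset(
        X=np.clip(X, 0.0, None), dX=dX, dv_positions=z, times=times, cycles=cycles
    )
    return TruthDataset(dataset=ds, true_params=p, true_scale=scale, trajectory=traj)


def _logistic_up(z, border, w):
    return 1.0 / (1.0 + np.exp(-(z - border) / w))


def _logistic_down(z, border, w):
    return 1.0 / (1.0 + np.exp((z - border) / w))


def generate_fish_profiles(cfg: FishConfig = FishConfig()) -> pd.DataFrame:
    """FISH-like target profiles for sna, vnd, sog and zen at NC14.

    sna fills [0, sna_border]; vnd and sog are bands whose ventral edge sits
    at the sna border (they are sna-repressed there) and whose dorsal
    half-max edges sit at the configured vnd/sog borders; zen occupies the
    dorsal domain beyond its border.  Levels are in [0, 1] on the NC14
    nucleus-center grid.  Columns: gene, dv_position, level.
    """
    n = cfg.n14
    z = (np.arange(n) + 0.5) / n
    w = cfg.sharpness
    profiles = {
        "sna": _logistic_down(z, cfg.sna_border, w),
        "vnd": _logistic_up(z, cfg.sna_border, w) * _logistic_down(z, cfg.vnd_border, w),
        "sog": _logistic_up(z, cfg.sna_border, w) * _logistic_down(z, cfg.sog_border, w),
        "zen": _logistic_up(z, cfg.zen_border, w),
    }
    rows = []
    for gene in GENES:
        for zi, v in zip(z, profiles[gene]):
            rows.append({"gene": gene, "dv_position": zi, "level": v})
    return pd.DataFrame(rows)


def fish_profile_matrix(df: pd.DataFrame):
    """(dv_positions, levels matrix (n, 4)) from a tidy FISH profile table."""
    z = np.sort(df["dv_position"].unique())
    mat = np.column_stack(
        [
            df[df["gene"] == g].sort_values("dv_position")["level"].to_numpy()
            for g in GENES
        ]
    )
    return z, mat
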