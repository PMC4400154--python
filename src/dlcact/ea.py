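"""(lambda + mu) evolutionary strategy for rate-constant and gene-parameter fits.

Each optimization run starts from ``lam`` individuals drawn either from a
discrete log-spanning value grid (dynamics fits; entries for exchange rates
and basal dissociation damped 100-fold) or uniformly from a box (gene fits).
The top ``mu`` individuals are grouped into mating sets of five; each group
produces children by per-parameter uniform crossover between two randomly
chosen parents followed by a multiplicative log-space mutation biased toward
the group leader.  Survivors are the best ``mu`` of the union of parents and
children (strict elitism), so the best score never increases.  Runs are fully
deterministic given the seed, and individual evaluations are independent of
evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EAConfig",
    "FitResult",
    "EquilibriumSummary",
    "value_grid",
    "init_population",
    "evaluate_population",
    "next_generation",
    "run_ea",
    "weighted_param_stats",
    "weighted_median",
    "equilibrium_constants",
]

log = logging.getLogger(__name__)

IMPORT_EXPORT_PAIRS = {
    "dl": ("zeta_dl", "xi_dl"),
    "dl/Cact": ("zeta_dc", "xi_dc"),
    "Cact": ("zeta_cact", "xi_cact"),
}


def value_grid() -> np.ndarray:
    """The discrete initialization set {1..9} x 10^{-2,-1,0} (27 values)."""
    return np.array(
        [d * 10.0**e for e in (-2, -1, 0) for d in range(1, 10)], dtype=float
    )


@dataclass(frozen=True)
class EAConfig:
    """Settings of one evolutionary optimization run.

    The dynamics-fit configuration of record is ``lam=500, mu=100`` with 25
    generations; gene-expression fits use ``lam=250, mu=50``.  Reduced
    configurations (smaller ``lam``/``generations``) keep the same operators.
    """

    param_names: tuple
    lam: int = 500
    mu: int = 100
    group_size: int = 5
    generations: int = 25
    seed: int = 0
    # initialization: either the discrete grid (with damped names) or a box
    init_mode: str = "grid"  # "grid" | "uniform"
    damped_params: tuple = ()
    bounds: tuple = (0.0, 3.0)  # uniform-init box, gene fits
    # optional per-parameter (lo, hi) init ranges overriding `bounds`
    bounds_per_param: tuple | None = None
    # mutation scheme: a per-parameter mutation probability, a log-normal
    # scale, and a pull toward the group leader; mutation_sigma_final, when
    # set, anneals the scale geometrically across the run
    mutation_rate: float = 0.25
    leader_bias: float = 0.1
    mutation_sigma: float = 0.5
    mutation_sigma_final: float | None = None
    # success-rule step-size control: when enabled, the scale grows by
    # adapt_factor whenever more than adapt_success of a generation's
    # children enter the elite and shrinks otherwise (annealing is ignored)
    sigma_adapt: bool = False
    adapt_factor: float = 1.5
    adapt_success: float = 0.2
    sigma_min: float = 0.02
    sigma_max: float = 3.0

    def __post_init__(self):
        if self.mu > self.lam:
            raise ValueError("mu must not exceed lam")
        if self.mu % self.group_size:
            raise ValueError("mu must be divisible by group_size")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.init_mode not in ("grid", "uniform"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")

    def sigma_at(self, generation: int) -> float:
        """Mutation scale for a 1-based generation, annealed geometrically."""
        s0, s1 = self.mutation_sigma, self.mutation_sigma_final
        if s1 is None or s0 == 0 or self.generations == 1:
            return s0
        frac = (generation - 1) / (self.generations - 1)
        return float(s0 * (s1 / s0) ** frac)

    @property
    def n_params(self) -> int:
        return len(self.param_names)


@dataclass
class FitResult:
    """Ranked survivors of one run plus RSS-weighted parameter statistics."""

    param_names: tuple
    params: np.ndarray  # (mu, d), ranked best-first
    rss: np.ndarray  # (mu,), non-decreasing
    weighted_mean: np.ndarray
    weighted_std: np.ndarray
    weighted_median_rss: float
    history: list = field(default_factory=list)  # (generation, best, median)

    @property
    def best_params(self) -> np.ndarray:
        return self.params[0]

    @property
    def best_rss(self) -> float:
        return float(self.rss[0])

    def to_records(self):
        return [
            {"rank": i, "rss": float(r), **dict(zip(self.param_names, p))}
            for i, (p, r) in enumerate(zip(self.params, self.rss))
        ]


@dataclass
class EquilibriumSummary:
    """log10 nuclear import/export equilibrium constants across runs."""

    log_ratios: dict  # species -> array over runs
    quantiles: dict  # species -> (q25, median, q75)


def init_population(cfg: EAConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the initial (lam, d) parameter matrix."""
    d = cfg.n_params
    if cfg.init_mode == "grid":
        grid = value_grid()
        P = rng.choice(grid, size=(cfg.lam, d))
        damp = [i for i, n in enumerate(cfg.param_names) if n in cfg.damped_params]
        P[:, damp] /= 100.0
        return P
    if cfg.bounds_per_param is not None:
        b = np.asarray(cfg.bounds_per_param, dtype=float)
        if b.shape != (d, 2):
            raise ValueError("bounds_per_param must be (n_params, 2)")
        return rng.uniform(b[:, 0], b[:, 1], size=(cfg.lam, d))
    lo, hi = cfg.bounds
    return rng.uniform(lo, hi, size=(cfg.lam, d))


def evaluate_population(P: np.ndarray, objective) -> np.ndarray:
    """Score each row; failures map to +inf rather than crashing the run.

    Rows are evaluated independently, so scores do not depend on evaluation
    order and a parallel map would produce identical results.
    """
    scores = np.empty(len(P))
    for i, row in enumerate(P):
        try:
            s = float(objective(row))
        except Exception as e:  # noqa: BLE001 - objective failures are data
            log.warning("objective failed on individual %d: %s", i, e)
            s = np.inf
        scores[i] = s if np.isfinite(s) or s == np.inf else np.inf
    return scores


def _rank(P: np.ndarray, scores: np.ndarray):
    order = np.argsort(scores, kind="stable")  # ties broken by insertion order
    return P[order], scores[order]


def next_generation(
    parents: np.ndarray, cfg: EAConfig, rng: np.random.Generator,
    sigma: float | None = None,
) -> np.ndarray:
    """Produce lam children from the ranked top-mu parents.

    Parents are grouped five-at-a-time in rank order; each group contributes
    an equal share of the children.  A child takes each parameter from one of
    two randomly chosen parents in its group, then, with probability
    ``mutation_rate``, the value is replaced by
    ``exp((1-b) ln v + b ln v_leader + N(0, sigma_m))`` -- a multiplicative
    perturbation whose mean is pulled toward the group leader.
    """
    if sigma is None:
        sigma = cfg.mutation_sigma
    mu, d = parents.shape
    n_groups = mu // cfg.group_size
    per_group = cfg.lam // n_groups
    counts = [per_group + (1 if g < cfg.lam % n_groups else 0) for g in range(n_groups)]
    children = np.empty((cfg.lam, d))
    row = 0
    floor = 1e-12  # keep log-space mutation defined for near-zero parameters
    for g in range(n_groups):
        group = parents[g * cfg.group_size : (g + 1) * cfg.group_size]
        leader = group[0]
        for _ in range(counts[g]):
            pa, pb = rng.choice(cfg.group_size, size=2, replace=False)
            pick = rng.integers(0, 2, size=d).astype(bool)
            child = np.where(pick, group[pa], group[pb])
            mutate = rng.random(d) < cfg.mutation_rate
            noise = rng.normal(0.0, sigma, size=d)
            logv = np.log(np.maximum(child, floor))
            logl = np.log(np.maximum(leader, floor))
            mutated = np.exp(
                (1.0 - cfg.leader_bias) * logv + cfg.leader_bias * logl + noise
            )
            children[row] = np.where(mutate, mutated, child)
            row += 1
    return np.clip(children, floor, None)


def run_ea(objective, cfg: EAConfig, callback=None) -> FitResult:
    """Run the full (lambda + mu) loop and return the ranked survivors.

    ``objective`` maps a parameter vector to a scalar score (lower is
    better); exceptions inside it count as +inf.  ``callback(gen, best,
    median)`` is invoked once per generation when given.
    """
    rng = np.random.default_rng(cfg.seed)
    P = init_population(cfg, rng)
    scores = evaluate_population(P, objective)
    P, scores = _rank(P, scores)
    parents, parent_scores = P[: cfg.mu], scores[: cfg.mu]
    history = []
    sigma = cfg.mutation_sigma
    for gen in range(1, cfg.generations + 1):
        if not cfg.sigma_adapt:
            sigma = cfg.sigma_at(gen)
        children = next_generation(parents, cfg, rng, sigma=sigma)
        child_scores = evaluate_population(children, objective)
        if cfg.sigma_adapt:
            success = float(np.mean(child_scores < parent_scores[-1]))
            if success > cfg.adapt_success:
                sigma = min(sigma * cfg.adapt_factor, cfg.sigma_max)
            else:
                sigma = max(sigma / cfg.adapt_factor, cfg.sigma_min)
        pool = np.vstack([parents, children])
        pool_scores = np.concatenate([parent_scores, child_scores])
        pool, pool_scores = _rank(pool, pool_scores)
        parents, parent_scores = pool[: cfg.mu], pool_scores[: cfg.mu]
        best = float(parent_scores[0])
        median = float(np.median(parent_scores))
        history.append((gen, best, median))
        log.info("generation %d: best %.6g median %.6g", gen, best, median)
        if callback is not None:
            callback(gen, best, median)
    mean, std = weighted_param_stats(parents, parent_scores)
    return FitResult(
        param_names=cfg.param_names,
        params=parents,
        rss=parent_scores,
        weighted_mean=mean,
        weighted_std=std,
        weighted_median_rss=weighted_median(parent_scores, 1.0 / parent_scores),
        history=history,
    )


def weighted_param_stats(params: np.ndarray, rss: np.ndarray):
    """Inverse-RSS-weighted mean and standard deviation per parameter.

    Weights are ``w_i = (1/rss_i) / sum_j (1/rss_j)``, so better fits count
    more.  The std is the population form ``sqrt(sum w (x - m)^2)``.
    """
    params = np.asarray(params, dtype=float)
    rss = np.asarray(rss, dtype=float)
    if params.size == 0:
        raise ValueError("empty result")
    if np.any(rss <= 0):
        raise ValueError("rss must be positive for inverse-RSS weighting")
    finite = np.isfinite(rss)
    if not np.all(finite):
        params, rss = params[finite], rss[finite]
    w = (1.0 / rss) / np.sum(1.0 / rss)
    mean = w @ params
    var = w @ (params - mean) ** 2
    return mean, np.sqrt(var)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / np.sum(w)
    return float(v[np.searchsorted(cum, 0.5)])


def equilibrium_constants(results: list) -> EquilibriumSummary:
    """Nuclear import/export equilibrium constants across optimization runs.

    For each run the RSS-weighted mean parameter set defines
    ``log10(zeta_s / xi_s)`` per species; positive values favor import.
    """
    ratios = {s: [] for s in IMPORT_EXPORT_PAIRS}
    for res in results:
        means = dict(zip(res.param_names, res.weighted_mean))
        for species, (zi, xi) in IMPORT_EXPORT_PAIRS.items():
            if zi in means and xi in means and means[xi] > 0:
                ratios[species].append(np.log10(means[zi] / means[xi]))
    ratios = {s: np.asarray(v) for s, v in ratios.items()}
    quant = {
        s: tuple(np.quantile(v, [0.25, 0.5, 0.75])) if len(v) else (np.nan,) * 3
        for s, v in ratios.items()
    }
    return EquilibriumSummary(log_ratios=ratios, quantiles=quant)
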