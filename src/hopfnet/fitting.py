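"""Fitting the whole-brain model to empirical PLI connectivity.

The goodness of fit of a parameter cell (K, lambda) is the Pearson
correlation between the off-diagonal entries of the simulated and empirical
PLI matrices. Because simulations depend on the random initial condition,
every cell is evaluated over a shared, seed-paired ensemble of initial
conditions, giving a distribution of goodness values per cell and a
distribution of optimal coupling strengths per excitability value.

The central empirical regularity this module quantifies is the square-root
scaling of the optimum: the best-fitting K grows as K = k sqrt(lambda), so
the fit is summarized by the normalized coupling strength k (least-squares
slope through the origin on (sqrt(lambda), mean optimal K)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .connectome import ConnectomeMatrix
from .errors import UndefinedCorrelationError, ValidationError
from .model import (
    ModelParameters,
    SimulationSettings,
    rescaled_initial_condition,
    sample_initial_conditions,
    simulate,
)
from .spectral import PLIMatrix, pli_from_timeseries

DEFAULT_K_GRID = np.geomspace(0.1, 30.0, 31)
DEFAULT_LAMBDA_GRID = np.arange(0.0, 51.0, 5.0)
DEFAULT_LAMBDA_MIN_FIT = 5.0


@dataclass(frozen=True)
class FitGrid:
    """Goodness-of-fit samples over a (lambda, K) grid.

    ``r`` has shape (n_lambda, n_K, n_ic); cell (i, j) holds one Pearson r
    per initial condition, with the same seed-paired ensemble in every cell.
    """

    K_values: np.ndarray
    lambda_values: np.ndarray
    r: np.ndarray
    ic_seed: int

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        expected = (len(self.lambda_values), len(self.K_values))
        if r.ndim != 3 or r.shape[:2] != expected:
            raise ValidationError(f"r must be {expected} x n_ic, got {r.shape}")
        if np.any(r < -1 - 1e-12) or np.any(r > 1 + 1e-12):
            raise ValidationError("Pearson r out of [-1, 1]")
        object.__setattr__(self, "r", r)

    @property
    def n_ic(self) -> int:
        return self.r.shape[2]

    def mean_surface(self) -> np.ndarray:
        """Goodness surface averaged over initial conditions (n_lambda, n_K)."""
        return self.r.mean(axis=2)


@dataclass(frozen=True)
class CouplingCurve:
    """Optimal coupling strength per excitability, per initial condition."""

    lambda_values: np.ndarray
    optimal_K: np.ndarray  # (n_lambda, n_ic)

    @property
    def mean(self) -> np.ndarray:
        return self.optimal_K.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.optimal_K.std(axis=1)


@dataclass(frozen=True)
class NormalizedCouplingFit:
    """Least-squares fit of K = k sqrt(lambda) through the origin."""

    k: float
    residual_ss: float
    lambda_used: np.ndarray

    def __post_init__(self):
        if self.k < 0:
            raise ValidationError("fitted normalized coupling must be >= 0")


def _retained_pairs(values: np.ndarray, exclude: frozenset[int]) -> np.ndarray:
    keep = np.array([i for i in range(values.shape[0]) if i not in exclude])
    sub = values[np.ix_(keep, keep)]
    iu = np.triu_indices(len(keep), k=1)
    return sub[iu]


def goodness_of_fit(
    sim: PLIMatrix,
    emp: PLIMatrix,
    exclude: frozenset[int] | set[int] = frozenset(),
) -> float:
    """Pearson correlation between simulated and empirical PLI pairs.

    Computed over the off-diagonal upper-triangle entries of the retained
    submatrix after removing the ``exclude`` regions' rows and columns from
    both matrices. Thresholded zeros count as data points (the comparison is
    between full matrices).
    """
    if sim.labels != emp.labels:
        raise ValidationError("simulated and empirical PLI labels differ")
    exclude = frozenset(exclude)
    bad = [i for i in exclude if not 0 <= i < sim.n_regions]
    if bad:
        raise ValidationError(f"exclude indices out of range: {bad}")
    a = _retained_pairs(sim.values, exclude)
    b = _retained_pairs(emp.values, exclude)
    if len(a) < 3:
        raise ValidationError(
            f"only {len(a)} region pairs retained; need >= 3 for the objective"
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("zero variance in PLI pairs")
    return float(sstats.pearsonr(a, b).statistic)


def simulate_pli(
    K: float,
    lambda_: float,
    W: ConnectomeMatrix,
    omega: np.ndarray,
    ic: np.ndarray,
    settings: SimulationSettings = SimulationSettings(),
    C: float = 20.0,
    coupling_gain: np.ndarray | None = None,
) -> PLIMatrix:
    """Simulate one run and push it through the PLI pipeline."""
    params = ModelParameters(K=K, lambda_=lambda_, omega=omega, C=C,
                             coupling_gain=coupling_gain)
    ts = simulate(params, W, ic, settings)
    return pli_from_timeseries(ts)


def evaluate_cell(
    K: float,
    lambda_: float,
    W: ConnectomeMatrix,
    omega: np.ndarray,
    emp: PLIMatrix,
    ics: list[np.ndarray],
    settings: SimulationSettings = SimulationSettings(),
    exclude: frozenset[int] = frozenset(),
    C: float = 20.0,
) -> list[float]:
    """Goodness of fit of one (K, lambda) cell, one value per initial condition."""
    rs = []
    for i, ic in enumerate(ics):
        try:
            sim = simulate_pli(K, lambda_, W, omega, ic, settings, C)
            rs.append(goodness_of_fit(sim, emp, exclude))
        except Exception as exc:
            raise type(exc)(
                f"cell K={K:.4g}, lambda={lambda_:.4g}, ic #{i}: {exc}"
            ) from exc
    return rs


def grid_search(
    W: ConnectomeMatrix,
    omega: np.ndarray,
    emp: PLIMatrix,
    K_grid: np.ndarray = DEFAULT_K_GRID,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_ic: int = 10,
    seed: int = 0,
    settings: SimulationSettings = SimulationSettings(),
    exclude: frozenset[int] = frozenset(),
    C: float = 20.0,
    sim_cache: dict | None = None,
) -> FitGrid:
    """Two-dimensional grid search over (K, lambda).

    Every cell is evaluated on the same ensemble of ``n_ic`` seeded initial
    conditions (cells are paired, so per-initial-condition optimum curves are
    well defined). ``sim_cache`` may be passed (a dict) to reuse simulated
    PLI matrices across calls that share W, omega, settings and seed — e.g.
    when scanning thresholds of the empirical matrix, which does not affect
    the simulations.
    """
    K_grid = np.asarray(K_grid, dtype=float)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if K_grid.size == 0 or lambda_grid.size == 0:
        raise ValidationError("parameter grids must be nonempty")
    if n_ic < 1:
        raise ValidationError("need n_ic >= 1")
    ics = sample_initial_conditions(n_ic, W.n_regions, seed)
    r = np.empty((len(lambda_grid), len(K_grid), n_ic))
    for il, lam in enumerate(lambda_grid):
        for ik, K in enumerate(K_grid):
            for ii, ic in enumerate(ics):
                key = (float(K), float(lam), ii)
                sim = None if sim_cache is None else sim_cache.get(key)
                if sim is None:
                    sim = simulate_pli(K, lam, W, omega, ic, settings, C)
                    if sim_cache is not None:
                        sim_cache[key] = sim
                r[il, ik, ii] = goodness_of_fit(sim, emp, exclude)
    return FitGrid(K_values=K_grid, lambda_values=lambda_grid, r=r, ic_seed=seed)


def optimal_coupling_curve(grid: FitGrid) -> CouplingCurve:
    """Per excitability and per initial condition, the K maximizing r.

    Ties are broken toward the smallest K (the weakest coupling consistent
    with the optimum); the K grid is assumed sorted ascending.
    """
    if np.any(np.diff(grid.K_values) <= 0):
        raise ValidationError("K grid must be strictly increasing")
    best = np.argmax(grid.r, axis=1)  # first (= smallest-K) argmax
    return CouplingCurve(
        lambda_values=grid.lambda_values,
        optimal_K=grid.K_values[best],
    )


def fit_normalized_coupling(
    curve: CouplingCurve,
    lambda_min: float = DEFAULT_LAMBDA_MIN_FIT,
) -> NormalizedCouplingFit:
    """Least squares through the origin of mean optimal K on sqrt(lambda).

    Closed form: k = sum(K_mean * sqrt(lambda)) / sum(lambda). Excitabilities
    below ``lambda_min`` are excluded — the square-root scaling breaks down
    near the bifurcation, where amplitude dynamics still shape the phases.
    """
    mask = (curve.lambda_values >= lambda_min) & (curve.lambda_values > 0)
    if not np.any(mask):
        raise ValidationError("no excitability values above lambda_min with lambda > 0")
    lam = curve.lambda_values[mask]
    Kbar = curve.mean[mask]
    k = float(np.sum(Kbar * np.sqrt(lam)) / np.sum(lam))
    rss = float(np.sum((Kbar - k * np.sqrt(lam)) ** 2))
    return NormalizedCouplingFit(k=k, residual_ss=rss, lambda_used=lam)


def select_optimal_threshold(
    emp_raw: PLIMatrix,
    W: ConnectomeMatrix,
    omega: np.ndarray,
    threshold_grid: list[float],
    K_grid: np.ndarray = DEFAULT_K_GRID,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_ic: int = 3,
    seed: int = 0,
    settings: SimulationSettings = SimulationSettings(),
    C: float = 20.0,
) -> float:
    """Pick the proportional threshold of the empirical PLI with the best fit.

    Runs the grid search once per candidate threshold (simulations are shared
    across thresholds — only the objective changes) and returns the threshold
    whose best mean goodness of fit is largest; ties break toward the
    smallest threshold.
    """
    from .spectral import threshold_pli

    if not threshold_grid:
        raise ValidationError("threshold grid must be nonempty")
    if any(not 0 <= t < 100 for t in threshold_grid):
        raise ValidationError("thresholds must lie in [0, 100)")
    cache: dict = {}
    best_percent, best_r = None, -np.inf
    for percent in sorted(threshold_grid):
        emp = threshold_pli(emp_raw, percent) if percent > 0 else emp_raw
        grid = grid_search(W, omega, emp, K_grid, lambda_grid, n_ic, seed,
                           settings, C=C, sim_cache=cache)
        r_best = grid.mean_surface().max()
        if r_best > best_r:
            best_percent, best_r = percent, r_best
    return float(best_percent)


def matched_pair_pli_correlation(
    W: ConnectomeMatrix,
    omega: np.ndarray,
    k: float,
    lambda_pair: tuple[float, float] = (10.0, 40.0),
    n_ic: int = 10,
    seed: int = 0,
    settings: SimulationSettings = SimulationSettings(),
    C: float = 20.0,
) -> float:
    """Mean PLI correlation between simulations at matched normalized coupling.

    For each initial condition, the model is simulated at both excitability
    values with K = k sqrt(lambda) and the initial state rescaled by the
    limit-cycle radius ratio; the off-diagonal Pearson correlation of the two
    PLI matrices is averaged over initial conditions. Values near 1 express
    the invariance of the phase dynamics under the square-root scaling.
    """
    lam1, lam2 = lambda_pair
    ics = sample_initial_conditions(n_ic, W.n_regions, seed)
    rs = []
    for ic in ics:
        pli1 = simulate_pli(k * np.sqrt(lam1), lam1, W, omega, ic, settings, C)
        ic2 = rescaled_initial_condition(ic, lam1, lam2)
        pli2 = simulate_pli(k * np.sqrt(lam2), lam2, W, omega, ic2, settings, C)
        rs.append(goodness_of_fit(pli1, pli2))
    return float(np.mean(rs))
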