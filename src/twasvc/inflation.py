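"""The inflation slope Phi: closed form, empirical estimation, expectations.

Under a polygenic target trait the TWAS Z-score variance grows as

    var(Z) ~ 1 + N * h2 * Phi(mediator),

where N is the GWAS sample size, h2 the polygenic heritability of the target
trait, and Phi a mediator-specific slope.  Phi has a closed form in terms of
the prediction weights and the LD matrix,

    Phi = (1/M) * (w' Sigma^2 w) / (w' Sigma w),

with M the effective number of causal variants.  Because M and the true LD
matrix are hard to pin down for real data, Phi is also estimated empirically
as the regression slope of average Z^2 on N*h2 over a simulation grid of
polygenic null traits; the closed form serves as the oracle for that
estimator on synthetic fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .synthetic_data import (AlternativeSpec, GenotypeMatrix, WeightSet,
                             _unit_variance_draws, standardize_columns)
from .twas_core import predict_mediator, zscore_matrix

logger = logging.getLogger("twasvc")


# ---------------------------------------------------------------------------
# Closed-form Phi
# ---------------------------------------------------------------------------

def theoretical_phi(w: WeightSet, sigma: np.ndarray, M: int,
                    sigma_variant_ids: Optional[Sequence[str]] = None) -> float:
    """(1/M) * (w' Sigma^2 w) / (w' Sigma w) for prediction weights w.

    When the model covers a subset of the variants spanned by ``sigma``,
    pass ``sigma_variant_ids`` so the weight vector is padded with zeros into
    the right coordinates.
    """
    sigma = np.asarray(sigma, dtype=float)
    m = sigma.shape[0]
    if sigma.shape != (m, m):
        raise ValueError("sigma must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-10):
        raise ValueError("sigma must be symmetric")
    if M < 1:
        raise ValueError("M must be at least 1")
    if sigma_variant_ids is not None:
        idx = {v: j for j, v in enumerate(sigma_variant_ids)}
        gamma = np.zeros(m)
        for vid, wt in zip(w.variant_ids, w.weights):
            if vid not in idx:
                raise ValueError(f"variant {vid!r} not covered by sigma")
            gamma[idx[vid]] = wt
    else:
        if w.weights.shape[0] != m:
            raise ValueError("weight length does not match sigma; pass "
                             "sigma_variant_ids for subset models")
        gamma = w.weights
    v = sigma @ gamma
    denom = gamma @ v
    if denom <= 0:
        raise ValueError("w' Sigma w is not positive (weights in the null "
                         "space of Sigma)")
    return float((v @ v) / denom / M)


# ---------------------------------------------------------------------------
# Simulation grid and slope fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationGrid:
    """(N, h2) cells over which polygenic null traits are simulated."""

    cells: tuple  # of (N, h2) pairs
    n_reps_per_cell: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.n_reps_per_cell < 2:
            raise ValueError("need at least 2 replicates per cell")
        x = {round(N * h2, 12) for N, h2 in self.cells}
        if len(x) < 2:
            raise ValueError("grid must span at least 2 distinct N*h2 values "
                             "for the slope to be identifiable")
        for N, h2 in self.cells:
            if N < 3:
                raise ValueError("cell sample sizes must be at least 3")
            if not (0.0 <= h2 < 1.0):
                raise ValueError("cell h2 values must lie in [0, 1)")

    @classmethod
    def from_factors(cls, sample_sizes=(1000, 2000, 5000),
                     h2_values=(0.0, 0.2, 0.5, 0.8),
                     n_reps_per_cell: int = 300, seed: int = 0) -> "SimulationGrid":
        cells = tuple((int(N), float(h2)) for N in sample_sizes for h2 in h2_values)
        return cls(cells=cells, n_reps_per_cell=n_reps_per_cell, seed=seed)

    @property
    def x_values(self) -> np.ndarray:
        return np.array([N * h2 for N, h2 in self.cells])


@dataclass
class GridFit:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float


def fit_inflation_slope(x: Sequence[float], y: Sequence[float],
                        y_se: Optional[Sequence[float]] = None,
                        weighted: bool = False) -> GridFit:
    """OLS of cell-mean Z^2 on N*h2, with a free intercept.

    When per-cell standard errors are supplied, the slope and intercept
    uncertainties propagate them through the OLS weights (the cells are
    heteroskedastic: var(Z^2) grows with the inflation); otherwise the
    classical homoskedastic formulas are used.  ``weighted=True`` switches the
    point estimate to inverse-variance weighted least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = x.shape[0]
    if y.shape[0] != k or k < 3:
        raise ValueError("need at least 3 matched (x, y) cells")
    if y_se is not None:
        y_se = np.asarray(y_se, dtype=float)
    if weighted:
        if y_se is None:
            raise ValueError("weighted fit requires per-cell standard errors")
        wts = 1.0 / y_se ** 2
    else:
        wts = np.ones(k)
    wsum = wts.sum()
    xbar = (wts * x).sum() / wsum
    ybar = (wts * y).sum() / wsum
    sxx = (wts * (x - xbar) ** 2).sum()
    if sxx <= 0:
        raise ValueError("x values are all equal; slope unidentifiable")
    slope = (wts * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    tss = (wts * (y - ybar) ** 2).sum()
    rss = (wts * resid ** 2).sum()
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    # uncertainty: propagate per-cell SEs through the linear estimator weights
    a_slope = wts * (x - xbar) / sxx
    a_int = wts / wsum - xbar * a_slope
    if y_se is not None:
        slope_se = float(np.sqrt((a_slope ** 2 * y_se ** 2).sum()))
        intercept_se = float(np.sqrt((a_int ** 2 * y_se ** 2).sum()))
    else:
        s2 = rss / (k - 2)
        slope_se = float(np.sqrt(s2 / sxx))
        intercept_se = float(np.sqrt(s2 * (1.0 / k + xbar ** 2 / sxx)))
    return GridFit(slope=float(slope), intercept=float(intercept),
                   slope_se=slope_se, intercept_se=intercept_se, r2=float(r2))


@dataclass
class PhiEstimate:
    """Empirical inflation slope for one mediator.

    ``phi`` is the clamped-at-zero slope; ``phi_raw`` keeps the raw
    regression coefficient and ``clamped`` records whether clamping fired.
    """

    mediator_id: str
    phi: float
    phi_raw: float
    se: float
    intercept: float
    intercept_se: float
    r2: float
    grid: Optional[SimulationGrid] = None
    n_reps_per_cell: int = 0
    clamped: bool = False
    cell_means: Optional[np.ndarray] = None
    cell_ses: Optional[np.ndarray] = None

    @classmethod
    def from_fit(cls, mediator_id: str, fit: GridFit,
                 grid: Optional[SimulationGrid] = None,
                 cell_means=None, cell_ses=None) -> "PhiEstimate":
        clamped = fit.slope < 0
        if clamped:
            logger.info("mediator %s: negative raw slope %.3g clamped to 0",
                        mediator_id, fit.slope)
        return cls(mediator_id=mediator_id, phi=max(fit.slope, 0.0),
                   phi_raw=fit.slope, se=fit.slope_se, intercept=fit.intercept,
                   intercept_se=fit.intercept_se, r2=fit.r2, grid=grid,
                   n_reps_per_cell=(grid.n_reps_per_cell if grid else 0),
                   clamped=clamped, cell_means=cell_means, cell_ses=cell_ses)


# ---------------------------------------------------------------------------
# Empirical Phi estimation
# ---------------------------------------------------------------------------

def _cell_z2(X_sub: np.ndarray, P_sub: np.ndarray, h2: float, reps: int,
             rng: np.random.Generator, effect_dist: str, df: float,
             noise_dist: str) -> np.ndarray:
    """K x reps matrix of Z^2 for one grid cell (traits shared across mediators)."""
    n, m = X_sub.shape
    if h2 > 0:
        delta = _unit_variance_draws(rng, (m, reps), effect_dist, df)
        g = X_sub @ delta
        g = g - g.mean(axis=0)
        sd = g.std(axis=0)
        g *= np.sqrt(h2) / sd
    else:
        g = 0.0
    eps = _unit_variance_draws(rng, (n, reps), noise_dist, df) * np.sqrt(1.0 - h2)
    Y = g + eps
    z = zscore_matrix(P_sub, Y)
    return z ** 2


def estimate_phi_empirical_batch(G_ref: GenotypeMatrix,
                                 weights: List[WeightSet],
                                 grid: SimulationGrid,
                                 effect_dist: str = "normal",
                                 df: float = 5.0,
                                 noise_dist: str = "normal",
                                 weighted: bool = False) -> List[PhiEstimate]:
    """Estimate Phi for many mediators on a shared simulation grid.

    For each grid cell an N-subsample of the reference panel is drawn without
    replacement, ``n_reps_per_cell`` polygenic null traits are simulated on
    it, every mediator is tested against every trait, and the per-cell mean
    Z^2 values are regressed on N*h2.  All mediators share the same simulated
    traits, as one would when annotating a whole model database.
    """
    if not weights:
        raise ValueError("need at least one mediator")
    n_ref = G_ref.n_individuals
    max_n = max(N for N, _ in grid.cells)
    if n_ref < max_n:
        raise ValueError(f"reference panel has {n_ref} individuals but the "
                         f"grid needs up to {max_n}")
    dosages = G_ref.dosages
    idx = G_ref.variant_index()
    # dense weight matrix aligned to the panel's variants
    W = np.zeros((G_ref.m_variants, len(weights)))
    for k, w in enumerate(weights):
        hit = False
        for vid, wt in zip(w.variant_ids, w.weights):
            if vid in idx:
                W[idx[vid], k] = wt
                hit = True
        if not hit:
            raise ValueError(f"mediator {w.mediator_id!r} has no variant in "
                             "the reference panel")

    ss = np.random.SeedSequence(grid.seed)
    children = ss.spawn(len(grid.cells))
    K, R = len(weights), grid.n_reps_per_cell
    means = np.empty((len(grid.cells), K))
    ses = np.empty((len(grid.cells), K))
    for c, ((N, h2), child) in enumerate(zip(grid.cells, children)):
        rng = np.random.default_rng(child)
        rows = rng.choice(n_ref, size=N, replace=False)
        X_sub = standardize_columns(dosages[rows])
        P_sub = X_sub @ W
        z2 = _cell_z2(X_sub, P_sub, h2, R, rng, effect_dist, df, noise_dist)
        means[c] = z2.mean(axis=1)
        ses[c] = z2.std(axis=1, ddof=1) / np.sqrt(R)

    x = grid.x_values
    out = []
    for k, w in enumerate(weights):
        fit = fit_inflation_slope(x, means[:, k], y_se=ses[:, k], weighted=weighted)
        out.append(PhiEstimate.from_fit(w.mediator_id, fit, grid=grid,
                                        cell_means=means[:, k].copy(),
                                        cell_ses=ses[:, k].copy()))
    return out


def estimate_phi_empirical(G_ref: GenotypeMatrix, w: WeightSet,
                           grid: SimulationGrid, **kwargs) -> PhiEstimate:
    """Single-mediator convenience wrapper around the batch estimator."""
    return estimate_phi_empirical_batch(G_ref, [w], grid, **kwargs)[0]


# ---------------------------------------------------------------------------
# Expected Z^2
# ---------------------------------------------------------------------------

def expected_z_variance(N: int, h2: float, phi: float) -> float:
    """Null-model Z-score variance: 1 + N * h2 * Phi."""
    if N < 1:
        raise ValueError("N must be at least 1")
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    if phi < 0:
        raise ValueError("phi must be nonnegative (clamp upstream)")
    return 1.0 + N * h2 * phi


def expected_z2_alternative(spec: AlternativeSpec, N: int, phi: float) -> float:
    """Expected Z^2 under the alternative model:

    1 + N*h2_delta*sigma_Y2/(sigma_Y2 - tau2*beta^2*sigma_T2) * Phi
      + N*tau2*beta^2*sigma_T2/(sigma_Y2 - tau2*beta^2*sigma_T2).

    At beta = 0 this reduces exactly to :func:`expected_z_variance`; the
    prediction precision tau2 enters only through the product with beta, so
    it cannot affect type-I error.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    if phi < 0:
        raise ValueError("phi must be nonnegative")
    denom = spec.sigma_Y2 - spec.tau2 * spec.beta ** 2 * spec.sigma_T2
    if denom <= 0:
        raise ValueError("sigma_Y2 - tau2*beta^2*sigma_T2 must be positive")
    signal = N * spec.tau2 * spec.beta ** 2 * spec.sigma_T2 / denom
    inflation = N * spec.h2_delta * spec.sigma_Y2 / denom * phi
    return 1.0 + inflation + signal
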