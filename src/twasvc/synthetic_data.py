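"""Seeded simulators for genotypes, prediction weights, and target traits.

The simulated world follows the standard TWAS generative model: a mediating
trait ``T`` is a linear combination of genotype dosages, ``T = sum_k gamma_k
X_k``, and a target trait ``Y`` either ignores the genome (non-polygenic
null), carries an infinitesimal polygenic background ``sum_k X_k delta_k``
(polygenic null), or additionally receives a true mediator effect ``beta * T``
(alternative).  Every simulator is fully determined by its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger("twasvc")

_EFFECT_DISTS = ("normal", "student_t")


def _unit_variance_draws(rng: np.random.Generator, size, dist: str, df: float) -> np.ndarray:
    """i.i.d. draws with population variance 1 from a normal or scaled t."""
    if dist == "normal":
        return rng.standard_normal(size)
    if dist == "student_t":
        if df <= 2:
            raise ValueError("student_t draws need df > 2 for a finite variance")
        return rng.standard_t(df, size) * np.sqrt((df - 2.0) / df)
    raise ValueError(f"unknown distribution tag {dist!r}; expected one of {_EFFECT_DISTS}")


# ---------------------------------------------------------------------------
# LD specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LdSpec:
    """Block-diagonal LD structure for simulated genotypes.

    Each block is either exchangeable with a single within-block dosage
    correlation in [0, 1), or an explicit correlation matrix.  Identity LD is
    the special case of all blocks of size 1 (or correlation 0).
    """

    m_variants: int
    block_sizes: tuple
    block_corrs: tuple  # float per block, or an explicit ndarray per block

    def __post_init__(self):
        if sum(self.block_sizes) != self.m_variants:
            raise ValueError(
                f"block sizes sum to {sum(self.block_sizes)}, expected {self.m_variants}"
            )
        if len(self.block_sizes) != len(self.block_corrs):
            raise ValueError("need one correlation entry per block")
        for i, (size, corr) in enumerate(zip(self.block_sizes, self.block_corrs)):
            if np.isscalar(corr):
                if not (0.0 <= corr < 1.0):
                    raise ValueError(f"block {i}: exchangeable correlation {corr} not in [0, 1)")
            else:
                mat = np.asarray(corr, dtype=float)
                if mat.shape != (size, size):
                    raise ValueError(f"block {i}: matrix shape {mat.shape} != ({size}, {size})")
                if not np.allclose(mat, mat.T, atol=1e-10):
                    raise ValueError(f"block {i}: correlation matrix is not symmetric")
                if np.min(np.linalg.eigvalsh(mat)) < -1e-10:
                    raise ValueError(f"block {i}: correlation matrix is not positive semi-definite")

    @classmethod
    def identity(cls, m: int) -> "LdSpec":
        return cls(m_variants=m, block_sizes=(1,) * m, block_corrs=(0.0,) * m)

    @property
    def is_identity(self) -> bool:
        for size, corr in zip(self.block_sizes, self.block_corrs):
            if size == 1:
                continue
            if np.isscalar(corr) and corr == 0.0:
                continue
            if not np.isscalar(corr) and np.allclose(np.asarray(corr), np.eye(size)):
                continue
            return False
        return True

    def block_matrix(self, i: int) -> np.ndarray:
        size, corr = self.block_sizes[i], self.block_corrs[i]
        if np.isscalar(corr):
            return np.full((size, size), float(corr)) + (1.0 - float(corr)) * np.eye(size)
        return np.asarray(corr, dtype=float)

    def correlation_matrix(self) -> np.ndarray:
        """Dense m x m target dosage correlation matrix (small fixtures only)."""
        out = np.zeros((self.m_variants, self.m_variants))
        start = 0
        for i, size in enumerate(self.block_sizes):
            out[start:start + size, start:start + size] = self.block_matrix(i)
            start += size
        return out


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """n x m dosage matrix with variant metadata.

    ``dosages`` holds raw 0-2 dosages, or column-standardized values when
    ``standardized`` is True (mean 0, variance 1 per column, ddof=0).
    """

    dosages: np.ndarray
    variant_ids: list
    allele_freqs: np.ndarray
    standardized: bool = False
    ld_spec: Optional[LdSpec] = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        n, m = self.dosages.shape
        if len(self.variant_ids) != m or self.allele_freqs.shape[0] != m:
            raise ValueError("variant_ids and allele_freqs must match the column count")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self) -> dict:
        return {v: j for j, v in enumerate(self.variant_ids)}

    def standardize(self) -> "GenotypeMatrix":
        """Return a copy with each column centered and scaled to variance 1."""
        if self.standardized:
            return self
        X = standardize_columns(self.dosages)
        return GenotypeMatrix(X, list(self.variant_ids), self.allele_freqs.copy(),
                              standardized=True, ld_spec=self.ld_spec)


def standardize_columns(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise ValueError(f"column {j} is constant (monomorphic); cannot standardize")
    return (X - mu) / sd


def _latent_correlation(target_r: float, f1: float, f2: float) -> float:
    """Latent Gaussian correlation whose thresholded haplotype indicators
    realize a dosage correlation of ``target_r`` at allele freqs f1, f2."""
    if target_r <= 0:
        return 0.0
    z1, z2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    target_p11 = f1 * f2 + target_r * np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))

    def gap(rho):
        cov = np.array([[1.0, rho], [rho, 1.0]])
        p11 = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([z1, z2])
        return p11 - target_p11

    hi = 0.9999
    if gap(hi) < 0:  # requested correlation not attainable at these freqs
        logger.warning("target dosage correlation %.3f not attainable at freqs "
                       "(%.3f, %.3f); capping latent correlation", target_r, f1, f2)
        return hi
    return float(optimize.brentq(gap, max(target_r - 1e-9, 0.0), hi, xtol=1e-10))


def simulate_genotypes(n: int,
                       ld: LdSpec,
                       maf_range=(0.05, 0.5),
                       seed: int = 0,
                       standardize: bool = False) -> GenotypeMatrix:
    """Simulate Hardy-Weinberg dosages with optional block LD.

    Independent variants are Binomial(2, f) draws.  Correlated blocks use a
    Gaussian-copula construction: two latent haplotype vectors per individual
    are drawn with a calibrated latent correlation and thresholded at the
    allele-frequency quantile, so the realized dosage correlation approximates
    the requested within-block correlation.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range {maf_range} must lie within (0, 0.5]")

    rng = np.random.default_rng(seed)
    m = ld.m_variants
    freqs = rng.uniform(lo, hi, size=m) if lo < hi else np.full(m, lo)
    dosages = np.empty((n, m))

    start = 0
    for i, size in enumerate(ld.block_sizes):
        cols = slice(start, start + size)
        f = freqs[cols]
        corr = ld.block_corrs[i]
        exchangeable_zero = np.isscalar(corr) and corr == 0.0
        if size == 1 or exchangeable_zero:
            dosages[:, cols] = rng.binomial(2, f, size=(n, size))
        else:
            if np.isscalar(corr):
                f_bar = float(np.mean(f))
                rho_lat = _latent_correlation(float(corr), f_bar, f_bar)
                latent_R = np.full((size, size), rho_lat) + (1 - rho_lat) * np.eye(size)
            else:
                latent_R = np.asarray(corr, dtype=float)
            try:
                L = np.linalg.cholesky(latent_R + 1e-12 * np.eye(size))
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"block {i}: latent correlation matrix is not "
                                 f"positive semi-definite") from exc
            thresh = stats.norm.ppf(f)  # P(Z < thresh) = f per variant
            hap1 = rng.standard_normal((n, size)) @ L.T < thresh
            hap2 = rng.standard_normal((n, size)) @ L.T < thresh
            dosages[:, cols] = hap1.astype(float) + hap2.astype(float)
        start += size

    variant_ids = [f"snp_{j + 1}" for j in range(m)]
    G = GenotypeMatrix(dosages, variant_ids, freqs, standardized=False, ld_spec=ld)
    return G.standardize() if standardize else G


# ---------------------------------------------------------------------------
# Prediction weights
# ---------------------------------------------------------------------------

@dataclass
class WeightSet:
    """Per-mediator prediction weights (the observable gamma-tilde).

    ``true_weights`` holds the generative gamma when the mediator was
    simulated; real prediction models carry only the noisy weights.
    """

    mediator_id: str
    variant_ids: list
    weights: np.ndarray
    true_weights: Optional[np.ndarray] = None
    n_model_variants: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variant_ids) != self.weights.shape[0]:
            raise ValueError("weights and variant_ids must have equal length")
        if self.true_weights is not None:
            self.true_weights = np.asarray(self.true_weights, dtype=float)
            if self.true_weights.shape != self.weights.shape:
                raise ValueError("true_weights must match weights in length")
        if not np.any(self.weights != 0):
            raise ValueError(f"mediator {self.mediator_id!r} has no nonzero weight")
        if self.n_model_variants == 0:
            self.n_model_variants = int(np.count_nonzero(self.weights))


def simulate_mediator_weights(m: int,
                              n_nonzero: int,
                              dist: str = "normal",
                              df: float = 5.0,
                              seed: int = 0,
                              mediator_id: str = "sim_mediator",
                              variant_ids: Optional[Sequence[str]] = None) -> WeightSet:
    """Draw a sparse-or-dense weight vector over ``m`` candidate variants.

    Exactly ``n_nonzero`` seeded positions receive nonzero weights drawn from
    the requested distribution; the returned WeightSet stores only those
    variants (a sparse model over the candidate panel).
    """
    if not (1 <= n_nonzero <= m):
        raise ValueError(f"n_nonzero must be in [1, {m}], got {n_nonzero}")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(m, size=n_nonzero, replace=False))
    draws = _unit_variance_draws(rng, n_nonzero, dist, df)
    # resample the (measure-zero in theory) exact zeros so sparsity is exact
    while np.any(draws == 0.0):
        zeros = draws == 0.0
        draws[zeros] = _unit_variance_draws(rng, int(zeros.sum()), dist, df)
    if variant_ids is None:
        variant_ids = [f"snp_{j + 1}" for j in range(m)]
    ids = [variant_ids[j] for j in positions]
    return WeightSet(mediator_id=mediator_id, variant_ids=ids, weights=draws,
                     true_weights=draws.copy(), n_model_variants=n_nonzero)


# ---------------------------------------------------------------------------
# Target traits
# ---------------------------------------------------------------------------

@dataclass
class TraitVector:
    """A simulated target trait with its generative metadata."""

    values: np.ndarray
    h2: float
    effect_dist: str
    seed: int
    kind: str  # null_nonpolygenic | null_polygenic | alternative

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def simulate_null_trait(n: int, dist: str = "normal", df: float = 5.0,
                        seed: int = 0) -> TraitVector:
    """Non-polygenic null trait: i.i.d. unit-variance draws, no genetics."""
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    values = _unit_variance_draws(rng, n, dist, df)
    return TraitVector(values, h2=0.0, effect_dist=dist, seed=seed,
                       kind="null_nonpolygenic")


def _scaled_component(raw: np.ndarray, target_var: float) -> np.ndarray:
    """Center ``raw`` and rescale to an exact sample variance (ddof=0)."""
    raw = raw - raw.mean()
    sd = raw.std()
    if sd == 0:
        raise ValueError("degenerate component with zero variance")
    return raw * (np.sqrt(target_var) / sd)


def simulate_polygenic_trait(G: GenotypeMatrix,
                             h2: float,
                             effect_dist: str = "normal",
                             df: float = 5.0,
                             seed: int = 0,
                             noise_dist: str = "normal",
                             exact_scale: bool = True,
                             allow_noise_free: bool = False) -> TraitVector:
    """Polygenic null trait: every variant contributes a small effect.

    Y = s * (X @ delta) + eps, with delta i.i.d. from ``effect_dist`` over all
    variants and eps i.i.d. with variance 1 - h2.  By default the rescaling s
    pins the sample variance of the genetic component to h2 exactly, removing
    one Monte Carlo noise source; ``exact_scale=False`` scales in expectation
    only (delta variance h2 / m on standardized dosages).
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    if h2 == 1.0 and not allow_noise_free:
        raise ValueError("h2 = 1 gives a noise-free trait; pass allow_noise_free=True")
    if G.n_individuals < 2 or G.m_variants < 1:
        raise ValueError("genotype matrix is empty")
    rng = np.random.default_rng(seed)
    X = G.standardize().dosages
    n, m = X.shape
    if h2 > 0:
        delta = _unit_variance_draws(rng, m, effect_dist, df)
        g_raw = X @ delta
        if exact_scale:
            g = _scaled_component(g_raw, h2)
        else:
            g = g_raw * np.sqrt(h2 / m)
    else:
        g = np.zeros(n)
    eps = _unit_variance_draws(rng, n, noise_dist, df) * np.sqrt(max(1.0 - h2, 0.0))
    return TraitVector(g + eps, h2=h2, effect_dist=effect_dist, seed=seed,
                       kind="null_polygenic" if h2 > 0 else "null_nonpolygenic")


# ---------------------------------------------------------------------------
# Alternative model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlternativeSpec:
    """Parameters of the alternative model Y = beta*T + polygenic + noise.

    tau2 is the prediction precision var(T) / var(T_tilde); h2_delta is the
    fraction of var(Y) contributed by the polygenic background.
    """

    beta: float
    tau2: float
    sigma_T2: float = 1.0
    sigma_Y2: float = 1.0
    h2_delta: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.tau2 <= 1.0):
            raise ValueError("tau2 must lie in (0, 1]")
        if self.sigma_T2 <= 0 or self.sigma_Y2 <= 0:
            raise ValueError("sigma_T2 and sigma_Y2 must be positive")
        if not (0.0 <= self.h2_delta < 1.0):
            raise ValueError("h2_delta must lie in [0, 1)")
        if self.sigma_Y2 - self.tau2 * self.beta ** 2 * self.sigma_T2 <= 0:
            raise ValueError("sigma_Y2 - tau2*beta^2*sigma_T2 must be positive")

    @property
    def noise_variance(self) -> float:
        return self.sigma_Y2 * (1.0 - self.h2_delta) - self.beta ** 2 * self.sigma_T2


@dataclass
class AlternativeDraw:
    """One draw from the alternative model: the target trait and the
    observable (noisy-weight) mediator prediction tested against it."""

    trait: TraitVector
    prediction: np.ndarray
    true_mediator: np.ndarray


def simulate_alternative_study(G: GenotypeMatrix,
                               w: WeightSet,
                               spec: AlternativeSpec,
                               seed: int = 0,
                               effect_dist: str = "normal",
                               df: float = 5.0) -> AlternativeDraw:
    """Draw (Y, T_tilde) under the alternative model.

    The true mediator T is built from ``w.true_weights`` and rescaled to
    sample variance sigma_T2.  The observable prediction T_tilde adds a
    genotype-spanned error component, orthogonalized against T in-sample and
    scaled so var(T)/var(T_tilde) equals tau2 exactly.  Y = beta*T + polygenic
    background at h2_delta*sigma_Y2 + independent noise.
    """
    if w.true_weights is None:
        raise ValueError("alternative simulation requires true_weights on the WeightSet")
    if spec.noise_variance <= 0:
        raise ValueError("infeasible spec: sigma_Y2*(1-h2_delta) - beta^2*sigma_T2 <= 0")
    rng = np.random.default_rng(seed)
    X = G.standardize().dosages
    n, m = X.shape
    idx = G.variant_index()
    gamma = np.zeros(m)
    for vid, wt in zip(w.variant_ids, w.true_weights):
        if vid not in idx:
            raise ValueError(f"variant {vid!r} of mediator {w.mediator_id!r} "
                             "missing from the genotype matrix")
        gamma[idx[vid]] = wt

    T = _scaled_component(X @ gamma, spec.sigma_T2)
    if spec.tau2 < 1.0:
        err_w = rng.standard_normal(m)
        E = X @ err_w
        E = E - E.mean()
        E -= T * (E @ T) / (T @ T)  # in-sample orthogonal to T
        E = _scaled_component(E, spec.sigma_T2 * (1.0 - spec.tau2) / spec.tau2)
        t_tilde = T + E
    else:
        t_tilde = T.copy()

    if spec.h2_delta > 0:
        delta = _unit_variance_draws(rng, m, effect_dist, df)
        b = _scaled_component(X @ delta, spec.h2_delta * spec.sigma_Y2)
    else:
        b = np.zeros(n)
    eps = rng.standard_normal(n) * np.sqrt(spec.noise_variance)
    y = spec.beta * T + b + eps
    trait = TraitVector(y, h2=spec.h2_delta, effect_dist=effect_dist, seed=seed,
                        kind="alternative")
    return AlternativeDraw(trait=trait, prediction=t_tilde, true_mediator=T)


def simulate_alternative_trait(G: GenotypeMatrix, w: WeightSet,
                               spec: AlternativeSpec, seed: int = 0,
                               effect_dist: str = "normal",
                               df: float = 5.0) -> TraitVector:
    """Target-trait view of :func:`simulate_alternative_study`."""
    return simulate_alternative_study(G, w, spec, seed=seed,
                                      effect_dist=effect_dist, df=df).trait
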