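"""Mediator prediction and the per-mediator association test.

The association statistic is the one whose calibration the package is about:
ordinary least squares of the target trait on the predicted mediator, with an
intercept, reporting Z = beta_hat / se and a two-sided standard-normal
p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import GenotypeMatrix, TraitVector, WeightSet

logger = logging.getLogger("twasvc")

RESULT_COLUMNS = ["mediator_id", "n", "beta_hat", "se", "z", "p",
                  "phi", "correction_factor", "z_corrected", "p_corrected"]


@dataclass
class TwasResult:
    """One mediator-trait association, with optional variance-controlled fields."""

    mediator_id: str
    beta_hat: float
    se: float
    z: float
    p: float
    n: int
    z_corrected: Optional[float] = None
    p_corrected: Optional[float] = None
    correction_factor: Optional[float] = None
    phi_used: Optional[float] = None


def predict_mediator(G: GenotypeMatrix, w: WeightSet,
                     missing: str = "error") -> np.ndarray:
    """Weighted sum of dosage columns: the genetically predicted mediator.

    ``missing`` controls variants of the model absent from G: "error"
    (default) raises; "drop" skips them with a warning.  All model variants
    missing is always a hard error.
    """
    if missing not in ("error", "drop"):
        raise ValueError("missing policy must be 'error' or 'drop'")
    idx = G.variant_index()
    cols, wts, absent = [], [], []
    for vid, wt in zip(w.variant_ids, w.weights):
        if vid in idx:
            cols.append(idx[vid])
            wts.append(wt)
        else:
            absent.append(vid)
    if absent:
        if not cols:
            raise ValueError(f"all model variants of mediator {w.mediator_id!r} "
                             "are missing from the genotype matrix")
        if missing == "error":
            raise ValueError(f"mediator {w.mediator_id!r}: {len(absent)} model "
                             f"variant(s) missing (first: {absent[0]!r})")
        logger.warning("mediator %s: dropping %d missing variant(s)",
                       w.mediator_id, len(absent))
    return G.dosages[:, cols] @ np.asarray(wts)


def _as_values(y: Union[TraitVector, np.ndarray, Sequence[float]]) -> np.ndarray:
    if isinstance(y, TraitVector):
        return y.values
    return np.asarray(y, dtype=float)


def association_test(t_pred: Union[np.ndarray, Sequence[float]],
                     y: Union[TraitVector, np.ndarray, Sequence[float]],
                     mediator_id: str = "mediator",
                     t_reference: bool = False) -> TwasResult:
    """Simple OLS of y on t_pred with an intercept.

    The standard error is residual-based with n-2 degrees of freedom; the
    p-value uses the standard-normal reference by default (``t_reference=True``
    switches to Student t with n-2 df).
    """
    t = np.asarray(t_pred, dtype=float)
    yv = _as_values(y)
    n = t.shape[0]
    if yv.shape[0] != n:
        raise ValueError("t_pred and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    tc = t - t.mean()
    sxx = tc @ tc
    if sxx <= 0 or sxx / n < 1e-24 * max(1.0, float(t @ t) / n):
        raise ValueError(f"mediator {mediator_id!r}: constant predicted mediator")
    yc = yv - yv.mean()
    beta_hat = (tc @ yc) / sxx
    resid = yc - beta_hat * tc
    rss = resid @ resid
    if rss <= 1e-24 * max(yc @ yc, 1e-300):
        raise ValueError(f"mediator {mediator_id!r}: perfect fit (degenerate, "
                         "zero residual variance)")
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    z = beta_hat / se
    if t_reference:
        p = 2.0 * stats.t.sf(abs(z), n - 2)
    else:
        p = 2.0 * stats.norm.sf(abs(z))
    return TwasResult(mediator_id=mediator_id, beta_hat=float(beta_hat),
                      se=float(se), z=float(z), p=float(max(p, np.nextafter(0, 1))),
                      n=int(n))


def run_twas(G: GenotypeMatrix,
             weights: List[WeightSet],
             y: Union[TraitVector, np.ndarray],
             missing: str = "error") -> pd.DataFrame:
    """One association row per usable mediator.

    Mediators that fail their preconditions (all variants missing, constant
    prediction, degenerate fit) are skipped with a logged reason, recorded in
    ``df.attrs['skipped']``; an empty usable set is an error.
    """
    ids = [w.mediator_id for w in weights]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate mediator_id(s): {dup}")
    rows, skipped = [], []
    for w in weights:
        try:
            t_pred = predict_mediator(G, w, missing=missing)
            res = association_test(t_pred, y, mediator_id=w.mediator_id)
        except ValueError as exc:
            logger.warning("skipping mediator %s: %s", w.mediator_id, exc)
            skipped.append((w.mediator_id, str(exc)))
            continue
        rows.append(res)
    if not rows:
        raise ValueError("no usable mediator produced a result")
    df = results_to_frame(rows)
    df.attrs["skipped"] = skipped
    return df


def results_to_frame(results: List[TwasResult]) -> pd.DataFrame:
    df = pd.DataFrame({
        "mediator_id": [r.mediator_id for r in results],
        "n": [r.n for r in results],
        "beta_hat": [r.beta_hat for r in results],
        "se": [r.se for r in results],
        "z": [r.z for r in results],
        "p": [r.p for r in results],
        "phi": [r.phi_used for r in results],
        "correction_factor": [r.correction_factor for r in results],
        "z_corrected": [r.z_corrected for r in results],
        "p_corrected": [r.p_corrected for r in results],
    })
    return df[RESULT_COLUMNS]


def zscore_matrix(P: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized OLS Z-scores for every (predictor, trait) pair.

    P is n x K predicted mediators, Y is n x R traits; the returned K x R
    matrix matches :func:`association_test` Z values to floating precision
    (the t-statistic identity z = r*sqrt(n-2)/sqrt(1-r^2)).
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if P.shape[0] != Y.shape[0]:
        raise ValueError("P and Y must share the individual dimension")
    n = P.shape[0]
    Pc = P - P.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    pn = np.linalg.norm(Pc, axis=0)
    yn = np.linalg.norm(Yc, axis=0)
    if np.any(pn == 0) or np.any(yn == 0):
        raise ValueError("constant predictor or trait column")
    r = (Pc.T @ Yc) / np.outer(pn, yn)
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    return r * np.sqrt((n - 2) / (1.0 - r ** 2))
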