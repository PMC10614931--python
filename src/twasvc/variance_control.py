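"""Per-mediator variance control for TWAS Z-scores.

Analogous to genomic control but with a mediator-specific factor: each
Z-score is divided by sqrt(1 + N * h2 * Phi), the square root of its modeled
null variance, where N is the GWAS sample size, h2 the polygenic heritability
of the target trait, and Phi the mediator's inflation slope.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .inflation import PhiEstimate, expected_z_variance

logger = logging.getLogger("twasvc")


def correction_factor(N: int, h2: float, phi: float) -> float:
    """sqrt(1 + N * h2 * Phi); always >= 1 for nonnegative inputs."""
    return float(np.sqrt(expected_z_variance(N, h2, phi)))


def _phi_table(phis) -> pd.DataFrame:
    """Normalize PhiEstimate lists / dicts / DataFrames to (mediator_id, phi)."""
    if isinstance(phis, pd.DataFrame):
        if not {"mediator_id", "phi"}.issubset(phis.columns):
            raise ValueError("phi table needs 'mediator_id' and 'phi' columns")
        df = phis[["mediator_id", "phi"]].copy()
    elif isinstance(phis, dict):
        df = pd.DataFrame({"mediator_id": list(phis.keys()),
                           "phi": list(phis.values())})
    else:
        items = list(phis)
        if not all(isinstance(e, PhiEstimate) for e in items):
            raise ValueError("phis must be a DataFrame, dict, or PhiEstimate list")
        df = pd.DataFrame({"mediator_id": [e.mediator_id for e in items],
                           "phi": [e.phi for e in items]})
    if df["mediator_id"].duplicated().any():
        dup = sorted(df.loc[df["mediator_id"].duplicated(), "mediator_id"].unique())
        raise ValueError(f"duplicate mediator_id(s) in phi table: {dup}")
    if (df["phi"] < 0).any():
        raise ValueError("phi values must be nonnegative (clamp upstream)")
    return df


def apply_correction(results: pd.DataFrame, N: int, h2: float,
                     phis, missing: str = "keep",
                     binary_trait: bool = False) -> pd.DataFrame:
    """Divide each Z by its correction factor and recompute p-values.

    ``phis`` maps mediator_id -> Phi (DataFrame, dict, or PhiEstimate list).
    Rows without a Phi are left uncorrected and flagged (``missing='keep'``,
    default) or dropped (``missing='drop'``).  Original z and p columns are
    preserved untouched.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 must lie in [0, 1]")
    if N < 1:
        raise ValueError("N must be at least 1")
    if missing not in ("keep", "drop"):
        raise ValueError("missing policy must be 'keep' or 'drop'")
    if binary_trait:
        logger.warning("binary target trait: the linear-model correction is a "
                       "balanced-design approximation; no effective-N "
                       "adjustment is applied")
    phi_df = _phi_table(phis)
    out = results.copy()
    phi_map = dict(zip(phi_df["mediator_id"], phi_df["phi"].astype(float)))
    matched = out["mediator_id"].map(phi_map)
    unmatched = matched.isna()
    if unmatched.any():
        missing_ids = out.loc[unmatched, "mediator_id"].tolist()
        logger.warning("%d result row(s) have no Phi (first: %s); policy=%s",
                       len(missing_ids), missing_ids[0], missing)
        if missing == "drop":
            out = out.loc[~unmatched].copy()
            matched = matched.loc[~unmatched]
            unmatched = matched.isna()
    factors = np.sqrt(1.0 + N * h2 * matched.to_numpy(dtype=float))
    z_corr = out["z"].to_numpy(dtype=float) / factors
    out["phi"] = matched.to_numpy(dtype=float)
    out["correction_factor"] = factors
    out["z_corrected"] = z_corr
    with np.errstate(invalid="ignore"):
        out["p_corrected"] = 2.0 * stats.norm.sf(np.abs(z_corr))
    out["phi_missing"] = unmatched.to_numpy()
    return out


def bonferroni_summary(results: pd.DataFrame,
                       alpha: float = 0.05) -> Tuple[int, int]:
    """Counts of Bonferroni-significant rows before and after correction.

    The threshold is alpha / n_tested, with n_tested the number of rows
    carrying a p-value of the respective kind (raw or corrected).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if len(results) == 0:
        raise ValueError("empty results table")

    def _count(col: str) -> int:
        if col not in results.columns:
            logger.warning("column %r absent; counting 0 significant", col)
            return 0
        p = pd.to_numeric(results[col], errors="coerce").dropna()
        if len(p) == 0:
            logger.warning("no %s values present; counting 0 significant", col)
            return 0
        return int((p < alpha / len(p)).sum())

    return _count("p"), _count("p_corrected")
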