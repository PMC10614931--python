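"""Readers and writers: dosage matrices, weight tables, model stores,
Phi tables, result tables, and run configuration.

All tabular formats are tab-separated UTF-8 with a header row, '.' decimal,
and no index column.  Data tables are written at full float precision;
report files round to 6 significant digits.  Writers are deterministic given
identical inputs.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .inflation import PhiEstimate
from .synthetic_data import GenotypeMatrix, WeightSet
from .twas_core import RESULT_COLUMNS

logger = logging.getLogger("twasvc")

PHI_COLUMNS = ["mediator_id", "phi", "phi_raw", "se", "intercept",
               "clamped", "n_cells", "reps"]


# ---------------------------------------------------------------------------
# Dosage matrices
# ---------------------------------------------------------------------------

def write_dosages(G: GenotypeMatrix, path) -> None:
    """Plain tab-delimited dosage matrix with a one-line variant-id header."""
    df = pd.DataFrame(G.dosages, columns=G.variant_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_dosages(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    dosages = df.to_numpy(dtype=float)
    freqs = np.clip(dosages.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    return GenotypeMatrix(dosages, list(df.columns), freqs, standardized=False)


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Dosages from a VCF: the DS FORMAT field when present, summed GT
    otherwise.  Requires cyvcf2."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF dosages requires cyvcf2") from exc
    ids, cols = [], []
    vcf = VCF(str(path))
    for var in vcf:
        vid = var.ID or f"{var.CHROM}_{var.POS}_{var.REF}_{var.ALT[0]}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(var.genotypes, dtype=object)
            col = np.array([float(g[0]) + float(g[1]) for g in gts])
        ids.append(vid)
        cols.append(col)
    if not cols:
        raise ValueError(f"no variants read from {path}")
    dosages = np.column_stack(cols)
    freqs = np.clip(dosages.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
    return GenotypeMatrix(dosages, ids, freqs, standardized=False)


# ---------------------------------------------------------------------------
# Weight tables and model stores
# ---------------------------------------------------------------------------

@dataclass
class ModelStore:
    """PredictDB-style relational bundle of weights plus per-mediator extras.

    ``weights`` rows: mediator_id, variant_id, ref_allele, alt_allele, weight.
    ``extra`` rows: mediator_id, n_model_variants, phi, phi_se.
    """

    build_id: str
    weights: pd.DataFrame
    extra: pd.DataFrame

    def validate(self) -> None:
        w_ids = set(self.weights["mediator_id"])
        e_ids = set(self.extra["mediator_id"])
        if w_ids != e_ids:
            only_w = sorted(w_ids - e_ids)[:3]
            only_e = sorted(e_ids - w_ids)[:3]
            raise ValueError("weights and extra tables disagree on mediators "
                             f"(weights-only: {only_w}, extra-only: {only_e})")
        if "phi" in self.extra.columns:
            phi = pd.to_numeric(self.extra["phi"], errors="coerce")
            if (phi.dropna() < 0).any():
                raise ValueError("extra table contains negative phi values")


def _weights_from_frame(df: pd.DataFrame) -> List[WeightSet]:
    dup = df.duplicated(subset=["mediator_id", "variant_id"])
    if dup.any():
        pair = df.loc[dup, ["mediator_id", "variant_id"]].iloc[0].tolist()
        raise ValueError(f"duplicate (mediator, variant) row: {pair}")
    n_zero = int((df["weight"] == 0).sum())
    if n_zero:
        logger.info("dropping %d zero-weight row(s)", n_zero)
        df = df[df["weight"] != 0]
    out = []
    for mid, grp in df.groupby("mediator_id", sort=True):
        out.append(WeightSet(mediator_id=str(mid),
                             variant_ids=[str(v) for v in grp["variant_id"]],
                             weights=grp["weight"].to_numpy(dtype=float)))
    return out


def read_weights(path, format: str = "tsv") -> Tuple[List[WeightSet], Optional[ModelStore]]:
    """Load per-mediator prediction weights.

    ``format='tsv'`` expects columns mediator_id, variant_id, weight (plus
    optional ref_allele / alt_allele, preserved for harmonization);
    ``format='sqlite_store'`` reads a PredictDB-style store and returns it as
    the second element.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"mediator_id", "variant_id", "weight"}
        if not required.issubset(df.columns):
            raise ValueError(f"weight TSV must have columns {sorted(required)}")
        return _weights_from_frame(df), None
    if format == "sqlite_store":
        store = load_store(path)
        return _weights_from_frame(store.weights), store
    raise ValueError(f"unknown weight format {format!r}")


def write_weights(weights: List[WeightSet], path) -> None:
    rows = []
    for w in weights:
        for vid, wt in zip(w.variant_ids, w.weights):
            rows.append((w.mediator_id, vid, "N", "N", wt))
    df = pd.DataFrame(rows, columns=["mediator_id", "variant_id",
                                     "ref_allele", "alt_allele", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def save_store(store: ModelStore, path) -> None:
    store.validate()
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        store.weights.to_sql("weights", con, index=False)
        store.extra.to_sql("extra", con, index=False)
        pd.DataFrame({"key": ["build_id"], "value": [store.build_id]}
                     ).to_sql("meta", con, index=False)
        con.commit()
    finally:
        con.close()


def load_store(path) -> ModelStore:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    con = sqlite3.connect(path)
    try:
        weights = pd.read_sql("SELECT * FROM weights", con)
        extra = pd.read_sql("SELECT * FROM extra", con)
        meta = pd.read_sql("SELECT * FROM meta", con)
    finally:
        con.close()
    build = dict(zip(meta["key"], meta["value"])).get("build_id", "")
    store = ModelStore(build_id=str(build), weights=weights, extra=extra)
    store.validate()
    return store


# ---------------------------------------------------------------------------
# Phi and result tables
# ---------------------------------------------------------------------------

def phi_estimates_to_frame(estimates: List[PhiEstimate]) -> pd.DataFrame:
    return pd.DataFrame({
        "mediator_id": [e.mediator_id for e in estimates],
        "phi": [e.phi for e in estimates],
        "phi_raw": [e.phi_raw for e in estimates],
        "se": [e.se for e in estimates],
        "intercept": [e.intercept for e in estimates],
        "clamped": [e.clamped for e in estimates],
        "n_cells": [len(e.grid.cells) if e.grid else 0 for e in estimates],
        "reps": [e.n_reps_per_cell for e in estimates],
    })[PHI_COLUMNS]


def write_phi(estimates: List[PhiEstimate], path,
              store: Optional[ModelStore] = None,
              store_path=None, build_id: Optional[str] = None) -> None:
    """Write a Phi TSV and optionally upsert phi/phi_se into a model store.

    When a store is given, ``build_id`` must match ``store.build_id`` so that
    Phi values are never mixed across model builds.
    """
    if not estimates:
        raise ValueError("no Phi estimates to write")
    df = phi_estimates_to_frame(estimates)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if store is not None:
        if build_id is None or build_id != store.build_id:
            raise ValueError(f"build_id mismatch: estimates tagged {build_id!r} "
                             f"but store is {store.build_id!r}")
        extra = store.extra.copy()
        phi_map = {e.mediator_id: (e.phi, e.se) for e in estimates}
        if "phi" not in extra.columns:
            extra["phi"] = np.nan
        if "phi_se" not in extra.columns:
            extra["phi_se"] = np.nan
        hit = extra["mediator_id"].isin(phi_map)
        extra.loc[hit, "phi"] = [phi_map[m][0] for m in extra.loc[hit, "mediator_id"]]
        extra.loc[hit, "phi_se"] = [phi_map[m][1] for m in extra.loc[hit, "mediator_id"]]
        store.extra = extra
        if store_path is not None:
            save_store(store, store_path)


def read_phi(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"mediator_id", "phi"}.issubset(df.columns):
        raise ValueError("phi table needs 'mediator_id' and 'phi' columns")
    return df


def phi_from_store(store: ModelStore) -> pd.DataFrame:
    if "phi" not in store.extra.columns:
        raise ValueError(f"model store {store.build_id!r} carries no phi column")
    df = store.extra[["mediator_id", "phi"]].dropna()
    return df.reset_index(drop=True)


def write_results(results: pd.DataFrame, path) -> None:
    """Result table writer; missing corrected fields become empty, never 0."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep="\t", index=False, na_rep="",
                         float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize_weights(weights_df: pd.DataFrame,
                      variants_df: pd.DataFrame) -> pd.DataFrame:
    """Align weight effect alleles to the genotype panel's alt alleles.

    ``weights_df`` needs (variant_id, ref_allele, alt_allele, weight);
    ``variants_df`` needs (variant_id, ref_allele, alt_allele).  Swapped
    alleles flip the weight sign (possibly after strand complement);
    strand-ambiguous A/T and C/G variants and unresolvable rows are dropped
    with a logged count.
    """
    panel = {str(r.variant_id): (str(r.ref_allele).upper(), str(r.alt_allele).upper())
             for r in variants_df.itertuples()}
    rows, n_ambig, n_drop = [], 0, 0
    for r in weights_df.itertuples():
        vid = str(r.variant_id)
        if vid not in panel:
            n_drop += 1
            continue
        ref, alt = str(r.ref_allele).upper(), str(r.alt_allele).upper()
        if _is_ambiguous(ref, alt):
            n_ambig += 1
            continue
        p_ref, p_alt = panel[vid]
        flip = None
        if (ref, alt) == (p_ref, p_alt):
            flip = 1.0
        elif (ref, alt) == (p_alt, p_ref):
            flip = -1.0
        else:
            cref = _COMPLEMENT.get(ref, "?")
            calt = _COMPLEMENT.get(alt, "?")
            if (cref, calt) == (p_ref, p_alt):
                flip = 1.0
            elif (cref, calt) == (p_alt, p_ref):
                flip = -1.0
        if flip is None:
            n_drop += 1
            continue
        row = r._asdict()
        row.pop("Index", None)
        row["weight"] = float(r.weight) * flip
        rows.append(row)
    if n_ambig or n_drop:
        logger.warning("harmonization dropped %d ambiguous and %d unmatched "
                       "variant row(s)", n_ambig, n_drop)
    return pd.DataFrame(rows, columns=[c for c in weights_df.columns])


# ---------------------------------------------------------------------------
# Configuration / provenance
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Key-value run configuration from JSON or YAML (by file suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    return cfg


def write_provenance(out_path, config: dict) -> None:
    """Echo the effective configuration next to an output file."""
    side = Path(str(out_path) + ".provenance.json")
    side.write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")
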