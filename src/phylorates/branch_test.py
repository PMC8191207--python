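"""Rapidly-evolving-gene (REG) calling from branch-model likelihoods.

Inputs are per-gene log-likelihoods of the one-ratio model (a single ω for
the whole tree, ``lnL0``) and the two-ratio model (separate foreground and
background ω, ``lnL1``), as produced by a codon-model program; this module
never optimizes codon models itself.  The likelihood-ratio statistic
2(lnL1−lnL0) is referred to a χ² distribution with df = k1−k0 (1 by
default).  A gene is a REG when its foreground ω exceeds the background ω
and the raw LRT P value is below α; a second flag additionally requires the
Benjamini–Hochberg adjusted P value (computed within each foreground group)
to pass α.

Foreground groups follow the body-size partition of the 20-carnivore study:
small (body mass < 12 kg and head-body length < 1 m), extremely large
(body mass > 350 kg), and extremely small (body mass < 1 kg, a subset of
small); everything else is background.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import NestingError, RatesTableError

__all__ = [
    "lrt",
    "bh_fdr",
    "classify_regs",
    "assign_size_groups",
    "read_branch_model_tsv",
    "write_reg_tsv",
]

NESTING_TOL = 1e-6

BRANCH_MODEL_COLUMNS = ["gene", "group", "lnL0", "lnL1", "omega_fg", "omega_bg"]

# body-size group thresholds (g and cm)
EXTREMELY_LARGE_MASS_G = 350_000.0
SMALL_MASS_G = 12_000.0
SMALL_LENGTH_CM = 100.0
EXTREMELY_SMALL_MASS_G = 1_000.0


def lrt(lnL0: float, lnL1: float, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio test of the two-ratio against the one-ratio model.

    Returns ``(stat, p)`` with ``stat = 2(lnL1 − lnL0)`` and ``p`` the upper
    χ²_df tail.  Small negative statistics (within 1e-6) are clamped to zero;
    larger violations indicate a failed upstream optimization and raise.
    """
    stat = 2.0 * (lnL1 - lnL0)
    if stat < -2.0 * NESTING_TOL:
        raise NestingError(
            f"lnL1 ({lnL1}) < lnL0 ({lnL0}): models not nested or "
            "optimization failed upstream"
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values, aligned with the input
    order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_regs(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the LRT and the foreground-faster rule to a branch-model table.

    ``records`` needs columns ``gene, group, lnL0, lnL1, omega_fg, omega_bg``
    and optionally ``k0, k1`` (df = k1−k0, default 1).  FDR adjustment is
    applied within each foreground group separately.  Returns the table with
    ``lrt_stat, df, p_value, p_adjusted, is_reg, is_reg_fdr`` appended.
    """
    missing = [c for c in BRANCH_MODEL_COLUMNS if c not in records.columns]
    if missing:
        raise RatesTableError(f"branch-model table missing columns: {missing}")
    if records.duplicated(subset=["gene", "group"]).any():
        dup = records[records.duplicated(subset=["gene", "group"])].iloc[0]
        raise RatesTableError(f"duplicate gene×group row: {dup['gene']} × {dup['group']}")
    out = records.copy().reset_index(drop=True)
    if "k0" in out.columns and "k1" in out.columns:
        out["df"] = (out["k1"] - out["k0"]).astype(int)
    else:
        out["df"] = 1
    stats_p = [lrt(r.lnL0, r.lnL1, int(r.df)) for r in out.itertuples()]
    out["lrt_stat"] = [s for s, _ in stats_p]
    out["p_value"] = [p for _, p in stats_p]
    out["p_adjusted"] = np.nan
    for _, idx in out.groupby("group").groups.items():
        out.loc[idx, "p_adjusted"] = bh_fdr(out.loc[idx, "p_value"].to_numpy())
    faster = out["omega_fg"] > out["omega_bg"]
    out["is_reg"] = faster & (out["p_value"] < alpha)
    out["is_reg_fdr"] = out["is_reg"] & (out["p_adjusted"] < alpha)
    return out


def assign_size_groups(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Label species by body-size group from a phenotype table.

    Input columns: ``species``, ``body_mass_g``, ``head_body_length_cm``.
    Output adds boolean columns ``is_small``, ``is_extremely_small``,
    ``is_extremely_large`` and a primary ``group`` label
    (``extremely_large`` > ``small`` > ``background``; extremely small
    species are a subset of small).  Species with a missing phenotype are
    labeled ``unassigned`` and logged.
    """
    needed = ["species", "body_mass_g", "head_body_length_cm"]
    missing = [c for c in needed if c not in phenotypes.columns]
    if missing:
        raise RatesTableError(f"phenotype table missing columns: {missing}")
    out = phenotypes[needed].copy()
    mass = out["body_mass_g"].astype(float)
    length = out["head_body_length_cm"].astype(float)
    ok = np.isfinite(mass) & np.isfinite(length)
    out["is_extremely_large"] = ok & (mass > EXTREMELY_LARGE_MASS_G)
    out["is_small"] = ok & (mass < SMALL_MASS_G) & (length < SMALL_LENGTH_CM)
    out["is_extremely_small"] = out["is_small"] & (mass < EXTREMELY_SMALL_MASS_G)
    group = np.where(~ok, "unassigned",
                     np.where(out["is_extremely_large"], "extremely_large",
                              np.where(out["is_small"], "small", "background")))
    out["group"] = group
    for sp in out.loc[out["group"] == "unassigned", "species"]:
        logging.getLogger(__name__).warning(
            "species %s has missing phenotype; unassigned", sp)
    return out


def read_branch_model_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "group": str},
                     na_values=["NA"])
    missing = [c for c in BRANCH_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise RatesTableError(f"{path}: missing columns {missing}")
    return df


def write_reg_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              lineterminator="\n", float_format="%.10g")
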