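"""Per-gene per-branch dN/dS tables and the root-to-tip ω statistic.

The per-branch table is the surrogate for free-ratio codon-model output: one
row per gene × branch with non-synonymous (dN) and synonymous (dS) divergence
and their ratio ω.  A branch is an *outlier* (excluded from averaging) when dN
or dS falls below a small threshold, 0.0002 by default, because the ratio is
numerically meaningless when either count is essentially zero.  The species
statistic is the unweighted mean of ω over the valid branches on the
root-to-tip path, log10-transformed for regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import RatesTableError
from .phylo import PhyloTree, root_to_tip_path

__all__ = [
    "DEFAULT_RATE_THRESHOLD",
    "BranchRatesTable",
    "branch_is_valid",
    "root_to_tip_omega",
    "read_rates_tsv",
    "write_rates_tsv",
    "read_root_to_tip_tsv",
    "write_root_to_tip_tsv",
]

DEFAULT_RATE_THRESHOLD = 0.0002

RATES_COLUMNS = ["gene", "branch", "dN", "dS", "omega"]
RTT_COLUMNS = ["gene", "species", "omega_bar", "log10_omega_bar", "n_valid_branches"]


@dataclass
class BranchRatesTable:
    """Long-format per-branch rates for one or more genes.

    ``df`` has columns ``gene, branch, dN, dS, omega``; ``omega`` is NaN where
    undefined (dS = 0 with no explicit value supplied).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RATES_COLUMNS if c not in self.df.columns]
        if missing:
            raise RatesTableError(f"rates table missing columns: {missing}")
        if self.df.duplicated(subset=["gene", "branch"]).any():
            dup = self.df[self.df.duplicated(subset=["gene", "branch"])].iloc[0]
            raise RatesTableError(
                f"duplicate gene×branch row: {dup['gene']} × {dup['branch']}"
            )
        for col in ("dN", "dS"):
            vals = self.df[col]
            if vals.isna().any() or (vals < 0).any():
                raise RatesTableError(f"column {col} must be non-negative and complete")

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.df["gene"]))

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.df[self.df["gene"] == gene]

    def check_branches(self, tree: PhyloTree) -> None:
        """Every branch id must resolve to a non-root node of ``tree``."""
        known = set(tree.parent) - {tree.root}
        bad = sorted(set(self.df["branch"]) - known)
        if bad:
            raise RatesTableError(f"branch ids not present in tree: {bad}")


def branch_is_valid(dN: float, dS: float,
                    threshold: float = DEFAULT_RATE_THRESHOLD) -> bool:
    """A branch contributes to the root-to-tip average only if both dN and dS
    reach ``threshold`` (the "less than" outlier rule is strict, so equality
    passes)."""
    if dN < 0 or dS < 0:
        raise ValueError(f"dN and dS must be non-negative, got ({dN}, {dS})")
    return dN >= threshold and dS >= threshold


def root_to_tip_omega(tree: PhyloTree, rates: BranchRatesTable,
                      threshold: float = DEFAULT_RATE_THRESHOLD,
                      method: str = "mean") -> pd.DataFrame:
    """Per-species mean ω over valid branches on the root-to-tip path.

    Returns a frame with columns ``gene, species, omega_bar, log10_omega_bar,
    n_valid_branches``; ``omega_bar`` is NaN when no valid branch exists on
    the path (the species is dropped from downstream regression).  A branch
    missing from the table counts as invalid.

    ``method`` selects the path summary: ``"mean"`` (default) is the
    unweighted arithmetic mean of branch ω; ``"ratio_of_sums"`` is
    sum(dN)/sum(dS) over the same valid branches, provided as an alternative
    aggregation for sensitivity analysis.
    """
    if method not in ("mean", "ratio_of_sums"):
        raise ValueError(f"unknown method {method!r}")
    rates.check_branches(tree)
    paths = {tip: root_to_tip_path(tree, tip) for tip in tree.tips}
    rows = []
    for gene in rates.genes:
        sub = rates.for_gene(gene).set_index("branch")
        for tip, path in paths.items():
            omegas = []
            dn_sum = ds_sum = 0.0
            for br in path:
                if br not in sub.index:
                    continue
                rec = sub.loc[br]
                dn, ds = float(rec["dN"]), float(rec["dS"])
                if not branch_is_valid(dn, ds, threshold):
                    continue
                om = float(rec["omega"])
                if np.isnan(om):
                    continue
                omegas.append(om)
                dn_sum += dn
                ds_sum += ds
            if omegas:
                if method == "mean":
                    bar = float(np.mean(omegas))
                else:
                    bar = dn_sum / ds_sum
                rows.append((gene, tip, bar,
                             np.log10(bar) if bar > 0 else np.nan, len(omegas)))
            else:
                rows.append((gene, tip, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=RTT_COLUMNS)


def _recompute_omega(df: pd.DataFrame) -> pd.DataFrame:
    with np.errstate(divide="ignore", invalid="ignore"):
        om = df["dN"] / df["dS"]
    df = df.copy()
    df["omega"] = om.replace([np.inf, -np.inf], np.nan)
    return df


def read_rates_tsv(path) -> BranchRatesTable:
    """Read a branch-rates TSV (``gene, branch, dN, dS[, omega]``).

    When the ``omega`` column is absent it is recomputed as dN/dS; a dS of
    zero yields NaN (the branch is invalid under the outlier rule anyway).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "branch": str},
                     na_values=["NA"], keep_default_na=True)
    required = ["gene", "branch", "dN", "dS"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RatesTableError(f"{path}: missing columns {missing}")
    for col in ("dN", "dS"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise RatesTableError(f"{path}: non-numeric values in column {col}")
    if "omega" not in df.columns:
        df = _recompute_omega(df)
    elif not np.issubdtype(df["omega"].dtype, np.number):
        raise RatesTableError(f"{path}: non-numeric values in column omega")
    return BranchRatesTable(df[RATES_COLUMNS].reset_index(drop=True))


def write_rates_tsv(table: BranchRatesTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, na_rep="NA",
                    lineterminator="\n", float_format="%.10g")


def read_root_to_tip_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "species": str},
                     na_values=["NA"])
    missing = [c for c in RTT_COLUMNS if c not in df.columns]
    if missing:
        raise RatesTableError(f"{path}: missing columns {missing}")
    return df[RTT_COLUMNS]


def write_root_to_tip_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              lineterminator="\n", float_format="%.10g")
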