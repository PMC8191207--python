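"""Two-step P-value calibration and the dual-phenotype BSAG decision.

Instead of correcting the genome scan for multiple testing, each
gene × phenotype regression is subjected to a robustness calibration built
from three P values:

* ``p_all`` — the PGLS P value on all species with complete data;
* ``p_robust`` — the P value after discarding the single species with the
  largest absolute residual of the full fit;
* ``p_max`` — the maximum P value over refits each dropping one species.

A gene is a body-size-associated gene (BSAG) when all three P values fall
below α for *both* phenotypes (head-body length and body mass); its
direction (positive/negative) is the sign of the body-mass slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .errors import FitError, TooFewSpeciesError
from .pgls import DEFAULT_MIN_SPECIES, PGLSFit, pgls_gene
from .phylo import PhyloTree, lambda_transform, vcv_matrix
from .rates import BranchRatesTable, DEFAULT_RATE_THRESHOLD, root_to_tip_omega

__all__ = [
    "CalibrationResult",
    "BSAGRecord",
    "ScanResult",
    "two_step_calibration",
    "classify_bsag",
    "scan_genome",
    "PHENOTYPE_COLUMNS",
]

logger = logging.getLogger(__name__)

# phenotype name -> column of the phenotype table (raw units: cm, g)
PHENOTYPE_COLUMNS = {
    "head_body_length": "head_body_length_cm",
    "body_mass": "body_mass_g",
}


@dataclass
class CalibrationResult:
    """Three calibration P values for one gene × phenotype."""

    gene: str
    phenotype: str
    n_used: int
    p_all: float = np.nan
    p_robust: float = np.nan
    p_max: float = np.nan
    slope_all: float = np.nan
    lambda_hat: float = np.nan
    dropped_species: str | None = None
    leave_one_out_p: dict[str, float] = field(default_factory=dict)
    complete: bool = False
    reason: str | None = None

    def significant(self, alpha: float) -> bool:
        return (self.complete and self.p_all < alpha
                and self.p_robust < alpha and self.p_max < alpha)


@dataclass
class BSAGRecord:
    """A gene called body-size-associated for both phenotypes."""

    gene: str
    direction: str                  # "positive" | "negative" (body-mass slope)
    length_result: CalibrationResult
    mass_result: CalibrationResult
    sign_concordant: bool


@dataclass
class ScanResult:
    calibration: pd.DataFrame       # one row per gene × phenotype
    bsags: list[BSAGRecord]
    counts: dict[str, int]
    skipped: dict[str, str]         # gene -> reason

    @property
    def bsag_table(self) -> pd.DataFrame:
        rows = []
        for rec in self.bsags:
            le, ma = rec.length_result, rec.mass_result
            rows.append({
                "gene": rec.gene, "direction": rec.direction,
                "sign_concordant": rec.sign_concordant,
                "slope_length": le.slope_all, "slope_mass": ma.slope_all,
                "lambda_length": le.lambda_hat, "lambda_mass": ma.lambda_hat,
                "p_all_length": le.p_all, "p_robust_length": le.p_robust,
                "p_max_length": le.p_max,
                "p_all_mass": ma.p_all, "p_robust_mass": ma.p_robust,
                "p_max_mass": ma.p_max,
            })
        cols = ["gene", "direction", "sign_concordant", "slope_length",
                "slope_mass", "lambda_length", "lambda_mass",
                "p_all_length", "p_robust_length", "p_max_length",
                "p_all_mass", "p_robust_mass", "p_max_mass"]
        return pd.DataFrame(rows, columns=cols)


def _whitened_residuals(fit: PGLSFit, tree: PhyloTree) -> np.ndarray:
    C = vcv_matrix(tree, fit.species)
    V = lambda_transform(C, fit.lambda_hat if fit.lambda_hat is not None else 1.0)
    L = cholesky(V, lower=True)
    return solve_triangular(L, fit.residuals, lower=True)


def two_step_calibration(rtt: pd.DataFrame, phenotype: pd.Series, tree: PhyloTree,
                         gene: str, phenotype_name: str,
                         mode: str = "drop-from-full",
                         min_species: int = DEFAULT_MIN_SPECIES,
                         fixed_lambda: float | None = None,
                         residual_scale: str = "raw") -> CalibrationResult:
    """Compute ``p_all``, ``p_robust`` and ``p_max`` for one gene × phenotype.

    ``mode`` controls the species set used for the leave-one-out refits behind
    ``p_max``: ``"drop-from-full"`` (default) drops each species from the full
    set; ``"drop-from-robust"`` drops each from the set that already excludes
    the largest-residual species.  ``residual_scale`` selects raw response
    residuals (default) or residuals whitened by the fitted covariance when
    identifying the largest-residual species.  The phylogenetic covariance is
    re-restricted at every refit and λ re-estimated unless ``fixed_lambda``
    is given.
    """
    if mode not in ("drop-from-full", "drop-from-robust"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    if residual_scale not in ("raw", "whitened"):
        raise ValueError(f"unknown residual scale {residual_scale!r}")

    def fit_on(species_subset: list[str] | None) -> PGLSFit:
        sub = rtt if species_subset is None else rtt[rtt["species"].isin(species_subset)]
        return pgls_gene(sub, phenotype, tree, min_species=min_species,
                         fixed_lambda=fixed_lambda)

    try:
        full = fit_on(None)
    except FitError as exc:
        return CalibrationResult(gene=gene, phenotype=phenotype_name, n_used=0,
                                 complete=False, reason=str(exc))
    res = CalibrationResult(gene=gene, phenotype=phenotype_name, n_used=full.n,
                            p_all=full.p_value, slope_all=full.slope,
                            lambda_hat=full.lambda_hat if full.lambda_hat is not None
                            else np.nan)
    species = list(full.species)
    need = full.n - (1 if mode == "drop-from-full" else 2)
    if need < min_species:
        res.reason = (f"{full.n} species leaves refits below the minimum of "
                      f"{min_species}")
        return res

    resid = full.residuals if residual_scale == "raw" else _whitened_residuals(full, tree)
    dropped = species[int(np.argmax(np.abs(resid)))]
    res.dropped_species = dropped
    robust_set = [s for s in species if s != dropped]
    try:
        robust = fit_on(robust_set)
        res.p_robust = robust.p_value
        loo_base = species if mode == "drop-from-full" else robust_set
        loo: dict[str, float] = {}
        for s in loo_base:
            loo[s] = fit_on([t for t in loo_base if t != s]).p_value
    except FitError as exc:
        res.reason = f"refit failed: {exc}"
        return res
    res.leave_one_out_p = loo
    res.p_max = max(loo.values())
    res.complete = True
    return res


def classify_bsag(res_length: CalibrationResult, res_mass: CalibrationResult,
                  alpha: float = 0.05) -> BSAGRecord | None:
    """BSAG iff all six P values are below α; direction follows the body-mass
    slope, with discordant slope signs flagged rather than dropped."""
    if not (res_length.significant(alpha) and res_mass.significant(alpha)):
        return None
    direction = "positive" if res_mass.slope_all > 0 else "negative"
    concordant = np.sign(res_length.slope_all) == np.sign(res_mass.slope_all)
    return BSAGRecord(gene=res_length.gene, direction=direction,
                      length_result=res_length, mass_result=res_mass,
                      sign_concordant=bool(concordant))


def scan_genome(rates: BranchRatesTable, phenotypes: pd.DataFrame,
                tree: PhyloTree, alpha: float = 0.05,
                threshold: float = DEFAULT_RATE_THRESHOLD,
                min_species: int = DEFAULT_MIN_SPECIES,
                mode: str = "drop-from-full",
                fixed_lambda: float | None = None) -> ScanResult:
    """Run the full BSAG scan: root-to-tip ω, per-phenotype calibration, and
    the dual-phenotype decision, for every gene in ``rates``.

    ``phenotypes`` must have columns ``species``, ``head_body_length_cm`` and
    ``body_mass_g``.  Genes that cannot be calibrated are skipped with a
    logged reason; the scan never aborts on a single gene.
    """
    phen = phenotypes.set_index("species")
    rtt_all = root_to_tip_omega(tree, rates, threshold=threshold)
    cal_rows: list[CalibrationResult] = []
    bsags: list[BSAGRecord] = []
    skipped: dict[str, str] = {}
    sig_counts = {name: 0 for name in PHENOTYPE_COLUMNS}
    for gene in rates.genes:
        rtt = rtt_all[rtt_all["gene"] == gene]
        results: dict[str, CalibrationResult] = {}
        for name, col in PHENOTYPE_COLUMNS.items():
            results[name] = two_step_calibration(
                rtt, phen[col], tree, gene=gene, phenotype_name=name,
                mode=mode, min_species=min_species, fixed_lambda=fixed_lambda)
        cal_rows.extend(results.values())
        if not all(r.complete for r in results.values()):
            reasons = "; ".join(f"{n}: {r.reason}" for n, r in results.items()
                                if not r.complete)
            skipped[gene] = reasons
            logger.info("gene %s skipped (%s)", gene, reasons)
            continue
        for name, r in results.items():
            if r.significant(alpha):
                sig_counts[name] += 1
        rec = classify_bsag(results["head_body_length"], results["body_mass"], alpha)
        if rec is not None:
            bsags.append(rec)

    cal_df = pd.DataFrame([{
        "gene": r.gene, "phenotype": r.phenotype, "n": r.n_used,
        "slope": r.slope_all, "lambda_hat": r.lambda_hat,
        "p_all": r.p_all, "p_robust": r.p_robust, "p_max": r.p_max,
        "complete": r.complete,
    } for r in cal_rows])
    counts = {
        "n_genes": len(rates.genes),
        "n_skipped": len(skipped),
        "significant_head_body_length": sig_counts["head_body_length"],
        "significant_body_mass": sig_counts["body_mass"],
        "n_bsag": len(bsags),
        "n_bsag_positive": sum(r.direction == "positive" for r in bsags),
        "n_bsag_negative": sum(r.direction == "negative" for r in bsags),
    }
    assert counts["n_bsag"] <= min(counts["significant_head_body_length"],
                                   counts["significant_body_mass"])
    return ScanResult(calibration=cal_df, bsags=bsags, counts=counts,
                      skipped=skipped)
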