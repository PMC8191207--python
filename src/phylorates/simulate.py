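"""Seed-reproducible synthetic datasets with the statistical structure the
analysis assumes.

The generator emulates the data flow of a 20-carnivore comparative study:

* a Yule (pure-birth) chronogram rescaled to unit height;
* log10 body mass evolving by Brownian motion on that tree, and log10
  head-body length following mass allometrically with independent Brownian
  noise (emitted in g and cm);
* per-gene branch tables whose tip-level log10 root-to-tip ω is linearly
  related to log10 body mass with phylogenetically correlated residuals —
  effect genes carry a planted slope β, null genes have β = 0;
* protein alignments with planted group-fixed residues and gap columns;
* branch-model likelihood records under null and alternative regimes.

Branch-level ω values are realized by minimum-norm least squares on the
path-incidence system mapping branch ω to tip path-means, then clipped to a
positive range; the *achieved* tip averages (recomputed after clipping and
after marking sub-threshold branches invalid) are stored as ground truth, so
recovery tests are judged against what the data actually contain rather than
the pre-clipping targets.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .branch_test import assign_size_groups
from .errors import SimulationError
from .fixed_changes import ProteinAlignment
from .phylo import PhyloCovariance, PhyloTree, lambda_transform, parse_newick, vcv_matrix
from .rates import BranchRatesTable, DEFAULT_RATE_THRESHOLD, branch_is_valid

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "brownian_sample",
    "simulate_phenotypes",
    "simulate_gene_rates",
    "simulate_alignment",
    "simulate_lrt_records",
    "simulate_dataset",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
OMEGA_CLIP = (1e-4, 10.0)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror a 20-carnivore
    body-size scan.

    Masses are log10 grams (root at 10 kg with unit Brownian variance over
    the unit-height tree spans roughly 100 g to 1000 kg, the carnivore
    range); length follows the cube-root allometry of body mass.  Gene-level
    defaults plant a slope of 0.4 with strong phylogenetic signal (λ = 0.9)
    and residual scatter 0.3 on the log10 ω scale; per-branch synonymous
    divergence is log-normal with median 0.05.
    """

    n_species: int = 20
    seed: int = 0
    tree_source: str = "yule"           # "yule" | "fixed"
    newick: str | None = None           # used when tree_source == "fixed"
    # phenotypes
    root_log10_mass_g: float = 4.0
    mass_bm_sigma2: float = 1.0
    length_allometry_intercept: float = 0.47
    length_allometry_slope: float = 0.33
    length_bm_sigma2: float = 0.01
    # gene plan
    n_effect_genes: int = 30
    n_null_genes: int = 170
    effect_beta: float = 0.4
    gene_lambda: float = 0.9
    gene_sigma: float = 0.3
    mean_log10_omega: float = -0.85     # ω ≈ 0.14 at the root mass
    # branch rates
    dS_log_median: float = 0.05
    dS_log_sigma: float = 0.5
    subthreshold_fraction: float = 0.05
    rate_threshold: float = DEFAULT_RATE_THRESHOLD
    # alignment plan
    n_alignments: int = 6
    alignment_length: int = 300
    planted_sites_per_gene: int = 1
    gap_columns_per_gene: int = 3
    alignment_mutation_rate: float = 0.02
    # LRT plan
    n_null_records: int = 100
    n_alt_records: int = 20
    lrt_noncentrality: float = 10.0

    def validate(self) -> None:
        if self.n_species < 3:
            raise SimulationError("n_species must be at least 3")
        for name in ("mass_bm_sigma2", "gene_sigma", "dS_log_sigma",
                     "dS_log_median"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        if self.length_bm_sigma2 < 0:
            raise SimulationError("length_bm_sigma2 must be non-negative")
        for name in ("n_effect_genes", "n_null_genes", "n_null_records",
                     "n_alt_records", "n_alignments"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        if not 0 <= self.subthreshold_fraction <= 1:
            raise SimulationError("subthreshold_fraction must be in [0, 1]")
        if self.lrt_noncentrality < 0:
            raise SimulationError("lrt_noncentrality must be non-negative")
        if not np.isfinite(self.effect_beta):
            raise SimulationError("effect_beta must be finite")


@dataclass
class SimulatedDataset:
    """A complete synthetic study with its ground truth."""

    config: SimulationConfig
    tree: PhyloTree
    newick: str
    phenotypes: pd.DataFrame         # species, head_body_length_cm, body_mass_g
    rates: BranchRatesTable          # all genes, long format
    truth_params: pd.DataFrame       # gene, beta, lambda_g, sigma_g, is_effect
    truth_rtt: pd.DataFrame          # gene, species, achieved log10 ω̄, n_valid
    alignments: list[ProteinAlignment] = field(default_factory=list)
    planted_sites: pd.DataFrame | None = None
    focal_species: list[str] = field(default_factory=list)
    lrt_records: pd.DataFrame | None = None


def simulate_tree(n: int, seed: int) -> PhyloTree:
    """Yule (pure-birth) topology on ``n`` tips, branch lengths rescaled so
    the tree height is exactly 1; deterministic under ``seed``.  Tips are
    labeled ``sp01 … spNN``."""
    if n < 3:
        raise SimulationError(f"need at least 3 tips, got {n}")
    taxa = dendropy.TaxonNamespace([f"sp{i + 1:02d}" for i in range(n)])
    pyrng = random.Random(seed)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=n, rng=pyrng)
    tree.is_rooted = True
    # the process stops exactly at the nth speciation, leaving zero-length
    # terminal edges; extend every tip by one more Yule waiting time
    extra = pyrng.expovariate(n * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None  # drop the origin stem
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    out = parse_newick(newick)
    scale = out.height
    for b in out.branch_length:
        out.branch_length[b] /= scale
    out._depths.clear()
    return out


def brownian_sample(C: PhyloCovariance | np.ndarray, mean: float, sigma2: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One multivariate-normal draw with covariance ``sigma2 · C`` (the
    Brownian-motion tip distribution) around ``mean``."""
    M = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    if sigma2 < 0:
        raise SimulationError("sigma2 must be non-negative")
    n = M.shape[0]
    if sigma2 == 0:
        return np.full(n, float(mean))
    w, U = np.linalg.eigh(M)
    if w.min() < -1e-9 * max(w.max(), 1.0):
        raise SimulationError("covariance matrix is not positive semi-definite")
    w = np.clip(w, 0.0, None)
    z = rng.standard_normal(n)
    return mean + np.sqrt(sigma2) * (U @ (np.sqrt(w) * z))


def simulate_phenotypes(tree: PhyloTree, cfg: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Body mass (g) by Brownian motion in log10 space; head-body length (cm)
    allometric in mass with independent Brownian noise."""
    C = vcv_matrix(tree)
    log_mass = brownian_sample(C, cfg.root_log10_mass_g, cfg.mass_bm_sigma2, rng)
    noise = brownian_sample(C, 0.0, cfg.length_bm_sigma2, rng)
    log_len = (cfg.length_allometry_intercept
               + cfg.length_allometry_slope * log_mass + noise)
    return pd.DataFrame({
        "species": C.species,
        "head_body_length_cm": 10.0 ** log_len,
        "body_mass_g": 10.0 ** log_mass,
    })


def _path_incidence(tree: PhyloTree) -> tuple[list[str], list[str], np.ndarray]:
    """Rows = tips, columns = branches (child-node ids); entry 1/|path| when
    the branch lies on the tip's root-to-tip path."""
    tips = tree.tips
    branches = [n for n in tree._postorder() if tree.parent[n] is not None]
    bindex = {b: j for j, b in enumerate(branches)}
    A = np.zeros((len(tips), len(branches)))
    for i, tip in enumerate(tips):
        path = tree.ancestors(tip)[1:]
        for b in path:
            A[i, bindex[b]] = 1.0 / len(path)
    return tips, branches, A


def simulate_gene_rates(tree: PhyloTree, phenotypes: pd.DataFrame, gene: str,
                        beta: float, lambda_g: float, sigma_g: float,
                        cfg: SimulationConfig,
                        rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One gene's branch table with a planted rate–mass relationship.

    Tip targets on the log10 scale are ``u = α + β·log10(mass) + ε`` with
    ``ε ~ N(0, σ_g²·C(λ_g))``.  Branch ω solves the path-incidence system
    for path-mean targets ``10^u`` constructively: internal branches receive
    a jittered baseline just below the smallest tip target, and each
    terminal branch — which lies on exactly one root-to-tip path — absorbs
    its tip's remaining signal, so every branch ω is positive and the tip
    path-means are exact before clipping to ``OMEGA_CLIP``.  dS is
    log-normal per branch (a configured fraction forced below the validity
    threshold), dN = ω·dS.  Returns the branch rows and the achieved per-tip
    truth (mean ω over valid branches, recomputed from the emitted table).
    """
    if sigma_g <= 0:
        raise SimulationError("sigma_g must be positive")
    C = vcv_matrix(tree)
    log_mass = np.log10(
        phenotypes.set_index("species").loc[C.species, "body_mass_g"].to_numpy())
    eps = brownian_sample(lambda_transform(C, lambda_g), 0.0, sigma_g ** 2, rng)
    alpha = cfg.mean_log10_omega - beta * cfg.root_log10_mass_g
    u = alpha + beta * log_mass + eps
    targets = 10.0 ** u

    tips, branches, A = _path_incidence(tree)
    if np.linalg.matrix_rank(A) < len(tips):
        raise SimulationError("degenerate tree: path-incidence system is singular")
    bindex = {b: j for j, b in enumerate(branches)}
    # internal baseline 0.9·min(target) with ±10% jitter keeps every terminal
    # solution strictly positive: L·t_i − (L−1)·0.99·min(t) > 0
    base = 0.9 * targets.min()
    omega = base * rng.uniform(0.9, 1.1, size=len(branches))
    tgt = dict(zip(tips, targets))
    for tip in tips:
        path = [bindex[b] for b in tree.ancestors(tip)[1:]]
        inner = [j for j in path if j != bindex[tip]]
        omega[bindex[tip]] = len(path) * tgt[tip] - omega[inner].sum()
    omega = np.clip(omega, *OMEGA_CLIP)

    nb = len(branches)
    dS = rng.lognormal(mean=np.log(cfg.dS_log_median),
                       sigma=cfg.dS_log_sigma, size=nb)
    sub = rng.random(nb) < cfg.subthreshold_fraction
    dS[sub] = rng.uniform(1e-6, cfg.rate_threshold * 0.5, size=sub.sum())
    dN = omega * dS

    rows = pd.DataFrame({"gene": gene, "branch": branches,
                         "dN": dN, "dS": dS, "omega": omega})

    valid = np.array([branch_is_valid(a, b, cfg.rate_threshold)
                      for a, b in zip(dN, dS)])
    bindex = {b: j for j, b in enumerate(branches)}
    truth_rows = []
    for tip in tips:
        path = [bindex[b] for b in tree.ancestors(tip)[1:]]
        ok = [j for j in path if valid[j]]
        if ok:
            bar = float(np.mean(omega[ok]))
            truth_rows.append((gene, tip, bar, np.log10(bar), len(ok)))
        else:
            truth_rows.append((gene, tip, np.nan, np.nan, 0))
    truth = pd.DataFrame(truth_rows, columns=[
        "gene", "species", "omega_bar", "log10_omega_bar", "n_valid_branches"])
    return rows, truth


def simulate_alignment(species: list[str], length: int, focal: list[str],
                       planted: list[tuple[int, str, str]],
                       gap_columns: list[int], rng: np.random.Generator,
                       gene: str = "gene", mutation_rate: float = 0.02,
                       ) -> tuple[ProteinAlignment, pd.DataFrame]:
    """Random protein alignment with planted group-fixed columns.

    ``planted`` holds (1-based column, focal residue, background residue)
    triples; every focal row gets the focal residue and every other row the
    background residue at those columns.  ``gap_columns`` each receive a gap
    in one random non-focal row.  Away from planted columns rows are the
    consensus sequence with independent random substitutions at
    ``mutation_rate``, so chance fixed-looking columns are possible (and
    counted by false-positive studies) but rare.
    """
    cols = [c for c, _, _ in planted]
    if len(set(cols)) != len(cols):
        raise SimulationError("planted columns must be distinct")
    overlap = set(cols) & set(gap_columns)
    if overlap:
        raise SimulationError(f"planted columns also listed as gap columns: {sorted(overlap)}")
    for c in cols + list(gap_columns):
        if not 1 <= c <= length:
            raise SimulationError(f"column {c} outside 1..{length}")
    bad = [s for s in focal if s not in species]
    if bad:
        raise SimulationError(f"focal species not in species list: {bad}")

    aas = np.array(list(AA20))
    consensus = rng.choice(aas, size=length)
    rows: dict[str, np.ndarray] = {}
    for sp in species:
        seq = consensus.copy()
        mut = rng.random(length) < mutation_rate
        for j in np.flatnonzero(mut):
            choices = [a for a in AA20 if a != seq[j]]
            seq[j] = choices[rng.integers(len(choices))]
        rows[sp] = seq
    focal_set = set(focal)
    for col, fres, bres in planted:
        for sp in species:
            rows[sp][col - 1] = fres if sp in focal_set else bres
    non_focal = [s for s in species if s not in focal_set] or list(species)
    for col in gap_columns:
        victim = non_focal[rng.integers(len(non_focal))]
        rows[victim][col - 1] = "-"

    aln = ProteinAlignment(gene=gene,
                           rows={sp: "".join(seq) for sp, seq in rows.items()})
    registry = pd.DataFrame(
        [(gene, c, f, b) for c, f, b in planted],
        columns=["gene", "column", "focal_residue", "background_residue"])
    return aln, registry


def simulate_lrt_records(n_null: int, n_alt: int, noncentrality: float,
                         rng: np.random.Generator,
                         group: str = "small") -> pd.DataFrame:
    """Branch-model likelihood records: null genes with central χ²₁
    statistics and foreground ω ≈ background ω; alternative genes with
    noncentral χ²₁ statistics and elevated foreground ω."""
    if n_null < 0 or n_alt < 0:
        raise SimulationError("record counts must be non-negative")
    if noncentrality < 0:
        raise SimulationError("noncentrality must be non-negative")
    recs = []
    for i in range(n_null):
        stat = rng.chisquare(1)
        lnL0 = -5000.0 + 100.0 * rng.standard_normal()
        obg = rng.lognormal(np.log(0.15), 0.4)
        ofg = obg * np.exp(0.05 * rng.standard_normal())
        recs.append((f"null{i + 1:04d}", group, lnL0, lnL0 + stat / 2.0,
                     ofg, obg, False))
    for i in range(n_alt):
        stat = rng.noncentral_chisquare(1, noncentrality) if noncentrality > 0 \
            else rng.chisquare(1)
        lnL0 = -5000.0 + 100.0 * rng.standard_normal()
        obg = rng.lognormal(np.log(0.1), 0.4)
        ofg = obg * rng.uniform(2.0, 8.0)
        recs.append((f"alt{i + 1:04d}", group, lnL0, lnL0 + stat / 2.0,
                     ofg, obg, True))
    return pd.DataFrame(recs, columns=["gene", "group", "lnL0", "lnL1",
                                       "omega_fg", "omega_bg", "is_alt_truth"])


def _pick_focal(phenotypes: pd.DataFrame) -> list[str]:
    """Extremely small species for the alignment plant; falls back to the two
    lightest species when the Brownian draw produced fewer than two."""
    groups = assign_size_groups(phenotypes)
    focal = list(groups.loc[groups["is_extremely_small"], "species"])
    if len(focal) < 2:
        focal = list(phenotypes.sort_values("body_mass_g")["species"].head(2))
    return focal


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic study described by ``cfg``: tree,
    phenotypes, per-gene branch tables with ground truth, alignments with a
    planted-site registry, and branch-model likelihood records."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    if cfg.tree_source == "fixed":
        if not cfg.newick:
            raise SimulationError("tree_source='fixed' requires a newick string")
        tree = parse_newick(cfg.newick)
    elif cfg.tree_source == "yule":
        tree = simulate_tree(cfg.n_species, seed=int(rng.integers(2 ** 31)))
    else:
        raise SimulationError(f"unknown tree_source {cfg.tree_source!r}")
    phenotypes = simulate_phenotypes(tree, cfg, rng)

    gene_rows, truth_rtt_rows, params = [], [], []
    for i in range(cfg.n_effect_genes + cfg.n_null_genes):
        is_effect = i < cfg.n_effect_genes
        gene = f"gene{i + 1:04d}"
        beta = cfg.effect_beta if is_effect else 0.0
        rows, truth = simulate_gene_rates(tree, phenotypes, gene, beta,
                                          cfg.gene_lambda, cfg.gene_sigma,
                                          cfg, rng)
        gene_rows.append(rows)
        truth_rtt_rows.append(truth)
        params.append((gene, beta, cfg.gene_lambda, cfg.gene_sigma, is_effect))
    rates = BranchRatesTable(pd.concat(gene_rows, ignore_index=True)
                             if gene_rows else pd.DataFrame(
                                 columns=["gene", "branch", "dN", "dS", "omega"]))
    truth_params = pd.DataFrame(params, columns=["gene", "beta", "lambda_g",
                                                 "sigma_g", "is_effect"])
    truth_rtt = (pd.concat(truth_rtt_rows, ignore_index=True)
                 if truth_rtt_rows else pd.DataFrame())

    focal = _pick_focal(phenotypes)
    alignments, registries = [], []
    species = tree.tips
    for i in range(cfg.n_alignments):
        gene = f"aln{i + 1:04d}"
        positions = rng.choice(
            np.arange(1, cfg.alignment_length + 1),
            size=cfg.planted_sites_per_gene + cfg.gap_columns_per_gene,
            replace=False)
        planted_cols = positions[:cfg.planted_sites_per_gene]
        gaps = list(positions[cfg.planted_sites_per_gene:])
        planted = []
        for col in planted_cols:
            f, b = rng.choice(np.array(list(AA20)), size=2, replace=False)
            planted.append((int(col), str(f), str(b)))
        aln, reg = simulate_alignment(species, cfg.alignment_length, focal,
                                      planted, [int(g) for g in gaps], rng,
                                      gene=gene,
                                      mutation_rate=cfg.alignment_mutation_rate)
        alignments.append(aln)
        registries.append(reg)
    planted_sites = (pd.concat(registries, ignore_index=True) if registries
                     else pd.DataFrame(columns=["gene", "column",
                                                "focal_residue",
                                                "background_residue"]))

    lrt_records = simulate_lrt_records(cfg.n_null_records, cfg.n_alt_records,
                                       cfg.lrt_noncentrality, rng)
    return SimulatedDataset(config=cfg, tree=tree, newick=tree.to_newick(),
                            phenotypes=phenotypes, rates=rates,
                            truth_params=truth_params, truth_rtt=truth_rtt,
                            alignments=alignments, planted_sites=planted_sites,
                            focal_species=focal, lrt_records=lrt_records)


def config_to_dict(cfg: SimulationConfig) -> dict:
    return asdict(cfg)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset in exactly the formats the pipeline reads: Newick,
    phenotype TSV, rates TSV, aligned FASTA, LRT TSV, plus truth TSVs and a
    YAML manifest echoing the configuration and seed."""
    import os

    import yaml

    from .fixed_changes import write_alignment_fasta
    from .rates import write_rates_tsv

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(ds.newick + "\n")
    kw = dict(sep="\t", index=False, na_rep="NA", lineterminator="\n",
              float_format="%.10g")
    ds.phenotypes.to_csv(os.path.join(outdir, "phenotypes.tsv"), **kw)
    write_rates_tsv(ds.rates, os.path.join(outdir, "rates.tsv"))
    ds.truth_params.to_csv(os.path.join(outdir, "truth_params.tsv"), **kw)
    ds.truth_rtt.to_csv(os.path.join(outdir, "truth_root_to_tip.tsv"), **kw)
    if ds.lrt_records is not None:
        ds.lrt_records.to_csv(os.path.join(outdir, "lrt_records.tsv"), **kw)
    alndir = os.path.join(outdir, "alignments")
    os.makedirs(alndir, exist_ok=True)
    for aln in ds.alignments:
        write_alignment_fasta(aln, os.path.join(alndir, f"{aln.gene}.fasta"))
    if ds.planted_sites is not None:
        ds.planted_sites.to_csv(os.path.join(outdir, "planted_sites.tsv"), **kw)
    manifest = {"config": config_to_dict(ds.config),
                "focal_species": list(ds.focal_species),
                "n_genes": len(ds.truth_params)}
    with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
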