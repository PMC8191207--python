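# Methods

`phylorates` implements a comparative-genomics pipeline that asks, for every
gene in a clade, whether its long-term protein evolutionary rate tracks a
continuous phenotype — here body size in carnivores — while respecting the
non-independence of species that share evolutionary history. This note
documents the statistical model, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the numerical
choices and known limitations.

## The rate statistic: root-to-tip ω

For one gene, the input is a per-branch table of non-synonymous (dN) and
synonymous (dS) divergence and their ratio ω = dN/dS, as produced by a
free-ratio codon model (the package never fits codon models; those tables
are its input surrogate). The species-level statistic is the **unweighted
arithmetic mean of ω over the branches on the path from the root to that
species' tip**. Because ω is a ratio of two small estimated quantities, a
branch with dN < t or dS < t (default t = 0.0002 substitutions/site) is
marked invalid and excluded from the average — a near-zero denominator or
numerator would otherwise make a single branch dominate the path mean. If
every path branch is invalid the species gets `NA` and is dropped from that
gene's regression. Root-to-tip means are log10-transformed before
regression to improve normality; an alternative sum(dN)/sum(dS) path
aggregation is exposed via `method="ratio_of_sums"` for sensitivity
analysis but is not used by default, since the plain mean is the
conventional definition of the statistic.

## PGLS with maximum-likelihood Pagel's λ

The association model per gene × phenotype is

    y = β₀ + β₁·x + ε,   ε ~ N(0, σ² V(λ)),

with y the log10 root-to-tip ω, x the log10 phenotype (head-body length in
cm or body mass in g; base-10 chosen for consistency with the rate
transform), and V(λ) the Brownian-motion variance–covariance matrix of the
ultrametric tree with off-diagonal entries multiplied by Pagel's λ ∈ [0, 1].
C_ij is the depth of the most recent common ancestor of species i and j.
λ = 1 is pure Brownian covariance; λ = 0 recovers ordinary least squares.

Estimation: GLS through a Cholesky factorization of V; σ̂² for the slope
standard error uses the unbiased n−2 divisor and the slope is tested with a
two-sided t on n−2 degrees of freedom. λ is profiled out by maximizing the
Gaussian likelihood (ML, not REML): a coarse grid with step 0.05 over
[0, 1] followed by bounded scalar refinement (absolute tolerance 1e-6)
around the best grid point, keeping the refined value only if it does not
fall below the grid optimum — the profile likelihood is often flat or
bimodal near the boundaries, and the grid-first strategy makes the result
deterministic and reorder-invariant. λ is re-estimated on every refit and
the covariance is rebuilt on exactly the species used (complete cases
only; a gene needs at least 10 species with defined values, configurable).

**Finite-sample caveat.** With λ *fixed* at its generating value the t-test
p-values are exactly uniform under the null (verified by simulation). With
λ *estimated per gene* at n = 20 the test is mildly anti-conservative
(null rejection rates of roughly 7–15% at α = 0.05 depending on the tree
shape), because λ̂ is noisy and boundary-biased and its uncertainty is not
propagated into the t distribution. This is a known property of PGLS at
small n, and it is precisely why the scan's decisions rest on the two-step
calibration below rather than on a single p-value; the calibrated
procedure's empirical type-I rate is at or below the nominal 5% in the
package's own 500-null-gene check.

## Two-step calibration and the BSAG call

For each gene × phenotype the scan reports three P values:

- **p_all** — the PGLS p on all complete-case species;
- **p_robust** — after removing the single species with the largest
  absolute raw residual of the full fit;
- **p_max** — the maximum p over leave-one-out refits.

Defaults decided where the design was genuinely open: the
largest-residual species is chosen on the **raw response scale** (the
plainest reading; a whitened-residual option is exposed via
`residual_scale="whitened"`), and the leave-one-out refits drop each
species **from the full set** (`mode="drop-from-full"`, so the list has n
entries and includes the robust refit itself); the alternative reading —
dropping each species from the already-robust n−1 set — ships as
`mode="drop-from-robust"`. Every refit rebuilds the covariance and
re-estimates λ. A gene whose refits would fall below the minimum species
count is flagged incomplete and excluded rather than partially calibrated.

A gene is a **body-size-associated gene (BSAG)** when all three P values
are below α = 0.05 for *both* phenotypes (six thresholds). Direction
(positive/negative) is the sign of the body-mass slope; if the two
phenotype slopes disagree the record is flagged `sign_concordant=False`
rather than dropped, so discordance is visible downstream.

## REG calling from branch-model likelihoods

Rapidly-evolving-gene calls consume per-gene log-likelihood pairs of a
one-ratio model (lnL0, single ω) and a two-ratio model (lnL1, separate
foreground/background ω). The statistic 2(lnL1 − lnL0) is referred to
χ²_df with df = k1 − k0 (default 1); negative statistics within 1e-6 are
clamped to zero, larger violations raise (nesting failure upstream). A REG
requires foreground ω > background ω **and** raw p < 0.05; `is_reg_fdr`
additionally requires the Benjamini–Hochberg adjusted p (computed within
each foreground group separately, since the groups are reported as separate
lists) to pass. Body-size groups from the phenotype table: extremely large
(mass > 350 kg), small (mass < 12 kg AND head-body length < 1 m),
extremely small (mass < 1 kg, a subset of small), background otherwise.

## Fixed amino-acid changes

A column of a protein alignment is a fixed change for a focal group when
all focal species share one residue, no scanned background species carries
it, and the column is free of gaps and ambiguity codes ('X' is treated
like a gap: ambiguity cannot certify fixation). Strict mode (default)
additionally requires a uniform background residue — the pattern of every
reported example site — while relaxed mode accepts a heterogeneous
background. Rows outside the focal and background sets (outgroup,
reference) are ignored. Alignment columns are 1-based; positions can be
mapped onto an ungapped reference row (e.g. human) by counting non-gap
reference characters, yielding labels like "S513L"; sites at reference
gaps keep their alignment coordinate unlabeled. Protein-domain intervals
are *inputs* (1-based inclusive, reference coordinates); the package does
not run domain scans.

## The synthetic-data generator

The generator produces complete, seed-reproducible studies with the
statistical structure the analysis assumes, plus ground truth for recovery
tests. Defaults describe a 20-species clade emulating the carnivore study:

- **Tree**: Yule (pure-birth) topology, rescaled to height 1. dendropy's
  simulator stops at the nth speciation, so one extra Exp(nλ) waiting time
  is appended to all tip edges before rescaling (otherwise the two newest
  tips have zero-length branches).
- **Phenotypes**: log10 body mass is Brownian with root 4.0 (10 kg) and
  unit variance over the unit-height tree — tip masses span roughly 100 g
  to 1000 kg, the carnivore range, so the body-size groups are populated.
  log10 head-body length = 0.47 + 0.33·log10 mass + independent Brownian
  noise (variance 0.01): the cube-root allometry with a cat-sized anchor.
- **Gene rates**: tip-level targets u = α + β·log10(mass) + ε with
  ε ~ N(0, σ_g²·C(λ_g)); defaults β = 0.4 for effect genes (0 for nulls),
  λ_g = 0.9, σ_g = 0.3, α set so ω ≈ 0.14 at the root mass. Branch ω is
  realized constructively: internal branches receive a jittered baseline
  just below the smallest tip target and each terminal branch absorbs its
  tip's remaining signal. Because a terminal branch lies on exactly one
  root-to-tip path, the tip path-means equal the targets exactly and all
  branch ω are positive by construction (a minimum-norm least-squares
  realization was tried first and rejected: on 20-tip trees it drives a
  quarter to a third of branch ω negative, and clipping then attenuates
  the planted slope far beyond the recovery tolerance). ω is finally
  clipped to [1e-4, 10] and the **achieved** tip means — recomputed from
  the emitted table after clipping and after sub-threshold invalidation —
  are stored as ground truth, so recovery tests are judged against what
  the data actually contain. dS is log-normal (median 0.05, a plausible
  per-branch synonymous divergence; only relative structure matters), a
  configured fraction (default 5%) forced below the validity threshold,
  and dN = ω·dS.
- **Alignments**: random consensus protein with per-row substitutions at
  rate 0.02, planted group-fixed columns, and gap columns placed in one
  random non-focal row. The focal set is the extremely small group of the
  simulated phenotypes, falling back to the two lightest species when the
  Brownian draw produced fewer than two.
- **LRT records**: null statistics drawn central χ²₁ with ω_fg ≈ ω_bg;
  alternatives noncentral χ²₁ (default noncentrality 10) with elevated
  foreground ω.

What the generator does **not** emulate: codon-level sequence evolution
(dN/dS tables are drawn, not estimated, so estimator noise and
branch-length-dependent sampling error in real codeml output are absent);
correlated rate variation between genes; phenotype measurement error;
missing data patterns of real orthology tables. Passing recovery tests
therefore demonstrates the correctness of the inference machinery under
its own model assumptions, not robustness to codon-model misspecification.

## Numerical choices and degenerate inputs

- Non-positive-definite covariance, constant predictors, and fewer than
  three observations raise typed errors; non-ultrametric trees warn but do
  not abort (real chronogram exports carry rounding error; GLS remains
  defined). Ultrametricity tolerance: 1e-6 relative.
- Branch identity is the child-node label; unlabeled internal nodes get
  deterministic post-order labels `N<k>`, so rate tables join trees
  reproducibly. Polytomies are allowed.
- TSV outputs use a literal `NA`, UTF-8, LF endings, `%.10g` floats — a
  bit-exact output contract (same seed ⇒ identical files).
- Problem sizes in the validation suite (20-tip trees; 500 reps for λ
  recovery; 200 genes for slope recovery; 500 null genes for type-I; 2,000
  LRT draws; 1,000 FDR vectors; 100 alignment instances) were chosen as
  the smallest sizes at which the Monte-Carlo error of each check is well
  below its decision margin.

## Known limitations

- Only Pagel's λ is offered as a covariance transform (no OU/κ/δ), only
  one predictor per fit, and no measurement-error model.
- The per-gene ML-λ t-test anti-conservatism discussed above means raw
  `p_all` values should not be used alone for discovery at small n; use
  the calibrated triple.
- `p_max` depends on the chosen leave-one-out mode when the largest
  residual is ambiguous; both readings are shipped and the default
  documented.
- The fixed-change scanner certifies patterns in the supplied rows only;
  it cannot detect alignment error or paralogy.
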