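# Methods

This note documents the models, the numerical choices and what the
synthetic studies do and do not establish.

## Proteomics preprocessing

Protein groups are kept when they have at least `min_peptides` (default 2)
unique peptides **and** nonzero intensity in at least
`ceil(min_detect_frac · n_samples)` samples (default 75%).  The filter is
applied before imputation, so "detected" means observed, not inferred.

The normalization chain is arcsinh → imputation → per-sample median
scaling → conversion to log2 units.  Two choices deserve explanation:

- **log2 units, not a second logarithm.**  For MS-scale intensities
  arcsinh x ≈ ln 2x, so arcsinh output is already logarithmic; composing a
  further log2 would double-log the data and shrink a 2-fold abundance
  change to a few hundredths of a unit, detaching the conventional
  |Δ| > 1.5 selection threshold from any meaningful fold change.  The
  final step therefore divides by ln 2, expressing the arcsinh values in
  log2 units: a protein that doubles moves by ≈ 1.0, and deltas read as
  log2 fold changes.
- **Imputation.**  Missing values (zeros) are imputed on the arcsinh scale
  with scikit-learn's iterative imputer driven by a random-forest
  regressor (10 trees, ≤ 10 iterations, fixed seed) — a replicable
  analogue of iterative random-forest imputation; matrices too small to
  support it (< 30 proteins or < 4 samples) fall back to k-NN (k = 10).
  An all-zero protein row is an error: nothing constrains its imputation.

Median scaling multiplies each sample so its median equals the grand
median of sample medians (the target the procedure leaves unstated is
fixed this way for determinism); afterwards sample medians agree to 1e-9.
Deltas average replicate columns within each (cell line, condition) before
subtracting control from treated; differential proteins use a strict
|Δ| > threshold.

## Functional network

The graphical model over proteins is the maximum-weight spanning forest on
|Pearson ρ| computed across all normalized columns — the exact maximum-
likelihood decomposable model of treewidth 1 (Chow–Liu), deterministic
with ties broken by lexicographic edge id.  Branches are produced by
deleting the `n_branches − 1` lightest forest edges.  The branch count is
a configuration parameter; at genome scale a granularity of roughly one
branch per 115 proteins mirrors common practice, but at toy scale
(~120 proteins) that default collapses to 2 branches, so the demo and the
recovery study set 10 explicitly (~1 branch per module of 12).

Branch labels come from one-sided hypergeometric over-representation
against the background of all network proteins: the smallest-p term wins
when raw p < α (default 0.05); Benjamini–Hochberg q-values over all
branch × term tests are reported alongside.  Node activity is the mean
delta of the branch proteins annotated with the branch's label — not of
all branch members — so a mislabeled hanger-on cannot dilute the signal.

Response models use exhaustive best-subset OLS up to `max_terms`
predictors ranked by adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1);
rank-deficient subsets are skipped with a warning.  With few observations
best-subset selection inflates R²; the orthogonal-response check in the
test suite bounds that inflation (|adj R²| < 0.15 at n = 50, 5 candidate
features, k ≤ 2).

## GPR scoring and E-flux

GPR rules are parsed with AND binding tighter than OR; evaluation is
arithmetic: OR sums its defined operands (isozymes add capacity), AND
takes the minimum (a complex is limited by its scarcest subunit).  An
unmeasured gene is dropped from its operator rather than scored 0 — under
partial proteome coverage, zeroing would block every complex touching an
unmeasured subunit and leave almost no feasible flux.  A rule with no
measured gene yields no score and the reaction keeps its original bounds.
Scores are computed from linear-scale intensities (summing log-scale
values would corrupt the OR semantics), min–max rescaled to [0, 1] within
one sample across all scored reactions (the Uniform(min, max) CDF), and
applied as bounds: [0, a′] for irreversible, [−a′, a′] for reversible
reactions.  If every raw score is equal there is no dynamic range; all
bounds open to 1 with a warning.  Exchange reactions are never E-flux
scaled; only the dynamic-FBA glucose bound moves.

## LP engine

All solves use scipy's HiGHS interface with primal feasibility 1e-9 and
dual tolerance 1e-7, so runs are deterministic.  FVA fixes biomass at
`fraction · μ*` with a 1e-9 slack — tight enough that ranges agree with
exhaustive vertex enumeration to well below 1e-6 on toy fixtures.  The
maximum-total-flux solution splits v = v⁺ − v⁻ (v± ≥ 0, capped by the
bounds) and maximizes Σ(v⁺ + v⁻) with biomass pinned at μ*; on networks
with open (infinite) bounds Σ|v| can be unbounded, so caps come from the
finite model bounds and a warning is emitted otherwise.  The Monte-Carlo
sampler draws directions uniformly on the unit sphere (seeded) and
maximizes each over the optimal face — every sample is an exact LP vertex
and an extreme alternate optimum, which is what flux-change screening
wants to stress; it is not a uniform sampler of the face's interior.

## Dynamic FBA

Quasi-steady state: metabolism equilibrates faster than biomass X (cell
counts) and medium glucose G (mM) change.  Per step of `dt` (default 1 h
over 72 h): the uptake bound is min(vmax_glc, G/(X·dt·yield_scale)), a
static FBA gives μ and the uptake flux, X multiplies by e^{μ dt}, and G
decreases by flux × the *integrated* biomass v·X·(e^{μ dt} − 1)/μ ×
yield_scale, clamped at the glucose remaining.  Integrating biomass
exactly over the step (rather than using X·dt) removes the ~μ·dt/2
per-step consumption bias of a plain Euler update and makes the curve
insensitive to halving dt (< 1% on all toy regimes tested).  Growth stops
when μ < 1e-9 (glucose exhausted); no death phase is modeled.
`yield_scale` converts flux·cells·h to mM; the packaged defaults carry the
experimental seeding densities (MCF7 37, T47D 31, MDAMB231 30,
MDAMB468 58 cells in the counted area) and the 200 mg/dl = 11.1 mM medium
glucose used by the growth validation driver.

## Flux activities and change detection

A pathway's flux activity is Σ|v| over its reactions (absolute values, so
a reversible cycle cannot cancel itself; reactions without a subsystem
pool under "unassigned").  A reaction is treatment-responsive when
|v_treated − v_control| exceeds `frac` (default 0.95) of the **union** of
the two conditions' FVA ranges — the union is used because neither
condition's range is privileged; zero-width ranges are excluded to avoid
0/0.  Monte-Carlo support is the fraction of sampled solution pairs
(index-paired when counts match, Cartesian otherwise) whose change also
exceeds the criterion; zero-support flags are reported, never dropped.
With tiny score sets (a handful of scored reactions), min–max
normalization pins the weakest reaction to 0 and noise alone can flag
reactions — the controlled bottleneck study, where ground truth is known,
is the calibrated check.

## Median-effect dose–response

fa/(1 − fa) = (D/Dm)^m is linear in log–log space; (m, Dm) come from
least squares on log(fa/(1−fa)) vs log D.  Points with viability ≥ 100%
(growth stimulation) or ≤ 0% (complete kill) have undefined log-odds and
are excluded and counted rather than clipped; at least 2 usable points are
required.  Fits are invariant to dose-unit rescaling (Dm rescales, m does
not).  A two-stage grid search over (m, Dm) minimizing the same
log-odds SSE serves as an independent check and agrees within 1% on the
printed viability rows.

## Synthetic data: what it emulates, what it does not

Toy metabolic models chain an uptake exchange (the only bottleneck, so the
FBA optimum equals the uptake bound), a linear pathway, a block of
parallel degenerate routes (alternate optima for FVA/Monte-Carlo) and a
biomass sink; internal reactions draw GPR rules from a fixed grammar
(single gene / AND pair / OR pair) over fresh genes, and blocks carry
subsystem labels.  Fluxes are dimensionless and the biomass coefficient
is 1.

Synthetic proteomes draw base log2 intensities from N(20, 2) (MS-like
dynamic range).  Annotated terms behave as co-regulated modules: a
cell-line-level latent factor (sd 1.0 log2) shared by all columns of a
line — which cancels exactly in treated − control deltas — plus a small
per-column jitter (sd 0.3).  This modular background matters: with i.i.d.
background proteins, weakest-edge cutting of the spanning forest peels
singletons off one giant branch and no planted module can be isolated;
real proteomes are modular, and so is the generator.  Condition effects
are added on the log2 scale to the proteins of affected terms;
measurement noise is N(0, 0.25) per (protein, line, condition) with
N(0, 0.1) replicate noise; duplicates mirror paired perturbation
experiments; missingness injects zeros uniformly; unique-peptide counts
are ≥ 1 with a controllable fraction below 2.

The analytic standard error used by the recovery study follows from this
design: var(activity) = [2σ_jit²/reps + 2(σ_bio² + σ_rep²/reps)/m] / L
for m averaged module proteins and L (cell line, drug) pairs.  The
recovery study (120 proteins in ten 12-protein modules, 6 lines,
duplicates, −1.0 planted on one module, 10 branches, α = 0.05) labels the
planted module in 100/100 seeded runs and recovers the effect within 3 SE
in 98/100 — the residual misses come from per-sample median scaling,
whose small shared bias the SE deliberately excludes.

What passing does **not** show: the generator has no peptide-level
structure, no intensity-dependent missingness, no batch effects, no
overlapping annotation terms, and the toy models have none of the
thousands of coupled reactions, isozyme redundancy or exchange repertoire
of a genome-scale reconstruction.  Results on synthetic data validate the
machinery, not biological conclusions.

## Problem sizes

Defaults keep every study small enough for interactive runs: toy models
≤ 12 reactions (exhaustive vertex enumeration stays cheap), 120-protein
proteomes, 100-sample Monte-Carlo, 100-run recovery studies, 72 × 1 h
dynamic-FBA steps.  All are configuration parameters.

## Known limitations

- The maximum-Σ|v| LP can place futile flux on reversible pairs when caps
  allow it; on irreversible toy networks it is exactly the maximum-total-
  flux vertex.
- Min–max score normalization is sensitive to outliers in the score
  distribution (the maximum defines the scale) and, with very few scored
  reactions, to noise at the minimum.
- Best-subset regression with n of order 6 observations is descriptive,
  not inferential; no p-values are reported for selected subsets.
- The Monte-Carlo sampler characterizes extreme alternate optima, not the
  volume of the optimal face.
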