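# Methods

## Scope

`provsel` implements the analysis chain used for multi-site provenance
trials: per-site and across-site linear mixed models fitted by REML,
likelihood-ratio tests for random terms, variance-component proportions,
sequential fixed-effect mean squares, BLUP-based provenance means, the
genotype–ideotype distance index (MGIDI) within sites, and the
WAASB/WAASBY/MTSI stability indices across sites. A synthetic-trial
generator reproduces the design of a mature three-site Douglas fir trial so
the whole chain can be exercised and validated without field data.

## Mixed models and REML

Within a site, for one trait,

    Y_jkl = mu + B_k + P_j + (PxB)_jk + e_jkl,

with blocks fixed and P_j ~ N(0, V_p), (PxB)_jk ~ N(0, V_pb),
e ~ N(0, V_r) independent Gaussians. Across sites,

    Y_ijkl = mu + S_i + B_k(i) + P_j + (SxP)_ij + e_ijkl,

with site and block-within-site fixed and the provenance and interaction
terms random. Gaussianity of all random terms is assumed throughout; it is
also what the generator draws.

Estimation profiles the restricted likelihood over the variance ratios
gamma_m = sigma_m^2 / sigma_e^2. With Z the stacked random-effect indicator
matrix, V = sigma_e^2 (I + Z Gamma Z'), and the Woodbury identity reduces
log|V|, X'V^-1X, and y'Py to dense q×q operations on the cross-products
Z'Z, Z'X, Z'y (q = total random-effect levels; a few hundred to a couple of
thousand here). sigma_e^2 has a closed-form profile solution. The ratios are
optimised by L-BFGS-B under box constraints [0, 1e8], relative tolerance
1e-8 on the restricted log-likelihood, at most 500 iterations, from two
starting points (0.1 and 1.0); an estimate on the lower box boundary is
reported as a zero component, not dropped. BLUPs are the conditional means
u = Gamma Z' H^-1 (y - X beta). Missing trait values are removed listwise
per trait.

The likelihood-ratio test for a random term compares REML log-likelihoods of
nested models with identical fixed effects; the statistic max(0, 2*delta) is
referred to a chi-square with 1 df. This is the convention of the standard
mixed-model testing tools for these trials; it is conservative relative to
the 50:50 boundary mixture, which is a known property, not a defect.

Variance proportions within a site are V_p/(V_p+V_r) and V_r/(V_p+V_r): the
provenance-by-block component is excluded from the denominator because that
is the convention under which published per-site shares for this kind of
trial are arithmetically consistent with their printed V_p and V_r columns.
Across sites the denominator is V_p + V_ge + V_r.

Fixed-term mean squares are sequential (type I) sums of squares on the
observations, F-tested against the REML residual variance with denominator
df = n − rank(X). Significance is rendered as "*" (p ≤ 0.05), "**"
(p ≤ 0.01), "***" (p ≤ 0.001), "ns" otherwise.

The across-site analysis set defaults to the provenances present at every
site (38 in the default design): interaction BLUPs for provenance–site pairs
never observed are pure shrinkage artifacts (exactly 0), which would
spuriously flag partially tested provenances as maximally stable. An
all-provenance mode is available; absent pairs keep the BLUP 0.

## Selection indices

MGIDI operates on a genotype × trait matrix of predicted means (average
fixed-effect value plus provenance BLUP; raw means can be supplied
instead). Traits are rescaled linearly to 0–100 with 100 in the desirable
direction (all three default traits are higher-is-better: larger diameter
and height mean growth, a higher pruned height means fewer knots). The
correlation matrix of the rescaled traits is eigendecomposed; factors with
eigenvalue ≥ 1 are retained (at least one); loadings are eigenvectors scaled
by sqrt(eigenvalue), varimax-rotated (Kaiser-normalised, tolerance 1e-5,
max 1000 sweeps), each column sign-flipped so its largest-magnitude entry is
positive. Factor scores use the regression method, Z R^-1 L, and the
ideotype (100 on every trait) passes through the identical standardisation
and scoring transform, so a genotype that attains every per-trait maximum
has distance exactly zero. A singular correlation matrix is
ridge-regularised (1e-8 on the diagonal) with a warning. With a single trait
the pipeline degenerates gracefully (R = [[1]], one factor, index ∝
rescaled deviation), so single-trait rankings equal trait rankings.

The selected-set size is round-half-even(n · intensity/100) with a minimum
of 1, computed in exact rational arithmetic so float representation of the
intensity cannot flip a half-way case. This rounding reproduces the
selected-set sizes 55→8, 49→7, 48→7 at 15% and 38→8 at 20%. Ties at the
selection boundary are all included and a warning notes the realised
intensity.

WAASB uses all p = min(g−1, e−1) axes of the SVD of the interaction-BLUP
matrix — the index is defined as a weighted average over the axes, so
truncation would change it. The axis weights EP_k are normalised over the
used axes (they sum to 1). An all-zero matrix yields WAASB 0 for every
genotype. WAASBY weights default to 50:50 performance:stability and are
configurable. If performance or WAASB is constant across genotypes, that
component is set to 100 for everyone (all equally optimal) with a warning;
both constant at once is an error. The MTSI reuses the MGIDI pipeline
verbatim on the genotype × trait WAASBY matrix (WAASBY is always
higher-is-better).

Selection differentials are reported per trait and site as
100·(selected mean − overall mean)/overall mean, rounded to one decimal,
with both means taken over provenance means (each provenance weighted
equally), the convention consistent with how site means accompany published
differential tables for these trials.

## The synthetic generator

`simulate_met` draws, per trait,

    Y = mu + S_i + B_k(i) + P_j + (SxP)_ij + (PxB)_jk(i) + e,

storing the drawn P_j and (SxP)_ij as a truth block for recovery checks. A
single master seed spawns deterministic substreams per stage, so output is
bit-reproducible and a provenance shared by several sites reuses the same
P_j draw everywhere — the property that identifies the across-site model.
Blocks are fixed, user-supplied offsets by default (matching how the
analysis treats them); a random draw is available for stress tests. V_pb
defaults to 0 in multi-site scenarios because the across-site model does
not carry the term.

Default parameters emulate the 47-year three-site trial: grand means 33.03
cm (DBH), 29.50 m (TH), 17.47 m (PH); per-site fixed offsets that reproduce
the observed site means; V_p per trait the average of the per-site REML
components (4.01 / 2.32 / 1.03); V_ge from the across-site fit (3.91 / 1.75
/ 0.92); V_r the average per-site residual (55.94 / 19.90 / 8.71), which
makes the simulated per-site SDs match the reported 7–8 cm and 3–5 m. The
published across-site residual components are not used for generation
because they are inconsistent with the per-site residuals and with the
reported trait SDs; they are retained as simulation truths in the recovery
tests. Block offsets default to small fixed gradients (±1 cm DBH, ±0.5 m
TH, ±0.3 m PH).

Random terms are drawn with a cross-trait correlation (DBH–TH 0.7, DBH–PH
0.4, TH–PH 0.5) applied to every random component. This is a deliberate
design choice: diameter and height growth are strongly correlated in mature
conifers, and the factor-analytic indices presuppose correlated traits —
with independent traits the trait correlation matrix is near-identity, the
Kaiser criterion retains a single noise-contrast factor, and selection
differentials can come out negative, which is not the behaviour of the
trials the generator emulates. Independent traits remain available by
omitting `trait_correlation`.

Mortality is independent Bernoulli survival per tree (default survival 1.0,
since no survival figure is available for the emulated trial; unbalanced
data are exercised in tests). A draw that empties a plot whose provenance
remains in the dataset is redrawn; failing that, the provenance is dropped
from that site and logged.

What the generator does **not** emulate: spatial autocorrelation within
plots, climate-driven site effects, non-Gaussian trait distributions,
age trends, or measurement error structure beyond i.i.d. residuals. Passing
tests therefore demonstrate correctness of the estimators and indices under
the stated model, not robustness to field artefacts outside it.

## Problem sizes and numerical choices

Parameter-recovery tests run at ten times the trial's provenance count (550
provenances for the single-site model, 380 common provenances across three
sites), where the chi-square sampling error of a variance component is
about 6–8% relative — comfortably inside the 15% assertion. The full
default-scenario pipeline (34,200 trees, 9 per-site fits plus reduced
models, 3 across-site fits plus two reduced models each, both indices)
completes in a few seconds.

Degenerate inputs are errors, not silent results: constant traits cannot be
rescaled; a single block, site, or provenance cannot be fitted; duplicate
(site, provenance, block, tree) keys and non-numeric trait cells are
rejected at parse time with the offending row named.

## Known limitations

- REML log-likelihoods are comparable only within this package's constant
  convention; cross-package LRT mixing is not supported.
- The chi-square df-1 reference for variance-component LRTs is conservative
  at the boundary.
- No Satterthwaite/Kenward–Roger denominator degrees of freedom;
  fixed-effect F tests use the residual-df approximation.
- Heteroscedastic per-site residual variances and spatial models are out of
  scope.
- REML estimates are not exactly invariant to duplicating observations
  (per-plot residual df changes); the effect is O(1/plot size).
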