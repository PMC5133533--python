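# Methods

## Annotation model

Every variant is assigned a functional category $s \in \{1,\dots,6\}$:
the major digit of a RegulomeDB-style category string when present
(sub-categories such as `1a`/`2b` collapse to their leading digit, the
only level the weighting uses); otherwise a PolyPhen2 prediction mapped
as probably damaging → 1, possibly damaging → 3, benign → 5; otherwise
category 6. RegulomeDB always wins when both annotations exist, since
the fallback is meant for nonsynonymous variants the regulatory
database does not cover. PolyPhen2 strings are matched
case-insensitively with underscore/space tolerance; confidence scores
are not used — only the categorical call.

The category-to-weight transform is quadratic in the reverse category
order, $f(s) = (7-s)^2$, taking values 36, 25, 16, 9, 4, 1 for
categories 1–6. The quadratic shape deliberately flattens the
low-confidence end: windows containing only category-5/6 variants (the
large majority genome-wide) are near-unweighted, so the data dominate
there, while the rare category-1/2 variants get a large boost. The
kernel tests consume $f(s)$ as the variance-scale weight
$\omega_j^2$; the burden test uses $f(s)$ directly as $\omega_j$ —
the two families' formulas are intentionally asymmetric, matching how
each statistic scales in its weights.

## Windowing

Chromosomes are tiled with windows of `window_length` 4000 bp advancing
by `step` 2000 bp, anchored at coordinate 1 (1-based inclusive ends).
Anchoring at a fixed origin rather than at the first variant makes the
grid deterministic and independent of the variant set. Every interior
position is covered by exactly `window_length/step` = 2 windows; only
windows containing at least one variant are returned, and only windows
retaining at least one rare variant after filtering are tested — the
Bonferroni denominator counts tested windows and is recorded in the run
report, with skipped windows and their reasons in a side table.

## Kinship and the null mixed model

Pedigree kinship uses the standard tabular recursion (founders-first
order): $\phi_{ii} = \tfrac12(1+\phi_{fm})$,
$\phi_{ij} = \tfrac12(\phi_{fj} + \phi_{mj})$. Inbreeding is supported
($\phi_{ii}$ may exceed 1/2). The random-effect covariance is
$2\Phi$, computed on the full pedigree and only then subset to the
analyzed individuals, so relatedness through unphenotyped connectors is
preserved. Phenotyped individuals absent from the pedigree are treated
as unrelated founders with a warning.

The null model `Y = X·gamma + delta + eps` is fitted once by REML.
After a one-time eigendecomposition $2\Phi = U D U'$, the likelihood
depends on the variance ratio $\lambda = \sigma^2_g/\sigma^2_e$ only
through diagonal operations; $\sigma^2_e$ is concentrated out
analytically and $\lambda$ is found by bounded scalar minimisation of
the profiled REML criterion on the log scale
($\log\lambda \in [-20, 12]$, tolerance $10^{-10}$), with the boundary
$\sigma^2_g = 0$ evaluated explicitly and kept when it dominates. The
upper bound caps the ratio at $e^{12}$; profiles that still increase
there correspond to data where the family structure absorbs essentially
all variance (e.g. a phenotype dominated by one family-shared outlier
of many SDs), which the simulator avoids by using realistic effect
sizes. Per-window tests reuse the fit through cross-products computed
in the eigenbasis (`G'PY`, `G'PG`) without materialising the $n \times
n$ projection; the full `P` is available for diagnostics and is
verified against the fast path in the tests.

## Test statistics and their null distributions

All six tests are score tests sharing the null fit. The kernel
statistic is $T = \sum_j \omega_j^2 (G_j' P Y)^2$; the burden statistic
is $(b'PY)^2 / (b'Pb)$ with $b = G\omega$.

Asymptotically $T$ follows the mixture $\sum_k \lambda_k \chi^2_1$ with
$\lambda_k$ the eigenvalues of $W^{1/2} G'PG\, W^{1/2}$, and the burden
statistic follows $\chi^2_1$. Both references plug the REML variance
estimate into $P$ as if known. Because that estimate shares residual
degrees of freedom with the statistic, the plug-in kernel test is
measurably conservative at cohort scale (empirical level ≈ 0.046 at
n = 440 in the null simulation) — the same phenomenon that makes a
z-test with estimated variance conservative relative to the t-test.
The package therefore evaluates the exact finite-sample null of the
variance-scaled ratio: writing the whitened residuals as
$z \sim N(0, I_K)$ with $K = n - p$ residual df, the rejection event
$T > t$ is the event that the signed mixture
$\sum_k (a_k - t/K)\chi^2_1 - (t/K)\chi^2_{K-m}$ is positive, which the
same inversion machinery computes. With a single (or repeated)
eigenvalue this reduces to a Beta$(m/2, (K-m)/2)$ closed form; the
burden case is then exactly the classical regression t/F test. The
exact and asymptotic references agree as $K \to \infty$ (verified
numerically), the empirical level centres on 0.05, and all six methods
coincide exactly on single-variant windows. The ratio construction is
conditional on the estimated variance *ratio* $\hat\lambda$; its
estimation noise is second-order and is covered by the type-I
simulation.

### Quadratic-form tail computation

Mixture tails are computed by characteristic-function inversion
(Imhof's representation) with a vectorised midpoint rule. The
discretisation step is set by Poisson-summation aliasing control (wrap
period beyond the distribution's effective support, tail mass below
$e^{-65}$); the truncation point comes from Imhof's analytic bound at
$10^{-9}$. When few effective degrees of freedom make the integrand
decay too slowly, the distribution is convolved with a small Gaussian
(a convergence-factor device) whose scale is kept at or below
$2\times10^{-3}$ of the distribution SD; the induced error is
$O(\tau^2)$, about $10^{-6}$ in the worst configuration exercised
(validated against an exact conditioning-integral oracle). If the
inversion fails its sanity checks, or the tail is below the inversion
noise floor ($10^{-11}$), the Liu–Tang–Zhang three-moment approximation
is used instead; each result carries a flag (`exact`/`imhof`/`liu`)
recording the path. Eigenvalues below $10^{-10}$ of the largest are
truncated to zero.

## Rarity filter

Within each window, alleles are folded so the counted allele is minor;
missing genotypes are imputed to twice the observed MAF; monomorphic
columns and columns with MAF ≥ 0.05 (strict) are removed. MAFs are
computed from the analyzed sample's non-missing calls. The flat burden
weighting is the MAF < 5% indicator realised as "filter, then unit
weights".

## Synthetic cohorts

The generator emulates a family-based sequencing study with the exact
generative process the tests assume:

* **Pedigrees** — three-generation 11-member families (grandparent
  couple, three children, two married-in spouses, four grandchildren);
  default 40 families (440 individuals), all matings between
  non-relatives.
* **Genotypes** — founder haplotypes Bernoulli(MAF) per site, offspring
  by Mendelian gene-dropping; site MAFs uniform on $(1/2n, 0.05)$;
  sites independent by default, with an optional within-window latent
  Gaussian correlation mode for robustness checks.
* **Categories** — i.i.d. from genome-typical frequencies
  (0.26, 2.71, 2.12, 7.56, 30.76, 56.59% for categories 1–6).
* **Phenotypes** — $Y = 120 + Z\gamma + G\beta + \delta + \varepsilon$
  with $\delta \sim N(0, \sigma^2_g\, 2\Phi)$,
  $\sigma^2_g = \sigma^2_e = 1$, covariates age/sex/smoking/medication
  with effects (0.3, 2.0, 1.5, −2.0) — blood-pressure-flavoured scales.
  Under the null $\beta = 0$.
* **Effect models** — `doubleton` plants a category-1 variant with
  exactly two minor alleles and a chosen per-allele effect in one
  window (a 4-SD effect ≈ 6 units is the "strong but realistic"
  reference point); `category1`/`mixed` put uni- or mixed-direction
  effects on the category-1 variants of the causal window.

What the generator does **not** emulate: linkage disequilibrium beyond
the optional block mode, MAF spectra skewed toward singletons,
non-Gaussian trait noise, ascertainment, genotyping error or
missingness patterns. Passing tests therefore demonstrate correctness
of the statistical machinery under its own assumptions, not robustness
to those real-data features.

## Type-I-error experiment

The calibration experiment crosses 50 null windows (19 variants each)
with 200 phenotype replicates on a cohort of 72 families
(792 individuals — matching the scale of the family study design the
method targets), refitting the null model per replicate and testing
every window with all six methods: 10,000 tests per method, with the
empirical rejection fraction at $\alpha = 0.05$ reported alongside a
99% binomial band. The window × replicate tests share each replicate's
phenotype draw, so the band treats as independent tests that are
mildly clustered; across probe seeds the observed dispersion matched
the binomial standard error. Runtime is about half a minute on one
CPU; `scripts/acceptance.py` runs exactly this experiment.

## Numerical conventions and edge cases

* Coordinates are 1-based inclusive everywhere except the BED export
  (converted at the writer, noted in its header).
* Chromosome names are normalised by stripping a `chr` prefix.
* Multi-allelic VCF records split into one column per alternate allele.
* A window whose variants are all filtered is skipped with a reason,
  not an error; a burden orthogonal to the residual space returns
  p = 1 with a `degenerate` flag; a zero statistic returns p = 1.
* P-values are floored at the smallest positive double rather than
  returned as 0.
* Fixed seeds make the simulator, the experiments and `scan` output
  byte-identical across runs.

## Known limitations

* Quantitative traits only; no binary-trait (logistic) branch.
* Pedigree kinship only; no genotype-based (GRM) relatedness.
* The exact ratio null conditions on the estimated variance ratio; at
  very small cohorts (tens of individuals) the remaining ratio noise is
  untested territory.
* Sliding windows only — no gene- or annotation-defined grouping units.
* The Bonferroni correction over overlapping windows is conservative;
  no effective-number-of-tests adjustment is provided.
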