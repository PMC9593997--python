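# Methods

## Summary-level penalized regression

The expression model is ordinary least squares on the standardized scale,
$Y = Xw + \epsilon$, with $X$ the $N \times p$ column-standardized genotype
matrix of a gene's cis-SNPs. Expanding the residual sum of squares shows
the objective depends on the data only through $r = X'Y/N$ (per-SNP
marginal correlations) and $R = X'X/N$ (LD). The quantity the coordinate
descent solver minimizes is

$$F(w) = \tfrac12\big(w'\tilde R w + \theta\,w'w\big) - w'\tilde r + J_\lambda(w),$$

whose LASSO coordinate update is $S(z_j, \lambda)/(1+\theta)$ with
$z_j = \tilde r_j - \sum_{l \ne j}\tilde R_{jl}\hat w_l$. The module also
exposes `objective()`, the conventional doubled form
$w'\tilde R w - 2 w'\tilde r + \theta w'w + J_\lambda(w)$; note the two
differ by the usual factor-of-two bookkeeping between the quadratic and
the penalty — the per-sweep descent guarantee holds for $F$, which is what
`CdResult.objective_path` records and what the descent tests assert.

### Marginal effects from z-scores

$\tilde r_j = Z_j / \sqrt{N_j - 1 + Z_j^2}$ inverts the t-statistic of a
per-SNP simple regression, so $|\tilde r_j| < 1$ always. Meta-analysed
eQTL resources report per-SNP sample sizes; these are kept per SNP and
never replaced by the cohort maximum, which would bias $\tilde r$ for
SNPs measured in fewer cohorts.

### Penalty families and coordinate updates

All updates are the canonical univariate minimizers with the ridge
$(1+\theta)$ folded into the denominator (write $d_0 = 1+\theta$,
$S$ = soft threshold):

| family | penalty $J_\lambda(w)$ (per coordinate, $t=|w|$) | update |
|---|---|---|
| lasso | $\lambda t$ | $S(z,\lambda)/d_0$ |
| elastic net | $\lambda(\alpha t + \tfrac{1-\alpha}{2}t^2)$ | $S(z,\alpha\lambda)/(d_0 + (1-\alpha)\lambda)$ |
| MCP ($\gamma>1$) | $\lambda t - t^2/2\gamma$ capped at $\gamma\lambda^2/2$ | firm: $S(z,\lambda)/(d_0 - 1/\gamma)$ if $|z| \le \gamma\lambda d_0$, else $z/d_0$ |
| SCAD ($\gamma>2$) | three-piece | $S(z,\lambda)/d_0$; $S(z,\tfrac{\gamma\lambda}{\gamma-1})/(d_0-\tfrac{1}{\gamma-1})$; $z/d_0$ on $|z| \le \lambda(d_0+1)$, $\le \gamma\lambda d_0$, beyond |
| MNet | MCP at $\alpha\lambda$ plus $\tfrac{(1-\alpha)\lambda}{2}t^2$ | firm with denominator $d_0 + (1-\alpha)\lambda$ |

Each reduces to the LASSO update as its extra terms vanish, and each is
verified against its closed form under identity LD.

Defaults: $\gamma_{\mathrm{MCP}} = 3$, $\gamma_{\mathrm{SCAD}} = 3.7$
(the standard literature choices), $\alpha = 0.5$ for elastic net/MNet,
$\theta \in \{0, 0.1, 0.2, 0.4, 0.8\}$, 50 log-spaced $\lambda$ values
from $\lambda_{\max} = \max_j |\tilde r_j|$ down to $0.01\,\lambda_{\max}$
with warm starts along the decreasing path, initialization $w^0 = 0$,
convergence when the largest absolute coordinate change in a sweep falls
below $10^{-5}$ (at most 1,000 sweeps; non-convergence is a warning, not
an error). Dual-route check: with $r$ and $R$ computed in-sample, the
summary-based LASSO/elastic-net solutions match scikit-learn's
individual-level solvers to $<10^{-6}$ across the $\lambda$ path.

### Tuning, admission, Cauchy weights

Per family, the grid point maximizing tuning-cohort $R^2$ (squared
Pearson correlation between $X\hat w$ and observed expression) is kept;
ties prefer the sparsest model, then the largest $\lambda$, so selection
is deterministic. All-zero weight vectors and zero-variance predictions
define $R^2 = 0$ rather than NaN. One model per family then goes to
held-out validation; the admission rule keeps models with validation
$R^2 \ge 0.005$ (boundary inclusive). The same validation $R^2$ supplies
the Cauchy combination weights, on the grounds that it is the unbiased
estimate of each model's predictive value; tuning $R^2$ is used only for
grid selection. The choice of $R^2 \ge 0.005$ rather than the common 0.01
is motivated by Cramér's null law: under no association, regression $R^2
\sim \mathcal B((p-1)/2, (n-p)/2)$, and at $p = 34$, $n = 31{,}684$,
$\alpha = 0.05/16{,}884$ the rejection region starts at $\approx 0.00263$,
so 0.005 is conservative while 0.01 discards genuinely predictable genes.

## Shrinkage LD estimator

Off-diagonal entries of the reference-panel correlation matrix are damped
by $\exp(-2 N_e c_{ij}/m)$, with $c_{ij}$ the genetic distance in
centimorgans, $N_e = 11{,}400$ the effective population size and $m = 183$
the genetic-map sample size (1000 Genomes OMNI maps); entries with factor
below $c = 10^{-3}$ become exact zeros, i.e. everything beyond
$m\ln(10^3)/2N_e \approx 0.0554$ cM. Genetic positions are linearly
interpolated at SNP coordinates, clamped at the map ends. Shrinkage never
increases a magnitude, preserves symmetry and the unit diagonal, and
together with any $\theta > 0$ ridge yields a positive-definite system.
Missing panel genotypes are mean-imputed per SNP before standardization.

## Association testing

Per model, $\tilde Z = Z\hat w/\sqrt{\hat w' V \hat w}$ with a two-sided
normal p-value; $\tilde Z$ is invariant to positive rescaling of $\hat w$.
For real-data scans $V$ defaults to the shrunk estimator (an external
reference panel's raw LD can be indefinite, which the burden denominator
rejects with guidance); a `raw` mode is available. In the simulation
experiments $V$ is the in-cohort raw LD: there the null z-scores are
correlated exactly by the cohort's sample LD, and shrinking only the
denominator would misestimate the statistic's variance — an artifact of
the evaluation, not a property of the method.

The Cauchy combination $T = \sum_j \tilde R_j^2 \tan\{(0.5-p_j)\pi\}$
(normalized weights) is approximately standard Cauchy under the null for
arbitrary dependence; $p = 0.5 - \arctan(T)/\pi$. For $p_j < 10^{-15}$
the term is replaced by its tail equivalent $\tilde R_j^2/(p_j\pi)$, and
very large $T$ maps back through $1/(T\pi)$ — standard numerical guards
for extreme significance. With a single model the combination is the
identity map. Direction is a plain majority vote over per-model signs
(unweighted; an exact tie reports `unknown`). The transcriptome scan's
Bonferroni denominator is the number of genes actually tested (models
admitted and at least one overlapping GWAS SNP), logged explicitly;
untested genes are recorded, not erred on.

## Simulation framework

Study conditions follow the large-blood-eQTL setting: 31,684 training,
369 tuning, 10,000 test samples, 877 cis-SNPs, significance threshold
$0.05/20{,}000 = 2.5\times10^{-6}$; grids $h_e^2 \in \{0.005, 0.01, 0.1\}$
(plus 0.05 for the sample-size studies), $h_p^2 \in \{0.1,0.2,0.5,0.8\}$,
$p_{\mathrm{causal}} \in \{0.01,0.05,0.1,0.2\}$.

**Genotypes.** Two haplotypes per individual are drawn from a latent
Gaussian with block-AR(1) correlation (blocks of 20 SNPs; per-block
target correlation from $U(0.2, 0.9)$) and thresholded at the MAF
quantile (MAF per SNP uniform on [0.01, 0.5]), so Hardy–Weinberg holds by
construction. Because thresholding attenuates correlation, the block
parameter is interpreted on the *genotype* scale and mapped to the latent
scale through the tetrachoric relation (solved at the block's mean MAF);
realized adjacent-pair genotype LD then tracks the block parameter to
within the intended tolerance at moderate values, while very high targets
remain capped for pairs of dissimilar MAF — a genuine constraint of
binary-valued variables. SNPs are spaced 2,300 bp apart (877 SNPs spanning
a ~2 Mb cis window), and the accompanying genetic map concentrates
recombination in hotspots at block boundaries (~0.1 cM each, 0.01 cM/Mb
background, ~1 cM/Mb on average): a map consistent with the LD structure,
so the shrinkage estimator preserves within-block LD and zeroes
cross-block entries that are truly near zero.

**Expression and phenotype.** $\lceil p_{\mathrm{causal}}\,p\rceil$ causal
SNPs are drawn uniformly per replicate; effects start $N(0,1)$ and are
rescaled so the *realized* variance of $Xw$ equals $h_e^2$ exactly; noise
has variance $1-h_e^2$. The trait is $Y=\beta E+\epsilon_p$, with $\beta$
rescaled so the realized variance of $\beta E$ equals $h_p^2$ (the
"proportion of phenotypic variance explained by expression" reading); a
`genetic` mode instead anchors on $\mathrm{var}(\beta Xw)$, since the two
conventions give visibly different power. Summary statistics are per-SNP
simple-regression z-scores, and
`standardized_marginal_effects(make_summary(X, E))` recovers the sample
correlations (an identity the tests verify).

**Experiments.** The accuracy experiment trains on summary statistics
from the training cohort (in-cohort shrunk LD), selects by tuning $R^2$,
and reports held-out test $R^2$ of the selected model; an oracle variant
fits the same grid from exact individual-level $r$ and raw $R$. The power
experiment adds an independent GWAS cohort (10,000 samples), admits
models at validation $R^2 \ge 0.005$, and counts combined p-values below
$2.5\times10^{-6}$. The type-I experiment reuses each fitted weight set
across many pure-noise GWAS replicates (vectorized marginal z-scores per
cohort). A single seed streams into per-replicate substreams
(`SeedSequence.spawn`), so all outputs are bit-reproducible.

**Problem sizes in the shipped tests.** The acceptance suite runs the
full sample sizes with desk-scale replicate counts: 14 replicates for the
full-size accuracy/oracle comparison, 12 per low-heritability regime,
8 per training-size point for the monotonicity checks, and 5 weight sets
× 1,200 nulls (6,000 total, with 200 SNPs and 3,000 training samples) for
type-I error. Monte-Carlo standard errors at these sizes are comfortably
inside the asserted tolerances.

## Known limitations

- **Synthetic LD is weaker than real cis-window LD.** Real cis regions
  contain long haplotype blocks with near-unit correlations, so their
  effective dimension is far below the SNP count; independent 20-SNP
  AR(1) blocks have a several-fold larger effective dimension. The
  penalized fit's estimation error grows with effective dimension, so
  absolute imputation $R^2$ under this generator sits below what the same
  pipeline achieves on real biobank genotypes (at $h_e^2=0.05$,
  $p_{\mathrm{causal}}=0.2$, full training size, the generator yields
  mean test $R^2 \approx 0.037$ for both the summary-based and the
  individual-level fit). Conclusions that transfer are the *relative*
  ones: summary-based and individual-level fits agree closely, accuracy
  and power increase with training size and heritability, and type-I
  error is controlled. Absolute accuracy levels do not transfer.
- The latent-Gaussian generator cannot reach very high genotype
  correlations between SNPs of dissimilar MAF (the phi-coefficient
  bound), and draws MAF independently per SNP, unlike real blocks where
  tightly linked SNPs share frequency histories.
- Strand-ambiguous (A/T, C/G) variants are dropped during filtering;
  non-ambiguous complement flips are resolved; unresolvable allele pairs
  are dropped and counted in the log. Indels and multi-allelic records
  are out of scope.
- Synthetic genotypes satisfy Hardy–Weinberg by construction, so the HWE
  filter of real pipelines is exercised only through the I/O layer.
- Cross-tissue borrowing, fine-mapping, colocalization, and dosage (BGEN)
  input are out of scope.
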