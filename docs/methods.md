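# Methods

## The model

`divergene` analyses a dichotomous cohort (case/control, responder/
non-responder, ...) by replacing every genotype with an *individualised log
Bayes factor* (LBF) and studying the correlation structure of the resulting
matrix.

For variable $j$ with genotype categories $g \in \{0, 1, 2\}$ (alternate-
allele dosage; $\{0, 2\}$ for hemizygous males on the X chromosome; $k$
category indices for categorical variables such as imputed HLA alleles or
collection centre), two multinomial models are estimated from the data:

$$\hat P(g \mid \text{case}) = \frac{n^{\text{case}}_{gj} + c}
{n^{\text{case}}_{\cdot j} + k c}, \qquad
\hat P(g \mid \text{control}) \text{ analogously},$$

with pseudocount $c$ (default 0.5, Jeffreys-style; guarantees finite LBFs
for categories unseen in one class).  Each observed genotype is then
replaced by

$$\mathrm{LBF}_{ij} = \ln \hat P(g_{ij} \mid \text{case})
- \ln \hat P(g_{ij} \mid \text{control}),$$

and a missing genotype by 0 (no evidence either way).  The matrix keeps the
data's dimensions; positive cells are evidence for case membership.
X-linked variables are modelled per sex stratum, which is why a sex check is
part of QC.  Frequencies are estimated on the analysis cohort itself (no
leave-one-out); with $n$ in the hundreds the self-influence of one subject
on its own cell is $O(1/n)$ and is absorbed by the permutation null, which
re-estimates models under every relabelling.

Because class-conditional frequencies are used without any
allele-frequency weighting, rare variants keep their full evidential weight;
no MAF filter is applied anywhere outside the relatedness scan.

## Eigen-scaled PCA and the projected loading

Columns of the LBF matrix are standardised (constant columns dropped) and
decomposed by SVD, $X_s = U S V^\top$.  Subject scores are $US$, eigenvalues
$\lambda_k = s_k^2/(n-1)$, and variable loadings are the correlation-style
$V\sqrt{\lambda}$ — each component is scaled by its eigenvalue so components
are directly comparable and the biplot shows subjects and variables in one
space.  The case/control contrast defines a unit direction in component
space (difference of class-mean score vectors, oriented cases-positive; a
supplementary-dummy-variable correlation variant is available and coincides
up to scale).  A variable's **projected loading** — its scaled loading
dotted with this direction — measures its contribution to the case/control
distinction.

Per-component signs are fixed deterministically (largest-magnitude loading
positive, then case-mean positive), and all projections are invariant to
component sign flips.

## Permutation significance

The case/control labels are permuted and the *entire* pipeline — model
estimation, LBF transform, PCA, direction, projections — is re-run per
permutation (default 10 000; the test suite and the acceptance script use
100–200).  A Gaussian mixture with 1–3 components (BIC-selected, ties to
fewer) is fitted to each variable's permutation distribution, and the
p-value is the mixture's upper-tail mass beyond the observed projected
loading (one-sided in the case-positive orientation; a two-sided switch
exists).  The parametric tail gives resolution far below
1/n\_permutations, which is the point of fitting a mixture rather than
counting exceedances.  Genome-wide significance uses the Šidák threshold
$1-(1-\alpha)^{1/m}$ at the exact number of variables (computed with
`expm1`/`log1p` for precision), with Benjamini–Hochberg step-up flags
reported alongside.

Two properties of this statistic are worth knowing:

* The permutation null of a projected loading is **not centred at zero**:
  the LBF transform aligns every variable with its own (permuted) contrast,
  so $E_{\text{case}}[\mathrm{LBF}] \ge E_{\text{control}}[\mathrm{LBF}]$
  under any labelling and null projections carry a positive offset.  The
  per-variable mixture null absorbs this.
* All variables share one observed labelling and one permutation ensemble,
  so p-values are correlated across variables: on a single dataset the
  pooled p-value distribution can sit a few percent off uniform even though
  the procedure is calibrated marginally (the mean empirical rank of the
  observed statistic within its null is 0.5 across datasets).  Pooled
  uniformity diagnostics on one dataset should be read with this in mind.

### Choosing the number of components

The component count K (default 5) should reflect where the case/control
contrast lives, judged from the scree plot; an automatic option retains
components whose eigenvalue exceeds the mean.  In data whose disease signal
is carried by large blocks of correlated variants, the contrast dominates
the first component and small K suffices.  With mutually *independent*
variants (as the synthetic generator produces), a handful of associated
columns cannot lift the contrast above the Marchenko–Pastur bulk — spiked-
covariance theory puts the detection edge at $\sum_j \rho_j^2 >
\sqrt{m/n}$ — so the contrast direction is spread across many components
and a deep stack (hundreds of components at $m/n = 2$, which is what the
eigenvalue-above-mean rule selects there) is needed to recover it.  The
signal-recovery check in the acceptance suite runs at K=400 for this
reason; as K approaches the rank, the projected loading approaches the
per-variable correlation with the class indicator.

## Quality control

Applied before analysis, with strict (">") thresholds throughout:

* **Sex**: inferred from X heterozygosity (male < 0.02, female > 0.20,
  else unknown — cutoffs are standard array-QC practice, configurable);
  flagged when inferred and reported disagree.
* **Sample missingness** above 5%.
* **Relatedness**: share of identical genotype codes over up to 5 000
  co-observed SNPs with MAF above 0.48; under HWE at MAF 0.5 an unrelated
  pair is expected at $\sum_g f_g^2 = 0.375$, so a flag threshold of 0.8
  (configurable; not a published value) separates duplicates/first-degree
  pairs cleanly.  The higher-missingness member of a flagged pair is
  removed.
* **Variants**: monomorphic in the whole population; missing above 5%;
  Hardy–Weinberg exact test in controls at $p < 10^{-8}$ (females only for
  X-linked variants; categorical variables exempt).  The exact test is the
  standard conditional-on-allele-counts formulation, summing probabilities
  of heterozygote counts no more probable than the observed one.  A variant
  can be flagged under several reasons but is removed once.

## Ancestry homogenisation

Reference panels (one reference population, several contrast populations)
are co-analysed with the study cohort: LBF models contrast reference
against contrast labels, the PCA is fitted on the panels, and study
subjects are projected as passive supplementary points so they cannot
distort the contrast.  k-means (k=1 by default) locates the reference
centre; the member covariance defines a Mahalanobis metric; a subject is
kept iff its squared distance is within the $\chi^2_{1-\alpha}$ quantile
(df = component count), default $\alpha = 0.2$.  The "$\alpha$ percentile"
is read as excluding the $\alpha$ tail; a flag selects the complementary
reading.  Finally the cohort is sex-balanced to a case/control sex odds
ratio of 1 by subsampling the over-represented sex stratum of the more
imbalanced class only (cases, in the sex-skewed cohorts this emulates).

## Variant-to-gene mapping and network expansion

Significant variants are expanded to proxies with dosage $r^2 \ge 0.6$
(composite LD on unphased dosages) within 1 Mb.  A (variant, gene) evidence
row exists when the variant lies strictly within 40 kb of the gene interval
extended by a 1 kb strand-aware promoter, or when a functional/QTL/
chromatin record links them.  Four criteria in [0, 1] — functional
consequence severity, QTL strength, linear proximity
$\max(0, 1 - d/40\,000)$, chromatin contact — are combined by TOPSIS
against the theoretical best (1,1,1,1) and worst (0,0,0,0) profiles with
weights 0.35/0.35/0.2/0.1; no vector normalisation is applied because the
anchors are fixed.  Per-gene score is the maximum over rows; genes at
score ≥ 0.4 are "mapped".  Drug tractability is the maximum of a gene's
term scores from a fixed 19-term table (Approved Drug = 1.0 ... Small
Molecule Binder = 0.1).  PPI expansion keeps edges with confidence ≥ 0.5;
seed–seed edges then need no further condition, and a non-seed interactor
is retained iff it keeps edges to at least two distinct seed genes.

## The synthetic generator

`simdata` emulates the structure of an SNP-array case/control study:
controls in HWE at per-variant MAFs (uniform on a configurable range),
cases tilted at planted risk loci via the multiplicative-allelic-risk
closed form $p' = \mathrm{OR}\,p/(1-p+\mathrm{OR}\,p)$, X-linked variants
with sex-dependent coding, and planted QC pathologies: monomorphic
variants, high-missingness variants and samples, HWE violators (controls
drawn fully inbred), related pairs (duplicate-with-noise, 5% of sites
redrawn), sex-label flips, and ancestry outliers (Balding–Nichols
frequency perturbation at a configurable $F_{st}$).  Reference panels
share base frequencies and diverge by Balding–Nichols draws; panel
frequencies are recorded so additional subjects of a population can be
drawn (`sample_from_panel`).  All randomness flows from one root seed
through named per-purpose streams.

What the generator does **not** emulate: linkage disequilibrium between
distinct variants, genotyping-batch effects, realistic allele-frequency
spectra, admixture gradients.  Passing tests therefore demonstrate the
statistical machinery (calibration, recovery, filters) under idealised
independence, not performance on LD-structured real data — in particular,
real data concentrate disease signal into low-dimensional LD blocks where
small K suffices, which independent columns cannot reproduce (see the K
discussion above).

## Numerical choices and problem sizes

* Exact LAPACK SVD for small matrices; seeded randomized SVD (10
  oversamples, 4 power iterations) for large ones; the permutation engine
  can run the randomized solver in float32 with 2 power iterations where
  throughput matters (the observed analysis and the null then share the
  same solver settings).
* GMM fits use one initialisation, covariance regularisation scaled to the
  null variance; p-values are floored at the smallest positive double.
* The test suite runs permutation analyses at 100–200 permutations,
  cohorts of 500+500 subjects and 2 000 variants; the acceptance script
  uses 300–400 subjects per arm and 600–1 800 variants, chosen to exercise
  every stage at desk scale.
* Degenerate inputs: zero-variance permutation nulls give p = 1 at the
  observed constant (else the floor); singular reference covariances get a
  ridge of $10^{-6}\,\mathrm{tr}$; classes with zero observations for a
  variable fall back to pooled frequencies with a warning.

## Known limitations

* Continuous co-variables (expression, clinical measurements) are not
  transformed; the LBF machinery covers categorical data only.
* LBF models are estimated in-sample (no leave-one-out); see above.
* The relatedness identity threshold and sex-inference cutoffs are
  field-standard defaults, not derived quantities.
* PPI expansion treats the edge list as undirected and ignores self-loops.
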