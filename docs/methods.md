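# Methods

`retroprev` implements a comparative-oncology analysis linking recent
non-LTR retrotransposon (L1/SINE) activity and cancer-gene-ortholog load to
neoplasia and malignancy prevalence across mammals. This note documents the
models, the defaults and why they were chosen, the numerical details, and
what the synthetic validation does and does not demonstrate.

## Cohort construction

Neoplasia prevalence is the fraction of a species' necropsies reporting any
tumor (benign or malignant); malignancy prevalence the fraction reporting a
malignant tumor. Prevalences are stored as exact fractions in [0, 1];
percentages are formatting only. Species are retained only with

* at least 20 necropsy records (`thresholds.min_necropsies`, default 20) —
  below this, prevalence estimates are dominated by sampling error;
* at least one recorded neoplasia **and** one malignancy. Cancer occurs in
  essentially all mammals, so observed zeros are treated as undersampling
  artifacts, not biology. Because it is ambiguous whether a species with
  tumors but no recorded malignancy should be excluded from neoplasia-response
  models, `thresholds.require_malignant: false` relaxes the rule to
  neoplasia-only; the default excludes on either zero.

Excluded species are logged with every applicable reason (insufficient-n
listed first, deterministically). Missing longevity is allowed; such species
drop out only of models that include longevity, which maximises per-model
sample size.

Each retained species receives regression weight w = 1/sqrt(n necropsies),
so prevalences estimated from many necropsies are trusted more.

## Active-element classification

A repeat annotation row is a "potentially active" element when it looks like
a recent, intact insertion:

* **L1**: interval length within ±10% of the 6,100 bp family consensus
  (i.e. in [5490, 6710]) and divergence ≤ 5%. The consensus length and
  tolerance are configurable.
* **SINE**: length in [100, 400] bp and divergence ≤ 5%.

All bounds are inclusive (the divergence bound is stated as ≤; inclusivity
for the length windows is chosen by analogy and is switchable). Element
length is the annotated interval length; fragments split across rows are not
merged — full-length filtering makes defragmentation moot for L1, and SINEs
rarely fragment below the window. Divergence is taken from the annotation's
per-hit substitution percentage as given; no Kimura re-correction.

The combined burden is n(active L1) + n(active SINE). Species with zero
full-length L1s keep their SINE count in the combined tally: those SINEs are
genuine recent insertions mobilised in trans, and dropping them would zero
out exactly the species whose L1 machinery is fragmented or unannotated.

Input dialects: RepeatMasker `.out` (1-based inclusive coordinates,
converted to 0-based half-open) and a BED6+ dialect with the class/family
string in the name column and percent divergence in the score column. The
synthetic generator writes the same BED dialect, so fixtures and real data
share one parser.

## Proximity and genic-insertion metrics

Distances from active elements to their nearest gene use a pure edge-gap
convention: overlap (≥ 1 shared base) is 0; bookended intervals are 0; else
`min over targets of max(t.start − q.end, q.start − t.end)`. Some
closest-feature tools report gap+1; `dialect="gap1"` reproduces that. All
downstream inference compares species, so the choice shifts every distance
by at most 1 bp. Strand is ignored. Queries on chromosomes lacking any
target are excluded from the statistics and counted, not given sentinel
values.

Per species the pipeline reports the median and the **IQR mean** — the mean
over distances inside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] — because raw means are
dominated by a long right tail of gene-desert insertions. Quartiles use
linear interpolation between order statistics (position (n−1)·p, the default
of mainstream statistical environments). Genic-insertion counts are the
number of distinct active elements overlapping ≥ 1 gene; a repeat spanning
several genes counts once. Gene intervals are taken as given (full gene
spans); no exon/transcript resolution. L1 and SINE distances are pooled for
the combined models.

Both interval operations run in O((n+m) log m) on sorted edge arrays and are
required by the test suite to agree exactly with an O(n·m) brute-force scan.

## Cancer-gene-ortholog load

Census genes are mapped to orthogroups through their query-proteome protein
id; a gene's contribution to a species is the species' gene count in that
orthogroup (0 when unassigned — treated as "no detectable ortholog", not an
error). Totals and the somatic / germline / oncogene / TSG / fusion tallies
sum contributions per cancer gene, not per orthogroup: two census genes
collapsing into one orthogroup each contribute the species count
(`dedupe=True` collapses to unique orthogroups for sensitivity analysis).
Genes with role "both" count toward oncogene **and** TSG tallies — a choice
worth remembering when interpreting the strong oncogene–TSG correlation.
Orthogroup member lists and gene-count tables are cross-validated on parse;
any disagreement is a hard error naming the offending orthogroups.

## Trait transforms

All responses and predictors are transformed along Tukey's ladder of powers
over the grid −2 to 2 in steps of 0.025 (configurable), choosing the power
that maximises the Shapiro–Wilk W of the transformed vector; the transform
is x^p for p > 0, log x at p = 0, and −(x^p) for p < 0 so order is always
preserved. Count predictors containing zeros restrict the grid to positive
powers rather than adding an offset (an optional +c offset is available).
Predictors are then min–max scaled to [0, 1] so slopes are comparable across
models; the transform is applied before scaling.

Grubbs' test (two-sided, single outlier; critical value from the
t-distribution at α/(2n) with n−2 df) flags extreme values, but flagged
points are reported and never auto-removed — extreme longevities and
ortholog counts in this domain are real biology, not errors.

## Weighted PGLS with estimated Pagel's λ

The core model for response y (transformed) with design X:

    y ~ Normal(X β, V),   V = σ² C(λ) + τ² diag(w²)

C is the Brownian variance–covariance matrix of the phylogeny (C_ij = depth
of the MRCA of tips i and j); C(λ) multiplies its off-diagonal entries by
Pagel's λ ∈ [0, 1]; w is the 1/sqrt(n) sampling-error vector. β is profiled
out by GLS at each covariance; (λ, σ², τ²) maximise the exact multivariate-
normal log-likelihood (ML, not REML). Estimating the proportionality τ²
absorbs the unknown scale of the sampling errors after transformation —
after Tukey-transforming the response, 1/sqrt(n) can only be proportional to
the residual standard error, not equal to it. A strict mode (`error_scale=
"fixed"`) pins τ = 1 for use when the weights are absolute standard
deviations.

Numerics: for estimated τ² the likelihood is profiled to two parameters
(λ and g = τ²/σ²) with σ² in closed form; optimisation is bounded L-BFGS-B
with multi-starts at λ ∈ {0.1, 0.5, 0.9} plus explicit boundary candidates
(λ = 0, λ = 1, g = 0), so λ̂ can land exactly on a boundary and the
estimated-λ fit always nests the fixed-λ fits (its log-likelihood is the
maximum of the three; tested). Covariances are Cholesky-factorised with a
tiny-jitter fallback; a rank-deficient design is a hard error.

Inference: t-tests with n − |β| df (the conventional GLS choice);
R² = 1 − (e'V⁻¹e)/(y_c'V⁻¹y_c) with y_c the response centred at its GLS
mean — a GLS-weighted R², chosen because the underlying model is GLS;
ordinary-scale R² from other software will differ. AIC = −2 lnL + 2k with
k counting every estimated parameter: |β| + 1 (σ²) + 1 if λ is estimated
+ 1 if τ² is estimated. Residual diagnostics use normalized residuals
V^{−1/2}e: Shapiro–Wilk for normality and a Breusch–Pagan-type score test
for heteroscedasticity (the specific tests are this package's choice).
Collinearity in multiple regressions is screened with VIFs (flag > 5).

Model comparison fits λ ∈ {0, λ̂, 1} and tabulates AICs. BH-FDR (step-up,
q = 0.05) is applied within each model-family × response group, matching
per-table correction; a global family is configurable.

## Synthetic data and what validation shows

The generators emulate the study's data-generating conditions with known
ground truth:

* **Trees**: pure-birth (Yule) with unit depth — the simplest ultrametric
  model; tree shape is not a quantity of interest.
* **Traits**: drawn from exactly the PGLS generative model above.
* **Necropsies**: neoplasia ~ Binomial(n, prevalence), malignant ~
  Binomial(neoplasia, conversion fraction) — hierarchical, so count nesting
  holds by construction.
* **Landscapes**: uniform placements; active elements are generated inside
  the activity windows, inactive ones violate ≥ 1 criterion; truth counts,
  genic insertions, and nearest-gene distances are recorded via a
  brute-force scan independent of the pipeline's algorithms. Repeat–repeat
  overlap is not prevented (no metric depends on it).
* **Study fixture** (`simulate_study`): 55 species (the real cohort size);
  necropsy totals log-uniform on [20, 500] (the filter floor, and the real
  dataset averages ≈ 55 records/species); combined active counts log-normal
  on a λ-structured latent (TE burden is heritable along the tree); true
  neoplasia prevalence rises linearly with min–max-scaled log burden over
  ~0.5 of the prevalence range plus Brownian noise (sd 0.03); malignant
  conversion 0.4. The effect is deliberately strong: the fixture is a
  correctness/power harness, not a replica of the real effect sizes, which
  would require the 55 genome assemblies and the necropsy database.

Validation sizes (chosen as the package's standard study sizes): interval
oracle agreement on 1,000 random instances; classification fidelity on 100
landscapes; λ/slope recovery with 300 replicates on 200-tip trees at
λ ∈ {0, 0.5, 1}; type-I error with 1,000 null replicates at 100 tips; AIC
ordering on 200 signal-free replicates; pipeline power on 100 end-to-end
replicates. Passing these shows the estimators are correctly implemented
and calibrated **under the assumed generative model**; it does not show that
real repeat annotations are accurate, that necropsy records are unbiased
across zoos, or that the linear-on-transformed-scale model is the true
biology.

## Known limitations

* ML (not REML) λ and σ² estimates carry the usual small-sample downward
  variance bias; REML is exposed as a flag-level extension point but the
  reported analyses use ML.
* λ̂ at the boundaries {0, 1} makes its standard error ill-defined; the
  package reports the point estimate only.
* The per-hit divergence column is trusted as given; pipelines that
  recompute Kimura-corrected divergence will classify borderline elements
  differently.
* Fragmented L1 copies are invisible to the full-length filter; species
  whose assemblies shatter L1s will have understated burdens (the combined
  L1+SINE measure partly compensates).
* The Breusch–Pagan-type test on normalized residuals has low power at
  n ≈ 50.
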