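# Methods

## Data model and filtering

The pipeline consumes a taxa × samples integer count table with
genus/species labels (species may be empty for reads classified only to
genus; phylotype labels such as "HOT 272" are ordinary species strings)
and a per-sample metadata table (group PHIV/PHEU, age in years, binary
sex, race-white, ethnicity-Hispanic, dental-visit and antibiotic-use
indicators, periodontitis and caries status, total sequencing reads).
Missing covariates on included samples are an error; no imputation is
performed. An optional `UNMATCHED` row holding reads the upstream
classifier could not assign is dropped with a logged read total.

Exclusions run in a fixed order: antibiotic use in the prior 3 months →
samples with < 200 reads → taxa with pooled relative abundance < 10⁻⁵ →
taxa present in fewer than 10 subjects. "Pooled relative abundance" is
the taxon's grand total divided by the overall grand total; a per-sample
variant was considered and rejected because the rule's purpose is to
remove globally negligible phylotypes. "Present" means a non-zero count
in a subject's pooled sample, with no minimum-count refinement. Both
thresholds are strict (`<`), so a taxon exactly at 10⁻⁵, or present in
exactly 10 subjects, is retained. Every filter is idempotent and reports
conserved accounting (input = output + removed).

## Alpha diversity and rarefaction

Shannon diversity uses log base 2 by default (the QIIME convention;
configurable and recorded in output). Simpson diversity is reported as
1 − D ∈ [0, 1). Diversity is computed on unrarefied counts; rarefaction
is used only for richness curves, restricted to samples with ≥ 65,000
reads. The rarefaction expectation is exact (hypergeometric):
E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], evaluated with log-gamma to remain
stable at amplicon depths; a seeded Monte-Carlo mode (subsampling
without replacement) exists mainly as a cross-check and converges to the
analytic value. Group comparisons default to Welch's t test, since
diversity distributions are typically skewed with unequal spread;
Student's test is available for strict replication.

## Negative-binomial screen

Each taxon is fitted with an NB2 regression (log link; variance
μ + μ²/k; dispersion 1/k estimated by maximum likelihood jointly with
the coefficients, with a BFGS restart on non-convergence). Covariates:
group indicator (PHIV = 1), age, sex, dental visit, race, ethnicity, and
total sequencing reads. Total reads enters as a natural-log covariate
with a free coefficient by default — it is an adjustment variable, not
an exposure-time offset — and an `offset` mode (coefficient fixed at 1)
is provided for sensitivity analysis; in simulations the two differ
negligibly. Inference on the group coefficient is Wald (two-sided normal
p-value; CI = exp(θ̂ ± 1.96·SE)), which maps directly onto rate-ratio
reporting; a likelihood-ratio alternative was checked in simulation and
agrees closely. Non-converged fits (including SEs above 10³) are
reported with NaN estimates, flagged, counted in the log, and excluded
from the multiple-testing family — they never raise.

Genus-level analysis aggregates, per genus, only the reads not
classified to species ("genus-only" rows), the convention used in the
tables this layout mirrors; genera without a genus-only row are omitted
in that mode, and a `total` mode sums all rows of the genus instead.
Species-level and genus-level screens form separate Benjamini–Hochberg
families at q = 0.05. BH decisions are computed via statsmodels'
`fdr_bh` and are property-tested against a direct step-up evaluation.

## FPRP and BFDP

FPRP is evaluated at the *observed* p-value α with power computed for a
two-sided z test at level α against the alternative θ₁ = |ln 1.5| (the
same expected rate ratio is applied symmetrically to enriched and
depleted taxa). The power term uses `isf`/`sf` forms so that the
extremely small p-values produced by strong depletions do not underflow
(a naive `1 − Φ(...)` implementation silently returns FPRP = 1 there).
BFDP uses the closed-form approximate Bayes factor with prior variance W
elicited so that the 97.5th percentile of the prior rate-ratio
distribution is 1.5: W = (ln 1.5 / 1.96)² ≈ 0.0428; W is configurable.
Both quantities are computed at priors 0.001, 0.01 and 0.05; the
composite noteworthiness flag uses π = 0.01 and requires BH
significance plus (FPRP < 0.5 and BFDP < 0.5), or FPRP < 0.2, or
BFDP < 0.2.

## Disease-association models

For each taxon (or summed etiologic set), a logistic model regresses the
outcome on group, the taxon's log₁₀ count, their product, the adjustment
covariates, and log₁₀ total sample counts (log-transformed for scale
comparability with the taxon term). Zeros are replaced by half the
taxon's minimum non-zero count, computed across all included samples
with groups pooled. Per-group odds ratios per tenfold count increase are
exp(b_taxon) for PHEU and exp(b_taxon + b_interaction) for PHIV, with
the PHIV CI from the summed coefficient variance. Separation and other
degenerate fits are detected by convergence failure, |coefficients| > 50
or SEs > 10², and rendered as the literal string `Undefined` in output
tables rather than raising.

## Synthetic cohorts

The generator emulates the analyzed study design: 154 + 100 samples,
depths log-uniform on [1,330, 230,039] (matching the heavy right skew of
real amplicon depths), several hundred taxa with baseline log-abundances
softmax-normalized (default N(0, 2.5), giving a realistically uneven
composition), NB counts with mean depth × abundance × exp(group and
covariate effects) and per-taxon size parameters (default lognormal with
median 1), and logistic disease outcomes whose log-odds depend on log₁₀
taxon counts with group-specific slopes — the same half-minimum
transform the analysis applies, so recovery experiments are internally
consistent. Because counts are drawn taxon-wise, realized column sums
fluctuate around the drawn depth rather than matching the bounds
exactly. Covariate distributions are not estimates of the real cohort:
age ~ U(10, 22) (the study's age range), binaries Bernoulli(0.5),
configurable. The deterministic `reference_cohort_frame` reconstructs
the published 279-sample enrollment roster (antibiotic flags and the
periodontitis × caries cross-tabulation) for the tabulation checks.

What the generator does *not* emulate: taxon–taxon correlation
(co-occurrence networks), compositional closure, zero inflation beyond
NB, taxonomy misassignment, and any real covariate structure. Passing
calibration tests therefore demonstrates correctness of the estimators
under the assumed sampling model, not robustness to these real-data
features.

## Calibration experiment sizes

Validity checks use replicate cohorts at the study's n = 254 with the
study's depth range. Null/coverage experiments for the NB screen use
150-taxon equal-abundance communities so the focal taxon holds a
realistic < 1% share — in very small communities (tens of taxa) the
focal taxon's own contribution to the total-reads covariate induces a
visible conditioning bias that is a property of the total-count
adjustment itself, not of the estimator. Replicate counts are 200–400
per experiment, placing the Monte-Carlo standard error of a rejection
rate near 0.01–0.015. Interaction-model experiments use 30-taxon
communities (the logistic model conditions on one taxon at a time, where
community size is immaterial) with a ln 2 interaction log-OR on the
caries outcome.

## Known limitations

- Wald inference is mildly anti-conservative for highly overdispersed
  taxa (size parameter k ≤ 1) at n ≈ 254; the effect is within the
  tested tolerance but visible.
- The genus-only aggregation silently omits genera whose reads are all
  species-assigned; use `total` mode when that is not desired.
- FPRP/BFDP are post-hoc filters on Wald summaries, not a full Bayesian
  re-analysis; non-normal priors are out of scope.
- Etiologic-set membership is configuration (YAML), not inference; taxa
  missing from the count table are reported and skipped.
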