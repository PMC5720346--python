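# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the design decisions that were genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Per-gene linear model and variance moderation

Each study is analysed separately. For gene *i* the log2 expression is
modelled as a linear function of group (case/control), batch, sex, age and
anxiety, with Gaussian errors of gene-specific variance σ_i². The design is
treatment-coded with fixed reference levels (control, lowest batch, male,
anxiety 0); factors observed at a single level are dropped with a logged
warning, and the sensitivity variants (no anxiety term; added BMI term) are
expressed by changing the covariate tuple.

The case/control coefficient is tested with a moderated t-statistic. The
hierarchical model takes σ_i² as scaled inverse chi-square with prior degrees
of freedom d₀ and prior value s₀²; the residual variance s_i² then follows a
scaled F distribution, and matching the first two moments of log s_i² via
digamma/trigamma identities yields method-of-moments estimates of (d₀, s₀²).
The trigamma inversion is done by bisection to a relative tolerance of 1e−8.
When the observed spread of log s² does not exceed its sampling spread (or
the estimate exceeds 1e6), d₀ is flagged infinite: the posterior variance
collapses to s₀² and the reference distribution becomes normal. d₀ = 0 is
accepted as the no-shrinkage limit and reproduces the ordinary t exactly
(special-cased so the identity is bitwise, not just numerical). Genes with
s_i² = 0 are excluded from hyperparameter estimation but still shrunk
(s̃² = d₀s₀²/(d₀+d)). Two-sided p-values are floored at the smallest positive
double and never reported as 0.

**Permutations.** Case/control labels are permuted within batch strata —
batch is the largest nuisance factor, and stratified shuffling preserves it
under the null. The moderated t is recomputed per permutation with the same
prior as the observed analysis; the Monte-Carlo p uses the add-one estimator,
so min p = 1/(B+1). Exhaustive enumeration over all distinct stratified
labelings is available for tiny designs (capped at 1e5 assignments). A
caveat the tests make explicit: when the prior dominates (d₀ → ∞) the
moderated t is no longer per-gene studentized and its permutation null
deviates from the asymptotic reference; under the generator's
heterogeneous-variance conditions (d₀ ≈ 4) the two agree to ~0.01 RMS.

**Module eigengene.** A gene module is summarised by the first principal
component of its gene-standardised expression (sample sd, ddof = 1), scaled
to unit variance and sign-oriented to correlate positively with the module
mean; group differences are tested with a two-sided Welch t-test.

## 2. Replication threshold and consensus sets

With aligned per-gene p-values from the two studies (alignment by gene-id
intersection, logged), the overlap profile records, at every threshold, the
per-study significant counts O1 and O2, the joint count O11, the chance
expectation E11 = O1·O2/N, and the ratio R = O11/E11. The grid is the sorted
union of all observed p-values ≤ .05 plus the endpoint .05 — the counts are
step functions that change only at observed values, so this grid is exact.
R is defined as 0 when O11 = E11 = 0 and flagged infinite when E11 = 0 <
O11. Ties are handled by ≤ comparisons.

**q2 rule and its null guard.** The point rule — q2 = largest threshold ≤
.05 with R ≥ 2 — is not usable on its own: under two independent null
studies the exact grid always contains tiny thresholds where a single chance
joint hit gives O11 = 1 against E11 ≪ 1, and moderate thresholds show ≥ 2×
fluctuations, so the raw rule fires on roughly half of pure-noise study
pairs. Threshold selection is therefore gated by a seeded Monte-Carlo test
of cross-study independence: the pairing of the two p-value lists is broken
by permutation (200 draws by default) and the observed maximum standardized
overlap excess, max_h (O11 − E11)/√(E11 + 1), is referred to its permutation
distribution. If independence is not rejected at the 5% level the pipeline
reports "no replicated signal" (a distinct exit code, not an error); when it
is rejected, the point rule is applied unchanged. The +1 pseudo-count in the
statistic keeps near-empty cells from dominating. A Dirichlet-resampling
credible band for R is available for plotting and reporting but plays no
role in selection.

Genes passing q2 in both studies are partitioned by fold-change sign: both
positive → UP, both negative → DOWN, anything else (including an exactly
zero estimate) → discordant. Fisher's combination X² = −2(ln p₁ + ln p₂) ~
χ²₄ with Benjamini–Hochberg control at FDR 10% (statsmodels implementation)
corroborates the selection; zero p-values are an input error — callers floor
first.

A scale effect worth knowing: at a lenient selected threshold (q2 = .05 under
a strong planted signal) the number of chance joint hits grows linearly with
the number of null genes, so the sign-concordant fraction of the replicated
set is dilution-dependent — about 0.97 with 5,000 genes and 200 planted
effects, falling to about 0.90 at 18,863 genes by the same O1·O2/N
arithmetic. The recovery experiments in the acceptance suite run at 5,000
genes with only the shared signal planted; the end-to-end acceptance script
reports the full-scale default so the dilution is visible rather than
hidden.

## 3. Enrichment

One-sided hypergeometric upper-tail p per term, computed independently per
term (no ontology-graph decorrelation — the reported Annotated / Found /
Expected columns are the classic flat-test quantities, and the multiplicity
correction is a flat Bonferroni α/n_terms). The universe is caller-supplied
— typically the genes measured on the platform — never hard-coded. Depletion
(found < expected) is flagged but never tested. GMT parsing restricts sets
to the universe, deduplicates members within a line, drops empty-after-
restriction sets with a warning, and reports malformed lines by number.

## 4. Bioscalar

Signature scores are means of within-study z-scored genes (ddof = 1);
z-scoring makes the scores and the tertile cutoff comparable across studies
and keeps high-variance genes from dominating; raw-scale averaging sits
behind a flag. Constant genes are dropped with a warning. The coupling line
is fit on cases only and controls are projected onto the case line for
comparability. Projection is orthogonal, and the signed coordinate is
anchored at the foot of the perpendicular from the origin — for a line
through the origin this is exactly the distance of the projected point from
the origin, positive in the direction of increasing meanUP. The tertile
cutoff is the ⌈2n/3⌉-th order statistic of case bioscalars (nearest-rank);
ties at the cutoff are classified non-inflamed (strict >), so the flagged
subgroup is the top tertile and its sensitivity is identically 1 — the
implementation computes it rather than asserting it, as a tautology guard.
The cutoff is computed per study; pooling across studies is a caller choice.

## 5. Synthetic-data generator

The generator emulates two independent whole-blood case-control microarray
studies on a shared probe set. Defaults encode the reference conditions:
18,863 genes; 113/57 and 94/100 cases/controls; 200 shared DE genes with
|log2FC| = 0.8 (sd 0), 55% overexpressed; 100 study-specific DE genes per
study; gene variances scaled-inverse-chi-square with d₀ = 4, s₀² = 0.25
log2² (placeholder values chosen to be stressed, not estimates of any real
dataset); additive covariate effects with per-gene coefficients N(0, sd) —
batch 0.2, sex 0.1, age 0.005/yr, anxiety 0.1; covariates Bernoulli(0.5)
except age ~ U(20, 65); baseline abundance N(7, 1). Noise is Gaussian on
the log2 scale, with an optional unit-variance t-noise switch for robustness
checks. All randomness flows from one seed through `numpy`'s spawning
`SeedSequence`, so truth assignment and each study draw from independent,
individually reproducible streams.

**Coupling.** Each case receives a latent scalar g ~ N(0, c) added to the
planted UP genes and subtracted from the planted DOWN genes. Writing v_U and
v_D for the averaging-noise variances of the two signature means, the
case-level correlation of the raw means is −c/√((c+v_U)(c+v_D)); solving
the quadratic ρ²(c+v_U)(c+v_D) = c² for c targets rho exactly on the raw
scale. Because the default scores z-score genes first (down-weighting
high-variance genes, which carry noise but not extra latent signal), the
fitted correlation runs slightly stronger than the raw-scale target —
within the ±0.1 band the recovery tests check. rho_target = −1 is rejected:
with additive gene noise it requires unbounded latent variance.

**What the generator does not emulate:** probe-level artifacts, array
normalisation effects, batch nonlinearity, correlated gene-gene noise within
pathways, heavy-tailed or skewed expression, or realistic effect-size
spectra. Passing tests therefore demonstrate the correctness and calibration
of the machinery under the stated model — not that real blood data will show
effects of this size. In particular the planted regime (|log2FC| = 0.8
averaged over ~100-gene signatures) yields near-perfect subject separation
(Cohen's d ≫ 1, AUC ≈ 1), far stronger than the moderate separations real
case-control transcriptome data produce.

## 6. Problem sizes used by the checks

Null calibration: 50 seed pairs at 5,000 genes, 40/40 per study. Recovery:
10 seeds at 5,000 genes with 200 planted shared effects at the reference
sample sizes. Coupling recovery: 20 seeds at 2,000 genes, 100 cases.
Hyperparameter recovery: 20,000 genes at d = 10. Counting oracles: 1,000
random instances each for overlap counting and enrichment (universe ≤ 200).
The end-to-end script runs the full 18,863-gene default once. These sizes
are the package's own choices for routine verification; all scale linearly
if enlarged.

## 7. Known limitations

- Two studies only; the multi-study generalisation (combining > 2 p-value
  lists) is out of scope.
- The q2 grid search and null guard assume exchangeable gene-level p-values
  under the null; strong inter-gene correlation would make the guard
  anti-conservative.
- The enrichment test treats terms as independent; ontology-aware
  decorrelation is deliberately not implemented.
- The eigengene uses a plain SVD; no network construction or module
  detection is provided — module membership is caller-supplied.
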