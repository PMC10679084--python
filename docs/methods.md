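# Methods

## Study design

The package reimplements, as tested library code, a complete two-sample MR
study of six leukocyte-count traits (eosinophil, lymphocyte, neutrophil,
monocyte, basophil, total white cells) on rheumatoid arthritis risk:
instrument selection per trait, harmonization against the outcome GWAS,
three univariable estimators with a sensitivity suite, MR-PRESSO,
leave-one-out, one multivariable MR over all traits, and a
Bonferroni-corrected report. The real GWAS inputs (large blood-cell
consortium and disease GWAS downloads) are out of scope; a synthetic
generator reproduces their statistical structure so every stage is
exercised end to end with known truth.

## Model and assumptions

Each SNP *j* is an instrumental variable for the exposure: valid
instruments satisfy relevance (γ_j ≠ 0), independence from confounders,
and the exclusion restriction (effect on the outcome only through the
exposure). Summary data enter as (β̂_Xj, se_Xj) and (β̂_Yj, se_Yj); the
outcome scale is log-odds, so exp(θ) is an odds ratio per unit (SD) of
exposure.

Estimators are the standard summary-data set, written from their defining
equations (weighted means and weighted least squares via the normal
equations; the test suite checks them against independently coded
brute-force oracles and against a second WLS implementation):

* Wald ratio with first-order delta-method SE (se_Yj/|β̂_Xj|). The term in
  se_Xj is dropped — appropriate for strong instruments (mean F ≫ 10); a
  second-order option exists behind a flag.
* IVW fixed/random. "Random effects" is multiplicative overdispersion,
  SE × max(1, √(Q/(J−1))), not an additive τ² model: this matches the
  convention of the summary-data MR software family, and the floor at 1
  means the random model never reports less uncertainty than the fixed
  one. IVW inference is normal.
* MR-Egger with intercept; inference by t on J−2 df, SEs carrying
  φ = max(1, √(RSS_w/(J−2))). Egger is not invariant to allele
  orientation, so rows are deterministically flipped to β̂_Xj ≥ 0 first.
* Weighted median by linear interpolation of the order statistics at
  cumulative standardized weight (Σ_{i≤k} w_i − w_k/2)/Σw = 1/2; SE from a
  parametric bootstrap (θ̂_j* ~ N(θ̂_j, se_j²), default 1,000 replicates,
  seed mandatory for reproducibility).
* MR-PRESSO: observed leave-one-out weighted RSS against a simulated null
  (β*_Xj ~ N(β̂_Xj, se_Xj²), β*_Yj ~ N(θ̂₍₋j₎β̂_Xj, se_Yj²)); per-SNP
  outlier p-values Bonferroni-flagged at 0.05/J; distortion test against
  random removal of equally many instruments. All empirical p-values use
  (r+1)/(n+1), so none is ever exactly 0 and a fixed seed fixes every
  p-value bit-for-bit. Default n_sim = 1,000.
* MVMR: WLS of β̂_Y on the J×K exposure-effect matrix, weights 1/se_Y²,
  no intercept; Q_A on J−K df with the same multiplicative φ; conditional
  instrument strength per exposure as the mean weighted squared residual
  of its effect column after regressing out the other columns (zero
  covariance between exposure-effect estimates is assumed — the actual
  sample overlap between source GWAS is unknowable from summary data; see
  limitations).

## Selection and harmonization rules

Stage order: significance filter (strict p < 5×10⁻⁸) → greedy clumping →
confounder-list exclusion → palindrome removal. Clumping takes the
lowest-p unassigned SNP as index and discards same-chromosome SNPs within
the window (|Δpos| ≤ window_kb × 1000) with r² ≥ 0.01; ties on p break by
(chrom, pos, snp_id) so results are order-independent. SNPs absent from
the LD sidecar count as unlinked (sparse LD files list only nonzero
pairs). LD is always an input, never estimated. Palindromic SNPs are
removed unconditionally — no frequency-based strand rescue — because
allele frequency cannot resolve strand reliably near 0.5.

Harmonization matches on SNP id (both source studies are rsID-keyed;
positions may disagree across genome builds), aligns the outcome to the
exposure's effect allele by direct match, swap (negate β, reflect EAF), or
strand complement (A↔T, C↔G) followed by either; irreconcilable allele
pairs are dropped and audited. EAF discordance > 0.2 on retained SNPs
warns but never drops — it is a data-quality signal, not an exclusion
rule. SNPs missing from the outcome GWAS are dropped (no proxy lookup).

The MVMR instrument set is the union of per-trait genome-wide-significant
SNPs, jointly clumped with each SNP scored by its minimum p across traits,
then harmonized pairwise to the first exposure's alleles. This assembly is
a design choice (stated, not hidden): it keeps every trait's strong
instruments while guaranteeing one LD-independent set.

## Synthetic data generator

Per SNP: maf ~ Uniform(maf_range); γ_j ~ N(0, σ_γ²); standard errors from
the standardized-trait closed form se = 1/√(2·maf(1−maf)·n) (exact, no
noise on SEs); β̂_Xj ~ N(γ_j, se_Xj²); a fraction π of SNPs get pleiotropic
α_j ~ N(μ_α, τ_α²) added to the outcome mean (optionally correlated with
γ_j to break InSIDE); β̂_Yj ~ N(θγ_j + α_j, se_Yj²); Wald p-values; alleles
drawn with a configurable palindromic fraction; the outcome file is
perturbed by allele-swap and strand-flip rates so harmonization is
genuinely exercised; an LD sidecar carries block structure (constant r²
within blocks of consecutive SNPs). One master seed expands into named
per-component streams.

Defaults echo the scale of the emulated study: J = 400 candidate SNPs
(the study's six traits contributed 159–425 instruments each),
n_exposure = 500,000, n_outcome = 58,284, maf ∈ (0.05, 0.5),
σ_γ = 0.0275 giving expected mean F ≈ 140 (the study reported mean F
119.6–176.3), 20% palindromic SNPs, 20% allele swaps and 5% strand flips
between files, LD blocks of 4 at r² = 0.4. θ defaults to 0.3 (≈ OR 1.35
per SD, the order of the study's headline effect).

What the generator does **not** emulate: individual-level genotypes and
case/control liability (outcome effects are drawn directly on the
log-odds scale under the Gaussian summary-statistic approximation);
between-SNP correlation of the *estimates* (the LD structure lives only
in the sidecar, so clumping behaviour is exercised but estimator inputs
are independent across SNPs); winner's-curse from discovery in an
external sample; sample overlap between exposure and outcome GWAS
(two-sample regime assumed). Passing tests therefore certify the
estimators and the pipeline plumbing under the stated generative model,
not robustness to those real-data features.

## Monte-Carlo study designs

Problem sizes are the package's own study design, chosen once:

* **Null calibration** — θ = 0, no pleiotropy, J = 200, 1,000 replicates:
  rejection rates of the IVW test and Egger intercept test at α = 0.05
  should sit near nominal ([0.03, 0.07] allowing binomial noise).
* **Recovery** — θ = 0.3, J = 100, σ_γ set from the closed-form mean-F
  relation to give mean F ≈ 60, 500 replicates; the outcome GWAS is sized
  at n = 10,000 so that Monte-Carlo sampling error dominates the known
  O(θ/F̄) ≈ 0.005 weak-instrument attenuation of summary-data IVW —
  otherwise a 3-MC-SE band on the mean would test that attenuation rather
  than implementation correctness. Checks: mean within 3 MC-SEs of 0.3,
  95% CI coverage in [0.92, 0.97].
* **Robustness ordering** — 40% invalid instruments with same-sign
  pleiotropy (μ_α = 0.03, τ_α = 0.01) and instruments oriented to the
  exposure-increasing allele (γ folded positive): with sign-symmetric γ
  the ratio bias of directional pleiotropy averages out, so orientation
  is what makes "directional" directional on the ratio scale. The valid
  60% holds >50% of the weight, so |bias(weighted median)| should be
  < |bias(IVW)| on matched replicates (200).
* **MR-PRESSO** — J = 20, n_sim = 1,000; one injected outlier at 10
  outcome-SEs should be flagged in ≥95% of 200 runs; the per-SNP
  false-flag rate on clean SNPs stays ≤ 5% (it is ≈ 0.2% by construction
  of the Bonferroni bound) and ≥90% of clean runs end with an empty flag
  set.
* **End-to-end** — six independently simulated exposures (J = 200 SNP
  pool each), one causal at θ = 0.3; full selection → harmonization →
  IVW → Bonferroni (0.05/6) per replicate; exactly the causal trait
  should be flagged in ≥90% of 100 replicates. PRESSO and leave-one-out
  are exercised in the single-run pipeline tests rather than inside this
  replication loop.
* **MVMR recovery** — K = 5 exposures equicorrelated at ρ = 0.5, only
  exposure 1 with direct effect 0.3, J = 100, 500 replicates: exposure 1
  centered on 0.3, the others on 0, coverage in [0.92, 0.97].

The worked example in `analysis/` uses a separate six-trait simulation
with exposure correlation 0.25, chosen so that correlation-borne *total*
effects of null traits are visible univariably while only the causal
trait survives multivariable adjustment — the total-versus-direct
contrast that motivates MVMR.

## Numerical choices and edge cases

Strict inequality at the significance threshold; clumping asserts
r² ≤ 1 and non-negative windows; IVW with one instrument reduces to the
Wald ratio (fixed model only); Egger requires J ≥ 3, PRESSO J ≥ 4,
MVMR J > K with a hard error naming collinear exposures on (near-)rank
deficiency rather than silently dropping a column; simulated Wald
p-values are floored at 1e-300 to stay inside (0, 1]; file round-trips
preserve full float precision with "NA" as the missing token; empirical
p-values are never 0 by the plus-one rule.

## Known limitations

First-order ratio SEs understate uncertainty for genuinely weak
instruments; MVMR ignores covariance between a SNP's effect estimates
across exposures (overlapping source cohorts would need a covariance
input); palindrome handling never attempts EAF-based strand inference;
confounder exclusion takes an id list as input (no annotation-service
queries); the generator's independence of summary statistics across SNPs
means LD-induced estimator correlation is not represented.
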