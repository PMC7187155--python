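# Methods

This note records the models, conventions and numerical choices behind
each stage, the parameters that matter, and what the synthetic-data
generator does and does not emulate.

## qPCR quantification

**Model.** Each reaction is assumed to be exponential over some stretch
of cycles, F(c) ≈ N₀·Eᶜ, between a baseline noise floor and a plateau.
The window-of-linearity fit subtracts the mean fluorescence over an
early-cycle range (default cycles 3–8; disable with
`baseline_cycles=None` for baseline-free inputs) and regresses
log₁₀ of the corrected fluorescence on cycle over every contiguous
candidate window of 4–6 cycles. Candidates must lie strictly below the
plateau (before the first cycle reaching 80 % of the corrected maximum)
and strictly above a noise floor (0.1 % of the corrected maximum). The
window with the highest r² wins; ties break to the longer, then the
earlier window. Then E = 10^slope, N₀ = 10^intercept, and
Ct = (log₁₀ T − intercept)/slope for threshold T.

The noise floor is this package's own windowing rule: without it,
short stretches of near-zero baseline noise occasionally beat the true
log-linear region on r², and efficiency estimates scatter far outside
the plausible range. With it, 2 % multiplicative signal noise yields
per-reaction efficiency estimates within a few hundredths of the
generating value.

**Threshold.** Any common-per-gene threshold cancels between a sample
and its plate's standard curve; the default is the geometric mean of
windowed fluorescence across a gene's reactions on the plate, with a
constant override available. Standard curves are fitted per plate per
gene, and samples are calibrated only against their own plate.

**QC rule.** Duplicates pass iff both efficiencies, expressed as
(E − 1) × 100, lie in [75, 125] inclusive, and the sample standard
deviation (divisor n − 1) of the two Cts is ≤ 0.5. Boundary values
pass. A failed window fit fails the pair outright.

**Back-calculation base.** The standard curve regresses Ct on log₁₀
concentration, so the back-calculation uses N₀ᵢ = 10^((Ctᵢ − bᵢ)/mᵢ).
Any base works if used consistently on both sides (it cancels in the
slope–exponential composition); the base is configurable
(`WindowConfig.log_base`) and defaults to the qPCR convention of 10.
On a perfect dilution series the slope is m = −1/log₁₀(E), e.g.
−3.3219 for perfect doubling.

**Degenerate inputs.** Curves with no eligible window, or a
non-positive fitted slope, are flagged `no_amplification` and fail QC
downstream; a sample missing any of the four genes yields an
incomplete profile that is excluded from filtering and modelling.

## Grouped IQR filter

Within each gene × species × rearing-light cell, proportions outside
[Q1 − 1.5·IQR, Q3 + 1.5·IQR] flag their sample; a flagged sample is
removed for all four genes, because each proportion is defined relative
to the others. Quartiles use linear interpolation between order
statistics (numpy default, R type 7). The filter runs exactly one
pass — survivors are not re-filtered, so the operation is not claimed
to be idempotent. Groups of fewer than four samples are skipped with a
warning since their quartiles are unstable. Sex is not part of the
grouping key; hybrids form their own species level.

## LWS genotyping

The amplicon layout (exon spans, intron span, first encoded residue,
frame offset) is explicit configuration; the packaged default is a
498-bp amplicon carrying a 91-bp intron between exons 4 and 5, with the
diagnostic codons for residues 216 and 230 on exon 4 and 275 on exon 5.
Classification operates at the nucleotide level: a site's triplet is
expanded over IUPAC ambiguity codes and translated; a site is H-type,
P-type, heterozygous (both residues reachable — the double-peak
signature) or neither. Any "neither" site → UNRESOLVED; otherwise any
heterozygous site → HET; otherwise all-H → HH, all-P → PP; a mixed pure
H/P pattern is left UNRESOLVED rather than forced. Reverse-orientation
input is reverse-complemented before the forward path, so strand choice
cannot change a call. Pedigree imputation assigns a genotype only when
the parental cross forces one, never overwrites a sequenced call, and
flags (but keeps) sequenced calls that contradict a forced expectation.

## Preference scoring

Scores follow the dichotomous-choice formula exactly; a behaviour with
zero events for either male yields an undefined (not zero) score for
that behaviour only, and undefined scores are excluded from per-female
means — imputing 0 would fabricate indifference. Validity thresholds
(20 min interaction, 60 min wall clock, 3 quivers per male) are sharp:
the boundary values themselves pass. Repeatability uses the one-way
ANOVA variance-component (ICC(1)) estimator with the unbalanced-design
n₀ coefficient; negative among-female components truncate to zero. The
estimator agrees with pingouin's ICC(1,1) to numerical precision on
balanced designs.

## Association stage

**Random structure.** Candidate random intercepts (e.g. dam, sire,
female, observer) are fitted as variance components over a single
all-encompassing group — the standard device for crossed random
intercepts — with REML; the structure minimising AIC over all subsets
wins, ties toward fewer terms. AIC is computed from the REML
log-likelihood with k = (fixed parameters) + (variance components) + 1,
a constant fixed part making the comparison valid. Age is continuous,
so it competes in the same comparison as a protected fixed covariate
rather than a random intercept (an age-binned random intercept can be
substituted by passing a binned column as a candidate).

**Fixed effects.** Each droppable term (one not nested in a retained
interaction) is tested by an ML likelihood-ratio test; backward
elimination removes the least significant term above α = 0.05 and
refits until all remaining terms are significant, giving the minimum
adequate model. Elimination is deterministic given data and α.

**Small-sample calibration.** The plain χ² LRT is liberal in small
samples (its statistic inflates by roughly n/(n − p)). The package
therefore scales the statistic by (n − p_full)/n by default; for
Gaussian fixed-effects models this is the monotone transform of the
exact F test, and a 500-replicate Gaussian null at n = 60 with a
12-parameter fixed part rejects at ≈ 5 % (≈ 11 % uncorrected). Pass
`correction="none"` for the raw statistic.

**Contrasts.** Estimated marginal means average model predictions over
the reference grid (cartesian product of observed factor levels,
continuous covariates at their means). All pairwise differences within
a family (optionally one family per level of a conditioning factor)
are tested with z statistics; the single-step adjusted p-value is
P(max_j |Z_j| > |z_i|) under the joint multivariate-normal law of the
contrast estimates (the max-|z| analogue of the Tukey test), computed
by MVN integration with a Šidák fallback. Adjusted p is never below
raw p, and a family of one is unadjusted. Non-estimable contrasts are
marked rather than dropped silently.

**Non-convergence.** If no candidate random structure converges the
model falls back to no random terms with a warning; a reduced model
that fails during elimination keeps its term and is flagged.

## Synthetic-data generator

The generator emulates all four input streams with a fixed seed tree
(every stream independently seeded from the plan seed, so adding
samples does not perturb other streams).

- **Cohort** — 77 females in the genotype-by-species composition of
  the study population (20 blue PP, 12 red HH, 10 red HET, 31 hybrid
  HET, 4 hybrid PP), split evenly between rearing lights, in full-sib
  families of up to six.
- **qPCR** — F(c) = baseline + sat(N₀·Eᶜ)·(1 + ε), with
  sat(s) = s·plateau/(s + plateau) and ε ~ N(0, 0.02) multiplicative
  noise by default; per-gene efficiencies 1.88–1.95, plateau 10⁴,
  baseline 50 fluorescence units, 50 cycles, template amounts chosen so
  Cts fall in the realistic 15–25 range, duplicate reactions, and a
  five-point ten-fold construct dilution series per plate per gene.
  True proportions are species baselines (blue higher LWS / lower RH2A
  than red, hybrids intermediate) shifted ±0.04 on LWS/SWS2a by deep
  rearing, with per-gene jitter sd 0.03, renormalised. The `ideal()`
  variant (no noise, no saturation, no jitter) is the exact algebraic
  round trip: the quantification stage recovers its proportions to
  better than 1e-6. With saturation active, exact recovery is
  impossible in principle — the logistic bend distorts the log-linear
  window at the ~10⁻³ level even below the 80 % cutoff — which is why
  exactness is claimed only for the ideal mode.
- **Sequences** — one amplicon per female on a shared stop-free exonic
  background with the genotype's diagnostic codons planted and
  heterozygotes IUPAC-merged at the differing positions.
- **Trials** — three trials per female per test light; quiver counts
  3 + Poisson (valid by design), lateral displays 1 + Poisson; positive
  responses Bernoulli with P(positive | red) = σ(θ), P(positive | blue)
  = σ(−θ), so the expected score is tanh(θ/2). The latent preference θ
  sums a genotype effect under shallow test light (+0.5 HH, −0.5 PP, 0
  HET; zero under deep — the study's qualitative interaction pattern),
  a rearing-light effect (±0.2, deep-reared toward red) and a
  per-female N(0, 0.3) intercept. Five percent of trials receive an
  injected protocol violation to exercise the validity rule.

**What the generator does not emulate** — and hence what passing tests
cannot show about real data: probe chemistry and inter-plate technical
drift beyond independent noise; linked inheritance or recombination
(genotypes are planted, not transmitted); sequencing errors other than
clean double peaks; observer bias, male-identity effects or temporal
structure within trials; and survival or sampling biases. Round-trip
tests validate the pipeline's algebra and decision rules, not the
biology.

## Problem sizes and tolerances in the test suite

Simulation-based checks use sizes chosen to keep Monte-Carlo error
well inside the asserted tolerances: 50 generator seeds of 8-sample
plates for the noisy quantification error (median ≤ 0.02); 200 random
instances for filter-oracle equivalence; 500 Gaussian-null replicates
at n = 60 for LRT calibration (rate within 0.05 ± 0.02); 50 seeds of a
90-female × 6-trial design for the low-repeatability regime (true
R = 0.1, mean estimate within ±0.05); and 12 full-cohort behavioural
replicates for the genotype-vs-species interaction comparison (> 80 %
of replicates must favour genotype). The end-to-end run uses the full
default plan.

## Known limitations

- Kenward–Roger degrees of freedom are not implemented; inference is
  LRT-based throughout, with the Bartlett-type scaling above.
- The amplicon coordinate layout is a packaged default consistent with
  the 498-bp/91-bp-intron fragment; users aligning real chromatogram
  calls should verify the layout against reference sequence before
  trusting residue numbering.
- The MVN integral behind the single-step adjustment is numerical
  (SciPy); for large contrast families the Šidák fallback may engage.
- One-pass filtering means re-running the filter on its own output may
  remove further samples; this mirrors the single-step protocol and is
  intentional.
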