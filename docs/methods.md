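# Methods

This note documents the models and procedures implemented in `divpheno`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data validation does and does not
show.

## Mention detection and assertion (clinical_text)

Mentions are located with a **closed stem list** — diverticula, diverticulae,
diverticular, diverticuli, diverticulitis, diverticulosis, diverticulum —
matched case-insensitively on word boundaries. A raw `diverticul*` prefix
wildcard is deliberately not used: it would match surgical-history terms
such as *diverticulectomy*, which are ambiguous evidence of current
disease. The concept is DIVERTICULITIS exactly when the matched stem is
*diverticulitis*; every other stem is DIVERTICULUM_ANY.

Sentence splitting breaks after `. ! ? ;` followed by whitespace and at
newlines, with two guards: a period between digits never splits (report
measurements such as "35.5 cm"), and a configurable abbreviation list
("Dr.", "e.g.", …) suppresses splitting after known abbreviations.

Assertion classification is a trigger-and-scope algorithm in the
NegEx/ConText family. The shipped lexicon (~75 entries, plain TSV, fully
editable) covers seven trigger categories: pre-negation (forward scope),
post-negation (backward), pseudo-negation (assigns nothing; absorbs any
negation phrase it contains, e.g. "no increase" neutralises "no"),
termination ("but", "however" — closes open scopes), hypothetical ("rule
out", "evaluate for", "if"), other-experiencer ("family history of",
"mother"), and historical ("history of", "h/o"). Within a sentence,
triggers are located by longest match; each opens a scope in its direction
that ends at a termination trigger, another trigger of the same category,
its token cap, or the sentence boundary. Defaults: forward scopes cap at
10 tokens, backward at 5 (the NegEx convention); both are per-trigger
configurable, with a sentinel for sentence-end scoping. When scopes of
different categories cover the same mention the precedence is
negated > other-experiencer > hypothetical > historical.

Two open calls were decided as follows and are configurable:
**historical mentions count as positive** for phenotyping, because
diverticulosis is a chronic condition and the phenotype is lifetime
presence; **other-experiencer mentions never count**. Indication-style
phrasing ("evaluate for diverticulitis") is handled by the hypothetical
trigger family rather than by section segmentation, which is out of scope.

## Phenotyping algorithms

All three algorithms enforce: diverticulitis case ⇒ diverticulosis case;
exclusion applies to both conditions or neither; each patient gets exactly
one status per condition per algorithm.

**Text-driven.** Exclusion codes (prefixes 556, 558, 560.2 on ICD-9; K51,
K52, K56.2 on ICD-10; editable list) exclude outright. Otherwise, over all
colonoscopy/imaging reports: a positively asserted diverticulitis mention ⇒
case for both; else a positively asserted mention of any stem ⇒
diverticulosis case (diverticulitis control), which a
diverticulitis-specific diagnosis code (ICD-9 562.11/562.13 or a K57
diverticulitis code; shipped list) can promote to a diverticulitis case —
codes supplement by OR, never demote. Controls need ≥ 1 qualifying report,
no positive mention, and no diverticular code ever; everyone else is
unclassified. Requiring examination for controls makes the absence of a
mention informative; a patient with diverticular codes but no positive
text is left unclassified rather than called a control.

**Structured.** A 562.\*/K57.\* code dated in the window `[p, p + 7]` days
(both ends inclusive — "within 7 days after" naturally includes day 0 and
day 7) of any colonoscopy/imaging procedure date `p` makes a case;
diverticulitis-specific codes in the window make a diverticulitis case.
Text positivity is merged by OR when reports exist. Classification is
invariant to shifting all dates by a constant.

**Phecode comparator.** Codes-only: any event mapping to phecode 562 or a
child ⇒ case (562.2 ⇒ diverticulitis case); a would-be control carrying an
exclusion-list code is excluded instead. Here case status takes priority
over exclusion, matching the comparator's role of counting every coded
patient.

Validation reports PPV per stratum against gold labels; a stratum with
zero reviewed patients reports PPV as missing, never 0. The comparison
report gives fold increase n_A/n_B and overlap as a fraction of A's cases,
each missing when its denominator is unavailable.

## Phecodes and the phenome matrix

Mapping is an exact lookup on the dot-normalised ICD code, then closure
over ancestors by decimal truncation (562.11 → 562.1 → 562). The package
ships a small **synthetic** map/definitions fixture (the 562 family, its
gastrointestinal exclusion sources, and a few unrelated phecodes for null
columns); the loaders accept a user-supplied export of the full published
map with the same columns. A patient is a case for a phecode with
≥ `min_code_count` mapped events (default 1 — no code-count convention is
imposed; set 2 for sensitivity analyses), excluded if any event maps into
the phecode's exclusion range, else control. The minimum-case filter keeps
columns with ≥ 30 cases (boundary kept) and is idempotent.

## Logistic association

`fit_logistic` is IRLS with step-halving. Convergence: max |score| < 1e-8
or relative log-likelihood change < 1e-10, capped at 50 iterations.
Standard errors come from the observed information at the optimum;
p-values are two-sided Wald (a likelihood-ratio variant is a flag away).
Complete/quasi-complete separation makes the score vanish while |β| → ∞,
so any |β| > 15 is flagged as separation and reported non-converged rather
than raised. A rank-deficient design raises an error naming the collinear
columns (QR diagnostic).

GWAS: per variant, additive ALT dosage + sex + age at colonoscopy + site
one-hots (alphabetically first site as reference, for determinism) +
PC1–PC10. Missing dosages drop samples per variant (no imputation,
matching standard GWAS tool behaviour); monomorphic variants are dropped
with a logged reason. The diverticulosis analysis compares diverticulosis
cases (with or without diverticulitis) to controls; the diverticulitis
analysis compares diverticulitis cases to controls and drops
diverticulosis-only patients entirely.

LD pruning is greedy: candidates with p < 1e-6 in ascending p (ties by
chromosome, position); keep a candidate iff r² < 0.1 against every kept
variant. r² is the squared Pearson correlation over jointly non-missing
samples; a zero-variance pair is treated as r² = 1, which conservatively
retains only the better hit.

PheWAS tests one SNP against every phecode column with dosage + PC1–10 +
site (following the PC/site adjustment convention; sex/age can be added
via `covariate_columns`). The BH-FDR family is the converged phecodes for
that SNP (per-SNP families, as PheWAS tables are reported per SNP);
non-converged phecodes are reported but excluded from the family. BH is
the step-up rule with adjusted values min_{j≥i} m·p(j)/j capped at 1.

## Power model

Allelic two-proportion test. Given effect-allele frequency p, genotype
frequencies follow Hardy–Weinberg; penetrances follow
logit⁻¹(b₀ + g·log ψ) with b₀ solved by Brent's method so the population
prevalence matches; case/control allele frequencies follow by Bayes' rule
(controls are unaffected, not population); power is the two-sided normal
z-test with the null SE pooled at the configured allocation. Defaults:
α = 5×10⁻⁸, target power 0.80, case fraction 0.10 (a 1:9 cohort, as in a
diverticulitis-style analysis). `min_n` bisects on n (power is monotone)
and returns the exact integer; a helper rounds to the nearest 1,000 for
reporting. As ψ → 1 power tends to α; balanced allocation needs roughly a
third of the subjects of a 1:9 design at these parameters.

## Synthetic cohort generator

The generator emulates a multi-site colonoscopy cohort: nine sites weighted
by realistic subject counts; 57.8% diverticulosis among examined patients
with ~10% of those inflamed; 54.6% female; age 62.5 ± 12.2 years.
Genotypes are drawn under Hardy–Weinberg per configured (EAF, log-OR)
variant; the diverticulosis liability is logistic over planted variant
effects plus modest sex (log-OR 0.10, male) and age (0.03/year, centred)
effects, with the intercept calibrated by bisection **on the realised
linear predictors** so the empirical prevalence hits the target;
diverticulitis is drawn conditionally. Each patient gets one colonoscopy
procedure; notes are rendered from an editable template bank (affirmed /
negated / neutral sentences plus hypothetical and family-history
distractors that stress the assertion rules); ICD codes are emitted
truth-dependently — diverticulosis codes at sensitivity 0.30 (the ICD
stream deliberately undercounts text-documented diverticulosis, as coded
data do), diverticulitis codes at 0.90, spurious codes at 1 − 0.99 — with
dates jittered uniformly over [−14, 21] days around the procedure so the
7-day window has passing and failing instances by construction; 5% of
patients receive exclusion-list codes. All draws come from one
`default_rng(seed)` in fixed order, so a config + seed reproduces the
cohort exactly. `noise_free()` switches off text/coding noise for
recovery testing.

What the generator does **not** emulate: realistic clinical language
beyond the template bank (no misspellings, section headers, OCR noise),
longitudinal visit structure, relatedness between samples, population
stratification correlated with genotype (the PCs are pure noise), or
site-specific documentation practices. Passing the noise-free recovery and
planted-effect tests therefore shows the pipeline's logic is correct under
its stated assumptions — not that the NLP rules would reach the same PPV
on real clinical prose.

## Problem sizes and numerical choices

The validation suite uses cohorts of 1,500–5,000 patients: null-GWAS
calibration uses 200 null variants at n = 5,000 (rate within 3 binomial
SDs of α at α ∈ {0.05, 0.01}); planted-effect recovery uses 100 replicates
at n = 5,000, EAF 0.3, OR 1.5 (|mean log-OR bias| < 0.05); pruning is
checked exhaustively against a subset-enumeration oracle for up to 8
candidates; BH-FDR against the enumerated definition on 1,000 random
vectors. The logistic grid-search oracle is iterated per-coordinate grid
refinement (40 rounds, halving width), independent of the IRLS path it
checks. Ties in pruning are broken by (chromosome, position); phecode
columns sort numerically; site one-hots use the alphabetically first site
as reference — all for bit-for-bit reproducibility.

## Known limitations

- The trigger lexicon is a curated default, not a validated clinical
  resource; assertion accuracy on real notes depends on extending it.
- The phecode fixture covers only the codes the package exercises; real
  PheWAS requires the user-supplied full map.
- Sex-specific phecode restrictions are not implemented.
- The power model is the allelic normal approximation; exact or
  simulation-based power will differ slightly at extreme allele
  frequencies or tiny case counts.
- The structured algorithm trusts procedure tables; procedures inferred
  from CPT codes are not derived automatically.
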