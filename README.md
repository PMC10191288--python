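# divpheno

Rule-based EHR phenotyping for diverticular disease, with the downstream
genetic-association toolchain: covariate-adjusted logistic GWAS, greedy LD
pruning of suggestive hits, phecode-based PheWAS with Benjamini–Hochberg
FDR, a case-control GWAS power calculator, and a synthetic multi-site EHR
generator so every stage can be validated end to end with known ground
truth.

## The problem

Diverticulosis (colonic diverticula) and diverticulitis (their
inflammation) are common, under-coded conditions. Billing codes alone miss
most diverticulosis found at colonoscopy, because an incidental finding is
often described only in the free-text procedure report. `divpheno`
implements three patient-classification algorithms over electronic health
records and the statistics to compare and use them:

- **Text-driven (NLP)** — scan colonoscopy / abdominal-imaging report text
  for `diverticul*` mentions; assert each mention (affirmed, negated,
  hypothetical, other-experiencer, historical) with a NegEx/ConText-style
  trigger-and-scope algorithm; any positively asserted mention makes a
  diverticulosis case, a positively asserted *diverticulitis* mention makes
  a case for both conditions. Diagnosis codes can supplement, never demote.
- **Structured** — an ICD-9 562.\* / ICD-10 K57.\* code dated within 7 days
  (inclusive) after a colonoscopy or imaging procedure makes a case;
  text positivity is merged in by OR when reports exist.
- **Phecode comparator** — the traditional codes-only approach: any event
  mapping to phecode 562/562.1/562.2.

Controls must be *examined and clean*: at least one qualifying procedure or
report, no diverticular code ever, no positive mention. Patients with
related gastrointestinal conditions (ulcerative enterocolitis ICD-9 556,
regional enteritis 558, volvulus 560.2, …) are excluded. A diverticulitis
case is always also a diverticulosis case.

## The statistics

Association testing is maximum-likelihood logistic regression (IRLS, Wald
tests, explicit separation flagging) with sex, age at colonoscopy, study
site and 10 principal components as covariates for GWAS; PC + site
adjustment for PheWAS across the patient × phecode matrix (phecodes kept
only with ≥ 30 cases), with BH-FDR at q = 0.05 per SNP. Suggestive hits
(p < 10⁻⁶) are pruned greedily to mutual LD r² < 0.1.

The power calculator uses the allelic (allele-count) two-proportion test:
genotype frequencies from Hardy–Weinberg at effect-allele frequency *p*,
per-genotype penetrances from a log-additive odds model with per-allele OR
ψ and intercept solved so the population prevalence matches, expected case
and control allele frequencies by Bayes' rule, and a two-sided normal
z-test with the configured case:control allocation.

## Worked example

```python
from divpheno import annotate, summarize_document

note = ("Scattered diverticula were seen in the sigmoid colon. "
        "No evidence of diverticulitis.")
mentions = annotate(note)
for m in mentions:
    print(m.matched_text, "->", m.assertion.value)
print(summarize_document(mentions))
```

prints

```
diverticula -> affirmed
diverticulitis -> negated
DocumentAssertion(positive_diverticulosis=True, positive_diverticulitis=False,
                  any_negated_mention=True, mention_count=2)
```

— the affirmed `diverticula` makes the note diverticulosis-positive while
the negated `diverticulitis` does not count against it. And for the power
calculator:

```python
from divpheno import PowerParams, min_n

params = PowerParams(eaf=0.18, prevalence=0.10, odds_ratio=1.20,
                     alpha=5e-8, power=0.80, case_fraction=0.10)
print(min_n(params))   # 41497
```

— an OR-1.2 variant at 18% frequency needs ~41,500 participants for 80%
power at genome-wide significance with a 1:9 case:control cohort (≈ 15,500
with balanced 1:1 allocation).

Longer narrative walk-throughs live in `examples/` (annotating notes,
phenotyping patients, simulating a cohort and recovering a planted GWAS
signal, PheWAS, power curves); a thin CLI (`divpheno simulate|phenotype|
validate|compare|gwas|prune|phewas|power|pipeline`) wraps the same
functions for shell use.

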