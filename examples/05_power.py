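"""Case-control GWAS power: how many participants does a weak variant need?

Uses the allelic test under Hardy-Weinberg genotype frequencies and a
log-additive odds model. The example variant: effect-allele frequency 0.18,
disease prevalence 0.10, per-allele OR 1.20, genome-wide alpha 5e-8, with a
1:9 case:control cohort.
"""

from divpheno import PowerParams, gwas_power, min_n
from divpheno.association import min_n_rounded

params = PowerParams(eaf=0.18, prevalence=0.10, odds_ratio=1.20,
                     alpha=5e-8, power=0.80, case_fraction=0.10)

n = min_n(params)
print(f"minimum total participants for 80% power: {n}  (~{min_n_rounded(params):,})")
for n_probe in (5_000, 15_000, 30_000, n):
    print(f"  power at n={n_probe:>6d}: {gwas_power(params, n_probe):.3f}")

balanced = PowerParams(eaf=0.18, prevalence=0.10, odds_ratio=1.20,
                       alpha=5e-8, power=0.80, case_fraction=0.5)
print(f"with balanced 1:1 allocation instead: {min_n(balanced)}")

# Power rises steeply with n; tens of thousands of participants are needed
# for an OR-1.2 variant at genome-wide significance, and a balanced design
# needs far fewer subjects than a 1:9 one.
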