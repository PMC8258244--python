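"""Full two-sample MR on a synthetic dataset with a known causal effect.

Generates a 99-instrument exposure study (941,280 samples, instruments
explaining ~1% of variance) and a case-control outcome study with a
planted protective effect of OR 0.80 per unit exposure, harmonizes
alleles, and runs the four univariable estimators plus diagnostics.
"""

import math

from summr import (build_set, egger, f_statistic, gen_two_sample, ivw,
                   leave_one_out, max_likelihood, weighted_median)

theta_true = math.log(0.80)
exposure, outcome, instruments, truth = gen_two_sample(
    J=99, theta_true=theta_true, palindromic_fraction=0.15, seed=42)

hset = build_set(exposure, outcome, instruments)
print(f"harmonized {hset.n_active}/{len(instruments)} instruments "
      f"({sum(hset.table['palindromic'])} palindromic retained by "
      "frequency alignment)")
_, overall_f = f_statistic(hset)
print(f"overall instrument strength: F = {overall_f:.1f}\n")

print(f"planted effect: OR = {math.exp(theta_true):.2f}")
for result in (ivw(hset), max_likelihood(hset),
               weighted_median(hset, n_boot=1000, seed=1), egger(hset)):
    print(" ", result)
egger_res = egger(hset)
print(f"  Egger intercept p = {egger_res.intercept_pvalue:.2f} "
      "(no directional pleiotropy planted, so expect > 0.05)")

loo = leave_one_out(hset)
print(f"\nleave-one-out: {int(loo['outside_full_ci'].sum())} of "
      f"{len(loo)} omissions leave the all-SNP 95% CI")
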