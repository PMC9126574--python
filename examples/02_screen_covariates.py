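"""Which covariates relate to head circumference?

Step one of the cutoff definition: Spearman correlations of HC with
brain volume, height, age and education; a pooled t-test of HC by sex;
and one multivariate OLS of HC on all five. Variables significant in
the multivariate model (two-tailed alpha 0.05) define the strata used
for the microcephaly cutoffs.
"""

from cephalomine import GeneratorConfig, generate_cohort, screen_variables

cohort = generate_cohort(GeneratorConfig(n_subjects=2508, seed=1))
report = screen_variables(cohort)

for r in report.results:
    ci = ""
    if r.ci_low is not None:
        ci = f" (95% CI {r.ci_low:.3f} to {r.ci_high:.3f})"
    print(f"{r.method:9s} {r.variable:16s} {r.estimate:+.3f}{ci}  p={r.p_value:.2g}")
print("\nsignificant in the multivariate model:", sorted(report.significant))

# Expected: brain volume, sex and height significant; age and education
# not — so cutoffs are stratified by sex and height only.
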