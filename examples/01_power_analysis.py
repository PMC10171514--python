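"""A-priori sample size for a multiple-regression study.

Computes the smallest total N at which the fixed-model R²-deviation-from-zero
F test (noncentrality f²·N, numerator df = number of predictors) reaches the
target power.  The printed N is the number of participants a study with a
small effect (f² = 0.04), six predictors (a polygenic score plus five
covariates) and 95% power would have to recruit.
"""

from neuromediate import stats

query = stats.PowerQuery(f2=0.04, alpha=0.05, power=0.95, n_predictors=6)
n = stats.required_sample_size(query)
print(f"required total sample size: N = {n}")
print(f"power at N:   {stats.f_test_power(n, query):.4f}")
print(f"power at N-1: {stats.f_test_power(n - 1, query):.4f}")
# N is minimal: the power crosses the 0.95 target exactly between N-1 and N.
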