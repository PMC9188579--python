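"""Prevalence statistics: exact binomial CI, g-test, Kruskal-Wallis.

A pattern observed in 120 of 2000 patients in one race stratum and 90 of
2000 in another: how precise are the prevalence estimates, and do the
rates differ across groups?
"""

import numpy as np

from morbidmine import clopper_pearson, g_test, kruskal_wallis

# Exact (Clopper-Pearson) 95% interval: inverts the binomial tails, so
# coverage is guaranteed >= 95% at any n.
for x, n in [(120, 2000), (90, 2000), (3, 40)]:
    ci = clopper_pearson(x, n)
    print(f"x={x:4d} n={n:4d}  prevalence={ci.point:.4f}  "
          f"95% CI [{ci.lower:.4f}, {ci.upper:.4f}]")

# g-test of independence on the races x (present, absent) table.
table = [[120, 1880], [90, 1910], [150, 1850]]
res = g_test(table)
print(f"\ng-test: G={res.statistic:.3f}, df={res.df}, p={res.p_value:.4g}")
print("   (G = 2*sum O*ln(O/E); small p => prevalence differs across groups)")

# Kruskal-Wallis on BMI across groups — the sensitivity check that median
# BMI differences are not driving prevalence differences within a weight
# class.
rng = np.random.default_rng(0)
groups = [rng.normal(34, 3, 400), rng.normal(34.5, 3, 400), rng.normal(34, 3, 300)]
kw = kruskal_wallis(groups)
print(f"\nKruskal-Wallis on BMI: H={kw.statistic:.3f}, df={kw.df}, p={kw.p_value:.4g}")
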