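"""Recompute published cohort arithmetic from the packaged count tables.

The marginal count tables of the 10,350-subject cohort are shipped as CSV
resources; prevalences, chi-square p-values and diagnostic-odds-ratio
identities all follow from them by computation.
"""

from gmdhscreen.evaluation import chi_square_test, proportion_ci
from gmdhscreen.fixtures import (
    COHORT_TOTAL,
    count_table,
    load_marginal_counts,
    load_performance_table,
)
from gmdhscreen.outcomes import prevalence_from_counts

counts = load_marginal_counts("all")
for outcome in ("worriedness", "depression", "mild_moderate"):
    prev = prevalence_from_counts(counts, outcome, "family_size_cat",
                                  total=COHORT_TOTAL)
    print(f"prevalence of {outcome:14s} = {prev}%")
# 23.7 / 20.1 / 11.1 percent — identical whichever feature's rows are used,
# because every (consistent) feature partitions the same cohort.

chi = chi_square_test(count_table(counts, "abdominal_obesity", "worriedness"))
print(f"\nabdominal obesity x worriedness: chi2={chi['statistic']:.2f}, "
      f"p={chi['p']:.3f}")

perf = load_performance_table().set_index(["outcome", "classifier"])
row = perf.loc[("depression", "GMDH")]
se, sp = row["se"] / 100, row["sp"] / 100
print(f"\ndepression GMDH row: Se={row['se']}%, Sp={row['sp']}% -> "
      f"DOR = {se / (1 - se) * sp / (1 - sp):.1f} (published {row['dor']})")
lo, hi = proportion_ci(0.79, 2080)
print(f"Wilson 95% CI of Se=79% at n=2080: ({100 * lo:.1f}, {100 * hi:.1f})"
      f" -> prints as (77, 81)")
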