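"""Exhaustive best-subset search over all 65,535 predictor combinations.

Evaluates the apparent (training-data) hit rates of every non-empty
subset of the 16 candidate predictors and reports the best-apparent tier:
the subsets whose predictions produce the identical best 2x2 table.  Ties
are common because correlated predictors can substitute for one another.
"""

import nldrkit as nk

cohort = nk.generate(nk.GeneratorConfig(n=128, seed=1))
labeled = nk.dichotomize(cohort, 210.0)

result = nk.search_all(labeled)
ok = [r for r in result.results if r.status == "ok"]
print(f"evaluated {len(result.results)} subsets ({len(ok)} fittable)")

a, b, c, d = result.best_table.as_tuple()
best = nk.hit_rates(result.best_table)
print(f"best 2x2 table (A,B,C,D) = ({a},{b},{c},{d}): "
      f"total {best.total:.1f}%, sensitivity {best.sensitivity:.1f}%")
print(f"{len(result.best_table_tier)} subsets share that exact table "
      f"({100 * len(result.best_table_tier) / len(result.results):.3f}% of all)")
for mask in result.best_table_tier[:5]:
    print("   ", "+".join(nk.mask_to_names(mask)))
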