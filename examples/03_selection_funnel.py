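"""True-hit-rate estimation and the final-model selection funnel.

The apparent hit rate is optimistic; leave-one-out cross-validation and
the .632 bootstrap estimate the rate expected on future donors.  The
funnel chains them: keep the best-apparent tier, cross-validate it, then
let the .632 estimator pick the winner among the survivors.
"""

import nldrkit as nk
from nldrkit.validate import Boot632Config

cohort = nk.generate(nk.GeneratorConfig(n=128, seed=1))
labeled = nk.dichotomize(cohort, 210.0)

cfg = Boot632Config(n_boot=500, seed=1)
model, report = nk.select_final_model(labeled, cfg, cv_band_pp=1.6)

print(f"stage 1: best-apparent tier of {len(report.stage1_tier)} subsets")
print(f"stage 2: LOOCV keeps {len(report.stage2_survivors)} within "
      f"{report.cv_band_pp} pp of the best CV total")
print(f"stage 3: .632 winner = {'+'.join(report.winner_names())}")

winner = report.winner_names()
apparent = nk.apparent_rates(labeled, winner)
cv = nk.loocv_rates(labeled, winner)
est = next(r.rates for r in report.stage3 if r.mask == report.winner_mask)
print(f"apparent total {apparent.total:.1f}%  >  LOOCV {cv.total:.1f}%  "
      f"~  .632 estimate {est.total:.1f}%")
print("the gap between apparent and estimated rates is the training-data "
      "optimism the estimators correct")
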