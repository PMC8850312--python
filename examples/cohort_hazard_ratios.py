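"""Cox proportional-hazards models on a simulated prospective cohort.

Simulates 20,000 subjects with a BMI-like exposure, a uric-acid-like
mediator and a ~1% cumulative-incidence survival outcome, then fits the
nested model-1/2/3 suite: hazard ratios per exposure SD, for the overweight
threshold, and across mediator quartiles.
"""

from mrmediate import CohortSimConfig, ph_check, run_model_suite, simulate_cohort
from mrmediate.cohort_models import MODEL2_COVARIATES, fit_cox, per_sd

cohort = simulate_cohort(CohortSimConfig(seed=5))
print(f"subjects: {len(cohort)}, events: {int(cohort.event.sum())}")

suite = run_model_suite(cohort, models=(3,))
print(suite.round(3).to_string(index=False))

scaled, sd = per_sd(cohort["bmi"])
with_sd = cohort.assign(bmi_sd=scaled)
fit = fit_cox(with_sd, ["bmi_sd"] + MODEL2_COVARIATES)
print()
print(f"exposure SD = {sd:.2f}; PH-check p-values (p < 0.05 flags a violation):")
print(ph_check(fit, with_sd).round(3).to_string())
print()
print("The per-SD exposure HR should sit near the simulated truth of 1.25;")
print("mediator quartile HRs rise monotonically from the Q1 reference.")
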