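"""Counterfactual mediation of a survival outcome.

Fits the linear mediator model and the Cox outcome model on a simulated
cohort and decomposes the per-SD exposure effect into natural direct and
indirect (through-the-mediator) components on the log-hazard-ratio scale.
The generator's ground-truth proportion mediated is ln(1.05)/ln(1.3125),
about 0.179.
"""

from mrmediate import CohortSimConfig, mediate, mediation_bootstrap, simulate_cohort

cfg = CohortSimConfig(seed=13)
cohort = simulate_cohort(cfg)

res, med_fit, _ = mediate(cohort, "bmi", "ua")
print(f"mediator slope (units per exposure unit): {med_fit.beta1:.3f} (truth 6.0)")
print(f"NDE (HR per SD): {res.nde_hr:.3f}  95% CI {tuple(round(x, 3) for x in res.nde_ci)}")
print(f"NIE (HR per SD): {res.nie_hr:.3f}  95% CI {tuple(round(x, 3) for x in res.nie_ci)}")
print(f"TE  (HR per SD): {res.te_hr:.3f}")
print(f"proportion mediated: {res.proportion_mediated:.3f} "
      f"(generator truth {cfg.true_proportion_mediated:.3f})")

boot = mediation_bootstrap(cohort, "bmi", "ua", n_boot=200, seed=13)
print(f"bootstrap PM 95% CI: {tuple(round(x, 3) for x in boot.pm_ci)}")
print()
print("TE factors exactly into NDE x NIE on the HR scale; the proportion")
print("mediated is the indirect share of the total log-hazard effect.")
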