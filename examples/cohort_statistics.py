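"""End-to-end synthetic-cohort analysis.

Generates a 135-control / 65-psychosis cohort whose control dials mature
with education, computes windowed attributes, and runs the statistical
battery: Spearman and partial Spearman correlations, multiple regression,
and the dropout proportion comparison.
"""

import pandas as pd

import wordgraphs as wg

cohort, meta = wg.generate_cohort(wg.CohortSpec(seed=11))
rows = []
for t in cohort:
    m = wg.windowed_profile(t).mean_attributes
    rows.append({"group": t.group.value, "age": t.age_years,
                 "edu": t.education_years, "N": m.N, "RE": m.RE,
                 "LSC": m.LSC, "ASP": m.ASP})
df = pd.DataFrame(rows)
ctrl = df[df.group == "control"]
psy = df[df.group == "psychosis"]

alpha8 = wg.bonferroni(0.05, 8)
print(f"Spearman vs education (Bonferroni alpha = {alpha8.reported}):")
for attr in ("N", "RE", "LSC", "ASP"):
    rc = wg.spearman(ctrl.edu, ctrl[attr], alpha_corrected=alpha8.exact)
    rp = wg.spearman(psy.edu, psy[attr], alpha_corrected=alpha8.exact)
    print(f"  {attr:>3}: control rho = {rc.statistic:+.3f} "
          f"(p = {rc.p_value:.2e}, sig = {rc.significant})   "
          f"psychosis rho = {rp.statistic:+.3f} (sig = {rp.significant})")

part = wg.partial_spearman(ctrl.age, ctrl.N, ctrl.edu,
                           covariate_name="education")
plain = wg.spearman(ctrl.age, ctrl.N)
print(f"\ncontrol N vs age: rho = {plain.statistic:+.3f}; adjusted for "
      f"education: {part.statistic:+.3f} (p = {part.p_value:.3f})")

reg = wg.multiple_regression(ctrl.N, ctrl.age, ctrl.edu)
print(f"OLS N ~ age + education: R^2 = {reg.r_squared:.2f}, "
      f"coef_age = {reg.coef_age:+.3f}, coef_edu = {reg.coef_edu:+.3f}, "
      f"difference = {reg.coef_diff:+.3f}")

drop = meta.groupby("group").dropout.agg(["sum", "count"])
chi = wg.proportion_test(int(drop.loc['psychosis', 'sum']),
                         int(drop.loc['psychosis', 'count']),
                         int(drop.loc['control', 'sum']),
                         int(drop.loc['control', 'count']))
print(f"\nschool dropout: psychosis "
      f"{100 * drop.loc['psychosis', 'sum'] / drop.loc['psychosis', 'count']:.0f}% "
      f"vs control "
      f"{100 * drop.loc['control', 'sum'] / drop.loc['control', 'count']:.0f}%, "
      f"chi^2 = {chi.statistic:.1f}, p = {chi.p_value:.2e}")
print()
print("Education, not age, carries the maturation signal: the age "
      "correlation collapses once education is adjusted for, and only the "
      "control group shows significant education correlations.")
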