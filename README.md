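# wordgraphs

Non-semantic word-graph analysis of speech transcripts, for researchers in
computational psychiatry and language development who quantify discourse
*structure* — how speech moves between words — rather than its content.

A transcript is represented as a directed multigraph: each unique word is
a node, each consecutive word pair a directed edge. Four attributes
summarise each graph, computed on 30-word moving windows (15-word step) to
control for verbosity:

- **N** — nodes: lexical diversity,
- **RE** — repeated edges: short-range recurrence,
- **LSC** — largest strongly connected component: long-range recurrence
  ("speech connectedness"),
- **ASP** — average shortest path over reachable ordered pairs: graph size.

On top of the attributes the package provides:

- **shuffle normalization**: each window is shuffled 100 times (same
  words, random order) and the observed attribute is divided by the
  shuffled mean, measuring distance from random word order;
- the **saturating-exponential maturation model**
  `f(t) = f0 + (f_inf − f0)(1 − exp(−t/T))` fit to attribute means binned
  by integer years of age or education — bounded, SEM-weighted nonlinear
  least squares recovering the initial value `f0`, asymptote `f_inf`,
  characteristic time `T` (years) and dynamic range `|f_inf − f0|`;
- a **temporal-order permutation null** (shuffle the years, re-analyse,
  compare) and the accompanying **statistical battery**: Spearman and
  partial Spearman rank correlations, OLS multiple regression on age and
  education, Kruskal-Wallis + Wilcoxon rank-sum with Bonferroni
  correction, KS/Levene distribution checks, and 2×2 chi-square;
- a **synthetic cohort generator** whose dials (novelty, perseveration,
  long-range return) map one-to-one onto N/RE/LSC, with control subjects
  maturing along the exponential curve in education years and
  psychosis-like subjects staying flat — so the whole pipeline is testable
  end to end without access to clinical recordings.

See `docs/methods.md` for definitions, conventions and numerical choices.

## Worked example

`examples/cohort_statistics.py` generates a 135-control / 65-psychosis
synthetic cohort, computes windowed attributes and runs the battery:

```
Spearman vs education (Bonferroni alpha = 0.0063):
    N: control rho = +0.719 (p = 9.96e-23, sig = True)   psychosis rho = -0.147 (sig = False)
   RE: control rho = -0.610 (p = 4.28e-15, sig = True)   psychosis rho = +0.049 (sig = False)
  LSC: control rho = +0.586 (p = 7.90e-14, sig = True)   psychosis rho = -0.070 (sig = False)
  ASP: control rho = +0.668 (p = 8.28e-19, sig = True)   psychosis rho = -0.145 (sig = False)

control N vs age: rho = +0.579; adjusted for education: +0.076 (p = 0.383)
OLS N ~ age + education: R^2 = 0.71, coef_age = +0.007, coef_edu = +0.549, difference = +0.541

school dropout: psychosis 58% vs control 21%, chi^2 = 26.9, p = 2.11e-07
```

Reading the numbers: in the control group lexical diversity, connectedness
and graph size rise with education while short-range repetition falls —
all significant at the Bonferroni-corrected level — whereas the flat
psychosis-like group shows no education correlation. The age correlation
disappears once education is adjusted for, and the regression attributes
the signal to the education slope: education, not age, carries the
maturation. The other scripts in `examples/` walk through graph
construction, windowing, shuffle normalization, and the maturation fit
with its permutation null, each printing and explaining its output.

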