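# psynet

Psychometric network analysis of questionnaire data, built around the
workflow used in two-group symptom-network studies: how does the network of
self-efficacy beliefs (10-item General Self-Efficacy Scale, GSES) differ
between adolescents with clinically significant depressive symptoms
(PHQ-9 total ≥ 10) and healthy controls, and which items bridge the
self-efficacy and depression symptom clusters?

It is aimed at researchers in clinical psychology / psychiatric
epidemiology who estimate regularized partial-correlation networks over
ordinal item responses and need the full companion toolkit — stability,
group comparison, bridge analysis — plus a simulator for power and
recovery studies when raw questionnaire data cannot be shared.

## What it computes

* **Network estimation.** Items are nodes; edges are regularized partial
  correlations `w_ij = −θ_ij / √(θ_ii θ_jj)` from a sparse precision matrix
  Θ fitted by the graphical lasso, which maximizes
  `log det Θ − tr(SΘ) − λ Σ_{i≠j} |θ_ij|` over a descending λ path.  λ is
  selected by the extended BIC, `EBIC = −2L + E log n + 4γ E log p` with
  `γ = 0.5` by default.
* **Centrality.** Strength `Σ_j |w_ij|`, one-step expected influence
  `Σ_j w_ij`, and closeness / betweenness on shortest paths with edge
  lengths `1/|w_ij|`.
* **Stability.** Nonparametric bootstrap CIs for edge weights, and the
  case-dropping subset bootstrap: the CS-coefficient is the largest
  proportion of participants that can be dropped while the correlation
  between original and subset centralities stays ≥ 0.7 with 95%
  probability.
* **Group comparison (NCT).** Permutation test of network invariance
  (`M = max_{i<j} |w_ij^A − w_ij^B|`) and global-strength invariance
  (`S = |Σ|w^A| − Σ|w^B||`), with per-edge difference tests classified as
  strengthened / weakened / lost / new link.
* **Bridge centrality.** Per node, the summed absolute (bridge strength)
  and signed (bridge expected influence) weight crossing between the
  a-priori item communities (GSES vs PHQ-9).
* **Simulation.** A latent-Gaussian threshold generator that draws ordinal
  two-group samples from planted partial-correlation networks, with group
  differences injected as edge edits and an exact global-strength gap.
* **Descriptives.** Pooled-variance t tests, Cohen's d, (Yates-corrected)
  chi-square and Pearson correlation tables for the demographic comparison.

## Worked example

```python
from psynet import (AnalysisConfig, GeneratorConfig, run_full_analysis)

cfg = AnalysisConfig(
    generator=GeneratorConfig(n_control=3094, n_depressed=560),
    estimator={"n_lambda": 50},
    stability_B=250, nct_iterations=1000, seed=1,
)
report = run_full_analysis(cfg)
print(report.network_summaries["depressed"]["nonzero_edges"],
      report.network_summaries["depressed"]["global_strength"])
print(report.nct_summary)
```

prints (seed 1):

```
42 4.133...
{'M': 0.159..., 'S': 0.285..., 'p_M': 0.00999..., 'p_S': 0.000999...,
 'global_strength_a': 4.418..., 'global_strength_b': 4.133..., ...}
```

i.e. the simulated depressed group's self-efficacy network keeps 42 of 45
possible edges with global strength 4.13 versus 4.42 in the control group;
the permutation test rejects both structural invariance (M = 0.159,
p = 0.01) and global-strength invariance (S = 0.285, p = 0.001),
recovering the planted weakening of the depressed group's network.

The same pipeline runs from the shell:

```bash
psynet simulate --seed 1 --out sim/          # two-group CSV + ground truth
psynet report   --seed 1 --out results/      # full study report
psynet compare  --data-a a.csv --data-b b.csv --seed 1 --out nct/
```

## Layout

```
src/psynet/
  scales.py        GSES/PHQ-9 I/O, scoring, depression classification
  descriptives.py  pooled t, Cohen's d, chi-square, correlation tables
  simulate.py      planted-network two-group Likert generator
  _glasso.py       graphical-lasso coordinate-descent kernel (numba)
  ggm.py           correlation input, EBIC path selection, network summaries
  centrality.py    strength, closeness, betweenness, expected influence
  stability.py     edge bootstrap, case-dropping bootstrap, CS-coefficient
  nct.py           permutation network comparison test, edge change table
  bridge.py        bridge strength / expected influence across communities
  pipeline.py      end-to-end study pipeline and report export
  cli.py           click command-line interface
```

See `docs/methods.md` for the statistical conventions, generator design
and known limitations.
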