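# evosel

Wrapper-based feature selection for multi-class expression data, with
survival-analysis evaluation of the selected biomarker panel.

## The problem

Multi-class cancer classification from miRNA-seq expression poses a
combinatorial question: which small panel of features (miRNAs) carries the
signal that separates the cancer types? Filter statistics score features one
at a time and miss interactions; exhaustive subset search is infeasible.
`evosel` implements a stochastic wrapper strategy:

1. **Feature reordering by stochastic neighbor embedding (SNE).** Features
   are standardized, treated as points, and embedded into one dimension by
   minimizing the Kullback-Leibler divergence between row-conditional
   Gaussian neighbor distributions, `KL(P‖Q) = Σᵢ Σⱼ pᵢⱼ log(pᵢⱼ/qᵢⱼ)`.
   Sorting along the embedding axis places highly correlated features next
   to each other — an implicit clustering.
2. **Subset search by CMA-ES.** A covariance matrix adaptation evolution
   strategy samples weight vectors `w ∈ ℝᴰ` from `N(m, σ²C)`; a feature `i`
   is selected when `wᵢ ≥ t` (threshold `t = 0.5`). Each decoded subset `S`
   is scored by stratified 5-fold cross-validated accuracy of a pluggable
   classifier (RF / SVM / NB / K-NN / DT) under a size penalty

   `f(x) = accuracy(S) − α·max(0, |S| − Υ)/D`

   with `α = 0.5` and target panel size `Υ`. CMA-ES updates its mean by
   weighted recombination of the μ best solutions, its covariance by
   rank-one (evolution path) plus rank-μ updates, and its step size by
   cumulative step-size adaptation.
3. **Stabilization across runs.** The search is repeated R times; features
   are ranked by how often they appear in run-best subsets, and a
   forward-selection scan over cumulative prefixes of the ranked list picks
   the final panel with maximal cross-validated accuracy. The expected
   number of distinct features seen after R runs under uniform selection,
   `E = D − D(1 − S/D)ᴿ`, quantifies when additional runs stop adding
   information (at `D = 199`, `S = 10`, `R = 50` the integer part is 183
   and one further run adds ≈ 1 new feature).
4. **Survival evaluation.** Each selected feature is assessed by univariate
   Cox proportional-hazards regression `h(τ, x) = h₀(τ)exp(xβ)` fitted by
   Newton–Raphson on the Breslow-tie partial likelihood, with the Breslow
   cumulative baseline hazard, hazard ratio `exp(β)`, Wald p-values,
   two-group ANOVA up/down-regulation calls with Benjamini–Hochberg FDR,
   and miRNA–target negative-correlation ranking across cancer types.

## Worked example

```python
from evosel import (ClassifierSpec, ExpressionSimDesign, RunConfig,
                    SubsetSelectionModel, simulate_expression)

design = ExpressionSimDesign(n_classes=5, samples_per_class=30,
                             n_features=50, informative_per_class=1,
                             effect_delta=2.0, seed=100)
X, y, truth = simulate_expression(design)

cfg = RunConfig.desk(classifier=ClassifierSpec(kind="knn"),
                     upsilon=5, master_seed=200)
result = SubsetSelectionModel(X, y, cfg).fit()
print(result.summary())
```

```
Subset selection results
========================================================
runs: 10  generations: 30  population: 20
classifier: knn  cv folds: 5
selected 9 features (cv accuracy 0.7733):
  feat0000, feat0001, feat0002, feat0003, feat0004, feat0015, feat0017, feat0019, feat0036

top of frequency ranking:
feature               freq  mean value
feat0000                10      0.7257
feat0001                10      0.7257
feat0002                10      0.7257
feat0003                10      0.7257
feat0004                10      0.7257
feat0036                 4      0.7192
feat0015                 3      0.7078
feat0017                 2      0.7350
feat0019                 2      0.7350
feat0028                 2      0.7350
```

The five planted informative features (`feat0000`–`feat0004`, one per
class, shifted by 2 noise SD in their class) head the selected panel; the
panel's stratified 5-fold K-NN accuracy is 0.773 against a 0.2 chance
level for five balanced classes. Survival evaluation of a feature:

```python
from evosel import UnivariateCox, SurvivalSimDesign, simulate_survival

x, records = simulate_survival(SurvivalSimDesign(n=400, beta_true=0.7, seed=5))
fit = UnivariateCox(x, records).fit()
print(fit.summary())
```

```
Univariate Cox proportional hazards
====================================================
      coef        HR        se       z           p
    0.6306    1.8788    0.0653    9.65   4.768e-22
95% CI for coef: [0.5026, 0.7587]
converged: True after 4 iterations
log partial likelihood: -1541.1820
```

The simulated truth is β = 0.7 (hazard ratio e^0.7 ≈ 2.01); the fit
recovers it within 1.1 standard errors, and the Wald test firmly rejects
the null of no association.

A command-line interface mirrors the library:
`evosel simulate`, `evosel select`, `evosel coverage -D 199 -S 10 -R 50`,
`evosel cox`, and `evosel associate`.

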