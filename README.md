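# ricotype

Cooking-quality **ideotype** analysis for indica rice panels.

Breeding programs traditionally classify cooked-rice texture by amylose
content (AC), yet accessions within the same AC class can still cook and
taste differently. `ricotype` implements the multivariate route to finer
classes: extract a 25-variable quality panel per accession from instrument
traces — RVA pasting curves, oscillatory rheometry sweeps, and two-cycle
texture-profile analysis (TPA) — prune correlation-redundant variables,
group accessions by Ward clustering, characterise the resulting quality
clusters, and identify which variables drive membership using multinomial
logistic regression and random-forest permutation importance. A synthetic
data module generates every input (curves with planted landmarks,
cluster-structured panels, sensory score sets), so the whole pipeline runs
and is tested without any external data.

It is written for grain-quality and food-phenomics researchers who want a
scripted, reproducible version of this analysis for their own panels.

## The models in brief

**Curve features.** From a rheometry sweep (35→95→35 °C at 4 °C min⁻¹) the
package extracts the gel point (first crossing of tan δ = G″/G′ through 1 on
heating), G′max, G″ at G′max, tan δ at G′max, G′trough, and the slopes
S1–S4 between these landmarks. From an RVA heat–hold–cool trace: peak (PV),
trough (TV) and final (FV) viscosities, with breakdown BD = PV − TV,
setback SB = FV − PV and lift-off LO = FV − TV (so LO = BD + SB exactly),
peak time and pasting temperature. From a TPA trace: hardness (first-peak
force), adhesiveness (pull-off work), cohesiveness (lobe-area ratio) and
springiness (downstroke-time ratio T2/T1).

**Classification.** With cluster k as an unordered response, each sample i
gets a linear score f(Xᵢ, k) = βₖ·Xᵢ (reference cluster scored 0) and class
probabilities by softmax; coefficients are fit by maximum likelihood.
Predictors enter by forward stepwise selection under AIC =
deviance + 2·(free parameters); retained variables are tested by
likelihood-ratio χ² (df = number of non-reference clusters) and the fit is
summarised by McFadden, Cox & Snell and Cragg & Uhler pseudo-R².
Per-cluster variable importance is the out-of-bag permutation importance of
a 500-tree random forest with 3 candidate variables per split.

## Worked example

```python
import ricotype as rt

bundle = rt.run_pipeline(rt.PipelineConfig(seed=1))
s = bundle["summary"]
print(s["n_variables"])          # {'input': 25, 'pruned': 19, 'selected': 8}
print(s["cluster_sizes"])        # {1: 94, 2: 83, 3: 34}
print(round(s["accuracy_pct"], 2), round(s["aic"], 2))   # 91.0 119.95
print({k: round(v, 2) for k, v in s["pseudo_r2"].items()})
# {'mcfadden': 0.81, 'cox_snell': 0.81, 'cragg_uhler': 0.93}
```

This generates a 211-accession synthetic panel at the study-scale cluster
moments (three clusters, generating sizes 114/70/27), prunes the six
redundant variables (the |r| > 0.75 partners of GT, PV and G′max), Ward-cuts
at k = 3, selects predictors by forward AIC and reports the fit: here 8 of
19 variables retained, 91.0 % resubstitution accuracy, and pseudo-R² in the
0.8–0.95 range. The same stages are available as numbered drivers:

```bash
python analysis/01_simulate.py --seed 1   # curves, panel, sensory scores
python analysis/02_extract_features.py    # landmark extraction + identities
python analysis/03_prune_panel.py         # Pearson matrix, 25 -> 19 variables
python analysis/04_cluster.py             # Ward k=3, profile table
python analysis/05_classify.py --seed 1   # forward-AIC logit, LR, forests
python analysis/06_sensory.py             # 150-mm line-scale summaries
```

Each writes its tables under `results/`.

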