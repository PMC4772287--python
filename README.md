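# regact

Tools for asking "which transcription factors best explain the expression
of this gene?" — and for following the answer into the clinic.

The motivating problem is the regulation of MITF, the master regulator of
melanocytes and melanoma cells, whose expression level steers a tumour
between proliferative and invasive states. `regact` implements the full
modelling chain for this kind of question:

1. **Evidence integration** — per-source TF→target binding evidence
   (curated direct/indirect annotations, ChIP compendia, consortium ChIP
   matrices, promoter total-binding-affinity z-scores) is filtered by
   reliability rules and condensed into a numeric *edge strength* es_{t,i}.
2. **TF activity** — the activity of TF *t* in sample *j* is the
   edge-strength-weighted mean of its targets' z-scored expression:
   act_{t,j} = Σ_i es_{t,i} g_{i,j} / Σ_i es_{t,i}.
3. **Best-subset LAD regression** — the modelled gene's expression is
   predicted as g̃_j = β0 + Σ_t β_t act_{t,j} by minimising Σ_j |g_j − g̃_j|
   with at most k nonzero coefficients, solved to global optimality as a
   mixed-integer linear program (HiGHS). A bottom-up scan over k with
   leave-one-out cross-validation ranks regulator sets; frozen models
   transfer to independent cohorts.
4. **Clinical models** — an L1 linear model of Breslow thickness on gene
   expression, T-stage thickness subgroups, and a 10-fold cross-validated
   maximally-selected survival cutpoint with a selection-corrected log-rank
   p-value.
5. **qPCR quantification** — ΔΔCt fold changes from Ct triplicates.
6. **Synthetic data** — a generator with planted activator/inhibitor
   regulators, a bimodal regulator analogue, and linked clinical tables, so
   the whole pipeline is testable without any external download.

Intended users: computational biologists modelling transcriptional
regulation from expression panels plus public binding evidence, and anyone
needing honest cardinality-constrained L1 regression with cross-validation.

## Worked example

```python
from regact import (GroundTruth, RegressionProblem, bottom_up_scan,
                    generate_regulatory_dataset, transfer_predict)

# 19 candidate TFs, 40 samples; planted activator TF01 (+1.5) and
# bimodal inhibitor TF02 (-1.0), response noise sigma = 0.2
data = generate_regulatory_dataset(GroundTruth(seed=7))
problem = RegressionProblem(data.activities, data.response)

scan = bottom_up_scan(problem, k_max=2)
print(scan.to_frame().to_string(index=False))
```

```
 k  selected  objective   cv_pcc
 1      TF01  34.378277 0.704828
 2 TF01,TF02   6.292721 0.988371
```

Each row is an independently fitted model with at most k regulators:
`objective` is the in-sample sum of absolute errors and `cv_pcc` the
Pearson correlation between held-out LOO predictions and the measured
response. The solver finds the planted activator alone at k = 1 and both
planted regulators at k = 2, where held-out performance jumps to r ≈ 0.99.

```python
model = scan.rows[-1]["model"]
print({t: round(v, 3) for t, v in model.coefficients[model.selected].items()},
      round(model.intercept, 3))
# {'TF01': 1.489, 'TF02': -0.97} 0.462   (truth: +1.5, -1.0, 0.5)

cohort_b = generate_regulatory_dataset(GroundTruth(seed=7), n_samples=33, seed=99)
_, r = transfer_predict(model, cohort_b.activities, cohort_b.response)
print(f"transfer r = {r:.3f}")
# transfer r = 0.992
```

The frozen coefficients predict an independently generated 33-sample
cohort with r = 0.992 — the cross-dataset check that separates a real
regulatory signal from within-panel overfitting.

A command-line interface mirrors the library
(`regact simulate | integrate-evidence | normalize | activity | fit | scan |
cv | transfer | cutpoint | thickness-fit | thickness-groups | ddct`), reading
and writing tab-separated files with provenance headers.

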