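# kernelfuse

Kernel-level fusion of clinical and gene-expression data for binary outcome
prediction — a **weighted LS-SVM classifier** in which the patient-similarity
kernel built from a small mixed-type clinical record is weighted by the
kernel built from the high-dimensional expression profile, plus the
companion **kernel GEVD** score pipeline, leave-one-out hyperparameter
selection, and a repeated stratified-holdout AUC benchmark.

The intended user is a biostatistician or machine-learning researcher who
has, for each patient, (i) an expression matrix (samples × genes), (ii) a
clinical table of continuous / ordinal / nominal variables, and (iii) a
binary outcome (relapse, treatment response, mutation status, …), and who
wants a single classifier that exploits both views instead of choosing
between them.

## The model

A least-squares SVM trains by one linear solve.  The fusion variant
regresses the labels on the clinical view's feature map φ₁ while weighting
the residual vector e by the inverse covariance of the centered expression
feature map Φ₂c:

```
min_{v,e,b}  (γ/2) eᵀ(Φ₂cᵀΦ₂c)⁻¹e + (1/2) vᵀv    s.t.  y = Φ₁cᵀv + b·1 + e
```

Residual directions that the cohort's expression profiles vary in are cheap;
directions orthogonal to the expression structure are penalized hard.  In
the dual everything collapses onto the two centered Gram matrices:

```
[ 0    1ᵀ              ] [ b ]   [ 0 ]
[ 1    Ω₁c + γ⁻¹ Ω₂c   ] [ α ] = [ y ],      f(x) = Σᵢ αᵢ[K₁(x,xᵢ) + γ⁻¹K₂(x,xᵢ)] + b
```

so mixed-type clinical data and 10³–10⁴-dimensional expression data enter
through same-sized N × N kernel matrices.  Dropping the labels and
maximizing weighted projected variance instead gives kernel GEVD,
`Ω₁c α = λ Ω₂c α`, whose dual directions provide low-dimensional patient
scores for a downstream LS-SVM.  Hyperparameters (σ₁, σ₂, γ) are selected
by the AUC of pooled leave-one-out decision values on the training set.
See `docs/methods.md` for assumptions, conventions and edge cases.

## Worked example

```python
import numpy as np
from kernelfuse import SyntheticConfig, generate_two_view, run_benchmark

# a 120-patient cohort, 2000 genes, 7 mixed-type clinical variables,
# 30% positives, moderate complementary signal in both views
ds = generate_two_view(SyntheticConfig(n_samples=120, seed=1))

res = run_benchmark(
    ds,
    methods=("cl_lssvm", "ma_lssvm", "weighted_lssvm"),
    n_reps=10,                                # stratified 2/3-1/3 splits
    sigma_multipliers=(0.5, 1.0, 2.0),        # RBF bandwidth grid per view
    gamma_values=(0.01, 1.0, 100.0),          # regularization grid
)
print(res.summary().round(4))
```

which prints

```
                mean_auc  std_auc  p_vs_reference
cl_lssvm          0.9179   0.0270           0.002
ma_lssvm          0.7964   0.0639           0.002
weighted_lssvm    0.9396   0.0241             NaN
```

`cl_lssvm` and `ma_lssvm` are single-view RBF LS-SVMs on the clinical and
expression data; `weighted_lssvm` is the fusion classifier.  Each mean/std
summarizes the per-repetition test AUCs (every method sees the same splits,
is tuned by LOO-CV on each training set, and is scored on continuous
decision values); `p_vs_reference` is the two-sided paired Wilcoxon
signed-rank p-value against the weighted LS-SVM — here the fusion model
outperforms both single views (p = 0.002 with 10 paired repetitions).

The same machinery is scriptable from the shell:

```bash
kernelfuse simulate --n-samples 120 --seed 1 --outdir data/
kernelfuse gridsearch --datadir data/ --method weighted_lssvm --out cv_table.tsv
kernelfuse benchmark --datadir data/ --n-reps 100 --outdir results/
```

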