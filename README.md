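# rxncontext

Joint chemical-context prediction for Buchwald–Hartwig coupling reactions.

Choosing the *chemical context* of a C–N coupling — the palladium
(pre-)catalyst, the ligand, the base, the solvent and any further reagents —
is the step that most often decides whether the reaction works at all.
`rxncontext` predicts that context **jointly**, as one categorical label per
known context, instead of predicting each species independently and hoping
the pieces are compatible. It is aimed at synthesis-planning and
reaction-automation work where recommendations must come from a fixed menu of
lab-proven condition sets.

## The method

A reaction *record* is one transformation (aryl halide + amine → coupled
product); each *variation* of a record is one experimental run with a
specific context, a yield and a date. The pipeline:

1. **Context construction.** Context chemicals are assigned one of six roles
   (catalyst, pre-catalyst, ligand, base, solvent, reagent) from curated
   lists, with a Pd/Pt-element fallback for catalysts. The canonically
   sorted species per category form a context key; the `k = 30` most common
   contexts (after discarding variations with yield `< 20 %`) define the
   label space.
2. **Featurization.** Each molecule is a 1024-bit fingerprint (512-bit
   extended-connectivity, radius 3, concatenated with a 512-bit path
   fingerprint, maximum path length 7). The model input is the *difference
   fingerprint* `fp(product) − Σ fp(reactant)`, an integer vector whose
   negative entries are substructure environments lost in the reaction and
   positive entries environments gained.
3. **Models.** Two feed-forward networks:
   the **single-label** model (1×1024 hidden, dropout 0.60, Adam,
   lr 6.1·10⁻⁴, 10 epochs, batch 64, softmax) trains on the highest-yield
   context per record with categorical cross-entropy weighted by yield;
   the **multi-label** model (1×512 hidden, dropout 0.64, lr 9.2·10⁻⁴,
   20 epochs, softmax by default, sigmoid available) trains on the
   bitwise-or of all recorded contexts with binary cross-entropy.
4. **Evaluation.** Top-*k* accuracy, label ranking average precision (LRAP),
   samples-averaged Jaccard, the rank curve (rank of the worst-ranked true
   context ÷ number of true contexts), per-context sensitivity/specificity,
   top-1/top-3 confusion likelihood matrices, partial-agreement scoring by
   category, and popularity baselines.
5. **Temporal analysis.** Per-year context-usage matrices and a year-ranged
   retraining experiment quantifying how models trained on stale eras
   degrade — context usage drifts as new catalyst/ligand systems replace old
   ones.

Real ELN reaction data of this kind is proprietary, so the package ships a
**synthetic generator** that emulates its statistical shape (long-tailed
context popularity with mean imbalance ratio ≈ 7, label cardinality ≈ 1.03,
86 % single-variation records, yields ≥ 20 % with a small sub-20 tail, a
context-replacement event mid-range) while planting a *learnable* rule:
the preferred context is a function of the aryl halide (Cl/Br/I), the amine
class (primary/secondary aliphatic, aniline, cyclic secondary) and steric
hindrance — all visible to circular fingerprints by construction, so models
can be scored against an exact ground truth.

## Worked example

```python
import numpy as np
import rxncontext as rc
from rxncontext import evaluate

ds = rc.generate(rc.rule_recovery_config(seed=1))   # 2000 records, 8 contexts
result = rc.filter_and_label(ds, k=8)
X = rc.featurize_examples(result.single_table)
Y = np.stack([ex.label_vector for ex in result.single_table])

bundle = rc.train(result.single_table, X,
                  rc.default_config("single", seed=0),
                  result.label_space, split_seed=0)
va = bundle.val_indices
scores = rc.predict(bundle, X[va])
print(f"top-1 {evaluate.topk_accuracy(scores, Y[va], 1):.3f}",
      f"top-3 {evaluate.topk_accuracy(scores, Y[va], 3):.3f}")
```

prints (RDKit 2024.09.2, single CPU):

```
top-1 0.897 top-3 0.934
```

With 10 % label noise the attainable top-1 is about 0.9: the model has
essentially recovered the planted rule. (The popularity baseline on the same
split is top-1 0.348 / top-3 0.624; `models.benchmark_single_config()`, the
configuration selected by the package's tuner for this benchmark, reaches
mean top-3 ≈ 0.955 over three runs.) The scripts in `examples/` walk
through dataset inspection, multi-label training, and the temporal-drift
experiment the same way; `rxncontext --help` exposes the same pipeline as
shell subcommands (`simulate`, `prepare`, `train`, `evaluate`, `temporal`,
`tune`) for config-driven reproducible runs.

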