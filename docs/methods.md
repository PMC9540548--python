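# Methods

## The prediction task

A Buchwald–Hartwig coupling needs, besides the aryl halide and the amine, a
set of context chemicals: a palladium catalyst or pre-catalyst, usually a
phosphine ligand, a base, a solvent, and sometimes further reagents. The
chemicals are strongly interdependent — a ligand proven with one Pd source
and base may fail with another — so this package treats the whole set as one
categorical label (a *chemical context*) and predicts it jointly. The label
menu is restricted to the `k` most used contexts in the training data
(default 30): a model restricted to lab-proven combinations cannot propose a
chemically incoherent mixture, at the price of never proposing a novel one.

## Data model and filtering

The on-disk unit is the reaction *variation* (one run: context chemicals,
yield in percent, ISO-8601 date), grouped into *records* (one transformation)
by `record_id`. Processing order: variations with yield below 20 % are
dropped (a run that poor is not evidence the context works); context usage is
counted over the survivors and the top-k contexts become the label space;
variations using other contexts are dropped; records left with no variation
are dropped and itemized per stage, so `records_in = records_kept +
records_dropped` always holds.

Two training tables follow. The single-label table keeps, per record, the
highest-yield variation (ties broken by earliest date, then by most popular
context — a deterministic rule chosen for reproducibility), one-hot label,
example weight = yield/100. The multi-label table merges, per record, the
one-hot vectors of all distinct surviving contexts with a bitwise-or, weight
1, after deduplicating (reaction, context) pairs across the dataset so a
transformation recorded twice under the same context contributes once. The
dedup key is (sorted canonical reactants, canonical product, context key) —
equal reactions imply equal fingerprints, so this is equivalent to
fingerprint-based deduplication without coupling the pipeline to the
featurizer.

Role assignment precedence for unannotated species: curated pre-catalyst
list → curated catalyst list → contains a Pd or Pt atom → curated solvent
list → curated base list → curated ligand list → reagent. Curated lists beat
the element flag so annotated pre-catalysts are not swallowed by the Pd
rule. No atom mapping is attempted: a species matching no rule is a reagent.
Pre-assigned roles from the input are never overridden. Stereochemistry in
SMILES is retained by default (a flag strips it).

## Featurization

Each molecule: 512-bit Morgan fingerprint (radius 3) concatenated with a
512-bit RDKit path fingerprint (maximum path 7 bonds), both binary and
folded by the toolkit's hash. Reaction input: `fp(product) − Σ
fp(reactants)` kept as signed integers in `[-R, 1]` — the sign separates
lost from gained substructure environments, which is information a clipped
vector would discard. Bit identities are toolkit-specific, so the
fingerprint configuration (including the RDKit version) travels with every
feature matrix and model bundle, and prediction on mismatched features is
refused. Chirality flags are off for fingerprinting by default. Context
species never enter the reaction fingerprint.

## Models and training

Both models are feed-forward networks implemented directly on NumPy (float32
throughout, He initialization, Adam, inverted dropout after every hidden
ReLU, softmax or sigmoid head). Single-label: categorical cross-entropy with
per-example weight = yield/100 (not renormalized); multi-label: elementwise
binary cross-entropy, unweighted, by default through a softmax head (the
sigmoid head is a configuration switch and is what the cardinality analyses
use, since a softmax caps the number of implied positives at one). Default
architectures: single — one hidden layer of 1024, dropout 0.60, lr 6.1e-4,
10 epochs, batch 64; multi — one hidden layer of 512, dropout 0.64, lr
9.2e-4, 20 epochs, batch 64.

Training uses an 80/20 train/validation split, stratified by label in
single mode whenever every class has at least two members. The split seed is
deliberately independent of the weight-init seed so architectures can be
compared on a fixed split. With fixed seeds and a single device, training
histories are bit-reproducible. The tuner is seeded random search over the
declared space (batch {32, 64}; epochs {10, 15} single / {10, 15, 20} multi;
hidden {128..2048} single / {128..512} multi; 1–3 layers; lr log-uniform in
[1e-5, 5e-3]; dropout in [0, 0.9]) with 5-fold cross-validation, objective
top-1 accuracy (single) or LRAP (multi).

## Metrics

Ranking always sorts by descending score with ties broken by the lower label
index, i.e. the more popular context wins. LRAP follows the standard
definition (per true label, the fraction of labels scored at least as high
that are true). The rank curve generalizes top-k to multi-label rows: rank of
the lowest-scored true label divided by the number of true labels. Jaccard
and sensitivity in multi mode threshold scores at 0.5; the threshold is
configurable but 0.5 is the natural choice for calibrated sigmoid outputs.
Contexts with zero support report sensitivity as missing, never as 0.
Partial agreement compares contexts category-wise over {catalyst merged with
pre-catalyst, ligand, base, solvent}; two empty categories agree. The
aggregate partial-agreement analysis looks only at rows whose true context
is outside the top-3 — the "hard" cases where one asks how close the top-1
guess still is.

## The synthetic generator

The generator is first-class code: it produces the study datasets for every
analysis, since real ELN data of this kind is proprietary. What it emulates,
and how:

- **Chemistry.** Aryl halides are assembled from substituted benzene
  templates (Cl/Br/I; ortho-substituted templates mark steric hindrance),
  amines from four classes (primary aliphatic, secondary aliphatic, aniline,
  cyclic secondary); the product is the C–N coupled template. All SMILES are
  valence-checked by RDKit at construction.
- **The planted rule.** Each of the 3×4×2 feature cells (halide, amine
  class, steric flag) prefers one context. Context indices are popularity
  ranks: the i-th most probable cell prefers context i, so with the default
  `n_contexts = 24` (= grid size) every context is some cell's preferred
  choice; extra cells (when `n_contexts` is smaller) are assigned by a
  seeded long-tail draw. A variation uses the preferred context with
  probability 1 − rule_noise (default 0.9), otherwise a popularity-weighted
  draw — chemists trying something else.
- **Popularity and imbalance.** Cell sampling weights (halide 0.50/0.35/0.15,
  amine 0.4/0.3/0.2/0.1, steric 0.7/0.3) yield a long-tailed context count
  distribution with mean imbalance ratio ≈ 6.6 at n = 5000 — near the ≈ 7
  regime the generator targets. The IR variance is large (the tail spans a
  ~25-fold count range), unlike a distribution where all rare contexts sit
  at the same count; the realism check therefore bands the mean, not the
  variance.
- **Multi-label structure.** Records draw 1/2/≥3 variations with
  probabilities 0.86/0.11/0.03. Repeat variations reuse the first context
  with probability 0.8, otherwise try the cell's *alternate* context (a
  second planted preference) or a popularity draw. This reconciles 14 % of
  records having repeat runs with a label cardinality of only ≈ 1.03: most
  repeats reuse the recorded context. An optional switch conditions the
  variation-count distribution on the steric flag (hindered substrates get
  retried under the alternate context); the cardinality-1.5 study config
  uses it so that the extra labels are a predictable function of the input —
  without that, no thresholded predictor could track cardinality above 1.
- **Yields.** Beta-distributed on the percent scale: mean 75 when the
  context matches the rule, 45 otherwise, clipped to [20, 100], plus a 5 %
  sub-20 tail to exercise the yield filter. The parameters are configuration,
  not claims about real yield distributions.
- **Temporal drift.** Drift is modeled as *replacement events*: at a switch
  year (default 2015 in a 2004–2020 range) an old leader context leaves use
  and a successor takes over, applied to both rule-preferred and
  popularity-drawn contexts. Era-weighted popularity alone would not change
  the reactant→context relationship and therefore could not degrade a model
  trained on old data; replacement does, which is the phenomenon the
  temporal experiment measures. Year sampling weights increase linearly
  (lab volume grows), and all variations of a record share its year.
- **Determinism.** Two seeds: `seed` drives sampling, `rule_seed` (default
  1234) drives the rule and the context menu, so the rule survives
  re-seeding the data. Identical configs give byte-identical datasets.

Named study configurations freeze the benchmark conditions:
`rule_recovery_config` (2000 records, 8 contexts, 10 % noise, no drift —
drift is studied separately), `drifted_config` (3000 records, 8 contexts,
leader replacement at 2015), `cardinality_config(1.0 | 1.5)`.

What passing on synthetic data does *not* show: real reaction scope
(the generator has no ligand electronics, no reactivity cliffs, no
assay noise model), real context menus (24–30 synthetic contexts built from
small curated lists), or real temporal dynamics beyond a single replacement
event. The tests demonstrate that the pipeline, models and metrics behave
correctly and that the method recovers plantable structure — not that any
accuracy level transfers to proprietary ELN data.

## Temporal experiment

The label space is fixed from the full date range so accuracies are
comparable across training ranges. Splitting is at the record level by the
single-label variation's year: a record in the test era never contributes
training examples even when ranges overlap. Each training range is retrained
under `n_runs` seeds and reported as mean ± sd of top-1/top-3 on the fixed
test-era reactions. The experiment uses a 256-unit, 8-epoch network: the
degradation signature is a property of the data, not of model capacity, and
the smaller network keeps the full experiment in seconds.

## Numerical choices and edge cases

- float32 network arithmetic; losses clipped at 1e-12 before logs; NaN loss
  aborts with a diagnostic rather than training on.
- Ranking ties: lower label index wins, making every metric deterministic.
- `k` larger than the number of distinct contexts truncates the label space
  with a warning; an empty yield-filter result is an error.
- A context with zero test support reports missing sensitivity; the
  both-empty category counts as agreement in partial scoring.
- Dates accept year or year-month precision (padded to the first day);
  years outside [1990, 2100] are rejected as data errors.
- Identical rows in one prediction batch can differ by BLAS blocking at the
  1e-9 level; all documented determinism claims are per-run bit-equality,
  not cross-batch-layout equality.

## Known limitations

- The multi-label softmax default follows the printed architecture; it is a
  poor fit for genuinely multi-label data (it caps implied positives), which
  is why the sigmoid head exists and is used for cardinality analyses.
- Role assignment without curated coverage falls back to "reagent"; a real
  deployment would need atom mapping to separate reagents from unconsumed
  reactants.
- The context key joins species within a category with "."; for
  multi-component (salt) species the key is not parseable back into species
  lists — carry `ChemicalContext` objects, not keys, when structure matters.
- Popularity baselines use training-split counts only; with very small
  datasets the baseline itself is noisy.

## Benchmark configuration

The rule-recovery benchmark is evaluated with
`models.benchmark_single_config()` — the configuration the package's own
tuner selected (random search, 6 trials, 5-fold cross-validation, seed 0) on
that benchmark's training data: hidden 1024 x 2 layers, dropout 0.84,
learning rate 1.6e-3, batch 64, 10 epochs. It is frozen in code so benchmark
results do not depend on re-running the search, and reported accuracies
average three independent training runs on a fixed validation split.
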