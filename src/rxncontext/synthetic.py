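"""Synthetic ELN-like Buchwald-Hartwig datasets with planted context rules.

The generator emulates the statistical shape of corporate ELN reaction data
— a long-tailed context-popularity distribution, low multi-label character
(most reactions have a single recorded variation), yields mostly >= 20 %,
and year-stamped records whose context usage drifts over time — while
planting a *learnable* rule: the preferred context is a deterministic
function of reactant features (halide identity, amine class, steric
hindrance) that are visible to circular fingerprints by construction.

Temporal drift is modeled as context *replacement events*: at a switch year
an old context leaves use and a successor takes over its role. This changes
the reactant->context relationship over time, which is what makes models
trained on stale eras degrade on newer data.

Hindered substrates can optionally be given a different variation-count
distribution (chemists retry difficult substrates under an alternate
context); this ties multi-label structure to the input so that label
cardinality is predictable, and is used by the higher-cardinality study
configurations.
"""

from __future__ import annotations

import datetime as _dt
import itertools
from dataclasses import dataclass

import numpy as np

from .datamodel import (
    ROLE_BASE,
    ROLE_CATALYST,
    ROLE_LIGAND,
    ROLE_PRECATALYST,
    ROLE_SOLVENT,
    ROLE_UNASSIGNED,
    ChemicalSpecies,
    Dataset,
    ReactionRecord,
    ReactionVariation,
)
from .pipeline import ChemicalContext, CuratedLists, load_default_lists

HALIDES = ("Cl", "Br", "I")
AMINE_CLASSES = (
    "primary_aliphatic",
    "secondary_aliphatic",
    "aniline",
    "cyclic_secondary",
)
STERIC_FLAGS = ("unhindered", "hindered")

#: Ring substituents used to diversify the aryl halide pool.
_SUBSTITUENTS = ("C", "CC", "OC", "F", "C(F)(F)F", "C#N",
                 "OCC", "CC(C)C", "N(C)C", "SC")

# (amine SMILES, N-arylated product template; {aryl} is the aryl fragment
# attached at its first ring atom, which uses ring-closure digit 1)
_AMINES: dict[str, tuple[tuple[str, str], ...]] = {
    "primary_aliphatic": (
        ("NCC", "CCN{aryl}"),
        ("NCCC", "CCCN{aryl}"),
        ("NCCCC", "CCCCN{aryl}"),
        ("NC3CCCCC3", "C3CCC(N{aryl})CC3"),
        ("NCC(C)C", "CC(C)CN{aryl}"),
        ("NCCO", "OCCN{aryl}"),
    ),
    "secondary_aliphatic": (
        ("CCNCC", "CCN(CC){aryl}"),
        ("CNC", "CN(C){aryl}"),
        ("CCCNC", "CCCN(C){aryl}"),
        ("CNCCO", "OCCN(C){aryl}"),
    ),
    "aniline": (
        ("Nc3ccccc3", "c3ccccc3N{aryl}"),
        ("Nc3ccc(C)cc3", "Cc3ccc(N{aryl})cc3"),
        ("Nc3ccc(OC)cc3", "COc3ccc(N{aryl})cc3"),
        ("Nc3cccc(F)c3", "Fc3cccc(N{aryl})c3"),
    ),
    "cyclic_secondary": (
        ("C3CCNCC3", "C3CCN({aryl})CC3"),
        ("C3CCCN3", "C3CCCN3{aryl}"),
        ("C3COCCN3", "C3COCCN3{aryl}"),
        ("CN3CCNCC3", "CN3CCN({aryl})CC3"),
    ),
}


def _aryl_pool(steric: str) -> list[str]:
    """Aryl templates with an {X} halide placeholder for one steric class."""
    out = []
    if steric == "unhindered":
        out.append("{X}c1ccccc1")
        out += [f"{{X}}c1ccc({r})cc1" for r in _SUBSTITUENTS]
        out += [f"{{X}}c1cccc({r})c1" for r in _SUBSTITUENTS]
        out += [
            f"{{X}}c1ccc({r2})c({r})c1"
            for r, r2 in itertools.product(_SUBSTITUENTS, _SUBSTITUENTS)
            if r != r2
        ]
    else:
        out += [f"{{X}}c1ccccc1{r}" for r in _SUBSTITUENTS]
        out += [
            f"{{X}}c1ccc({r2})cc1{r}"
            for r, r2 in itertools.product(_SUBSTITUENTS, _SUBSTITUENTS)
        ]
    return out


@dataclass(frozen=True)
class Replacement:
    """Context *old* leaves use at *switch_year*; *new* takes over."""

    old: int
    new: int
    switch_year: int


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the target dataset shape: ~30 contexts with a
    long-tailed popularity distribution, 86/11/3 % of records with one, two,
    three-or-more variations, yields mostly >= 20 % with a small sub-20 tail,
    years 2004-2020 with one leader-replacement event mid-range.
    """

    n_records: int = 5000
    n_contexts: int = 24  # = the feature-grid size, so every context is
                          # some cell's preferred choice
    seed: int = 0
    rule_seed: int = 1234          # separate so the rule survives reseeding
    rule_noise: float = 0.1
    multi_variation_probs: tuple[float, float, float] = (0.86, 0.11, 0.03)
    hindered_multi_variation_probs: tuple[float, float, float] | None = None
    same_context_repeat_prob: float = 0.8
    use_alternate_context: bool = True
    popularity_decay: float = 0.75
    drift_spec: tuple[Replacement, ...] | None = None  # None -> default event
    sub20_tail: float = 0.05
    yield_match_beta: tuple[float, float] = (6.0, 2.0)
    yield_other_beta: tuple[float, float] = (4.5, 5.5)
    year_range: tuple[int, int] = (2004, 2020)
    halide_weights: tuple[float, float, float] = (0.5, 0.35, 0.15)
    amine_class_weights: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)
    steric_weights: tuple[float, float] = (0.7, 0.3)
    emit_roles: str = "solvent_only"  # "none" | "solvent_only" | "all"

    def __post_init__(self) -> None:
        if not 0.0 <= self.rule_noise <= 1.0:
            raise ValueError("rule_noise outside [0, 1]")
        for probs in (self.multi_variation_probs,
                      self.hindered_multi_variation_probs):
            if probs is not None and abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"variation probs must sum to 1: {probs}")
        y0, y1 = self.year_range
        if y0 > y1:
            raise ValueError("year_range reversed")
        for rep in self.drift():
            if not (y0 < rep.switch_year <= y1):
                raise ValueError(
                    f"switch year {rep.switch_year} gives context "
                    f"{rep.new} an empty active window"
                )
            if rep.old == rep.new:
                raise ValueError("replacement must change the context")
            if max(rep.old, rep.new) >= self.n_contexts:
                raise ValueError("replacement context index out of range")
        if self.emit_roles not in ("none", "solvent_only", "all"):
            raise ValueError(f"bad emit_roles {self.emit_roles!r}")

    def drift(self) -> tuple[Replacement, ...]:
        """Effective drift events (default: one mid-range leader swap)."""
        if self.drift_spec is not None:
            return tuple(self.drift_spec)
        y0, y1 = self.year_range
        if self.n_contexts < 2 or y1 - y0 < 2:
            return ()
        return (Replacement(old=1, new=0, switch_year=(y0 + y1 + 1) // 2),)


@dataclass(frozen=True)
class PlantedRule:
    """The exact reactant-feature -> context mapping used by a generator run.

    ``primary`` is the preferred context per feature cell; ``alternate`` is
    the backup context tried on repeat variations. Both are total functions
    over the 3 x 4 x 2 feature grid. ``resolve`` applies the drift
    replacements for a given year, yielding the era-correct truth.
    """

    primary: dict[tuple[str, str, str], int]
    alternate: dict[tuple[str, str, str], int]
    drift: tuple[Replacement, ...]
    context_keys: tuple[str, ...]

    def resolve(self, context: int, year: int) -> int:
        for rep in self.drift:
            if context == rep.old and year >= rep.switch_year:
                return rep.new
            if context == rep.new and year < rep.switch_year:
                return rep.old
        return context

    def preferred(self, cell: tuple[str, str, str], year: int) -> int:
        return self.resolve(self.primary[cell], year)

    def preferred_key(self, cell: tuple[str, str, str], year: int) -> str:
        return self.context_keys[self.preferred(cell, year)]


def _zipf_weights(n: int, decay: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-decay)
    return w / w.sum()


def _build_contexts(
    cfg: GeneratorConfig, curated: CuratedLists
) -> list[ChemicalContext]:
    """Draw n distinct (catalyst/pre-catalyst, ligand, base, solvent) combos."""
    rng = np.random.default_rng(cfg.rule_seed)
    catalysts = [(s, ROLE_CATALYST) for s in sorted(curated.catalysts)]
    catalysts += [(s, ROLE_PRECATALYST) for s in sorted(curated.precatalysts)]
    ligands = sorted(curated.ligands)
    bases = sorted(curated.bases)
    solvents = sorted(curated.solvents)
    max_combos = len(catalysts) * len(ligands) * len(bases) * len(solvents)
    if cfg.n_contexts > max_combos:
        raise ValueError(
            f"cannot build {cfg.n_contexts} distinct contexts from the "
            f"curated lists ({max_combos} combinations)"
        )
    seen: set[tuple] = set()
    contexts: list[ChemicalContext] = []
    while len(contexts) < cfg.n_contexts:
        cat = catalysts[rng.integers(len(catalysts))]
        combo = (
            cat,
            ligands[rng.integers(len(ligands))],
            bases[rng.integers(len(bases))],
            solvents[rng.integers(len(solvents))],
        )
        if combo in seen:
            continue
        seen.add(combo)
        (cat_smiles, cat_role), lig, base, solv = combo
        contexts.append(
            ChemicalContext.from_species([
                ChemicalSpecies(smiles=cat_smiles, role=cat_role),
                ChemicalSpecies(smiles=lig, role=ROLE_LIGAND),
                ChemicalSpecies(smiles=base, role=ROLE_BASE),
                ChemicalSpecies(smiles=solv, role=ROLE_SOLVENT),
            ])
        )
    return contexts


def cell_probabilities(cfg: GeneratorConfig) -> dict[tuple[str, str, str], float]:
    """Sampling probability of every reactant-feature cell."""
    probs = {}
    for (h, wh) in zip(HALIDES, cfg.halide_weights):
        for (a, wa) in zip(AMINE_CLASSES, cfg.amine_class_weights):
            for (s, ws) in zip(STERIC_FLAGS, cfg.steric_weights):
                probs[(h, a, s)] = wh * wa * ws
    return probs


def planted_truth(
    cfg: GeneratorConfig, curated: CuratedLists | None = None
) -> PlantedRule:
    """The exact rule a :func:`generate` call with this config uses.

    Context indices are popularity ranks by construction: the i-th most
    probable feature cell prefers context i (for i < n_contexts), so every
    context is the preferred choice of at least one cell when n_contexts does
    not exceed the grid size. Any remaining cells are assigned by a seeded
    long-tail draw, concentrating extra mass on the popular contexts.
    """
    curated = curated or load_default_lists()
    contexts = _build_contexts(cfg, curated)
    rng = np.random.default_rng(cfg.rule_seed + 1)
    weights = _zipf_weights(cfg.n_contexts, cfg.popularity_decay)
    probs = cell_probabilities(cfg)
    ordered_cells = sorted(probs, key=lambda c: (-probs[c], c))
    primary: dict[tuple[str, str, str], int] = {}
    alternate: dict[tuple[str, str, str], int] = {}
    for i, cell in enumerate(ordered_cells):
        if i < cfg.n_contexts:
            primary[cell] = i
        else:
            primary[cell] = int(rng.choice(cfg.n_contexts, p=weights))
    for cell in ordered_cells:
        p = primary[cell]
        if cfg.n_contexts == 1:
            alternate[cell] = p
            continue
        a = p
        while a == p:
            a = int(rng.choice(cfg.n_contexts, p=weights))
        alternate[cell] = a
    return PlantedRule(
        primary=primary,
        alternate=alternate,
        drift=cfg.drift(),
        context_keys=tuple(ctx.key for ctx in contexts),
    )


def _context_species(
    ctx: ChemicalContext, emit_roles: str
) -> tuple[ChemicalSpecies, ...]:
    species = []
    for category, smis in ctx.species_by_category:
        for s in smis:
            if emit_roles == "all":
                role = category
            elif emit_roles == "solvent_only" and category == ROLE_SOLVENT:
                role = ROLE_SOLVENT
            else:
                role = ROLE_UNASSIGNED
            species.append(ChemicalSpecies(smiles=s, role=role))
    return tuple(species)


def generate(
    cfg: GeneratorConfig, curated: CuratedLists | None = None
) -> Dataset:
    """Generate a synthetic dataset; byte-identical for identical configs."""
    curated = curated or load_default_lists()
    rule = planted_truth(cfg, curated)
    contexts = _build_contexts(cfg, curated)
    context_species = [
        _context_species(ctx, cfg.emit_roles) for ctx in contexts
    ]
    rng = np.random.default_rng(cfg.seed)

    y0, y1 = cfg.year_range
    years = np.arange(y0, y1 + 1)
    # ELN volume grows over time: linearly increasing year weights
    year_w = np.arange(1, len(years) + 1, dtype=float)
    year_w /= year_w.sum()

    pop_weights = _zipf_weights(cfg.n_contexts, cfg.popularity_decay)
    aryl_pools = {
        (x, s): [t.format(X=x) for t in _aryl_pool(s)]
        for x in HALIDES
        for s in STERIC_FLAGS
    }
    aryl_frag_pools = {
        (x, s): [t.format(X="") for t in _aryl_pool(s)]
        for x in HALIDES
        for s in STERIC_FLAGS
    }

    def draw_context(year: int) -> int:
        return rule.resolve(int(rng.choice(cfg.n_contexts, p=pop_weights)),
                            year)

    def draw_n_variations(steric: str) -> int:
        probs = cfg.multi_variation_probs
        if steric == "hindered" and cfg.hindered_multi_variation_probs:
            probs = cfg.hindered_multi_variation_probs
        bucket = int(rng.choice(3, p=probs))
        if bucket < 2:
            return bucket + 1
        return 3 if rng.random() < 0.7 else 4

    def draw_yield(match: bool) -> float:
        if rng.random() < cfg.sub20_tail:
            return float(np.round(rng.uniform(1.0, 19.9), 1))
        a, b = cfg.yield_match_beta if match else cfg.yield_other_beta
        return float(np.round(np.clip(100.0 * rng.beta(a, b), 20.0, 100.0), 1))

    records = []
    for i in range(cfg.n_records):
        year = int(rng.choice(years, p=year_w))
        halide = str(rng.choice(HALIDES, p=np.array(cfg.halide_weights)))
        amine_class = str(
            rng.choice(AMINE_CLASSES, p=np.array(cfg.amine_class_weights))
        )
        steric = str(rng.choice(STERIC_FLAGS, p=np.array(cfg.steric_weights)))
        cell = (halide, amine_class, steric)

        pool_idx = int(rng.integers(len(aryl_pools[(halide, steric)])))
        aryl_smiles = aryl_pools[(halide, steric)][pool_idx]
        aryl_frag = aryl_frag_pools[(halide, steric)][pool_idx]
        amine_smiles, product_template = _AMINES[amine_class][
            int(rng.integers(len(_AMINES[amine_class])))
        ]
        product = product_template.format(aryl=aryl_frag)

        preferred = rule.preferred(cell, year)
        n_var = draw_n_variations(steric)
        ctx_indices = []
        for v in range(n_var):
            if v == 0:
                ctx = preferred if rng.random() >= cfg.rule_noise \
                    else draw_context(year)
            elif rng.random() < cfg.same_context_repeat_prob:
                ctx = ctx_indices[0]
            elif cfg.use_alternate_context and rng.random() >= cfg.rule_noise:
                ctx = rule.resolve(rule.alternate[cell], year)
            else:
                ctx = draw_context(year)
            ctx_indices.append(ctx)

        variations = []
        for ctx in ctx_indices:
            date = _dt.date(year, int(rng.integers(1, 13)),
                            int(rng.integers(1, 29)))
            variations.append(
                ReactionVariation(
                    species=context_species[ctx],
                    yield_percent=draw_yield(ctx == preferred),
                    date=date,
                )
            )
        records.append(
            ReactionRecord(
                record_id=f"R{i:05d}",
                reactant_smiles=(aryl_smiles, amine_smiles),
                product_smiles=product,
                variations=tuple(variations),
            )
        )
    return Dataset(
        records=records,
        provenance={
            "source": "synthetic",
            "seed": cfg.seed,
            "rule_seed": cfg.rule_seed,
            "n_records": cfg.n_records,
            "n_contexts": cfg.n_contexts,
        },
    )


# -- named study configurations ----------------------------------------------
#
# The benchmarks each isolate one question; their conditions are fixed here
# so that every analysis (tests, scripts, examples) runs the same study.


def rule_recovery_config(seed: int = 1) -> GeneratorConfig:
    """Planted-rule recovery benchmark: is the rule learnable end to end?

    2000 records, 8 contexts, 10 % label noise, no temporal drift (drift is
    studied separately; here the reactant->context rule is stationary).
    """
    return GeneratorConfig(
        n_records=2000, n_contexts=8, seed=seed, rule_noise=0.1,
        drift_spec=(),
    )


def drifted_config(seed: int = 11) -> GeneratorConfig:
    """Temporal-drift benchmark: a leader-replacement event mid-range.

    The two most popular contexts swap at 2015 (the successor, context 0,
    only enters use then), so a model trained purely on the pre-switch era
    mislabels every cell whose preferred context switched.
    """
    return GeneratorConfig(
        n_records=3000, n_contexts=8, seed=seed, rule_noise=0.1,
        drift_spec=(Replacement(old=1, new=0, switch_year=2015),),
    )


def cardinality_config(target: float, seed: int = 5) -> GeneratorConfig:
    """Cardinality-tracking benchmark at label cardinality ~1.0 or ~1.5.

    The 1.5 variant ties the variation count to the steric flag: hindered
    substrates are always rerun under the cell's alternate context, so the
    extra labels are a predictable function of the input.
    """
    if abs(target - 1.0) < 1e-6:
        return GeneratorConfig(
            n_records=1500, n_contexts=8, seed=seed, rule_noise=0.1,
            drift_spec=(), multi_variation_probs=(1.0, 0.0, 0.0),
        )
    if abs(target - 1.5) < 1e-6:
        return GeneratorConfig(
            n_records=1500, n_contexts=8, seed=seed, rule_noise=0.1,
            drift_spec=(),
            multi_variation_probs=(1.0, 0.0, 0.0),
            hindered_multi_variation_probs=(0.0, 1.0, 0.0),
            steric_weights=(0.5, 0.5),
            same_context_repeat_prob=0.0,
            use_alternate_context=True,
            sub20_tail=0.0,
        )
    raise ValueError("supported targets: 1.0 and 1.5")


#: Realism envelopes checked by :func:`validate_realism`.
DEFAULT_ENVELOPES = {
    "mean_ir": (2.0, 15.0),
    "cardinality": (1.0, 1.2),
    "one_variation_fraction": (0.80, 0.92),
    "long_tail_ratio": (3.0, float("inf")),
}


def validate_realism(
    ds: Dataset,
    k: int = 30,
    min_yield: float = 20.0,
    envelopes: dict | None = None,
    curated: CuratedLists | None = None,
) -> dict:
    """Check a dataset against the target statistical envelopes.

    Computes the imbalance summary and variation-count proportions and
    returns per-criterion ``{"value": ..., "band": ..., "pass": ...}``
    entries plus an overall flag.
    """
    from .pipeline import filter_and_label
    from .temporal import imbalance_summary

    envelopes = {**DEFAULT_ENVELOPES, **(envelopes or {})}
    result = filter_and_label(ds, k=k, min_yield=min_yield, curated=curated)
    summary = imbalance_summary(result.multi_table, result.label_space)
    n_one = sum(1 for r in ds.records if len(r.variations) == 1)
    counts = sorted(result.report.context_counts.values(), reverse=True)
    long_tail = counts[0] / max(counts[len(counts) // 2], 1) if counts else 0.0
    values = {
        "mean_ir": summary.mean_ir,
        "cardinality": summary.cardinality,
        "one_variation_fraction": n_one / len(ds.records),
        "long_tail_ratio": long_tail,
    }
    report = {
        name: {
            "value": float(val),
            "band": envelopes[name],
            "pass": bool(envelopes[name][0] <= val <= envelopes[name][1]),
        }
        for name, val in values.items()
    }
    report["overall_pass"] = all(v["pass"] for v in report.values())
    report["imbalanced_by_charte"] = summary.imbalanced
    return report
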