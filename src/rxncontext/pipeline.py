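"""Chemical-context construction, filtering and label tables.

The *chemical context* of a reaction is the set of non-reactant chemicals —
(pre-)catalyst, ligand, base, solvent and other reagents — treated as a
single categorical label. This module assigns roles to context chemicals,
builds canonical context keys, applies the yield and top-k popularity
filters, and produces the single-label (highest-yield variation per record,
yield-weighted) and multi-label (bitwise-or of the record's one-hot context
vectors) training tables.
"""

from __future__ import annotations

import functools
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .datamodel import (
    CATEGORY_ORDER,
    ROLE_BASE,
    ROLE_CATALYST,
    ROLE_LIGAND,
    ROLE_PRECATALYST,
    ROLE_REAGENT,
    ROLE_SOLVENT,
    ROLE_UNASSIGNED,
    ChemicalSpecies,
    Dataset,
    canonicalize_smiles,
    mol_from_smiles,
)

DEFAULT_TOP_K = 30
DEFAULT_MIN_YIELD = 20.0

_LIST_FILES = {
    ROLE_CATALYST: "catalysts.smi",
    ROLE_PRECATALYST: "precatalysts.smi",
    ROLE_LIGAND: "ligands.smi",
    ROLE_BASE: "bases.smi",
    ROLE_SOLVENT: "solvents.smi",
}


@dataclass(frozen=True)
class CuratedLists:
    """Curated role lists: frozensets of canonical SMILES per category."""

    catalysts: frozenset[str] = frozenset()
    precatalysts: frozenset[str] = frozenset()
    ligands: frozenset[str] = frozenset()
    bases: frozenset[str] = frozenset()
    solvents: frozenset[str] = frozenset()

    @classmethod
    def from_dir(cls, directory) -> "CuratedLists":
        import os

        kwargs = {}
        for role, fname in _LIST_FILES.items():
            path = os.path.join(str(directory), fname)
            entries: set[str] = set()
            if os.path.exists(path):
                with open(path) as fh:
                    for line in fh:
                        line = line.strip()
                        if line and not line.startswith("#"):
                            entries.add(canonicalize_smiles(line))
            kwargs[_ROLE_TO_FIELD[role]] = frozenset(entries)
        return cls(**kwargs)


_ROLE_TO_FIELD = {
    ROLE_CATALYST: "catalysts",
    ROLE_PRECATALYST: "precatalysts",
    ROLE_LIGAND: "ligands",
    ROLE_BASE: "bases",
    ROLE_SOLVENT: "solvents",
}


def load_default_lists() -> CuratedLists:
    """Load the curated lists shipped with the package."""
    kwargs = {}
    for role, fname in _LIST_FILES.items():
        text = resources.files("rxncontext.data").joinpath(fname).read_text()
        entries = {
            canonicalize_smiles(line.strip())
            for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        }
        kwargs[_ROLE_TO_FIELD[role]] = frozenset(entries)
    return CuratedLists(**kwargs)


@functools.lru_cache(maxsize=100_000)
def _contains_pd_or_pt(smiles: str) -> bool:
    mol = mol_from_smiles(smiles)
    return any(a.GetSymbol() in ("Pd", "Pt") for a in mol.GetAtoms())


def assign_roles(
    species: list[ChemicalSpecies],
    curated: CuratedLists,
    product: str | None = None,
) -> list[ChemicalSpecies]:
    """Assign a role to every species whose role is ``unassigned``.

    Precedence: curated pre-catalyst list > curated catalyst list > contains a
    Pd or Pt atom > curated solvent list > curated base list > curated ligand
    list > reagent. Pre-assigned roles are kept untouched. The *product* is
    accepted for interface completeness; no atom mapping is attempted, so a
    species matching no rule is a reagent.
    """
    if not species:
        raise ValueError("a context must contain at least one species")
    out = []
    for sp in species:
        if sp.role != ROLE_UNASSIGNED:
            out.append(sp)
            continue
        canon = canonicalize_smiles(sp.smiles)
        if canon in curated.precatalysts:
            role = ROLE_PRECATALYST
        elif canon in curated.catalysts:
            role = ROLE_CATALYST
        elif _contains_pd_or_pt(canon):
            role = ROLE_CATALYST
        elif canon in curated.solvents:
            role = ROLE_SOLVENT
        elif canon in curated.bases:
            role = ROLE_BASE
        elif canon in curated.ligands:
            role = ROLE_LIGAND
        else:
            role = ROLE_REAGENT
        out.append(ChemicalSpecies(smiles=sp.smiles, name=sp.name, role=role))
    return out


@dataclass(frozen=True)
class ChemicalContext:
    """A categorized, canonically ordered set of context species.

    Equal multisets of species produce identical keys regardless of input
    order; the key is the unit of prediction (the label).
    """

    species_by_category: tuple[tuple[str, tuple[str, ...]], ...]

    @classmethod
    def from_species(cls, species: list[ChemicalSpecies]) -> "ChemicalContext":
        if not species:
            raise ValueError("empty species list")
        by_cat: dict[str, list[str]] = {c: [] for c in CATEGORY_ORDER}
        for sp in species:
            if sp.role == ROLE_UNASSIGNED:
                raise ValueError(
                    f"species {sp.smiles!r} has no assigned role; run "
                    "assign_roles first"
                )
            by_cat[sp.role].append(canonicalize_smiles(sp.smiles))
        return cls(
            species_by_category=tuple(
                (cat, tuple(sorted(set(by_cat[cat])))) for cat in CATEGORY_ORDER
            )
        )

    def species(self, category: str) -> tuple[str, ...]:
        return dict(self.species_by_category).get(category, ())

    @property
    def key(self) -> str:
        return "|".join(
            ".".join(smis) for _, smis in self.species_by_category
        )

    @classmethod
    def from_key(cls, key: str) -> "ChemicalContext":
        """Best-effort inverse of :attr:`key`.

        The key joins species within a category with ``.``, which is ambiguous
        for multi-component (salt) species; prefer carrying the original
        :class:`ChemicalContext` objects (see ``PipelineResult.contexts_by_key``).
        """
        parts = key.split("|")
        if len(parts) != len(CATEGORY_ORDER):
            raise ValueError(f"malformed context key: {key!r}")
        return cls(
            species_by_category=tuple(
                (cat, tuple(p.split(".")) if p else ())
                for cat, p in zip(CATEGORY_ORDER, parts)
            )
        )


def build_context(species: list[ChemicalSpecies]) -> ChemicalContext:
    """Group role-assigned species into a canonical :class:`ChemicalContext`."""
    return ChemicalContext.from_species(species)


@dataclass
class LabelSpace:
    """Ordered label space: context keys sorted by descending usage count."""

    contexts: list[str]
    counts: list[int]

    def __post_init__(self) -> None:
        if len(self.contexts) != len(self.counts):
            raise ValueError("contexts and counts length mismatch")
        self._index = {k: i for i, k in enumerate(self.contexts)}

    def __len__(self) -> int:
        return len(self.contexts)

    def index(self, key: str) -> int:
        return self._index[key]

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"contexts": self.contexts, "counts": self.counts}, fh,
                      indent=1)

    @classmethod
    def from_json(cls, path) -> "LabelSpace":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(contexts=payload["contexts"], counts=payload["counts"])

    @classmethod
    def from_counts(cls, counts: dict[str, int], k: int) -> "LabelSpace":
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > len(counts):
            warnings.warn(
                f"k={k} exceeds the {len(counts)} distinct contexts; "
                "label space truncated"
            )
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        return cls(
            contexts=[key for key, _ in ordered],
            counts=[c for _, c in ordered],
        )


@dataclass
class LabeledExample:
    """One training example: a reaction, a label vector, a weight, a year."""

    record_id: str
    reactants: tuple[str, ...]
    product: str
    label_vector: np.ndarray
    weight: float
    year: int

    @property
    def label_index(self) -> int:
        """Index of the single set bit (single-label tables only)."""
        (idx,) = np.flatnonzero(self.label_vector)
        return int(idx)


@dataclass
class PipelineReport:
    """Per-stage accounting of the filtering pipeline."""

    records_in: int = 0
    variations_in: int = 0
    variations_dropped_yield: int = 0
    variations_dropped_context: int = 0
    records_dropped_yield: int = 0
    records_dropped_context: int = 0
    records_dropped_duplicate: int = 0
    records_kept: int = 0
    context_counts: dict = field(default_factory=dict)
    variation_count_proportions: dict = field(default_factory=dict)

    @property
    def records_dropped(self) -> int:
        return (self.records_dropped_yield + self.records_dropped_context
                + self.records_dropped_duplicate)


@dataclass
class PipelineResult:
    label_space: LabelSpace
    single_table: list[LabeledExample]
    multi_table: list[LabeledExample]
    report: PipelineReport
    contexts_by_key: dict = field(default_factory=dict)


def _variation_context(variation, curated: CuratedLists,
                       product: str) -> ChemicalContext:
    species = assign_roles(list(variation.species), curated, product)
    return build_context(species)


def filter_and_label(
    ds: Dataset,
    k: int = DEFAULT_TOP_K,
    min_yield: float = DEFAULT_MIN_YIELD,
    curated: CuratedLists | None = None,
) -> PipelineResult:
    """Apply the yield and top-k context filters and build both label tables.

    Stages: (a) drop variations with yield below *min_yield*; (b) count
    context usage over survivors and keep the *k* most common contexts,
    dropping variations with other contexts; (c) single-label table: per
    record the highest-yield surviving variation (ties: earliest date, then
    lowest context index), one-hot label, weight = yield fraction; (d)
    multi-label table: per record the bitwise-or of the one-hot vectors of
    its distinct surviving contexts, weight 1. Duplicate (reaction, context)
    pairs contribute once to the multi-label merge.
    """
    if not ds.records:
        raise ValueError("empty dataset")
    if not (0.0 <= min_yield <= 100.0):
        raise ValueError("min_yield must lie in [0, 100]")
    curated = curated or load_default_lists()

    report = PipelineReport(records_in=len(ds.records),
                            variations_in=ds.n_variations)

    # stage (a): yield filter, with context keys computed for survivors
    surviving: dict[str, list[tuple]] = {}
    contexts_by_key: dict[str, ChemicalContext] = {}
    for rec in ds.records:
        kept = []
        for v in rec.variations:
            if v.yield_percent < min_yield:
                report.variations_dropped_yield += 1
                continue
            ctx = _variation_context(v, curated, rec.product_smiles)
            contexts_by_key.setdefault(ctx.key, ctx)
            kept.append((v, ctx.key))
        if kept:
            surviving[rec.record_id] = kept
        else:
            report.records_dropped_yield += 1

    # stage (b): top-k context popularity over surviving variations
    counts: dict[str, int] = {}
    for kept in surviving.values():
        for _, key in kept:
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        raise ValueError("no variation survives the yield filter")
    label_space = LabelSpace.from_counts(counts, k)

    records_by_id = {r.record_id: r for r in ds.records}
    single_table: list[LabeledExample] = []
    multi_table: list[LabeledExample] = []
    seen_reaction_context: set = set()
    n_labels = len(label_space)

    for record_id in sorted(surviving):
        rec = records_by_id[record_id]
        kept = [
            (v, key) for v, key in surviving[record_id] if key in label_space
        ]
        dropped = len(surviving[record_id]) - len(kept)
        report.variations_dropped_context += dropped
        if not kept:
            report.records_dropped_context += 1
            continue
        report.records_kept += 1

        # single-label: highest yield, then earliest date, then lowest index
        best_v, best_key = min(
            kept,
            key=lambda vk: (
                -vk[0].yield_percent,
                vk[0].date,
                label_space.index(vk[1]),
            ),
        )
        one_hot = np.zeros(n_labels, dtype=np.int8)
        one_hot[label_space.index(best_key)] = 1
        single_table.append(
            LabeledExample(
                record_id=record_id,
                reactants=rec.reactant_smiles,
                product=rec.product_smiles,
                label_vector=one_hot,
                weight=best_v.yield_percent / 100.0,
                year=best_v.year,
            )
        )

        # multi-label: bitwise-or over distinct (reaction, context) pairs
        reaction_id = rec.canonical_reaction()
        multi = np.zeros(n_labels, dtype=np.int8)
        for v, key in kept:
            pair = (reaction_id, key)
            if pair in seen_reaction_context:
                continue
            seen_reaction_context.add(pair)
            multi[label_space.index(key)] = 1
        if not multi.any():
            # every (reaction, context) pair already seen under another record
            report.records_kept -= 1
            report.records_dropped_duplicate += 1
            single_table.pop()
            continue
        multi_table.append(
            LabeledExample(
                record_id=record_id,
                reactants=rec.reactant_smiles,
                product=rec.product_smiles,
                label_vector=multi,
                weight=1.0,
                year=min(v.year for v, _ in kept),
            )
        )

    report.context_counts = {
        key: counts[key] for key in label_space.contexts
    }
    n_ctx = [int(ex.label_vector.sum()) for ex in multi_table]
    total = len(n_ctx) or 1
    report.variation_count_proportions = {
        "1": sum(1 for c in n_ctx if c == 1) / total,
        "2": sum(1 for c in n_ctx if c == 2) / total,
        ">=3": sum(1 for c in n_ctx if c >= 3) / total,
    }
    return PipelineResult(
        label_space=label_space,
        single_table=single_table,
        multi_table=multi_table,
        report=report,
        contexts_by_key={
            key: contexts_by_key[key] for key in label_space.contexts
        },
    )


def dataset_report(result: PipelineResult) -> dict:
    """Summarize the pipeline accounting as a plain dictionary.

    Conservation holds by construction: ``records_in == records_kept +
    records_dropped`` itemized by stage.
    """
    r = result.report
    return {
        "records_in": r.records_in,
        "variations_in": r.variations_in,
        "records_kept": r.records_kept,
        "records_dropped_yield": r.records_dropped_yield,
        "records_dropped_context": r.records_dropped_context,
        "records_dropped_duplicate": r.records_dropped_duplicate,
        "variations_dropped_yield": r.variations_dropped_yield,
        "variations_dropped_context": r.variations_dropped_context,
        "n_labels": len(result.label_space),
        "context_counts": r.context_counts,
        "distinct_context_proportions": r.variation_count_proportions,
    }


def variation_context_table(
    ds: Dataset,
    curated: CuratedLists | None = None,
    min_yield: float = DEFAULT_MIN_YIELD,
) -> list[tuple[str, int, str, float]]:
    """(record_id, year, context_key, yield) for every surviving variation.

    Used by the temporal analyses, which count context usage per year.
    """
    curated = curated or load_default_lists()
    rows = []
    for rec in ds.records:
        for v in rec.variations:
            if v.yield_percent < min_yield:
                continue
            ctx = _variation_context(v, curated, rec.product_smiles)
            rows.append((rec.record_id, v.year, ctx.key, v.yield_percent))
    return rows
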