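"""Domain types for Buchwald-Hartwig reaction data.

The unit of record keeping mirrors an electronic lab notebook (ELN): a
:class:`ReactionRecord` is one unique chemical transformation (reactants to a
single product); each :class:`ReactionVariation` is one experimental run of
that transformation with a specific set of context chemicals, a yield and a
date.
"""

from __future__ import annotations

import datetime as _dt
import functools as _functools
from dataclasses import dataclass, field, replace
from typing import Optional

from rdkit import Chem
from rdkit import RDLogger

# RDKit parse failures are reported through exceptions, not the C++ logger.
RDLogger.DisableLog("rdApp.error")

ROLE_CATALYST = "catalyst"
ROLE_PRECATALYST = "pre-catalyst"
ROLE_LIGAND = "ligand"
ROLE_BASE = "base"
ROLE_SOLVENT = "solvent"
ROLE_REAGENT = "reagent"
ROLE_UNASSIGNED = "unassigned"

#: Context categories in the fixed order used for context keys.
CATEGORY_ORDER = (
    ROLE_CATALYST,
    ROLE_PRECATALYST,
    ROLE_LIGAND,
    ROLE_BASE,
    ROLE_SOLVENT,
    ROLE_REAGENT,
)

ALLOWED_ROLES = frozenset(CATEGORY_ORDER) | {ROLE_UNASSIGNED}

MIN_YEAR, MAX_YEAR = 1990, 2100


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`InvalidSmilesError` on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidSmilesError(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return mol


@_functools.lru_cache(maxsize=200_000)
def canonicalize_smiles(smiles: str, strip_stereo: bool = False) -> str:
    """Return the canonical form of *smiles*.

    Canonicalization is idempotent. Stereochemistry is retained by default;
    pass ``strip_stereo=True`` to drop it. Results are cached, since ELN-like
    datasets repeat the same context species across thousands of rows.
    """
    mol = mol_from_smiles(smiles)
    if strip_stereo:
        Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class ChemicalSpecies:
    """One context chemical: a SMILES, an optional name and a role."""

    smiles: str
    name: Optional[str] = None
    role: str = ROLE_UNASSIGNED

    def __post_init__(self) -> None:
        if self.role not in ALLOWED_ROLES:
            raise ValueError(
                f"role {self.role!r} not in {sorted(ALLOWED_ROLES)}"
            )
        mol_from_smiles(self.smiles)

    def canonical(self) -> "ChemicalSpecies":
        return replace(self, smiles=canonicalize_smiles(self.smiles))


@dataclass(frozen=True)
class ReactionVariation:
    """One experimental run: context chemicals, yield in percent, date."""

    species: tuple[ChemicalSpecies, ...]
    yield_percent: float
    date: _dt.date

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not self.species:
            raise ValueError("a variation needs at least one context species")
        if not (0.0 <= self.yield_percent <= 100.0):
            raise ValueError(f"yield {self.yield_percent} outside [0, 100]")
        if not (MIN_YEAR <= self.date.year <= MAX_YEAR):
            raise ValueError(f"date year {self.date.year} outside "
                             f"[{MIN_YEAR}, {MAX_YEAR}]")

    @property
    def year(self) -> int:
        return self.date.year


@dataclass(frozen=True)
class ReactionRecord:
    """One unique transformation plus its recorded variations."""

    record_id: str
    reactant_smiles: tuple[str, ...]
    product_smiles: str
    variations: tuple[ReactionVariation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactant_smiles", tuple(self.reactant_smiles))
        object.__setattr__(self, "variations", tuple(self.variations))
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.reactant_smiles:
            raise ValueError("a record needs at least one reactant")
        if not self.variations:
            raise ValueError(f"record {self.record_id}: no variations")
        for s in self.reactant_smiles:
            mol_from_smiles(s)
        mol_from_smiles(self.product_smiles)

    def canonical_reaction(self) -> tuple[tuple[str, ...], str]:
        """Canonical identity of the transformation (order-independent)."""
        return (
            tuple(sorted(canonicalize_smiles(s) for s in self.reactant_smiles)),
            canonicalize_smiles(self.product_smiles),
        )


@dataclass
class Dataset:
    """A collection of reaction records with provenance metadata."""

    records: list[ReactionRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record_ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_variations(self) -> int:
        return sum(len(r.variations) for r in self.records)

    def years(self) -> list[int]:
        return sorted({v.year for r in self.records for v in r.variations})


def parse_date(value: str) -> _dt.date:
    """Parse an ISO-8601 date; year or year-month precision is accepted."""
    value = str(value).strip()
    for fmt, pad in (("%Y-%m-%d", None), ("%Y-%m", "-01"), ("%Y", "-01-01")):
        try:
            return _dt.datetime.strptime(
                value + (pad or ""), "%Y-%m-%d" if pad else fmt
            ).date()
        except ValueError:
            continue
    raise ValueError(f"cannot parse date {value!r} (expect ISO-8601)")
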