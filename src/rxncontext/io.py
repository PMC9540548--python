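"""Readers and writers for the on-disk dataset formats.

Two formats are supported. The CSV format stores one reaction *variation* per
row, grouped into records by ``record_id``; the JSON format stores a list of
record objects. Both round-trip through :func:`read_dataset` /
:func:`write_dataset` up to SMILES canonicalization.

CSV columns::

    record_id, reactant_smiles (dot-separated), product_smiles,
    species_smiles (dot-separated), species_roles (semicolon-separated,
    aligned with species_smiles, may be "unassigned"), yield_percent,
    date (ISO-8601)

A ``rxn_smiles`` column of the form ``reactants>agents>product`` is accepted
as an alternative to the first three columns; agents become unassigned
context species.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import pandas as pd

from .datamodel import (
    ChemicalSpecies,
    Dataset,
    InvalidSmilesError,
    ReactionRecord,
    ReactionVariation,
    parse_date,
)

CSV_COLUMNS = [
    "record_id",
    "reactant_smiles",
    "product_smiles",
    "species_smiles",
    "species_roles",
    "yield_percent",
    "date",
]


class DatasetFormatError(ValueError):
    """Schema-level problem: missing column, empty file, unknown format."""


@dataclass
class RowError:
    row: int  # 1-based data row number (header excluded)
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row}: {self.message}"


class DatasetParseError(ValueError):
    """One or more rows failed to parse; carries the per-row report."""

    def __init__(self, errors: list[RowError]):
        self.errors = errors
        lines = "; ".join(str(e) for e in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} bad row(s): {lines}{more}")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".csv", ".tsv"):
        return "csv"
    if ext == ".json":
        return "json"
    raise DatasetFormatError(f"cannot infer format from {path!r}; pass format=")


def _split_dot(smiles_field: str) -> list[str]:
    # Context species are dot-separated *whole species*; a species may itself
    # contain dots (salts), so the writer separates species with " . " while a
    # plain "." remains an intra-species disconnection.
    return [s.strip() for s in str(smiles_field).split(" . ") if s.strip()]


def _join_dot(smiles_list) -> str:
    return " . ".join(smiles_list)


def _row_to_variation(row: pd.Series, rownum: int, errors: list[RowError]):
    """Parse one CSV row into (record_id, reactants, product, variation)."""
    try:
        if "rxn_smiles" in row and isinstance(row["rxn_smiles"], str) \
                and row["rxn_smiles"].strip():
            parts = row["rxn_smiles"].split(">")
            if len(parts) != 3:
                raise ValueError(f"rxn_smiles needs 2 '>': {row['rxn_smiles']!r}")
            reactants = [s for s in parts[0].split(".") if s]
            agents = [s for s in parts[1].split(".") if s]
            product = parts[2]
            species_smiles = _split_dot(row.get("species_smiles", "") or "")
            species_smiles = list(species_smiles) + agents
            roles = ["unassigned"] * len(species_smiles)
        else:
            reactants = _split_dot(row["reactant_smiles"])
            # reactants never contain salts in this schema; also accept plain dots
            if len(reactants) == 1 and "." in reactants[0]:
                reactants = reactants[0].split(".")
            product = str(row["product_smiles"])
            species_smiles = _split_dot(row["species_smiles"])
            roles = [r.strip() for r in str(row["species_roles"]).split(";")]
        if len(roles) != len(species_smiles):
            raise ValueError(
                f"{len(species_smiles)} species but {len(roles)} roles"
            )
        yield_percent = float(row["yield_percent"])
        date = parse_date(row["date"])
        species = tuple(
            ChemicalSpecies(smiles=s, role=r)
            for s, r in zip(species_smiles, roles)
        )
        variation = ReactionVariation(
            species=species, yield_percent=yield_percent, date=date
        )
        return str(row["record_id"]), tuple(reactants), product, variation
    except (ValueError, InvalidSmilesError, KeyError) as exc:
        errors.append(RowError(rownum, str(exc)))
        return None


def _read_csv(path: str) -> Dataset:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise DatasetFormatError(f"empty dataset file: {path}")
    has_rxn = "rxn_smiles" in df.columns
    required = ["record_id", "species_smiles", "yield_percent", "date"]
    if not has_rxn:
        required += ["reactant_smiles", "product_smiles", "species_roles"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"missing required column(s): {missing}")

    errors: list[RowError] = []
    grouped: dict[str, dict] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        parsed = _row_to_variation(row, i, errors)
        if parsed is None:
            continue
        record_id, reactants, product, variation = parsed
        entry = grouped.setdefault(
            record_id,
            {"reactants": reactants, "product": product, "variations": []},
        )
        entry["variations"].append(variation)
    if errors:
        raise DatasetParseError(errors)

    records = []
    for record_id, entry in grouped.items():
        try:
            records.append(
                ReactionRecord(
                    record_id=record_id,
                    reactant_smiles=entry["reactants"],
                    product_smiles=entry["product"],
                    variations=tuple(entry["variations"]),
                )
            )
        except (ValueError, InvalidSmilesError) as exc:
            errors.append(RowError(0, f"record {record_id}: {exc}"))
    if errors:
        raise DatasetParseError(errors)
    # deterministic order regardless of input row order
    records.sort(key=lambda r: r.record_id)
    return Dataset(records=records, provenance={"source": str(path)})


def _read_json(path: str) -> Dataset:
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        objs = payload.get("records", [])
        provenance = payload.get("provenance", {})
    else:
        objs, provenance = payload, {}
    if not objs:
        raise DatasetFormatError(f"empty dataset file: {path}")
    errors: list[RowError] = []
    records = []
    for i, obj in enumerate(objs, start=1):
        try:
            variations = tuple(
                ReactionVariation(
                    species=tuple(
                        ChemicalSpecies(
                            smiles=sp["smiles"],
                            name=sp.get("name"),
                            role=sp.get("role", "unassigned"),
                        )
                        for sp in v["species"]
                    ),
                    yield_percent=float(v["yield_percent"]),
                    date=parse_date(v["date"]),
                )
                for v in obj["variations"]
            )
            records.append(
                ReactionRecord(
                    record_id=str(obj["record_id"]),
                    reactant_smiles=tuple(obj["reactant_smiles"]),
                    product_smiles=obj["product_smiles"],
                    variations=variations,
                )
            )
        except (ValueError, InvalidSmilesError, KeyError) as exc:
            errors.append(RowError(i, str(exc)))
    if errors:
        raise DatasetParseError(errors)
    records.sort(key=lambda r: r.record_id)
    if not isinstance(provenance, dict):
        provenance = {"source": provenance}
    provenance.setdefault("source", str(path))
    return Dataset(records=records, provenance=provenance)


def read_dataset(path: str, format: str | None = None) -> Dataset:
    """Read a dataset from *path* (CSV or JSON; inferred from the suffix)."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "json":
        return _read_json(path)
    raise DatasetFormatError(f"unknown format {fmt!r} (use 'csv' or 'json')")


def write_dataset(ds: Dataset, path: str, format: str | None = None) -> None:
    """Write *ds* to *path*; ``read_dataset(write_dataset(ds))`` round-trips."""
    fmt = _infer_format(path, format)
    if fmt == "csv":
        rows = []
        for rec in ds.records:
            for v in rec.variations:
                rows.append(
                    {
                        "record_id": rec.record_id,
                        "reactant_smiles": _join_dot(rec.reactant_smiles),
                        "product_smiles": rec.product_smiles,
                        "species_smiles": _join_dot(
                            sp.smiles for sp in v.species
                        ),
                        "species_roles": ";".join(
                            sp.role for sp in v.species
                        ),
                        "yield_percent": v.yield_percent,
                        "date": v.date.isoformat(),
                    }
                )
        pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
    elif fmt == "json":
        payload = {
            "provenance": ds.provenance,
            "records": [
                {
                    "record_id": rec.record_id,
                    "reactant_smiles": list(rec.reactant_smiles),
                    "product_smiles": rec.product_smiles,
                    "variations": [
                        {
                            "species": [
                                {
                                    "smiles": sp.smiles,
                                    "name": sp.name,
                                    "role": sp.role,
                                }
                                for sp in v.species
                            ],
                            "yield_percent": v.yield_percent,
                            "date": v.date.isoformat(),
                        }
                        for v in rec.variations
                    ],
                }
                for rec in ds.records
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise DatasetFormatError(f"unknown format {fmt!r} (use 'csv' or 'json')")
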