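"""Shared fixtures: tiny hand-built datasets and one small synthetic dataset."""

import datetime as dt

import pytest

import rxncontext as rc
from rxncontext.datamodel import (
    ChemicalSpecies,
    Dataset,
    ReactionRecord,
    ReactionVariation,
)


def species(smiles, role="unassigned"):
    return ChemicalSpecies(smiles=smiles, role=role)


def make_variation(context_species, yield_percent, date=dt.date(2015, 6, 1)):
    return ReactionVariation(
        species=tuple(context_species), yield_percent=yield_percent, date=date
    )


# three simple contexts built from the shipped curated lists
CTX_A = [  # Pd black / PPh3 / NaOtBu / toluene
    species("[Pd]"),
    species("c1ccc(P(c2ccccc2)c2ccccc2)cc1"),
    species("CC(C)(C)[O-].[Na+]"),
    species("Cc1ccccc1", role="solvent"),
]
CTX_B = [  # Pd(OAc)2 / PtBu3 / Cs2CO3 / dioxane
    species("CC(=O)O[Pd]OC(C)=O"),
    species("CC(C)(C)P(C(C)(C)C)C(C)(C)C"),
    species("O=C([O-])[O-].[Cs+].[Cs+]"),
    species("C1COCCO1", role="solvent"),
]
CTX_C = [  # allylPdCl / PCy3 / K3PO4 / THF
    species("C=CC[Pd]Cl"),
    species("C1CCC(P(C2CCCCC2)C2CCCCC2)CC1"),
    species("O=P([O-])([O-])[O-].[K+].[K+].[K+]"),
    species("C1CCOC1", role="solvent"),
]

def make_record(record_id, variations, reactants=("Brc1ccccc1", "C1CCNCC1"),
                product="C2CCN(c1ccccc1)CC2"):
    return ReactionRecord(
        record_id=record_id,
        reactant_smiles=reactants,
        product_smiles=product,
        variations=tuple(variations),
    )


@pytest.fixture(scope="session")
def curated():
    return rc.load_default_lists()


@pytest.fixture()
def toy_dataset():
    """Three records: multi-context, duplicate-context, low-yield-only."""
    r1 = make_record(
        "R1",
        [
            make_variation(CTX_A, 80.0, dt.date(2014, 3, 1)),
            make_variation(CTX_B, 45.0, dt.date(2015, 3, 1)),
        ],
    )
    r2 = make_record(
        "R2",
        [
            make_variation(CTX_A, 45.0, dt.date(2013, 1, 5)),
            make_variation(CTX_A, 80.0, dt.date(2016, 1, 5)),
        ],
        reactants=("Clc1ccc(C)cc1", "CCNCC"),
        product="CCN(CC)c1ccc(C)cc1",
    )
    r3 = make_record(
        "R3",
        [make_variation(CTX_C, 12.0, dt.date(2012, 7, 9))],
        reactants=("Ic1ccccc1", "NCC"),
        product="CCNc1ccccc1",
    )
    return Dataset(records=[r1, r2, r3], provenance={"source": "toy"})


@pytest.fixture(scope="session")
def small_synthetic():
    """800 records, 6 contexts, no drift — shared across fast model tests."""
    cfg = rc.GeneratorConfig(
        n_records=800, n_contexts=6, seed=3, rule_noise=0.0, drift_spec=()
    )
    ds = rc.generate(cfg)
    result = rc.filter_and_label(ds, k=6)
    X = rc.featurize_examples(result.single_table)
    return cfg, ds, result, X
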