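import numpy as np
import pytest

from mixtriage.tables_io import (
    ROLE_ACTIVE,
    ROLE_COFORMULANT,
    CompositionEntry,
    ProductRecord,
    SubstanceRecord,
)


@pytest.fixture
def toy_registry():
    """2 active substances + 5 co-formulants, of which two share a CAS and
    one has no SMILES."""
    return [
        SubstanceRecord("as01", "alpha-cide", ROLE_ACTIVE, cas="107534-96-3", smiles="AS1"),
        SubstanceRecord("as02", "beta-cide", ROLE_ACTIVE, cas="178928-70-6", smiles="AS2"),
        SubstanceRecord("cf01", "amide solvent", ROLE_COFORMULANT, cas="14433-76-2", smiles="C1"),
        SubstanceRecord("cf02", "amide solvent (alt name)", ROLE_COFORMULANT, cas="14433-76-2", smiles="C1b"),
        SubstanceRecord("cf03", "surfactant", ROLE_COFORMULANT, cas="57-55-6", smiles="C3"),
        SubstanceRecord("cf04", "mineral blend", ROLE_COFORMULANT, cas="7732-18-5", smiles=None),
        SubstanceRecord("cf05", "pyrrolidone", ROLE_COFORMULANT, cas=None, smiles="C5"),
    ]


def make_product(pid, sales_kg, composition_percent):
    entries = tuple(
        CompositionEntry(pid, sid, pct / 100.0) for sid, pct in composition_percent
    )
    return ProductRecord(pid, sales_kg, entries)


@pytest.fixture
def toy_products():
    """4-product landscape for spreadsheet-style sales checks."""
    return [
        make_product("p1", 1000.0, [("as01", 25.0), ("cf01", 25.0)]),
        make_product("p2", 500.0, [("as01", 10.0), ("cf02", 10.0), ("cf03", 40.0)]),
        make_product("p3", 2000.0, [("as02", 50.0), ("cf04", 30.0)]),
        make_product("p4", 100.0, [("as02", 5.0), ("cf05", 90.0)]),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
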