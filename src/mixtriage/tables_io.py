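"""Data model and CSV input/output for formulation landscapes.

All mass quantities are stored internally as fractions in [0, 1]; every
file interface accepts and emits percentages, which is how formulation
composition is conventionally reported.  Files are UTF-8, comma-delimited,
decimal point ".".

Tables
------
registry.csv       substance_id,cas,name,smiles,role,is_class
products.csv       product_id,sales_kg
composition.csv    product_id,substance_id,percent
doseresponse.csv   treatment,conc_mg_L,response_pct,replicate
priority_report.csv product_id,trigger,detail_json
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

ROLE_ACTIVE = "active_substance"
ROLE_COFORMULANT = "co_formulant"
_ROLES = frozenset({ROLE_ACTIVE, ROLE_COFORMULANT})

# exclusion reasons for the QSAR-eligibility filter
REASON_NO_SMILES = "no_smiles"
REASON_DUPLICATE_CAS = "duplicate_cas"
REASON_NOT_COFORMULANT = "not_coformulant"
REASON_SUBSTANCE_CLASS = "substance_class"

_MASS_TOL = 1e-9

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def is_valid_cas(cas: str) -> bool:
    """Check format and check digit of a CAS registry number.

    The check digit is the weighted sum of the preceding digits (weights
    1, 2, 3, ... from the rightmost digit leftwards) modulo 10.
    """
    m = _CAS_RE.match(cas.strip())
    if m is None:
        return False
    digits = m.group(1) + m.group(2)
    total = sum(int(d) * w for w, d in enumerate(reversed(digits), start=1))
    return total % 10 == int(m.group(3))


@dataclass(frozen=True)
class SubstanceRecord:
    """One registry entry: an active substance or a co-formulant.

    ``smiles`` is treated as an opaque identifier (no chemistry engine);
    ``is_class`` marks substance classes such as polymers, minerals or
    natural extracts, which cannot be represented by a single structure.
    """

    substance_id: str
    name: str
    role: str
    cas: str | None = None
    smiles: str | None = None
    is_class: bool = False

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.substance_id!r}")


@dataclass(frozen=True)
class ExcludedSubstance:
    """A registry entry removed by the QSAR-eligibility filter, with reason."""

    record: SubstanceRecord
    reason: str


@dataclass(frozen=True)
class CompositionEntry:
    product_id: str
    substance_id: str
    mass_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mass_fraction <= 1.0):
            raise SchemaError(
                f"mass fraction {self.mass_fraction} out of [0, 1] for "
                f"{self.substance_id!r} in {self.product_id!r}"
            )


@dataclass(frozen=True)
class ProductRecord:
    """A formulated product: annual sales plus its composition list."""

    product_id: str
    sales_kg: float
    composition: tuple[CompositionEntry, ...]

    def __post_init__(self) -> None:
        if self.sales_kg < 0:
            raise SchemaError(f"negative sales for {self.product_id!r}")
        total = sum(e.mass_fraction for e in self.composition)
        if total > 1.0 + _MASS_TOL:
            raise SchemaError(
                f"composition of {self.product_id!r} sums to {total:.6f} > 1"
            )


@dataclass(frozen=True)
class MixtureSpec:
    """Mass fractions of the components making up a dosed mixture.

    ``components`` maps treatment label to the fraction pi_i of the total
    dosed mass; fractions must sum to 1.
    """

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        fracs = [f for _, f in self.components]
        if any(f < 0 for f in fracs):
            raise ValueError("mixture fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {sum(fracs)}, expected 1")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.components)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f for _, f in self.components], dtype=float)


@dataclass
class DoseResponseDataset:
    """Concentration/response observations for one treatment.

    Concentrations are mg/L; responses are % of solvent control.  Zero-dose
    rows are the plate controls and are kept in the arrays.
    """

    treatment_label: str
    concentrations: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray
    mixture_spec: MixtureSpec | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        self.replicate_ids = np.asarray(self.replicate_ids)
        if self.concentrations.shape != self.responses.shape:
            raise SchemaError("concentrations and responses differ in length")
        if self.concentrations.shape != self.replicate_ids.shape:
            raise SchemaError("replicate ids differ in length from observations")
        if np.any(self.concentrations < 0):
            raise SchemaError("negative concentration")

    @property
    def n_obs(self) -> int:
        return int(self.concentrations.size)

    @property
    def positive_doses(self) -> np.ndarray:
        return self.concentrations[self.concentrations > 0]

    @property
    def control_responses(self) -> np.ndarray:
        return self.responses[self.concentrations == 0]

    def n_distinct_positive(self) -> int:
        return int(np.unique(self.positive_doses).size)


@dataclass(frozen=True)
class PriorityCall:
    """One product flagged for follow-up testing, with a machine-readable
    trigger and a structured detail payload."""

    product_id: str
    trigger: str
    detail: Mapping[str, object] = field(default_factory=dict)

    def detail_json(self) -> str:
        return json.dumps(dict(self.detail), sort_keys=True)


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    return df


def _numeric(df: pd.DataFrame, col: str, name: str) -> np.ndarray:
    try:
        return pd.to_numeric(df[col]).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{name}: non-numeric value in column {col!r}") from exc


def load_registry(path: str | Path) -> list[SubstanceRecord]:
    """Read registry.csv.  Duplicate substance ids are a schema error;
    a malformed CAS is kept as a record without CAS, with a warning."""
    df = _read_csv(path, ["substance_id", "cas", "name", "smiles", "role"])
    dup = df["substance_id"][df["substance_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate substance_id: {sorted(set(dup))}")
    records = []
    for row in df.itertuples(index=False):
        cas = row.cas.strip() or None
        if cas is not None and not is_valid_cas(cas):
            warnings.warn(
                f"malformed CAS {cas!r} for {row.substance_id!r}; dropped",
                stacklevel=2,
            )
            cas = None
        is_class = str(getattr(row, "is_class", "")).strip().lower() in {
            "1", "true", "yes",
        }
        records.append(
            SubstanceRecord(
                substance_id=row.substance_id,
                name=row.name,
                role=row.role,
                cas=cas,
                smiles=row.smiles.strip() or None,
                is_class=is_class,
            )
        )
    return records


def write_registry(records: Iterable[SubstanceRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "substance_id": r.substance_id,
                "cas": r.cas or "",
                "name": r.name,
                "smiles": r.smiles or "",
                "role": r.role,
                "is_class": int(r.is_class),
            }
            for r in records
        ],
        columns=["substance_id", "cas", "name", "smiles", "role", "is_class"],
    )
    df.to_csv(path, index=False)


def registry_by_id(records: Iterable[SubstanceRecord]) -> dict[str, SubstanceRecord]:
    return {r.substance_id: r for r in records}


def filter_unique_coformulants(
    registry: Sequence[SubstanceRecord],
) -> tuple[list[SubstanceRecord], list[ExcludedSubstance]]:
    """Reduce a registry to the unique, structure-bearing co-formulants that
    can be submitted to structure-based prediction tools.

    Exclusion reasons, applied in order: active substances
    (``not_coformulant``), substance classes such as polymers or mineral
    mixtures (``substance_class``), entries without a SMILES
    (``no_smiles``), and entries collapsing onto an already-seen CAS — or,
    for CAS-less entries, an identical SMILES (``duplicate_cas``).  The
    first-seen entry of each duplicate group is kept.  Substances excluded
    here remain part of the sales stream.
    """
    eligible: list[SubstanceRecord] = []
    excluded: list[ExcludedSubstance] = []
    seen_keys: set[str] = set()
    for rec in registry:
        if rec.role != ROLE_COFORMULANT:
            excluded.append(ExcludedSubstance(rec, REASON_NOT_COFORMULANT))
            continue
        if rec.is_class:
            excluded.append(ExcludedSubstance(rec, REASON_SUBSTANCE_CLASS))
            continue
        if rec.smiles is None:
            excluded.append(ExcludedSubstance(rec, REASON_NO_SMILES))
            continue
        key = f"CAS:{rec.cas}" if rec.cas else f"SMILES:{rec.smiles}"
        if key in seen_keys:
            excluded.append(ExcludedSubstance(rec, REASON_DUPLICATE_CAS))
            continue
        seen_keys.add(key)
        eligible.append(rec)
    return eligible, excluded


def load_products(
    products_path: str | Path,
    composition_path: str | Path,
    registry: Sequence[SubstanceRecord] | None = None,
) -> list[ProductRecord]:
    """Read products.csv + composition.csv; composition percentages are
    converted to mass fractions.  When a registry is supplied, every product
    must contain at least one active substance."""
    pdf = _read_csv(products_path, ["product_id", "sales_kg"])
    if pdf["product_id"].duplicated().any():
        raise SchemaError("duplicate product_id in products table")
    sales = dict(zip(pdf["product_id"], _numeric(pdf, "sales_kg", "products")))

    cdf = _read_csv(composition_path, ["product_id", "substance_id", "percent"])
    pct = _numeric(cdf, "percent", "composition")
    comp: dict[str, list[CompositionEntry]] = {pid: [] for pid in sales}
    for (pid, sid), p in zip(
        zip(cdf["product_id"], cdf["substance_id"]), pct, strict=True
    ):
        if pid not in comp:
            raise SchemaError(f"composition references unknown product {pid!r}")
        comp[pid].append(CompositionEntry(pid, sid, p / 100.0))

    roles = {r.substance_id: r.role for r in registry} if registry else None
    products = []
    for pid, sales_kg in sales.items():
        entries = tuple(comp[pid])
        if roles is not None and not any(
            roles.get(e.substance_id) == ROLE_ACTIVE for e in entries
        ):
            raise SchemaError(f"product {pid!r} has no active substance")
        products.append(ProductRecord(pid, float(sales_kg), entries))
    return products


def write_products(
    products: Iterable[ProductRecord],
    products_path: str | Path,
    composition_path: str | Path,
) -> None:
    prows, crows = [], []
    for p in products:
        prows.append({"product_id": p.product_id, "sales_kg": repr(p.sales_kg)})
        for e in p.composition:
            crows.append(
                {
                    "product_id": e.product_id,
                    "substance_id": e.substance_id,
                    "percent": repr(e.mass_fraction * 100.0),
                }
            )
    pd.DataFrame(prows, columns=["product_id", "sales_kg"]).to_csv(
        products_path, index=False
    )
    pd.DataFrame(crows, columns=["product_id", "substance_id", "percent"]).to_csv(
        composition_path, index=False
    )


def load_dose_response(path: str | Path) -> list[DoseResponseDataset]:
    """Read a long-format viability table, grouped by treatment label.
    Zero-concentration rows are kept as controls."""
    df = _read_csv(path, ["treatment", "conc_mg_L", "response_pct", "replicate"])
    if df.empty:
        return []
    conc = _numeric(df, "conc_mg_L", "doseresponse")
    resp = _numeric(df, "response_pct", "doseresponse")
    if np.any(conc < 0):
        raise SchemaError("doseresponse: negative concentration")
    df = df.assign(_conc=conc, _resp=resp)
    datasets = []
    for label, grp in df.groupby("treatment", sort=True):
        datasets.append(
            DoseResponseDataset(
                treatment_label=str(label),
                concentrations=grp["_conc"].to_numpy(),
                responses=grp["_resp"].to_numpy(),
                replicate_ids=grp["replicate"].to_numpy(),
            )
        )
    return datasets


def write_dose_response(
    datasets: Iterable[DoseResponseDataset], path: str | Path
) -> None:
    rows = []
    for ds in datasets:
        for c, r, rep in zip(ds.concentrations, ds.responses, ds.replicate_ids):
            rows.append(
                {
                    "treatment": ds.treatment_label,
                    "conc_mg_L": repr(float(c)),
                    "response_pct": repr(float(r)),
                    "replicate": rep,
                }
            )
    pd.DataFrame(
        rows, columns=["treatment", "conc_mg_L", "response_pct", "replicate"]
    ).to_csv(path, index=False)


def write_priority_report(calls: Iterable[PriorityCall], path: str | Path) -> None:
    """One row per call, deterministically ordered by (product_id, trigger,
    detail) so identical inputs give byte-identical reports."""
    rows = sorted(
        (
            {
                "product_id": c.product_id,
                "trigger": c.trigger,
                "detail_json": c.detail_json(),
            }
            for c in calls
        ),
        key=lambda r: (r["product_id"], r["trigger"], r["detail_json"]),
    )
    pd.DataFrame(rows, columns=["product_id", "trigger", "detail_json"]).to_csv(
        path, index=False
    )


def load_priority_report(path: str | Path) -> list[PriorityCall]:
    df = _read_csv(path, ["product_id", "trigger", "detail_json"])
    return [
        PriorityCall(row.product_id, row.trigger, json.loads(row.detail_json))
        for row in df.itertuples(index=False)
    ]
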