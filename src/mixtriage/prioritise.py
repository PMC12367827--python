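"""Rule-based prioritisation of formulated products.

Four independent evidence streams flag products for follow-up in vitro
testing:

* two-source organ-toxicity scoring of co-formulants — a statistical
  alert suite (binary alerts per sub-model) and an expert rule-based
  system (ordinal likelihood levels) each contribute one point, giving a
  score of 0-2 per substance and endpoint;
* formulation-content thresholds — a score-2 co-formulant triggers when
  its content exceeds 0.1% of the product, a score-1 co-formulant when it
  exceeds 10%;
* toxicokinetic pairing — a product triggers when a co-formulant is an
  in-scope predicted inhibitor (confidence > 50%) of a CYP isoenzyme or
  the P-gp efflux transporter and an active substance in the same product
  is an in-scope predicted substrate of the same target;
* sales ranking — products containing one of the top-selling
  co-formulants (annual co-formulant sales = product sales × content).

All threshold comparisons are strict, matching the "exceeds"/"above"
wording of the underlying rules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import SchemaError
from .tables_io import (
    ROLE_ACTIVE,
    ROLE_COFORMULANT,
    PriorityCall,
    ProductRecord,
    SubstanceRecord,
    _numeric,
    _read_csv,
)

ENDPOINT_HEPATOTOXICITY = "hepatotoxicity"
ENDPOINT_NEPHROTOXICITY = "nephrotoxicity"

#: statistical sub-model suites per endpoint
SUBMODEL_SUITES: dict[str, tuple[str, ...]] = {
    ENDPOINT_HEPATOTOXICITY: (
        "bile_duct_disorder",
        "cholestasis",
        "liver_damage",
        "liver_enzyme_abnormality",
    ),
    ENDPOINT_NEPHROTOXICITY: (
        "bladder_disorder",
        "blood_in_urine",
        "kidney_functional_test_abnormality",
        "nephropathy",
        "renal_disorder",
        "urolithiasis",
    ),
}

ADME_TARGETS = ("CYP1A2", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A4", "P_gp")

TRIGGER_SCORE2 = "organ_tox_score2"
TRIGGER_SCORE1 = "organ_tox_score1"
TRIGGER_ADME = "adme_pair"
TRIGGER_TOP_SALES = "top_sales"
TRIGGERS = (TRIGGER_SCORE2, TRIGGER_SCORE1, TRIGGER_ADME, TRIGGER_TOP_SALES)

DEFAULT_THRESHOLDS = {2: 0.001, 1: 0.10}  # mass fractions
DEFAULT_CONF_MIN = 0.5
DEFAULT_FRAC_MIN = 0.001
DEFAULT_TOP_N_SALES = 10
DEFAULT_ENDPOINTS = (ENDPOINT_HEPATOTOXICITY,)


class Likelihood(enum.IntEnum):
    """Ordinal likelihood vocabulary of expert structure-activity systems.

    ``EQUIVOCAL`` is the lowest level counted as a positive prediction;
    ``NOTHING_TO_REPORT`` means the system has no knowledge to base a
    prediction on, which scores like a negative but is kept distinct for
    auditability.
    """

    NOTHING_TO_REPORT = 0
    INACTIVE_OR_NO_ALERT = 1
    IMPOSSIBLE = 2
    IMPROBABLE = 3
    DOUBTED = 4
    EQUIVOCAL = 5
    PLAUSIBLE = 6
    PROBABLE = 7
    CERTAIN = 8

    @property
    def is_positive(self) -> bool:
        return self >= Likelihood.EQUIVOCAL

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Likelihood":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise SchemaError(f"unknown likelihood level {label!r}") from None


POSITIVE_LEVELS = frozenset(
    {
        Likelihood.EQUIVOCAL,
        Likelihood.PLAUSIBLE,
        Likelihood.PROBABLE,
        Likelihood.CERTAIN,
    }
)


@dataclass(frozen=True)
class StatisticalAlerts:
    """Binary alerts of a statistical model suite for one substance and
    endpoint (4 hepatotoxicity sub-models, 6 nephrotoxicity sub-models)."""

    substance_id: str
    endpoint: str
    submodel_alerts: Mapping[str, int]

    def __post_init__(self) -> None:
        suite = SUBMODEL_SUITES.get(self.endpoint)
        if suite is None:
            raise SchemaError(f"unknown endpoint {self.endpoint!r}")
        for name, alert in self.submodel_alerts.items():
            if name not in suite:
                raise SchemaError(
                    f"sub-model {name!r} not in the {self.endpoint} suite"
                )
            if alert not in (0, 1):
                raise SchemaError(f"alert value {alert!r} not binary")

    @property
    def n_alerts(self) -> int:
        return sum(self.submodel_alerts.values())


@dataclass(frozen=True)
class AdmePrediction:
    """Substrate/inhibitor call of an ADME prediction tool for one target.

    ``in_scope`` is the applicability-domain flag; confidence is only
    meaningful for in-scope predictions, and out-of-scope predictions
    never qualify for pairing.
    """

    substance_id: str
    target: str
    mode: str  # "substrate" | "inhibitor"
    in_scope: bool
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.target not in ADME_TARGETS:
            raise SchemaError(f"unknown ADME target {self.target!r}")
        if self.mode not in ("substrate", "inhibitor"):
            raise SchemaError(f"unknown ADME mode {self.mode!r}")
        if self.in_scope and self.confidence is None:
            raise SchemaError("in-scope prediction without confidence")


@dataclass(frozen=True)
class EndpointScore:
    """Combined two-source organ-toxicity score: one point from the
    statistical suite (any positive alert), one from the expert system
    (likelihood at least equivocal)."""

    substance_id: str
    endpoint: str
    statistical_hit: bool
    expert_hit: bool

    @property
    def score(self) -> int:
        return int(self.statistical_hit) + int(self.expert_hit)


@dataclass(frozen=True)
class SalesRecord:
    """Annual sales of one co-formulant aggregated over all products.

    Entries sharing a CAS number are one record; CAS-less substances
    aggregate by substance id.
    """

    key: str
    cas: str | None
    sales_kg: float
    substance_ids: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# scoring


def score_endpoint(
    stat: StatisticalAlerts | None,
    expert: Likelihood | None,
    substance_id: str | None = None,
    endpoint: str | None = None,
) -> EndpointScore:
    """Combine both prediction sources into a 0-2 score.

    Either source may be missing (counts as no hit).  When ``stat`` is
    given, its substance and endpoint take precedence and a conflicting
    explicit ``endpoint`` argument is an error.
    """
    if stat is not None:
        if endpoint is not None and endpoint != stat.endpoint:
            raise ValueError(
                f"endpoint mismatch: {endpoint!r} vs {stat.endpoint!r}"
            )
        if substance_id is not None and substance_id != stat.substance_id:
            raise ValueError("substance mismatch between sources")
        substance_id, endpoint = stat.substance_id, stat.endpoint
    if substance_id is None or endpoint is None:
        raise ValueError("substance_id and endpoint required when stat is missing")
    statistical_hit = stat is not None and stat.n_alerts >= 1
    expert_hit = expert is not None and expert.is_positive
    return EndpointScore(substance_id, endpoint, statistical_hit, expert_hit)


def score_all(
    stat_alerts: Mapping[tuple[str, str], StatisticalAlerts],
    expert_calls: Mapping[tuple[str, str], Likelihood],
) -> list[EndpointScore]:
    """Score every (substance, endpoint) pair seen by either source."""
    keys = sorted(set(stat_alerts) | set(expert_calls))
    return [
        score_endpoint(
            stat_alerts.get(key), expert_calls.get(key),
            substance_id=key[0], endpoint=key[1],
        )
        for key in keys
    ]


# ---------------------------------------------------------------------------
# prioritisation streams


def _role_map(registry: Sequence[SubstanceRecord]) -> dict[str, str]:
    return {r.substance_id: r.role for r in registry}


def prioritise_organ_toxicity(
    scores: Iterable[EndpointScore],
    products: Sequence[ProductRecord],
    registry: Sequence[SubstanceRecord],
    thresholds: Mapping[int, float] | None = None,
    endpoints: Sequence[str] = DEFAULT_ENDPOINTS,
) -> list[PriorityCall]:
    """Emit one call per (product, co-formulant, endpoint) whose score-s
    content threshold is strictly exceeded.  Score 2 takes precedence over
    score 1 for the same pair.

    Nephrotoxicity is excluded by default — the statistical nephrotoxicity
    suite is considered too insensitive to drive testing decisions — and
    can be re-enabled via ``endpoints``.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    roles = _role_map(registry)
    by_substance: dict[tuple[str, str], EndpointScore] = {}
    for s in scores:
        if s.endpoint in endpoints:
            by_substance[(s.substance_id, s.endpoint)] = s
    calls: list[PriorityCall] = []
    for product in products:
        for entry in product.composition:
            if roles.get(entry.substance_id) != ROLE_COFORMULANT:
                continue
            for endpoint in endpoints:
                sc = by_substance.get((entry.substance_id, endpoint))
                if sc is None or sc.score == 0:
                    continue
                if entry.mass_fraction > thresholds[sc.score]:
                    trigger = TRIGGER_SCORE2 if sc.score == 2 else TRIGGER_SCORE1
                    calls.append(
                        PriorityCall(
                            product.product_id,
                            trigger,
                            {
                                "substance_id": entry.substance_id,
                                "endpoint": endpoint,
                                "score": sc.score,
                                "mass_percent": entry.mass_fraction * 100.0,
                                "statistical_hit": sc.statistical_hit,
                                "expert_hit": sc.expert_hit,
                            },
                        )
                    )
    return calls


def prioritise_adme_pairs(
    preds: Iterable[AdmePrediction],
    products: Sequence[ProductRecord],
    registry: Sequence[SubstanceRecord],
    conf_min: float = DEFAULT_CONF_MIN,
    frac_min: float = DEFAULT_FRAC_MIN,
    substrate_as: set[str] | None = None,
) -> list[PriorityCall]:
    """Flag products where a co-formulant inhibitor and an active-substance
    substrate of the same target co-occur.

    A co-formulant qualifies when it is an in-scope inhibitor with
    confidence > ``conf_min`` present above ``frac_min`` of the product
    mass; an active substance qualifies as an in-scope substrate with
    confidence > ``conf_min`` (optionally restricted to a hepatotoxic
    active-substance list via ``substrate_as``).  One call per (product,
    target), listing every qualifying inhibitor-substrate pair.
    """
    roles = _role_map(registry)
    inhibitors: dict[tuple[str, str], float] = {}
    substrates: dict[tuple[str, str], float] = {}
    for p in preds:
        if not p.in_scope or p.confidence is None or p.confidence <= conf_min:
            continue
        table = inhibitors if p.mode == "inhibitor" else substrates
        key = (p.substance_id, p.target)
        table[key] = max(table.get(key, 0.0), p.confidence)

    calls: list[PriorityCall] = []
    for product in products:
        for target in ADME_TARGETS:
            inh = [
                (e.substance_id, inhibitors[(e.substance_id, target)], e.mass_fraction)
                for e in product.composition
                if roles.get(e.substance_id) == ROLE_COFORMULANT
                and (e.substance_id, target) in inhibitors
                and e.mass_fraction > frac_min
            ]
            if not inh:
                continue
            sub = [
                (e.substance_id, substrates[(e.substance_id, target)])
                for e in product.composition
                if roles.get(e.substance_id) == ROLE_ACTIVE
                and (e.substance_id, target) in substrates
                and (substrate_as is None or e.substance_id in substrate_as)
            ]
            if not sub:
                continue
            pairs = [
                {
                    "inhibitor": i_id,
                    "inhibitor_confidence": i_conf,
                    "inhibitor_mass_percent": i_frac * 100.0,
                    "substrate": s_id,
                    "substrate_confidence": s_conf,
                }
                for i_id, i_conf, i_frac in inh
                for s_id, s_conf in sub
            ]
            calls.append(
                PriorityCall(
                    product.product_id,
                    TRIGGER_ADME,
                    {"target": target, "pairs": pairs},
                )
            )
    return calls


def compute_coformulant_sales(
    products: Sequence[ProductRecord],
    registry: Sequence[SubstanceRecord],
) -> list[SalesRecord]:
    """Annual co-formulant sales: sum over products of product sales (kg)
    times the co-formulant's mass fraction, aggregated by CAS (entries with
    the same CAS are one record; CAS-less entries aggregate by id)."""
    by_id = {r.substance_id: r for r in registry}
    totals: dict[str, float] = {}
    members: dict[str, set[str]] = {}
    cas_of: dict[str, str | None] = {}
    for product in products:
        for entry in product.composition:
            rec = by_id.get(entry.substance_id)
            if rec is None or rec.role != ROLE_COFORMULANT:
                continue
            key = rec.cas if rec.cas else rec.substance_id
            totals[key] = totals.get(key, 0.0) + product.sales_kg * entry.mass_fraction
            members.setdefault(key, set()).add(rec.substance_id)
            cas_of[key] = rec.cas
    return [
        SalesRecord(key, cas_of[key], totals[key], tuple(sorted(members[key])))
        for key in sorted(totals)
    ]


def rank_top_sales(
    sales: Sequence[SalesRecord],
    products: Sequence[ProductRecord],
    registry: Sequence[SubstanceRecord],
    n: int = DEFAULT_TOP_N_SALES,
    frac_min: float = 0.0,
) -> list[PriorityCall]:
    """Flag products containing one of the ``n`` best-selling co-formulants
    (ties broken by aggregation-key lexicographic order).  One call per
    (product, top co-formulant) present above ``frac_min``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(sales, key=lambda r: (-r.sales_kg, r.key))[:n]
    rank_of: dict[str, tuple[int, SalesRecord]] = {}
    for rank, rec in enumerate(ranked, start=1):
        for sid in rec.substance_ids:
            rank_of[sid] = (rank, rec)
    calls: list[PriorityCall] = []
    for product in products:
        for entry in product.composition:
            hit = rank_of.get(entry.substance_id)
            if hit is None or not entry.mass_fraction > frac_min:
                continue
            rank, rec = hit
            calls.append(
                PriorityCall(
                    product.product_id,
                    TRIGGER_TOP_SALES,
                    {
                        "substance_id": entry.substance_id,
                        "sales_rank": rank,
                        "coformulant_sales_kg": rec.sales_kg,
                        "mass_percent": entry.mass_fraction * 100.0,
                    },
                )
            )
    return calls


def merge_priorities(
    *call_collections: Iterable[PriorityCall],
) -> tuple[list[PriorityCall], dict]:
    """Concatenate calls from all streams and summarise unique products
    overall and per trigger (a multi-trigger product counts once in the
    unique total)."""
    calls = [c for coll in call_collections for c in coll]
    per_trigger: dict[str, set[str]] = {t: set() for t in TRIGGERS}
    for c in calls:
        per_trigger.setdefault(c.trigger, set()).add(c.product_id)
    unique = set().union(*per_trigger.values()) if per_trigger else set()
    summary = {
        "n_calls": len(calls),
        "n_unique_products": len(unique),
        "unique_products": sorted(unique),
        "per_trigger": {t: len(s) for t, s in per_trigger.items()},
        "products_per_trigger": {t: sorted(s) for t, s in per_trigger.items()},
    }
    return calls, summary


# ---------------------------------------------------------------------------
# prediction-table I/O (schemas documented in the module docstring of
# :mod:`mixtriage.tables_io`)


def load_stat_alerts(
    path: str | Path,
) -> dict[tuple[str, str], StatisticalAlerts]:
    """Read stat_alerts.csv (substance_id,endpoint,submodel,alert) into
    per-(substance, endpoint) alert bundles."""
    df = _read_csv(path, ["substance_id", "endpoint", "submodel", "alert"])
    alerts = _numeric(df, "alert", "stat_alerts").astype(int)
    bundles: dict[tuple[str, str], dict[str, int]] = {}
    for (sid, ep, sub), alert in zip(
        zip(df["substance_id"], df["endpoint"], df["submodel"]), alerts, strict=True
    ):
        bundles.setdefault((sid, ep), {})[sub] = int(alert)
    return {
        (sid, ep): StatisticalAlerts(sid, ep, sub_alerts)
        for (sid, ep), sub_alerts in bundles.items()
    }


def load_expert_calls(path: str | Path) -> dict[tuple[str, str], Likelihood]:
    """Read expert_calls.csv (substance_id,endpoint,likelihood).  Several
    calls for the same substance/endpoint collapse to the highest level."""
    df = _read_csv(path, ["substance_id", "endpoint", "likelihood"])
    out: dict[tuple[str, str], Likelihood] = {}
    for row in df.itertuples(index=False):
        key = (row.substance_id, row.endpoint)
        level = Likelihood.from_label(row.likelihood)
        if key not in out or level > out[key]:
            out[key] = level
    return out


def load_adme(path: str | Path) -> list[AdmePrediction]:
    """Read adme.csv (substance_id,target,mode,in_scope,confidence).
    Confidence may be empty for out-of-scope rows."""
    df = _read_csv(path, ["substance_id", "target", "mode", "in_scope", "confidence"])
    preds = []
    for row in df.itertuples(index=False):
        in_scope = str(row.in_scope).strip().lower() in {"1", "true", "yes"}
        conf_raw = str(row.confidence).strip()
        confidence = float(conf_raw) if conf_raw else None
        preds.append(
            AdmePrediction(row.substance_id, row.target, row.mode, in_scope, confidence)
        )
    return preds


def write_stat_alerts(
    bundles: Mapping[tuple[str, str], StatisticalAlerts] | Iterable[StatisticalAlerts],
    path: str | Path,
) -> None:
    import pandas as pd

    items = bundles.values() if isinstance(bundles, Mapping) else bundles
    rows = [
        {
            "substance_id": b.substance_id,
            "endpoint": b.endpoint,
            "submodel": sub,
            "alert": alert,
        }
        for b in items
        for sub, alert in sorted(b.submodel_alerts.items())
    ]
    pd.DataFrame(
        rows, columns=["substance_id", "endpoint", "submodel", "alert"]
    ).to_csv(path, index=False)


def write_expert_calls(
    calls: Mapping[tuple[str, str], Likelihood], path: str | Path
) -> None:
    import pandas as pd

    rows = [
        {"substance_id": sid, "endpoint": ep, "likelihood": level.label}
        for (sid, ep), level in sorted(calls.items())
    ]
    pd.DataFrame(rows, columns=["substance_id", "endpoint", "likelihood"]).to_csv(
        path, index=False
    )


def write_adme(preds: Iterable[AdmePrediction], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "substance_id": p.substance_id,
            "target": p.target,
            "mode": p.mode,
            "in_scope": int(p.in_scope),
            "confidence": "" if p.confidence is None else repr(p.confidence),
        }
        for p in preds
    ]
    pd.DataFrame(
        rows, columns=["substance_id", "target", "mode", "in_scope", "confidence"]
    ).to_csv(path, index=False)
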