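"""Ground-truth-labelled synthetic data for every pipeline stage.

The real composition landscape behind this workflow (authorised products
in Germany and their formulations) is confidential, so every stage is
exercised on a generated stand-in: a registry of active substances and
co-formulants, product compositions with annual sales, in-silico
prediction tables with controllable sensitivity/specificity, and
dose-response data with a controllable synergy factor.

Scale defaults mirror the real landscape (~1048 co-formulant entries,
~1603 products, ~185 hepatotoxic active substances); prevalence defaults
for alerts and inhibitor/substrate status echo the reported alert counts
of the commercial tools at that scale.  Sales are log-normal so a handful
of bulk co-formulants (water, solvents) dominate the ranking, matching
the heavily skewed published top-10 table.

Everything is deterministic under the seed.  The ``TruthBundle`` records
which products *should* be flagged by each trigger when predictions are
error-free, which makes exact end-to-end recovery testable.

Synergy is modelled as a potency multiplier ``s`` >= 1 on the mixture's
effective dose — a minimal stand-in for a toxicokinetic interaction
(e.g. CYP inhibition raising the internal dose) whose model deviation
ratio is analytically known: noiseless data generated with factor ``s``
have MDR exactly ``s``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .prioritise import (
    ADME_TARGETS,
    DEFAULT_CONF_MIN,
    DEFAULT_FRAC_MIN,
    DEFAULT_THRESHOLDS,
    DEFAULT_TOP_N_SALES,
    ENDPOINT_HEPATOTOXICITY,
    ENDPOINT_NEPHROTOXICITY,
    SUBMODEL_SUITES,
    TRIGGER_ADME,
    TRIGGER_SCORE1,
    TRIGGER_SCORE2,
    TRIGGER_TOP_SALES,
    AdmePrediction,
    Likelihood,
    StatisticalAlerts,
    write_adme,
    write_expert_calls,
    write_stat_alerts,
)
from .tables_io import (
    ROLE_ACTIVE,
    ROLE_COFORMULANT,
    CompositionEntry,
    DoseResponseDataset,
    MixtureSpec,
    ProductRecord,
    SubstanceRecord,
    write_dose_response,
    write_products,
    write_registry,
)

_ENDPOINTS = (ENDPOINT_HEPATOTOXICITY, ENDPOINT_NEPHROTOXICITY)

_POSITIVE_LEVELS = (
    Likelihood.EQUIVOCAL,
    Likelihood.PLAUSIBLE,
    Likelihood.PROBABLE,
    Likelihood.CERTAIN,
)
_NEGATIVE_LEVELS = (
    Likelihood.NOTHING_TO_REPORT,
    Likelihood.INACTIVE_OR_NO_ALERT,
    Likelihood.IMPROBABLE,
    Likelihood.DOUBTED,
)


@dataclass(frozen=True)
class LandscapeConfig:
    """Generator configuration; defaults are the study conditions."""

    n_products: int = 1603
    n_coformulants: int = 1048
    n_active_substances: int = 185
    smiles_availability: float = 0.65
    duplicate_cas_rate: float = 0.10
    class_rate: float = 0.15
    #: log-normal annual product sales, parameters in log-kg
    sales_mu_log_kg: float = 8.0
    sales_sigma_log_kg: float = 2.0
    as_per_product: tuple[int, int] = (1, 3)
    coformulants_per_product: tuple[int, int] = (2, 8)
    #: per-endpoint prevalence of true statistical / expert positives
    stat_positive_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            ENDPOINT_HEPATOTOXICITY: 0.22,
            ENDPOINT_NEPHROTOXICITY: 0.10,
        }
    )
    expert_positive_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            ENDPOINT_HEPATOTOXICITY: 0.07,
            ENDPOINT_NEPHROTOXICITY: 0.16,
        }
    )
    #: per-target prevalence of true inhibitors (co-formulants)
    inhibitor_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "P_gp": 0.086, "CYP1A2": 0.027, "CYP2C9": 0.023,
            "CYP2C19": 0.008, "CYP2D6": 0.004, "CYP3A4": 0.010,
        }
    )
    #: per-target prevalence of true substrates (active substances)
    substrate_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "P_gp": 0.21, "CYP1A2": 0.115, "CYP2C9": 0.071,
            "CYP2C19": 0.060, "CYP2D6": 0.016, "CYP3A4": 0.126,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("smiles_availability", "duplicate_cas_rate", "class_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_products", "n_coformulants", "n_active_substances"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_products > 0 and self.n_active_substances == 0:
            raise ConfigError("products need at least one active substance")
        for name in ("as_per_product", "coformulants_per_product"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ConfigError(f"invalid range for {name}: ({lo}, {hi})")
        if self.coformulants_per_product[1] > self.n_coformulants:
            raise ConfigError("coformulants_per_product exceeds n_coformulants")
        for rates in (
            self.stat_positive_rate, self.expert_positive_rate,
            self.inhibitor_rate, self.substrate_rate,
        ):
            for k, v in rates.items():
                if not (0.0 <= v <= 1.0):
                    raise ConfigError(f"rate {k}={v} out of [0, 1]")


@dataclass
class TruthBundle:
    """Ground truth behind a generated landscape.

    ``trigger_products`` holds, per trigger, the products that error-free
    predictions would flag under the default rule parameters.
    """

    eligible_ids: tuple[str, ...]
    as_ids: tuple[str, ...]
    stat_positive: dict[tuple[str, str], bool]
    stat_n_alerts: dict[tuple[str, str], int]
    expert_level: dict[tuple[str, str], Likelihood]
    inhibitors: set[tuple[str, str]]
    substrates: set[tuple[str, str]]
    sales_by_key: dict[str, float]
    trigger_products: dict[str, frozenset[str]]

    def to_jsonable(self) -> dict:
        return {
            "eligible_ids": list(self.eligible_ids),
            "as_ids": list(self.as_ids),
            "stat_positive": [
                [sid, ep, bool(v)] for (sid, ep), v in sorted(self.stat_positive.items())
            ],
            "expert_level": [
                [sid, ep, lv.label] for (sid, ep), lv in sorted(self.expert_level.items())
            ],
            "inhibitors": sorted(list(t) for t in self.inhibitors),
            "substrates": sorted(list(t) for t in self.substrates),
            "sales_by_key": dict(sorted(self.sales_by_key.items())),
            "trigger_products": {
                t: sorted(s) for t, s in self.trigger_products.items()
            },
        }


@dataclass
class Landscape:
    registry: list[SubstanceRecord]
    products: list[ProductRecord]
    truth: TruthBundle
    config: LandscapeConfig


def _make_cas(rng: np.random.Generator) -> str:
    """Random CAS-format number with a valid check digit."""
    body = rng.integers(10_000, 9_999_999)
    suffix = rng.integers(10, 99)
    digits = f"{body}{suffix:02d}"
    check = sum(int(d) * w for w, d in enumerate(reversed(digits), start=1)) % 10
    return f"{body}-{suffix:02d}-{check}"


def gen_landscape(config: LandscapeConfig | None = None) -> Landscape:
    """Generate registry, products and ground truth; fully seeded."""
    config = LandscapeConfig() if config is None else config
    config.validate()
    rng = np.random.default_rng(config.seed)

    registry: list[SubstanceRecord] = []
    for i in range(config.n_active_substances):
        registry.append(
            SubstanceRecord(
                substance_id=f"as{i:04d}",
                name=f"active substance {i}",
                role=ROLE_ACTIVE,
                cas=_make_cas(rng),
                smiles=f"AS{i}",
            )
        )

    cas_pool: list[str] = []
    eligible_ids: list[str] = []
    seen_cas: set[str] = set()
    for i in range(config.n_coformulants):
        sid = f"cf{i:04d}"
        is_class = bool(rng.random() < config.class_rate)
        duplicate = (
            not is_class and cas_pool and rng.random() < config.duplicate_cas_rate
        )
        cas = str(rng.choice(cas_pool)) if duplicate else _make_cas(rng)
        if not duplicate:
            cas_pool.append(cas)
        has_smiles = not is_class and rng.random() < config.smiles_availability
        registry.append(
            SubstanceRecord(
                substance_id=sid,
                name=f"co-formulant {i}",
                role=ROLE_COFORMULANT,
                cas=cas,
                smiles=f"CF{i}" if has_smiles else None,
                is_class=is_class,
            )
        )
        # mirror of tables_io.filter_unique_coformulants, kept as the
        # generator's own bookkeeping
        if not is_class and has_smiles and cas not in seen_cas:
            seen_cas.add(cas)
            eligible_ids.append(sid)

    # ---- truth labels on QSAR-eligible co-formulants --------------------
    stat_positive: dict[tuple[str, str], bool] = {}
    stat_n_alerts: dict[tuple[str, str], int] = {}
    expert_level: dict[tuple[str, str], Likelihood] = {}
    for sid in eligible_ids:
        for ep in _ENDPOINTS:
            pos = bool(rng.random() < config.stat_positive_rate[ep])
            stat_positive[(sid, ep)] = pos
            stat_n_alerts[(sid, ep)] = (
                int(rng.integers(1, len(SUBMODEL_SUITES[ep]) + 1)) if pos else 0
            )
            if rng.random() < config.expert_positive_rate[ep]:
                expert_level[(sid, ep)] = _POSITIVE_LEVELS[
                    rng.integers(len(_POSITIVE_LEVELS))
                ]
            else:
                expert_level[(sid, ep)] = _NEGATIVE_LEVELS[
                    rng.integers(len(_NEGATIVE_LEVELS))
                ]

    inhibitors: set[tuple[str, str]] = set()
    for sid in eligible_ids:
        for target in ADME_TARGETS:
            if rng.random() < config.inhibitor_rate[target]:
                inhibitors.add((sid, target))
    substrates: set[tuple[str, str]] = set()
    for rec in registry[: config.n_active_substances]:
        for target in ADME_TARGETS:
            if rng.random() < config.substrate_rate[target]:
                substrates.add((rec.substance_id, target))

    # ---- products -------------------------------------------------------
    as_ids = [r.substance_id for r in registry if r.role == ROLE_ACTIVE]
    cf_ids = [r.substance_id for r in registry if r.role == ROLE_COFORMULANT]
    products: list[ProductRecord] = []
    for j in range(config.n_products):
        pid = f"p{j:04d}"
        n_as = int(rng.integers(config.as_per_product[0], config.as_per_product[1] + 1))
        n_cf = int(
            rng.integers(
                config.coformulants_per_product[0],
                config.coformulants_per_product[1] + 1,
            )
        )
        chosen_as = rng.choice(as_ids, size=min(n_as, len(as_ids)), replace=False)
        chosen_cf = rng.choice(cf_ids, size=n_cf, replace=False)
        as_total = float(rng.uniform(0.05, 0.5))
        as_fracs = rng.dirichlet(np.full(len(chosen_as), 2.0)) * as_total
        cf_total = float(rng.uniform(0.3, 1.0 - as_total))
        # alpha < 1 gives a few dominant co-formulants plus trace ones
        cf_fracs = rng.dirichlet(np.full(n_cf, 0.5)) * cf_total
        cf_fracs = np.maximum(cf_fracs, 1e-6)
        entries = [
            CompositionEntry(pid, sid, float(f))
            for sid, f in zip(chosen_as, as_fracs)
        ] + [
            CompositionEntry(pid, sid, float(f))
            for sid, f in zip(chosen_cf, cf_fracs)
        ]
        sales = float(
            np.exp(rng.normal(config.sales_mu_log_kg, config.sales_sigma_log_kg))
        )
        products.append(ProductRecord(pid, sales, tuple(entries)))

    truth = TruthBundle(
        eligible_ids=tuple(eligible_ids),
        as_ids=tuple(as_ids),
        stat_positive=stat_positive,
        stat_n_alerts=stat_n_alerts,
        expert_level=expert_level,
        inhibitors=inhibitors,
        substrates=substrates,
        sales_by_key={},
        trigger_products={},
    )
    _fill_truth_triggers(truth, registry, products)
    return Landscape(registry, products, truth, config)


def _fill_truth_triggers(
    truth: TruthBundle,
    registry: Sequence[SubstanceRecord],
    products: Sequence[ProductRecord],
) -> None:
    """Ground-truth trigger sets under the default rule parameters,
    computed with plain loops over the truth tables."""
    by_id = {r.substance_id: r for r in registry}
    score: dict[str, int] = {}
    for sid in truth.eligible_ids:
        key = (sid, ENDPOINT_HEPATOTOXICITY)
        s = int(truth.stat_positive[key]) + int(truth.expert_level[key].is_positive)
        score[sid] = s

    score2, score1, adme, top_sales = set(), set(), set(), set()
    sales_by_key: dict[str, float] = {}
    key_members: dict[str, set[str]] = {}
    for product in products:
        for e in product.composition:
            rec = by_id[e.substance_id]
            if rec.role != ROLE_COFORMULANT:
                continue
            s = score.get(e.substance_id, 0)
            if s == 2 and e.mass_fraction > DEFAULT_THRESHOLDS[2]:
                score2.add(product.product_id)
            elif s == 1 and e.mass_fraction > DEFAULT_THRESHOLDS[1]:
                score1.add(product.product_id)
            key = rec.cas if rec.cas else rec.substance_id
            sales_by_key[key] = (
                sales_by_key.get(key, 0.0) + product.sales_kg * e.mass_fraction
            )
            key_members.setdefault(key, set()).add(rec.substance_id)
        for target in ADME_TARGETS:
            has_inh = any(
                by_id[e.substance_id].role == ROLE_COFORMULANT
                and (e.substance_id, target) in truth.inhibitors
                and e.mass_fraction > DEFAULT_FRAC_MIN
                for e in product.composition
            )
            has_sub = any(
                by_id[e.substance_id].role == ROLE_ACTIVE
                and (e.substance_id, target) in truth.substrates
                for e in product.composition
            )
            if has_inh and has_sub:
                adme.add(product.product_id)

    top_keys = {
        key
        for key, _ in sorted(sales_by_key.items(), key=lambda kv: (-kv[1], kv[0]))[
            :DEFAULT_TOP_N_SALES
        ]
    }
    top_ids = set().union(*(key_members[k] for k in top_keys)) if top_keys else set()
    for product in products:
        if any(
            e.substance_id in top_ids and e.mass_fraction > 0.0
            for e in product.composition
        ):
            top_sales.add(product.product_id)

    truth.sales_by_key = sales_by_key
    truth.trigger_products = {
        TRIGGER_SCORE2: frozenset(score2),
        TRIGGER_SCORE1: frozenset(score1),
        TRIGGER_ADME: frozenset(adme),
        TRIGGER_TOP_SALES: frozenset(top_sales),
    }


# ---------------------------------------------------------------------------
# prediction tables with sensitivity/specificity knobs


def gen_prediction_tables(
    truth: TruthBundle,
    sensitivity: float = 1.0,
    specificity: float = 1.0,
    out_of_scope_rate: float = 0.05,
    seed: int = 0,
) -> tuple[
    dict[tuple[str, str], StatisticalAlerts],
    dict[tuple[str, str], Likelihood],
    list[AdmePrediction],
]:
    """Emulate the three prediction tools on the truth labels.

    Each true positive is flagged with probability ``sensitivity``, each
    true negative with probability ``1 - specificity``.  With both at 1
    the tables equal the truth exactly.  Out-of-scope marking (ADME
    applicability domain) is applied to true-negative rows only, so it
    never hides a true interaction.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ConfigError("sensitivity and specificity must be in [0, 1]")
    rng = np.random.default_rng(seed)

    stat: dict[tuple[str, str], StatisticalAlerts] = {}
    expert: dict[tuple[str, str], Likelihood] = {}
    for sid in truth.eligible_ids:
        for ep in _ENDPOINTS:
            key = (sid, ep)
            suite = SUBMODEL_SUITES[ep]
            true_pos = truth.stat_positive[key]
            flagged = rng.random() < (sensitivity if true_pos else 1.0 - specificity)
            n_alerts = (truth.stat_n_alerts[key] if true_pos else 1) if flagged else 0
            hot = set(
                rng.choice(len(suite), size=n_alerts, replace=False)
            ) if n_alerts else set()
            stat[key] = StatisticalAlerts(
                sid, ep, {m: int(i in hot) for i, m in enumerate(suite)}
            )

            level = truth.expert_level[key]
            if level.is_positive:
                expert[key] = (
                    level
                    if rng.random() < sensitivity
                    else Likelihood.IMPROBABLE
                )
            else:
                expert[key] = (
                    Likelihood.EQUIVOCAL
                    if rng.random() >= specificity
                    else level
                )

    adme: list[AdmePrediction] = []

    def _adme_rows(ids: Sequence[str], mode: str, true_set: set) -> None:
        for sid in ids:
            for target in ADME_TARGETS:
                is_true = (sid, target) in true_set
                flagged = rng.random() < (
                    sensitivity if is_true else 1.0 - specificity
                )
                out = (not is_true) and rng.random() < out_of_scope_rate
                conf = (
                    float(rng.uniform(0.55, 0.99))
                    if flagged
                    else float(rng.uniform(0.01, 0.45))
                )
                adme.append(
                    AdmePrediction(
                        sid, target, mode,
                        in_scope=not out,
                        confidence=None if out else conf,
                    )
                )

    _adme_rows(truth.eligible_ids, "inhibitor", truth.inhibitors)
    _adme_rows(truth.as_ids, "substrate", truth.substrates)
    return stat, expert, adme


# ---------------------------------------------------------------------------
# dose-response generators


def default_doses(b: float, n: int = 8) -> np.ndarray:
    """Eight-point geometric dose design spanning b/16 .. 16 b (mg/L)."""
    return np.geomspace(b / 16.0, b * 16.0, n)


def gen_dose_response(
    params: Mapping[str, float],
    model: str = "exponential",
    doses: np.ndarray | None = None,
    reps: int = 3,
    noise_sd: float = 5.0,
    n_controls: int = 3,
    seed: int = 0,
    label: str = "treatment",
) -> DoseResponseDataset:
    """Viability data from a known curve: ``reps`` technical replicates at
    each of eight concentrations plus zero-dose controls, with i.i.d.
    Gaussian noise on the % response."""
    from .dose_response import _MODEL_FUNCS  # local import avoids cycle

    if reps < 1:
        raise ConfigError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if doses is None:
        doses = default_doses(params["b"])
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ConfigError("doses must be positive")
    conc = np.concatenate([np.zeros(n_controls), np.repeat(doses, reps)])
    reps_ids = np.concatenate(
        [np.arange(n_controls), np.tile(np.arange(reps), doses.size)]
    )
    clean = _MODEL_FUNCS[model](
        conc, params["a"], params["b"], params["c"], params["d"]
    )
    noisy = clean + rng.normal(0.0, noise_sd, size=conc.shape) if noise_sd > 0 else clean
    return DoseResponseDataset(
        treatment_label=label,
        concentrations=conc,
        responses=noisy,
        replicate_ids=reps_ids,
    )


def mixture_b(b_components: Mapping[str, float], spec: MixtureSpec) -> float:
    """Mass-fraction-weighted harmonic potency scale of a parallel mixture."""
    return 1.0 / sum(frac / b_components[lbl] for lbl, frac in spec.components)


def gen_mixture_response(
    a: float,
    c: float,
    d: float,
    b_components: Mapping[str, float],
    spec: MixtureSpec,
    synergy_s: float = 1.0,
    model: str = "exponential",
    doses: np.ndarray | None = None,
    reps: int = 3,
    noise_sd: float = 5.0,
    n_controls: int = 3,
    seed: int = 0,
    label: str = "mixture",
) -> DoseResponseDataset:
    """Mixture viability data under concentration addition with an optional
    synergy factor: the effective dose is multiplied by ``s``, i.e. the
    observed potency scale is b_mix / s.  ``s = 1`` reproduces the CA
    curve exactly; the true MDR equals ``s``."""
    if synergy_s <= 0:
        raise ConfigError("synergy factor must be positive")
    b_mix = mixture_b(b_components, spec)
    if doses is None:
        doses = default_doses(b_mix)
    ds = gen_dose_response(
        {"a": a, "b": b_mix / synergy_s, "c": c, "d": d},
        model=model,
        doses=doses,
        reps=reps,
        noise_sd=noise_sd,
        n_controls=n_controls,
        seed=seed,
        label=label,
    )
    ds.mixture_spec = spec
    return ds


# ---------------------------------------------------------------------------
# fixture bundle

#: default two-component mixture study: parallel exponential curves with
#: shared (a, c, d) and a fourfold potency difference
DEFAULT_MIX_SHARED = {"a": 100.0, "c": 0.0, "d": 2.0}
DEFAULT_MIX_B = {"compound_A": 10.0, "compound_B": 40.0}
DEFAULT_MIX_SPEC = MixtureSpec((("compound_A", 0.5), ("compound_B", 0.5)))


def gen_fixture_bundle(
    outdir: str | Path,
    config: LandscapeConfig | None = None,
    sensitivity: float = 1.0,
    specificity: float = 1.0,
    noise_sd: float = 5.0,
    synergy_s: float = 1.0,
) -> Path:
    """Write a complete CSV fixture bundle plus truth.json to ``outdir``."""
    config = LandscapeConfig() if config is None else config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scape = gen_landscape(config)
    write_registry(scape.registry, outdir / "registry.csv")
    write_products(
        scape.products, outdir / "products.csv", outdir / "composition.csv"
    )
    stat, expert, adme = gen_prediction_tables(
        scape.truth, sensitivity, specificity, seed=config.seed + 1
    )
    write_stat_alerts(stat, outdir / "stat_alerts.csv")
    write_expert_calls(expert, outdir / "expert_calls.csv")
    write_adme(adme, outdir / "adme.csv")

    shared, bmap, spec = DEFAULT_MIX_SHARED, DEFAULT_MIX_B, DEFAULT_MIX_SPEC
    datasets = [
        gen_dose_response(
            {**shared, "b": b}, noise_sd=noise_sd,
            seed=config.seed + 10 + i, label=lbl,
        )
        for i, (lbl, b) in enumerate(sorted(bmap.items()))
    ]
    datasets.append(
        gen_mixture_response(
            shared["a"], shared["c"], shared["d"], bmap, spec,
            synergy_s=synergy_s, noise_sd=noise_sd,
            seed=config.seed + 20, label="mixture",
        )
    )
    write_dose_response(datasets, outdir / "doseresponse.csv")

    truth_doc = scape.truth.to_jsonable()
    truth_doc["mixture_study"] = {
        "shared": shared,
        "b_components": bmap,
        "spec": {lbl: frac for lbl, frac in spec.components},
        "synergy_s": synergy_s,
        "true_b_mix": mixture_b(bmap, spec),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    return outdir
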