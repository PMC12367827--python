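"""Dose-response fitting and concentration-addition mixture modelling.

Two four-parameter sigmoid families are fitted to viability data
expressed as % of solvent control:

* exponential:  y = a * [c - (c - 1) * exp(-(x/b)^d)]
* Hill:         y = a * [1 + (c - 1) * x^d / (b^d + x^d)]

In both, ``a`` is the response at zero dose, ``a*c`` the asymptote at
infinite dose, ``b`` a dose scale in mg/L and ``d`` a shape exponent.
Model choice is by lowest AIC (Gaussian residuals, constant dropped:
AIC = n ln(RSS/n) + 2k), ties going to the exponential model.

The EC50 — the dose producing 50% of the zero-dose response — has closed
forms in both families and exists only when the asymptotic fold change
``c`` is below 0.5.

Mixtures are assessed against concentration addition (Loewe additivity):
components are fitted jointly with shared (a, c, d) and component-specific
potency scales b_i (the parallel-curve assumption), and the theoretical
mixture curve is the shared-shape model with the mass-fraction-weighted
harmonic scale b_mix = 1 / sum(pi_i / b_i).  Deviation from additivity is
quantified by the model deviation ratio MDR = EC50_predicted /
EC50_observed; a mixture is called more than additive (synergistic) when
MDR exceeds the threshold (default 2) and less than additive
(antagonistic) below its reciprocal.

The IC50 of enzyme-inhibition data is estimated separately with the
four-parameter logistic on log10 concentration,
Y = Bottom + (Top-Bottom) / (1 + 10^((LogIC50 - X) * HillSlope)).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .errors import (
    ClassificationError,
    DegenerateFitError,
    UnreachableLevelError,
)
from .tables_io import DoseResponseDataset, MixtureSpec

MODEL_EXPONENTIAL = "exponential"
MODEL_HILL = "hill"
MODEL_FOURPL = "fourpl"

#: tie-break preference for AIC model selection
_MODEL_PREFERENCE = {MODEL_EXPONENTIAL: 0, MODEL_HILL: 1, MODEL_FOURPL: 2}

_AIC_TIE_TOL = 1e-9
DEFAULT_MDR_THRESHOLD = 2.0

CALL_ADDITIVE = "additive"
CALL_MORE_THAN_ADDITIVE = "more_than_additive"
CALL_LESS_THAN_ADDITIVE = "less_than_additive"

# parameter bounds shared by both sigmoid families: response scale a,
# dose scale b, fold change c, shape d
_LOWER = np.array([1e-6, 1e-9, 0.0, 0.05])
_UPPER = np.array([1e6, 1e12, 5.0, 10.0])

_C_STARTS = (0.0, 0.25)
_D_STARTS = (0.5, 1.0, 2.0, 4.0)


def exponential_model(
    x: np.ndarray, a: float, b: float, c: float, d: float
) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return a * (c - (c - 1.0) * np.exp(-((x / b) ** d)))


def hill_model(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    xd = x**d
    return a * (1.0 + (c - 1.0) * xd / (b**d + xd))


def fourpl_model(
    logx: np.ndarray, bottom: float, top: float, logic50: float, hillslope: float
) -> np.ndarray:
    logx = np.asarray(logx, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logic50 - logx) * hillslope))


_MODEL_FUNCS: dict[str, Callable] = {
    MODEL_EXPONENTIAL: exponential_model,
    MODEL_HILL: hill_model,
}


def aic_gaussian(rss: float, n: int, k: int) -> float:
    """AIC under i.i.d. Gaussian residuals, constant term dropped.  A zero
    RSS (exact interpolation) is floored at the smallest positive float."""
    return n * math.log(max(rss, np.finfo(float).tiny) / n) + 2 * k


@dataclass(frozen=True)
class FitResult:
    model: str
    params: Mapping[str, float]
    rss: float
    n_obs: int
    k_params: int
    aic: float
    converged: bool
    ec50: float | None = None
    treatment_label: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.params
        if self.model == MODEL_FOURPL:
            return fourpl_model(
                np.log10(np.asarray(x, dtype=float)),
                p["Bottom"], p["Top"], p["LogIC50"], p["HillSlope"],
            )
        return _MODEL_FUNCS[self.model](x, p["a"], p["b"], p["c"], p["d"])


@dataclass(frozen=True)
class ParallelFit:
    """Joint fit of several treatments with shared (a, c, d) and one
    potency scale b per treatment (relative-potency assumption)."""

    model: str
    a: float
    c: float
    d: float
    b: Mapping[str, float]
    rss: float
    n_obs: int
    k_params: int
    aic: float
    converged: bool

    def curve(self, label: str) -> Callable[[np.ndarray], np.ndarray]:
        b = self.b[label]
        return lambda x: _MODEL_FUNCS[self.model](x, self.a, b, self.c, self.d)


@dataclass(frozen=True)
class CAPrediction:
    """Theoretical mixture dose-response under concentration addition."""

    model: str
    a: float
    c: float
    d: float
    b_components: Mapping[str, float]
    fractions: Mapping[str, float]
    b_mix: float
    ec50_mix: float | None
    mdr: float | None = None
    call: str | None = None
    ec50_observed: float | None = None

    def curve(self, x: np.ndarray) -> np.ndarray:
        return _MODEL_FUNCS[self.model](x, self.a, self.b_mix, self.c, self.d)


# ---------------------------------------------------------------------------
# EC50 closed forms


def ec50_exponential(params: Mapping[str, float]) -> float:
    """Closed-form dose giving 50% of the zero-dose response:
    x = b * (-ln((c - 0.5)/(c - 1)))^(1/d).  Requires c < 0.5."""
    b, c, d = params["b"], params["c"], params["d"]
    if c >= 0.5:
        raise UnreachableLevelError(
            f"50% of control unreachable: asymptotic fold change c={c} >= 0.5"
        )
    return b * (-math.log((c - 0.5) / (c - 1.0))) ** (1.0 / d)


def ec50_hill(params: Mapping[str, float]) -> float:
    """Closed-form EC50 of the Hill family; occupancy at 50% of control is
    theta = 0.5/(1 - c), so x = b * (theta/(1 - theta))^(1/d)."""
    b, c, d = params["b"], params["c"], params["d"]
    if c >= 0.5:
        raise UnreachableLevelError(
            f"50% of control unreachable: asymptotic fold change c={c} >= 0.5"
        )
    theta = 0.5 / (1.0 - c)
    return b * (theta / (1.0 - theta)) ** (1.0 / d)


_EC50_FUNCS = {MODEL_EXPONENTIAL: ec50_exponential, MODEL_HILL: ec50_hill}


def _try_ec50(model: str, params: Mapping[str, float]) -> float | None:
    try:
        return _EC50_FUNCS[model](params)
    except UnreachableLevelError:
        return None


# ---------------------------------------------------------------------------
# single-treatment fitting


def _check_fit_data(data: DoseResponseDataset, min_distinct: int = 5) -> None:
    if data.n_distinct_positive() < min_distinct:
        raise ValueError(
            f"{data.treatment_label!r}: need >= {min_distinct} distinct positive "
            f"concentrations, got {data.n_distinct_positive()}"
        )
    if np.ptp(data.responses) == 0:
        raise DegenerateFitError(
            f"{data.treatment_label!r}: all responses identical"
        )


def _a_start(data: DoseResponseDataset) -> float:
    controls = data.control_responses
    if controls.size:
        return float(controls.mean())
    lowest = data.positive_doses.min()
    return float(data.responses[data.concentrations == lowest].mean())


def _multistart(
    residuals: Callable[[np.ndarray], np.ndarray],
    starts: Iterable[np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
) -> tuple[np.ndarray, float, bool]:
    """Deterministic multi-start least squares; best RSS wins."""
    best_x, best_rss, converged = None, np.inf, False
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-12, upper - 1e-12)
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=(lower, upper),
                xtol=1e-13, ftol=1e-13, gtol=1e-13, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - pathological start
            continue
        rss = float(2.0 * res.cost)
        if rss < best_rss:
            best_x, best_rss = res.x, rss
        converged = converged or bool(res.success)
    if best_x is None:
        raise DegenerateFitError("no optimiser start produced a solution")
    return best_x, best_rss, converged


def fit_model(data: DoseResponseDataset, model: str = MODEL_EXPONENTIAL) -> FitResult:
    """Least-squares fit of one sigmoid family to one treatment.

    Initialisation is a deterministic 8-point grid: a at the control mean,
    b at the geometric mean of the positive doses, c in {0, 0.25} and d in
    {0.5, 1, 2, 4}.
    """
    if model not in _MODEL_FUNCS:
        raise ValueError(f"unknown model {model!r}")
    _check_fit_data(data)
    func = _MODEL_FUNCS[model]
    x, y = data.concentrations, data.responses
    a0 = _a_start(data)
    b0 = float(np.exp(np.mean(np.log(data.positive_doses))))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return func(x, *theta) - y

    starts = [
        np.array([a0, b0, c0, d0]) for c0 in _C_STARTS for d0 in _D_STARTS
    ]
    theta, rss, converged = _multistart(residuals, starts, _LOWER, _UPPER)
    params = dict(zip(("a", "b", "c", "d"), map(float, theta)))
    n, k = data.n_obs, 4
    return FitResult(
        model=model,
        params=params,
        rss=rss,
        n_obs=n,
        k_params=k,
        aic=aic_gaussian(rss, n, k),
        converged=converged,
        ec50=_try_ec50(model, params),
        treatment_label=data.treatment_label,
    )


def select_model_aic(fits: Sequence[FitResult]) -> FitResult:
    """Pick the fit with the lowest AIC; exact ties prefer the exponential
    model.  Selection is invariant under re-ordering of the input."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    n_obs = {f.n_obs for f in fits}
    if len(n_obs) != 1:
        raise ValueError("AIC comparison requires fits on identical observations")
    return min(
        fits, key=lambda f: (round(f.aic / _AIC_TIE_TOL), _MODEL_PREFERENCE[f.model])
    )


def fit_best(data: DoseResponseDataset) -> FitResult:
    """Fit both sigmoid families and return the AIC-preferred one."""
    return select_model_aic(
        [fit_model(data, MODEL_EXPONENTIAL), fit_model(data, MODEL_HILL)]
    )


# ---------------------------------------------------------------------------
# joint parallel fitting and the CA construction


def fit_parallel(
    datasets: Sequence[DoseResponseDataset], model: str = MODEL_EXPONENTIAL
) -> ParallelFit:
    """Fit several treatments jointly with shared (a, c, d) and one b per
    treatment — the relative-potency structure the CA construction needs."""
    if model not in _MODEL_FUNCS:
        raise ValueError(f"unknown model {model!r}")
    if not datasets:
        raise ValueError("no datasets")
    labels = [ds.treatment_label for ds in datasets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate treatment labels in joint fit")
    for ds in datasets:
        _check_fit_data(ds)
    func = _MODEL_FUNCS[model]
    xs = [ds.concentrations for ds in datasets]
    ys = [ds.responses for ds in datasets]
    a0 = float(np.mean([_a_start(ds) for ds in datasets]))
    b0s = [float(np.exp(np.mean(np.log(ds.positive_doses)))) for ds in datasets]

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, c, d = theta[0], theta[1], theta[2]
        bs = theta[3:]
        return np.concatenate(
            [func(x, a, b, c, d) - y for x, y, b in zip(xs, ys, bs)]
        )

    k = 3 + len(datasets)
    lower = np.concatenate(
        [[_LOWER[0], _LOWER[2], _LOWER[3]], np.full(len(datasets), _LOWER[1])]
    )
    upper = np.concatenate(
        [[_UPPER[0], _UPPER[2], _UPPER[3]], np.full(len(datasets), _UPPER[1])]
    )
    starts = [
        np.concatenate([[a0, c0, d0], b0s]) for c0 in _C_STARTS for d0 in _D_STARTS
    ]
    theta, rss, converged = _multistart(residuals, starts, lower, upper)
    n = sum(ds.n_obs for ds in datasets)
    return ParallelFit(
        model=model,
        a=float(theta[0]),
        c=float(theta[1]),
        d=float(theta[2]),
        b={lbl: float(b) for lbl, b in zip(labels, theta[3:])},
        rss=rss,
        n_obs=n,
        k_params=k,
        aic=aic_gaussian(rss, n, k),
        converged=converged,
    )


def fit_parallel_best(datasets: Sequence[DoseResponseDataset]) -> ParallelFit:
    """Joint parallel fit under both families, AIC-selected (ties to the
    exponential model)."""
    fits = [fit_parallel(datasets, m) for m in (MODEL_EXPONENTIAL, MODEL_HILL)]
    return min(
        fits, key=lambda f: (round(f.aic / _AIC_TIE_TOL), _MODEL_PREFERENCE[f.model])
    )


def ca_mixture_curve(parallel: ParallelFit, spec: MixtureSpec) -> CAPrediction:
    """Theoretical mixture curve under concentration addition.

    With parallel component curves, a mixture dosed at total concentration
    D contains pi_i * D of component i, and Loewe's sum
    sum(pi_i * D / ED_i) = 1 at every effect level collapses to a single
    potency scale b_mix = 1 / sum(pi_i / b_i): the mixture curve is the
    shared-shape model with that scale.
    """
    fracs = spec.fractions
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    for lbl in spec.labels:
        if lbl not in parallel.b:
            raise ValueError(f"component {lbl!r} missing from the joint fit")
        if parallel.b[lbl] <= 0:
            raise ValueError(f"non-positive potency scale for {lbl!r}")
    b_mix = 1.0 / sum(
        frac / parallel.b[lbl] for lbl, frac in zip(spec.labels, fracs)
    )
    params = {"a": parallel.a, "b": b_mix, "c": parallel.c, "d": parallel.d}
    return CAPrediction(
        model=parallel.model,
        a=parallel.a,
        c=parallel.c,
        d=parallel.d,
        b_components={lbl: parallel.b[lbl] for lbl in spec.labels},
        fractions=dict(zip(spec.labels, map(float, fracs))),
        b_mix=float(b_mix),
        ec50_mix=_try_ec50(parallel.model, params),
    )


def loewe_effective_dose(
    component_curves: Mapping[str, Callable[[float], float]],
    spec: MixtureSpec,
    level: float,
    dose_bracket: tuple[float, float] = (1e-12, 1e12),
) -> float:
    """General Loewe solver: total mixture dose reaching a response level.

    Inverts each (strictly monotone) component curve numerically at the
    level and combines the effective doses harmonically,
    D = 1 / sum(pi_i / ED_i(level)).  Serves as the brute-force oracle for
    the parallel-curve construction and does not assume shared shape.
    """
    lo, hi = dose_bracket
    denom = 0.0
    for lbl, frac in spec.components:
        if frac == 0.0:
            continue
        curve = component_curves[lbl]
        f_lo, f_hi = curve(lo) - level, curve(hi) - level
        if f_lo * f_hi > 0:
            raise UnreachableLevelError(
                f"level {level} not attainable by component {lbl!r}"
            )
        ed = optimize.brentq(
            lambda x: curve(x) - level, lo, hi, xtol=1e-15, rtol=1e-14
        )
        denom += frac / ed
    if denom == 0.0:
        raise ValueError("mixture has no non-zero component")
    return 1.0 / denom


def classify_deviation(
    mixture_fit: FitResult,
    prediction: CAPrediction,
    mdr_threshold: float = DEFAULT_MDR_THRESHOLD,
) -> CAPrediction:
    """Complete a CA prediction with the model deviation ratio and call.

    MDR = EC50 predicted under additivity / EC50 observed for the mixture.
    MDR > threshold means the observed curve is left-shifted (more than
    additive); MDR < 1/threshold means right-shifted (less than additive).
    """
    if mixture_fit.ec50 is None or prediction.ec50_mix is None:
        raise ClassificationError("EC50 missing on the observed or predicted side")
    if mdr_threshold <= 1.0:
        raise ValueError("mdr_threshold must exceed 1")
    mdr = prediction.ec50_mix / mixture_fit.ec50
    if mdr > mdr_threshold:
        call = CALL_MORE_THAN_ADDITIVE
    elif mdr < 1.0 / mdr_threshold:
        call = CALL_LESS_THAN_ADDITIVE
    else:
        call = CALL_ADDITIVE
    return dataclasses.replace(
        prediction, mdr=float(mdr), call=call, ec50_observed=mixture_fit.ec50
    )


# ---------------------------------------------------------------------------
# four-parameter logistic IC50


def fit_fourpl_ic50(data: DoseResponseDataset) -> FitResult:
    """Fit the 4PL on X = log10(concentration) and report IC50 = 10^LogIC50
    in mg/L (stored in the ``ec50`` field).  Zero-dose controls cannot be
    log-transformed and are excluded from the fit."""
    if data.n_distinct_positive() < 5:
        raise ValueError("need >= 5 distinct positive concentrations")
    mask = data.concentrations > 0
    logx = np.log10(data.concentrations[mask])
    y = data.responses[mask]
    if np.ptp(y) == 0:
        raise DegenerateFitError("all responses identical")

    def residuals(theta: np.ndarray) -> np.ndarray:
        return fourpl_model(logx, *theta) - y

    lo, hi = float(y.min()), float(y.max())
    mid = float(np.median(logx))
    lower = np.array([-1e6, -1e6, logx.min() - 6.0, -50.0])
    upper = np.array([1e6, 1e6, logx.max() + 6.0, 50.0])
    starts = [
        np.array([lo, hi, mid, slope]) for slope in (1.0, -1.0, 3.0, -3.0)
    ] + [np.array([hi, lo, mid, slope]) for slope in (1.0, -1.0)]
    theta, rss, converged = _multistart(residuals, starts, lower, upper)
    params = dict(
        zip(("Bottom", "Top", "LogIC50", "HillSlope"), map(float, theta))
    )
    n, k = int(mask.sum()), 4
    return FitResult(
        model=MODEL_FOURPL,
        params=params,
        rss=rss,
        n_obs=n,
        k_params=k,
        aic=aic_gaussian(rss, n, k),
        converged=converged,
        ec50=float(10.0 ** params["LogIC50"]),
        treatment_label=data.treatment_label,
    )
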