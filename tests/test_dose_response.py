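import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from mixtriage.dose_response import (
    CALL_ADDITIVE,
    CALL_LESS_THAN_ADDITIVE,
    CALL_MORE_THAN_ADDITIVE,
    FitResult,
    ParallelFit,
    aic_gaussian,
    ca_mixture_curve,
    classify_deviation,
    ec50_exponential,
    ec50_hill,
    exponential_model,
    fit_fourpl_ic50,
    fit_model,
    fit_parallel,
    fourpl_model,
    hill_model,
    loewe_effective_dose,
    select_model_aic,
)
from mixtriage.errors import (
    ClassificationError,
    DegenerateFitError,
    UnreachableLevelError,
)
from mixtriage.synthetic import gen_dose_response
from mixtriage.tables_io import DoseResponseDataset, MixtureSpec


def make_parallel(a, c, d, b, model="exponential"):
    return ParallelFit(
        model=model, a=a, c=c, d=d, b=dict(b),
        rss=0.0, n_obs=0, k_params=3 + len(b), aic=0.0, converged=True,
    )


def make_fit(ec50):
    return FitResult(
        model="exponential", params={}, rss=0.0, n_obs=1, k_params=4,
        aic=0.0, converged=True, ec50=ec50,
    )


# ---------------------------------------------------------------------------
# model forms


def test_model_boundary_values():
    for f in (exponential_model, hill_model):
        assert f(0.0, 120.0, 10.0, 0.3, 2.0) == pytest.approx(120.0)
        assert f(1e12, 120.0, 10.0, 0.3, 2.0) == pytest.approx(36.0, rel=1e-6)


def test_hill_half_scale_identity():
    # for c = 0 the dose b gives exactly a/2
    assert hill_model(10.0, 100.0, 10.0, 0.0, 1.7) == pytest.approx(50.0)


def test_fourpl_printed_formula_values():
    # midpoint identity and a direct evaluation at X = 1
    assert fourpl_model(0.0, 0.0, 100.0, 0.0, 1.0) == pytest.approx(50.0)
    assert fourpl_model(1.0, 0.0, 100.0, 0.0, 1.0) == pytest.approx(
        100.0 / (1.0 + 10.0**-1), abs=1e-9
    )
    assert fourpl_model(1.0, 0.0, 100.0, 0.0, 1.0) == pytest.approx(90.909, abs=1e-3)


# ---------------------------------------------------------------------------
# EC50 closed forms


def test_ec50_exponential_analytic_cases():
    # 100*exp(-x/10) = 50  ->  x = 10 ln 2
    assert ec50_exponential({"b": 10.0, "c": 0.0, "d": 1.0}) == pytest.approx(
        10.0 * np.log(2.0)
    )
    # substitute (b=5, c=0.2, d=2): 5*(-ln 0.375)^(1/2)
    assert ec50_exponential({"b": 5.0, "c": 0.2, "d": 2.0}) == pytest.approx(
        5.0 * (-np.log(0.375)) ** 0.5
    )
    assert ec50_exponential({"b": 5.0, "c": 0.2, "d": 2.0}) == pytest.approx(
        4.952, abs=1e-3
    )


@pytest.mark.parametrize("d", [0.3, 1.0, 2.7])
def test_ec50_exponential_c0_symmetry(d):
    assert ec50_exponential({"b": 7.0, "c": 0.0, "d": d}) == pytest.approx(
        7.0 * np.log(2.0) ** (1.0 / d)
    )


@pytest.mark.parametrize("func", [ec50_exponential, ec50_hill])
def test_ec50_unreachable_level(func):
    with pytest.raises(UnreachableLevelError):
        func({"b": 10.0, "c": 0.6, "d": 1.0})


@settings(max_examples=300, derandomize=True)
@given(
    b=st.floats(0.01, 1e3),
    c=st.floats(0.0, 0.49),
    d=st.floats(0.2, 5.0),
    model=st.sampled_from(["exponential", "hill"]),
)
def test_ec50_closed_form_equals_bisection(b, c, d, model):
    """The closed-form EC50 is the root of model(x) = a/2 to 1e-9 relative."""
    a = 100.0
    func = exponential_model if model == "exponential" else hill_model
    ec50 = (ec50_exponential if model == "exponential" else ec50_hill)(
        {"b": b, "c": c, "d": d}
    )
    root = optimize.brentq(
        lambda x: func(x, a, b, c, d) - a / 2.0,
        ec50 * 1e-3, ec50 * 1e3, xtol=1e-300, rtol=1e-14,
    )
    assert ec50 == pytest.approx(root, rel=1e-9)


# ---------------------------------------------------------------------------
# single-curve fitting


@pytest.mark.parametrize("model", ["exponential", "hill"])
def test_noiseless_recovery(model):
    true = {"a": 100.0, "b": 10.0, "c": 0.0, "d": 1.0}
    ds = gen_dose_response(true, model=model, noise_sd=0.0, seed=0)
    fit = fit_model(ds, model)
    assert fit.converged
    for k, v in true.items():
        assert fit.params[k] == pytest.approx(v, rel=1e-6, abs=1e-6)
    assert fit.ec50 == pytest.approx(
        (ec50_exponential if model == "exponential" else ec50_hill)(true), rel=1e-6
    )


def test_increasing_curve_fits_without_ec50():
    # activation-type data: response rises to a*c with c > 1
    true = {"a": 100.0, "b": 10.0, "c": 2.0, "d": 1.5}
    ds = gen_dose_response(true, noise_sd=0.0, seed=0)
    fit = fit_model(ds)
    assert fit.params["c"] == pytest.approx(2.0, rel=1e-5)
    assert fit.ec50 is None


def test_fit_requires_five_distinct_doses():
    ds = DoseResponseDataset(
        "x", np.array([1.0, 2.0, 4.0, 8.0]), np.array([90.0, 70.0, 40.0, 10.0]),
        np.zeros(4),
    )
    with pytest.raises(ValueError, match="distinct positive"):
        fit_model(ds)


def test_degenerate_responses_rejected():
    conc = np.concatenate([[0.0], np.geomspace(1, 100, 8)])
    ds = DoseResponseDataset("x", conc, np.full(9, 50.0), np.zeros(9))
    with pytest.raises(DegenerateFitError):
        fit_model(ds)


# ---------------------------------------------------------------------------
# AIC selection


def test_select_model_aic_argmin_and_ordering_invariance():
    f1 = FitResult("exponential", {}, 1.0, 24, 4, 101.2, True)
    f2 = FitResult("hill", {}, 1.0, 24, 4, 99.8, True)
    assert select_model_aic([f1, f2]).model == "hill"
    assert select_model_aic([f2, f1]).model == "hill"


def test_select_model_aic_tie_prefers_exponential():
    f1 = FitResult("exponential", {}, 1.0, 24, 4, 100.0, True)
    f2 = FitResult("hill", {}, 1.0, 24, 4, 100.0, True)
    assert select_model_aic([f2, f1]).model == "exponential"


def test_select_model_aic_empty_rejected():
    with pytest.raises(ValueError):
        select_model_aic([])


def test_aic_definition():
    assert aic_gaussian(10.0, 24, 4) == pytest.approx(24 * np.log(10.0 / 24) + 8)


def test_aic_selects_true_model_majority():
    """Data simulated from a steep exponential curve should usually be
    AIC-classified as exponential."""
    true = {"a": 100.0, "b": 10.0, "c": 0.0, "d": 3.0}
    wins = 0
    n_runs = 50
    for i in range(n_runs):
        ds = gen_dose_response(true, noise_sd=3.0, seed=i)
        best = select_model_aic([fit_model(ds, "exponential"), fit_model(ds, "hill")])
        wins += best.model == "exponential"
    assert wins > n_runs / 2


# ---------------------------------------------------------------------------
# concentration addition


def test_ca_single_component_sham_reduction():
    par = make_parallel(100.0, 0.0, 1.0, {"A": 12.0})
    pred = ca_mixture_curve(par, MixtureSpec((("A", 1.0),)))
    assert pred.b_mix == pytest.approx(12.0)
    x = np.geomspace(0.1, 100, 20)
    np.testing.assert_allclose(pred.curve(x), par.curve("A")(x), rtol=1e-12)


def test_ca_harmonic_combination_worked_example():
    par = make_parallel(100.0, 0.0, 1.0, {"A": 10.0, "B": 40.0})
    spec = MixtureSpec((("A", 0.5), ("B", 0.5)))
    pred = ca_mixture_curve(par, spec)
    assert pred.b_mix == pytest.approx(16.0)
    assert pred.ec50_mix == pytest.approx(16.0 * np.log(2.0), rel=1e-12)
    assert pred.ec50_mix == pytest.approx(11.09, abs=5e-3)


def test_ca_equal_components_permutation_symmetry():
    par = make_parallel(100.0, 0.1, 2.0, {"A": 8.0, "B": 8.0, "C": 8.0})
    for split in [(1 / 3, 1 / 3, 1 / 3), (0.6, 0.3, 0.1)]:
        spec = MixtureSpec(tuple(zip("ABC", split)))
        assert ca_mixture_curve(par, spec).b_mix == pytest.approx(8.0)


def test_ca_rejects_bad_fractions():
    par = make_parallel(100.0, 0.0, 1.0, {"A": 10.0, "B": 40.0})
    with pytest.raises(ValueError):
        ca_mixture_curve(par, MixtureSpec((("A", 0.7), ("B", 0.3000001))))


def test_sham_self_mixture_identity():
    """Mixing a compound with itself at any split reproduces the single
    curve to 1e-9 (Loewe sham additivity)."""
    par = make_parallel(95.0, 0.05, 1.8, {"X": 7.0, "Y": 7.0})
    for split in [(0.5, 0.5), (0.2, 0.8), (0.99, 0.01)]:
        pred = ca_mixture_curve(par, MixtureSpec((("X", split[0]), ("Y", split[1]))))
        x = np.geomspace(0.01, 1000, 50)
        np.testing.assert_allclose(
            pred.curve(x), par.curve("X")(x), rtol=1e-9, atol=1e-9
        )


def test_loewe_oracle_agrees_with_parallel_construction():
    """General Loewe inversion and the harmonic construction agree over 21
    response levels whenever the component curves are parallel."""
    par = make_parallel(100.0, 0.1, 1.7, {"A": 5.0, "B": 50.0})
    spec = MixtureSpec((("A", 0.3), ("B", 0.7)))
    pred = ca_mixture_curve(par, spec)
    curves = {lbl: par.curve(lbl) for lbl in ("A", "B")}
    levels = np.linspace(15.0, 95.0, 21)  # attainable range is (10, 100)
    for level in levels:
        d_oracle = loewe_effective_dose(curves, spec, level)
        d_ca = optimize.brentq(
            lambda x: pred.curve(x) - level, 1e-9, 1e9, xtol=1e-300, rtol=1e-14
        )
        assert d_ca == pytest.approx(d_oracle, rel=1e-6)


def test_loewe_single_and_identical_component_shams():
    par = make_parallel(100.0, 0.0, 1.0, {"A": 10.0, "B": 10.0})
    curves = {lbl: par.curve(lbl) for lbl in ("A", "B")}
    only_a = MixtureSpec((("A", 1.0),))
    ed = loewe_effective_dose(curves, only_a, 50.0)
    assert ed == pytest.approx(10.0 * np.log(2.0), rel=1e-9)
    for split in [(0.5, 0.5), (0.1, 0.9)]:
        both = MixtureSpec((("A", split[0]), ("B", split[1])))
        assert loewe_effective_dose(curves, both, 50.0) == pytest.approx(ed, rel=1e-9)


def test_loewe_unattainable_level():
    par = make_parallel(100.0, 0.4, 1.0, {"A": 10.0})
    with pytest.raises(UnreachableLevelError):
        loewe_effective_dose(
            {"A": par.curve("A")}, MixtureSpec((("A", 1.0),)), 20.0
        )


# ---------------------------------------------------------------------------
# deviation classification


def test_classify_deviation_rule():
    par = make_parallel(100.0, 0.0, 1.0, {"A": 10.0, "B": 40.0})
    pred = ca_mixture_curve(par, MixtureSpec((("A", 0.5), ("B", 0.5))))
    pred16 = pred  # predicted EC50 = 16 ln2

    done = classify_deviation(make_fit(pred16.ec50_mix / 3.2), pred16)
    assert done.mdr == pytest.approx(3.2)
    assert done.call == CALL_MORE_THAN_ADDITIVE

    done = classify_deviation(make_fit(pred16.ec50_mix), pred16)
    assert done.mdr == pytest.approx(1.0)
    assert done.call == CALL_ADDITIVE

    done = classify_deviation(make_fit(pred16.ec50_mix * 4.0), pred16)
    assert done.mdr == pytest.approx(0.25)
    assert done.call == CALL_LESS_THAN_ADDITIVE


def test_classify_deviation_missing_ec50():
    par = make_parallel(100.0, 0.0, 1.0, {"A": 10.0})
    pred = ca_mixture_curve(par, MixtureSpec((("A", 1.0),)))
    with pytest.raises(ClassificationError):
        classify_deviation(make_fit(None), pred)


def test_mdr_scales_inversely_with_observed_concentration_scale():
    """Scaling observed mixture concentrations by s scales the observed
    EC50 by s and hence the MDR by 1/s."""
    true = {"a": 100.0, "b": 16.0, "c": 0.0, "d": 2.0}
    ds = gen_dose_response(true, noise_sd=3.0, seed=7, label="mix")
    par = make_parallel(100.0, 0.0, 2.0, {"A": 10.0, "B": 40.0})
    pred = ca_mixture_curve(par, MixtureSpec((("A", 0.5), ("B", 0.5))))
    s = 5.0
    scaled = DoseResponseDataset(
        "mix", ds.concentrations * s, ds.responses, ds.replicate_ids
    )
    mdr1 = classify_deviation(fit_model(ds), pred).mdr
    mdr2 = classify_deviation(fit_model(scaled), pred).mdr
    assert mdr2 == pytest.approx(mdr1 / s, rel=1e-6)


# ---------------------------------------------------------------------------
# joint parallel fitting


def test_parallel_fit_recovers_shared_shape_and_potencies():
    shared = {"a": 100.0, "c": 0.0, "d": 2.0}
    datasets = [
        gen_dose_response({**shared, "b": b}, noise_sd=0.0, seed=0, label=lbl)
        for lbl, b in [("A", 10.0), ("B", 40.0)]
    ]
    par = fit_parallel(datasets)
    assert par.converged
    assert par.a == pytest.approx(100.0, rel=1e-6)
    assert par.d == pytest.approx(2.0, rel=1e-6)
    assert par.b["A"] == pytest.approx(10.0, rel=1e-6)
    assert par.b["B"] == pytest.approx(40.0, rel=1e-6)


# ---------------------------------------------------------------------------
# 4PL IC50


def test_fourpl_noiseless_recovery():
    conc = np.geomspace(10**-1.5, 10**1.5, 8)
    x = np.log10(conc)
    y = fourpl_model(x, 0.0, 100.0, 0.0, -1.0)
    ds = DoseResponseDataset("nda", conc, y, np.zeros(8))
    fit = fit_fourpl_ic50(ds)
    assert fit.params["LogIC50"] == pytest.approx(0.0, abs=1e-7)
    assert fit.ec50 == pytest.approx(1.0, rel=1e-6)
    # value at the midpoint is (Top+Bottom)/2
    assert fit.predict([1.0])[0] == pytest.approx(50.0, abs=1e-5)
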