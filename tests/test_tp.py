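"""Trophic-position equation and uncertainty propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aminotp import (
    DomainError,
    Method,
    TDFParams,
    ValidationError,
    classify_dataset,
    estimate_dataset,
    generate,
    propagate_monte_carlo,
    propagate_taylor,
    trophic_position,
)
from aminotp.simulate import FoodWebLabel, SpeciesSpec, SyntheticConfig

finite = dict(allow_nan=False, allow_infinity=False)


@pytest.mark.parametrize(
    "glu, phe, beta, tdf, expected",
    [
        (5.0, 5.0, 0.0, 7.6, 1.0),      # autotroph: glu == phe, beta 0
        (7.6, 8.4, 8.4, 7.6, 2.0),      # herbivore on C3: glu - phe = TDF - beta
        (18.6, 0.0, -3.4, 7.6, 3.0),    # marine carnivore: (18.6 - 3.4)/7.6 + 1
    ],
)
def test_equation_anchors(glu, phe, beta, tdf, expected):
    assert trophic_position(glu, phe, beta, tdf) == pytest.approx(expected)


def test_tdf_domain():
    with pytest.raises(DomainError):
        trophic_position(10.0, 5.0, 8.4, 0.0)
    with pytest.raises(DomainError):
        trophic_position(10.0, 5.0, 8.4, -7.6)
    with pytest.raises(DomainError):
        TDFParams(mean=-1.0)


@settings(max_examples=200, derandomize=True)
@given(
    glu=st.floats(min_value=-30, max_value=40, **finite),
    phe=st.floats(min_value=-30, max_value=40, **finite),
    beta=st.floats(min_value=-5, max_value=10, **finite),
    tdf=st.floats(min_value=1.0, max_value=15.0, **finite),
    eps=st.floats(min_value=0.01, max_value=5.0, **finite),
)
def test_monotonicity(glu, phe, beta, tdf, eps):
    """TP strictly increases in glu and beta, strictly decreases in phe."""
    base = trophic_position(glu, phe, beta, tdf)
    assert trophic_position(glu + eps, phe, beta, tdf) > base
    assert trophic_position(glu, phe, beta + eps, tdf) > base
    assert trophic_position(glu, phe + eps, beta, tdf) < base


def test_taylor_zero_sigma_collapses_to_plugin():
    est = propagate_taylor(20.0, 5.0, 0.0, 0.0, 8.4, 0.0, TDFParams(7.6, 0.0))
    assert est.tp_sd == 0.0
    assert est.tp_mean == pytest.approx(trophic_position(20.0, 5.0, 8.4, 7.6))


def test_taylor_single_term_derivative():
    # only glu uncertain: sd = sigma_glu / TDF
    est = propagate_taylor(20.0, 5.0, 0.5, 0.0, 8.4, 0.0, TDFParams(7.6, 0.0))
    assert est.tp_sd == pytest.approx(0.5 / 7.6)


@settings(max_examples=100, derandomize=True)
@given(
    sg=st.floats(min_value=0, max_value=2, **finite),
    sp_=st.floats(min_value=0, max_value=2, **finite),
)
def test_taylor_sd_symmetric_in_aa_sigmas(sg, sp_):
    a = propagate_taylor(20.0, 5.0, sg, sp_, 8.4, 1.6)
    b = propagate_taylor(20.0, 5.0, sp_, sg, 8.4, 1.6)
    assert a.tp_sd == pytest.approx(b.tp_sd)


def test_taylor_matches_mc_at_published_parameters():
    """Linearization error stays below 10% relative at the field's values."""
    taylor = propagate_taylor(20.0, 5.0, 0.5, 0.5, 8.4, 1.6, TDFParams(7.6, 1.2))
    mc = propagate_monte_carlo(
        20.0, 5.0, 0.5, 0.5, 8.4, 1.6, TDFParams(7.6, 1.2), n_draws=10**6, seed=7
    )
    assert abs(taylor.tp_sd - mc.tp_sd) / mc.tp_sd < 0.10
    assert taylor.second_order_mean_shift == pytest.approx(
        (20.0 - 5.0 + 8.4) * 1.2**2 / 7.6**3
    )


def test_taylor_matches_mc_in_small_tdf_sigma_regime():
    tdf = TDFParams(7.6, 0.05 * 7.6)
    taylor = propagate_taylor(20.0, 5.0, 0.5, 0.5, 8.4, 1.6, tdf)
    mc = propagate_monte_carlo(20.0, 5.0, 0.5, 0.5, 8.4, 1.6, tdf, n_draws=10**6, seed=7)
    assert abs(taylor.tp_sd - mc.tp_sd) / mc.tp_sd < 0.02


def test_mc_closed_form_limit_when_tdf_certain():
    # sigma_TDF = 0: sd -> sqrt(sg^2 + sp^2 + sb^2) / TDF
    expected = math.sqrt(0.5**2 + 0.5**2 + 1.6**2) / 7.6
    mc = propagate_monte_carlo(
        20.0, 5.0, 0.5, 0.5, 8.4, 1.6, TDFParams(7.6, 0.0), n_draws=10**6, seed=11
    )
    assert mc.tp_sd == pytest.approx(expected, rel=0.005)


def test_mc_determinism_and_degenerate_inputs():
    kwargs = dict(n_draws=2000, seed=123)
    a = propagate_monte_carlo(20.0, 5.0, 0.5, 0.5, 8.4, 1.6, **kwargs)
    b = propagate_monte_carlo(20.0, 5.0, 0.5, 0.5, 8.4, 1.6, **kwargs)
    assert (a.tp_mean, a.tp_sd) == (b.tp_mean, b.tp_sd)

    degenerate = propagate_monte_carlo(
        20.0, 5.0, 0.0, 0.0, 8.4, 0.0, TDFParams(7.6, 0.0), n_draws=1000, seed=1
    )
    assert degenerate.tp_sd == 0.0
    assert degenerate.tp_mean == pytest.approx(trophic_position(20.0, 5.0, 8.4, 7.6))

    with pytest.raises(ValidationError):
        propagate_monte_carlo(20.0, 5.0, 0.5, 0.5, 8.4, 1.6, n_draws=10, seed=1)


def test_mc_mean_exceeds_plugin_when_only_tdf_uncertain():
    """Jensen's inequality: E[1/TDF] > 1/E[TDF] for a positive TDF spread."""
    plugin = trophic_position(20.0, 5.0, 8.4, 7.6)
    mc = propagate_monte_carlo(
        20.0, 5.0, 0.0, 0.0, 8.4, 0.0, TDFParams(7.6, 1.2), n_draws=10**6, seed=3
    )
    # independent high-precision oracle: Gauss-Hermite quadrature of
    # E[(glu - phe + beta)/T + 1] under T ~ N(7.6, 1.2) truncated at 0
    nodes, weights = np.polynomial.hermite_e.hermegauss(201)
    t = 7.6 + 1.2 * nodes
    keep = t > 0
    w = weights[keep] / weights[keep].sum()
    quad_mean = float(np.sum(w * ((20.0 - 5.0 + 8.4) / t[keep] + 1.0)))
    assert mc.tp_mean > plugin
    assert quad_mean > plugin
    assert mc.tp_mean == pytest.approx(quad_mean, rel=1e-3)


def test_mc_tdf_rejection_bookkeeping():
    # TDF barely positive with a wide sigma forces rejections.
    mc = propagate_monte_carlo(
        10.0, 5.0, 0.0, 0.0, 8.4, 0.0, TDFParams(1.0, 2.0), n_draws=5000, seed=5
    )
    assert mc.n_rejected > 0
    assert mc.tp_sd >= 0


def test_estimate_dataset_contract(small_dataset):
    assignments = classify_dataset(small_dataset)
    estimates, notices = estimate_dataset(small_dataset, assignments)
    assert len(estimates) == 2  # frug_1 is bulk-only
    assert any("frug_1" in n for n in notices)
    assert all(e.method is Method.TAYLOR_FIRST_ORDER for e in estimates)

    # AA sample without an assignment is an error naming the sample
    with pytest.raises(ValidationError, match="pisc_1"):
        estimate_dataset(small_dataset, assignments[1:])

    # MC requires a seed; given one, results are order-independent
    with pytest.raises(ValidationError, match="seed"):
        estimate_dataset(small_dataset, assignments, method=Method.MONTE_CARLO)
    mc1, _ = estimate_dataset(
        small_dataset, assignments, method=Method.MONTE_CARLO, n_draws=2000, seed=9
    )
    from aminotp import Dataset

    rev = Dataset(list(reversed(small_dataset.samples)))
    mc2, _ = estimate_dataset(
        rev, list(reversed(assignments)), method=Method.MONTE_CARLO, n_draws=2000, seed=9
    )
    by_id = {e.sample_id: e for e in mc2}
    for e in mc1:
        assert by_id[e.sample_id].tp_mean == e.tp_mean


def test_estimate_dataset_empty_aa():
    from aminotp import Dataset, IsotopeSample

    ds = Dataset([IsotopeSample("x", "sp", -25.0, 8.0)])
    estimates, notices = estimate_dataset(ds, classify_dataset(ds))
    assert estimates == []
    assert len(notices) == 1


def test_parameter_recovery_bias_and_calibration():
    """Known-truth simulation: estimates are unbiased and well calibrated.

    1000 C3 individuals at true TP 3 with 0.5 per-mil measurement noise;
    propagation with sigma_TDF = sigma_beta = 0 so the closed-form sampling
    sd sqrt(2) * 0.5 / 7.6 applies, and |error| <= 3 sd for >= 99% of samples.
    """
    cfg = SyntheticConfig(
        species_specs=(SpeciesSpec("c3_consumer", 3.0, FoodWebLabel.C3_TERRESTRIAL, 1000),),
        seed=2024,
        baseline_phe_sd=1.5,
        sigma_meas=0.5,
    )
    ds, truth = generate(cfg)
    assignments = classify_dataset(ds)
    tdf = TDFParams(7.6, 0.0)
    # zero out beta uncertainty to isolate measurement noise
    from aminotp.baseline import ClassifierConfig, FoodWebLabel as L

    cls = ClassifierConfig(betas={L.MARINE: (-3.4, 0.0), L.C4_TERRESTRIAL: (-0.4, 0.0), L.C3_TERRESTRIAL: (8.4, 0.0)})
    assignments = classify_dataset(ds, config=cls)
    estimates, _ = estimate_dataset(ds, assignments, tdf)
    tps = np.array([e.tp_mean for e in estimates])
    sds = np.array([e.tp_sd for e in estimates])
    closed_form = math.sqrt(2) * 0.5 / 7.6
    assert abs(tps.mean() - 3.0) <= 0.02
    assert abs(tps.std(ddof=1) - closed_form) / closed_form <= 0.05
    assert np.mean(np.abs(tps - 3.0) <= 3 * sds) >= 0.99
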