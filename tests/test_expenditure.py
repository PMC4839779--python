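"""Expenditure: AUC totals, average cost, NWBI, budget solver, tier schedule."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvagree import (
    Agreement,
    DomainError,
    PriceVolumeModel,
    average_cost_closed_form,
    nwbi,
    price_at,
    solve_decay_for_budget,
    tier_schedule,
    total_expenditure_analytic,
    total_expenditure_trapezoid,
)


def test_nwbi_worked_example_hepatitis_c():
    """35,000 EUR per patient over one million candidates is 35 billion EUR."""
    assert nwbi(35_000, 1_000_000) == 35_000_000_000


def test_nwbi_basics_and_domain():
    assert nwbi(9050, 20_000) == 181_000_000
    assert nwbi(123.45, 1) == 123.45
    with pytest.raises(DomainError):
        nwbi(0, 10)
    with pytest.raises(DomainError):
        nwbi(100, 0)


@pytest.mark.parametrize(
    "model_fixture, n, expected_avg",
    [("ranibizumab_model", 20_000, 7_705), ("sofosbuvir_model", 60_000, 14_969)],
)
def test_average_cost_matches_published_values(model_fixture, n, expected_avg, request):
    """Average cost per patient over the candidate population, to +/-1 EUR
    (the published figures carry intermediate rounding of k)."""
    model = request.getfixturevalue(model_fixture)
    analytic = total_expenditure_analytic(model, n)
    assert analytic.average_per_patient == pytest.approx(expected_avg, abs=1.0)
    assert average_cost_closed_form(model, n) == pytest.approx(expected_avg, abs=1.0)


def test_closed_form_average_is_identical_to_analytic(ranibizumab_model, sofosbuvir_model):
    for model, n in ((ranibizumab_model, 20_000), (sofosbuvir_model, 60_000)):
        avg = total_expenditure_analytic(model, n).average_per_patient
        assert average_cost_closed_form(model, n) == pytest.approx(avg, rel=1e-12)


def test_flat_model_totals_are_linear():
    flat = PriceVolumeModel(f_price=500.0, decay_k=0.0)
    summary = total_expenditure_analytic(flat, 1_000)
    assert summary.total == 500_000.0
    assert summary.average_per_patient == 500.0
    assert average_cost_closed_form(flat, 1_000) == 500.0


def test_summary_internal_consistency(ranibizumab_model):
    s = total_expenditure_analytic(ranibizumab_model, 20_000)
    assert s.total == pytest.approx(s.average_per_patient * s.n_patients, rel=1e-12)
    assert price_at(ranibizumab_model, 20_000) <= s.average_per_patient <= ranibizumab_model.f_price


def test_single_panel_trapezoid_closed_form(sofosbuvir_model):
    n = 60_000
    one_panel = total_expenditure_trapezoid(sofosbuvir_model, n, step=n)
    expected = n * (sofosbuvir_model.f_price + price_at(sofosbuvir_model, n)) / 2
    assert one_panel.total == pytest.approx(expected, rel=1e-12)


def test_fine_trapezoid_agrees_with_analytic(ranibizumab_model):
    analytic = total_expenditure_analytic(ranibizumab_model, 20_000).total
    trap = total_expenditure_trapezoid(ranibizumab_model, 20_000, step=1.0).total
    assert trap == pytest.approx(analytic, abs=0.01)
    assert trap >= analytic


def test_trapezoid_error_shrinks_quadratically_with_step(sofosbuvir_model):
    """Halving the step cuts the quadrature error by ~4x (second-order rule)."""
    analytic = total_expenditure_analytic(sofosbuvir_model, 60_000).total
    err = lambda step: total_expenditure_trapezoid(sofosbuvir_model, 60_000, step).total - analytic
    ratio = err(200.0) / err(100.0)
    assert 3.8 <= ratio <= 4.2


def test_trapezoid_rejects_bad_step(ranibizumab_model):
    for step in (0.0, -1.0, 30_000):
        with pytest.raises(DomainError):
            total_expenditure_trapezoid(ranibizumab_model, 20_000, step)


@settings(max_examples=60, derandomize=True)
@given(
    decay_k=st.floats(1e-5, 1e-3),
    n=st.floats(1_000.0, 1e6),
    frac=st.floats(0.01, 1.0),
)
def test_trapezoid_always_bounds_analytic_from_above(decay_k, n, frac):
    """Exponential decay is convex, so every trapezoidal estimate of the AUC
    is >= the exact integral, strictly so when the discretization error is
    resolvable above float rounding (ranges chosen so it is)."""
    model = PriceVolumeModel(f_price=10_000.0, decay_k=decay_k)
    trap = total_expenditure_trapezoid(model, n, step=frac * n).total
    assert trap > total_expenditure_analytic(model, n).total


def test_analytic_total_monotone_in_n_and_k():
    base = PriceVolumeModel(f_price=10_000.0, decay_k=5e-5)
    faster = PriceVolumeModel(f_price=10_000.0, decay_k=1e-4)
    t = lambda m, n: total_expenditure_analytic(m, n).total
    assert t(base, 20_000) < t(base, 40_000)
    assert t(faster, 20_000) < t(base, 20_000)


def test_budget_solver_round_trips_the_forward_model(sofosbuvir_model):
    """Feeding the forward model's own total back through the solver recovers
    its decay constant."""
    cap = total_expenditure_analytic(sofosbuvir_model, 60_000).total
    solved = solve_decay_for_budget(37_500, 60_000, cap)
    assert solved.decay_k == pytest.approx(sofosbuvir_model.decay_k, rel=1e-8)
    assert total_expenditure_analytic(solved, 60_000).total == pytest.approx(cap, rel=1e-10)


@pytest.mark.parametrize("decay_k", [1e-7, 1e-6, 1e-5, 1e-4, 1e-3])
def test_budget_solver_inverts_expenditure_across_k_range(decay_k):
    model = PriceVolumeModel(f_price=20_000.0, decay_k=decay_k)
    cap = total_expenditure_analytic(model, 100_000).total
    solved = solve_decay_for_budget(20_000.0, 100_000, cap)
    assert solved.decay_k == pytest.approx(decay_k, rel=1e-8)


def test_budget_solver_no_discount_and_domain_cases():
    flat = solve_decay_for_budget(100.0, 1_000, 100_000.0)  # cap == undiscounted NWBI
    assert flat.decay_k == 0.0
    assert solve_decay_for_budget(100.0, 1_000, 200_000.0).decay_k == 0.0
    with pytest.raises(DomainError):
        solve_decay_for_budget(100.0, 1_000, 0.0)


def test_tier_schedule_single_band_is_average_cost(ranibizumab_model):
    [(band, price)] = tier_schedule(ranibizumab_model, [20_000])
    assert band == (0.0, 20_000.0)
    assert price == pytest.approx(average_cost_closed_form(ranibizumab_model, 20_000), rel=1e-12)


def test_tier_schedule_flat_model_prices_at_full_price():
    flat = PriceVolumeModel(f_price=321.0, decay_k=0.0)
    for _, price in tier_schedule(flat, [100, 500, 900]):
        assert price == pytest.approx(321.0, rel=1e-12)


def test_tier_schedule_conserves_total_expenditure(sofosbuvir_model):
    edges = [5_000, 15_000, 30_000, 60_000]
    schedule = tier_schedule(sofosbuvir_model, edges)
    stepped_total = sum((hi - lo) * price for (lo, hi), price in schedule)
    analytic = total_expenditure_analytic(sofosbuvir_model, 60_000).total
    assert stepped_total == pytest.approx(analytic, rel=1e-9)


def test_tier_schedule_rejects_unsorted_edges(ranibizumab_model):
    with pytest.raises(DomainError):
        tier_schedule(ranibizumab_model, [10_000, 5_000])
    with pytest.raises(DomainError):
        tier_schedule(ranibizumab_model, [])


def test_agreement_derives_nwbi(ranibizumab_model):
    a = Agreement(drug="ranibizumab", model=ranibizumab_model, tot_pt=20_000)
    assert a.nwbi == pytest.approx(9050 * 20_000)
    with pytest.raises(DomainError):
        Agreement(drug="x", model=ranibizumab_model, tot_pt=0)
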