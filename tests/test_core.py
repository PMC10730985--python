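"""The arithmetic core: ARR, NNT, annualization, cost of control, indices."""

from decimal import Decimal

import pytest
from hypothesis import given, strategies as st

from costcontrol import (
    Conventions,
    CostOfControlModel,
    DomainError,
    UndefinedNNTError,
    absolute_risk_reduction,
    annualize,
    cost_of_control,
    drug_cost_index,
    nnt,
    relative_cost_index,
    run_base_case,
)
from costcontrol.trial import CostOfControlRow

from reference_values import BASE_COSTS, COMPOSITE, NNTS, WORKED_ANNUAL, WORKED_INDEX

fractions = st.decimals(min_value=Decimal("0.001"), max_value=Decimal("1"), places=3)


@pytest.mark.parametrize(
    "monthly, rounded, expected",
    [
        ("486946.24", True, "5843355"),
        ("489762.03", True, "5877144"),
        ("486946.24", False, "5843354.88"),
        ("0", True, "0"),
        ("0", False, "0"),
    ],
)
def test_annualize(monthly, rounded, expected):
    assert annualize(Decimal(monthly), rounded) == Decimal(expected)


def test_annualize_rejects_negative_price():
    with pytest.raises(DomainError):
        annualize(Decimal("-1"))


@pytest.mark.parametrize(
    "p_active, p_ref, expected",
    [("0.79", "0", "0.79"), ("0.67", "0", "0.67"), ("0.5", "0.5", "0")],
)
def test_absolute_risk_reduction(p_active, p_ref, expected):
    assert absolute_risk_reduction(Decimal(p_active), Decimal(p_ref)) == Decimal(expected)


def test_negative_arr_rejected():
    with pytest.raises(DomainError):
        absolute_risk_reduction(Decimal("0.3"), Decimal("0.5"))


@pytest.mark.parametrize(
    "arr, expected",
    [("0.79", "1.27"), ("0.67", "1.49"), ("1.0", "1.00"), ("0.08", "12.50"), ("0.47", "2.13")],
)
def test_nnt_rounds_half_up_to_two_decimals(arr, expected):
    assert nnt(Decimal(arr)) == Decimal(expected)


def test_nnt_alternative_precision():
    # the same quantity displayed at 1 decimal, as headline summaries print it
    assert nnt(Decimal("0.67"), decimals=1) == Decimal("1.5")
    assert nnt(Decimal("0.08"), decimals=1) == Decimal("12.5")


def test_nnt_undefined_at_zero_arr():
    with pytest.raises(UndefinedNNTError, match="NNT undefined"):
        nnt(Decimal(0))


@given(p1=fractions, p2=fractions)
def test_nnt_monotone_decreasing_in_responder_share(p1, p2):
    """A better-performing drug never needs more patients treated per responder."""
    lo, hi = sorted([p1, p2])
    assert nnt(hi) <= nnt(lo)


@pytest.mark.parametrize(
    "annual, n, expected",
    [
        ("5843355", "1.27", "7421060.85"),
        ("5877144", "12.5", "73464300.00"),
        ("123456.78", "1.00", "123456.78"),
    ],
)
def test_cost_of_control(annual, n, expected):
    assert cost_of_control(Decimal(annual), Decimal(n)) == Decimal(expected)


@given(
    annual=st.decimals(min_value=Decimal("1"), max_value=Decimal("100000000"), places=0),
    n=st.decimals(min_value=Decimal("1.00"), max_value=Decimal("50.00"), places=2),
    k=st.integers(min_value=2, max_value=9),
)
def test_cost_of_control_is_linear(annual, n, k):
    assert cost_of_control(annual * k, n) == cost_of_control(annual, n) * k


def test_drug_cost_index_reproduces_published_pair():
    """Two-arm price-parity pair: each annual cost over the other's."""
    idx = drug_cost_index(WORKED_ANNUAL, reference="sema")
    for arm in ("sema", "dula"):
        assert abs(idx[arm] - WORKED_INDEX[arm]) < Decimal("5e-7")
    # the pair is geometrically symmetric about 1
    assert abs(idx["sema"] * idx["dula"] - 1) < Decimal("1e-20")


def test_drug_cost_index_equal_costs_and_errors():
    same = {"a": Decimal("100"), "b": Decimal("100")}
    assert drug_cost_index(same, "a") == {"a": Decimal(1), "b": Decimal(1)}
    with pytest.raises(DomainError):
        drug_cost_index(same, "missing")
    with pytest.raises(DomainError):
        drug_cost_index({"a": Decimal(0), "b": Decimal(1)}, "a")


def _row(endpoint, arm, coc):
    return CostOfControlRow(
        endpoint_id=endpoint,
        arm_id=arm,
        arr=Decimal("0.5"),
        nnt=Decimal("2.00"),
        annual_cost=Decimal(coc) / 2,
        cost_of_control=Decimal(coc),
    )


def test_relative_cost_index_reference_and_scaling():
    rows = relative_cost_index(
        [_row("e", "ref", "7421060.72"), _row("e", "other", "8766823.37")], "ref"
    )
    ref, other = rows
    assert ref.relative_index == 1 and ref.scaled_index == 100_000
    assert abs(other.relative_index - Decimal("1.181343706")) < Decimal("2e-6")
    two_to_one = relative_cost_index([_row("e", "ref", "100"), _row("e", "other", "200")], "ref")
    assert two_to_one[1].scaled_index == 200_000


def test_relative_cost_index_requires_reference_rows():
    with pytest.raises(DomainError, match="reference"):
        relative_cost_index([_row("e", "other", "100")], "ref")


def test_base_case_reproduces_published_costs(base_results):
    """All 12 published base-column cells, exact to the centavo."""
    for (endpoint, arm), expected in BASE_COSTS.items():
        row = base_results.row(endpoint, arm)
        assert row.nnt == NNTS[(endpoint, arm)]
        assert row.cost_of_control == expected
        assert row.cost_of_control == row.annual_cost * row.nnt


def test_base_case_composite_headline_ratio(base_results):
    """Bringing one patient to the composite target costs 28% more with the comparator."""
    ratio = base_results.cost_ratio(COMPOSITE)
    assert ratio.quantize(Decimal("0.01")) == Decimal("1.28")


def test_relative_index_matches_unrounded_recomputation(base_results):
    for row in base_results.rows:
        ref = base_results.row(row.endpoint_id, "sema")
        recomputed = Decimal(str(row.cost_of_control)) / Decimal(str(ref.cost_of_control))
        assert abs(row.relative_index - recomputed) < Decimal("1e-9")
        assert row.scaled_index == int((row.relative_index * 100_000).quantize(Decimal(1)))


def test_symmetric_dataset_yields_identical_rows(tmp_path):
    """Equal proportions and prices in both arms: mirrored rows, index 1."""
    import pandas as pd

    edf = pd.DataFrame(
        [
            ["e1", "target", "glycemic", "a", "50", "100"],
            ["e1", "target", "glycemic", "b", "50", "100"],
        ],
        columns=["endpoint_id", "label", "kind", "arm_id", "proportion_pct", "n"],
    )
    pdf = pd.DataFrame(
        [
            ["a", "A", "1", "1", "100.00", "100.00", "100.00"],
            ["b", "B", "1", "1", "100.00", "100.00", "100.00"],
        ],
        columns=["arm_id", "drug_label", "pack_mg", "pens_per_pack",
                 "monthly_base", "monthly_min", "monthly_max"],
    )
    res = CostOfControlModel.from_dataframes(edf, pdf, focal="a", comparator="b").fit()
    a, b = res.row("e1", "a"), res.row("e1", "b")
    assert a.cost_of_control == b.cost_of_control
    assert a.relative_index == b.relative_index == 1


def test_doubling_prices_scales_costs_not_indices(reference_dataset):
    """Scale invariance: x2 prices doubles every absolute cost, fixes every index.

    Uses the unrounded-annual convention, since rounding to the peso is the
    one deliberately non-linear step; the residual is the final centavo
    quantization of the cost product.
    """
    doubled = reference_dataset.model_copy(deep=True)
    for p in doubled.pricing:
        p.monthly_base *= 2
        p.monthly_min *= 2
        p.monthly_max *= 2
    conv = Conventions(round_annual_to_peso=False)
    base = run_base_case(reference_dataset, conv)
    scaled = run_base_case(doubled, conv)
    for r0, r2 in zip(base, scaled):
        assert abs(r2.cost_of_control - 2 * r0.cost_of_control) <= Decimal("0.02")
        assert abs(r2.relative_index - r0.relative_index) < Decimal("1e-6")
        assert r2.scaled_index == r0.scaled_index
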