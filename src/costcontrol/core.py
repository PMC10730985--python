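"""Cost-of-control arithmetic: ARR, NNT, annualization, absolute and relative costs.

The model asks a deliberately simple payer question: *what does one year of
drug spend cost per patient brought to a clinical target?*  For each endpoint
and arm,

    ARR  = p_active − p_reference        (reference assumed 0: placebo-zero)
    NNT  = 1 / ARR                       (rounded half-up to 2 decimals)
    cost of control = annual drug cost × NNT

with a one-year horizon, no discounting and 100% adherence.  All rounding is
commercial (half-up), matching how published pharmacoeconomic tables are
printed, and the rounding *order* matters for exact reproduction: NNT is
rounded before the multiplication, and the annual cost is the monthly price
× 12 rounded to the nearest peso (a flag disables the peso rounding, which
min/max price scenarios use — see :mod:`costcontrol.sensitivity`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP, localcontext
from typing import Mapping

from .errors import DomainError, UndefinedNNTError
from .trial import CostOfControlRow, TrialDataset

__all__ = [
    "Conventions",
    "annualize",
    "absolute_risk_reduction",
    "nnt",
    "cost_of_control",
    "drug_cost_index",
    "relative_cost_index",
    "run_base_case",
]

PESO = Decimal("1")
CENT = Decimal("0.01")
MONTHS_PER_YEAR = 12
INDEX_SCALE = 100_000
#: Working precision for unrounded ratios (relative indices, cost indices).
RATIO_PRECISION = 28


@dataclass(frozen=True)
class Conventions:
    """Rounding and comparison conventions of the cost model.

    nnt_decimals
        Decimal places NNT is rounded (half-up) to before entering the cost
        product. 2 reproduces published tables.
    round_annual_to_peso
        Whether annual cost = monthly × 12 is rounded to the nearest peso
        before the cost product.
    reference_proportion
        The responder share assumed for the implicit comparator of the ARR;
        0 encodes the placebo-zero convention.
    """

    nnt_decimals: int = 2
    round_annual_to_peso: bool = True
    reference_proportion: Decimal = Decimal(0)


def _as_decimal(x: object) -> Decimal:
    return x if isinstance(x, Decimal) else Decimal(str(x))


def annualize(monthly: Decimal | str | float, round_to_peso: bool = True) -> Decimal:
    """Annual drug cost from a monthly price (one pack per month, 100% adherence)."""
    monthly = _as_decimal(monthly)
    if monthly < 0:
        raise DomainError("monthly price must be non-negative")
    annual = monthly * MONTHS_PER_YEAR
    return annual.quantize(PESO, ROUND_HALF_UP) if round_to_peso else annual


def absolute_risk_reduction(
    p_active: Decimal | str | float, p_reference: Decimal | str | float = Decimal(0)
) -> Decimal:
    """ARR between an active arm and a (by default zero-response) reference."""
    p_active, p_reference = _as_decimal(p_active), _as_decimal(p_reference)
    for name, p in (("p_active", p_active), ("p_reference", p_reference)):
        if not Decimal(0) <= p <= Decimal(1):
            raise DomainError(f"{name} must lie in [0, 1], got {p}")
    if p_active < p_reference:
        raise DomainError(
            "p_active < p_reference: negative ARR unsupported under the placebo-zero convention"
        )
    return p_active - p_reference


def nnt(arr: Decimal | str | float, decimals: int = 2) -> Decimal:
    """Number needed to treat, 1/ARR rounded half-up to ``decimals`` places.

    Clamped below at 1 (one cannot treat fewer than one patient per responder).
    """
    arr = _as_decimal(arr)
    if not Decimal(0) <= arr <= Decimal(1):
        raise DomainError(f"ARR must lie in [0, 1], got {arr}")
    if arr == 0:
        raise UndefinedNNTError("no patients reach target; NNT undefined/infinite")
    if decimals < 0:
        raise DomainError("decimals must be >= 0")
    with localcontext() as ctx:
        ctx.prec = RATIO_PRECISION
        raw = Decimal(1) / arr
    quantum = Decimal(1).scaleb(-decimals)
    return max(raw.quantize(quantum, ROUND_HALF_UP), Decimal(1).quantize(quantum))


def cost_of_control(annual_cost: Decimal | str | float, nnt_value: Decimal | str | float) -> Decimal:
    """Annual expenditure to bring one patient to target: annual cost × NNT, at 2 dp."""
    annual_cost, nnt_value = _as_decimal(annual_cost), _as_decimal(nnt_value)
    if annual_cost < 0:
        raise DomainError("annual cost must be non-negative")
    if nnt_value < 1:
        raise DomainError("NNT must be >= 1")
    return (annual_cost * nnt_value).quantize(CENT, ROUND_HALF_UP)


def drug_cost_index(costs: Mapping[str, Decimal], reference: str) -> dict[str, Decimal]:
    """Price-parity index: each arm's annual cost over the mean of the *other* arms'.

    For the two-arm case this is simply each cost divided by the other's, the
    convention under which published index pairs multiply to 1 (e.g. a pair
    like 0.9931/1.0069 for near-identical annual costs).  ``reference`` must
    name an arm present in ``costs`` (it anchors reporting order only).
    """
    if reference not in costs:
        raise DomainError(f"reference arm {reference!r} not among costs")
    if len(costs) < 2:
        raise DomainError("need at least two arms")
    dec = {arm: _as_decimal(c) for arm, c in costs.items()}
    if any(c <= 0 for c in dec.values()):
        raise DomainError("all annual costs must be positive")
    out: dict[str, Decimal] = {}
    with localcontext() as ctx:
        ctx.prec = RATIO_PRECISION
        for arm, cost in dec.items():
            others = [c for a, c in dec.items() if a != arm]
            out[arm] = cost / (sum(others) / len(others))
    return out


def relative_cost_index(
    rows: list[CostOfControlRow], reference_arm: str
) -> list[CostOfControlRow]:
    """Fill each row's relative cost index versus the reference arm.

    ``relative_index = cost_of_control(arm) / cost_of_control(reference)`` per
    endpoint; ``scaled_index`` is the same ratio per 100,000 (reference arm
    = 100,000), the display convention of payer dashboards.  Rows whose NNT is
    undefined keep ``None`` indices; a missing reference row is an error.
    """
    ref = {
        r.endpoint_id: r for r in rows if r.arm_id == reference_arm
    }
    out: list[CostOfControlRow] = []
    for row in rows:
        base = ref.get(row.endpoint_id)
        if base is None:
            raise DomainError(
                f"no reference-arm ({reference_arm!r}) row for endpoint {row.endpoint_id!r}"
            )
        if row.undefined or base.undefined or base.cost_of_control == 0:
            out.append(row.model_copy(update={"relative_index": None, "scaled_index": None}))
            continue
        with localcontext() as ctx:
            ctx.prec = RATIO_PRECISION
            rel = row.cost_of_control / base.cost_of_control
        scaled = int((rel * INDEX_SCALE).quantize(PESO, ROUND_HALF_UP))
        out.append(row.model_copy(update={"relative_index": rel, "scaled_index": scaled}))
    return out


def _arm_rows(
    dataset: TrialDataset,
    arm: str,
    annual: Decimal,
    conventions: Conventions,
    proportions: Mapping[tuple[str, str], Decimal] | None = None,
) -> list[CostOfControlRow]:
    rows = []
    for definition in dataset.endpoints:
        key = (definition.id, arm)
        p = proportions[key] if proportions is not None else dataset.result(*key).proportion
        arr = absolute_risk_reduction(p, conventions.reference_proportion)
        if arr == 0:
            rows.append(
                CostOfControlRow(
                    endpoint_id=definition.id,
                    arm_id=arm,
                    arr=arr,
                    nnt=None,
                    annual_cost=annual,
                    cost_of_control=None,
                    undefined=True,
                )
            )
            continue
        n = nnt(arr, conventions.nnt_decimals)
        rows.append(
            CostOfControlRow(
                endpoint_id=definition.id,
                arm_id=arm,
                arr=arr,
                nnt=n,
                annual_cost=annual,
                cost_of_control=cost_of_control(annual, n),
            )
        )
    return rows


def run_base_case(
    dataset: TrialDataset, conventions: Conventions = Conventions()
) -> list[CostOfControlRow]:
    """Full base-case cost-of-control table: one row per endpoint × arm.

    Uses each arm's monthly *base* price annualized under the stated
    convention, the placebo-zero ARR, and the focal arm as reference of the
    relative index.
    """
    rows: list[CostOfControlRow] = []
    for arm in dataset.arms:
        annual = annualize(dataset.prices(arm).monthly_base, conventions.round_annual_to_peso)
        rows.extend(_arm_rows(dataset, arm, annual, conventions))
    return relative_cost_index(rows, dataset.focal_arm)
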