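"""One-way sensitivity analyses: binomial-SE perturbation and price scenarios.

Two deterministic stress tests around the base case:

1. **Responder-share perturbation.** Each observed proportion is shifted by
   one binomial standard error, ``SE = sqrt(p(1-p)/n)``, in the direction
   *against* the focal drug (focal arm down, comparator up), and the cost
   table is recomputed at base prices.  If the focal drug remains cheaper per
   controlled patient under this deck-stacking, the base-case conclusion is
   robust to sampling noise in the trial proportions.

2. **Price scenarios.** Each drug's price is moved to the bound of its
   observed market range (best case for the focal drug: focal at minimum,
   comparator at maximum; worst case: the opposite) and costs recomputed
   with unchanged base-case NNTs.

Scenario annualization note: min/max price points are annualized *without*
peso rounding by default while the base point keeps the peso-rounded
convention; this mixed convention is what reproduces published scenario
tables to the peso (see docs/methods.md), and both behaviours are
flag-controllable.
"""

from __future__ import annotations

import math
import warnings
from decimal import Decimal
from typing import Literal

from pydantic import BaseModel, model_validator

from .core import Conventions, _arm_rows, annualize, relative_cost_index
from .errors import DomainError
from .trial import CostOfControlRow, TrialDataset

__all__ = [
    "ScenarioSpec",
    "SensitivityResult",
    "standard_error",
    "one_way_perturb",
    "run_price_scenario",
]

PricePoint = Literal["base", "min", "max"]


class ScenarioSpec(BaseModel):
    """Which price point each arm uses in a pricing scenario."""

    name: Literal["base", "best_for_focal", "worst_for_focal"]
    focal_price_point: PricePoint
    comparator_price_point: PricePoint

    @model_validator(mode="after")
    def _consistent(self) -> "ScenarioSpec":
        expected = {
            "base": ("base", "base"),
            "best_for_focal": ("min", "max"),
            "worst_for_focal": ("max", "min"),
        }[self.name]
        if (self.focal_price_point, self.comparator_price_point) != expected:
            raise ValueError(
                f"scenario {self.name!r} requires price points {expected}, got "
                f"({self.focal_price_point!r}, {self.comparator_price_point!r})"
            )
        return self

    @classmethod
    def from_name(cls, name: str) -> "ScenarioSpec":
        points = {
            "base": ("base", "base"),
            "best_for_focal": ("min", "max"),
            "worst_for_focal": ("max", "min"),
        }
        if name not in points:
            raise DomainError(f"unknown scenario {name!r}; expected one of {sorted(points)}")
        focal, comp = points[name]
        return cls(name=name, focal_price_point=focal, comparator_price_point=comp)


class SensitivityResult(BaseModel):
    """A recomputed cost table plus the description of what was varied."""

    scenario: ScenarioSpec | str
    rows: list[CostOfControlRow]
    perturbed_proportions: dict[str, Decimal] = {}

    @model_validator(mode="after")
    def _clamped(self) -> "SensitivityResult":
        for key, p in self.perturbed_proportions.items():
            if not Decimal(0) <= p <= Decimal(1):
                raise ValueError(f"perturbed proportion for {key} outside [0, 1]")
        return self


def standard_error(p: float | Decimal, n: int) -> float:
    """Binomial standard error of an observed proportion: sqrt(p(1-p)/n)."""
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"p must lie in [0, 1], got {p}")
    if n < 1 or int(n) != n:
        raise DomainError(f"n must be a positive integer, got {n}")
    return math.sqrt(p * (1.0 - p) / n)


def _key(endpoint_id: str, arm_id: str) -> str:
    return f"{endpoint_id}/{arm_id}"


def one_way_perturb(
    dataset: TrialDataset,
    against_focal: bool = True,
    conventions: Conventions = Conventions(),
) -> SensitivityResult:
    """Shift every proportion by one binomial SE and recompute the cost table.

    With ``against_focal`` (the default, the conservative direction) the focal
    arm's proportions drop by one SE and the comparator's rise by one SE;
    ``against_focal=False`` reverses both signs.  Perturbed values are clamped
    to [0, 1] with a warning.  A perturbed proportion of exactly 0 makes that
    row's NNT undefined; the row is kept and flagged rather than dropped.
    Prices stay at the monthly base under the base-case annualization.
    """
    perturbed: dict[tuple[str, str], Decimal] = {}
    for r in dataset.results:
        se = Decimal(str(standard_error(r.proportion, r.n)))
        down = (r.arm_id == dataset.focal_arm) == against_focal
        p = r.proportion - se if down else r.proportion + se
        if p < 0 or p > 1:
            clamped = min(max(p, Decimal(0)), Decimal(1))
            warnings.warn(
                f"perturbed proportion {p} for {_key(r.endpoint_id, r.arm_id)} "
                f"clamped to {clamped}",
                stacklevel=2,
            )
            p = clamped
        perturbed[(r.endpoint_id, r.arm_id)] = p

    rows: list[CostOfControlRow] = []
    for arm in dataset.arms:
        annual = annualize(dataset.prices(arm).monthly_base, conventions.round_annual_to_peso)
        rows.extend(_arm_rows(dataset, arm, annual, conventions, proportions=perturbed))
    rows = relative_cost_index(rows, dataset.focal_arm)
    return SensitivityResult(
        scenario="se_perturbation_against_focal" if against_focal else "se_perturbation_for_focal",
        rows=rows,
        perturbed_proportions={_key(e, a): p for (e, a), p in perturbed.items()},
    )


def run_price_scenario(
    dataset: TrialDataset,
    scenario: ScenarioSpec,
    conventions: Conventions = Conventions(),
    round_annual: bool | None = None,
) -> SensitivityResult:
    """Recompute the cost table with each arm priced at the scenario's point.

    NNTs are the unchanged base-case NNTs (proportions are not varied here).
    ``round_annual=None`` applies the per-point default: peso rounding for the
    base price point, unrounded annualization for min/max bounds.
    """
    points = {
        dataset.focal_arm: scenario.focal_price_point,
        dataset.comparator_arm: scenario.comparator_price_point,
    }
    rows: list[CostOfControlRow] = []
    for arm in dataset.arms:
        point = points[arm]
        do_round = (point == "base") if round_annual is None else round_annual
        annual = annualize(dataset.prices(arm).monthly(point), do_round)
        rows.extend(_arm_rows(dataset, arm, annual, conventions))
    rows = relative_cost_index(rows, dataset.focal_arm)
    return SensitivityResult(scenario=scenario, rows=rows)
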