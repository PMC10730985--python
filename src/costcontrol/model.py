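"""Model/Results interface to the cost-of-control analysis.

`CostOfControlModel` wraps a validated trial dataset plus the rounding
conventions; `fit()` evaluates the deterministic model (it is an exact
calculation, not an estimation) and returns a `CostOfControlResults`
carrying the per-endpoint cost table, with sensitivity analyses and a
printable summary hanging off it::

    model = CostOfControlModel.from_files("endpoints.csv", "prices.csv",
                                          focal="sema", comparator="dula")
    res = model.fit()
    print(res.summary())
    worst = res.price_scenario("worst_for_focal")
"""

from __future__ import annotations

from decimal import Decimal
from pathlib import Path

import pandas as pd

from . import __about__
from .core import Conventions, annualize, drug_cost_index, run_base_case
from .sensitivity import (
    ScenarioSpec,
    SensitivityResult,
    one_way_perturb,
    run_price_scenario,
)
from .trial import CostOfControlRow, TrialDataset, read_trial_dataset

__all__ = ["CostOfControlModel", "CostOfControlResults"]

ASSUMPTIONS = (
    "one-year horizon, no discounting, 100% adherence, drug costs only, "
    "placebo-zero ARR (NNT = 1/p)"
)


class CostOfControlModel:
    """Annual cost per patient brought to target, for a two-arm drug comparison.

    Parameters
    ----------
    dataset
        Validated endpoint proportions, arm sizes and monthly price records.
    nnt_decimals
        Decimal places the NNT is rounded (half-up) to before the cost
        product; default 2.
    round_annual_to_peso
        Whether the base annual cost (monthly × 12) is rounded to the nearest
        peso before the cost product; default True.
    """

    def __init__(
        self,
        dataset: TrialDataset,
        *,
        nnt_decimals: int = 2,
        round_annual_to_peso: bool = True,
    ):
        self.dataset = dataset
        self.conventions = Conventions(
            nnt_decimals=nnt_decimals, round_annual_to_peso=round_annual_to_peso
        )

    @classmethod
    def from_files(
        cls,
        endpoint_path: str | Path,
        price_path: str | Path,
        *,
        focal: str,
        comparator: str,
        default_n: int = 299,
        **conventions,
    ) -> "CostOfControlModel":
        ds = read_trial_dataset(
            endpoint_path, price_path, focal=focal, comparator=comparator, default_n=default_n
        )
        return cls(ds, **conventions)

    @classmethod
    def from_dataframes(
        cls,
        endpoints: pd.DataFrame,
        prices: pd.DataFrame,
        *,
        focal: str,
        comparator: str,
        default_n: int = 299,
        **conventions,
    ) -> "CostOfControlModel":
        """Build from in-memory tables in the same schema as the input files."""
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            ep, pp = Path(tmp) / "endpoints.csv", Path(tmp) / "prices.csv"
            endpoints.to_csv(ep, index=False)
            prices.to_csv(pp, index=False)
            ds = read_trial_dataset(ep, pp, focal=focal, comparator=comparator, default_n=default_n)
        return cls(ds, **conventions)

    def fit(self) -> "CostOfControlResults":
        """Evaluate the base case and return the results object."""
        rows = run_base_case(self.dataset, self.conventions)
        return CostOfControlResults(self, rows)


def rows_to_frame(rows: list[CostOfControlRow]) -> pd.DataFrame:
    """Cost rows as a DataFrame (Decimals preserved in object columns)."""
    return pd.DataFrame([r.model_dump() for r in rows])


class CostOfControlResults:
    """Base-case cost-of-control table plus derived quantities and analyses."""

    def __init__(self, model: CostOfControlModel, rows: list[CostOfControlRow]):
        self.model = model
        self.rows = rows

    # -- accessors -------------------------------------------------------------

    @property
    def table(self) -> pd.DataFrame:
        return rows_to_frame(self.rows)

    def row(self, endpoint_id: str, arm_id: str) -> CostOfControlRow:
        for r in self.rows:
            if r.endpoint_id == endpoint_id and r.arm_id == arm_id:
                return r
        raise KeyError((endpoint_id, arm_id))

    @property
    def annual_costs(self) -> dict[str, Decimal]:
        """Annualized base drug cost per arm, under the model's convention."""
        conv = self.model.conventions
        return {
            p.arm_id: annualize(p.monthly_base, conv.round_annual_to_peso)
            for p in self.model.dataset.pricing
        }

    @property
    def drug_cost_index(self) -> dict[str, Decimal]:
        """Price-parity index of annual costs (two-arm: each over the other)."""
        return drug_cost_index(self.annual_costs, self.model.dataset.focal_arm)

    def cost_ratio(self, endpoint_id: str) -> Decimal:
        """Comparator/focal cost-of-control ratio for one endpoint."""
        ds = self.model.dataset
        rel = self.row(endpoint_id, ds.comparator_arm).relative_index
        if rel is None:
            raise ValueError(f"ratio undefined for endpoint {endpoint_id!r}")
        return rel

    # -- sensitivity analyses --------------------------------------------------

    def se_perturbation(self, against_focal: bool = True) -> SensitivityResult:
        """One-way binomial-SE perturbation of the responder proportions."""
        return one_way_perturb(self.model.dataset, against_focal, self.model.conventions)

    def price_scenario(self, name: str = "worst_for_focal") -> SensitivityResult:
        """Best/worst market-price scenario for the focal drug."""
        spec = ScenarioSpec.from_name(name)
        return run_price_scenario(self.model.dataset, spec, self.model.conventions)

    # -- presentation ----------------------------------------------------------

    def summary(self) -> str:
        """Printable statsmodels-style summary of the base case."""
        ds = self.model.dataset
        labels = {e.id: e.label for e in ds.endpoints}
        annual = self.annual_costs
        lines = [
            "Cost-of-Control Model Results".center(78),
            "=" * 78,
            f"Focal arm:       {ds.focal_arm}",
            f"Comparator arm:  {ds.comparator_arm}",
            f"Assumptions:     {ASSUMPTIONS}",
            f"Annual drug cost (COP): "
            + ", ".join(f"{a}={annual[a]}" for a in ds.arms),
            f"Package version: {__about__.__version__}",
            "-" * 78,
            f"{'endpoint':<38}{'arm':<6}{'NNT':>7}{'cost of control':>18}{'rel.':>8}",
            "-" * 78,
        ]
        for r in self.rows:
            label = labels[r.endpoint_id][:36]
            nnt_s = "inf" if r.undefined else f"{r.nnt}"
            coc_s = "undefined" if r.undefined else f"{r.cost_of_control}"
            rel_s = "" if r.relative_index is None else f"{r.relative_index:.4f}"
            lines.append(f"{label:<38}{r.arm_id:<6}{nnt_s:>7}{coc_s:>18}{rel_s:>8}")
        lines.append("=" * 78)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        ds = self.model.dataset
        return (
            f"<CostOfControlResults: {len(ds.endpoints)} endpoints, "
            f"arms {ds.focal_arm!r} vs {ds.comparator_arm!r}>"
        )
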