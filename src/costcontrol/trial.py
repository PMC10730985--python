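"""Domain types and delimited-text I/O for head-to-head trial endpoint and price data.

The model consumes two small tables:

* an *endpoints* table — per endpoint and treatment arm, the proportion of
  patients achieving the target (given as a percentage, as trial reports
  print it) and the arm size ``n``;
* a *prices* table — per drug, the monthly base/minimum/maximum pack price
  (here in Colombian pesos, COP, as published in the SISMED price system).

All currency amounts and proportions are carried as :class:`decimal.Decimal`
so that peso-level reproduction of published cost tables is well defined;
binary floating point never touches money.
"""

from __future__ import annotations

import json
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import SchemaError

__all__ = [
    "EndpointDefinition",
    "EndpointResult",
    "DrugPricing",
    "TrialDataset",
    "CostOfControlRow",
    "read_trial_dataset",
    "write_trial_dataset",
    "write_report",
    "read_report",
]

#: Default arm size when the endpoints file omits ``n`` (the SUSTAIN 7 arms
#: randomized ~299 patients each; 600 total is available via ``default_n``).
DEFAULT_ARM_SIZE = 299

ENDPOINT_COLUMNS = ["endpoint_id", "label", "kind", "arm_id", "proportion_pct", "n"]
PRICE_COLUMNS = [
    "arm_id",
    "drug_label",
    "pack_mg",
    "pens_per_pack",
    "monthly_base",
    "monthly_min",
    "monthly_max",
]


class EndpointDefinition(BaseModel):
    """A clinical target, e.g. ``HbA1c <7.0%`` or a composite of several conditions."""

    id: str
    label: str
    kind: Literal["glycemic", "weight", "composite"]

    @field_validator("id", "label")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("must be non-empty")
        return v


class EndpointResult(BaseModel):
    """Observed responder share for one endpoint in one arm.

    ``proportion`` is stored as a fraction in [0, 1]; ``n`` is the number of
    patients in that arm (the ``n`` of the binomial standard error).
    """

    endpoint_id: str
    arm_id: str
    proportion: Decimal
    n: int = Field(ge=1)

    @field_validator("proportion")
    @classmethod
    def _in_unit_interval(cls, v: Decimal) -> Decimal:
        if not Decimal(0) <= v <= Decimal(1):
            raise ValueError("proportion must lie in [0, 1]")
        return v


class DrugPricing(BaseModel):
    """Monthly pack price record for one drug (base plus observed min/max)."""

    arm_id: str
    drug_label: str
    pack_mg: Decimal
    pens_per_pack: int = Field(ge=1)
    monthly_base: Decimal = Field(gt=0)
    monthly_min: Decimal = Field(gt=0)
    monthly_max: Decimal = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "DrugPricing":
        if not self.monthly_min <= self.monthly_base <= self.monthly_max:
            raise ValueError("prices must satisfy monthly_min <= monthly_base <= monthly_max")
        return self

    def monthly(self, point: Literal["base", "min", "max"]) -> Decimal:
        """Return the requested monthly price point."""
        return {"base": self.monthly_base, "min": self.monthly_min, "max": self.monthly_max}[point]


class TrialDataset(BaseModel):
    """A validated two-arm trial dataset: endpoints, responder shares and prices.

    ``focal_arm`` is the treatment whose perspective defines best/worst price
    scenarios and serves as the reference of the relative cost index.
    """

    endpoints: list[EndpointDefinition]
    results: list[EndpointResult]
    pricing: list[DrugPricing]
    focal_arm: str
    comparator_arm: str

    @model_validator(mode="after")
    def _consistent(self) -> "TrialDataset":
        arms = {self.focal_arm, self.comparator_arm}
        if self.focal_arm == self.comparator_arm:
            raise ValueError("focal and comparator arms must differ")
        ids = [e.id for e in self.endpoints]
        if len(set(ids)) != len(ids):
            raise ValueError("endpoint ids must be unique")
        seen: set[tuple[str, str]] = set()
        for r in self.results:
            if r.arm_id not in arms:
                raise ValueError(f"result arm {r.arm_id!r} is neither focal nor comparator")
            if r.endpoint_id not in ids:
                raise ValueError(f"result references unknown endpoint {r.endpoint_id!r}")
            key = (r.endpoint_id, r.arm_id)
            if key in seen:
                raise ValueError(f"duplicate result for {key}")
            seen.add(key)
        for eid in ids:
            for arm in arms:
                if (eid, arm) not in seen:
                    raise ValueError(f"endpoint {eid!r} lacks a result for arm {arm!r}")
        priced = {p.arm_id for p in self.pricing}
        if len(self.pricing) != len(priced):
            raise ValueError("duplicate pricing record for an arm")
        if not arms <= priced:
            raise ValueError(f"pricing missing for arm(s) {sorted(arms - priced)}")
        if not priced <= arms:
            raise ValueError(f"pricing for unknown arm(s) {sorted(priced - arms)}")
        return self

    # -- convenience accessors -------------------------------------------------

    def result(self, endpoint_id: str, arm_id: str) -> EndpointResult:
        for r in self.results:
            if r.endpoint_id == endpoint_id and r.arm_id == arm_id:
                return r
        raise KeyError((endpoint_id, arm_id))

    def prices(self, arm_id: str) -> DrugPricing:
        for p in self.pricing:
            if p.arm_id == arm_id:
                return p
        raise KeyError(arm_id)

    @property
    def arms(self) -> tuple[str, str]:
        return (self.focal_arm, self.comparator_arm)


class CostOfControlRow(BaseModel):
    """One endpoint × arm line of the cost-of-control table.

    ``cost_of_control = annual_cost × nnt`` exactly at the stored precision;
    ``relative_index`` is the ratio to the focal (reference) arm's cost of
    control, and ``scaled_index`` the same ratio per 100,000. When the
    perturbed responder share hits zero the NNT is undefined (infinite): the
    row is kept with ``undefined=True`` rather than dropped.
    """

    endpoint_id: str
    arm_id: str
    arr: Decimal | None
    nnt: Decimal | None
    annual_cost: Decimal
    cost_of_control: Decimal | None
    relative_index: Decimal | None = None
    scaled_index: int | None = None
    undefined: bool = False

    @model_validator(mode="after")
    def _consistent(self) -> "CostOfControlRow":
        if self.undefined:
            return self
        if self.nnt is None or self.cost_of_control is None:
            raise ValueError("defined rows need nnt and cost_of_control")
        if self.nnt < 1:
            raise ValueError("nnt must be >= 1")
        return self


# -----------------------------------------------------------------------------
# Readers / writers
# -----------------------------------------------------------------------------


def _read_table(path: str | Path, columns: Sequence[str], optional: Iterable[str] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in columns if c not in df.columns and c not in set(optional)]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _decimal(value: object, *, row: object, field: str) -> Decimal:
    try:
        return Decimal(str(value).strip())
    except (InvalidOperation, AttributeError) as exc:
        raise SchemaError(f"not a decimal number: {value!r}", row=row, field=field) from exc


def read_trial_dataset(
    endpoint_path: str | Path,
    price_path: str | Path,
    focal: str,
    comparator: str,
    *,
    default_n: int = DEFAULT_ARM_SIZE,
) -> TrialDataset:
    """Read and validate the endpoints and prices files into a :class:`TrialDataset`.

    Proportions are given in the file as percentages (``79`` meaning 79%) and
    stored as exact decimal fractions (``0.79``). A missing/blank ``n`` falls
    back to ``default_n``.
    """
    edf = _read_table(endpoint_path, ENDPOINT_COLUMNS, optional=["n"])
    pdf = _read_table(price_path, PRICE_COLUMNS)

    endpoints: dict[str, EndpointDefinition] = {}
    results: list[EndpointResult] = []
    for i, rec in enumerate(edf.to_dict("records")):
        pct = _decimal(rec["proportion_pct"], row=i, field="proportion_pct")
        if not Decimal(0) <= pct <= Decimal(100):
            raise SchemaError(
                f"proportion_pct {pct} outside [0, 100]", row=i, field="proportion_pct"
            )
        n_raw = rec.get("n")
        if n_raw is None or (isinstance(n_raw, float) and pd.isna(n_raw)) or str(n_raw).strip() == "":
            n = default_n
        else:
            try:
                n = int(str(n_raw).strip())
            except ValueError as exc:
                raise SchemaError(f"n is not an integer: {n_raw!r}", row=i, field="n") from exc
        try:
            definition = EndpointDefinition(id=rec["endpoint_id"], label=rec["label"], kind=rec["kind"])
            result = EndpointResult(
                endpoint_id=rec["endpoint_id"],
                arm_id=rec["arm_id"],
                proportion=pct / Decimal(100),
                n=n,
            )
        except ValueError as exc:
            raise SchemaError(f"invalid endpoint record: {exc}", row=i) from exc
        prior = endpoints.get(definition.id)
        if prior is not None and prior != definition:
            raise SchemaError(
                f"endpoint {definition.id!r} redefined inconsistently", row=i, field="endpoint_id"
            )
        endpoints[definition.id] = definition
        if any(r.endpoint_id == result.endpoint_id and r.arm_id == result.arm_id for r in results):
            raise SchemaError(
                f"duplicate (endpoint, arm) pair {(result.endpoint_id, result.arm_id)}", row=i
            )
        results.append(result)

    pricing: list[DrugPricing] = []
    for i, rec in enumerate(pdf.to_dict("records")):
        try:
            pricing.append(
                DrugPricing(
                    arm_id=rec["arm_id"],
                    drug_label=rec["drug_label"],
                    pack_mg=_decimal(rec["pack_mg"], row=i, field="pack_mg"),
                    pens_per_pack=int(str(rec["pens_per_pack"]).strip()),
                    monthly_base=_decimal(rec["monthly_base"], row=i, field="monthly_base"),
                    monthly_min=_decimal(rec["monthly_min"], row=i, field="monthly_min"),
                    monthly_max=_decimal(rec["monthly_max"], row=i, field="monthly_max"),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"invalid price record: {exc}", row=i) from exc

    try:
        return TrialDataset(
            endpoints=list(endpoints.values()),
            results=results,
            pricing=pricing,
            focal_arm=focal,
            comparator_arm=comparator,
        )
    except ValueError as exc:
        raise SchemaError(f"inconsistent dataset: {exc}") from exc


def write_trial_dataset(
    dataset: TrialDataset, endpoint_path: str | Path, price_path: str | Path
) -> None:
    """Write a dataset back to the two delimited-text input files.

    Inverse of :func:`read_trial_dataset`: proportions are written as
    percentages with plain decimal points, so read → write → read round-trips
    to an identical dataset.
    """
    defs = {e.id: e for e in dataset.endpoints}
    erows = [
        {
            "endpoint_id": r.endpoint_id,
            "label": defs[r.endpoint_id].label,
            "kind": defs[r.endpoint_id].kind,
            "arm_id": r.arm_id,
            "proportion_pct": str(r.proportion * Decimal(100)),
            "n": r.n,
        }
        for r in dataset.results
    ]
    prows = [
        {
            "arm_id": p.arm_id,
            "drug_label": p.drug_label,
            "pack_mg": str(p.pack_mg),
            "pens_per_pack": p.pens_per_pack,
            "monthly_base": str(p.monthly_base),
            "monthly_min": str(p.monthly_min),
            "monthly_max": str(p.monthly_max),
        }
        for p in dataset.pricing
    ]
    pd.DataFrame(erows, columns=ENDPOINT_COLUMNS).to_csv(endpoint_path, index=False)
    pd.DataFrame(prows, columns=PRICE_COLUMNS).to_csv(price_path, index=False)


_REPORT_FIELDS = [
    "endpoint_id",
    "arm_id",
    "arr",
    "nnt",
    "annual_cost",
    "cost_of_control",
    "relative_index",
    "scaled_index",
    "undefined",
]


def _row_record(row: CostOfControlRow) -> dict[str, object]:
    rec: dict[str, object] = {}
    for f in _REPORT_FIELDS:
        v = getattr(row, f)
        rec[f] = str(v) if isinstance(v, Decimal) else v
    return rec


def write_report(
    rows: Sequence[CostOfControlRow],
    path: str | Path,
    format: Literal["delimited", "json"] = "delimited",
) -> None:
    """Write a cost-of-control table as CSV or JSON with plain decimal numbers."""
    if not rows:
        raise ValueError("cannot write an empty report")
    records = [_row_record(r) for r in rows]
    path = Path(path)
    if format == "delimited":
        pd.DataFrame(records, columns=_REPORT_FIELDS).to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: Literal["delimited", "json"] = "delimited") -> list[CostOfControlRow]:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if format == "delimited":
        records = pd.read_csv(path, dtype=str).to_dict("records")
        for rec in records:
            rec["undefined"] = str(rec.get("undefined", "False")).strip().lower() == "true"
    elif format == "json":
        records = json.loads(path.read_text())
    else:
        raise ValueError(f"unknown report format {format!r}")
    rows = []
    for rec in records:
        clean = {
            k: (None if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" else v)
            for k, v in rec.items()
        }
        if clean.get("scaled_index") is not None:
            clean["scaled_index"] = int(float(clean["scaled_index"]))
        rows.append(CostOfControlRow(**clean))
    return rows
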