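"""Packaged reference inputs: SUSTAIN 7 responder shares and SISMED 2021 prices.

The package ships the published desk-scale inputs of the semaglutide 1.0 mg
vs dulaglutide 1.5 mg comparison — the proportion of patients reaching each
of six glycemic/weight endpoints in the SUSTAIN 7 trial, and the monthly
base/min/max pack prices of both drugs from Colombia's SISMED price system
(December 2021, COP) — as two small CSV files in the input schema the
readers expect.
"""

from __future__ import annotations

from decimal import Decimal
from importlib import resources
from pathlib import Path

from .synthetic import SyntheticSpec
from .trial import TrialDataset, read_trial_dataset

__all__ = ["reference_paths", "load_reference_dataset", "reference_synthetic_spec"]

FOCAL_ARM = "sema"
COMPARATOR_ARM = "dula"


def reference_paths() -> tuple[Path, Path]:
    """Filesystem paths of the packaged endpoints and prices CSV files."""
    root = resources.files("costcontrol") / "data"
    return (Path(str(root / "sustain7_endpoints.csv")), Path(str(root / "sismed_2021_prices.csv")))


def load_reference_dataset() -> TrialDataset:
    """The packaged SUSTAIN 7 + SISMED dataset, validated (6 endpoints × 2 arms)."""
    endpoints, prices = reference_paths()
    return read_trial_dataset(endpoints, prices, focal=FOCAL_ARM, comparator=COMPARATOR_ARM)


def reference_synthetic_spec(seed: int = 0, n_per_arm: int = 299) -> SyntheticSpec:
    """A synthetic-trial spec whose truths mirror the packaged reference dataset.

    True responder proportions are the published SUSTAIN 7 shares and base
    prices the SISMED base prices; the price corridor half-widths (±2.5% for
    semaglutide, ±0.6% for dulaglutide) match the magnitude of the observed
    SISMED min/max ranges.
    """
    ds = load_reference_dataset()
    return SyntheticSpec(
        true_proportions={(r.endpoint_id, r.arm_id): r.proportion for r in ds.results},
        n_per_arm=n_per_arm,
        price_base={p.arm_id: p.monthly_base for p in ds.pricing},
        price_spread={"sema": Decimal("0.025"), "dula": Decimal("0.006")},
        seed=seed,
        focal_arm=ds.focal_arm,
        comparator_arm=ds.comparator_arm,
        endpoint_kinds={e.id: e.kind for e in ds.endpoints},
        endpoint_labels={e.id: e.label for e in ds.endpoints},
    )
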