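"""Synthetic two-arm trial generator with the statistical structure the model assumes.

Responder counts are drawn binomially per (endpoint, arm) at stated true
proportions and arm size, and market price ranges are built symmetrically
around a base price — exactly the shape of the real inputs (a responder
table plus a base/min/max price table), so every pipeline stage is testable
without external data.  A single integer seed drives one explicit
:class:`numpy.random.Generator`; there is no global random state.

What this emulates and what it does not: sampling noise in trial proportions
and a price corridor.  It does not simulate patient trajectories, dropout,
imperfect adherence or correlated endpoints — observed shares of *different*
endpoints in the same simulated arm are drawn independently, whereas in a
real trial they are nested (every patient at HbA1c ≤6.5% is also <7.0%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP, localcontext

import numpy as np
import pandas as pd

from .core import RATIO_PRECISION
from .errors import DomainError
from .sensitivity import standard_error
from .trial import (
    DrugPricing,
    EndpointDefinition,
    EndpointResult,
    TrialDataset,
)

__all__ = ["SyntheticSpec", "simulate_trial", "parameter_recovery_check", "RecoverySummary"]

CENT = Decimal("0.01")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a simulated head-to-head trial.

    true_proportions
        Map ``(endpoint_id, arm_id) -> true responder fraction``.
    n_per_arm
        Patients randomized to each arm.
    price_base
        Monthly base price per arm (COP).
    price_spread
        Half-width of the [min, max] price corridor relative to base,
        per arm (0.02 = ±2%).
    seed
        Single integer governing every random draw.
    """

    true_proportions: dict[tuple[str, str], Decimal]
    n_per_arm: int
    price_base: dict[str, Decimal]
    price_spread: dict[str, Decimal]
    seed: int
    focal_arm: str | None = None
    comparator_arm: str | None = None
    endpoint_kinds: dict[str, str] = field(default_factory=dict)
    endpoint_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise DomainError("n_per_arm must be >= 1")
        for key, p in self.true_proportions.items():
            if not Decimal(0) <= Decimal(p) <= Decimal(1):
                raise DomainError(f"true proportion for {key} outside [0, 1]")
        for arm, s in self.price_spread.items():
            if Decimal(s) < 0:
                raise DomainError(f"price spread for {arm!r} must be >= 0")

    @property
    def arms(self) -> tuple[str, str]:
        arms = list(self.price_base)
        if len(arms) != 2:
            raise DomainError("exactly two arms required")
        focal = self.focal_arm or arms[0]
        comparator = self.comparator_arm or next(a for a in arms if a != focal)
        return focal, comparator

    @property
    def endpoint_ids(self) -> list[str]:
        seen: list[str] = []
        for eid, _ in self.true_proportions:
            if eid not in seen:
                seen.append(eid)
        return seen


def simulate_trial(spec: SyntheticSpec) -> TrialDataset:
    """Draw one synthetic trial dataset; bit-identical for identical spec+seed.

    Observed proportions are stored at full decimal precision (never
    re-rounded to whole percentages); prices as base, base·(1−spread),
    base·(1+spread) quantized to centavos.
    """
    rng = np.random.default_rng(spec.seed)
    focal, comparator = spec.arms
    endpoints = [
        EndpointDefinition(
            id=eid,
            label=spec.endpoint_labels.get(eid, eid),
            kind=spec.endpoint_kinds.get(eid, "composite"),
        )
        for eid in spec.endpoint_ids
    ]
    results = []
    for eid in spec.endpoint_ids:
        for arm in (focal, comparator):
            p_true = float(spec.true_proportions[(eid, arm)])
            count = int(rng.binomial(spec.n_per_arm, p_true))
            with localcontext() as ctx:
                ctx.prec = RATIO_PRECISION
                p_obs = Decimal(count) / Decimal(spec.n_per_arm)
            results.append(
                EndpointResult(endpoint_id=eid, arm_id=arm, proportion=p_obs, n=spec.n_per_arm)
            )
    pricing = []
    for arm in (focal, comparator):
        base = Decimal(spec.price_base[arm])
        spread = Decimal(spec.price_spread.get(arm, Decimal(0)))
        pricing.append(
            DrugPricing(
                arm_id=arm,
                drug_label=arm,
                pack_mg=Decimal(1),
                pens_per_pack=1,
                monthly_base=base.quantize(CENT, ROUND_HALF_UP),
                monthly_min=(base * (1 - spread)).quantize(CENT, ROUND_HALF_UP),
                monthly_max=(base * (1 + spread)).quantize(CENT, ROUND_HALF_UP),
            )
        )
    return TrialDataset(
        endpoints=endpoints,
        results=results,
        pricing=pricing,
        focal_arm=focal,
        comparator_arm=comparator,
    )


def _round_half_up_2dp(x: np.ndarray) -> np.ndarray:
    # vectorized commercial rounding of positive values to 2 dp
    return np.floor(x * 100.0 + 0.5) / 100.0


@dataclass(frozen=True)
class RecoverySummary:
    """Bias/coverage summary of repeated simulation and re-analysis.

    by_arm
        One row per (endpoint, arm): true p, mean and SD of observed
        proportions, the analytic binomial SE at true p, their ratio, and the
        absolute bias of the mean in SE units.
    ordering
        One row per endpoint: the fraction of replicates in which the arm
        with the truly higher responder share ends up with the strictly lower
        cost of control at equal prices (NaN when the truths are tied), plus
        the tie fraction of rounded NNTs.
    """

    by_arm: pd.DataFrame
    ordering: pd.DataFrame
    replicates: int

    @property
    def max_abs_bias_in_se(self) -> float:
        return float(self.by_arm["abs_bias_in_se"].max())

    @property
    def sd_ratio_range(self) -> tuple[float, float]:
        return (float(self.by_arm["sd_ratio"].min()), float(self.by_arm["sd_ratio"].max()))


def parameter_recovery_check(spec: SyntheticSpec, replicates: int) -> RecoverySummary:
    """Re-simulate ``replicates`` trials and check the generator against theory.

    Verifies that observed proportions are unbiased (mean within 0.5 SE of
    truth), that their spread matches the binomial standard error, and — the
    end-to-end check — how often the truly better arm is also the cheaper one
    per controlled patient when both drugs cost the same.  Cost ordering uses
    the same rounded-NNT convention as the main pipeline; a zero responder
    count means an infinite NNT and counts as the more expensive arm.
    """
    if replicates < 100:
        raise DomainError("need at least 100 replicates for a meaningful summary")
    rng = np.random.default_rng(spec.seed)
    focal, comparator = spec.arms
    eids = spec.endpoint_ids
    truth = np.array(
        [[float(spec.true_proportions[(e, a)]) for a in (focal, comparator)] for e in eids]
    )  # (E, 2)
    n = spec.n_per_arm
    counts = rng.binomial(n, truth, size=(replicates, *truth.shape))
    phat = counts / n

    se = np.sqrt(truth * (1 - truth) / n)
    mean = phat.mean(axis=0)
    sd = phat.std(axis=0, ddof=1)
    by_arm = pd.DataFrame(
        {
            "endpoint_id": np.repeat(eids, 2),
            "arm_id": [a for _ in eids for a in (focal, comparator)],
            "true_p": truth.ravel(),
            "mean_observed": mean.ravel(),
            "sd_observed": sd.ravel(),
            "analytic_se": se.ravel(),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        by_arm["sd_ratio"] = np.where(by_arm["analytic_se"] > 0, by_arm["sd_observed"] / by_arm["analytic_se"], np.nan)
        by_arm["abs_bias_in_se"] = np.where(
            by_arm["analytic_se"] > 0,
            np.abs(by_arm["mean_observed"] - by_arm["true_p"]) / by_arm["analytic_se"],
            np.abs(by_arm["mean_observed"] - by_arm["true_p"]),
        )

    # equal-price cost ordering <=> rounded-NNT ordering; phat==0 -> infinite NNT
    with np.errstate(divide="ignore"):
        nnt_r = np.where(phat > 0, _round_half_up_2dp(1.0 / np.maximum(phat, 1e-300)), np.inf)
    ordering_rows = []
    for i, eid in enumerate(eids):
        hi, lo = (0, 1) if truth[i, 0] > truth[i, 1] else (1, 0)
        ties = float(np.mean(nnt_r[:, i, 0] == nnt_r[:, i, 1]))
        if truth[i, 0] == truth[i, 1]:
            frac = float("nan")
        else:
            frac = float(np.mean(nnt_r[:, i, hi] < nnt_r[:, i, lo]))
        ordering_rows.append(
            {
                "endpoint_id": eid,
                "frac_higher_p_cheaper": frac,
                "frac_nnt_tie": ties,
                "frac_focal_cheaper": float(np.mean(nnt_r[:, i, 0] < nnt_r[:, i, 1])),
                "frac_comparator_cheaper": float(np.mean(nnt_r[:, i, 1] < nnt_r[:, i, 0])),
            }
        )
    ordering = pd.DataFrame(ordering_rows)
    return RecoverySummary(by_arm=by_arm, ordering=ordering, replicates=replicates)


# re-export for callers that want the analytic SE without importing sensitivity
analytic_se = standard_error
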