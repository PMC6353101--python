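"""Cost and turnaround-time comparison across species-identification methods.

Itemized per-sample and per-batch (96-well) reagent/labour costs for each
identification method (probe-based qPCR, DNA barcoding, contracted
morphological identification), with totals and pairwise comparisons.

Some published tables carry printed totals that differ from the sum of
their printed components; tables here store both, and reports flag the
discrepancy instead of silently recomputing it away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class CostComponent:
    label: str
    per_sample_cost: float  # CAD
    per_batch_cost: float | None = None  # CAD per batch_size samples
    batch_size: int = 96

    def __post_init__(self) -> None:
        if self.per_sample_cost < 0:
            raise ValueError(f"{self.label}: negative per-sample cost")
        if self.per_batch_cost is not None and self.per_batch_cost < 0:
            raise ValueError(f"{self.label}: negative per-batch cost")


@dataclass
class MethodCostTable:
    method_name: str
    components: list[CostComponent]
    printed_per_sample_total: float | None = None
    printed_per_batch_total: float | None = None

    def __post_init__(self) -> None:
        labels = [c.label for c in self.components]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.method_name}: duplicate component labels")

    @property
    def per_sample_total(self) -> float:
        """Reported per-sample total: printed figure when available."""
        if self.printed_per_sample_total is not None:
            return self.printed_per_sample_total
        return total_cost(self, 1)[0]

    def total_discrepancies(self, tol: float = 0.005) -> dict[str, tuple[float, float]]:
        """Printed vs recomputed totals that disagree beyond half a cent."""
        out = {}
        per_sample, per_batch = total_cost(self, self.components[0].batch_size if self.components else 96)
        if (
            self.printed_per_sample_total is not None
            and abs(per_sample - self.printed_per_sample_total) > tol
        ):
            out["per_sample"] = (self.printed_per_sample_total, round(per_sample, 4))
        if (
            self.printed_per_batch_total is not None
            and abs(per_batch - self.printed_per_batch_total) > tol
        ):
            out["per_batch"] = (self.printed_per_batch_total, round(per_batch, 2))
        return out


@dataclass
class TimeEstimate:
    method_name: str
    steps: list[tuple[str, float, float]]  # (label, min_hours, max_hours)

    def __post_init__(self) -> None:
        for label, lo, hi in self.steps:
            if not 0 <= lo <= hi:
                raise ValueError(f"{label}: need 0 <= min <= max hours")


def total_cost(table: MethodCostTable, n_samples: int = 1) -> tuple[float, float]:
    """(per-sample total, batch total) summed over components.

    Components quoted per batch contribute that figure to the batch
    total; others scale per-sample cost by ``n_samples``. Exact sums are
    returned; round to cents only for display.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    per_sample = sum(c.per_sample_cost for c in table.components)
    batch = sum(
        c.per_batch_cost if c.per_batch_cost is not None else c.per_sample_cost * n_samples
        for c in table.components
    )
    return per_sample, batch


def total_time(est: TimeEstimate) -> tuple[float, float]:
    """Component-wise (min, max) hours."""
    lo = sum(s[1] for s in est.steps)
    hi = sum(s[2] for s in est.steps)
    return lo, hi


@dataclass
class MethodComparison:
    ranking: list[tuple[str, float]]  # (method, per-sample total) ascending
    pairwise_differences: dict[tuple[str, str], float]
    flagged_discrepancies: dict[str, dict[str, tuple[float, float]]]

    @property
    def cheapest(self) -> str:
        return self.ranking[0][0]


def compare_methods(
    tables: Sequence[MethodCostTable], n_samples: int = 1
) -> MethodComparison:
    """Rank methods by per-sample total (printed totals when available).

    Ties keep input order. Pairwise differences are reported for every
    ordered pair (cheaper, dearer); printed-vs-recomputed total
    disagreements are flagged per method.
    """
    if len(tables) < 2:
        raise ValueError("need at least two methods to compare")
    totals = [(t.method_name, t.per_sample_total) for t in tables]
    ranking = sorted(totals, key=lambda mt: mt[1])
    diffs = {}
    for i, (m_a, c_a) in enumerate(ranking):
        for m_b, c_b in ranking[i + 1 :]:
            diffs[(m_a, m_b)] = round(c_b - c_a, 2)
    flagged = {
        t.method_name: d for t in tables if (d := t.total_discrepancies())
    }
    return MethodComparison(
        ranking=ranking, pairwise_differences=diffs, flagged_discrepancies=flagged
    )


def format_cents(value: float) -> str:
    """Half-up cent rounding for display."""
    from decimal import Decimal, ROUND_HALF_UP

    return str(Decimal(str(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
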