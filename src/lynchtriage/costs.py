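"""Laboratory cost accounting for diagnostic strategies.

All prices are whole euros (2012 charge levels) and all arithmetic is
exact integer arithmetic, so totals are reproducible bit for bit.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

from .types import ANALYSES, ValidationError

PathLike = Union[str, Path]

#: Default unit prices in euros, charged 2012 levels.
DEFAULT_PRICES: dict[str, int] = {
    "mmr_functional": 356,
    "braf_v600e": 640,
    "sequencing_1_gene": 556,
    "sequencing_2_genes": 1022,
    "sequencing_3_genes": 1422,
    "sequencing_4_genes": 1689,
    "gene_panel": 1648,
}

#: Stable line-item order for reports.
LINE_ITEM_ORDER: tuple[str, ...] = ANALYSES


@dataclass(frozen=True)
class CostTable:
    prices: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PRICES))

    def __post_init__(self) -> None:
        for name, price in self.prices.items():
            if price < 0:
                raise ValidationError(f"negative price for {name!r}")

    def price(self, analysis: str) -> int:
        try:
            return self.prices[analysis]
        except KeyError:
            raise ValidationError(f"no price for analysis {analysis!r}") from None

    @classmethod
    def from_file(cls, path: PathLike) -> "CostTable":
        """Load a price table from YAML or JSON, overriding defaults."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValidationError("cost table file must map analysis -> price")
        prices = dict(DEFAULT_PRICES)
        for k, v in data.items():
            prices[str(k)] = int(v)
        return cls(prices=prices)


@dataclass(frozen=True)
class StrategyCostReport:
    name: str
    line_items: tuple[tuple[str, int, int, int], ...]  # (analysis, count, unit, subtotal)
    total: int

    def counts(self) -> dict[str, int]:
        return {a: c for a, c, _, _ in self.line_items}

    def to_dict(self) -> dict:
        return {
            "strategy": self.name,
            "line_items": [
                {"analysis": a, "count": c, "unit_price_eur": u, "subtotal_eur": s}
                for a, c, u, s in self.line_items
            ],
            "total_eur": self.total,
        }


def price_path(path: Iterable[str], table: CostTable | None = None) -> int:
    """Cost of one patient's ordered analysis path; empty path costs 0."""
    table = table or CostTable()
    return sum(table.price(a) for a in path)


def aggregate(
    counts: Mapping[str, int],
    table: CostTable | None = None,
    name: str = "strategy",
) -> StrategyCostReport:
    """Aggregate per-analysis counts into a priced strategy report with
    line items in a stable declared order."""
    table = table or CostTable()
    for a, c in counts.items():
        if c < 0:
            raise ValidationError(f"negative count for {a!r}")
    known = [a for a in LINE_ITEM_ORDER if a in counts]
    extra = sorted(set(counts) - set(LINE_ITEM_ORDER))
    items = []
    for a in known + extra:
        c = int(counts[a])
        if c == 0:
            continue
        unit = table.price(a)
        items.append((a, c, unit, c * unit))
    return StrategyCostReport(
        name=name,
        line_items=tuple(items),
        total=sum(s for _, _, _, s in items),
    )


def aggregate_paths(
    paths: Iterable[Iterable[str]],
    table: CostTable | None = None,
    name: str = "strategy",
) -> StrategyCostReport:
    """Pool per-patient analysis paths and aggregate (consistent with
    pricing each path then summing)."""
    counts: Counter[str] = Counter()
    for p in paths:
        counts.update(p)
    return aggregate(counts, table, name=name)


def compare_strategies(a: StrategyCostReport, b: StrategyCostReport) -> dict:
    """Excess cost of strategy b over strategy a, as an exact fraction
    and a rounded integer percent."""
    if a.total == 0:
        raise ValidationError("reference strategy has zero total cost")
    excess = b.total / a.total - 1.0
    return {
        "reference": a.name,
        "comparison": b.name,
        "reference_total_eur": a.total,
        "comparison_total_eur": b.total,
        "excess_fraction": excess,
        "excess_percent": round_percent(excess * 100.0),
    }


def round_percent(x: float) -> int:
    """Round half away from zero, matching printed whole-percent figures."""
    import math

    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def write_report(report: StrategyCostReport, tsv_path: PathLike, json_path: PathLike) -> None:
    lines = ["analysis\tcount\tunit_price_eur\tsubtotal_eur"]
    for a, c, u, s in report.line_items:
        lines.append(f"{a}\t{c}\t{u}\t{s}")
    lines.append(f"total\t\t\t{report.total}")
    Path(tsv_path).write_text("\n".join(lines) + "\n")
    Path(json_path).write_text(json.dumps(report.to_dict(), indent=1))
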