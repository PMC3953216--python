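"""Scenario-comparison reporting: percent change of every output-map total
relative to a baseline run."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .errors import DomainError
from .span import SpanOutputs

__all__ = ["ComparisonTable", "compare_scenarios", "percent_change"]


def percent_change(base_total: float, alt_total: float) -> float | None:
    """100 * (alt - base) / base, rounded half away from zero to one
    decimal place (locale-independent).  ``None`` when the baseline total
    is zero (reported as "n/a", never as infinity)."""
    if base_total == 0:
        return None
    raw = 100.0 * (alt_total - base_total) / base_total
    q = Decimal(repr(abs(raw))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q) if raw >= 0 else -float(q)


@dataclass
class ComparisonTable:
    """Rows = output-map names; one percent-change column per scenario."""

    rows: list[str]
    scenarios: list[str]
    changes: dict[str, dict[str, float | None]]  # row -> scenario -> change

    def to_text(self) -> str:
        width = max(len(r) for r in self.rows) + 2
        head = "".join(f"{s:>18}" for s in self.scenarios)
        lines = [f"{'output':<{width}}{head}"]
        for r in self.rows:
            cells = "".join(
                f"{self._fmt(self.changes[r][s]):>18}" for s in self.scenarios
            )
            lines.append(f"{r:<{width}}{cells}")
        return "\n".join(lines)

    @staticmethod
    def _fmt(v: float | None) -> str:
        return "n/a" if v is None else f"{v:+.1f}%"

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("output," + ",".join(self.scenarios) + "\n")
            for r in self.rows:
                cells = ",".join(
                    "n/a" if self.changes[r][s] is None else f"{self.changes[r][s]:.1f}"
                    for s in self.scenarios
                )
                fh.write(f"{r},{cells}\n")


def compare_scenarios(base: SpanOutputs,
                      alts: list[tuple[str, SpanOutputs]]) -> ComparisonTable:
    """Percent change of each output-map total for each scenario vs the
    baseline.  Totals, not cellwise means, are compared; all runs must
    share one grid geometry."""
    base_shape = base.theoretical_source.spec.shape
    for name, alt in alts:
        if alt.theoretical_source.spec.shape != base_shape:
            raise DomainError(f"scenario {name!r} is on a different grid")
    base_totals = base.totals()
    rows = list(SpanOutputs.MAP_NAMES)
    scenarios = [name for name, _ in alts]
    changes: dict[str, dict[str, float | None]] = {r: {} for r in rows}
    for name, alt in alts:
        alt_totals = alt.totals()
        for r in rows:
            changes[r][name] = percent_change(base_totals[r], alt_totals[r])
    return ComparisonTable(rows, scenarios, changes)
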