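"""Result containers shared by the continuous and binary calculators."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CriterionResult", "SampleSizeResult", "PrecisionProfile"]


@dataclass(frozen=True)
class CriterionResult:
    """Required sample size for one precision criterion."""

    criterion: str
    n: int
    se: float  # anticipated SE of the estimate at n (criterion's own scale)
    ci_width: float  # anticipated 95% CI width at n, on the reporting scale
    target_width: float
    performance: float  # the assumed true value of the measure
    events: int | None = None

    def as_row(self) -> dict:
        row = {
            "criterion": self.criterion,
            "n": self.n,
            "performance": self.performance,
            "SE": self.se,
            "CI width": self.ci_width,
            "target width": self.target_width,
        }
        if self.events is not None:
            row["events"] = self.events
        return row


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-criterion sample sizes and the binding (maximum) criterion.

    The minimum sample size for the validation study is the largest of the
    per-criterion requirements, so that every performance measure is
    estimated to its target precision.
    """

    per_criterion: tuple[CriterionResult, ...]
    design: object = field(repr=False, default=None)

    @property
    def n_required(self) -> int:
        return max(c.n for c in self.per_criterion)

    @property
    def binding_criterion(self) -> str:
        return max(self.per_criterion, key=lambda c: c.n).criterion

    @property
    def events_required(self) -> int | None:
        binding = max(self.per_criterion, key=lambda c: c.n)
        return binding.events

    def __getitem__(self, criterion: str) -> CriterionResult:
        for c in self.per_criterion:
            if c.criterion == criterion:
                return c
        raise KeyError(criterion)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.per_criterion]).set_index("criterion")

    def to_dict(self) -> dict:
        return {
            "criteria": [c.as_row() for c in self.per_criterion],
            "n_required": self.n_required,
            "events_required": self.events_required,
            "binding_criterion": self.binding_criterion,
        }

    def summary(self) -> str:
        lines = ["Sample size for external validation", "=" * 60]
        if self.design is not None and hasattr(self.design, "describe"):
            lines += [self.design.describe(), "-" * 60]
        tbl = self.table().copy()
        for col in ("performance", "SE", "CI width", "target width"):
            tbl[col] = tbl[col].map(lambda v: f"{v:.4g}")
        lines.append(tbl.to_string())
        lines.append("-" * 60)
        ev = self.events_required
        ev_txt = f" ({ev} events)" if ev is not None else ""
        lines.append(
            f"Minimum required sample size: {self.n_required}{ev_txt} "
            f"(binding criterion: {self.binding_criterion})"
        )
        return "\n".join(lines)


@dataclass(frozen=True)
class PrecisionProfile:
    """Anticipated precision of every performance estimate at a fixed n.

    The inverse of the sample size calculation: when an existing dataset of
    known size is to be used, report the expected 95% confidence interval for
    each measure conditional on that size (and any known dataset
    characteristics supplied as overrides).
    """

    n: int
    per_measure: tuple[dict, ...]  # measure, se, ci_lower, ci_upper, ci_width, performance
    assumptions: dict = field(default_factory=dict)

    def __getitem__(self, measure: str) -> dict:
        for m in self.per_measure:
            if m["measure"] == measure:
                return m
        raise KeyError(measure)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.per_measure)).set_index("measure")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "measures": [dict(m) for m in self.per_measure],
            "assumptions": dict(self.assumptions),
        }

    def summary(self) -> str:
        lines = [f"Anticipated precision at n = {self.n}", "=" * 60]
        tbl = self.table().copy()
        for col in tbl.columns:
            tbl[col] = tbl[col].map(lambda v: f"{v:.4g}" if isinstance(v, float) else v)
        lines.append(tbl.to_string())
        return "\n".join(lines)
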