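"""Worked-example arithmetic: repository adoption rates and selection funnels.

Two small, exactly-reproducible computations accompany the engine:

* :func:`adoption_percentage` — the share of repository datasets carrying
  SDRF annotation, rounded half-up to one decimal on the 0–100 scale (the
  convention that reproduces published adoption figures such as 156/9671 →
  1.6 and 376/9671 → 3.9);
* :func:`project_funnel` — a stepwise exclusion trace for dataset selection
  (e.g. 355 annotated projects → remove 93 lacking open-access articles →
  remove 21 cross-linking experiments → 241 retained).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .errors import DomainError, FunnelError


@dataclass(frozen=True)
class AdoptionStats:
    """An annotated-over-total count pair with its percentage, rounded
    half-up to one decimal on the 0–100 scale."""

    n_annotated: int
    n_total: int
    percent: float


def adoption_percentage(n_annotated: int, n_total: int) -> AdoptionStats:
    """Percentage of annotated datasets, one decimal, half-up rounding."""
    if n_total <= 0:
        raise DomainError(f"n_total must be positive, got {n_total}")
    if n_annotated < 0:
        raise DomainError(f"n_annotated must be non-negative, got {n_annotated}")
    if n_annotated > n_total:
        raise DomainError(
            f"n_annotated ({n_annotated}) cannot exceed n_total ({n_total})"
        )
    percent = (
        Decimal(100) * Decimal(n_annotated) / Decimal(n_total)
    ).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return AdoptionStats(
        n_annotated=n_annotated, n_total=n_total, percent=float(percent)
    )


@dataclass(frozen=True)
class FunnelStep:
    label: str
    removed: int
    remaining: int


@dataclass(frozen=True)
class FunnelResult:
    start: int
    steps: tuple[FunnelStep, ...]

    @property
    def remaining(self) -> int:
        return self.steps[-1].remaining if self.steps else self.start

    def trace(self) -> str:
        lines = [f"start: {self.start}"]
        for s in self.steps:
            lines.append(f"- {s.label}: -{s.removed} -> {s.remaining}")
        return "\n".join(lines)


def project_funnel(
    n_start: int, exclusions: Sequence[tuple[str, int]]
) -> FunnelResult:
    """Apply labeled exclusion counts in order; the running total may never
    go negative."""
    if n_start < 0:
        raise FunnelError(f"starting count must be non-negative, got {n_start}")
    running = n_start
    steps: list[FunnelStep] = []
    for label, count in exclusions:
        if count < 0:
            raise FunnelError(f"exclusion {label!r} has negative count {count}")
        running -= count
        if running < 0:
            raise FunnelError(
                f"exclusion {label!r} (-{count}) drives the running total "
                f"negative ({running})"
            )
        steps.append(FunnelStep(label=label, removed=count, remaining=running))
    return FunnelResult(start=n_start, steps=tuple(steps))
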