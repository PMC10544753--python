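"""Net performance of serial (AND) and parallel (OR) test combinations.

For independent tests, requiring *all* tests positive multiplies the
sensitivities and leaves a false positive only when every test falsely
fires, so ``SE = ∏ SEᵢ`` and ``SP = 1 − ∏ (1 − SPᵢ)``.  Calling *any*
positive test a positive mirrors the roles: ``SE = 1 − ∏ (1 − SEᵢ)`` and
``SP = ∏ SPᵢ``.  The pairwise identities extend associatively to any
number of tests.  Serial combination can only lower sensitivity and
raise specificity relative to each component; parallel combination does
the opposite.  Independence between tests is assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ScreeningPerformance",
    "net_serial",
    "net_parallel",
    "PUBLISHED_PERFORMANCE",
    "performance_table",
]


@dataclass(frozen=True)
class ScreeningPerformance:
    """A (sensitivity, specificity) pair for one screening method."""

    sensitivity: float
    specificity: float
    label: str = ""

    def __post_init__(self) -> None:
        for name, v in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


#: Published validation performance of the three scores.  The fat score
#: carries two validation cohorts (Finnish derivation, Italian external).
PUBLISHED_PERFORMANCE: dict[str, ScreeningPerformance] = {
    "hair": ScreeningPerformance(0.80, 0.89, "HAIR"),
    "gholam": ScreeningPerformance(0.76, 0.66, "Gholam"),
    "lfs_finnish": ScreeningPerformance(0.595, 0.797, "NASH liver fat score (Finnish)"),
    "lfs_italian": ScreeningPerformance(0.929, 0.327, "NASH liver fat score (Italian)"),
}


def _check(perfs: Sequence[ScreeningPerformance]) -> None:
    if len(perfs) < 2:
        raise ValueError("combination needs at least two tests")


def net_serial(perfs: Sequence[ScreeningPerformance]) -> ScreeningPerformance:
    """Net performance when *all* tests must be positive (serial / AND)."""
    _check(perfs)
    se = math.prod(p.sensitivity for p in perfs)
    sp = 1.0 - math.prod(1.0 - p.specificity for p in perfs)
    label = " AND ".join(p.label or "?" for p in perfs)
    return ScreeningPerformance(se, sp, label)


def net_parallel(perfs: Sequence[ScreeningPerformance]) -> ScreeningPerformance:
    """Net performance when *at least one* test is positive (parallel / OR)."""
    _check(perfs)
    se = 1.0 - math.prod(1.0 - p.sensitivity for p in perfs)
    sp = math.prod(p.specificity for p in perfs)
    label = " OR ".join(p.label or "?" for p in perfs)
    return ScreeningPerformance(se, sp, label)


def performance_table(perfs: Iterable[ScreeningPerformance]) -> str:
    """TSV table of performances (label, sensitivity, specificity)."""
    lines = ["label\tsensitivity\tspecificity"]
    for p in perfs:
        lines.append(f"{p.label}\t{p.sensitivity:.6f}\t{p.specificity:.6f}")
    return "\n".join(lines) + "\n"
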