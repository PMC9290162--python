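"""Coverage quality control (workflow step 3).

Every position of the assigned reference must be covered deeply enough that a
mutation anywhere in the amplicon could not have been missed; otherwise the
analysis is aborted. A failed QC is a controlled abort: the sample is stored
with status ``qc_failed`` and no negative call is ever reported, because a
"mutation absent" claim at an under-covered site would be clinically unsafe.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Pileup


@dataclass
class QCResult:
    passed: bool
    min_observed_coverage: int
    threshold_used: int
    failing_positions: list[int] = field(default_factory=list)  # 1-based

    def __post_init__(self) -> None:
        assert self.passed == (not self.failing_positions)

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "min_observed_coverage": self.min_observed_coverage,
            "threshold_used": self.threshold_used,
            "n_failing_positions": len(self.failing_positions),
            "failing_positions": self.failing_positions,
        }


def check_coverage(
    pileup: Pileup,
    min_coverage: int,
    region: tuple[int, int] | None = None,
) -> QCResult:
    """Fail QC at every position (within ``region``, default whole reference,
    1-based inclusive) covered by fewer than ``min_coverage`` reads.

    Raising the threshold can only shrink the passing set (monotone), and an
    empty pileup always fails for any positive threshold.
    """
    start, end = region if region is not None else (1, pileup.ref_length)
    cov = pileup.coverage[start - 1: end]
    failing = np.flatnonzero(cov < min_coverage) + start
    return QCResult(
        passed=len(failing) == 0,
        min_observed_coverage=int(cov.min()) if len(cov) else 0,
        threshold_used=min_coverage,
        failing_positions=failing.tolist(),
    )


def coverage_profile(pileup: Pileup) -> tuple[np.ndarray, dict]:
    """Per-position coverage vector plus a min/median/max summary."""
    cov = pileup.coverage
    summary = {
        "min": int(cov.min()) if len(cov) else 0,
        "median": float(np.median(cov)) if len(cov) else 0.0,
        "max": int(cov.max()) if len(cov) else 0,
    }
    return cov, summary
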