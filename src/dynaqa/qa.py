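"""Delivery-QA statistics.

Covers the statistics a physicist reads off a log-based QA report:

* per-leaf RMS of planned-minus-recorded position over beam-on samples
  (the log-viewer-style leaf-error analysis);
* the Pearson correlation used to validate that reconstructed-dose
  changes track measured-dose changes across induced error classes;
* the confidence limit ``|mean| + 1.96 x SD`` of paired DVH-metric
  differences, the basis for setting an action level;
* the per-plan DVH-metric comparison with a pass/flag verdict at the
  action level (default 1.0%: strict inequality, so a difference exactly
  at the level passes).

Two bundled benchmark tables (ten induced-error dose ratios; a 20-case
DVH audit with max-RMS leaf errors) ship as package data for fixture and
regression use.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .dose import DVHMetrics
from .dynalog import DeliveryRecord

__all__ = [
    "LeafErrorSummary",
    "PlanComparison",
    "ValidationRecord",
    "rms_leaf_errors",
    "pearson_correlation",
    "confidence_limit",
    "compare_plans",
    "load_table1",
    "load_table2",
    "table2_differences",
]

#: multiplier on the SD in the confidence limit (95% two-sided normal)
CL_FACTOR = 1.96


@dataclass(frozen=True)
class ValidationRecord:
    """One induced-error validation point: reconstructed vs measured ratio."""

    error_label: str
    dcalc_ratio: float
    dmeas_ratio: float

    def validate(self) -> None:
        if self.dcalc_ratio <= 0 or self.dmeas_ratio <= 0:
            raise ValueError("dose ratios must be positive")


@dataclass
class LeafErrorSummary:
    """Per-leaf RMS positional errors (mm); rows are banks (A, B)."""

    per_leaf_rms: np.ndarray  # (2, n_pairs)
    banks: tuple[str, str] = ("A", "B")

    @property
    def max_rms(self) -> float:
        return float(self.per_leaf_rms.max())


@dataclass
class PlanComparison:
    """Original vs reconstructed DVH metrics with an action-level verdict."""

    case_id: str
    original: DVHMetrics
    reconstructed: DVHMetrics
    action_level_pct: float

    @property
    def diffs(self) -> tuple[float, float, float]:
        """(dD98, dD2, dDmean) = reconstructed - original, % of prescription."""
        return tuple(
            r - o
            for r, o in zip(self.reconstructed.as_tuple(), self.original.as_tuple())
        )

    @property
    def verdict(self) -> str:
        return "flag" if any(abs(d) > self.action_level_pct for d in self.diffs) else "pass"


def rms_leaf_errors(record: DeliveryRecord) -> LeafErrorSummary:
    """Per-leaf RMS of (planned - recorded) over beam-on snapshots.

    Beam-hold samples are excluded: during a hold the controller is
    waiting for the leaves, so the discrepancy there is a controller
    state, not a delivery error.
    """
    record.validate()
    on = record.beam_on()
    if not on.any():
        raise ValueError("no beam-on snapshots in record")
    planned = record.positions("planned")[on]
    recorded = record.positions("recorded")[on]
    rms = np.sqrt(np.mean((planned - recorded) ** 2, axis=0))
    return LeafErrorSummary(per_leaf_rms=rms)


def pearson_correlation(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate sample: zero variance")
    xm = x - x.mean()
    ym = y - y.mean()
    return float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))


def confidence_limit(diffs) -> float:
    """``|mean(diffs)| + 1.96 x sample SD`` (n-1 denominator), same units."""
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least 2 differences")
    return float(abs(d.mean()) + CL_FACTOR * d.std(ddof=1))


def compare_plans(
    original: DVHMetrics,
    reconstructed: DVHMetrics,
    action_level_pct: float = 1.0,
    case_id: str = "",
) -> PlanComparison:
    """Pair two metric sets; flag when any |difference| exceeds the level."""
    return PlanComparison(
        case_id=case_id,
        original=original,
        reconstructed=reconstructed,
        action_level_pct=action_level_pct,
    )


# ---------------------------------------------------------------------------
# bundled benchmark tables
# ---------------------------------------------------------------------------


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("dynaqa.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_table1() -> pd.DataFrame:
    """Ten induced-error dose ratios (reconstructed-calculated vs measured)."""
    return _load_csv("table1_ratios.csv")


def load_table2() -> pd.DataFrame:
    """20-case DVH audit: original/reconstructed D98, D2, Dmean + max RMS (cm)."""
    return _load_csv("table2_dvh.csv")


def table2_differences(table: pd.DataFrame | None = None) -> np.ndarray:
    """The pooled reconstructed-minus-original metric differences (60 values)."""
    t = load_table2() if table is None else table
    return np.concatenate(
        [
            (t[f"{m}_recon"] - t[f"{m}_orig"]).to_numpy()
            for m in ("d98", "d2", "dmean")
        ]
    )
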