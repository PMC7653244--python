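"""Annexin V/PI quadrant statistics for apoptosis assays.

Events (cells) carry an annexin V-FITC signal (phosphatidylserine
externalization, the early-apoptosis marker) and a propidium iodide (PI)
signal (membrane permeabilization).  Quadrant gating with the standard kit
convention assigns each event to exactly one class:

* live        — annexin-negative / PI-negative
* early       — annexin-positive / PI-negative
* late        — annexin-positive / PI-positive
* necrotic    — annexin-negative / PI-positive

Values at a threshold count as positive.  The *apoptosis ratio* is
early + late.  Given a treated and a control summary, the early-apoptosis
contribution is the share of the treatment-induced increase in total
apoptosis that is carried by early apoptosis:

    100 * (early_t - early_c) / (apoptotic_t - apoptotic_c)

which may exceed 100% when late apoptosis decreased under treatment.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from memfluid._stats import welch_table

__all__ = [
    "EventTable",
    "ApoptosisSummary",
    "EarlyContribution",
    "gate",
    "early_contribution",
    "compare_apoptosis",
    "UndefinedContributionError",
]


class UndefinedContributionError(ZeroDivisionError):
    """Total apoptosis did not change; the contribution ratio is undefined."""


@dataclass
class EventTable:
    """Per-event annexin / PI measurements (arbitrary units)."""

    annexin: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.annexin = np.asarray(self.annexin, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.annexin.shape != self.pi.shape or self.annexin.ndim != 1:
            raise ValueError("annexin and pi must be equal-length 1-D arrays")
        if not (np.all(np.isfinite(self.annexin)) and np.all(np.isfinite(self.pi))):
            raise ValueError("event values must be finite")

    def __len__(self) -> int:
        return len(self.annexin)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "EventTable":
        return cls(annexin=df["annexin"].to_numpy(), pi=df["pi"].to_numpy())

    @classmethod
    def from_csv(cls, path: "str | Path") -> "EventTable":
        return cls.from_dataframe(pd.read_csv(path))


@dataclass
class ApoptosisSummary:
    """Quadrant percentages of one sample; percentages are of ``n_total``."""

    n_total: int
    pct_live: float
    pct_early: float
    pct_late: float
    pct_necrotic: float
    thresholds: tuple[float, float] | None = None

    @property
    def pct_apoptotic(self) -> float:
        """Apoptosis ratio: early + late apoptosis."""
        return self.pct_early + self.pct_late

    @classmethod
    def from_percentages(
        cls,
        pct_early: float,
        pct_late: float | None = None,
        pct_apoptotic: float | None = None,
        pct_necrotic: float = 0.0,
        n_total: int = 0,
    ) -> "ApoptosisSummary":
        """Build a summary from published percentages.

        Give either ``pct_late`` or the total ``pct_apoptotic`` (late is then
        total - early); live fills the remainder to 100%.
        """
        if pct_late is None:
            if pct_apoptotic is None:
                raise ValueError("give pct_late or pct_apoptotic")
            pct_late = pct_apoptotic - pct_early
        return cls(
            n_total=n_total,
            pct_live=100.0 - pct_early - pct_late - pct_necrotic,
            pct_early=pct_early,
            pct_late=pct_late,
            pct_necrotic=pct_necrotic,
        )


def gate(
    events: EventTable, annexin_threshold: float, pi_threshold: float
) -> ApoptosisSummary:
    """Quadrant-gate an event table (boundary values count as positive)."""
    n = len(events)
    if n == 0:
        raise ValueError("empty event table")
    if not (np.isfinite(annexin_threshold) and np.isfinite(pi_threshold)):
        raise ValueError("thresholds must be finite")
    a_pos = events.annexin >= annexin_threshold
    p_pos = events.pi >= pi_threshold
    counts = {
        "live": int(np.sum(~a_pos & ~p_pos)),
        "early": int(np.sum(a_pos & ~p_pos)),
        "late": int(np.sum(a_pos & p_pos)),
        "necrotic": int(np.sum(~a_pos & p_pos)),
    }
    assert sum(counts.values()) == n
    to_pct = 100.0 / n
    return ApoptosisSummary(
        n_total=n,
        pct_live=counts["live"] * to_pct,
        pct_early=counts["early"] * to_pct,
        pct_late=counts["late"] * to_pct,
        pct_necrotic=counts["necrotic"] * to_pct,
        thresholds=(float(annexin_threshold), float(pi_threshold)),
    )


@dataclass
class EarlyContribution:
    """Early-apoptosis share of a treatment-induced apoptosis increase."""

    percent: float
    exceeds_total: bool  # late apoptosis decreased; share exceeds 100%


def early_contribution(
    treated: ApoptosisSummary, control: ApoptosisSummary
) -> EarlyContribution:
    """Early-apoptosis contribution to the increase in total apoptosis (%).

    Raises :class:`UndefinedContributionError` when treated and control have
    the same total apoptosis.  Values above 100% are reported as-is with
    ``exceeds_total`` set.
    """
    d_total = treated.pct_apoptotic - control.pct_apoptotic
    if d_total == 0:
        raise UndefinedContributionError(
            "treated and control total apoptosis are equal"
        )
    d_early = treated.pct_early - control.pct_early
    pct = 100.0 * d_early / d_total
    return EarlyContribution(percent=float(pct), exceeds_total=pct > 100.0)


def compare_apoptosis(
    groups: Mapping[str, Sequence[float]],
    control: str,
) -> pd.DataFrame:
    """Replicate-level comparison table (mean, SD, n, Welch p vs control).

    ``groups`` maps a group name to replicate apoptosis percentages (or any
    scalar per-replicate statistic).
    """
    return welch_table(groups, control)
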