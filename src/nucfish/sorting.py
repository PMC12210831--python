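"""Flow-sorting gates: event gating, per-gate summaries, qPCR correlation.

Gates are half-open intervals [lower, upper) on log10 fluorescence, ordered
low to high (G1 < G2 < G3).  Gate bounds are user configuration — they can be
derived from a negative-control population (e.g. the first gate starting above
the control's 99th percentile) or placed at latent-class boundaries of the
simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

UNGATED = "ungated"
INVALID = "invalid"


@dataclass(frozen=True)
class GateScheme:
    """Ordered, pairwise-disjoint half-open gates on log10 fluorescence."""

    gates: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.gates:
            raise ValueError("at least one gate required")
        names = [g[0] for g in self.gates]
        if len(set(names)) != len(names):
            raise ValueError("gate names must be unique")
        prev_hi = -math.inf
        for name, lo, hi in self.gates:
            if not (lo < hi):
                raise ValueError(f"gate {name}: need lower < upper")
            if lo < prev_hi:
                raise ValueError("gates must be disjoint and increasing")
            prev_hi = hi
        object.__setattr__(
            self, "gates", tuple((str(n), float(lo), float(hi)) for n, lo, hi in self.gates)
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g[0] for g in self.gates)

    def assign_one(self, log10_fluorescence: float) -> str:
        for name, lo, hi in self.gates:
            if lo <= log10_fluorescence < hi:
                return name
        return UNGATED

    @classmethod
    def from_class_means(
        cls, means: Sequence[float], names: Sequence[str] | None = None, span: float = 3.0
    ) -> "GateScheme":
        """Place gate boundaries midway between consecutive latent-class means.

        The outermost bounds extend ``span`` log10 units beyond the extreme
        means.
        """
        means = sorted(means)
        if names is None:
            names = [f"G{i + 1}" for i in range(len(means))]
        bounds = (
            [means[0] - span]
            + [(a + b) / 2 for a, b in zip(means, means[1:])]
            + [means[-1] + span]
        )
        return cls(tuple((n, lo, hi) for n, lo, hi in zip(names, bounds, bounds[1:])))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    groups: tuple[str, ...]
    defined: bool = True  # False when either variable has zero variance

    def __post_init__(self) -> None:
        if self.defined and not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError("Pearson r out of [-1, 1]")
        if self.n < 3:
            raise ValueError("a reported correlation needs n >= 3")


def assign_gates(events: pd.DataFrame, scheme: GateScheme) -> pd.DataFrame:
    """Annotate each event with its gate (or "ungated" / "invalid").

    Events with nonpositive or non-finite fluorescence cannot be placed on the
    log scale; they are flagged "invalid" and excluded from summaries.  Every
    event receives exactly one label, so counts are conserved.
    """
    if "fluorescence" not in events.columns:
        raise ValueError("events table must have a 'fluorescence' column")
    out = events.copy()
    fluor = out["fluorescence"].to_numpy(dtype=float)
    labels = np.full(len(out), UNGATED, dtype=object)
    bad = ~np.isfinite(fluor) | (fluor <= 0)
    logf = np.where(bad, 0.0, np.log10(np.where(bad, 1.0, fluor)))
    for name, lo, hi in scheme.gates:
        labels[(~bad) & (logf >= lo) & (logf < hi)] = name
    labels[bad] = INVALID
    out["gate"] = labels
    return out


def gate_summary(events: pd.DataFrame, scheme: GateScheme) -> pd.DataFrame:
    """Per-gate n, mean fluorescence, SD and SEM (linear scale).

    Empty gates are reported with n = 0 and NaN moments so downstream joins
    see every configured gate.
    """
    if "gate" not in events.columns:
        raise ValueError("events must be gated first (assign_gates)")
    rows = []
    for name in scheme.names:
        vals = events.loc[events["gate"] == name, "fluorescence"].to_numpy(dtype=float)
        n = int(vals.size)
        mean = float(vals.mean()) if n else float("nan")
        sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
        sem = sd / math.sqrt(n) if n > 1 else float("nan")
        rows.append((name, n, mean, sd, sem))
    return pd.DataFrame(rows, columns=["gate", "n", "mean_fluorescence", "sd", "sem"])


def correlate_intensity_qpcr(
    gate_summaries: pd.DataFrame, qpcr: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation between per-gate mean fluorescence and qPCR abundance.

    Tables are joined on gate/group label; at least three matched groups are
    required.  Zero variance in either variable makes r undefined; the result
    is returned with ``defined=False`` and r = NaN rather than raising.
    """
    merged = gate_summaries.merge(
        qpcr, left_on="gate", right_on="group", how="inner"
    ).dropna(subset=["mean_fluorescence", "abundance"])
    if len(merged) < 3:
        raise ValueError(
            f"insufficient groups for correlation: {len(merged)} matched, need >= 3"
        )
    x = merged["mean_fluorescence"].to_numpy(dtype=float)
    y = merged["abundance"].to_numpy(dtype=float)
    groups = tuple(merged["gate"])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            r=float("nan"), n=len(merged), groups=groups, defined=False
        )
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n=len(merged), groups=groups)
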