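"""Chromatin-accessibility statistics from qPCR fold-enrichment (FE) tables.

A nuclease-accessibility qPCR assay reports fold enrichment per amplicon.
Target-gene FE values are normalized to an internal reference U_mean — the
per-replicate mean FE over three control-gene amplicons (5'UTR, intron,
3'UTR) — giving a relative accessibility

    RQ = 2 ** -(FE_target - U_mean),

which is log-transformed as log10(RQ + 1e-10) before statistics and
plotting.  Lower target FE than the reference means a more accessible locus
(RQ > 1).  Gate groups are compared by a paired t-test on per-replicate mean
log-RQ, pairing by replicate index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

LOG_OFFSET = 1e-10
REQUIRED_AMPLICONS = ("5'UTR", "intron", "3'UTR")


def u_mean(control_fe: Mapping[str, float] | Sequence[float]) -> float:
    """Internal reference: mean FE over the three control-gene amplicons.

    Accepts either a mapping amplicon -> FE (all of 5'UTR, intron, 3'UTR
    required; a missing amplicon is an error naming it) or a plain sequence of
    exactly three values.
    """
    if isinstance(control_fe, Mapping):
        missing = [a for a in REQUIRED_AMPLICONS if a not in control_fe]
        if missing:
            raise ValueError(f"missing control amplicon(s): {', '.join(missing)}")
        values = [float(control_fe[a]) for a in REQUIRED_AMPLICONS]
    else:
        values = [float(v) for v in control_fe]
        if len(values) != 3:
            raise ValueError(
                f"expected exactly 3 control FE values, got {len(values)}"
            )
    if not all(math.isfinite(v) for v in values):
        raise ValueError("control FE values must be finite")
    return sum(values) / 3.0


def rq(fe_target, u_mean_value):
    """Relative accessibility: 2 ** -(FE_target - U_mean).  Vectorizes."""
    fe = np.asarray(fe_target, dtype=float)
    u = np.asarray(u_mean_value, dtype=float)
    if not (np.all(np.isfinite(fe)) and np.all(np.isfinite(u))):
        raise ValueError("FE_target and U_mean must be finite")
    out = 2.0 ** -(fe - u)
    return float(out) if out.ndim == 0 else out


def log_rq(rq_value):
    """log10(RQ + 1e-10); the offset keeps RQ = 0 finite at -10.  Vectorizes."""
    r = np.asarray(rq_value, dtype=float)
    if np.any(r < 0):
        raise ValueError("RQ must be nonnegative")
    out = np.log10(r + LOG_OFFSET)
    return float(out) if out.ndim == 0 else out


def compute_rq_table(
    fe_table: pd.DataFrame,
    target_gene: str = "EEF2",
    control_gene: str = "UBC",
) -> pd.DataFrame:
    """Derive RQ and logRQ for every target-gene row of an FE table.

    The reference U_mean is computed per (group, replicate) from the control
    gene's three amplicons measured in the same group and replicate.
    Returns the target-gene rows with ``U_mean``, ``RQ`` and ``logRQ`` columns
    appended.
    """
    required = {"gene", "amplicon", "group", "replicate", "FE"}
    missing_cols = required - set(fe_table.columns)
    if missing_cols:
        raise ValueError(f"FE table missing column(s): {sorted(missing_cols)}")

    control = fe_table[fe_table["gene"] == control_gene]
    target = fe_table[fe_table["gene"] == target_gene].copy()
    if target.empty:
        raise ValueError(f"no rows for target gene {target_gene!r}")

    refs = {}
    for (group, rep), sub in control.groupby(["group", "replicate"]):
        refs[(group, rep)] = u_mean(dict(zip(sub["amplicon"], sub["FE"])))

    def _ref(row):
        key = (row["group"], row["replicate"])
        if key not in refs:
            raise ValueError(
                f"no control-gene ({control_gene}) measurements for group "
                f"{key[0]!r} replicate {key[1]}"
            )
        return refs[key]

    target["U_mean"] = target.apply(_ref, axis=1)
    target["RQ"] = rq(target["FE"].to_numpy(), target["U_mean"].to_numpy())
    target["logRQ"] = log_rq(target["RQ"].to_numpy())
    return target


@dataclass(frozen=True)
class PairedTestResult:
    group_a: str
    group_b: str
    n_pairs: int
    mean_difference: float  # mean of (b - a) per-replicate logRQ
    t: float
    df: int
    p: float
    degenerate: bool = False  # zero-variance differences: t and p undefined


def paired_t(differences: Sequence[float]) -> tuple[float, int, float, bool]:
    """Closed-form paired t-test on a vector of per-replicate differences.

    t = mean(d) / (SD(d) / sqrt(n)) with df = n - 1 and a two-sided p from
    the t distribution.  Zero-variance differences give an undefined statistic
    flagged degenerate (p = NaN), except the all-zero case where t = 0, p = 1.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 paired replicates")
    df = n - 1
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0, False
        return float("nan"), df, float("nan"), True
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p, False


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values (NaNs pass through)."""
    p = np.asarray(p_values, dtype=float)
    m = int(np.sum(np.isfinite(p)))
    order = np.argsort(np.where(np.isfinite(p), p, np.inf))
    adjusted = np.full_like(p, np.nan)
    running_max = 0.0
    for rank, idx in enumerate(order):
        if not np.isfinite(p[idx]):
            continue
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted.tolist()


def compare_gates(
    rq_table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    holm: bool = False,
) -> pd.DataFrame:
    """Paired t-tests on per-replicate mean logRQ between gate groups.

    ``rq_table`` is the output of :func:`compute_rq_table`; per-replicate
    means over amplicons are the pairing unit.  ``pairs`` defaults to all
    group pairs in sorted order.  Replicates present in one group but not the
    other are an error listing the missing pairs.  With ``holm=True`` a
    Holm-adjusted p-value column is added (off by default: single comparisons
    are reported raw).
    """
    if "logRQ" not in rq_table.columns:
        raise ValueError("rq_table must carry a logRQ column (see compute_rq_table)")
    rep_means = (
        rq_table.groupby(["group", "replicate"])["logRQ"].mean().unstack("group")
    )
    groups = sorted(rep_means.columns)
    if pairs is None:
        pairs = list(combinations(groups, 2))

    rows = []
    for ga, gb in pairs:
        for g in (ga, gb):
            if g not in rep_means.columns:
                raise ValueError(f"group {g!r} not present in table")
        sub = rep_means[[ga, gb]]
        unpaired = sub[sub.isna().any(axis=1)].index.tolist()
        if unpaired:
            raise ValueError(
                f"unpaired replicates for ({ga}, {gb}): {unpaired}"
            )
        d = (sub[gb] - sub[ga]).to_numpy()
        t, df, p, degenerate = paired_t(d)
        rows.append((ga, gb, len(d), float(d.mean()), t, df, p, degenerate))

    out = pd.DataFrame(
        rows,
        columns=[
            "group_a", "group_b", "n_pairs", "mean_difference",
            "t", "df", "p", "degenerate",
        ],
    )
    if holm:
        out["p_holm"] = holm_adjust(out["p"].tolist())
    return out
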