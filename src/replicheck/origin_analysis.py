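"""Per-origin replication amounts and the quintile time-course comparison.

From a baseline-1 G1-release profile, each origin's replication amount is the
mean copy number over the bins around the origin minus one — the fraction of
cells in which the locus has replicated, clipped to [0, 1].  Origins are then
grouped into trep quintiles (quintile 1 = earliest firing) and compared with
unpaired t-tests, early versus late.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import Origin, assign_quintiles
from .profile_pipeline import CopyProfile

__all__ = [
    "OriginReplication",
    "GroupComparison",
    "origin_replication",
    "quintile_summary",
    "compare_quintiles",
    "pooled_ttest",
]

log = logging.getLogger(__name__)

DEFAULT_HALFWIDTH = 5000


@dataclass(frozen=True)
class OriginReplication:
    """Replicated fraction of one origin at one timepoint."""

    name: str
    timepoint: float
    amount: float  # in [0, 1]
    quintile: int


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-group comparison (Student by default, Welch by flag)."""

    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    t: float
    p: float
    flavour: str = "student"
    degenerate: bool = False  # zero variance in both groups


def origin_replication(
    profile: CopyProfile,
    origins: list[Origin],
    timepoint: float = 0.0,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> list[OriginReplication]:
    """Window-mean replication amount for every origin on a profiled chromosome.

    amount = mean copy over unmasked bins whose midpoint lies within
    ``[pos - halfwidth, pos + halfwidth]``, minus 1, clipped to [0, 1].
    Origins whose window is entirely masked are dropped (and logged); windows
    at chromosome ends are truncated.
    """
    if profile.baseline != 1:
        raise ValueError("origin_replication expects a profile calibrated to baseline 1")
    quintiles = assign_quintiles(origins)
    on_profile = [o for o in origins if o.chrom in profile.genome.names]
    if not on_profile:
        raise ValueError("no origins fall on any profiled chromosome")
    out: list[OriginReplication] = []
    for o in on_profile:
        mids = profile.genome.bin_midpoints(o.chrom, profile.bin_width)
        sel = np.abs(mids - o.pos) <= halfwidth
        sel &= ~profile.masked[o.chrom]
        if not sel.any():
            log.warning("origin %s: window fully masked; dropped", o.name)
            continue
        amount = float(np.clip(profile.values[o.chrom][sel].mean() - 1.0, 0.0, 1.0))
        out.append(OriginReplication(o.name, timepoint, amount, quintiles[o.name]))
    return out


def _quantile(sorted_vals: np.ndarray, q: float) -> float:
    # linear interpolation between order statistics (numpy's default rule)
    return float(np.quantile(sorted_vals, q, method="linear"))


def quintile_summary(
    values: list[OriginReplication], timepoint: float | None = None
) -> pd.DataFrame:
    """Per-quintile n, mean, median and quartiles (linear-interpolated).

    An empty quintile yields a row with n = 0 and NaN statistics, flagged in
    the ``empty`` column.
    """
    if timepoint is not None:
        values = [v for v in values if v.timepoint == timepoint]
    rows = []
    for q in range(1, 6):
        amounts = np.sort([v.amount for v in values if v.quintile == q])
        if amounts.size == 0:
            rows.append({"quintile": q, "n": 0, "mean": np.nan, "median": np.nan,
                         "q1": np.nan, "q3": np.nan, "min": np.nan, "max": np.nan,
                         "empty": True})
            continue
        rows.append(
            {
                "quintile": q,
                "n": int(amounts.size),
                "mean": float(amounts.mean()),
                "median": _quantile(amounts, 0.5),
                "q1": _quantile(amounts, 0.25),
                "q3": _quantile(amounts, 0.75),
                "min": float(amounts.min()),
                "max": float(amounts.max()),
                "empty": False,
            }
        )
    return pd.DataFrame(rows)


def pooled_ttest(
    a: np.ndarray, b: np.ndarray, labels: tuple[str, str], welch: bool = False
) -> GroupComparison:
    """Unpaired two-sided t-test on two samples of scalars."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate: no within-group spread; identical means -> p = 1
        if a.mean() == b.mean():
            return GroupComparison(labels, (a.size, b.size),
                                   (float(a.mean()), float(b.mean())),
                                   t=0.0, p=1.0,
                                   flavour="welch" if welch else "student",
                                   degenerate=True)
        # means differ with zero spread: arbitrarily strong evidence
        return GroupComparison(labels, (a.size, b.size),
                               (float(a.mean()), float(b.mean())),
                               t=np.inf if a.mean() > b.mean() else -np.inf,
                               p=0.0, flavour="welch" if welch else "student",
                               degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        labels,
        (a.size, b.size),
        (float(a.mean()), float(b.mean())),
        t=float(res.statistic),
        p=float(res.pvalue),
        flavour="welch" if welch else "student",
    )


def compare_quintiles(
    a: list[OriginReplication] | np.ndarray,
    b: list[OriginReplication] | np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-sided t-test between two quintiles' replication amounts."""

    def _amounts(x):
        if len(x) and isinstance(x[0], OriginReplication):
            return np.array([v.amount for v in x])
        return np.asarray(x, dtype=float)

    return pooled_ttest(_amounts(a), _amounts(b), labels, welch=welch)
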