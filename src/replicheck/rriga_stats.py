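"""Re-replication-induced gene amplification (RRIGA) frequencies from plating.

The assay plates a dilution series of each culture on rich medium (viable
cell count) and undiluted culture on selective medium (Leu+ count, i.e.
cells in which re-initiation at the marked origin amplified the split
marker into a functional gene).  The amplification frequency is
%Leu+ = (Leu+ colonies per ml) / (viable cells per ml) * 100.

Plates of the same replicate and medium are averaged before the ratio;
replicate percentages are then summarised with mean and sample SD (n-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .origin_analysis import GroupComparison, pooled_ttest

__all__ = [
    "PlateCount",
    "RrigaResult",
    "cells_per_ml",
    "percent_leu",
    "compare_strains",
    "read_counts_tsv",
    "results_frame",
]

log = logging.getLogger(__name__)

PLATE_COLUMNS = ["strain", "timepoint", "replicate", "medium", "volume_ml",
                 "dilution", "colonies"]


@dataclass(frozen=True)
class PlateCount:
    strain: str
    timepoint: str  # {"pre-induction", "induced"} by convention
    replicate: int
    medium: str  # {"rich", "selective"}
    volume_ml: float
    dilution: float
    colonies: int

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.colonies < 0:
            raise ValueError("colonies must be >= 0")
        if self.medium not in ("rich", "selective"):
            raise ValueError(f"unknown medium {self.medium!r}")


@dataclass(frozen=True)
class RrigaResult:
    strain: str
    timepoint: str
    per_replicate: tuple[float, ...]  # %Leu+ per replicate
    mean: float
    sd: float  # sample SD (ddof=1); 0 when n == 1
    n: int
    undefined: bool = False  # viable count was zero


def cells_per_ml(count: PlateCount | pd.Series) -> float:
    """Back-calculate culture density from one plate: colonies * dilution / volume."""
    colonies = count.colonies if isinstance(count, PlateCount) else count["colonies"]
    dilution = count.dilution if isinstance(count, PlateCount) else count["dilution"]
    volume = count.volume_ml if isinstance(count, PlateCount) else count["volume_ml"]
    if volume <= 0:
        raise ValueError("volume_ml must be > 0")
    return float(colonies) * float(dilution) / float(volume)


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, pd.DataFrame):
        df = counts.copy()
    else:
        df = pd.DataFrame([c.__dict__ for c in counts])
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate-count table is missing columns {missing}")
    if (df["volume_ml"] <= 0).any() or (df["dilution"] < 1).any():
        raise ValueError("invalid volumes or dilution factors in plate-count table")
    if (df["colonies"] < 0).any():
        raise ValueError("negative colony counts")
    return df


def percent_leu(counts, strain: str | None = None,
                timepoint: str | None = None) -> RrigaResult:
    """%Leu+ for one strain/timepoint from matched rich and selective plates.

    Per replicate: (mean selective cells/ml across its plates) / (mean rich
    cells/ml across its plates) * 100; pairing across media is by replicate
    id.  A replicate with zero viable count yields an undefined (NaN)
    percentage, flagged rather than raised.
    """
    df = _as_frame(counts)
    if strain is not None:
        df = df[df["strain"] == strain]
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint]
    if df.empty:
        raise ValueError("no plate counts for the requested strain/timepoint")
    strain = str(df["strain"].iloc[0])
    timepoint = str(df["timepoint"].iloc[0])
    dens = df.assign(cells_per_ml=df.apply(cells_per_ml, axis=1))
    per_rep: list[float] = []
    undefined = False
    for rep, grp in dens.groupby("replicate"):
        rich = grp.loc[grp["medium"] == "rich", "cells_per_ml"]
        sel = grp.loc[grp["medium"] == "selective", "cells_per_ml"]
        if rich.empty or sel.empty:
            raise ValueError(f"replicate {rep}: needs at least one plate per medium")
        viable = rich.mean()
        if viable == 0:
            log.warning("%s/%s replicate %s: zero viable count; %%Leu+ undefined",
                        strain, timepoint, rep)
            per_rep.append(np.nan)
            undefined = True
            continue
        per_rep.append(float(sel.mean() / viable * 100.0))
    arr = np.array(per_rep, dtype=float)
    ok = arr[~np.isnan(arr)]
    mean = float(ok.mean()) if ok.size else np.nan
    sd = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    return RrigaResult(strain, timepoint, tuple(per_rep), mean, sd,
                       n=len(per_rep), undefined=undefined)


def compare_strains(a: RrigaResult, b: RrigaResult,
                    welch: bool = False) -> GroupComparison:
    """Unpaired two-sided t-test on per-replicate %Leu+ values."""
    av = np.array([x for x in a.per_replicate if not np.isnan(x)])
    bv = np.array([x for x in b.per_replicate if not np.isnan(x)])
    return pooled_ttest(av, bv, labels=(a.strain, b.strain), welch=welch)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a plate-count TSV with the PlateCount columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return _as_frame(df)


def results_frame(results: list[RrigaResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"strain": r.strain, "timepoint": r.timepoint, "n": r.n,
               "mean_percent_leu": r.mean, "sd_percent_leu": r.sd,
               "undefined": r.undefined}
        for i, v in enumerate(r.per_replicate, 1):
            row[f"replicate_{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
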