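"""Quantify re-replication from G2-baseline copy profiles.

Gains above the 2n baseline are summarised three ways: maximal runs of
supra-threshold bins (gained segments), a per-chromosome re-replication
index (mean copy minus 2), and per-origin peak heights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import Origin
from .profile_pipeline import CopyProfile

__all__ = [
    "GainSegment",
    "gain_segments",
    "chromosome_rerep_index",
    "peak_height",
]

log = logging.getLogger(__name__)

DEFAULT_GAIN_THRESHOLD = 0.2  # copy units above the 2n baseline
DEFAULT_MIN_BINS = 5


@dataclass(frozen=True)
class GainSegment:
    chrom: str
    start: int  # bp, half-open
    end: int
    mean_copy: float
    max_copy: float
    n_bins: int


def _check_baseline(profile: CopyProfile) -> None:
    if profile.baseline != 2:
        raise ValueError("re-replication analysis expects a baseline-2 (G2/M) profile")


def gain_segments(
    profile: CopyProfile,
    threshold: float = DEFAULT_GAIN_THRESHOLD,
    min_bins: int = DEFAULT_MIN_BINS,
) -> list[GainSegment]:
    """Maximal runs of unmasked bins with copy >= 2 + threshold.

    Runs shorter than ``min_bins`` are discarded; masked bins break runs and
    no gap-merging is performed.
    """
    _check_baseline(profile)
    segments: list[GainSegment] = []
    for chrom in profile.genome.names:
        v = profile.values[chrom]
        above = np.where(profile.masked[chrom], False, v >= 2.0 + threshold)
        if not above.any():
            continue
        starts, ends = profile.genome.bin_edges(chrom, profile.bin_width)
        padded = np.concatenate([[False], above, [False]]).astype(int)
        edges = np.flatnonzero(np.diff(padded))
        for lo, hi in zip(edges[::2], edges[1::2]):
            if hi - lo < min_bins:
                continue
            segments.append(
                GainSegment(
                    chrom=chrom,
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    mean_copy=float(v[lo:hi].mean()),
                    max_copy=float(v[lo:hi].max()),
                    n_bins=int(hi - lo),
                )
            )
    return segments


def segments_frame(segments: list[GainSegment]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "mean_copy", "max_copy", "n_bins"]
    return pd.DataFrame([s.__dict__ for s in segments], columns=cols)


def chromosome_rerep_index(profile: CopyProfile) -> pd.Series:
    """Per-chromosome mean copy number above baseline (mean(copy) - 2).

    Fully masked chromosomes are absent from the result (and logged).  The
    returned Series keeps genome order; sort descending for the ranking.
    """
    _check_baseline(profile)
    idx = {}
    for chrom in profile.genome.names:
        vals = profile.unmasked_values(chrom)
        if vals.size == 0:
            log.warning("chromosome %s fully masked; no rerep index", chrom)
            continue
        idx[chrom] = float(vals.mean() - 2.0)
    return pd.Series(idx, name="rerep_index")


def peak_height(
    profile: CopyProfile, origin: Origin, halfwidth: int = 5000
) -> float | None:
    """Maximum unmasked copy within [pos - halfwidth, pos + halfwidth].

    Returns None (and logs) when the window is fully masked.
    """
    _check_baseline(profile)
    mids = profile.genome.bin_midpoints(origin.chrom, profile.bin_width)
    sel = (np.abs(mids - origin.pos) <= halfwidth) & ~profile.masked[origin.chrom]
    if not sel.any():
        log.warning("origin %s: peak window fully masked", origin.name)
        return None
    return float(profile.values[origin.chrom][sel].max())
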