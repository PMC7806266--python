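"""Forward simulator of origin firing, fork progression and re-initiation.

Two scenarios are modelled, each producing a population-average copy-number
truth profile plus Poisson-sampled read counts:

* **G1-release S-phase entry.** Per cell, origin *i* fires at
  ``Ti = max(N(trep_i + transcription_delay, fire_sd_i), 0)``; with
  probability ``firing_block_prob`` (optionally restricted to the early or
  late checkpoint class) the origin is additionally held until
  ``release_time`` — the Rad53 arm acting on Sld3/Dbf4.  A position x is
  replicated at time t when any origin's fork has reached it,
  ``min_i(Ti + |x - pos_i| / fork_speed) <= t`` (passive replication
  included).  The population profile is 1 + (fraction of cells replicated).

* **G2/M re-replication.** Per cell, origin k re-initiates a
  Poisson(rerep_rate_k * rate_scale) number of times; each event adds one
  copy over ``[pos - L1, pos + L2]`` with L1, L2 ~ Exponential(fork_extent_mean)
  (onion-skin: contributions sum, no collision modelling).  The population
  profile is 2 + mean added copies.  With licensing disabled the profile is
  exactly 2 everywhere.

A third generator emits RRIGA plating counts (rich/selective colony counts
under the standard serial-dilution plan).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import GenomeSpec, Origin, checkpoint_classes
from .profile_pipeline import BinnedCoverage, CopyProfile

__all__ = [
    "SimConfig",
    "CheckpointConfig",
    "RerepConfig",
    "simulate_sphase",
    "simulate_g2_rereplication",
    "sample_reads",
    "simulate_rriga_counts",
    "default_plating_plan",
]

_CELL_CHUNK = 64  # cells per broadcast block; bounds peak memory


@dataclass(frozen=True)
class SimConfig:
    """Population and sampling parameters shared by both scenarios."""

    fork_speed: float = 1.5  # kb/min
    n_cells: int = 500
    read_depth: float = 100.0  # expected reads per bin per copy unit
    seed: int = 0
    bin_width: int = 1000

    def __post_init__(self) -> None:
        if self.fork_speed <= 0:
            raise ValueError("fork_speed must be > 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be > 0")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")


@dataclass(frozen=True)
class CheckpointConfig:
    """The two Rad53 arms restraining the G1/S transition.

    ``transcription_delay`` models the Swi6/SBF (G1/S transcription) arm: a
    uniform delay added to every origin's firing time; it is 0 when the
    uninhibitable Swi4 truncation is expressed.  ``firing_block_prob`` models
    the Sld3/Dbf4 arm: the probability that a given origin in a given cell is
    held until ``release_time``; it is 0 in the checkpoint-refractory
    sld3-A dbf4-A background.  ``block_scope`` restricts the block to one
    checkpoint class ("early"/"late") or applies it to all origins.
    """

    transcription_delay: float = 0.0  # minutes
    firing_block_prob: float = 0.0
    release_time: float = 0.0  # minutes
    block_scope: str = "all"  # {"all", "early", "late"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.firing_block_prob <= 1.0:
            raise ValueError("firing_block_prob must be in [0, 1]")
        if self.transcription_delay < 0:
            raise ValueError("transcription_delay must be >= 0")
        if self.block_scope not in ("all", "early", "late"):
            raise ValueError("block_scope must be 'all', 'early' or 'late'")


@dataclass(frozen=True)
class RerepConfig:
    """G2/M re-replication induction parameters.

    ``rate_scale`` multiplies every origin's rerep_rate; it encodes loss of
    the Rad53 brake on re-initiation (checkpoint-refractory strains re-fire
    more often).  ``licensing_enabled`` False is the wild-type
    licensing-control case: no re-initiation anywhere.
    """

    induction_time: float = 240.0  # minutes of induction; metadata only
    fork_extent_mean: float = 10.0  # kb, mean one-sided bubble extent
    licensing_enabled: bool = True
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.fork_extent_mean <= 0:
            raise ValueError("fork_extent_mean must be > 0")
        if self.rate_scale < 0:
            raise ValueError("rate_scale must be >= 0")


def _origins_by_chrom(origins: list[Origin], genome: GenomeSpec) -> dict[str, list[Origin]]:
    by: dict[str, list[Origin]] = {c: [] for c in genome.names}
    for o in origins:
        if o.chrom not in by:
            raise ValueError(f"origin {o.name!r} on chromosome {o.chrom!r} not in genome")
        by[o.chrom].append(o)
    for c in by:
        by[c].sort(key=lambda o: o.pos)
    return by


def simulate_sphase(
    genome: GenomeSpec,
    origins: list[Origin],
    t: float,
    cfg: SimConfig,
    chk: CheckpointConfig | None = None,
) -> CopyProfile:
    """Population-average S-phase copy profile at ``t`` minutes after release.

    Returns a truth :class:`CopyProfile` (baseline 1, nothing masked) whose
    bin values lie in [1, 2].  Chromosomes without origins stay at copy 1.
    Deterministic given ``cfg.seed``; because the per-cell firing times do
    not depend on ``t``, profiles at increasing ``t`` from the same seed are
    non-decreasing everywhere.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    chk = chk or CheckpointConfig()
    by_chrom = _origins_by_chrom(origins, genome)
    classes = checkpoint_classes(origins)
    speed_bp = cfg.fork_speed * 1000.0  # bp/min
    rng = np.random.default_rng(cfg.seed)
    values: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        ors = by_chrom[chrom]
        mids = genome.bin_midpoints(chrom, cfg.bin_width)
        if not ors:
            values[chrom] = np.ones(mids.size)
            continue
        pos = np.array([o.pos for o in ors], dtype=float)
        trep = np.array([o.trep for o in ors], dtype=float)
        sd = np.array([o.fire_sd for o in ors], dtype=float)
        blockable = np.array(
            [chk.block_scope in ("all", classes[o.name]) for o in ors]
        )
        travel = np.abs(mids[None, :] - pos[:, None]) / speed_bp  # (n_or, n_bins)
        # draw all per-cell firing times up front so that the stream of random
        # numbers is independent of t and of firing_block_prob comparisons
        draws = rng.normal(
            trep + chk.transcription_delay, sd, size=(cfg.n_cells, len(ors))
        )
        fire = np.maximum(draws, 0.0)
        u = rng.random(size=(cfg.n_cells, len(ors)))
        blocked = (u < chk.firing_block_prob) & blockable[None, :]
        fire = np.where(blocked, np.maximum(fire, chk.release_time), fire)
        replicated = np.zeros(mids.size)
        for lo in range(0, cfg.n_cells, _CELL_CHUNK):
            chunk = fire[lo : lo + _CELL_CHUNK]  # (m, n_or)
            arrival = (chunk[:, :, None] + travel[None, :, :]).min(axis=1)
            replicated += (arrival <= t).sum(axis=0)
        values[chrom] = 1.0 + replicated / cfg.n_cells
    masked = {c: np.zeros_like(values[c], dtype=bool) for c in genome.names}
    return CopyProfile(genome, cfg.bin_width, values, masked, baseline=1,
                       sample=f"sphase_t{t:g}")


def simulate_g2_rereplication(
    genome: GenomeSpec,
    origins: list[Origin],
    cfg: SimConfig,
    rr: RerepConfig,
) -> CopyProfile:
    """Population-average G2/M re-replication profile (baseline 2).

    Each re-initiation event lays an extra copy over an exponential-extent
    bubble around its origin; events are independent and additive, so the
    expected value at the origin itself is 2 + rerep_rate * rate_scale.
    """
    by_chrom = _origins_by_chrom(origins, genome)
    rng = np.random.default_rng(cfg.seed)
    extent_bp = rr.fork_extent_mean * 1000.0
    values: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        mids = genome.bin_midpoints(chrom, cfg.bin_width)
        added = np.zeros(mids.size)
        if rr.licensing_enabled:
            diff = np.zeros(mids.size + 1)
            for o in by_chrom[chrom]:
                lam = o.rerep_rate * rr.rate_scale
                if lam <= 0:
                    continue
                n_events = int(rng.poisson(lam, size=cfg.n_cells).sum())
                if n_events == 0:
                    continue
                l1 = rng.exponential(extent_bp, size=n_events)
                l2 = rng.exponential(extent_bp, size=n_events)
                lo = np.searchsorted(mids, o.pos - l1, side="left")
                hi = np.searchsorted(mids, o.pos + l2, side="right")
                np.add.at(diff, lo, 1.0)
                np.add.at(diff, hi, -1.0)
            added = np.cumsum(diff[:-1]) / cfg.n_cells
        values[chrom] = 2.0 + added
    masked = {c: np.zeros_like(values[c], dtype=bool) for c in genome.names}
    return CopyProfile(genome, cfg.bin_width, values, masked, baseline=2,
                       sample="g2_rerep")


def sample_reads(
    truth: CopyProfile, cfg: SimConfig, seed: int | None = None, sample: str = ""
) -> BinnedCoverage:
    """Poisson read counts from a truth profile: count ~ Poisson(depth * copy).

    A non-replicating reference is obtained by sampling from a flat profile
    at the scenario's baseline (see :func:`profile_pipeline.flat_profile`).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    counts = {}
    for chrom in truth.genome.names:
        copy = np.where(truth.masked[chrom], 0.0, truth.values[chrom])
        counts[chrom] = rng.poisson(cfg.read_depth * copy).astype(float)
    return BinnedCoverage(truth.genome, truth.bin_width, counts,
                          sample=sample or truth.sample)


def default_plating_plan() -> list[dict]:
    """The standard RRIGA plating plan.

    Per replicate: one rich plate of 0.1 ml at the 10^4-fold dilution (viable
    count) and two selective plates of undiluted culture, 0.1 ml and 0.01 ml
    (Leu+ count).
    """
    return [
        {"medium": "rich", "volume_ml": 0.1, "dilution": 1e4},
        {"medium": "selective", "volume_ml": 0.1, "dilution": 1.0},
        {"medium": "selective", "volume_ml": 0.01, "dilution": 1.0},
    ]


def simulate_rriga_counts(
    p_amp: float,
    n_viable_per_ml: float,
    plan: list[dict] | None = None,
    seed: int = 0,
    strain: str = "strain",
    timepoint: str = "induced",
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Simulated colony counts for one strain/timepoint.

    ``p_amp`` is the probability that a plated viable cell has undergone
    re-replication-induced gene amplification and grows on selective medium.
    Colony counts are Poisson with mean ``rate * n_viable_per_ml * volume /
    dilution`` where rate is 1 on rich and ``p_amp`` on selective plates.
    """
    if not 0.0 <= p_amp <= 1.0:
        raise ValueError("p_amp must be in [0, 1]")
    if n_viable_per_ml < 0:
        raise ValueError("n_viable_per_ml must be >= 0")
    plan = plan if plan is not None else default_plating_plan()
    for plate in plan:
        if plate["volume_ml"] <= 0 or plate["dilution"] < 1:
            raise ValueError(f"invalid plate spec {plate!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        for plate in plan:
            rate = p_amp if plate["medium"] == "selective" else 1.0
            mean = rate * n_viable_per_ml * plate["volume_ml"] / plate["dilution"]
            rows.append(
                {
                    "strain": strain,
                    "timepoint": timepoint,
                    "replicate": rep,
                    "medium": plate["medium"],
                    "volume_ml": plate["volume_ml"],
                    "dilution": plate["dilution"],
                    "colonies": int(rng.poisson(mean)),
                }
            )
    return pd.DataFrame(rows)
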