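"""Genome, origin and checkpoint-allele registries.

Coordinates are 0-based, half-open throughout; an origin position is a point
(the locus midpoint).  Origins carry their median replication time ``trep``
(minutes after S-phase entry in an unperturbed cycle), the per-cell spread of
their firing time, and an expected re-initiation rate used by the G2/M
re-replication simulator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "Origin",
    "AlleleDefinition",
    "load_genome",
    "load_origins",
    "assign_quintiles",
    "checkpoint_classes",
    "load_alleles",
    "get_allele",
    "count_mutated_sites",
    "default_genome",
    "default_origins",
]

N_QUINTILES = 5


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered set of chromosomes with lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        chroms = tuple((str(n), int(l)) for n, l in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return -(-self.length_of(chrom) // bin_width)

    def bin_edges(self, chrom: str, bin_width: int) -> tuple[np.ndarray, np.ndarray]:
        """Start/end arrays of the fixed-width grid; last bin truncated."""
        length = self.length_of(chrom)
        starts = np.arange(0, length, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, length)
        return starts, ends

    def bin_midpoints(self, chrom: str, bin_width: int) -> np.ndarray:
        starts, ends = self.bin_edges(chrom, bin_width)
        return (starts + ends) / 2.0


@dataclass(frozen=True)
class Origin:
    """A licensed replication origin.

    Parameters
    ----------
    chrom, pos, name
        Location (0-based point coordinate) and identifier.
    trep
        Median replication time in minutes; early origins have low trep.
    fire_sd
        Per-cell standard deviation of the firing time, minutes.
    rerep_rate
        Expected number of re-initiation events per cell per G2/M induction.
    """

    chrom: str
    pos: int
    name: str
    trep: float
    fire_sd: float = 5.0
    rerep_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.trep <= 0:
            raise ValueError(f"origin {self.name!r}: trep must be > 0, got {self.trep}")
        if self.fire_sd < 0:
            raise ValueError(f"origin {self.name!r}: fire_sd must be >= 0")
        if self.rerep_rate < 0:
            raise ValueError(f"origin {self.name!r}: rerep_rate must be >= 0")
        if self.pos < 0:
            raise ValueError(f"origin {self.name!r}: pos must be >= 0")


@dataclass(frozen=True)
class AlleleDefinition:
    """A checkpoint-site mutant allele: residues refractory to Rad53.

    ``mutated_residues`` is the ordered list of (position, substitution)
    pairs; substitutions are single amino-acid codes (A for the
    serine/threonine-to-alanine sites, R for the one arginine substitution
    in the Sld3 allele).
    """

    name: str
    mutated_residues: tuple[tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.mutated_residues:
            raise ValueError(f"allele {self.name!r}: mutated residue list is empty")
        positions = [p for p, _ in self.mutated_residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"allele {self.name!r}: positions must be strictly increasing")
        for _, sub in self.mutated_residues:
            if sub not in ("A", "R"):
                raise ValueError(f"allele {self.name!r}: unexpected substitution {sub!r}")


def load_genome(path) -> GenomeSpec:
    """Read a two-column TSV (chrom, length) into a :class:`GenomeSpec`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "length"):
        if col not in df.columns:
            raise ValueError(f"genome table is missing required column {col!r}")
    return GenomeSpec(tuple(zip(df["chrom"], df["length"].astype(int))))


def load_origins(path, genome: GenomeSpec) -> list[Origin]:
    """Read an origin table (TSV: chrom, pos, name, trep [, fire_sd, rerep_rate]).

    Positions are validated against ``genome``; a row on an unknown chromosome
    or beyond its chromosome end is rejected.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "name", "trep"):
        if col not in df.columns:
            raise ValueError(f"origin table is missing required column {col!r}")
    lengths = genome.lengths
    origins: list[Origin] = []
    for row in df.itertuples(index=False):
        if row.chrom not in lengths:
            raise ValueError(f"origin {row.name!r} is on unknown chromosome {row.chrom!r}")
        if not 0 <= row.pos < lengths[row.chrom]:
            raise ValueError(
                f"origin {row.name!r}: pos {row.pos} outside chromosome "
                f"{row.chrom!r} (length {lengths[row.chrom]})"
            )
        origins.append(
            Origin(
                chrom=str(row.chrom),
                pos=int(row.pos),
                name=str(row.name),
                trep=float(row.trep),
                fire_sd=float(getattr(row, "fire_sd", 5.0)),
                rerep_rate=float(getattr(row, "rerep_rate", 0.0)),
            )
        )
    return origins


def assign_quintiles(origins: list[Origin]) -> dict[str, int]:
    """Partition origins into five contiguous trep-ranked groups.

    Origins are ranked by trep ascending (ties broken by (chrom, pos) for
    determinism) and the rank range is split into five contiguous groups whose
    sizes differ by at most one; when n mod 5 != 0 the earlier quintiles take
    the extra member.  Quintile 1 is the earliest firing.
    """
    if len(origins) < N_QUINTILES:
        raise ValueError(f"need at least {N_QUINTILES} origins, got {len(origins)}")
    names = [o.name for o in origins]
    if len(set(names)) != len(names):
        raise ValueError("origin names must be unique for quintile assignment")
    ranked = sorted(origins, key=lambda o: (o.trep, o.chrom, o.pos))
    n = len(ranked)
    base, extra = divmod(n, N_QUINTILES)
    out: dict[str, int] = {}
    idx = 0
    for q in range(1, N_QUINTILES + 1):
        size = base + (1 if q <= extra else 0)
        for o in ranked[idx : idx + size]:
            out[o.name] = q
        idx += size
    return out


def checkpoint_classes(origins: list[Origin]) -> dict[str, str]:
    """Early/late dichotomy: early = trep below the median trep of the set."""
    if not origins:
        return {}
    med = float(np.median([o.trep for o in origins]))
    return {o.name: ("early" if o.trep < med else "late") for o in origins}


def _read_packaged(name: str):
    return importlib.resources.files("replicheck.data").joinpath(name)


_ALLELE_CACHE: dict[str, AlleleDefinition] | None = None


def load_alleles() -> dict[str, AlleleDefinition]:
    """Packaged checkpoint-site alleles (sld3-38A, dbf4-19A, dbf4-4A)."""
    global _ALLELE_CACHE
    if _ALLELE_CACHE is None:
        with importlib.resources.as_file(_read_packaged("alleles.tsv")) as p:
            df = pd.read_csv(p, sep="\t")
        alleles = {}
        for name, grp in df.groupby("name", sort=False):
            residues = tuple(zip(grp["position"].astype(int), grp["substitution"]))
            alleles[name] = AlleleDefinition(name=name, mutated_residues=residues)
        _ALLELE_CACHE = alleles
    return _ALLELE_CACHE


def get_allele(name: str) -> AlleleDefinition:
    alleles = load_alleles()
    try:
        return alleles[name]
    except KeyError:
        raise KeyError(
            f"unknown allele {name!r}; available: {sorted(alleles)}"
        ) from None


def count_mutated_sites(allele: AlleleDefinition | str) -> int:
    """Number of mutated residues in an allele (all substitutions counted)."""
    if isinstance(allele, str):
        allele = get_allele(allele)
    return len(allele.mutated_residues)


def default_genome() -> GenomeSpec:
    """The packaged yeast-scale toy genome used by the simulation scenarios."""
    with importlib.resources.as_file(_read_packaged("genome.tsv")) as p:
        return load_genome(p)


def default_origins(genome: GenomeSpec | None = None) -> list[Origin]:
    """The packaged 121-origin registry (chrIII carries elevated rerep rates)."""
    genome = genome or default_genome()
    with importlib.resources.as_file(_read_packaged("origins.tsv")) as p:
        return load_origins(p, genome)
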