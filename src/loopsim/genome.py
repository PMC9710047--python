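"""Genomic coordinate types and input parsing.

All coordinates are 0-based, half-open, in base pairs. Chromosome lists come
from two-column ``chrom.sizes`` files; extrusion barriers from BED6, where the
strand encodes the blocking direction and the score column may carry a
per-barrier occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

from .barriers import ExtrusionBarrier

__all__ = [
    "Chromosome",
    "GenomicInterval",
    "SimulationConfig",
    "load_chrom_sizes",
    "load_barriers",
    "write_barriers",
    "n_lefs",
]


@dataclass(frozen=True)
class Chromosome:
    """A named chromosome of a given length in bp."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("chromosome name must be non-empty")
        if not isinstance(self.length, int) or isinstance(self.length, bool):
            raise ValueError(f"chromosome {self.name!r}: length must be an integer")
        if self.length < 1:
            raise ValueError(
                f"chromosome {self.name!r}: length must be >= 1, got {self.length}"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class SimulationConfig:
    """All tunables of a loop-extrusion simulation run.

    Parameters
    ----------
    bin_size : int
        Contact-matrix resolution in bp.
    diagonal_width : int
        Maximum genomic separation (bp) at which contacts are stored.
    lef_density : float
        Loop-extrusion factors instantiated per Mbp of chromosome.
    processivity : float
        Mean total DNA (bp) extruded by one LEF over its bound lifetime;
        sets the per-epoch release probability ``2 * mean_stride / processivity``.
    mean_stride : int
        Mean bp extruded per unit per epoch. Defaults to ``bin_size``.
    stride_sd_fraction : float
        Stride standard deviation as a fraction of the mean stride.
    hard_stall_lifetime_multiplier : float
        Release probability divisor for LEFs stalled on both sides by a
        convergent bound barrier pair (>= 1).
    ncells : int
        Independent simulation instances per chromosome.
    target_contact_density : float | None
        Stop once mean contacts per band pixel reaches this value (default 1).
    target_epochs : int | None
        Alternative stopping rule: per-cell epoch budget. Exactly one of
        the two stopping rules governs termination (density by default).
    contact_sampling_fraction : float
        Per-epoch probability that an active LEF is sampled for contacts.
    tad_to_loop_contact_ratio : float
        Mean number of intra-TAD contacts registered per sampled loop contact.
    burn_in_window : int
        Number of epochs in each loop-size averaging window used by the
        burn-in stabilization criterion.
    burn_in_tolerance : float
        Relative change of the windowed mean loop size below which
        burn-in terminates.
    burn_in_max_epochs : int
        Hard cap on burn-in epochs.
    seed : int
        Master seed; per-task seeds are a pure function of it.
    """

    bin_size: int = 5_000
    diagonal_width: int = 3_000_000
    lef_density: float = 20.0
    processivity: float = 200_000.0
    mean_stride: int | None = None
    stride_sd_fraction: float = 0.05
    hard_stall_lifetime_multiplier: float = 5.0
    ncells: int = 512
    target_contact_density: float | None = 1.0
    target_epochs: int | None = None
    contact_sampling_fraction: float = 0.025
    tad_to_loop_contact_ratio: float = 1.0
    burn_in_window: int = 16
    burn_in_tolerance: float = 0.01
    burn_in_max_epochs: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_stride is None:
            self.mean_stride = self.bin_size
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if self.diagonal_width < self.bin_size:
            raise ValueError("diagonal_width must be >= bin_size")
        if self.lef_density <= 0:
            raise ValueError("lef_density must be > 0")
        if self.processivity <= 0:
            raise ValueError("processivity must be > 0")
        if self.mean_stride <= 0:
            raise ValueError("mean_stride must be > 0")
        if self.stride_sd_fraction < 0:
            raise ValueError("stride_sd_fraction must be >= 0")
        if self.hard_stall_lifetime_multiplier < 1:
            raise ValueError("hard_stall_lifetime_multiplier must be >= 1")
        if self.ncells < 1:
            raise ValueError("ncells must be >= 1")
        if not (0 < self.contact_sampling_fraction <= 1):
            raise ValueError("contact_sampling_fraction must be in (0, 1]")
        if self.tad_to_loop_contact_ratio < 0:
            raise ValueError("tad_to_loop_contact_ratio must be >= 0")
        if self.target_epochs is not None and self.target_epochs < 1:
            raise ValueError("target_epochs must be >= 1")
        if self.target_contact_density is not None and self.target_contact_density <= 0:
            raise ValueError("target_contact_density must be > 0")
        if self.target_epochs is not None:
            # the epoch budget takes over; density rule is switched off
            self.target_contact_density = None
        elif self.target_contact_density is None:
            raise ValueError(
                "one of target_contact_density / target_epochs must be set"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return SimulationConfig(**current)

    @property
    def mean_lifetime_epochs(self) -> float:
        """Expected LEF lifetime in epochs (geometric law)."""
        return self.processivity / (2.0 * self.mean_stride)


def load_chrom_sizes(path: str | Path) -> list[Chromosome]:
    """Parse a two-column (name, length) chrom.sizes TSV.

    Raises ``ValueError`` naming the offending line on malformed input, and on
    duplicate chromosome names or non-positive lengths.
    """
    chromosomes: list[Chromosome] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            name, length_str = parts
            try:
                length = int(length_str)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: length {length_str!r} is not an integer"
                ) from None
            if name in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            try:
                chromosomes.append(Chromosome(name, length))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return chromosomes


def write_chrom_sizes(chromosomes: Iterable[Chromosome], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in chromosomes:
            fh.write(f"{chrom.name}\t{chrom.length}\n")


def load_barriers(
    path: str | Path,
    default_occupancy: float = 0.8,
    default_puu: float = 0.7,
    score_dialect: str = "fraction",
) -> list[ExtrusionBarrier]:
    """Parse an extrusion-barrier BED6 file.

    The strand column encodes the blocking direction ('+' blocks
    reverse-moving units, '-' forward-moving units); '.' is rejected. The
    score column, when present and not '.', carries the barrier occupancy:
    either directly in [0, 1] (``score_dialect="fraction"``, the default) or
    as a UCSC 0-1000 score divided by 1000 (``score_dialect="ucsc"``). A
    missing/'.' score falls back to ``default_occupancy``. The barrier
    position is the interval midpoint rounded down. Barriers are returned
    sorted by (chrom, position).
    """
    if score_dialect not in ("fraction", "ucsc"):
        raise ValueError(f"unknown score dialect {score_dialect!r}")
    barriers: list[ExtrusionBarrier] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: barrier BED needs 6 columns "
                    f"(strand is required), got {len(parts)}"
                )
            chrom, start_s, end_s, _name, score_s, strand = parts[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if not (0 <= start < end):
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: strand must be '+' or '-' "
                    f"(blocking direction is required), got {strand!r}"
                )
            if score_s in (".", ""):
                occupancy = float(default_occupancy)
            else:
                try:
                    score = float(score_s)
                except ValueError:
                    raise ValueError(
                        f"{path}: line {lineno}: score {score_s!r} is not numeric"
                    ) from None
                occupancy = score / 1000.0 if score_dialect == "ucsc" else score
                if not (0.0 <= occupancy <= 1.0):
                    raise ValueError(
                        f"{path}: line {lineno}: occupancy {occupancy} outside [0, 1] "
                        f"(score {score_s!r}, dialect {score_dialect!r})"
                    )
            barriers.append(
                ExtrusionBarrier(
                    chrom=chrom,
                    position=(start + end) // 2,
                    blocking=strand,
                    occupancy=occupancy,
                    puu=float(default_puu),
                )
            )
    barriers.sort(key=lambda b: (b.chrom, b.position))
    return barriers


def write_barriers(barriers: Sequence[ExtrusionBarrier], path: str | Path) -> None:
    """Write barriers back to BED6 (1-bp intervals, occupancy in the score field)."""
    with open(path, "w") as fh:
        for i, b in enumerate(barriers):
            fh.write(
                f"{b.chrom}\t{b.position}\t{b.position + 1}\tbarrier_{i}"
                f"\t{b.occupancy:.6g}\t{b.blocking}\n"
            )


def n_lefs(chromosome: Chromosome | int, lef_density: float) -> int:
    """Number of LEFs instantiated on a chromosome: round(length * density / 1e6), >= 1."""
    if lef_density <= 0:
        raise ValueError("lef_density must be > 0")
    length = chromosome.length if isinstance(chromosome, Chromosome) else int(chromosome)
    return max(1, round(length * lef_density / 1e6))
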