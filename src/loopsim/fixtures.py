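"""Synthetic inputs: toy genomes, convergent barrier pairs, self-referential
reference matrices.

Everything any other module consumes (chrom.sizes, barrier BED, stripe BED,
reference coolers) can be generated here deterministically from a seed, so
simulations, scoring and optimizer-recovery experiments run without any
external data. Reference matrices are produced by the engine itself at known
parameters, with a JSON sidecar recording the generating configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .barriers import ExtrusionBarrier
from .engine import run_simulation
from .genome import Chromosome, SimulationConfig, write_chrom_sizes, write_barriers

__all__ = [
    "ToySystemSpec",
    "make_toy_genome",
    "make_barrier_annotation",
    "make_stripe_annotation",
    "make_reference_matrix",
    "make_toy_binary_matrices",
]


@dataclass
class ToySystemSpec:
    """Layout of a synthetic test system.

    ``n_pairs`` convergent ('+' then '-') barrier pairs are spread evenly
    along each chromosome; each pair spans ``pair_span`` bp and bounds a
    TAD-like domain.
    """

    chrom_lengths: tuple[int, ...] = (5_000_000,)
    chrom_prefix: str = "chrS"
    n_pairs: int = 4
    pair_span: int = 200_000
    occupancy: float = 0.85
    puu: float = 0.7
    seed: int = 0

    @property
    def chromosomes(self) -> list[Chromosome]:
        return [
            Chromosome(f"{self.chrom_prefix}{i + 1}", int(length))
            for i, length in enumerate(self.chrom_lengths)
        ]

    def barriers(self) -> list[ExtrusionBarrier]:
        out: list[ExtrusionBarrier] = []
        for chrom in self.chromosomes:
            for k in range(self.n_pairs):
                center = (k + 1) * chrom.length // (self.n_pairs + 1)
                left = center - self.pair_span // 2
                right = center + self.pair_span // 2
                if left < 0 or right >= chrom.length:
                    raise ValueError(
                        f"barrier pair {k} overlaps the ends of {chrom.name}"
                    )
                out.append(
                    ExtrusionBarrier(chrom.name, left, "+", self.occupancy, self.puu)
                )
                out.append(
                    ExtrusionBarrier(chrom.name, right, "-", self.occupancy, self.puu)
                )
        return out


def make_toy_genome(spec: ToySystemSpec, path: str | Path) -> list[Chromosome]:
    """Write the spec's chromosomes as a chrom.sizes file."""
    chromosomes = spec.chromosomes
    write_chrom_sizes(chromosomes, path)
    return chromosomes


def make_barrier_annotation(
    spec: ToySystemSpec, path: str | Path
) -> list[ExtrusionBarrier]:
    """Write the spec's convergent barrier pairs as BED6."""
    barriers = spec.barriers()
    write_barriers(barriers, path)
    return barriers


def make_stripe_annotation(
    spec: ToySystemSpec, path: str | Path, width: int = 20_000
) -> None:
    """Stripe BED around each barrier: '+' barriers anchor horizontal
    stripes (rows), '-' barriers vertical ones (columns)."""
    with open(path, "w") as fh:
        for b in spec.barriers():
            orient = "h" if b.blocking == "+" else "v"
            start = max(0, b.position - width // 2)
            fh.write(f"{b.chrom}\t{start}\t{b.position + width // 2}\t{orient}\n")


def make_reference_matrix(
    spec: ToySystemSpec,
    path: str | Path,
    config: SimulationConfig | None = None,
    sidecar: str | Path | None = None,
):
    """Run the engine at the spec's known parameters and write a cooler.

    The sidecar JSON records the generating parameters, so recovery
    experiments can compare optimizer output against the ground truth.
    """
    if config is None:
        config = SimulationConfig(seed=spec.seed)
    result = run_simulation(spec.chromosomes, spec.barriers(), config)
    result.write_cooler(path)
    meta = {
        "spec": asdict(spec),
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "total_contacts": result.report["total_contacts"],
    }
    sidecar = Path(sidecar) if sidecar else Path(str(path) + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, default=str))
    return result


def make_toy_binary_matrices(
    case: str, band_rows: int = 10, nbins: int = 50, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Golden binary band-matrix pairs for the scoring tools.

    Cases: ``identity`` (expected dissimilarity 0 everywhere), ``one-row-flip``
    (exactly one row's stripe end moved), ``random`` (a random pair, with
    expectations computed by per-vector enumeration).
    """
    rng = np.random.default_rng(seed)
    ref = (rng.random((band_rows, nbins)) < 0.3).astype(np.uint8)
    if case == "identity":
        tgt = ref.copy()
        expected = {"row_mismatches": 0}
    elif case == "one-row-flip":
        tgt = ref.copy()
        # move the stripe end of bin 5's row by force
        tgt[:, 5] = 0
        tgt[0, 5] = 1
        ref[:, 5] = 0
        ref[2, 5] = 1
        expected = {"row_mismatches": 1, "flipped_bin": 5}
    elif case == "random":
        tgt = (rng.random((band_rows, nbins)) < 0.3).astype(np.uint8)
        expected = {}
    else:
        raise ValueError(f"unknown case {case!r}")
    return ref, tgt, expected
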