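"""Genomic track outputs: LEF and barrier occupancy profiles.

Profiles are binned at 1 kbp by default and written as bedGraph (text) or
BigWig (when the output name ends in ``.bw``/``.bigwig`` and pyBigWig is
available).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .barriers import ExtrusionBarrier, normalized_occupancy
from .genome import Chromosome

__all__ = [
    "lef_occupancy_track",
    "barrier_occupancy_track",
    "write_track",
]


def lef_occupancy_track(
    raw_counts: np.ndarray, n_epochs: int, ncells: int
) -> np.ndarray:
    """Time-and-cell averaged extrusion-unit visits per bin.

    ``raw_counts`` is the per-bin tally of unit positions accumulated over
    every recorded epoch of every cell (as produced by
    ``run_simulation(record_tracks=True)``).
    """
    denom = max(n_epochs, 1)
    return np.asarray(raw_counts, dtype=float) / denom


def barrier_occupancy_track(
    barriers: Sequence[ExtrusionBarrier],
    chromosome: Chromosome,
    normalization_puu: float = 0.7,
    bin_size: int = 1_000,
) -> np.ndarray:
    """Per-bin barrier occupancy re-expressed at a reference P_UU.

    Each barrier's (occupancy, P_UU) is mapped to the occupancy an
    equivalent barrier with ``normalization_puu`` and the same P_BB would
    have, making barriers fitted with heterogeneous P_UU comparable. Bins
    holding several barriers take the maximum.
    """
    nbins = -(-chromosome.length // bin_size)
    out = np.zeros(nbins, dtype=float)
    for b in barriers:
        if b.chrom != chromosome.name:
            continue
        value = float(
            normalized_occupancy(b.occupancy, b.puu, reference_puu=normalization_puu)
        )
        idx = b.position // bin_size
        out[idx] = max(out[idx], value)
    return out


def write_track(
    path: str | Path,
    tracks: Mapping[str, np.ndarray],
    chromosomes: Sequence[Chromosome],
    bin_size: int,
) -> None:
    """Write per-chromosome binned values as bedGraph or BigWig."""
    path = Path(path)
    if path.suffix.lower() in (".bw", ".bigwig"):
        _write_bigwig(path, tracks, chromosomes, bin_size)
        return
    with open(path, "w") as fh:
        for chrom in chromosomes:
            values = tracks.get(chrom.name)
            if values is None:
                continue
            for i, v in enumerate(values):
                if v == 0:
                    continue
                start = i * bin_size
                end = min(start + bin_size, chrom.length)
                fh.write(f"{chrom.name}\t{start}\t{end}\t{v:.6g}\n")


def _write_bigwig(path, tracks, chromosomes, bin_size):
    import pyBigWig

    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(c.name, c.length) for c in chromosomes])
    for chrom in chromosomes:
        values = tracks.get(chrom.name)
        if values is None or not len(values):
            continue
        starts = np.arange(len(values), dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, chrom.length)
        bw.addEntries(
            [chrom.name] * len(values),
            starts.tolist(),
            ends=ends.tolist(),
            values=np.asarray(values, dtype=float).tolist(),
        )
    bw.close()
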