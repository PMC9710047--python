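"""The stochastic loop-extrusion engine.

A simulation instance ("cell") runs one chromosome. Each epoch:

1. inactive LEFs bind at uniformly drawn positions (both units collapsed,
   loop size 0);
2. extrusion units are indexed so they can be visited in genomic order;
3. a random subset of active LEFs registers contacts (one loop contact at
   the anchor pair, plus intra-TAD contacts drawn uniformly inside the loop);
4. candidate strides are drawn from a truncated normal per unit;
5. every barrier advances its two-state Markov chain;
6./7. LEF-barrier and LEF-LEF collisions truncate the candidate moves;
8. units advance to the resolved positions;
9. each LEF is released by a Bernoulli trial with probability
   ``2 * mean_stride / processivity`` (divided by the hard-stall multiplier
   when both units are stalled by a convergent bound barrier pair).

A burn-in phase (contact sampling off, LEFs bound progressively) runs first,
until the windowed mean loop size stops growing.

Collision semantics are those of a 1-bp micro-stepping process in which all
units advance simultaneously, never pass a bound blocking barrier or another
LEF's unit, and two approaching units end up adjacent, splitting the gap
(odd gap: the extra bp goes to the unit first in genomic order). The
resolver below computes the same outcome in closed form in a few sweeps
over the sorted units; the test suite checks the equivalence against an
explicit micro-stepping oracle.
"""

from __future__ import annotations

import math
import zlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit

from . import barriers as barriers_mod
from .barriers import ExtrusionBarrier, barrier_arrays, init_barrier_states
from .contacts import BandedContactMatrix, write_cooler
from .genome import Chromosome, GenomicInterval, SimulationConfig, n_lefs

__all__ = [
    "run_simulation",
    "SimulationResult",
    "index_units",
    "detect_and_resolve_collisions",
    "task_seed",
]

# stall codes
STALL_NONE = 0
STALL_BARRIER = 1
STALL_LEF = 2
STALL_BOUNDARY = 3


# ---------------------------------------------------------------------------
# collision resolution
# ---------------------------------------------------------------------------


@njit(cache=True)
def _resolve_sorted(p, d, lef, t, cap):  # pragma: no cover - exercised via wrapper
    """Closed-form equivalent of simultaneous 1-bp micro-stepping.

    ``p`` sorted unit positions, ``d`` +1 forward / -1 reverse, ``lef`` owner
    ids, ``t`` candidate targets already capped by boundaries and barriers,
    ``cap`` why the target was capped (0 stride, 1 barrier, 3 boundary).
    Returns final positions and stall codes.
    """
    m = p.size
    f = t.copy()
    stall = np.zeros(m, dtype=np.int8)

    # primary meetings of approaching different-LEF pairs: both stop
    # adjacent, splitting the gap (extra bp to the left unit)
    for k in range(m - 1):
        if d[k] == 1 and d[k + 1] == -1 and lef[k] != lef[k + 1] and t[k] >= t[k + 1]:
            g = p[k + 1] - p[k] - 1
            si = t[k] - p[k]
            sj = p[k + 1] - t[k + 1]
            a = (g + 1) // 2
            if g - sj > a:
                a = g - sj
            if a < 0:
                a = 0
            if a > si:
                a = si
            b = g - a
            if b < 0:
                b = 0
            if b > sj:
                b = sj
            f[k] = p[k] + a
            f[k + 1] = p[k + 1] - b

    # forward units queue up behind whatever is ahead of them
    for k in range(m - 2, -1, -1):
        if d[k] == 1:
            gap = 0 if lef[k] == lef[k + 1] else 1
            lim = f[k + 1] - gap
            v = f[k]
            if lim < v:
                v = lim
            if v < p[k]:
                v = p[k]
            f[k] = v

    # reverse units likewise, scanning the other way
    for k in range(1, m):
        if d[k] == -1:
            gap = 0 if lef[k] == lef[k - 1] else 1
            lim = f[k - 1] + gap
            v = f[k]
            if lim > v:
                v = lim
            if v > p[k]:
                v = p[k]
            f[k] = v

    for k in range(m):
        if d[k] == 1:
            disp = f[k] - p[k]
            want = t[k] - p[k]
        else:
            disp = p[k] - f[k]
            want = p[k] - t[k]
        if disp < want:
            stall[k] = STALL_LEF
        elif cap[k] != 0:
            stall[k] = cap[k]
    return f, stall


def index_units(
    rev_positions: np.ndarray, fwd_positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Stable rank orderings of reverse and forward units (ascending)."""
    rev_order = np.argsort(rev_positions, kind="stable")
    fwd_order = np.argsort(fwd_positions, kind="stable")
    return rev_order, fwd_order


def detect_and_resolve_collisions(
    rev_pos: np.ndarray,
    fwd_pos: np.ndarray,
    rev_stride: np.ndarray,
    fwd_stride: np.ndarray,
    chrom_length: int,
    barrier_pos: np.ndarray,
    barrier_blocks_reverse: np.ndarray,
    barrier_bound: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve one epoch of moves for ``n`` LEFs.

    Returns (new_rev, new_fwd, rev_stall, fwd_stall). Strides are candidate
    displacements in bp (reverse units move toward 0, forward units toward
    the chromosome end); bound blocking barriers stop a unit 1 bp short, and
    no two units of different LEFs may pass one another.
    """
    rev_pos = np.asarray(rev_pos, dtype=np.int64)
    fwd_pos = np.asarray(fwd_pos, dtype=np.int64)
    n = rev_pos.size
    if np.any(rev_pos > fwd_pos):
        raise ValueError("rev unit beyond fwd unit")

    # boundary-clipped targets
    rev_t = rev_pos - np.asarray(rev_stride, dtype=np.int64)
    fwd_t = fwd_pos + np.asarray(fwd_stride, dtype=np.int64)
    rev_cap = np.where(rev_t < 0, STALL_BOUNDARY, STALL_NONE).astype(np.int8)
    fwd_cap = np.where(fwd_t > chrom_length - 1, STALL_BOUNDARY, STALL_NONE).astype(
        np.int8
    )
    rev_t = np.maximum(rev_t, 0)
    fwd_t = np.minimum(fwd_t, chrom_length - 1)

    # barrier caps: first bound blocking barrier strictly beyond the unit
    barrier_pos = np.asarray(barrier_pos, dtype=np.int64)
    bound = np.asarray(barrier_bound, dtype=bool)
    blocks_rev = np.asarray(barrier_blocks_reverse, dtype=bool)
    b_rev = barrier_pos[bound & blocks_rev]  # '+' barriers, block reverse units
    b_fwd = barrier_pos[bound & ~blocks_rev]  # '-' barriers, block forward units

    if b_rev.size:
        idx = np.searchsorted(b_rev, rev_pos, side="left") - 1
        has = idx >= 0
        bp = b_rev[np.clip(idx, 0, None)]
        hit = has & (bp >= rev_t)
        rev_t = np.where(hit, bp + 1, rev_t)
        rev_cap = np.where(hit, STALL_BARRIER, rev_cap).astype(np.int8)
    if b_fwd.size:
        idx = np.searchsorted(b_fwd, fwd_pos, side="right")
        has = idx < b_fwd.size
        bp = b_fwd[np.clip(idx, None, b_fwd.size - 1)]
        hit = has & (bp <= fwd_t)
        fwd_t = np.where(hit, bp - 1, fwd_t)
        fwd_cap = np.where(hit, STALL_BARRIER, fwd_cap).astype(np.int8)

    # merge units into genomic rank order (stable tie-break by unit id,
    # reverse unit of a LEF before its forward unit)
    upos = np.concatenate([rev_pos, fwd_pos])
    udir = np.concatenate(
        [np.full(n, -1, dtype=np.int8), np.full(n, 1, dtype=np.int8)]
    )
    ulef = np.concatenate([np.arange(n), np.arange(n)]).astype(np.int64)
    uid = np.concatenate([2 * np.arange(n), 2 * np.arange(n) + 1])
    utgt = np.concatenate([rev_t, fwd_t])
    ucap = np.concatenate([rev_cap, fwd_cap])
    order = np.lexsort((uid, upos))

    f, stall = _resolve_sorted(
        upos[order], udir[order], ulef[order], utgt[order], ucap[order]
    )

    new_rev = np.empty(n, dtype=np.int64)
    new_fwd = np.empty(n, dtype=np.int64)
    rev_stall = np.empty(n, dtype=np.int8)
    fwd_stall = np.empty(n, dtype=np.int8)
    sorted_uid = uid[order]
    is_fwd = (sorted_uid % 2).astype(bool)
    lef_idx = sorted_uid // 2
    new_rev[lef_idx[~is_fwd]] = f[~is_fwd]
    rev_stall[lef_idx[~is_fwd]] = stall[~is_fwd]
    new_fwd[lef_idx[is_fwd]] = f[is_fwd]
    fwd_stall[lef_idx[is_fwd]] = stall[is_fwd]
    if np.any(new_rev > new_fwd):
        raise AssertionError("collision resolution produced crossed units")
    return new_rev, new_fwd, rev_stall, fwd_stall


# ---------------------------------------------------------------------------
# one simulation instance (chromosome x cell)
# ---------------------------------------------------------------------------


class _Instance:
    """Mutable state of one simulation instance."""

    def __init__(
        self,
        chrom_length: int,
        nlefs: int,
        barr: dict[str, np.ndarray],
        config: SimulationConfig,
        rng: np.random.Generator,
    ):
        self.L = int(chrom_length)
        self.n = int(nlefs)
        self.cfg = config
        self.rng = rng
        self.rev = np.zeros(self.n, dtype=np.int64)
        self.fwd = np.zeros(self.n, dtype=np.int64)
        self.active = np.zeros(self.n, dtype=bool)
        self.rev_stall = np.zeros(self.n, dtype=np.int8)
        self.fwd_stall = np.zeros(self.n, dtype=np.int8)
        self.b_pos = barr["position"]
        self.b_blocks_rev = barr["blocks_reverse"]
        self.b_puu = barr["puu"]
        self.b_pbb = barr["pbb"]
        self.b_state = init_barrier_states(barr["occupancy"], rng)
        self.release_p = min(1.0, 2.0 * config.mean_stride / config.processivity)

    # individual epoch steps -------------------------------------------------

    def bind(self, max_bind: int | None = None) -> None:
        inactive = np.flatnonzero(~self.active)
        if max_bind is not None:
            inactive = inactive[:max_bind]
        if inactive.size == 0:
            return
        pos = self.rng.integers(0, self.L, inactive.size)
        self.rev[inactive] = pos
        self.fwd[inactive] = pos
        self.rev_stall[inactive] = STALL_NONE
        self.fwd_stall[inactive] = STALL_NONE
        self.active[inactive] = True

    def sample_contacts(
        self, matrix: BandedContactMatrix, mode: str = "all"
    ) -> int:
        """Register contacts for a random subset of active LEFs; returns # stored."""
        act = np.flatnonzero(self.active)
        if act.size == 0:
            return 0
        sampled = act[self.rng.random(act.size) < self.cfg.contact_sampling_fraction]
        if sampled.size == 0:
            return 0
        stored = 0
        if mode in ("all", "loop-only"):
            stored += matrix.add_pairs(self.rev[sampled], self.fwd[sampled])
        if mode in ("all", "tad-only"):
            ratio = self.cfg.tad_to_loop_contact_ratio
            whole = int(math.floor(ratio))
            ntad = np.full(sampled.size, whole, dtype=np.int64)
            frac = ratio - whole
            if frac > 0:
                ntad += self.rng.random(sampled.size) < frac
            keep = ntad > 0
            if np.any(keep):
                lo = np.repeat(self.rev[sampled][keep], ntad[keep])
                hi = np.repeat(self.fwd[sampled][keep], ntad[keep])
                u = self.rng.integers(lo, hi + 1)
                v = self.rng.integers(lo, hi + 1)
                stored += matrix.add_pairs(u, v)
        return stored

    def generate_moves(self, count: int) -> np.ndarray:
        """Candidate strides: truncated normal, rounded to integer bp."""
        cfg = self.cfg
        sd = cfg.stride_sd_fraction * cfg.mean_stride
        strides = self.rng.normal(cfg.mean_stride, sd, count)
        return np.rint(np.maximum(strides, 0.0)).astype(np.int64)

    def step_barriers(self) -> None:
        if self.b_pos.size:
            self.b_state = barriers_mod.step_barrier_states(
                self.b_state, self.b_puu, self.b_pbb, self.rng
            )

    def extrude(self) -> None:
        act = np.flatnonzero(self.active)
        if act.size == 0:
            return
        strides = self.generate_moves(2 * act.size)
        new_rev, new_fwd, rstall, fstall = detect_and_resolve_collisions(
            self.rev[act],
            self.fwd[act],
            strides[: act.size],
            strides[act.size :],
            self.L,
            self.b_pos,
            self.b_blocks_rev,
            self.b_state,
        )
        self.rev[act] = new_rev
        self.fwd[act] = new_fwd
        self.rev_stall[act] = rstall
        self.fwd_stall[act] = fstall

    def release(self) -> int:
        act = np.flatnonzero(self.active)
        if act.size == 0 or self.release_p <= 0:
            return 0
        hard = (self.rev_stall[act] == STALL_BARRIER) & (
            self.fwd_stall[act] == STALL_BARRIER
        )
        p = np.where(
            hard, self.release_p / self.cfg.hard_stall_lifetime_multiplier,
            self.release_p,
        )
        released = act[self.rng.random(act.size) < p]
        self.active[released] = False
        return released.size

    def mean_loop_size(self) -> float:
        act = self.active
        if not np.any(act):
            return 0.0
        return float(np.mean(self.fwd[act] - self.rev[act]))

    # epoch / phases ---------------------------------------------------------

    def epoch(
        self,
        matrix: BandedContactMatrix | None = None,
        mode: str = "all",
        max_bind: int | None = None,
        track: np.ndarray | None = None,
        track_bin_size: int = 1_000,
    ) -> int:
        self.bind(max_bind)
        stored = 0
        if matrix is not None:
            stored = self.sample_contacts(matrix, mode)
        self.step_barriers()
        self.extrude()
        if track is not None:
            act = np.flatnonzero(self.active)
            np.add.at(track, self.rev[act] // track_bin_size, 1)
            np.add.at(track, self.fwd[act] // track_bin_size, 1)
        self.release()
        return stored

    def burn_in(self) -> int:
        """Contact-free warm-up until the windowed mean loop size stops growing."""
        cfg = self.cfg
        if self.n == 0:
            return 0
        lifetime = cfg.mean_lifetime_epochs
        if not math.isfinite(lifetime) or lifetime < 1:
            lifetime = 1.0
        bind_per_epoch = max(1, math.ceil(self.n / math.ceil(lifetime)))
        binding_done = math.ceil(self.n / bind_per_epoch)
        window = cfg.burn_in_window
        history: list[float] = []
        epochs = 0
        while epochs < cfg.burn_in_max_epochs:
            self.epoch(matrix=None, max_bind=bind_per_epoch)
            epochs += 1
            history.append(self.mean_loop_size())
            if epochs >= binding_done + 2 * window:
                m1 = float(np.mean(history[-window:]))
                m0 = float(np.mean(history[-2 * window : -window]))
                if m1 - m0 <= cfg.burn_in_tolerance * max(m0, 1.0):
                    break
        return epochs


# ---------------------------------------------------------------------------
# task scheduling and the public entry point
# ---------------------------------------------------------------------------


def task_seed(master_seed: int, chrom_name: str, cell: int) -> np.random.SeedSequence:
    """Per-task seed: a pure function of (master seed, chromosome, cell)."""
    return np.random.SeedSequence(
        [int(master_seed) & 0x7FFFFFFF, zlib.crc32(chrom_name.encode()), int(cell)]
    )


@dataclass
class Task:
    """All information needed to simulate one chromosome in one cell."""

    chrom: Chromosome
    cell: int
    seed: np.random.SeedSequence
    target_contacts: int | None
    target_epochs: int | None


@dataclass
class SimulationResult:
    """Aggregated output of a simulation run."""

    chromosomes: list[Chromosome]
    config: SimulationConfig
    matrices: dict[str, BandedContactMatrix]
    report: dict
    lef_tracks: dict[str, np.ndarray] | None = None
    track_bin_size: int = 1_000

    def write_cooler(self, path: str | Path) -> None:
        write_cooler(path, self.chromosomes, self.matrices, self.config.bin_size)

    def mean_contact_density(self) -> float:
        total = sum(m.total for m in self.matrices.values())
        pixels = sum(m.band_pixels for m in self.matrices.values())
        return total / pixels


def _simulate_cells(
    chrom: Chromosome,
    barr: dict[str, np.ndarray],
    config: SimulationConfig,
    cells: Sequence[int],
    contact_mode: str,
    record_tracks: bool,
    track_bin_size: int,
) -> tuple[np.ndarray, int, int, int, np.ndarray | None]:
    """Run a batch of cells for one chromosome; returns partial aggregates."""
    matrix = BandedContactMatrix(chrom.length, config.bin_size, config.diagonal_width)
    nlefs = n_lefs(chrom, config.lef_density)
    if config.target_contact_density is not None:
        cell_target = math.ceil(
            matrix.band_pixels * config.target_contact_density / config.ncells
        )
        cell_epochs = None
    else:
        cell_target = None
        cell_epochs = config.target_epochs
    track = (
        np.zeros(-(-chrom.length // track_bin_size), dtype=np.int64)
        if record_tracks
        else None
    )
    total_epochs = 0
    burn_in_epochs = 0
    for cell in cells:
        rng = np.random.default_rng(task_seed(config.seed, chrom.name, cell))
        inst = _Instance(chrom.length, nlefs, barr, config, rng)
        burn_in_epochs += inst.burn_in()
        registered = 0
        epochs = 0
        # generous cap: the run is governed by the density/epoch rule
        if cell_epochs is not None:
            hard_cap = cell_epochs
        else:
            expected_rate = max(
                nlefs * config.contact_sampling_fraction
                * (1.0 + config.tad_to_loop_contact_ratio),
                1e-9,
            )
            hard_cap = int(50 * cell_target / expected_rate) + 10_000
        while epochs < hard_cap:
            registered += inst.epoch(
                matrix=matrix,
                mode=contact_mode,
                track=track,
                track_bin_size=track_bin_size,
            )
            epochs += 1
            if cell_target is not None and registered >= cell_target:
                break
        total_epochs += epochs
    return matrix.counts, matrix.discards, total_epochs, burn_in_epochs, track


def _run_batch(args):
    return _simulate_cells(*args)


def run_simulation(
    chromosomes: Sequence[Chromosome],
    barriers: Sequence[ExtrusionBarrier],
    config: SimulationConfig,
    *,
    contact_mode: str = "all",
    workers: int = 1,
    record_tracks: bool = False,
    track_bin_size: int = 1_000,
    deleted_regions: Sequence[GenomicInterval] | None = None,
) -> SimulationResult:
    """Simulate loop-extrusion contacts genome-wide.

    One banded matrix per chromosome aggregates all ``config.ncells``
    instances. ``deleted_regions`` sets the occupancy of overlapped barriers
    to 0 (in-silico border deletion). Results are independent of ``workers``.
    """
    if not chromosomes:
        raise ValueError("no chromosomes to simulate")
    if contact_mode not in ("all", "loop-only", "tad-only"):
        raise ValueError(f"unknown contact mode {contact_mode!r}")
    names = {c.name for c in chromosomes}
    for b in barriers:
        if b.chrom not in names:
            raise ValueError(
                f"barrier at {b.chrom}:{b.position} is not on a simulated chromosome"
            )
    if deleted_regions:
        barriers = [
            b.with_params(occupancy=0.0)
            if any(r.contains(b.chrom, b.position) for r in deleted_regions)
            else b
            for b in barriers
        ]

    per_chrom_barriers = {
        c.name: barrier_arrays([b for b in barriers if b.chrom == c.name])
        for c in chromosomes
    }

    batches = []
    cells = np.arange(config.ncells)
    nsplit = 1 if workers <= 1 else min(workers * 4, config.ncells)
    for chrom in chromosomes:
        for chunk in np.array_split(cells, nsplit):
            if chunk.size:
                batches.append(
                    (
                        chrom,
                        per_chrom_barriers[chrom.name],
                        config,
                        chunk.tolist(),
                        contact_mode,
                        record_tracks,
                        track_bin_size,
                    )
                )

    matrices = {
        c.name: BandedContactMatrix(c.length, config.bin_size, config.diagonal_width)
        for c in chromosomes
    }
    tracks = (
        {
            c.name: np.zeros(-(-c.length // track_bin_size), dtype=np.int64)
            for c in chromosomes
        }
        if record_tracks
        else None
    )
    total_epochs = 0
    total_burn_in = 0

    if workers <= 1:
        results = map(_run_batch, batches)
    else:
        pool = ProcessPoolExecutor(max_workers=workers)
        results = pool.map(_run_batch, batches)
    for batch, (counts, discards, epochs, burn_in, track) in zip(batches, results):
        chrom = batch[0]
        matrices[chrom.name].counts += counts
        matrices[chrom.name].discards += discards
        total_epochs += epochs
        total_burn_in += burn_in
        if tracks is not None and track is not None:
            tracks[chrom.name] += track
    if workers > 1:
        pool.shutdown()

    total = sum(m.total for m in matrices.values())
    report = {
        "total_contacts": total,
        "total_discards": sum(m.discards for m in matrices.values()),
        "total_epochs": total_epochs,
        "burn_in_epochs": total_burn_in,
        "mean_contact_density": total
        / sum(m.band_pixels for m in matrices.values()),
        "ncells": config.ncells,
        "n_barriers": len(barriers),
        "contact_mode": contact_mode,
        "seed": config.seed,
    }
    return SimulationResult(
        chromosomes=list(chromosomes),
        config=config,
        matrices=matrices,
        report=report,
        lef_tracks=tracks,
        track_bin_size=track_bin_size,
    )
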