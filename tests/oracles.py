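"""Independent brute-force oracles used by the test suite.

The micro-stepping resolver advances every extrusion unit 1 bp at a time
(units visited in genomic rank order each sweep, budget spent only on actual
movement) and is the definitional semantics for collision resolution; the
engine's closed-form resolver must reproduce it exactly.
"""

from __future__ import annotations

import numpy as np

STALL_NONE = 0
STALL_BARRIER = 1
STALL_LEF = 2
STALL_BOUNDARY = 3


def micro_step_resolve(
    rev_pos,
    fwd_pos,
    rev_stride,
    fwd_stride,
    chrom_length,
    barrier_pos,
    barrier_blocks_reverse,
    barrier_bound,
):
    """1-bp micro-stepping reference for one epoch of extrusion.

    Same signature and return convention as
    ``loopsim.engine.detect_and_resolve_collisions``.
    """
    rev_pos = np.asarray(rev_pos, dtype=np.int64)
    fwd_pos = np.asarray(fwd_pos, dtype=np.int64)
    n = rev_pos.size
    pos = np.concatenate([rev_pos, fwd_pos]).astype(np.int64)
    dirs = np.concatenate([np.full(n, -1), np.full(n, 1)])
    lef = np.concatenate([np.arange(n), np.arange(n)])
    uid = np.concatenate([2 * np.arange(n), 2 * np.arange(n) + 1])
    budget = np.concatenate(
        [np.asarray(rev_stride, dtype=np.int64), np.asarray(fwd_stride, dtype=np.int64)]
    ).copy()
    order = np.lexsort((uid, pos))
    pos, dirs, lef, uid, budget = (
        pos[order],
        dirs[order],
        lef[order],
        uid[order],
        budget[order],
    )
    m = pos.size

    bpos = np.asarray(barrier_pos, dtype=np.int64)
    bound = np.asarray(barrier_bound, dtype=bool)
    blocks_rev = np.asarray(barrier_blocks_reverse, dtype=bool)
    block_rev_set = set(bpos[bound & blocks_rev].tolist())
    block_fwd_set = set(bpos[bound & ~blocks_rev].tolist())

    def blocked_reason(k):
        """Why unit k cannot take its next 1-bp step (None if it can)."""
        nxt = pos[k] + dirs[k]
        if nxt < 0 or nxt > chrom_length - 1:
            return STALL_BOUNDARY
        if dirs[k] == 1 and nxt in block_fwd_set:
            return STALL_BARRIER
        if dirs[k] == -1 and nxt in block_rev_set:
            return STALL_BARRIER
        if dirs[k] == 1 and k < m - 1:
            gap = 0 if lef[k] == lef[k + 1] else 1
            if nxt > pos[k + 1] - gap:
                return STALL_LEF
        if dirs[k] == -1 and k > 0:
            gap = 0 if lef[k] == lef[k - 1] else 1
            if nxt < pos[k - 1] + gap:
                return STALL_LEF
        return None

    moving = True
    while moving:
        moving = False
        for k in range(m):
            if budget[k] <= 0:
                continue
            if blocked_reason(k) is None:
                pos[k] += dirs[k]
                budget[k] -= 1
                moving = True

    stall = np.zeros(m, dtype=np.int8)
    for k in range(m):
        if budget[k] > 0:
            reason = blocked_reason(k)
            assert reason is not None
            stall[k] = reason

    new_rev = np.empty(n, dtype=np.int64)
    new_fwd = np.empty(n, dtype=np.int64)
    rev_stall = np.empty(n, dtype=np.int8)
    fwd_stall = np.empty(n, dtype=np.int8)
    for k in range(m):
        i, is_fwd = uid[k] // 2, uid[k] % 2
        if is_fwd:
            new_fwd[i] = pos[k]
            fwd_stall[i] = stall[k]
        else:
            new_rev[i] = pos[k]
            rev_stall[i] = stall[k]
    return new_rev, new_fwd, rev_stall, fwd_stall


def random_system(rng, chrom_length=100_000, max_lefs=10, max_barriers=10):
    """A random small extrusion system for oracle-equivalence testing."""
    n = int(rng.integers(1, max_lefs + 1))
    rev = rng.integers(0, chrom_length, n)
    fwd = rev + rng.integers(0, np.maximum(chrom_length - rev, 1))
    fwd = np.minimum(fwd, chrom_length - 1)
    strides = rng.integers(0, 15_000, 2 * n)
    nb = int(rng.integers(0, max_barriers + 1))
    bpos = np.sort(rng.choice(chrom_length, size=nb, replace=False)) if nb else np.array([], dtype=np.int64)
    blocks_rev = rng.random(nb) < 0.5
    bound = rng.random(nb) < 0.7
    return (
        rev.astype(np.int64),
        fwd.astype(np.int64),
        strides[:n],
        strides[n:],
        chrom_length,
        bpos.astype(np.int64),
        blocks_rev,
        bound,
    )
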