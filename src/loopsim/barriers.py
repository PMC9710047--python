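"""Two-state Markov model of extrusion barriers (CTCF sites).

A barrier is either Bound or Unbound. The chain is parameterized by the two
self-transition probabilities ``P_UU`` and ``P_BB``; its stationary Bound
probability is the barrier occupancy

    pi_B = (1 - P_UU) / ((1 - P_UU) + (1 - P_BB)).

Users typically specify the occupancy directly (BED score field or a uniform
value), and ``P_BB`` is derived from (pi_B, P_UU). Only Bound barriers block
extrusion units approaching from their blocking direction; Unbound barriers
are fully transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ExtrusionBarrier",
    "occupancy_to_pbb",
    "stationary_occupancy",
    "feasible_occupancy_range",
    "step_barrier_states",
    "init_barrier_states",
    "occupancy_from_chipseq",
    "normalized_occupancy",
]

#: strand convention: '+' barriers (motif 5'->3') block reverse-moving units,
#: '-' barriers block forward-moving units. Loops between a convergent
#: '+' ... '-' pair are therefore stalled on both sides.
BLOCK_REVERSE = "+"
BLOCK_FORWARD = "-"


def feasible_occupancy_range(puu: float) -> tuple[float, float]:
    """Occupancy interval for which a valid P_BB exists at the given P_UU.

    P_BB = 1 - (1 - P_UU)(1 - pi)/pi must lie in [0, 1], which holds iff
    pi >= (1 - P_UU) / (2 - P_UU).
    """
    return ((1.0 - puu) / (2.0 - puu), 1.0)


def occupancy_to_pbb(occupancy: float, puu: float, clamp: bool = False) -> float:
    """Bound self-transition probability from (occupancy, P_UU).

    With ``clamp=True`` an infeasible pair is clamped to P_BB = 0 (its
    realized stationary occupancy is then larger than requested); otherwise
    infeasible pairs raise ``ValueError`` naming the feasible range.
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError(f"occupancy must be in [0, 1], got {occupancy}")
    if not (0.0 <= puu <= 1.0):
        raise ValueError(f"P_UU must be in [0, 1], got {puu}")
    if occupancy == 0.0:
        # the chain is never Bound; P_BB is irrelevant
        return 0.0
    if occupancy == 1.0:
        return 1.0
    pbb = 1.0 - (1.0 - puu) * (1.0 - occupancy) / occupancy
    if pbb < 0.0:
        if clamp:
            return 0.0
        lo, hi = feasible_occupancy_range(puu)
        raise ValueError(
            f"(occupancy={occupancy}, P_UU={puu}) is infeasible: P_BB={pbb:.6g} < 0; "
            f"at this P_UU the occupancy must lie in [{lo:.6g}, {hi:.6g}]"
        )
    return pbb


def stationary_occupancy(puu: float, pbb: float) -> float:
    """Stationary Bound probability of the (P_UU, P_BB) chain."""
    if not (0.0 <= puu <= 1.0 and 0.0 <= pbb <= 1.0):
        raise ValueError("transition probabilities must be in [0, 1]")
    denom = (1.0 - puu) + (1.0 - pbb)
    if denom == 0.0:
        raise ValueError(
            "P_UU = P_BB = 1: both states are absorbing, "
            "the stationary distribution is undefined"
        )
    return (1.0 - puu) / denom


@dataclass(frozen=True)
class ExtrusionBarrier:
    """An extrusion barrier: position, blocking direction, chain parameters.

    ``blocking`` is the BED strand: '+' blocks reverse-moving (3'->5')
    extrusion units, '-' blocks forward-moving (5'->3') units.
    """

    chrom: str
    position: int
    blocking: str
    occupancy: float
    puu: float = 0.7

    def __post_init__(self) -> None:
        if self.blocking not in (BLOCK_REVERSE, BLOCK_FORWARD):
            raise ValueError(
                f"blocking direction must be '+' or '-', got {self.blocking!r}"
            )
        if self.position < 0:
            raise ValueError(f"barrier position must be >= 0, got {self.position}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy must be in [0, 1], got {self.occupancy}")
        if not (0.0 <= self.puu <= 1.0):
            raise ValueError(f"P_UU must be in [0, 1], got {self.puu}")

    @property
    def pbb(self) -> float:
        """Bound self-transition probability (clamped to feasibility).

        Stochastic-simulation contexts (e.g. optimizer-proposed genotypes)
        may request infeasible (occupancy, P_UU) pairs; the chain then runs
        with P_BB = 0. Use :func:`occupancy_to_pbb` for strict algebra.
        """
        return occupancy_to_pbb(self.occupancy, self.puu, clamp=True)

    def with_params(self, occupancy: float | None = None, puu: float | None = None):
        kwargs = {}
        if occupancy is not None:
            kwargs["occupancy"] = occupancy
        if puu is not None:
            kwargs["puu"] = puu
        return replace(self, **kwargs)


def init_barrier_states(
    occupancies: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Initial Bound/Unbound states: one Bernoulli(occupancy) draw per barrier."""
    occupancies = np.asarray(occupancies, dtype=float)
    return rng.random(occupancies.shape) < occupancies


def step_barrier_states(
    states: np.ndarray,
    puu: np.ndarray,
    pbb: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Markov-chain step for every barrier (True = Bound).

    Bound barriers stay Bound with probability P_BB; Unbound stay Unbound
    with probability P_UU.
    """
    u = rng.random(states.shape)
    stay = np.where(states, pbb, puu)
    return np.where(u < stay, states, ~states)


def normalized_occupancy(
    occupancy: float | np.ndarray,
    puu: float | np.ndarray,
    reference_puu: float = 0.7,
) -> float | np.ndarray:
    """Re-express occupancy at a reference P_UU, keeping P_BB fixed.

    Barriers fitted with different P_UU are not directly comparable by
    occupancy alone; mapping each (pi_B, P_UU) to the occupancy an
    equivalent barrier with ``reference_puu`` and the same P_BB would have
    puts them on a common scale (used for barrier-occupancy profile tracks).
    """
    occ = np.asarray(occupancy, dtype=float)
    puu_arr = np.broadcast_to(np.asarray(puu, dtype=float), occ.shape)
    out = np.zeros_like(occ)
    nz = occ > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pbb = 1.0 - (1.0 - puu_arr) * (1.0 - occ) / np.where(nz, occ, 1.0)
    pbb = np.clip(pbb, 0.0, 1.0)
    denom = (1.0 - reference_puu) + (1.0 - pbb)
    out[nz] = (1.0 - reference_puu) / denom[nz]
    # occupancy 1 maps to 1 for any reference
    out[occ >= 1.0] = 1.0
    if np.isscalar(occupancy):
        return float(out)
    return out


def occupancy_from_chipseq(
    signal: np.ndarray,
    signal_bin_size: int,
    out_bin_size: int = 1_000,
    logistic_midpoint: float = 1.0,
    logistic_steepness: float = 2.0,
    max_occupancy: float = 0.9,
) -> np.ndarray:
    """Map a ChIP-seq fold-change track to per-bin barrier occupancies.

    The signal (e.g. RAD21 fold-change over control, uniform bins of
    ``signal_bin_size`` bp) is averaged into ``out_bin_size`` bins and passed
    through a logistic function::

        occupancy(x) = max_occupancy / (1 + exp(-steepness * (x - midpoint)))

    Values are in [0, max_occupancy]; negative signal raises ``ValueError``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-dimensional")
    if np.any(signal < 0):
        raise ValueError("ChIP-seq signal must be non-negative")
    if out_bin_size % signal_bin_size != 0:
        raise ValueError(
            f"out_bin_size {out_bin_size} must be a multiple of "
            f"signal_bin_size {signal_bin_size}"
        )
    ratio = out_bin_size // signal_bin_size
    nbins = int(np.ceil(signal.size / ratio))
    padded = np.full(nbins * ratio, np.nan)
    padded[: signal.size] = signal
    with np.errstate(invalid="ignore"):
        binned = np.nanmean(padded.reshape(nbins, ratio), axis=1)
    return max_occupancy / (
        1.0 + np.exp(-logistic_steepness * (binned - logistic_midpoint))
    )


def barrier_arrays(barriers: Sequence[ExtrusionBarrier]) -> dict[str, np.ndarray]:
    """Column-oriented view of a barrier list (positions sorted ascending)."""
    order = np.argsort([b.position for b in barriers], kind="stable")
    return {
        "position": np.array([barriers[i].position for i in order], dtype=np.int64),
        "blocks_reverse": np.array(
            [barriers[i].blocking == BLOCK_REVERSE for i in order], dtype=bool
        ),
        "occupancy": np.array([barriers[i].occupancy for i in order], dtype=float),
        "puu": np.array([barriers[i].puu for i in order], dtype=float),
        "pbb": np.array([barriers[i].pbb for i in order], dtype=float),
    }
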