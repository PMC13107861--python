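"""Metropolis–Hastings simulated annealing of the bead chain.

The chain starts as a self-avoiding unit-step lattice walk inside a cubic
box of side 5*l (l = bead count).  At each temperature the sampler runs
single-bead moves until equilibrium — an average of 10 accepted moves per
bead, or 100 attempts per bead — then cools geometrically,
T_c = T0 * alpha^c.  Three schedule variants:

* ``standard``: T0 = 10, alpha = 0.9, stops at a temperature floor (or a
  round with zero accepted moves);
* ``coarse``:   same cooling, stops after three consecutive rounds with no
  accepted moves (used as the stage-1 schedule for very high-resolution
  targets);
* ``fast``:     alpha = 0.6, stops when the temperature reaches 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .imputation import ThetaMatrix
from .io_contacts import GenomeBinning, Structure
from .loss import LossParams, total_loss

__all__ = [
    "CoolingSchedule",
    "AnnealState",
    "AnnealResult",
    "initialize_structure",
    "propose_move",
    "metropolis_accept",
    "metropolis_step",
    "next_temperature",
    "anneal",
]


@dataclass(frozen=True)
class CoolingSchedule:
    """Geometric cooling T_c = T0 * alpha^c with per-variant stopping."""

    variant: str = "standard"
    T0: float = 10.0
    alpha: float = 0.9
    T_min: float = 0.1
    equilibrium_accepts_per_bead: int = 10
    equilibrium_max_attempts_per_bead: int = 100
    coarse_stop_rounds: int = 3
    T_floor: float = 1e-3
    max_cooling_steps: int = 200  # runtime safety bound
    step_size: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in ("standard", "coarse", "fast"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.T0 <= 0:
            raise ValueError("T0 must be > 0")

    @classmethod
    def standard(cls, **kw) -> "CoolingSchedule":
        return cls(variant="standard", alpha=kw.pop("alpha", 0.9), **kw)

    @classmethod
    def coarse(cls, **kw) -> "CoolingSchedule":
        return cls(variant="coarse", alpha=kw.pop("alpha", 0.9), **kw)

    @classmethod
    def fast(cls, **kw) -> "CoolingSchedule":
        return cls(variant="fast", alpha=kw.pop("alpha", 0.6), **kw)


def next_temperature(schedule: CoolingSchedule, c: int) -> float:
    """Temperature after c cooling steps: T0 * alpha^c."""
    if c < 0:
        raise ValueError("c must be >= 0")
    return schedule.T0 * schedule.alpha**c


@dataclass
class AnnealState:
    """Mutable sampler state (one structure, one temperature)."""

    structure: Structure
    temperature: float
    cooling_step: int = 0
    accepted: int = 0
    attempted: int = 0


@dataclass
class AnnealResult:
    """Final structure plus the per-round trajectory.

    ``history`` rows are (cooling_step, temperature, accepted, attempted,
    loss-after-round)."""

    structure: Structure
    history: list[tuple[int, float, int, int, float]]
    cooling_steps: int

    @property
    def final_loss(self) -> float:
        return self.history[-1][4] if self.history else float("nan")

    @property
    def initial_loss(self) -> float:
        # loss before any move is not stored; first-round loss is the
        # closest tracked proxy
        return self.history[0][4] if self.history else float("nan")


def initialize_structure(
    binning: GenomeBinning,
    seed: int,
    box_side: Optional[float] = None,
    max_restarts: int = 50,
) -> Structure:
    """Random self-avoiding unit-step lattice walk for the whole genome
    chain, inside a cubic box of side 5*l (volume (5l)^3), started at a
    random in-box site.  Deterministic per seed."""
    l = binning.n_beads
    if l < 1:
        raise ValueError("binning has no beads")
    side = float(box_side) if box_side is not None else 5.0 * l
    rng = np.random.default_rng(seed)
    steps = np.array(
        [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
        dtype=np.int64,
    )
    hi = int(np.floor(side))
    for _ in range(max_restarts):
        start = rng.integers(0, hi + 1, size=3)
        occupied = {tuple(start)}
        coords = np.empty((l, 3), dtype=np.float64)
        coords[0] = start
        pos = start.copy()
        ok = True
        for b in range(1, l):
            placed = False
            for _try in range(64):
                s = steps[rng.integers(0, 6)]
                cand = pos + s
                t = (int(cand[0]), int(cand[1]), int(cand[2]))
                if t in occupied:
                    continue
                if not (0 <= cand[0] <= hi and 0 <= cand[1] <= hi and 0 <= cand[2] <= hi):
                    continue
                pos = cand
                occupied.add(t)
                coords[b] = pos
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return Structure(coords, binning, side)
    raise RuntimeError("self-avoiding walk failed after restarts (box too small?)")


def propose_move(
    state: AnnealState, rng: np.random.Generator, step_size: float = 1.0
) -> tuple[int, np.ndarray]:
    """Uniform bead choice and a uniform displacement over the 26 unit
    lattice neighbour offsets (scaled by step_size)."""
    n = state.structure.n_beads
    if n < 1:
        raise ValueError("structure is empty")
    b = int(rng.integers(0, n))
    off = _kernels.OFFSETS[int(rng.integers(0, 26))]
    return b, state.structure.coords[b] + step_size * off


def metropolis_accept(delta_e: float, temperature: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE/T))."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_e <= 0.0:
        return True
    return bool(rng.random() < np.exp(-delta_e / temperature))


def metropolis_step(
    state: AnnealState,
    theta: ThetaMatrix,
    params: LossParams,
    rng: np.random.Generator,
    step_size: float = 1.0,
) -> bool:
    """One proposal + Metropolis decision on the state (Python reference
    path; the annealing loop uses the compiled equivalent).  Out-of-box
    proposals are rejected and counted as attempts."""
    from .loss import delta_loss

    b, new_pos = propose_move(state, rng, step_size)
    state.attempted += 1
    s = state.structure
    if np.any(new_pos < 0.0) or np.any(new_pos > s.box_side):
        return False
    de = delta_loss(s, b, new_pos, theta, params)
    if metropolis_accept(de, state.temperature, rng):
        s.coords[b] = new_pos
        state.accepted += 1
        return True
    return False


def anneal(
    structure: Structure,
    theta: ThetaMatrix,
    params: LossParams,
    schedule: CoolingSchedule,
    seed: int,
    callback: Optional[Callable[[int, float, int, int, float], None]] = None,
) -> AnnealResult:
    """Run the cooling loop from the given starting structure.

    Within each temperature round the sampler steps until 10*l accepts or
    100*l attempts, then cools.  Termination: standard — temperature floor
    or a zero-accept round; coarse — three consecutive zero-accept rounds;
    fast — temperature reaches T_min.  Fully deterministic for a fixed
    (inputs, params, schedule, seed)."""
    from .loss import _check_shared_binning

    _check_shared_binning(structure, theta)
    coords = np.ascontiguousarray(structure.coords.copy(), dtype=np.float64)
    cid = structure.binning.chrom_id_array()
    indptr, nbr, nbrv = theta.attraction_csr(params.theta_threshold)
    l = structure.n_beads
    target_accepts = schedule.equilibrium_accepts_per_bead * l
    max_attempts = schedule.equilibrium_max_attempts_per_bead * l
    round_seeds = np.random.SeedSequence(int(seed)).generate_state(
        schedule.max_cooling_steps + 1
    )
    out = Structure(coords, structure.binning, structure.box_side)
    history: list[tuple[int, float, int, int, float]] = []
    c = 0
    zero_rounds = 0
    while True:
        T = next_temperature(schedule, c)
        acc, att = _kernels.run_round(
            coords, cid, indptr, nbr, nbrv, _kernels.OFFSETS,
            T, schedule.step_size, structure.box_side,
            target_accepts, max_attempts,
            params.d_target, params.theta_threshold,
            params.w1, params.w2, params.w3,
            params.d_repel, params.w_bb, params.c_ratio,
            int(round_seeds[c]) & 0x7FFFFFFF,
        )
        e = total_loss(out, theta, params)
        history.append((c, T, acc, att, e))
        if callback is not None:
            callback(c, T, acc, att, e)
        zero_rounds = zero_rounds + 1 if acc == 0 else 0
        c += 1
        T_next = next_temperature(schedule, c)
        if schedule.variant == "standard":
            if zero_rounds >= 1 or T_next < schedule.T_floor:
                break
        elif schedule.variant == "coarse":
            if zero_rounds >= schedule.coarse_stop_rounds:
                break
        else:  # fast
            if T_next <= schedule.T_min:
                break
        if c >= schedule.max_cooling_steps:
            break
    return AnnealResult(out, history, cooling_steps=c)
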