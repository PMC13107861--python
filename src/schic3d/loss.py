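"""The reconstruction objective over the theta matrix.

Every bead pair contributes one of three regimes depending on its imputed
contact probability theta (plus a shared excluded-volume term):

* theta = 1 (observed or imputed contact): ``w1 * max(0, d - d_target)^2``
  — the most stringent pull toward the target contact distance;
* 0.7 <= theta < 1: ``w2 * theta * max(0, d - d_target)^2`` — a weaker pull;
* theta < 0.7: ``w3 * max(0, d_target - d)^2`` — a weak repulsion that keeps
  non-contacting pairs from collapsing onto each other.

All pairs additionally feel excluded volume ``w1 * max(0, d_repel - d)^2``.
Intra-chromosomal pair terms are weighted by the balancing coefficient
C_ratio = 1 / (floor(count_intra / count_inter) + 1) and inter-chromosomal
terms by 1 - C_ratio, so the scarce inter-chromosomal contacts are not
drowned out.  A backbone term ties consecutive beads of each chromosome
chain together, and the cubic confinement box is enforced by rejecting
moves that leave it (total_loss reports an infinite value for a structure
outside the box).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .imputation import ThetaMatrix
from .io_contacts import Structure

__all__ = [
    "LossParams",
    "compute_ratio_coefficient",
    "pair_loss",
    "total_loss",
    "delta_loss",
    "partitioned_loss",
]


@dataclass(frozen=True)
class LossParams:
    """Objective parameters (distances in lattice units).

    ``d_target`` is the contact target distance, ``theta_threshold`` the
    regime-2/3 boundary, ``w1 >= w2 >= w3`` the regime weights (stringency
    ordering), ``d_repel`` the excluded-volume distance, ``w_bb`` the
    backbone weight, and ``c_ratio`` the intra/inter balancing coefficient.
    """

    d_target: float = 8.0
    theta_threshold: float = 0.7
    w1: float = 1.0
    w2: float = 0.5
    w3: float = 0.1
    d_repel: float = 1.0
    w_bb: float = 1.0
    c_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (self.w1 >= self.w2 >= self.w3 > 0):
            raise ValueError("require w1 >= w2 >= w3 > 0")
        if not (0.0 < self.theta_threshold < 1.0):
            raise ValueError("theta_threshold must be in (0, 1)")
        if not (self.d_target > self.d_repel > 0):
            raise ValueError("require d_target > d_repel > 0")
        if not (0.0 < self.c_ratio <= 1.0):
            raise ValueError("c_ratio must be in (0, 1]")

    def with_c_ratio(self, count_intra: int, count_inter: int) -> "LossParams":
        return replace(
            self, c_ratio=compute_ratio_coefficient(count_intra, count_inter)
        )


def compute_ratio_coefficient(count_intra: int, count_inter: int) -> float:
    """Balancing coefficient C_ratio = 1 / (floor(count1/count2) + 1).

    count1/count2 are genome-wide intra-/inter-chromosomal contact counts of
    the binary observed matrix.  With no inter-chromosomal contacts the
    balancing is moot and 1.0 is returned (all weight on intra terms).
    """
    if count_intra < 0 or count_inter < 0:
        raise ValueError("counts must be >= 0")
    if count_intra + count_inter == 0:
        raise ValueError("at least one contact count must be positive")
    if count_inter == 0:
        return 1.0
    return 1.0 / (count_intra // count_inter + 1)


def pair_loss(theta: float, d: float, params: LossParams = LossParams()) -> float:
    """Single-pair loss (three regimes + shared excluded volume), unweighted
    by the intra/inter balancing."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    out = 0.0
    if theta >= 1.0:
        h = max(0.0, d - params.d_target)
        out += params.w1 * h * h
    elif theta >= params.theta_threshold:
        h = max(0.0, d - params.d_target)
        out += params.w2 * theta * h * h
    else:
        h = max(0.0, params.d_target - d)
        out += params.w3 * h * h
    g = max(0.0, params.d_repel - d)
    out += params.w1 * g * g
    return out


def _check_shared_binning(structure: Structure, theta: ThetaMatrix) -> None:
    if theta.n_beads != structure.n_beads:
        raise ValueError("structure and theta bead counts differ")
    if theta.binning is not None and theta.binning != structure.binning:
        raise ValueError("structure and theta binnings differ")


def _in_box(structure: Structure) -> bool:
    c = structure.coords
    return bool(np.all(c >= 0.0) and np.all(c <= structure.box_side))


def total_loss(structure: Structure, theta: ThetaMatrix, params: LossParams = LossParams()) -> float:
    """Full objective: weighted pair sum + backbone; infinite outside the
    confinement box."""
    _check_shared_binning(structure, theta)
    if not _in_box(structure):
        return float("inf")
    coords = np.ascontiguousarray(structure.coords, dtype=np.float64)
    cid = structure.binning.chrom_id_array()
    n = structure.n_beads
    ti, tj, tv = theta.attraction_entries(params.theta_threshold)
    e = _kernels.background_energy(
        coords, cid, 0, n, params.d_target, params.d_repel,
        params.w1, params.w3, params.c_ratio,
    )
    e += _kernels.theta_correction_energy(
        coords, cid, ti, tj, tv, params.d_target, params.theta_threshold,
        params.w1, params.w2, params.w3, params.c_ratio,
    )
    e += _kernels.backbone_energy(coords, cid, 0, n, params.d_target, params.w_bb)
    return float(e)


def delta_loss(
    structure: Structure,
    bead: int,
    new_pos: Sequence[float],
    theta: ThetaMatrix,
    params: LossParams = LossParams(),
) -> float:
    """Energy difference of moving one bead, from only the terms involving
    it; equals the full-recompute difference to floating-point accuracy."""
    _check_shared_binning(structure, theta)
    if not (0 <= bead < structure.n_beads):
        raise ValueError("bead index out of range")
    x, y, z = (float(v) for v in new_pos)
    if not (
        0.0 <= x <= structure.box_side
        and 0.0 <= y <= structure.box_side
        and 0.0 <= z <= structure.box_side
    ):
        raise ValueError("new_pos outside the confinement box")
    coords = np.ascontiguousarray(structure.coords, dtype=np.float64)
    cid = structure.binning.chrom_id_array()
    indptr, nbr, nbrv = theta.attraction_csr(params.theta_threshold)
    return float(
        _kernels.delta_energy(
            coords, cid, bead, x, y, z, indptr, nbr, nbrv,
            params.d_target, params.theta_threshold,
            params.w1, params.w2, params.w3,
            params.d_repel, params.w_bb, params.c_ratio,
        )
    )


def partitioned_loss(
    structure: Structure,
    theta: ThetaMatrix,
    params: LossParams = LossParams(),
    n_parts: int = 1,
) -> float:
    """total_loss evaluated as independent partial sums over ``n_parts``
    contiguous bead blocks (each pair charged to the block of its lower
    index), then combined.  Matches the serial sum to summation-order
    accuracy — the determinism contract behind parallel evaluation."""
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    _check_shared_binning(structure, theta)
    if not _in_box(structure):
        return float("inf")
    n = structure.n_beads
    n_parts = min(n_parts, max(n, 1))
    coords = np.ascontiguousarray(structure.coords, dtype=np.float64)
    cid = structure.binning.chrom_id_array()
    ti, tj, tv = theta.attraction_entries(params.theta_threshold)
    bounds = np.linspace(0, n, n_parts + 1).astype(np.int64)
    block_of = np.searchsorted(bounds, ti, side="right") - 1 if ti.size else ti
    parts = []
    for k in range(n_parts):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        e = _kernels.background_energy(
            coords, cid, lo, hi, params.d_target, params.d_repel,
            params.w1, params.w3, params.c_ratio,
        )
        e += _kernels.backbone_energy(coords, cid, lo, hi, params.d_target, params.w_bb)
        if ti.size:
            m = block_of == k
            e += _kernels.theta_correction_energy(
                coords, cid, ti[m], tj[m], tv[m],
                params.d_target, params.theta_threshold,
                params.w1, params.w2, params.w3, params.c_ratio,
            )
        parts.append(e)
    return float(sum(parts))
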