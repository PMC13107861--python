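"""Numba kernels for the pair-loss energy and the annealing inner loop.

The energy over all bead pairs is evaluated as a short-ranged background
(weak repulsion toward the target distance plus excluded volume, which both
vanish beyond the target distance) corrected by explicit terms for the pairs
whose imputed contact probability reaches the attraction regimes.  This makes
the per-move energy difference O(l + degree) instead of O(l^2) while staying
algebraically identical to the full pair sum.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: the 26 unit lattice neighbour offsets (all nonzero {-1,0,1}^3 vectors)
OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.float64,
)


@njit(cache=True)
def _regime_term(theta, d, d_target, thr, w1, w2):
    """Attraction term for a pair in regime 1 (theta == 1) or 2 (thr <= theta < 1)."""
    h = d - d_target
    if h <= 0.0:
        return 0.0
    if theta >= 1.0:
        return w1 * h * h
    return w2 * theta * h * h


@njit(cache=True)
def background_energy(coords, chrom_id, lo, hi, d_target, d_repel, w1, w3, c_ratio):
    """Sum of the regime-3 repulsion + excluded volume over all pairs (i, j)
    with lo <= i < hi and i < j < l, weighted intra/inter."""
    n = coords.shape[0]
    dt2 = d_target * d_target
    total = 0.0
    for i in range(lo, hi):
        xi = coords[i, 0]
        yi = coords[i, 1]
        zi = coords[i, 2]
        ci = chrom_id[i]
        for j in range(i + 1, n):
            dx = coords[j, 0] - xi
            dy = coords[j, 1] - yi
            dz = coords[j, 2] - zi
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < dt2:
                d = math.sqrt(d2)
                h = d_target - d
                e = w3 * h * h
                if d < d_repel:
                    g = d_repel - d
                    e += w1 * g * g
                w = c_ratio if chrom_id[j] == ci else 1.0 - c_ratio
                total += w * e
    return total


@njit(cache=True)
def theta_correction_energy(
    coords, chrom_id, ti, tj, tv, d_target, thr, w1, w2, w3, c_ratio
):
    """For pairs with theta >= thr: replace the background repulsion by the
    regime-1/2 attraction (excluded volume is shared and stays)."""
    total = 0.0
    for k in range(ti.shape[0]):
        i = ti[k]
        j = tj[k]
        dx = coords[j, 0] - coords[i, 0]
        dy = coords[j, 1] - coords[i, 1]
        dz = coords[j, 2] - coords[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        e = _regime_term(tv[k], d, d_target, thr, w1, w2)
        if d < d_target:
            h = d_target - d
            e -= w3 * h * h
        w = c_ratio if chrom_id[i] == chrom_id[j] else 1.0 - c_ratio
        total += w * e
    return total


@njit(cache=True)
def backbone_energy(coords, chrom_id, lo, hi, d_target, w_bb):
    """Chain term over consecutive beads (i, i+1) of the same chromosome,
    for lo <= i < hi."""
    n = coords.shape[0]
    total = 0.0
    for i in range(lo, min(hi, n - 1)):
        if chrom_id[i] != chrom_id[i + 1]:
            continue
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        h = d - d_target
        if h > 0.0:
            total += w_bb * h * h
    return total


@njit(cache=True)
def delta_energy(
    coords,
    chrom_id,
    b,
    nx,
    ny,
    nz,
    indptr,
    nbr,
    nbr_theta,
    d_target,
    thr,
    w1,
    w2,
    w3,
    d_repel,
    w_bb,
    c_ratio,
):
    """Energy difference of moving bead b to (nx, ny, nz); exactly the
    difference of the full pair sums restricted to terms involving b."""
    n = coords.shape[0]
    ox = coords[b, 0]
    oy = coords[b, 1]
    oz = coords[b, 2]
    cb = chrom_id[b]
    dt2 = d_target * d_target
    de = 0.0
    for j in range(n):
        if j == b:
            continue
        xj = coords[j, 0]
        yj = coords[j, 1]
        zj = coords[j, 2]
        dxo = xj - ox
        dyo = yj - oy
        dzo = zj - oz
        d2o = dxo * dxo + dyo * dyo + dzo * dzo
        dxn = xj - nx
        dyn = yj - ny
        dzn = zj - nz
        d2n = dxn * dxn + dyn * dyn + dzn * dzn
        if d2o < dt2 or d2n < dt2:
            contrib = 0.0
            if d2n < dt2:
                dn = math.sqrt(d2n)
                h = d_target - dn
                contrib += w3 * h * h
                if dn < d_repel:
                    g = d_repel - dn
                    contrib += w1 * g * g
            if d2o < dt2:
                do = math.sqrt(d2o)
                h = d_target - do
                contrib -= w3 * h * h
                if do < d_repel:
                    g = d_repel - do
                    contrib -= w1 * g * g
            w = c_ratio if chrom_id[j] == cb else 1.0 - c_ratio
            de += w * contrib
    # regime-1/2 corrections on b's imputed neighbours
    for k in range(indptr[b], indptr[b + 1]):
        j = nbr[k]
        th = nbr_theta[k]
        xj = coords[j, 0]
        yj = coords[j, 1]
        zj = coords[j, 2]
        dxo = xj - ox
        dyo = yj - oy
        dzo = zj - oz
        do = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
        dxn = xj - nx
        dyn = yj - ny
        dzn = zj - nz
        dn = math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
        corr = _regime_term(th, dn, d_target, thr, w1, w2) - _regime_term(
            th, do, d_target, thr, w1, w2
        )
        if dn < d_target:
            h = d_target - dn
            corr -= w3 * h * h
        if do < d_target:
            h = d_target - do
            corr += w3 * h * h
        w = c_ratio if chrom_id[j] == cb else 1.0 - c_ratio
        de += w * corr
    # backbone neighbours
    for j in (b - 1, b + 1):
        if 0 <= j < n and chrom_id[j] == cb:
            xj = coords[j, 0]
            yj = coords[j, 1]
            zj = coords[j, 2]
            dxo = xj - ox
            dyo = yj - oy
            dzo = zj - oz
            do = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
            dxn = xj - nx
            dyn = yj - ny
            dzn = zj - nz
            dn = math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
            hn = dn - d_target
            ho = do - d_target
            if hn > 0.0:
                de += w_bb * hn * hn
            if ho > 0.0:
                de -= w_bb * ho * ho
    return de


@njit(cache=True)
def run_round(
    coords,
    chrom_id,
    indptr,
    nbr,
    nbr_theta,
    offsets,
    temperature,
    step,
    box_side,
    target_accepts,
    max_attempts,
    d_target,
    thr,
    w1,
    w2,
    w3,
    d_repel,
    w_bb,
    c_ratio,
    seed,
):
    """One equilibrium cycle at fixed temperature: Metropolis single-bead
    moves until ``target_accepts`` accepts or ``max_attempts`` attempts.
    Moves proposing coordinates outside [0, box_side] are rejected (and
    counted as attempts). Mutates coords in place; returns (accepts, attempts)."""
    np.random.seed(seed)
    n = coords.shape[0]
    accepts = 0
    attempts = 0
    n_off = offsets.shape[0]
    while accepts < target_accepts and attempts < max_attempts:
        attempts += 1
        b = int(np.random.random() * n)
        if b >= n:
            b = n - 1
        k = int(np.random.random() * n_off)
        if k >= n_off:
            k = n_off - 1
        nx = coords[b, 0] + step * offsets[k, 0]
        ny = coords[b, 1] + step * offsets[k, 1]
        nz = coords[b, 2] + step * offsets[k, 2]
        if (
            nx < 0.0
            or nx > box_side
            or ny < 0.0
            or ny > box_side
            or nz < 0.0
            or nz > box_side
        ):
            continue
        de = delta_energy(
            coords, chrom_id, b, nx, ny, nz, indptr, nbr, nbr_theta,
            d_target, thr, w1, w2, w3, d_repel, w_bb, c_ratio,
        )
        if de <= 0.0 or np.random.random() < math.exp(-de / temperature):
            coords[b, 0] = nx
            coords[b, 1] = ny
            coords[b, 2] = nz
            accepts += 1
    return accepts, attempts
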