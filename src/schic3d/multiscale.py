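"""Two-step coarse-to-fine structure generation.

A coarse structure is annealed at low resolution, its coordinates are
linearly scaled by 0.12 * (low_resolution / high_resolution), ratio - 1
equidistant beads are interpolated between each pair of adjacent beads of
the same chromosome chain, and the result seeds a second annealing stage at
the high resolution.  The coarse stage captures global chromatin folding;
the refinement stage optimizes local bead packing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annealing import AnnealResult, CoolingSchedule, anneal, initialize_structure
from .imputation import GaussianImputeParams, gaussian_impute
from .io_contacts import (
    BinaryContactMatrix,
    ContactRecord,
    GenomeBinning,
    Structure,
    bin_contacts,
)
from .loss import LossParams

__all__ = [
    "MultiscaleConfig",
    "TwoStepResult",
    "default_schedules",
    "scale_structure",
    "interpolate_beads",
    "two_step_build",
]


def default_schedules(high_resolution: int) -> tuple[CoolingSchedule, CoolingSchedule]:
    """Stage pairing: identical standard schedules for targets at or above
    0.5 Mbp; coarse stage-1 + fast stage-2 below (the very-high-resolution
    adaptation, where bead counts make open-ended cooling prohibitive)."""
    if high_resolution >= 500_000:
        return CoolingSchedule.standard(), CoolingSchedule.standard()
    return CoolingSchedule.coarse(), CoolingSchedule.fast()


@dataclass(frozen=True)
class MultiscaleConfig:
    """Resolutions (bp) and schedules of the two stages; the scaling factor
    applied between them is ``scale_constant * (low / high)``."""

    low_resolution: int
    high_resolution: int
    scale_constant: float = 0.12
    stage1_schedule: Optional[CoolingSchedule] = None
    stage2_schedule: Optional[CoolingSchedule] = None

    def __post_init__(self) -> None:
        if self.low_resolution <= 0 or self.high_resolution <= 0:
            raise ValueError("resolutions must be > 0")
        if self.low_resolution < self.high_resolution:
            raise ValueError("low_resolution must be >= high_resolution")
        if self.scale_constant <= 0:
            raise ValueError("scale_constant must be > 0")
        if self.low_resolution % self.high_resolution != 0:
            warnings.warn(
                "low_resolution is not a multiple of high_resolution; "
                "interpolation requires an integer ratio",
                stacklevel=2,
            )

    @property
    def ratio(self) -> int:
        if self.low_resolution % self.high_resolution != 0:
            raise ValueError(
                "low/high resolution ratio is not an integer; choose resolutions "
                "with low_resolution a multiple of high_resolution"
            )
        return self.low_resolution // self.high_resolution

    @property
    def scale_factor(self) -> float:
        return self.scale_constant * (self.low_resolution / self.high_resolution)

    def schedules(self) -> tuple[CoolingSchedule, CoolingSchedule]:
        s1, s2 = default_schedules(self.high_resolution)
        return self.stage1_schedule or s1, self.stage2_schedule or s2


def _high_binning(binning: GenomeBinning, high_resolution: int) -> GenomeBinning:
    return GenomeBinning(binning.chrom_order, high_resolution)


def scale_structure(structure: Structure, config: MultiscaleConfig) -> Structure:
    """Multiply all coordinates by the scale factor and recenter into the
    high-resolution box (side 5 * high-resolution bead count).  Pairwise
    distance ratios are preserved exactly."""
    if structure.n_beads == 0:
        raise ValueError("structure is empty")
    high = _high_binning(structure.binning, config.high_resolution)
    side = 5.0 * high.n_beads
    scaled = structure.coords * config.scale_factor
    center = scaled.mean(axis=0)
    scaled = scaled - center + side / 2.0
    return Structure(scaled, structure.binning, side)


def interpolate_beads(
    structure: Structure, config: MultiscaleConfig, high_binning: GenomeBinning
) -> Structure:
    """Insert ratio - 1 equidistant beads on each within-chromosome segment
    of the (scaled) low-resolution chain.

    No interpolation crosses a chromosome boundary.  Trailing high-res beads
    past the last low-res bead extend along the last segment direction at the
    established spacing.  Output bead count equals the high binning's.
    """
    r = config.ratio  # raises on non-integer ratio
    if r < 1:
        raise ValueError("resolution ratio must be >= 1")
    low = structure.binning
    if high_binning.chrom_order != low.chrom_order:
        raise ValueError("low/high binnings must cover the same chromosomes")
    out = np.empty((high_binning.n_beads, 3), dtype=np.float64)
    lo_off = 0
    hi_off = 0
    for k in range(len(low.chrom_order)):
        m = low.n_bins[k]
        nh = high_binning.n_bins[k]
        P = structure.coords[lo_off: lo_off + m]
        for t in range(nh):
            kk, frac = divmod(t, r)
            if kk + 1 < m:
                q = P[kk] + (frac / r) * (P[kk + 1] - P[kk])
            elif m >= 2:
                # extrapolate past the final low-res bead
                sub = (P[m - 1] - P[m - 2]) / r
                q = P[m - 1] + (t - (m - 1) * r) * sub
            else:
                q = P[0]
            out[hi_off + t] = q
        lo_off += m
        hi_off += nh
    np.clip(out, 0.0, structure.box_side, out=out)
    return Structure(out, high_binning, structure.box_side)


@dataclass
class TwoStepResult:
    """Products of the two-stage build (final structure in ``structure``)."""

    stage1: AnnealResult
    initial_high: Structure
    stage2: AnnealResult
    low_matrix: BinaryContactMatrix
    high_matrix: BinaryContactMatrix
    loss_params_low: LossParams
    loss_params_high: LossParams

    @property
    def structure(self) -> Structure:
        return self.stage2.structure


def two_step_build(
    contacts: Sequence[ContactRecord],
    chrom_order: Sequence[tuple[str, Optional[str], int]],
    config: MultiscaleConfig,
    loss_params: LossParams = LossParams(),
    impute_params: GaussianImputeParams = GaussianImputeParams(),
    seed: int = 0,
) -> TwoStepResult:
    """Full coarse-to-fine pipeline from raw contacts to a high-resolution
    structure.

    (1) bin + Gaussian-impute + anneal at the low resolution; (2) scale and
    interpolate the coarse structure; (3) bin + impute at the high
    resolution and anneal from the interpolated start.  The intra/inter
    balancing coefficient is recomputed per stage from that stage's binary
    matrix.  Deterministic per seed.
    """
    s1_seed, s2_seed, init_seed = (
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(int(seed)).generate_state(3)
    )
    sched1, sched2 = config.schedules()

    low_binning = GenomeBinning(chrom_order, config.low_resolution)
    low_matrix = bin_contacts(contacts, low_binning)
    if low_matrix.n_contacts == 0:
        raise ValueError("no contacts fall inside the low-resolution binning")
    theta_low = gaussian_impute(low_matrix, impute_params)
    params_low = loss_params.with_c_ratio(*low_matrix.intra_inter_counts())
    start = initialize_structure(low_binning, seed=init_seed)
    stage1 = anneal(start, theta_low, params_low, sched1, seed=s1_seed)

    high_binning = GenomeBinning(chrom_order, config.high_resolution)
    scaled = scale_structure(stage1.structure, config)
    initial_high = interpolate_beads(scaled, config, high_binning)

    high_matrix = bin_contacts(contacts, high_binning)
    theta_high = gaussian_impute(high_matrix, impute_params)
    params_high = loss_params.with_c_ratio(*high_matrix.intra_inter_counts())
    stage2 = anneal(initial_high, theta_high, params_high, sched2, seed=s2_seed)
    return TwoStepResult(
        stage1=stage1,
        initial_high=initial_high,
        stage2=stage2,
        low_matrix=low_matrix,
        high_matrix=high_matrix,
        loss_params_low=params_low,
        loss_params_high=params_high,
    )
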