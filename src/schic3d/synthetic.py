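"""Ground-truth simulator for end-to-end recovery testing.

Generates confined multi-chromosome polymer conformations (unit-step random
walks with soft overlap rejection, each chromosome held inside its own
territory sphere within a spherical nucleus) and derives sparse binary
single-cell-Hi-C-like contacts from them: every bead pair closer than a
capture radius is observed with a capture probability, plus a small
fraction of spurious uniform contacts.  This emulates the statistical
character of real single-cell maps — binary, extremely sparse, with
intra-chromosomal contacts vastly outnumbering inter-chromosomal ones —
so that reconstruction quality can be measured against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .evaluation import (
    contact_group_stats,
    cross_resolution_concordance,
    distance_matrix,
)
from .imputation import GaussianImputeParams
from .io_contacts import (
    BinaryContactMatrix,
    ContactRecord,
    GenomeBinning,
    Structure,
    bin_contacts,
)
from .loss import LossParams
from .multiscale import MultiscaleConfig, two_step_build

__all__ = [
    "SyntheticGenomeSpec",
    "reference_spec",
    "two_block_graph_spec",
    "simulate_genome_structure",
    "simulate_sc_contacts",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Study conditions for one simulated cell.

    ``capture_radius`` (lattice units) bounds which bead pairs can be
    observed; ``capture_rate`` is the per-pair observation probability;
    ``target_pair_density``, when set, overrides capture_rate so that the
    expected contact count is that fraction of all bead pairs.
    ``territory_radius`` confines each chromosome walk around its own
    center, inducing chromosome territories inside the nucleus of
    ``confinement_radius``.
    """

    chromosomes: tuple[tuple[str, Optional[str], int], ...]
    resolution: int
    confinement_radius: float
    territory_radius: float
    capture_radius: float = 3.0
    capture_rate: float = 0.5
    noise_rate: float = 0.02
    target_pair_density: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.capture_rate <= 1.0):
            raise ValueError("capture_rate must be in [0, 1]")
        if not (0.0 <= self.noise_rate < 1.0):
            raise ValueError("noise_rate must be in [0, 1)")
        if self.territory_radius > self.confinement_radius:
            raise ValueError("territory must fit inside the confinement sphere")

    @property
    def binning(self) -> GenomeBinning:
        return GenomeBinning(self.chromosomes, self.resolution)


def reference_spec(seed: int = 0) -> SyntheticGenomeSpec:
    """The desk-scale reference instance: 3 chromosomes x 200 beads
    (l = 600) at 1 Mbp, capture radius 3, contact density ~1% of bead
    pairs — small enough for minutes-scale annealing, sparse enough to
    exercise the binary-input regime."""
    return SyntheticGenomeSpec(
        chromosomes=(
            ("chr1", None, 200_000_000),
            ("chr2", None, 200_000_000),
            ("chr3", None, 200_000_000),
        ),
        resolution=1_000_000,
        confinement_radius=25.0,
        territory_radius=10.0,
        capture_radius=3.0,
        target_pair_density=0.01,
        noise_rate=0.02,
        seed=seed,
    )


def two_block_graph_spec(seed: int = 5) -> SyntheticGenomeSpec:
    """Link-prediction benchmark instance: two 100-bead chromosome
    territories (the two graph blocks) whose contact graph is geometric —
    pairs within the capture radius observed at a 90% rate, within-block
    edges vastly dominating.  Near-deterministic geometry makes held-out
    edges predictable from shared neighbourhoods, which is the regime the
    edge-prediction imputer is meant for."""
    return SyntheticGenomeSpec(
        chromosomes=(
            ("chr1", None, 100_000_000),
            ("chr2", None, 100_000_000),
        ),
        resolution=1_000_000,
        confinement_radius=14.0,
        territory_radius=7.0,
        capture_radius=3.0,
        capture_rate=0.9,
        noise_rate=0.0,
        seed=seed,
    )


def simulate_genome_structure(spec: SyntheticGenomeSpec, seed: Optional[int] = None) -> Structure:
    """Grow each chromosome as a unit-step random walk with soft overlap
    rejection, confined to a territory sphere inside the nucleus.

    Territory centers are drawn inside the nucleus (margin one territory
    radius), so chromosomes occupy distinct regions and differ in radial
    position.  Coordinates are shifted into a cubic box of side
    2 * confinement_radius.  Deterministic per seed (defaults to
    ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    binning = spec.binning
    R = spec.confinement_radius
    rt = spec.territory_radius
    coords = np.empty((binning.n_beads, 3))
    off = 0
    min_sep2 = 0.7**2  # soft self-avoidance scale
    for k, nb in enumerate(binning.n_bins):
        for _attempt in range(50):
            # territory center inside the nucleus with a territory margin
            while True:
                c = rng.uniform(-1.0, 1.0, size=3) * (R - rt)
                if np.dot(c, c) <= (R - rt) ** 2:
                    break
            chain = np.empty((nb, 3))
            chain[0] = c
            ok = True
            for b in range(1, nb):
                placed = False
                for _try in range(60):
                    v = rng.normal(size=3)
                    v /= np.linalg.norm(v)
                    cand = chain[b - 1] + v
                    if np.sum((cand - c) ** 2) > rt * rt:
                        continue
                    d2 = np.sum((chain[:b] - cand) ** 2, axis=1)
                    if np.min(d2) < min_sep2:
                        continue
                    chain[b] = cand
                    placed = True
                    break
                if not placed:
                    ok = False
                    break
            if ok:
                break
        else:
            raise RuntimeError(
                f"chromosome {binning.chrom_order[k][0]}: walk failed after restarts "
                "(territory too small for its bead count?)"
            )
        coords[off: off + nb] = chain
        off += nb
    coords += R  # shift into [0, 2R]^3
    return Structure(coords, binning, box_side=2.0 * R)


def simulate_sc_contacts(
    truth: Structure, spec: SyntheticGenomeSpec, seed: Optional[int] = None
) -> list[ContactRecord]:
    """Derive binary single-cell-like contacts from a truth structure.

    Every bead pair with spatial distance below ``capture_radius`` is
    emitted with probability ``capture_rate`` (or the rate implied by
    ``target_pair_density``), plus ``noise_rate`` x (emitted count) uniform
    random spurious pairs.  Contact positions are bin midpoints; every
    record carries count 1."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    binning = truth.binning
    n = truth.n_beads
    d = pdist(truth.coords)
    iu = np.triu_indices(n, k=1)
    within = d < spec.capture_radius
    n_within = int(within.sum())
    rate = spec.capture_rate
    if spec.target_pair_density is not None and n_within > 0:
        n_pairs_total = n * (n - 1) // 2
        rate = min(1.0, spec.target_pair_density * n_pairs_total / n_within)
    emit = within & (rng.random(d.shape[0]) < rate)
    ei = iu[0][emit]
    ej = iu[1][emit]
    n_noise = int(round(spec.noise_rate * ei.size))
    if n_noise:
        ni = rng.integers(0, n, size=4 * n_noise)
        nj = rng.integers(0, n, size=4 * n_noise)
        keep = ni != nj
        ni, nj = ni[keep][:n_noise], nj[keep][:n_noise]
        ei = np.concatenate([ei, np.minimum(ni, nj)])
        ej = np.concatenate([ej, np.maximum(ni, nj)])
    rows = binning.bead_table()
    gpos = binning.genomic_position()
    records = []
    for a, b in zip(ei, ej):
        ca, ha, _, _ = rows[a]
        cb, hb, _, _ = rows[b]
        records.append(
            ContactRecord(
                ca, int(gpos[a]), cb, int(gpos[b]), hap_a=ha, hap_b=hb, count=1
            )
        )
    return records


def recovery_experiment(
    spec: SyntheticGenomeSpec,
    config: Optional[MultiscaleConfig] = None,
    loss_params: LossParams = LossParams(),
    impute_params: GaussianImputeParams = GaussianImputeParams(),
    n_seeds: int = 5,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Simulate truth -> contacts -> two-step build -> compare, per seed.

    Returns one row per replicate with intra-/inter-scope distance-matrix
    Pearson correlations against the truth and the overall contact vs
    non-contact distance statistics of the reconstruction.
    """
    if config is None:
        config = MultiscaleConfig(
            low_resolution=spec.resolution * 10, high_resolution=spec.resolution
        )
    rows = []
    for k in range(n_seeds):
        s = base_seed + 1000 * k
        truth = simulate_genome_structure(spec, seed=s)
        contacts = simulate_sc_contacts(truth, spec, seed=s + 1)
        result = two_step_build(
            contacts, spec.chromosomes, config, loss_params, impute_params, seed=s + 2
        )
        dm_truth = distance_matrix(truth)
        dm_rec = distance_matrix(result.structure)
        stats = contact_group_stats(dm_rec, result.high_matrix)
        overall = stats[stats["band"] == "overall"].iloc[0]
        rows.append(
            {
                "seed": s,
                "n_contacts": result.high_matrix.n_contacts,
                "intra_pearson": cross_resolution_concordance(dm_truth, dm_rec, "intra"),
                "inter_pearson": cross_resolution_concordance(dm_truth, dm_rec, "inter"),
                "contact_mean": overall["contact_mean"],
                "noncontact_mean": overall["noncontact_mean"],
                "rank_sum_p": overall["p_value"],
                "final_loss": result.stage2.final_loss,
            }
        )
    return pd.DataFrame(rows)
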