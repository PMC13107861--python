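import numpy as np
import pytest
from hypothesis import settings

import schic3d as sc

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def two_chrom_binning() -> sc.GenomeBinning:
    """Two 10-bead chromosomes at 1 Mbp."""
    return sc.GenomeBinning(
        [("chr1", None, 10_000_000), ("chr2", None, 10_000_000)], 1_000_000
    )


@pytest.fixture
def random_structure():
    """Factory: random coordinates in a generous box over a given binning."""

    def make(binning: sc.GenomeBinning, seed: int = 0, span: float = 30.0) -> sc.Structure:
        rng = np.random.default_rng(seed)
        side = 5.0 * binning.n_beads
        center = side / 2.0
        coords = rng.uniform(center - span, center + span, size=(binning.n_beads, 3))
        return sc.Structure(coords, binning, side)

    return make


@pytest.fixture
def small_theta(two_chrom_binning):
    """A theta matrix spanning all three regimes on the 20-bead genome."""
    pairs = np.array([[0, 3], [1, 7], [2, 15], [5, 6]])
    theta = np.array([1.0, 0.85, 0.75, 0.3])
    return sc.ThetaMatrix(20, pairs, theta, "gaussian", binning=two_chrom_binning)


@pytest.fixture
def ideal_chain_structure():
    """Factory fixture for unconfined random-walk (ideal-chain) polymers."""
    return _ideal_chain_structure


def _ideal_chain_structure(n_chains: int, length: int, seed: int) -> sc.Structure:
    """Unconfined unit-step random-walk chains (ideal-chain ensemble),
    offset far apart so inter-chain contacts are impossible."""
    rng = np.random.default_rng(seed)
    chains = []
    for k in range(n_chains):
        v = rng.normal(size=(length - 1, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        c = np.vstack([[0.0, 0.0, 0.0], np.cumsum(v, axis=0)])
        c -= c.min(axis=0)
        c[:, 2] += k * 1000.0
        chains.append(c)
    coords = np.vstack(chains)
    binning = sc.GenomeBinning(
        [(f"chr{k + 1}", None, length * 1_000_000) for k in range(n_chains)],
        1_000_000,
    )
    return sc.Structure(coords, binning, box_side=float(coords.max()) + 1.0)
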