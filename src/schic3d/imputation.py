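"""Contact-probability (theta) imputation for binary single-cell Hi-C maps.

A binary contact matrix is turned into a *theta matrix* of estimated contact
probabilities: observed pairs get theta = 1, and unobserved pairs get a
probability from either

* a 2D Gaussian proximity kernel in matrix-index space — a pair close (in
  bin indices) to an observed contact is likely a dropout of a true contact;
* a graph autoencoder (GAE): a two-layer graph-convolutional encoder and a
  logistic inner-product decoder trained to reconstruct the contact graph,
  whose predicted edge probabilities impute the zeros.

Theta drives the three-regime distance loss: theta = 1 pairs are pulled to
the target distance hardest, 0.7 <= theta < 1 pairs more weakly, and
everything else is only kept from collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix, identity

from .io_contacts import BinaryContactMatrix, GenomeBinning

__all__ = [
    "ThetaMatrix",
    "GaussianImputeParams",
    "GAEConfig",
    "gaussian_impute",
    "gae_impute",
    "evaluate_link_prediction",
    "normalized_adjacency",
]


@dataclass
class ThetaMatrix:
    """Sparse symmetric map of bead-pair contact probabilities.

    ``pairs`` is (m, 2) with i < j; ``theta`` the matching probabilities in
    (0, 1].  Pairs absent from the map have theta = 0.
    """

    n_beads: int
    pairs: np.ndarray
    theta: np.ndarray
    source: str
    binning: Optional[GenomeBinning] = None

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.theta = np.asarray(self.theta, dtype=np.float64).reshape(-1)
        if self.pairs.shape[0] != self.theta.shape[0]:
            raise ValueError("pairs/theta length mismatch")
        if self.pairs.size and np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("pairs must satisfy i < j")
        if np.any(self.theta <= 0.0) or np.any(self.theta > 1.0):
            raise ValueError("stored theta must be in (0, 1]")

    @property
    def n_entries(self) -> int:
        return int(self.pairs.shape[0])

    def theta_of(self, i: int, j: int) -> float:
        """Probability for an arbitrary pair (0.0 if absent)."""
        if i == j:
            return 0.0
        a, b = (i, j) if i < j else (j, i)
        if not hasattr(self, "_lookup"):
            self._lookup = {
                (int(p), int(q)): float(t)
                for (p, q), t in zip(self.pairs, self.theta)
            }
        return self._lookup.get((a, b), 0.0)

    def attraction_entries(self, threshold: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, theta) arrays of the entries with theta >= threshold
        (the only ones entering the attraction regimes of the loss)."""
        mask = self.theta >= threshold
        return (
            self.pairs[mask, 0].copy(),
            self.pairs[mask, 1].copy(),
            self.theta[mask].copy(),
        )

    def attraction_csr(self, threshold: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Symmetric CSR (indptr, neighbours, theta) of theta >= threshold
        entries, for per-bead neighbourhood scans."""
        ti, tj, tv = self.attraction_entries(threshold)
        rows = np.concatenate([ti, tj])
        cols = np.concatenate([tj, ti])
        vals = np.concatenate([tv, tv])
        order = np.argsort(rows, kind="stable")
        rows, cols, vals = rows[order], cols[order], vals[order]
        indptr = np.zeros(self.n_beads + 1, dtype=np.int64)
        np.add.at(indptr, rows + 1, 1)
        np.cumsum(indptr, out=indptr)
        return indptr, cols.astype(np.int64), vals.astype(np.float64)


@dataclass(frozen=True)
class GaussianImputeParams:
    """2D Gaussian kernel: ``sigma`` is the kernel width and ``window`` the
    half-width (both in bins) of the neighbourhood scanned around each
    observed contact."""

    sigma: float = 1.0
    window: int = 5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.window < 0:
            raise ValueError("window must be >= 0")


def gaussian_impute(matrix: BinaryContactMatrix, params: GaussianImputeParams = GaussianImputeParams()) -> ThetaMatrix:
    """Impute theta by the maximum Gaussian kernel response to any observed
    contact within a Chebyshev window in matrix-index space.

    theta(i, j) = 1 for observed pairs, otherwise
    max over observed (u, v) with Chebyshev offset <= window of
    exp(-((i-u)^2 + (j-v)^2) / (2 sigma^2)).
    """
    if matrix.n_contacts == 0:
        raise ValueError("matrix has no contacts")
    n = matrix.n_beads
    W = params.window
    obs = matrix.pairs
    # scan both orientations so the result is symmetric in index space
    oi = np.concatenate([obs[:, 0], obs[:, 1]])
    oj = np.concatenate([obs[:, 1], obs[:, 0]])
    di, dj = np.meshgrid(np.arange(-W, W + 1), np.arange(-W, W + 1), indexing="ij")
    di = di.ravel()
    dj = dj.ravel()
    kern = np.exp(-(di.astype(float) ** 2 + dj.astype(float) ** 2) / (2.0 * params.sigma**2))
    ci = (oi[:, None] + di[None, :]).ravel()
    cj = (oj[:, None] + dj[None, :]).ravel()
    tv = np.broadcast_to(kern, (oi.shape[0], kern.shape[0])).ravel()
    valid = (ci >= 0) & (ci < n) & (cj >= 0) & (cj < n) & (ci != cj)
    ci, cj, tv = ci[valid], cj[valid], tv[valid]
    a = np.minimum(ci, cj)
    b = np.maximum(ci, cj)
    keys = a * n + b
    uniq, inv = np.unique(keys, return_inverse=True)
    theta = np.zeros(uniq.shape[0])
    np.maximum.at(theta, inv, tv)
    # observed support is exactly 1
    obs_keys = obs[:, 0] * n + obs[:, 1]
    pos = np.searchsorted(uniq, obs_keys)
    theta[pos] = 1.0
    pairs = np.column_stack([uniq // n, uniq % n])
    nz = theta > 0.0  # kernel underflow at tiny sigma: absent means theta = 0
    return ThetaMatrix(
        n, pairs[nz], theta[nz], source="gaussian", binning=matrix.binning
    )


# ---------------------------------------------------------------------------
# graph autoencoder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GAEConfig:
    """Graph-autoencoder hyperparameters.

    ``embedding_size`` is the latent dimension F of the node embeddings;
    ``learning_rate`` is meant to be picked from {0.1, 0.001, 0.0001}.
    ``negative_sample_ratio`` negatives are drawn per positive edge each
    epoch.  Decoded probabilities >= ``promote_threshold`` are promoted to
    theta = 1; sparsification keeps decoded intra-chain pairs within
    ``band`` bins at theta >= ``keep_threshold`` and inter-chain pairs at
    theta >= ``inter_threshold`` (a containment choice: the full dense
    decode is quadratic in bead count).
    """

    embedding_size: int = 128
    hidden_size: int = 32
    learning_rate: float = 0.01
    epochs: int = 300
    negative_sample_ratio: float = 1.0
    holdout_fraction: float = 0.1
    seed: int = 0
    promote_threshold: float = 0.99
    keep_threshold: float = 0.5
    inter_threshold: float = 0.9
    band: int = 200
    early_stop_tol: float = 1e-4
    early_stop_window: int = 10

    def __post_init__(self) -> None:
        if self.embedding_size < 1:
            raise ValueError("embedding_size must be >= 1")
        if not (0.0 < self.holdout_fraction < 0.5):
            raise ValueError("holdout_fraction must be in (0, 0.5)")


def normalized_adjacency(matrix: BinaryContactMatrix) -> csr_matrix:
    """Symmetrically normalized adjacency with self-loops:
    D^(-1/2) (A + I) D^(-1/2), D the degree matrix of A + I."""
    A = matrix.to_csr() + identity(matrix.n_beads, format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)
    D = csr_matrix(
        (dinv, (np.arange(matrix.n_beads), np.arange(matrix.n_beads))),
        shape=A.shape,
    )
    return D @ A @ D


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _sample_non_edges(n: int, k: int, edge_set: set, rng: np.random.Generator) -> np.ndarray:
    """k uniform unordered non-edge pairs (i < j), rejection-sampled."""
    out = []
    while len(out) < k:
        need = k - len(out)
        i = rng.integers(0, n, size=2 * need + 8)
        j = rng.integers(0, n, size=2 * need + 8)
        for a, b in zip(i, j):
            if a == b:
                continue
            p = (int(a), int(b)) if a < b else (int(b), int(a))
            if p in edge_set:
                continue
            out.append(p)
            if len(out) == k:
                break
    return np.array(out, dtype=np.int64)


def _train_gae(matrix: BinaryContactMatrix, config: GAEConfig, rng: np.random.Generator) -> np.ndarray:
    """Train the GCN encoder by cross-entropy on observed edges vs sampled
    non-edges; returns the N x F embedding matrix Z.

    Encoder: Z = Ahat ReLU(Ahat X W0) W1 with Ahat the normalized adjacency
    (self-loops included); node features X are the per-partner interaction
    frequency vectors, i.e. the rows of the binary contact matrix.
    Optimized with Adam.
    """
    n = matrix.n_beads
    if n < 2 or matrix.n_contacts < 1:
        raise ValueError("graph needs >= 2 nodes and >= 1 edge")
    Ahat = normalized_adjacency(matrix)
    X = matrix.to_csr().toarray()
    Q = np.asarray(Ahat @ X)  # n x d, fixed through training
    d = Q.shape[1]
    h, F = config.hidden_size, config.embedding_size
    # Glorot initialization
    W0 = rng.normal(0.0, np.sqrt(2.0 / (d + h)), size=(d, h))
    W1 = rng.normal(0.0, np.sqrt(2.0 / (h + F)), size=(h, F))
    mom = [np.zeros_like(W0), np.zeros_like(W1)]
    vel = [np.zeros_like(W0), np.zeros_like(W1)]
    b1, b2, eps = 0.9, 0.999, 1e-8
    pos = matrix.pairs
    edge_set = {(int(a), int(b)) for a, b in pos}
    n_neg = max(1, int(round(config.negative_sample_ratio * pos.shape[0])))
    losses: list[float] = []
    for epoch in range(config.epochs):
        P = Q @ W0
        H = np.maximum(P, 0.0)
        M = np.asarray(Ahat @ H)
        Z = M @ W1
        neg = _sample_non_edges(n, n_neg, edge_set, rng)
        pi = np.concatenate([pos[:, 0], neg[:, 0]])
        pj = np.concatenate([pos[:, 1], neg[:, 1]])
        y = np.concatenate([np.ones(pos.shape[0]), np.zeros(neg.shape[0])])
        s = np.sum(Z[pi] * Z[pj], axis=1)
        p = _sigmoid(s)
        loss = float(
            -np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))
        )
        losses.append(loss)
        if len(losses) > config.early_stop_window:
            prev = losses[-config.early_stop_window - 1]
            if abs(prev - loss) < config.early_stop_tol * max(abs(prev), 1e-12):
                break
        g = (p - y) / y.shape[0]
        dZ = np.zeros_like(Z)
        np.add.at(dZ, pi, g[:, None] * Z[pj])
        np.add.at(dZ, pj, g[:, None] * Z[pi])
        dW1 = M.T @ dZ
        dM = dZ @ W1.T
        dH = np.asarray(Ahat @ dM)  # Ahat is symmetric
        dP = dH * (P > 0.0)
        dW0 = Q.T @ dP
        t = epoch + 1
        for k, (Wk, gk) in enumerate(((W0, dW0), (W1, dW1))):
            mom[k] = b1 * mom[k] + (1 - b1) * gk
            vel[k] = b2 * vel[k] + (1 - b2) * gk**2
            mhat = mom[k] / (1 - b1**t)
            vhat = vel[k] / (1 - b2**t)
            Wk -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
    P = Q @ W0
    H = np.maximum(P, 0.0)
    Z = np.asarray(Ahat @ H) @ W1
    return Z


def _candidate_pairs(binning: GenomeBinning, band: int) -> tuple[np.ndarray, np.ndarray]:
    """(intra-band pairs, inter-chain pairs), both as (m, 2) i < j arrays."""
    cid = binning.chrom_id_array()
    n = binning.n_beads
    intra = []
    for k in range(len(binning.chrom_order)):
        idx = np.flatnonzero(cid == k)
        lo, hi = idx[0], idx[-1] + 1
        for dsep in range(1, min(band, hi - lo - 1) + 1):
            i = np.arange(lo, hi - dsep)
            intra.append(np.column_stack([i, i + dsep]))
    intra_arr = (
        np.concatenate(intra, axis=0) if intra else np.empty((0, 2), dtype=np.int64)
    )
    inter = []
    for k1 in range(len(binning.chrom_order)):
        for k2 in range(k1 + 1, len(binning.chrom_order)):
            a = np.flatnonzero(cid == k1)
            b = np.flatnonzero(cid == k2)
            ii, jj = np.meshgrid(a, b, indexing="ij")
            inter.append(np.column_stack([ii.ravel(), jj.ravel()]))
    inter_arr = (
        np.concatenate(inter, axis=0) if inter else np.empty((0, 2), dtype=np.int64)
    )
    return intra_arr, inter_arr


def gae_impute(matrix: BinaryContactMatrix, config: GAEConfig = GAEConfig()) -> ThetaMatrix:
    """Impute theta by GAE link prediction on the full observed graph.

    Decoded probabilities are kept per the sparsification rule in
    :class:`GAEConfig`; probabilities >= ``promote_threshold`` become
    theta = 1; observed pairs are forced to theta = 1.  Deterministic per
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    Z = _train_gae(matrix, config, rng)
    n = matrix.n_beads
    intra, inter = _candidate_pairs(matrix.binning, config.band)
    kept_pairs = [matrix.pairs]
    kept_theta = [np.ones(matrix.n_contacts)]
    obs_keys = set(matrix.pairs[:, 0] * n + matrix.pairs[:, 1])
    for cand, thr in ((intra, config.keep_threshold), (inter, config.inter_threshold)):
        if cand.shape[0] == 0:
            continue
        p = _sigmoid(np.sum(Z[cand[:, 0]] * Z[cand[:, 1]], axis=1))
        keep = p >= thr
        cand, p = cand[keep], p[keep]
        p = np.where(p >= config.promote_threshold, 1.0, p)
        keys = cand[:, 0] * n + cand[:, 1]
        new = np.array([k not in obs_keys for k in keys], dtype=bool)
        kept_pairs.append(cand[new])
        kept_theta.append(p[new])
    pairs = np.concatenate(kept_pairs, axis=0)
    theta = np.concatenate(kept_theta)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return ThetaMatrix(
        n, pairs[order], theta[order], source="gae", binning=matrix.binning
    )


def evaluate_link_prediction(
    matrix: BinaryContactMatrix, config: GAEConfig = GAEConfig()
) -> tuple[float, float]:
    """Hold out a fraction of observed edges, train on the rest, and score
    the held-out edges against an equal number of sampled non-edges.

    Returns (area under the ROC curve, average precision).
    """
    from sklearn.metrics import average_precision_score, roc_auc_score

    rng = np.random.default_rng(config.seed)
    m = matrix.n_contacts
    n_hold = int(round(config.holdout_fraction * m))
    if n_hold < 1 or m - n_hold < 1:
        raise ValueError("too few edges to hold out")
    perm = rng.permutation(m)
    hold = matrix.pairs[perm[:n_hold]]
    keep = matrix.pairs[perm[n_hold:]]
    keep = keep[np.lexsort((keep[:, 1], keep[:, 0]))]
    train = BinaryContactMatrix(matrix.n_beads, keep, matrix.binning)
    Z = _train_gae(train, config, rng)
    all_edges = {(int(a), int(b)) for a, b in matrix.pairs}
    neg = _sample_non_edges(matrix.n_beads, n_hold, all_edges, rng)
    pi = np.concatenate([hold[:, 0], neg[:, 0]])
    pj = np.concatenate([hold[:, 1], neg[:, 1]])
    y = np.concatenate([np.ones(n_hold), np.zeros(n_hold)])
    scores = np.sum(Z[pi] * Z[pj], axis=1)
    return float(roc_auc_score(y, scores)), float(average_precision_score(y, scores))
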