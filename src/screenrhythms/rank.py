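"""Choosing the number of NMF components by consensus-clustering stability.

For a candidate K, the factorization is repeated from many random
initializations, each run fitted on a random subsample of participants
(Monti-style consensus clustering; 50% by default).  Each run assigns every
sampled participant to the component carrying their largest
(mass-normalized) weight, and the consensus matrix records, for every pair,
the fraction of co-sampled runs in which they were assigned together.  If K
matches the data's structure, assignments are stable and the consensus
matrix is nearly binary; instability smears it.  The resampling is what
makes too-small K unstable: *which* archetypes merge then depends on the
sample, whereas initialization alone converges to the same merge every run.

Stability is scored by the cophenetic correlation coefficient: average-
linkage hierarchical clustering of the distance matrix D = 1 - consensus
induces dendrogram (cophenetic) distances, and the coefficient is the
Pearson correlation between the off-diagonal entries of D and those
dendrogram distances.  A coefficient near 1 means the dendrogram reproduces
D faithfully, i.e. the clustering is stable.  K is chosen as the (smallest)
maximizer of the coefficient over a sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from .nmf import nmf_hals
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Consensus matrix and its cophenetic coefficient for one K."""

    k: int
    consensus: np.ndarray
    cophenetic: float
    n_runs: int


@dataclass
class KSelectionResult:
    """Cophenetic coefficients over a K sweep and the chosen K."""

    table: pd.DataFrame  # columns K, cophenetic
    best_k: int
    results: list

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _assignments(X: np.ndarray, k: int, seed: int, tol: float, max_iter: int) -> np.ndarray:
    dec = nmf_hals(X, k, seed=seed, tol=tol, max_iter=max_iter)
    # argmax of mass-normalized weights; row normalization cannot change it
    scores = dec.W * dec.H.sum(axis=0)
    return np.argmax(scores, axis=1)  # ties -> lowest component index


def consensus_matrix(
    X,
    k: int,
    n_runs: int = 30,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    subsample: float = 0.5,
) -> ConsensusResult:
    """Average co-assignment indicator over ``n_runs`` resampled restarts.

    Each run fits the factorization on a random ``subsample`` fraction of
    participants with a distinct deterministic seed derived from ``seed``;
    a pair's consensus entry averages over the runs in which both were
    sampled.  ``subsample=1.0`` recovers the plain restart-only consensus.
    A degenerate run in which a single component captures every sampled
    participant is logged but still counted.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if not 0 < subsample <= 1:
        raise ValueError("subsample must be in (0, 1]")
    Xm = X.X if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    n = Xm.shape[0]
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    n_sub = max(2, int(round(subsample * n)))
    for s in run_seeds:
        rng = np.random.default_rng(int(s))
        idx = np.sort(rng.choice(n, size=n_sub, replace=False)) if n_sub < n else np.arange(n)
        assign = _assignments(Xm[idx], k, int(rng.integers(2**31)), tol, max_iter)
        if len(np.unique(assign)) == 1:
            logger.warning("degenerate run (k=%d, seed=%d): one component took all", k, s)
        block = np.ix_(idx, idx)
        together[block] += assign[:, None] == assign[None, :]
        sampled[block] += 1.0
    consensus = np.divide(together, sampled, out=np.zeros((n, n)), where=sampled > 0)
    np.fill_diagonal(consensus, 1.0)
    return ConsensusResult(k, consensus, cophenetic_coefficient(consensus), n_runs)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of average-linkage clustering of 1 - consensus.

    Raises on fewer than three participants or when all pairwise distances
    are equal (zero variance makes the correlation undefined).
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus must be square")
    if C.shape[0] < 3:
        raise ValueError("need at least 3 participants")
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("consensus must be symmetric")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.ptp(condensed) == 0.0:
        raise ValueError("all pairwise distances equal; coefficient undefined")
    Z = linkage(condensed, method="average")
    coeff, _ = cophenet(Z, condensed)
    return float(coeff)


def select_k(
    X,
    k_min: int = 2,
    k_max: int = 7,
    n_runs: int = 30,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    subsample: float = 0.5,
) -> KSelectionResult:
    """Sweep K, score each by the cophenetic coefficient, pick the maximizer.

    The chosen K* is the smallest K attaining the maximum coefficient.
    Per-K seeds are derived deterministically from ``seed``.
    """
    Xm = X.X if isinstance(X, ProfileMatrix) else np.asarray(X, dtype=float)
    if not 2 <= k_min < k_max <= min(Xm.shape):
        raise ValueError(f"need 2 <= k_min < k_max <= {min(Xm.shape)}")
    ks = list(range(k_min, k_max + 1))
    k_seeds = np.random.SeedSequence(seed).generate_state(len(ks)) % (2**31)
    results = [
        consensus_matrix(
            Xm, k, n_runs=n_runs, seed=int(s), tol=tol, max_iter=max_iter,
            subsample=subsample,
        )
        for k, s in zip(ks, k_seeds)
    ]
    table = pd.DataFrame({"K": ks, "cophenetic": [r.cophenetic for r in results]})
    best_k = int(table.loc[table["cophenetic"].idxmax(), "K"])  # idxmax -> first max
    logger.info("cophenetic sweep %s -> K*=%d", ks, best_k)
    return KSelectionResult(table, best_k, results)
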