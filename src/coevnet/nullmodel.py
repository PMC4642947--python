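"""Column-shuffled randomised-MSA null library.

Shuffling each alignment column independently preserves per-column symbol
multisets (hence entropy) while destroying inter-column covariation. The
full estimator chain run over K shuffles calibrates every downstream
threshold: the pooled off-diagonal entry mean/sigma (3-sigma edge rule),
the per-position centrality mean E_R and sigma (difference profiles and
2-sigma node rule), and the randomised strength/connectivity reference
row of the network metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import coevo
from .errors import EstimationError
from .msa import Alignment

logger = logging.getLogger(__name__)


def _member_seed(seed: int, k: int) -> int:
    """Counter-derived per-member seed (independent, reproducible)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(k,))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def shuffle_columns(aln: Alignment, seed: int) -> Alignment:
    """Permute each column's symbols independently.

    Each column uses a deterministic stream derived from ``(seed, column)``
    so results are reproducible and column-order independent. Per-column
    symbol counts — and hence entropies — are exactly preserved.
    """
    if aln.N < 2:
        raise ValueError("need at least 2 sequences")
    out = aln.data.copy()
    for j in range(aln.L):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(j,))
        )
        out[:, j] = rng.permutation(out[:, j])
    return Alignment(ids=list(aln.ids), data=out)


@dataclass
class NullLibrary:
    """Summary of K coevolution matrices from column-shuffled alignments.

    Carries pooled off-diagonal entry moments, per-position centrality
    moments (stack retained for window statistics), and per-entry positive
    sums/counts sufficient to build the randomised reference row for any
    sub-network selection. Full matrices are retained only on request.
    """

    K: int
    seed: int
    L: int
    entry_mean: float
    entry_sigma: float
    E_R: np.ndarray              # (L,) mean centrality over the library
    sigma_E: np.ndarray          # (L,) per-position centrality sigma
    centralities: np.ndarray     # (K, L)
    pos_sum: np.ndarray          # (L, L) sum over members of positive parts
    pos_count: np.ndarray        # (L, L) count over members of positives
    entry_sum: np.ndarray        # (L, L) sum over members
    entry_sumsq: np.ndarray      # (L, L)
    valid: np.ndarray = None     # (L, L) scoreable off-diagonal entries
    matrices: Optional[list] = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = ~np.eye(self.L, dtype=bool)

    # -- randomised reference aggregates ------------------------------
    def aggregates(self, rows: np.ndarray, cols: np.ndarray,
                   symmetric: bool) -> tuple[float, float, float, int]:
        """Per-member mean (sum_pos, n_corr, n_pos) and n_matrix for a
        selection block, excluding the diagonal."""
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        block = np.ix_(rows, cols)
        diag = rows[:, None] == cols[None, :]
        defined = self.valid[block] & ~diag
        sum_pos = float(self.pos_sum[block][defined].sum()) / self.K
        n_pos = float(self.pos_count[block][defined].sum()) / self.K
        n_corr = float(defined.sum())
        n_matrix = int(len(rows) * len(cols))
        return sum_pos, n_corr, n_pos, n_matrix

    def column_entry_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column mean and sigma of null entries (defined,
        off-diagonal)."""
        n = np.maximum(self.K * self.valid.sum(axis=0), 1)
        mu = (self.entry_sum * self.valid).sum(axis=0) / n
        ex2 = (self.entry_sumsq * self.valid).sum(axis=0) / n
        sig = np.sqrt(np.maximum(ex2 - mu ** 2, 0.0))
        return mu, sig

    def difference_windows(self, n: int) -> np.ndarray:
        """Pooled window weights of per-member difference profiles.

        For each member, the member centrality is corrected against the
        library mean profile exactly as a real profile would be, and mean
        weights of all length-``n`` windows are collected. The mean and
        sigma of this pool set the 2-sigma primary-node threshold.
        """
        kernel = np.ones(n) / n
        pools = []
        denom = self.E_R.mean()
        for e in self.centralities:
            scale = e.mean() / denom if denom > 0 else 1.0
            dw = e - scale * self.E_R
            pools.append(np.convolve(dw, kernel, mode="valid"))
        return np.concatenate(pools)

    def window_stats(self, n: int) -> tuple[float, float]:
        pool = self.difference_windows(n)
        return float(pool.mean()), float(pool.std())

    # -- serialisation ------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "K": self.K,
            "seed": self.seed,
            "L": self.L,
            "entry_mean": self.entry_mean,
            "entry_sigma": self.entry_sigma,
            "E_R": self.E_R.tolist(),
            "sigma_E": self.sigma_E.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def build_library(
    aln: Alignment,
    K: int = 100,
    settings: Optional[coevo.EstimatorSettings] = None,
    seed: int = 0,
    keep_matrices: bool = False,
) -> NullLibrary:
    """Run the estimator chain over K column-shuffled copies of ``aln``.

    A member whose estimation fails is re-drawn once with a fresh seed
    before a hard error is raised.
    """
    from .netmetrics import eigen_centrality  # deferred: avoids cycle

    if K < 2:
        raise ValueError("library size K must be >= 2")
    settings = settings or coevo.EstimatorSettings()
    L = aln.L
    pos_sum = np.zeros((L, L))
    pos_count = np.zeros((L, L))
    entry_sum = np.zeros((L, L))
    entry_sumsq = np.zeros((L, L))
    cents = np.zeros((K, L))
    matrices = [] if keep_matrices else None
    valid = None
    pooled_n = 0
    pooled_s = 0.0
    pooled_s2 = 0.0
    for k in range(K):
        D = None
        for attempt in range(2):
            mseed = _member_seed(seed, k if attempt == 0 else K + k)
            try:
                shuffled = shuffle_columns(aln, mseed)
                D = coevo.coevolution_matrix(shuffled, settings)
                break
            except EstimationError:
                if attempt == 1:
                    raise
                logger.warning("null member %d failed; re-drawing once", k)
        V = D.values
        finite = ~np.isnan(V)
        if valid is None:
            valid = finite  # identical for every member: shuffling
            # preserves per-column gap counts, hence the scoreable set
        Vf = np.where(finite, V, 0.0)
        pos_sum += np.clip(Vf, 0.0, None)
        pos_count += (Vf > 0)
        entry_sum += Vf
        entry_sumsq += Vf ** 2
        vals = V[finite]
        pooled_n += vals.size
        pooled_s += vals.sum()
        pooled_s2 += (vals ** 2).sum()
        cents[k] = eigen_centrality(D).E
        if matrices is not None:
            matrices.append(D)
    mean = pooled_s / pooled_n
    sigma = float(np.sqrt(max(pooled_s2 / pooled_n - mean ** 2, 0.0)))
    return NullLibrary(
        K=K,
        seed=seed,
        L=L,
        entry_mean=float(mean),
        entry_sigma=sigma,
        E_R=cents.mean(axis=0),
        sigma_E=cents.std(axis=0),
        centralities=cents,
        pos_sum=pos_sum,
        pos_count=pos_count,
        entry_sum=entry_sum,
        entry_sumsq=entry_sumsq,
        valid=valid,
        matrices=matrices,
        settings=settings.__dict__.copy(),
    )
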