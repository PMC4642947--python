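"""Coevolution-matrix estimation.

The estimator chain follows the sparse-inverse-covariance approach to
direct-coupling analysis: normalized mutual information between alignment
columns, average-product correction, L1-penalised (graphical lasso)
precision-matrix estimation, direct information
``D_ij = W_ij / (W_ii * W_jj)``, and finally a column-mean normalisation
of the D distribution.

A note on sign: the off-diagonal entries of the precision matrix of a
similarity (nMI) matrix are *negative* for strongly coupled column pairs.
:func:`direct_information` therefore supports two conventions — ``"raw"``
(the literal ratio) and ``"coupling"`` (partial-correlation sign, i.e. the
off-diagonals negated) — and the assembled pipeline uses ``"coupling"`` so
that coupled pairs carry positive correlation values, which is what every
downstream threshold and "positive correlation" count assumes.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.covariance import graphical_lasso

from .errors import EstimationError
from .msa import Alignment, N_SYMBOLS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EstimatorSettings:
    """Tunable parameters of the coevolution estimator.

    weighting : "identity_cluster" or "none"
        With identity clustering, each sequence is down-weighted by the
        number of sequences within fractional identity >= ``theta`` of it.
    pseudocount : float
        Added to every cell of each 22x22 joint symbol table.
    rho : float
        Graphical-lasso L1 penalty; ``rho=0`` gives the dense inverse.
    eig_floor : float
        Minimum eigenvalue enforced by shrinkage toward the identity.
    max_gap_fraction : float
        Columns with a higher gap fraction cannot be scored and are
        masked (NaN rows/columns in the output matrix); deletion-tolerant
        segments of real families fall out of the analysis this way.
    """

    weighting: str = "identity_cluster"
    theta: float = 0.62
    pseudocount: float = 1.0
    rho: float = 1e-3
    eig_floor: float = 1e-3
    normalized_mi: bool = False
    apc: bool = True
    convention: str = "coupling"
    max_gap_fraction: float = 0.5


@dataclass
class PairFrequencies:
    """Weighted symbol frequencies of an alignment.

    Joint tables are materialised lazily via :meth:`joint`; the marginals
    and entropies are precomputed. ``effective_depth`` is the sum of
    sequence weights.
    """

    data: np.ndarray          # (N, L) int8 codes
    weights: np.ndarray       # (N,)
    pseudocount: float
    marginals: np.ndarray     # (L, 22) frequencies incl. pseudocount mass

    @property
    def L(self) -> int:
        return self.data.shape[1]

    @property
    def effective_depth(self) -> float:
        return float(self.weights.sum())

    @property
    def _total(self) -> float:
        return self.effective_depth + self.pseudocount * N_SYMBOLS ** 2

    def joint(self, i: int, j: int) -> np.ndarray:
        """The 22x22 joint frequency table of columns ``i`` and ``j``
        (0-based); sums to 1."""
        table = np.full((N_SYMBOLS, N_SYMBOLS), self.pseudocount)
        np.add.at(table, (self.data[:, i], self.data[:, j]), self.weights)
        return table / table.sum()

    def column_entropy(self) -> np.ndarray:
        """Per-column entropy in bits under the weighted, pseudocounted
        marginal distribution."""
        p = self.marginals
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return -terms.sum(axis=1)


def sequence_weights(aln: Alignment, theta: float = 0.62) -> np.ndarray:
    """Identity-cluster weights: 1 / (number of sequences with fractional
    identity >= theta to the sequence, itself included)."""
    X = aln.data
    N, L = X.shape
    idm = np.zeros((N, N), dtype=np.float32)
    for s in range(N_SYMBOLS):
        ind = (X == s).astype(np.float32)
        idm += ind @ ind.T
    neighbours = (idm / L >= theta).sum(axis=1)
    return 1.0 / neighbours


def pair_frequencies(
    aln: Alignment,
    weighting: str = "identity_cluster",
    theta: float = 0.62,
    pseudocount: float = 1.0,
) -> PairFrequencies:
    """Joint/marginal symbol frequencies with optional sequence weighting."""
    if aln.N < 2:
        raise ValueError("need at least 2 sequences")
    if weighting == "identity_cluster":
        w = sequence_weights(aln, theta).astype(float)
    elif weighting == "none":
        w = np.ones(aln.N)
    else:
        raise ValueError(f"unknown weighting scheme: {weighting!r}")
    total = w.sum() + pseudocount * N_SYMBOLS ** 2
    counts = np.zeros((aln.L, N_SYMBOLS))
    for s in range(N_SYMBOLS):
        counts[:, s] = ((aln.data == s) * w[:, None]).sum(axis=0)
    marginals = (counts + pseudocount * N_SYMBOLS) / total
    return PairFrequencies(
        data=aln.data, weights=w, pseudocount=pseudocount, marginals=marginals
    )


def mi_matrix(freqs: PairFrequencies, normalized: bool = True) -> np.ndarray:
    """Mutual-information matrix ``MI_ij = S_i + S_j - S_ij``.

    With ``normalized`` the entries are ``nMI_ij = MI_ij / S_ij`` (0 where
    the joint entropy vanishes). The diagonal is set to the column
    self-information S_i, which serves as the variance term for the
    downstream precision-matrix estimate.
    """
    X, w, alpha = freqs.data, freqs.weights, freqs.pseudocount
    N, L = X.shape
    total = freqs._total
    Hj = np.zeros((L, L))
    p0 = alpha / total
    base = -p0 * np.log2(p0) if alpha > 0 else 0.0
    present = [s for s in range(N_SYMBOLS) if (X == s).any()]
    inds = {s: (X == s) for s in present}
    for a in present:
        Iaw = (inds[a] * w[:, None]).T  # (L, N)
        for b in present:
            Cab = Iaw @ inds[b]
            P = (Cab + alpha) / total
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(P > 0, -P * np.log2(P), 0.0)
            Hj += term - base
    Hj += base * N_SYMBOLS ** 2
    Hi = freqs.column_entropy()
    MI = Hi[:, None] + Hi[None, :] - Hj
    if normalized:
        with np.errstate(divide="ignore", invalid="ignore"):
            M = np.where(Hj > 0, MI / Hj, 0.0)
    else:
        M = MI
    np.fill_diagonal(M, Hi)
    return M


def apc_correct(M: np.ndarray) -> np.ndarray:
    """Average-product correction over off-diagonal entries.

    ``corrected_ij = M_ij - mean_i(M) * mean_j(M) / mean(M)`` where the
    means are computed excluding the diagonal. The diagonal is preserved.
    An (off-diagonal) grand mean of zero skips the correction with a
    warning.
    """
    M = np.asarray(M, dtype=float)
    L = M.shape[0]
    if M.shape != (L, L):
        raise ValueError("matrix must be square")
    off = ~np.eye(L, dtype=bool)
    grand = M[off].mean()
    if grand == 0:
        warnings.warn("APC skipped: off-diagonal mean is zero", stacklevel=2)
        return M.copy()
    rowmean = (M * off).sum(axis=1) / (L - 1)
    corrected = M - np.outer(rowmean, rowmean) / grand
    np.fill_diagonal(corrected, np.diag(M))
    return corrected


@dataclass
class PrecisionMatrix:
    """Sparse-estimated inverse of the regularised nMI matrix."""

    Wmat: np.ndarray
    rho: float
    shrinkage: float  # gamma applied toward the identity

    def __post_init__(self) -> None:
        W = self.Wmat
        if not np.allclose(W, W.T, atol=1e-8):
            raise EstimationError("precision matrix is not symmetric")
        if (np.diag(W) <= 0).any():
            raise EstimationError("precision matrix has nonpositive diagonal")


def sparse_inverse(
    M: np.ndarray,
    rho: float = 1e-3,
    eig_floor: float = 1e-3,
) -> PrecisionMatrix:
    """L1-penalised precision matrix of a symmetric matrix.

    ``M`` is first shrunk toward the identity with the smallest mixing
    weight giving minimum eigenvalue >= ``eig_floor``. At ``rho=0`` the
    result is the plain inverse of the shrunk matrix.
    """
    M = np.asarray(M, dtype=float)
    M = (M + M.T) / 2
    emin = float(np.linalg.eigvalsh(M).min())
    gamma = 0.0
    if emin < eig_floor:
        gamma = (eig_floor - emin) / (1.0 - emin) if emin < 1.0 else 0.0
        gamma = min(max(gamma, 0.0), 1.0)
    Ms = (1 - gamma) * M + gamma * np.eye(M.shape[0])
    if rho == 0:
        W = np.linalg.inv(Ms)
    else:
        try:
            _, W = graphical_lasso(Ms, alpha=rho, max_iter=500)
        except FloatingPointError as exc:
            raise EstimationError(
                f"graphical lasso failed to converge at rho={rho}; "
                "try a larger rho or eig_floor"
            ) from exc
    W = (W + W.T) / 2
    return PrecisionMatrix(Wmat=W, rho=rho, shrinkage=gamma)


@dataclass
class CoevolutionMatrix:
    """Symmetric L x L matrix of (normalised) direct-information values.

    The diagonal is masked (NaN). ``positions`` carries 1-based position
    labels, preserved by sub-matrix extraction; ``provenance`` records the
    alignment hash and estimator settings.
    """

    values: np.ndarray
    positions: np.ndarray = None  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("coevolution matrix must be square")
        offmask = ~np.eye(V.shape[0], dtype=bool)
        off = V[offmask]
        if not np.isfinite(off[~np.isnan(off)]).all():
            raise ValueError("coevolution matrix has non-finite entries")
        np.fill_diagonal(V, np.nan)
        self.values = V
        if self.positions is None:
            self.positions = np.arange(1, V.shape[0] + 1)
        else:
            self.positions = np.asarray(self.positions, dtype=int)

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def offdiag_mask(self) -> np.ndarray:
        """Boolean mask of defined (non-diagonal, non-masked) entries."""
        return ~np.isnan(self.values)

    def offdiag_values(self) -> np.ndarray:
        return self.values[self.offdiag_mask()]

    def column_means(self) -> np.ndarray:
        """Per-column means over defined off-diagonal entries."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    # -- serialisation -----------------------------------------------
    def write_tsv(self, path: str | Path) -> None:
        """Dense TSV with a 1-based header row/column of positions."""
        with open(path, "w") as fh:
            fh.write("pos\t" + "\t".join(map(str, self.positions)) + "\n")
            for i, p in enumerate(self.positions):
                row = "\t".join(
                    "" if np.isnan(v) else f"{v:.6g}" for v in self.values[i]
                )
                fh.write(f"{p}\t{row}\n")

    def write_edge_list(self, path: str | Path) -> None:
        """Edge-list TSV (pos_i, pos_j, D_ij) for i < j."""
        iu = np.triu_indices(self.L, 1)
        with open(path, "w") as fh:
            fh.write("pos_i\tpos_j\tD\n")
            for i, j in zip(*iu):
                v = self.values[i, j]
                if not np.isnan(v):
                    fh.write(
                        f"{self.positions[i]}\t{self.positions[j]}\t{v:.6g}\n"
                    )


def direct_information(
    P: PrecisionMatrix, convention: str = "raw"
) -> CoevolutionMatrix:
    """Direct information ``D_ij = W_ij / (W_ii * W_jj)`` for i != j.

    ``convention="raw"`` is the literal ratio; ``convention="coupling"``
    negates the off-diagonals (partial-correlation sign) so that coupled
    pairs score positive. The diagonal is masked.
    """
    W = P.Wmat
    d = np.diag(W)
    if (d <= 0).any():
        raise EstimationError("precision diagonal must be strictly positive")
    D = W / np.outer(d, d)
    if convention == "coupling":
        D = -D
    elif convention != "raw":
        raise ValueError(f"unknown sign convention: {convention!r}")
    np.fill_diagonal(D, np.nan)
    return CoevolutionMatrix(values=D)


def normalize_matrix(D: CoevolutionMatrix) -> CoevolutionMatrix:
    """Column-mean normalisation: subtract the mean of the two columns'
    off-diagonal values from each entry, preserving symmetry:
    ``D'_ij = D_ij - (mean_i + mean_j) / 2``."""
    cm = D.column_means()
    cm = np.where(np.isnan(cm), 0.0, cm)
    V = D.values - (cm[:, None] + cm[None, :]) / 2
    return CoevolutionMatrix(
        values=V, positions=D.positions, provenance=dict(D.provenance)
    )


def high_scoring_threshold(
    D: CoevolutionMatrix, null, per_position: bool = False
) -> tuple[float | np.ndarray, np.ndarray]:
    """3-sigma edge threshold from the shuffled-library null.

    Returns ``(threshold, mask)`` with ``mask_ij = D_ij > threshold``.
    ``per_position`` switches from the pooled null sigma to per-position
    column statistics.
    """
    if null.K < 2:
        raise EstimationError("null library must have at least 2 members")
    if per_position:
        mu, sig = null.column_entry_stats()
        thr = mu[:, None] / 2 + mu[None, :] / 2 + 3 * np.sqrt(
            (sig[:, None] ** 2 + sig[None, :] ** 2) / 2
        )
    else:
        thr = null.entry_mean + 3 * null.entry_sigma
    with np.errstate(invalid="ignore"):
        mask = D.values > thr
    mask &= ~np.isnan(D.values)
    return thr, mask


def _alignment_hash(aln: Alignment) -> str:
    h = hashlib.sha256()
    h.update(aln.data.tobytes())
    h.update("|".join(aln.ids).encode())
    return h.hexdigest()[:16]


def scoreable_columns(aln: Alignment, max_gap_fraction: float) -> np.ndarray:
    """Boolean mask of columns whose gap fraction does not exceed the
    threshold; gap-dominated (deletion-tolerant) columns cannot be
    scored by the estimator."""
    from .msa import GAP_CODE

    gap_frac = (aln.data == GAP_CODE).mean(axis=0)
    return gap_frac <= max_gap_fraction


def coevolution_matrix(
    aln: Alignment, settings: Optional[EstimatorSettings] = None
) -> CoevolutionMatrix:
    """Run the full estimator chain on an alignment.

    MI (or nMI) -> APC -> shrinkage + graphical lasso -> direct
    information (coupling sign) -> column-mean normalisation.
    Gap-dominated columns are masked: their rows/columns carry NaN and
    are excluded from every downstream count and threshold.
    """
    settings = settings or EstimatorSettings()
    keep = scoreable_columns(aln, settings.max_gap_fraction)
    kept_idx = np.flatnonzero(keep)
    if kept_idx.size < 2:
        raise EstimationError("fewer than 2 scoreable columns")
    sub = Alignment(ids=list(aln.ids), data=aln.data[:, kept_idx]) \
        if kept_idx.size < aln.L else aln
    freqs = pair_frequencies(
        sub,
        weighting=settings.weighting,
        theta=settings.theta,
        pseudocount=settings.pseudocount,
    )
    M = mi_matrix(freqs, normalized=settings.normalized_mi)
    if settings.apc:
        M = apc_correct(M)
    P = sparse_inverse(M, rho=settings.rho, eig_floor=settings.eig_floor)
    D = direct_information(P, convention=settings.convention)
    D = normalize_matrix(D)
    if kept_idx.size < aln.L:
        full = np.full((aln.L, aln.L), np.nan)
        full[np.ix_(kept_idx, kept_idx)] = D.values
        if (~keep).any():
            logger.info("masked %d gap-dominated columns", int((~keep).sum()))
        D = CoevolutionMatrix(values=full)
    D.provenance = {
        "alignment_sha256": _alignment_hash(aln),
        "N": aln.N,
        "L": aln.L,
        "masked_columns": int((~keep).sum()),
        "settings": settings.__dict__.copy(),
        "shrinkage": P.shrinkage,
    }
    return D
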