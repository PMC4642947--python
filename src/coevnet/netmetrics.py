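"""Network representation of the coevolution matrix.

Residue positions are nodes, correlations are weighted edges. The module
provides eigenvector centrality of the matrix, windowed node weights and
the null-corrected difference profile, primary-node detection (2-sigma
rule), sub-network strength S_M and connectivity C normalised by the
shuffled-library reference (the Table-2/3 arithmetic), off-diagonal block
extraction, 3-node inter-domain networks and the centrality
autocorrelation used to detect the alpha-helical repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import eigh

from .coevo import CoevolutionMatrix

__all__ = [
    "CentralityProfile",
    "NodeWeightProfile",
    "PrimaryNode",
    "NetworkSelection",
    "NetworkMetrics",
    "eigen_centrality",
    "node_weights",
    "difference_profile",
    "detect_primary_nodes",
    "network_metrics",
    "submatrix",
    "three_node_network",
    "centrality_autocorrelation",
]


@dataclass
class CentralityProfile:
    """Principal-eigenvector centrality E (unit L2 norm, entries >= 0)
    and the leading eigenvalue lambda of the non-negative matrix."""

    E: np.ndarray
    lam: float

    @property
    def L(self) -> int:
        return self.E.size


def eigen_centrality(D: CoevolutionMatrix | np.ndarray) -> CentralityProfile:
    """Eigenvector centrality of a coevolution matrix.

    Negative entries are clipped to zero for this computation only
    (Perron-Frobenius then guarantees a non-negative principal vector);
    the unclipped matrix remains in force for all sums and thresholds.
    An all-zero matrix yields a uniform profile with lambda = 0.
    """
    V = D.values if isinstance(D, CoevolutionMatrix) else np.asarray(D, float)
    A = np.where(np.isnan(V), 0.0, V)
    A = np.clip((A + A.T) / 2, 0.0, None)
    L = A.shape[0]
    if not A.any():
        warnings.warn("all-zero matrix: uniform centrality, lambda=0",
                      stacklevel=2)
        return CentralityProfile(E=np.full(L, 1.0 / np.sqrt(L)), lam=0.0)
    lam, vec = eigh(A, subset_by_index=[L - 1, L - 1])
    E = vec[:, 0]
    # non-negative orientation
    if E.sum() < 0:
        E = -E
    E = np.clip(E, 0.0, None)
    E /= np.linalg.norm(E)
    return CentralityProfile(E=E, lam=float(lam[0]))


@dataclass
class PrimaryNode:
    """A merged run of qualifying windows, reported with its peak-mode
    position (all indices 1-based)."""

    start: int
    end: int
    peak: int
    weight: float

    def __str__(self) -> str:
        return f"node[{self.start}-{self.end}] peak={self.peak} W={self.weight:.4g}"


@dataclass
class NodeWeightProfile:
    """Windowed node weights and the null-corrected difference profile.

    ``W[k]`` is the mean centrality of the length-``n`` window starting at
    position ``k`` (0-based start; windows truncated at the terminus are
    excluded). ``deltaW`` is per-position, ``scale`` the ratio of real to
    null mean centrality (M_E / M_R).
    """

    n: int
    W: Optional[np.ndarray] = None
    deltaW: Optional[np.ndarray] = None
    scale: Optional[float] = None
    primary_nodes: list[PrimaryNode] = field(default_factory=list)


def node_weights(E: CentralityProfile | np.ndarray, n: int = 6) -> NodeWeightProfile:
    """Sliding-window (stride 1) mean centrality, W = sum(E)/n."""
    e = E.E if isinstance(E, CentralityProfile) else np.asarray(E, float)
    if n < 1:
        raise ValueError("window length must be >= 1")
    if n > e.size:
        raise ValueError(f"window length {n} exceeds profile length {e.size}")
    W = np.convolve(e, np.ones(n) / n, mode="valid")
    return NodeWeightProfile(n=n, W=W)


def difference_profile(E: CentralityProfile, null, n: int = 6) -> NodeWeightProfile:
    """Null-corrected difference profile deltaW_i = E_i - (M_E/M_R) E_R,i.

    The scale factor is the ratio of profile means, so the difference
    profile has zero mean by construction.
    """
    e = E.E
    ER = np.asarray(null.E_R, dtype=float)
    if e.size != ER.size:
        raise ValueError("real and null profiles differ in length")
    mR = ER.mean()
    if mR == 0:
        raise ValueError("null centrality mean is zero")
    scale = float(e.mean() / mR)
    dW = e - scale * ER
    W = np.convolve(dW, np.ones(n) / n, mode="valid")
    return NodeWeightProfile(n=n, W=W, deltaW=dW, scale=scale)


def detect_primary_nodes(
    profile: NodeWeightProfile,
    null,
    sigma: float = 2.0,
) -> list[PrimaryNode]:
    """Primary nodes: windows whose mean difference weight exceeds the
    null window-weight distribution mean by ``sigma`` standard deviations.

    Overlapping qualifying windows are merged; each merged run is one
    node, reported with the position of its peak deltaW (1-based).
    """
    if profile.deltaW is None:
        raise ValueError("difference profile required (call difference_profile)")
    n = profile.n
    mu, sd = null.window_stats(n)
    thr = mu + sigma * sd
    starts = np.flatnonzero(profile.W > thr)
    nodes: list[PrimaryNode] = []
    if starts.size == 0:
        return nodes
    run_start = prev = int(starts[0])
    runs = []
    for s in starts[1:]:
        s = int(s)
        if s <= prev + n - 1:  # windows overlap
            prev = s
        else:
            runs.append((run_start, prev))
            run_start = prev = s
    runs.append((run_start, prev))
    for a, b in runs:
        lo, hi = a, b + n - 1  # covered positions, 0-based inclusive
        seg = profile.deltaW[lo:hi + 1]
        peak = lo + int(np.argmax(seg))
        weight = float(profile.W[a:b + 1].max())
        nodes.append(PrimaryNode(start=lo + 1, end=hi + 1,
                                 peak=peak + 1, weight=weight))
    return nodes


# ---------------------------------------------------------------------
# selections and metrics


@dataclass
class NetworkSelection:
    """Row/column position sets (0-based indices into the matrix) defining
    an intra-domain block, inter-domain block, contact set or mask."""

    rows: np.ndarray
    cols: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.rows = np.unique(np.asarray(self.rows, dtype=int))
        self.cols = np.unique(np.asarray(self.cols, dtype=int))
        if self.rows.size == 0 or self.cols.size == 0:
            raise ValueError(f"selection {self.label!r} is empty")

    @property
    def symmetric(self) -> bool:
        return self.rows.size == self.cols.size and bool(
            (self.rows == self.cols).all()
        )

    @property
    def n_matrix(self) -> int:
        return int(self.rows.size * self.cols.size)

    @classmethod
    def intra(cls, positions: Iterable[int], label: str = "") -> "NetworkSelection":
        p = np.asarray(list(positions), dtype=int)
        return cls(rows=p, cols=p, label=label)

    @classmethod
    def inter(cls, rows: Iterable[int], cols: Iterable[int],
              label: str = "") -> "NetworkSelection":
        return cls(rows=np.asarray(list(rows), int),
                   cols=np.asarray(list(cols), int), label=label)


@dataclass
class NetworkMetrics:
    """The Table-2/3 aggregates of a (sub)network.

    ``sum_pos`` (sum of positive correlations), ``n_corr`` (entries with
    correlation values), ``n_pos`` (positive entries), ``n_matrix``
    (dim1*dim2), the derived density and raw strength, and — when a
    randomised reference is supplied — the normalised connectivity C and
    strength S_M. For symmetric selections both (i,j) and (j,i) are
    counted and the diagonal is excluded, the convention consistent with
    the printed N_Matrix = dim1*dim2.
    """

    label: str
    sum_pos: float
    n_corr: float
    n_pos: float
    n_matrix: int
    C: Optional[float] = None
    S_M: Optional[float] = None

    @property
    def density(self) -> float:
        return self.n_corr / self.n_matrix if self.n_matrix else 0.0

    @property
    def strength_raw(self) -> float:
        return self.sum_pos / self.n_pos if self.n_pos else 0.0

    def normalized_against(self, null_ref: "NetworkMetrics") -> "NetworkMetrics":
        """Fill C and S_M from a randomised reference row (Eqs for
        strength and connectivity)."""
        C = self.density / null_ref.density if null_ref.density else 0.0
        if self.n_pos == 0:
            warnings.warn(
                f"selection {self.label!r} has no positive correlations; S_M=0",
                stacklevel=2,
            )
            S_M = 0.0
        else:
            S_M = (self.strength_raw / null_ref.strength_raw
                   if null_ref.strength_raw else 0.0)
        return NetworkMetrics(
            label=self.label, sum_pos=self.sum_pos, n_corr=self.n_corr,
            n_pos=self.n_pos, n_matrix=self.n_matrix, C=C, S_M=S_M,
        )

    @classmethod
    def from_aggregates(
        cls,
        sum_pos: float,
        n_corr: float,
        n_pos: float,
        n_matrix: int,
        null_ref: Optional["NetworkMetrics"] = None,
        label: str = "",
    ) -> "NetworkMetrics":
        m = cls(label=label, sum_pos=sum_pos, n_corr=n_corr,
                n_pos=n_pos, n_matrix=n_matrix)
        if null_ref is not None:
            m = m.normalized_against(null_ref)
        return m

    def as_row(self) -> dict:
        return {
            "network": self.label,
            "sum_pos": self.sum_pos,
            "n_corr": self.n_corr,
            "n_pos": self.n_pos,
            "n_matrix": self.n_matrix,
            "density": self.density,
            "strength_raw": self.strength_raw,
            "C": self.C,
            "S_M": self.S_M,
        }


def _block_aggregates(values: np.ndarray, sel: NetworkSelection
                      ) -> tuple[float, float, float, int]:
    block = values[np.ix_(sel.rows, sel.cols)]
    diag = sel.rows[:, None] == sel.cols[None, :]
    defined = ~np.isnan(block) & ~diag
    vals = block[defined]
    return (
        float(vals[vals > 0].sum()),
        float(defined.sum()),
        float((vals > 0).sum()),
        sel.n_matrix,
    )


def network_metrics(
    D: CoevolutionMatrix,
    sel: NetworkSelection,
    null_ref: Optional["NullReference"] = None,
) -> NetworkMetrics:
    """Aggregate a selection block of the matrix into network metrics.

    ``null_ref`` may be a :class:`NetworkMetrics` (a randomised reference
    row) or a null library, in which case the reference row is built from
    the library restricted to the same selection.
    """
    sum_pos, n_corr, n_pos, n_matrix = _block_aggregates(D.values, sel)
    m = NetworkMetrics(label=sel.label, sum_pos=sum_pos, n_corr=n_corr,
                       n_pos=n_pos, n_matrix=n_matrix)
    if null_ref is None:
        return m
    ref = _resolve_null_ref(null_ref, sel)
    return m.normalized_against(ref)


def _resolve_null_ref(null_ref, sel: NetworkSelection) -> NetworkMetrics:
    if isinstance(null_ref, NetworkMetrics):
        return null_ref
    # duck-typed NullLibrary
    sp, nc, npos, nm = null_ref.aggregates(sel.rows, sel.cols, sel.symmetric)
    return NetworkMetrics(label=f"randomized[{sel.label}]", sum_pos=sp,
                          n_corr=nc, n_pos=npos, n_matrix=nm)


def submatrix(
    D: CoevolutionMatrix,
    rows: Sequence[int],
    cols: Sequence[int],
) -> tuple[CoevolutionMatrix, NetworkSelection]:
    """Extract an (off-diagonal) block, preserving original position
    labels. ``rows``/``cols`` are 0-based indices into the matrix."""
    rows = np.unique(np.asarray(rows, dtype=int))
    cols = np.unique(np.asarray(cols, dtype=int))
    for idx in (rows, cols):
        if idx.size and (idx.min() < 0 or idx.max() >= D.L):
            raise IndexError(
                f"selection positions out of range 0..{D.L - 1}"
            )
    sel = NetworkSelection(rows=rows, cols=cols)
    if sel.symmetric:
        block = CoevolutionMatrix(
            values=D.values[np.ix_(rows, rows)].copy(),
            positions=D.positions[rows],
            provenance=dict(D.provenance),
        )
        return block, sel
    # rectangular block: return as plain array wrapped in union-square form
    union = np.union1d(rows, cols)
    sq = np.full((union.size, union.size), np.nan)
    ri = np.searchsorted(union, rows)
    ci = np.searchsorted(union, cols)
    sq[np.ix_(ri, ci)] = D.values[np.ix_(rows, cols)]
    sq[np.ix_(ci, ri)] = D.values[np.ix_(cols, rows)]
    block = CoevolutionMatrix(values=sq, positions=D.positions[union],
                              provenance=dict(D.provenance))
    return block, sel


def three_node_network(
    D: CoevolutionMatrix,
    nodes: Sequence[PrimaryNode],
    null_ref=None,
) -> NetworkMetrics:
    """Metrics of the network formed by the top three primary nodes.

    The aggregates are the sum over the three unordered node pairs of the
    full symmetric block on the union of the two node windows, i.e.
    ``n_matrix = sum (|a|+|b|)^2`` — the convention recovered from the
    printed 3-node table rows.
    """
    if len(nodes) < 3:
        raise ValueError(
            f"need >= 3 primary nodes, have {len(nodes)}: "
            + "; ".join(str(n) for n in nodes)
        )
    top = sorted(nodes, key=lambda nd: nd.weight, reverse=True)[:3]
    windows = [np.arange(nd.start - 1, nd.end) for nd in top]
    tot = np.zeros(4)
    null_tot = np.zeros(4)
    for a in range(3):
        for b in range(a + 1, 3):
            union = np.union1d(windows[a], windows[b])
            sel = NetworkSelection.intra(union, label="pair")
            tot += np.array(_block_aggregates(D.values, sel))
            if null_ref is not None and not isinstance(null_ref, NetworkMetrics):
                null_tot += np.array(
                    null_ref.aggregates(sel.rows, sel.cols, True)
                )
    label = "3node(" + ",".join(str(nd.peak) for nd in top) + ")"
    m = NetworkMetrics(label=label, sum_pos=tot[0], n_corr=tot[1],
                       n_pos=tot[2], n_matrix=int(tot[3]))
    if null_ref is None:
        return m
    if isinstance(null_ref, NetworkMetrics):
        return m.normalized_against(null_ref)
    ref = NetworkMetrics(label="randomized[3node]", sum_pos=null_tot[0],
                         n_corr=null_tot[1], n_pos=null_tot[2],
                         n_matrix=int(null_tot[3]))
    return m.normalized_against(ref)


def centrality_autocorrelation(
    x: np.ndarray, max_lag: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Mean-centred normalised autocorrelation G over integer residue lags.

    Returns ``(lags, G, peak_lags)``; peaks are interior local maxima with
    G > 0. A constant profile yields all-zero G with a warning. The
    profile must be at least 3x the maximum lag.
    """
    x = np.asarray(x, dtype=float)
    if max_lag is None:
        max_lag = x.size // 3
    if x.size < 3 * max_lag:
        raise ValueError("profile shorter than 3x max lag")
    xc = x - x.mean()
    var = float(xc @ xc)
    lags = np.arange(1, max_lag + 1)
    if var == 0:
        warnings.warn("constant profile: autocorrelation undefined, zero G",
                      stacklevel=2)
        return lags, np.zeros(max_lag), []
    G = np.array([float(xc[:-k] @ xc[k:]) / var for k in lags])
    peaks = [
        int(lags[i])
        for i in range(1, len(G) - 1)
        if G[i] > G[i - 1] and G[i] > G[i + 1] and G[i] > 0
    ]
    return lags, G, peaks
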