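"""Model/Results interface over the coevolution-network analysis.

:class:`CoevolutionNetwork` is built from an alignment (plus optional
domain boundaries); :meth:`CoevolutionNetwork.fit` estimates the
coevolution matrix, calibrates it against a column-shuffled null library
and returns a :class:`CoevolutionNetworkResults` carrying the centrality
and difference profiles, primary nodes, the 3-sigma edge set, and
strength/connectivity metrics for any selection, with ``summary()``
producing a metrics table in the style of the domain-network tables.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coevo, msa, netmetrics, nullmodel
from .errors import ConfigError

logger = logging.getLogger(__name__)


class CoevolutionNetwork:
    """Coevolution-network model of a multiple sequence alignment.

    Parameters
    ----------
    alignment : msa.Alignment
        The (trimmed) alignment to analyse.
    settings : coevo.EstimatorSettings, optional
        Estimator parameters (sequence weighting, pseudocount, glasso rho).
    window : int
        Node window length in residues (default 6).
    domains : dict, optional
        name -> (start, end) 1-based inclusive column ranges.

    Examples
    --------
    >>> aln, truth, _ = synthdata.reference_bundle(seed=1)
    >>> res = CoevolutionNetwork(aln).fit(n_null=10, seed=1)
    >>> res.primary_nodes
    """

    def __init__(
        self,
        alignment: msa.Alignment,
        settings: Optional[coevo.EstimatorSettings] = None,
        window: int = 6,
        domains: Optional[dict] = None,
    ) -> None:
        self.alignment = alignment
        self.settings = settings or coevo.EstimatorSettings()
        self.window = int(window)
        self.domains = dict(domains or {})
        for name, (a, b) in self.domains.items():
            if not (1 <= a <= b <= alignment.L):
                raise ConfigError(
                    f"domain {name!r} range ({a}, {b}) outside 1..{alignment.L}"
                )

    @classmethod
    def from_file(cls, path: str | Path, format: str = "fasta",
                  **kwargs) -> "CoevolutionNetwork":
        return cls(msa.read_alignment(path, format=format), **kwargs)

    def fit(
        self,
        n_null: int = 100,
        seed: int = 0,
        keep_null_matrices: bool = False,
        node_sigma: float = 2.0,
    ) -> "CoevolutionNetworkResults":
        """Estimate the matrix, build the null library and derive profiles.

        ``n_null`` is the shuffled-library size (100 by default; smaller
        values widen every sigma-based threshold's sampling error).
        """
        D = coevo.coevolution_matrix(self.alignment, self.settings)
        null = nullmodel.build_library(
            self.alignment, K=n_null, settings=self.settings, seed=seed,
            keep_matrices=keep_null_matrices,
        )
        centrality = netmetrics.eigen_centrality(D)
        delta = netmetrics.difference_profile(centrality, null, n=self.window)
        nodes = netmetrics.detect_primary_nodes(delta, null, sigma=node_sigma)
        threshold, edge_mask = coevo.high_scoring_threshold(D, null)
        entropy = msa.shannon_entropy(self.alignment)
        full = np.arange(D.L)
        sp, nc, npos, nm = null.aggregates(full, full, True)
        randomized_row = netmetrics.NetworkMetrics(
            label="randomized", sum_pos=sp, n_corr=nc, n_pos=npos,
            n_matrix=nm, C=1.0, S_M=1.0)
        return CoevolutionNetworkResults(
            model=self,
            matrix=D,
            null=null,
            centrality=centrality,
            delta=delta,
            primary_nodes=nodes,
            edge_threshold=float(threshold),
            edge_mask=edge_mask,
            entropy=entropy,
            randomized_row=randomized_row,
            seed=seed,
        )


@dataclass
class CoevolutionNetworkResults:
    """Fitted coevolution network.

    Attributes
    ----------
    matrix : coevo.CoevolutionMatrix
        Normalised direct-information matrix (diagonal masked).
    null : nullmodel.NullLibrary
        Shuffled-library calibration (entry and centrality moments).
    centrality, delta
        Eigenvector centrality and the null-corrected difference profile.
    primary_nodes : list of netmetrics.PrimaryNode
        Windows exceeding the null window mean by 2 sigma, merged.
    edge_threshold, edge_mask
        The 3-sigma high-scoring threshold and its boolean edge mask.
    """

    model: CoevolutionNetwork
    matrix: coevo.CoevolutionMatrix
    null: nullmodel.NullLibrary
    centrality: netmetrics.CentralityProfile
    delta: netmetrics.NodeWeightProfile
    primary_nodes: list
    edge_threshold: float
    edge_mask: np.ndarray
    entropy: np.ndarray
    randomized_row: netmetrics.NetworkMetrics = None
    seed: int = 0

    # -- selections ---------------------------------------------------
    def selection(self, name: str) -> netmetrics.NetworkSelection:
        """A named selection: 'complete', a domain name, or 'A-B' for the
        inter-domain block of domains A and B."""
        if name == "complete":
            return netmetrics.NetworkSelection.intra(
                np.arange(self.matrix.L), label="complete")
        doms = self.model.domains
        if name in doms:
            a, b = doms[name]
            return netmetrics.NetworkSelection.intra(
                np.arange(a - 1, b), label=name)
        if "-" in name:
            left, right = name.split("-", 1)
            if left in doms and right in doms:
                a1, b1 = doms[left]
                a2, b2 = doms[right]
                return netmetrics.NetworkSelection.inter(
                    np.arange(a1 - 1, b1), np.arange(a2 - 1, b2), label=name)
        raise KeyError(f"unknown selection {name!r}")

    def metrics(
        self,
        sel: "str | netmetrics.NetworkSelection" = "complete",
        restrict_null: bool = False,
    ) -> netmetrics.NetworkMetrics:
        """Strength S_M and connectivity C of a selection.

        Every sub-network is normalised against the single global
        randomized-library row (the published tables' convention);
        ``restrict_null`` switches to the library reference restricted to
        the same block instead.
        """
        if isinstance(sel, str):
            sel = self.selection(sel)
        ref = self.null if restrict_null else self.randomized_row
        return netmetrics.network_metrics(self.matrix, sel, ref)

    def metrics_table(self, names: Optional[Sequence[str]] = None
                      ) -> pd.DataFrame:
        """One row per named network (complete, each domain, each
        inter-domain pair by default)."""
        if names is None:
            names = ["complete"] + list(self.model.domains)
            dom = list(self.model.domains)
            names += [f"{a}-{b}" for i, a in enumerate(dom)
                      for b in dom[i + 1:]]
        rows = [self.metrics(n).as_row() for n in names]
        return pd.DataFrame(rows)

    def three_node_metrics(self) -> netmetrics.NetworkMetrics:
        return netmetrics.three_node_network(
            self.matrix, self.primary_nodes, self.randomized_row)

    def autocorrelation(self, max_lag: Optional[int] = None):
        """Centrality autocorrelation over residue lags (helical-repeat
        detection)."""
        return netmetrics.centrality_autocorrelation(
            self.centrality.E, max_lag=max_lag)

    # -- frames and reports -------------------------------------------
    def per_position_frame(self) -> pd.DataFrame:
        """Per-position table: entropy, E, E_R, deltaW and the node
        weight of the window starting at the position (1-based)."""
        L = self.matrix.L
        W = np.full(L, np.nan)
        W[: self.delta.W.size] = self.delta.W
        return pd.DataFrame({
            "position": np.arange(1, L + 1),
            "entropy": self.entropy,
            "E": self.centrality.E,
            "E_R": self.null.E_R,
            "deltaW": self.delta.deltaW,
            "W": W,
        })

    def nodes_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"node_id": k + 1, "start": nd.start, "end": nd.end,
             "peak": nd.peak, "W": nd.weight}
            for k, nd in enumerate(self.primary_nodes)
        ], columns=["node_id", "start", "end", "peak", "W"])

    def summary(self) -> str:
        """Human-readable fit summary."""
        buf = io.StringIO()
        aln = self.model.alignment
        buf.write("Coevolution network results\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"alignment: N={aln.N} sequences, L={aln.L} columns\n")
        buf.write(f"null library: K={self.null.K}, seed={self.seed}\n")
        buf.write(
            f"edge threshold (null mean + 3 sigma): {self.edge_threshold:.4g}"
            f"  ->  {int(self.edge_mask.sum() // 2)} high-scoring pairs\n"
        )
        buf.write(f"leading eigenvalue: {self.centrality.lam:.4g}\n")
        buf.write(f"centrality scale M_E/M_R: {self.delta.scale:.4g}\n")
        buf.write(f"primary nodes ({len(self.primary_nodes)}):\n")
        for nd in self.primary_nodes:
            buf.write(f"  {nd}\n")
        buf.write("-" * 60 + "\n")
        with pd.option_context("display.width", 120):
            buf.write(self.metrics_table().round(3).to_string(index=False))
        buf.write("\n")
        return buf.getvalue()

    # -- plots --------------------------------------------------------
    def plot_centrality(self, ax=None):
        """Centrality, null profile and difference profile vs position."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        x = np.arange(1, self.matrix.L + 1)
        ax.plot(x, self.centrality.E, label="E", lw=1)
        ax.plot(x, self.delta.scale * self.null.E_R,
                label="scaled $E_R$", lw=1, ls="--")
        ax.plot(x, self.delta.deltaW, label=r"$\delta W$", lw=1)
        for nd in self.primary_nodes:
            ax.axvspan(nd.start, nd.end, alpha=0.15, color="red")
        ax.set_xlabel("position")
        ax.set_ylabel("centrality")
        ax.legend(fontsize=8)
        return ax

    def plot_matrix(self, ax=None):
        """The coevolution matrix as an image (diagonal masked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(self.matrix.values, origin="lower",
                       extent=(0.5, self.matrix.L + 0.5,
                               0.5, self.matrix.L + 0.5))
        plt.colorbar(im, ax=ax, label="D")
        ax.set_xlabel("position")
        ax.set_ylabel("position")
        return ax
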