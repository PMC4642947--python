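"""Mutation-defined sub-networks.

Lists of residue positions targeted by clockwise (CW) or counter-clockwise
(CCW) chemotaxis mutations define binary mask matrices over the coevolution
matrix; permuted "dummy" position lists of the same cardinality provide the
significance reference (the dummy/real S_M and C ratio distribution).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .coevo import CoevolutionMatrix
from .msa import ColumnMap
from .netmetrics import (
    CentralityProfile,
    NetworkMetrics,
    NetworkSelection,
    eigen_centrality,
    network_metrics,
)

logger = logging.getLogger(__name__)


@dataclass
class MutationList:
    """Reference-numbered residue positions with a phenotype label."""

    label: str                       # "CW", "CCW" or custom
    positions: frozenset[int]
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = frozenset(int(p) for p in self.positions)

    def __len__(self) -> int:
        return len(self.positions)


def read_mutation_lists(path: str | Path) -> dict[str, MutationList]:
    """Read two-column TSV (position, label) into per-label lists."""
    groups: dict[str, set[int]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in ("position", "pos"):
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 'position<TAB>label'")
            groups.setdefault(parts[1], set()).add(int(parts[0]))
    return {
        label: MutationList(label=label, positions=frozenset(pos),
                            source=str(path))
        for label, pos in groups.items()
    }


@dataclass
class MaskMatrix:
    """Binary symmetric mask: 1 at off-diagonal (i,j) with both positions
    in the mutation list; popcount = m(m-1) for m mapped positions."""

    B: np.ndarray
    mapped: np.ndarray          # 0-based matrix indices of mapped positions
    dropped: int = 0
    label: str = ""

    @property
    def popcount(self) -> int:
        return int(self.B.sum())


def build_mask(
    mlist: MutationList,
    cmap: Optional[ColumnMap],
    L: int,
) -> MaskMatrix:
    """Build the mask matrix for a mutation list.

    ``cmap`` maps reference residue numbers to alignment columns
    (1-based); pass ``None`` when positions are already 1-based matrix
    positions. Unmappable positions are logged and dropped; fewer than
    two mappable positions is an error.
    """
    mapped = []
    dropped = 0
    for p in sorted(mlist.positions):
        if cmap is None:
            col = p
        else:
            col = cmap.ref_to_col.get(p)
        if col is None or not (1 <= col <= L):
            dropped += 1
            logger.info("mutation position %s (%s) not mappable; dropped",
                        p, mlist.label)
            continue
        mapped.append(col - 1)
    if len(mapped) < 2:
        raise ValueError(
            f"mutation list {mlist.label!r}: fewer than 2 mappable positions"
        )
    idx = np.asarray(mapped, dtype=int)
    B = np.zeros((L, L), dtype=np.int8)
    B[np.ix_(idx, idx)] = 1
    np.fill_diagonal(B, 0)
    return MaskMatrix(B=B, mapped=idx, dropped=dropped, label=mlist.label)


def masked_network(
    D: CoevolutionMatrix,
    mask: MaskMatrix,
    null_ref=None,
) -> tuple[NetworkMetrics, CentralityProfile]:
    """Metrics and centrality of the element-wise product D o B.

    The selection is the symmetric block over the masked positions; the
    null reference (library or reference row) is restricted identically.
    """
    if mask.B.shape != D.values.shape:
        raise ValueError("mask and matrix dimensions differ")
    sel = NetworkSelection.intra(mask.mapped, label=mask.label or "mask")
    metrics = network_metrics(D, sel, null_ref)
    masked_values = np.where(mask.B > 0, D.values, np.nan)
    cent = eigen_centrality(CoevolutionMatrix(
        values=masked_values, positions=D.positions))
    return metrics, cent


@dataclass
class DummyPopulation:
    """Dummy/real ratio distribution for S_M and C."""

    n_dummies: int
    seed: int
    real: NetworkMetrics
    sm_ratio_mean: float
    sm_ratio_sigma: float
    c_ratio_mean: float
    c_ratio_sigma: float
    sm_ratios: np.ndarray = field(repr=False, default=None)
    c_ratios: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_dummies": self.n_dummies,
            "seed": self.seed,
            "real_S_M": self.real.S_M if self.real.S_M is not None
            else self.real.strength_raw,
            "real_C": self.real.C if self.real.C is not None
            else self.real.density,
            "S_M_ratio": [self.sm_ratio_mean, self.sm_ratio_sigma],
            "C_ratio": [self.c_ratio_mean, self.c_ratio_sigma],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def dummy_population(
    D: CoevolutionMatrix,
    real_list: MutationList,
    n_dummies: int = 1000,
    seed: int = 0,
    cmap: Optional[ColumnMap] = None,
    null_ref=None,
    mode: str = "uniform",
    candidate_positions: Optional[Sequence[int]] = None,
) -> DummyPopulation:
    """Distribution of dummy/real (S_M, C) ratios.

    Each dummy is a random position set of the same cardinality as the
    real list drawn from the analysable positions — uniformly without
    replacement (``mode="uniform"``) or as a contiguous block
    (``mode="contiguous"``). Without a null reference, the raw strength
    and density stand in for S_M and C; the normalisation cancels in the
    ratios either way.
    """
    if n_dummies < 100:
        raise ValueError("need at least 100 dummy draws")
    real_mask = build_mask(real_list, cmap, D.L)
    m = real_mask.mapped.size
    if candidate_positions is None:
        candidates = np.arange(D.L)
    else:
        candidates = np.unique(np.asarray(candidate_positions, int))
    if m > candidates.size:
        raise ValueError(
            f"list cardinality {m} exceeds {candidates.size} available positions"
        )
    real = network_metrics(
        D, NetworkSelection.intra(real_mask.mapped, label=real_list.label),
        null_ref,
    )
    real_sm = real.S_M if real.S_M is not None else real.strength_raw
    real_c = real.C if real.C is not None else real.density

    rng = np.random.default_rng(seed)
    sm = np.empty(n_dummies)
    cc = np.empty(n_dummies)
    for k in range(n_dummies):
        if mode == "uniform":
            pick = rng.choice(candidates, size=m, replace=False)
        elif mode == "contiguous":
            start = rng.integers(0, candidates.size - m + 1)
            pick = candidates[start:start + m]
        else:
            raise ValueError(f"unknown dummy mode: {mode!r}")
        dm = network_metrics(D, NetworkSelection.intra(pick, label="dummy"),
                             null_ref)
        sm[k] = dm.S_M if dm.S_M is not None else dm.strength_raw
        cc[k] = dm.C if dm.C is not None else dm.density
    sm_r = sm / real_sm if real_sm else np.full(n_dummies, np.nan)
    c_r = cc / real_c if real_c else np.full(n_dummies, np.nan)
    return DummyPopulation(
        n_dummies=n_dummies,
        seed=seed,
        real=real,
        sm_ratio_mean=float(np.nanmean(sm_r)),
        sm_ratio_sigma=float(np.nanstd(sm_r)),
        c_ratio_mean=float(np.nanmean(c_r)),
        c_ratio_sigma=float(np.nanstd(c_r)),
        sm_ratios=sm_r,
        c_ratios=c_r,
    )
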