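"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a protein-family alignment at desk scale: a few
hundred sequences, a per-column conservation (entropy) gradient, an
independent per-cell gap process, and planted covarying column pairs.
Coupling follows a diluted bijective symbol map: with probability ``c``
the symbol at the second column is a fixed permutation image of the
symbol at the first, otherwise it is drawn from the column's own
background distribution — simple, analytically tractable (MI -> S_i as
c -> 1) and sufficient for rank-based recovery tests. A toy ideal
alpha-helical Calpha trace with optional planted contact geometry and
mutation-position lists complete the bundle, with ground truth recorded
alongside every dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize

from .msa import GAP_CODE, Alignment, RESIDUES
from .mutnet import MutationList
from .structmap import Atom, Residue, StructureModel

N_RES = len(RESIDUES)  # 20


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic alignment.

    ``entropy_profile`` holds per-column target entropies in bits
    (default: a linear 0.5 -> 3.5 bit gradient, emulating the entropy /
    centrality covariation of real families); ``coupled_pairs`` is a list
    of (i, j, c) with 1-based columns and coupling strength c in [0, 1].
    """

    N: int = 300
    L: int = 120
    entropy_profile: Optional[np.ndarray] = None
    gap_rate: "float | np.ndarray" = 0.05
    coupled_pairs: list = field(default_factory=list)
    domains: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.entropy_profile is None:
            self.entropy_profile = np.linspace(0.5, 3.5, self.L)
        self.entropy_profile = np.asarray(self.entropy_profile, dtype=float)
        if self.entropy_profile.size != self.L:
            raise ValueError("entropy profile length must equal L")
        self.gap_rate = np.broadcast_to(
            np.asarray(self.gap_rate, dtype=float), (self.L,)).copy()
        if (self.gap_rate < 0).any() or (self.gap_rate >= 1).any():
            raise ValueError("per-column gap rates must lie in [0, 1)")
        if (self.entropy_profile > np.log2(N_RES) + 1e-12).any():
            raise ValueError(
                f"entropy target exceeds log2({N_RES}) bits"
            )
        seen = set()
        for (i, j, c) in self.coupled_pairs:
            if not (1 <= i <= self.L and 1 <= j <= self.L) or i == j:
                raise ValueError(f"invalid coupled pair ({i}, {j})")
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coupling strength {c} outside [0, 1]")
            seen.update((i, j))


@dataclass
class GroundTruth:
    """Planted signal record, serialised alongside every dataset."""

    coupled_pairs: list            # [(i, j, c)] 1-based
    node_segments: list            # [(start, end)] 1-based inclusive
    contacts: list = field(default_factory=list)
    far_pairs: list = field(default_factory=list)
    mutation_lists: dict = field(default_factory=dict)
    seed: int = 0

    def planted_positions(self) -> set[int]:
        pos = set()
        for (i, j, _c) in self.coupled_pairs:
            pos.update((i, j))
        return pos

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coupled_pairs": [[int(i), int(j), float(c)]
                              for i, j, c in self.coupled_pairs],
            "node_segments": [[int(a), int(b)] for a, b in self.node_segments],
            "contacts": [[int(a), int(b)] for a, b in self.contacts],
            "far_pairs": [[int(a), int(b)] for a, b in self.far_pairs],
            "mutation_lists": {
                k: sorted(v.positions) for k, v in self.mutation_lists.items()
            },
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _column_distribution(target_bits: float, rng: np.random.Generator
                         ) -> np.ndarray:
    """A 20-symbol distribution with the requested entropy: one dominant
    symbol at probability p, the rest uniform; p solved by bisection."""
    if target_bits <= 0:
        d = np.zeros(N_RES)
        d[rng.integers(N_RES)] = 1.0
        return d

    def H(p: float) -> float:
        q = (1 - p) / (N_RES - 1)
        h = -p * np.log2(p)
        if q > 0:
            h -= (N_RES - 1) * q * np.log2(q)
        return h

    if target_bits >= np.log2(N_RES) - 1e-9:
        p = 1.0 / N_RES
    else:
        p = brentq(lambda x: H(x) - target_bits, 1.0 / N_RES, 1 - 1e-12)
    d = np.full(N_RES, (1 - p) / (N_RES - 1))
    d[0] = p
    return rng.permutation(d)


def generate_msa(spec: SyntheticSpec) -> tuple[Alignment, GroundTruth]:
    """Draw an alignment from the spec; reproducible from (spec, seed).

    Columns are drawn independently to match the target entropies; each
    coupled pair (i, j, c) then overwrites column j with the bijective
    image of column i with probability c per sequence. Gaps are applied
    last as independent per-cell events at the column gap rate.
    """
    rng = np.random.default_rng(spec.seed)
    N, L = spec.N, spec.L
    data = np.zeros((N, L), dtype=np.int8)
    for j in range(L):
        dist = _column_distribution(spec.entropy_profile[j], rng)
        data[:, j] = rng.choice(N_RES, size=N, p=dist)
    for (i, j, c) in spec.coupled_pairs:
        perm = rng.permutation(N_RES)
        follow = rng.random(N) < c
        data[follow, j - 1] = perm[data[follow, i - 1]]
    if (spec.gap_rate > 0).any():
        gaps = rng.random((N, L)) < spec.gap_rate[None, :]
        data[gaps] = GAP_CODE
    ids = [f"seq{k:04d}_SP{k:04d}/1-{L}" for k in range(N)]
    aln = Alignment(ids=ids, data=data)
    segments = _infer_segments(spec.coupled_pairs)
    truth = GroundTruth(
        coupled_pairs=list(spec.coupled_pairs),
        node_segments=segments,
        seed=spec.seed,
    )
    return aln, truth


def _infer_segments(pairs: Sequence[tuple], min_run: int = 4) -> list:
    """Contiguous runs of planted endpoints (>= min_run long) are the
    planted node segments."""
    pos = sorted({p for (i, j, _c) in pairs for p in (i, j)})
    segments = []
    k = 0
    while k < len(pos):
        m = k
        while m + 1 < len(pos) and pos[m + 1] == pos[m] + 1:
            m += 1
        if m - k + 1 >= min_run:
            segments.append((pos[k], pos[m]))
        k = m + 1
    return segments


def reference_bundle(seed: int = 1) -> tuple[Alignment, GroundTruth, SyntheticSpec]:
    """The canonical desk-scale dataset: N=300, L=120, entropy gradient
    0.5 -> 3.5 bits, gap rate 0.05, and 8 pairs planted at c=0.9 — two
    position-wise coupled 6-residue segments (60-65 <-> 100-105) plus two
    isolated pairs (30, 75) and (45, 90)."""
    pairs = [(60 + k, 100 + k, 0.9) for k in range(6)]
    pairs += [(30, 75, 0.9), (45, 90, 0.9)]
    spec = SyntheticSpec(N=300, L=120, coupled_pairs=pairs, seed=seed)
    aln, truth = generate_msa(spec)
    return aln, truth, spec


# ---------------------------------------------------------------------
# toy structure


def _ideal_helix(L: int, rise: float = 1.5, twist_deg: float = 100.0,
                 radius: float = 2.3) -> np.ndarray:
    t = np.deg2rad(twist_deg) * np.arange(L)
    return np.column_stack(
        (radius * np.cos(t), radius * np.sin(t), rise * np.arange(L))
    )


def generate_structure(
    L: int,
    contacts: Sequence[tuple[int, int]] = (),
    far_pairs: Sequence[tuple[int, int]] = (),
    sequence: Optional[str] = None,
    seed: int = 0,
) -> tuple[StructureModel, GroundTruth]:
    """An ideal alpha-helical Calpha trace (rise 1.5 A, 100 deg twist,
    radius 2.3 A), refolded if necessary so planted contact pairs sit
    < 12 A apart and designated far pairs > 20 A apart (1-based residue
    pairs). Raises if the constraint set cannot be satisfied."""
    coords = _ideal_helix(L)
    contacts = [(int(a), int(b)) for a, b in contacts]
    far_pairs = [(int(a), int(b)) for a, b in far_pairs]
    for a, b in contacts + far_pairs:
        if not (1 <= a <= L and 1 <= b <= L) or a == b:
            raise ValueError(f"invalid residue pair ({a}, {b})")

    def violated(X: np.ndarray) -> bool:
        for a, b in contacts:
            if np.linalg.norm(X[a - 1] - X[b - 1]) >= 12.0:
                return True
        for a, b in far_pairs:
            if np.linalg.norm(X[a - 1] - X[b - 1]) <= 20.0:
                return True
        return False

    if violated(coords):
        bonds = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        target_bond = float(bonds.mean())

        def penalty(flat: np.ndarray) -> float:
            X = flat.reshape(L, 3)
            d = np.linalg.norm(np.diff(X, axis=0), axis=1)
            val = ((d - target_bond) ** 2).sum() * 10.0
            for a, b in contacts:
                dd = np.linalg.norm(X[a - 1] - X[b - 1])
                val += max(dd - 9.0, 0.0) ** 2
            for a, b in far_pairs:
                dd = np.linalg.norm(X[a - 1] - X[b - 1])
                val += max(25.0 - dd, 0.0) ** 2
            return val

        rng = np.random.default_rng(seed)
        x0 = coords + rng.normal(scale=0.1, size=coords.shape)
        res = minimize(penalty, x0.ravel(), method="L-BFGS-B",
                       options={"maxiter": 2000})
        coords = res.x.reshape(L, 3)
        if violated(coords):
            raise ValueError("infeasible contact/far constraint set")

    sequence = sequence or "A" * L
    if len(sequence) != L:
        raise ValueError("sequence length must equal L")
    residues = []
    for k in range(L):
        ca = Atom(name="CA", element="C", coord=coords[k])
        residues.append(Residue(chain="A", number=k + 1, aa=sequence[k],
                                ca=coords[k], atoms=[ca]))
    model = StructureModel(residues=residues, source="synthetic-helix")
    truth = GroundTruth(coupled_pairs=[], node_segments=[],
                        contacts=contacts, far_pairs=far_pairs, seed=seed)
    return model, truth


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Minimal PDB writer for Calpha traces (synthetic structures)."""
    one_to_three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    with open(path, "w") as fh:
        serial = 1
        for res in model.residues:
            name3 = one_to_three.get(res.aa, "UNK")
            for atom in res.atoms:
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:5d} {atom.name:^4s}{name3:>4s} "
                    f"{res.chain}{res.number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------
# mutation lists


def generate_mutation_lists(
    truth: GroundTruth,
    overlap: float,
    size: int = 12,
    L: Optional[int] = None,
    seed: int = 0,
) -> tuple[MutationList, MutationList]:
    """Two equal-size position lists: one overlapping the planted coupled
    positions at the stated fraction (emulating mutations that target
    network features) and one drawn uniformly at random from the
    non-planted positions."""
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = np.array(sorted(truth.planted_positions()), dtype=int)
    if L is None:
        L = int(planted.max()) if planted.size else 0
    others = np.setdiff1d(np.arange(1, L + 1), planted)
    n_in = int(round(overlap * size))
    n_in = min(n_in, planted.size)
    n_out = size - n_in
    if n_out > others.size:
        raise ValueError("not enough non-planted positions for list size")
    pick = np.concatenate([
        rng.choice(planted, size=n_in, replace=False) if n_in else [],
        rng.choice(others, size=n_out, replace=False) if n_out else [],
    ]).astype(int)
    random_pick = rng.choice(others, size=min(size, others.size),
                             replace=False).astype(int)
    targeted = MutationList(label="targeted", positions=frozenset(pick),
                            source=f"synthetic overlap={overlap}")
    background = MutationList(label="random", positions=frozenset(random_pick),
                              source="synthetic uniform")
    truth.mutation_lists = {"targeted": targeted, "random": background}
    return targeted, background


def write_mutation_list_tsv(lists: Sequence[MutationList],
                            path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tlabel\n")
        for ml in lists:
            for p in sorted(ml.positions):
                fh.write(f"{p}\t{ml.label}\n")
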