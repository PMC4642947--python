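"""Structure mapping: Calpha distances, contact statistics, solvent
accessibility, conserved surface patches and superposition RMSD.

Correlated positions are classified by Calpha-Calpha distance into a
contact zone (< 12 A), an intermediate band [12, 20] A and long range
(> 20 A); boundary values fall on the non-contact side. Solvent
accessibility is computed with the Shrake-Rupley rolling-probe method
(probe 1.4 A).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .coevo import CoevolutionMatrix
from .errors import FormatError, MappingError
from .msa import ALPHABET, Alignment, ColumnMap, trim_to_reference

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 12.0
LONG_RANGE_CUTOFF = 20.0

#: van der Waals radii (A) by element, used by Shrake-Rupley
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.70


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    @property
    def radius(self) -> float:
        return VDW_RADII.get(self.element, DEFAULT_RADIUS)


@dataclass
class Residue:
    chain: str
    number: int
    aa: str                      # one-letter code
    ca: np.ndarray               # (3,)
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class StructureModel:
    """Ordered Calpha-bearing residues of one chain of one model."""

    residues: list[Residue]
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])


def read_structure(path: str | Path, chain: Optional[str] = None) -> StructureModel:
    """Read a PDB file: first model, one chain, altlocs resolved to the
    highest occupancy, residues lacking a Calpha excluded (logged).
    Waters and hetero residues are skipped."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise FormatError(f"{path}: no models found") from None
    chains = {c.id: c for c in model}
    if chain is None:
        chain = next(iter(chains))
    if chain not in chains:
        raise FormatError(
            f"{path}: no chain {chain!r}; available: {sorted(chains)}"
        )
    residues: list[Residue] = []
    for res in chains[chain]:
        if res.id[0] != " ":  # hetero / water
            continue
        atoms: list[Atom] = []
        ca = None
        for atom in res:
            if atom.is_disordered():
                atom = max(atom.disordered_get_list(),
                           key=lambda a: a.get_occupancy() or 0.0)
            if atom.element == "H":
                continue
            a = Atom(name=atom.get_name(), element=atom.element or "C",
                     coord=np.asarray(atom.get_coord(), dtype=float))
            atoms.append(a)
            if a.name == "CA":
                ca = a.coord
        if ca is None:
            logger.info("%s chain %s residue %s lacks CA; excluded",
                        path.name, chain, res.id[1])
            continue
        aa = protein_letters_3to1.get(res.get_resname().upper(), "X")
        residues.append(Residue(chain=chain, number=res.id[1], aa=aa,
                                ca=ca, atoms=atoms))
    if not residues:
        raise FormatError(f"{path}: chain {chain} has no CA-bearing residues")
    return StructureModel(residues=residues, source=path.stem)


@dataclass
class ResidueMap:
    """Bijective map alignment column <-> structure residue.

    ``columns[k]`` (1-based alignment column) corresponds to
    ``residue_indices[k]`` (0-based index into the structure model).
    """

    columns: np.ndarray
    residue_indices: np.ndarray
    model: StructureModel
    coverage: float

    def __len__(self) -> int:
        return len(self.columns)

    def column_for_residue(self, idx: int) -> Optional[int]:
        hits = np.flatnonzero(self.residue_indices == idx)
        return int(self.columns[hits[0]]) if hits.size else None


def map_structure(aln: Alignment, model: StructureModel,
                  ref_id: Optional[str] = None,
                  min_identity: float = 0.5) -> ResidueMap:
    """Map alignment columns onto structure residues.

    The structure sequence is threaded into the alignment (or matched to
    an existing row named ``ref_id``); residue types must agree at every
    mapped position — a mismatch is a hard error, the correctness check
    for high-scoring correlation mapping.
    """
    ref_id = ref_id or model.source or "structure"
    _, cmap = trim_to_reference(aln, model.sequence, ref_id,
                                min_identity=min_identity)
    cols = np.array(sorted(cmap.col_to_ref), dtype=int)
    res_idx = np.array([cmap.col_to_ref[c] - 1 for c in cols], dtype=int)
    # type agreement between alignment reference row and structure
    if ref_id in aln.ids:
        row = aln.data[aln.ids.index(ref_id)]
        for c, ri in zip(cols, res_idx):
            sym = ALPHABET[row[c - 1]]
            if sym != model.residues[ri].aa and "X" not in (sym, model.residues[ri].aa):
                raise MappingError(
                    f"residue type mismatch at column {c}: alignment has "
                    f"{sym}, structure residue "
                    f"{model.residues[ri].number} is {model.residues[ri].aa}"
                )
    coverage = len(cols) / aln.L
    return ResidueMap(columns=cols, residue_indices=res_idx,
                      model=model, coverage=coverage)


def distance_matrix(model: StructureModel,
                    rmap: Optional[ResidueMap] = None) -> np.ndarray:
    """Pairwise Calpha Euclidean distances (A); symmetric, zero diagonal.

    With a residue map, rows/columns follow the mapped columns' order.
    """
    if rmap is not None:
        coords = model.ca_coords()[rmap.residue_indices]
    else:
        coords = model.ca_coords()
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 mapped residues")
    return cdist(coords, coords)


@dataclass
class ContactStats:
    """Per-distance-class correlation statistics.

    ``classes`` maps class name -> dict(count, mean, sigma, F) where F is
    the fraction of pairs above the 3-sigma high-scoring threshold.
    Classes: contact [0, 12) A, intermediate [12, 20] A, long (20, inf);
    the two-way split merges intermediate+long into "non_contact".
    """

    contact_cutoff: float
    long_range_cutoff: float
    classes: dict

    def two_way(self) -> dict:
        return {k: self.classes[k] for k in ("contact", "non_contact")}


def _class_stats(vals: np.ndarray, hs: np.ndarray) -> dict:
    n = int(vals.size)
    if n == 0:
        return {"count": 0, "mean": None, "sigma": None, "F": None}
    return {
        "count": n,
        "mean": float(vals.mean()),
        "sigma": float(vals.std()),
        "F": float(hs.mean()),
    }


def contact_stats(
    D: CoevolutionMatrix | np.ndarray,
    distances: np.ndarray,
    threshold_mask: np.ndarray,
    contact_cutoff: float = CONTACT_CUTOFF,
    long_range_cutoff: float = LONG_RANGE_CUTOFF,
) -> ContactStats:
    """Correlation statistics by Calpha distance class over unordered
    pairs (i < j). The distance classes partition all mapped pairs."""
    V = D.values if isinstance(D, CoevolutionMatrix) else np.asarray(D, float)
    if V.shape != distances.shape:
        raise ValueError("matrix and distance matrix dimensions differ")
    iu = np.triu_indices(V.shape[0], 1)
    vals = V[iu]
    dist = distances[iu]
    hs = threshold_mask[iu]
    ok = ~np.isnan(vals)
    vals, dist, hs = vals[ok], dist[ok], hs[ok]
    contact = dist < contact_cutoff
    longr = dist > long_range_cutoff
    inter = ~contact & ~longr
    classes = {
        "contact": _class_stats(vals[contact], hs[contact]),
        "intermediate": _class_stats(vals[inter], hs[inter]),
        "long_range": _class_stats(vals[longr], hs[longr]),
        "non_contact": _class_stats(vals[~contact], hs[~contact]),
    }
    return ContactStats(contact_cutoff=contact_cutoff,
                        long_range_cutoff=long_range_cutoff, classes=classes)


# ---------------------------------------------------------------------
# solvent accessibility (Shrake-Rupley)


def _sphere_points(n: int) -> np.ndarray:
    """Golden-spiral quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def solvent_accessibility(
    model: StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    normalize: bool = False,
) -> np.ndarray:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    Test points on each atom's expanded sphere (radius r + probe) are
    counted accessible when outside every neighbouring atom's expanded
    sphere; the accessible fraction scales the sphere area
    4 pi (r + probe)^2. Atom areas are summed per residue. With
    ``normalize`` the per-residue areas are divided by the largest
    per-residue area in the model (a relative-exposure score in [0, 1]).
    """
    atoms = [(ri, a) for ri, res in enumerate(model.residues)
             for a in res.atoms]
    if not atoms:
        raise ValueError("structure has no atoms")
    coords = np.array([a.coord for _, a in atoms])
    radii = np.array([a.radius for _, a in atoms])
    expanded = radii + probe
    tree = cKDTree(coords)
    unit = _sphere_points(n_points)
    areas = np.zeros(len(model.residues))
    max_reach = 2 * expanded.max()
    for i, (ri, atom) in enumerate(atoms):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d > expanded[j]
            if not accessible.any():
                break
        frac = accessible.mean()
        areas[ri] += frac * 4.0 * np.pi * expanded[i] ** 2
    if normalize and areas.max() > 0:
        areas = areas / areas.max()
    return areas


# ---------------------------------------------------------------------
# conserved surface patches


@dataclass
class SurfacePatch:
    """A contiguous run (> 4 columns) where both conservation and
    accessibility strictly exceed their profile means (1-based,
    inclusive)."""

    start: int
    end: int
    mean_conservation: float
    mean_accessibility: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def conservation_from_entropy(S: np.ndarray) -> np.ndarray:
    """Entropy-based conservation proxy: 1 - S_i / max(S)."""
    S = np.asarray(S, dtype=float)
    smax = S.max()
    return 1.0 - S / smax if smax > 0 else np.ones_like(S)


def surface_patches(
    conservation: np.ndarray,
    accessibility: np.ndarray,
    min_length: int = 5,
) -> list[SurfacePatch]:
    """Maximal runs of length >= ``min_length`` (the "> 4" rule) where
    both per-column scores strictly exceed their own means."""
    c = np.asarray(conservation, dtype=float)
    a = np.asarray(accessibility, dtype=float)
    if c.size != a.size:
        raise ValueError("profiles differ in length")
    qual = (c > c.mean()) & (a > a.mean())
    patches: list[SurfacePatch] = []
    i = 0
    while i < qual.size:
        if qual[i]:
            j = i
            while j + 1 < qual.size and qual[j + 1]:
                j += 1
            if j - i + 1 >= min_length:
                patches.append(SurfacePatch(
                    start=i + 1, end=j + 1,
                    mean_conservation=float(c[i:j + 1].mean()),
                    mean_accessibility=float(a[i:j + 1].mean()),
                ))
            i = j + 1
        else:
            i += 1
    return patches


# ---------------------------------------------------------------------
# superposition


def superpose_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
) -> float:
    """Least-squares rigid-body superposition RMSD (A) over paired
    Calpha coordinates ((n, 3) each, n >= 3)."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 common positions")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(Ac, Bc)
    return float(rssd / np.sqrt(A.shape[0]))


def superpose_models(
    model_a: StructureModel,
    model_b: StructureModel,
    pairs: Sequence[tuple[int, int]],
) -> float:
    """RMSD over a common set of residues; ``pairs`` are 0-based residue
    indices (idx_a, idx_b)."""
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    return superpose_rmsd(model_a.ca_coords()[ia], model_b.ca_coords()[ib])


# ---------------------------------------------------------------------
# annotated edge map


def edge_map(
    D: CoevolutionMatrix,
    threshold_mask: np.ndarray,
    rmap: ResidueMap,
    distances: np.ndarray,
    contact_cutoff: float = CONTACT_CUTOFF,
    long_range_cutoff: float = LONG_RANGE_CUTOFF,
) -> pd.DataFrame:
    """High-scoring pairs annotated with residues, distance and class.

    ``D``, ``threshold_mask`` and ``distances`` are all over the mapped
    columns (same order as ``rmap.columns``).
    """
    rows = []
    m = len(rmap)
    for i in range(m):
        for j in range(i + 1, m):
            if not threshold_mask[i, j]:
                continue
            d = distances[i, j]
            if d < contact_cutoff:
                klass = "contact"
            elif d > long_range_cutoff:
                klass = "long_range"
            else:
                klass = "intermediate"
            ra = rmap.model.residues[rmap.residue_indices[i]]
            rb = rmap.model.residues[rmap.residue_indices[j]]
            rows.append({
                "col_i": int(rmap.columns[i]),
                "col_j": int(rmap.columns[j]),
                "res_i": f"{ra.aa}{ra.number}",
                "res_j": f"{rb.aa}{rb.number}",
                "D": float(D.values[i, j]),
                "dist_A": float(d),
                "class": klass,
            })
    return pd.DataFrame(
        rows, columns=["col_i", "col_j", "res_i", "res_j", "D", "dist_A",
                       "class"],
    )
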