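"""Multiple sequence alignments: I/O, validation, concatenation, trimming,
and per-column Shannon entropy.

The alignment alphabet is the 20 standard amino acids, an "unknown" symbol
``X`` (to which non-standard residue codes B, Z, J, U, O are normalised) and
a single gap symbol ``-`` (the ``.`` gap dialect is normalised to ``-``).
Gaps are treated as a regular symbol throughout, in particular when
computing column entropies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import AlignmentError, EmptyResultError, FormatError, MappingError

logger = logging.getLogger(__name__)

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "X"
GAP = "-"
ALPHABET = RESIDUES + UNKNOWN + GAP
N_SYMBOLS = len(ALPHABET)  # 22
GAP_CODE = ALPHABET.index(GAP)
UNKNOWN_CODE = ALPHABET.index(UNKNOWN)

_NONSTANDARD = set("BZJUO*")

_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
for _c in _NONSTANDARD:
    _ENCODE[ord(_c)] = UNKNOWN_CODE
_ENCODE[ord(".")] = GAP_CODE


def _encode_row(row: str, identifier: str) -> np.ndarray:
    arr = np.frombuffer(row.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE[np.minimum(arr, 127)]
    bad = codes < 0
    if bad.any():
        # any other unexpected character is treated as unknown, but logged
        logger.warning(
            "record %s: %d unrecognised symbols mapped to '%s'",
            identifier, int(bad.sum()), UNKNOWN,
        )
        codes = np.where(bad, UNKNOWN_CODE, codes)
    return codes.astype(np.int8)


@dataclass
class Alignment:
    """A validated multiple sequence alignment.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, one per row.
    data : (N, L) int8 array
        Symbol codes into :data:`ALPHABET`.
    """

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2:
            raise AlignmentError("alignment data must be 2-dimensional")
        if len(self.ids) != self.data.shape[0]:
            raise AlignmentError("number of identifiers does not match depth")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate identifiers: {dup[:5]}")
        if self.N < 2:
            raise AlignmentError("alignment must contain at least 2 sequences")

    # -- dimensions ---------------------------------------------------
    @property
    def N(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        return self.data.shape[1]

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids: list[str] = []
        rows: list[np.ndarray] = []
        length = None
        for ident, row in records:
            if length is None:
                length = len(row)
            elif len(row) != length:
                raise AlignmentError(
                    f"record {ident!r} has length {len(row)}, expected {length}"
                )
            ids.append(ident)
            rows.append(_encode_row(row, ident))
        if not rows:
            raise FormatError("no sequence records found")
        return cls(ids=ids, data=np.vstack(rows))

    # -- accessors ----------------------------------------------------
    def row(self, i: int) -> str:
        return "".join(ALPHABET[c] for c in self.data[i])

    def ungapped(self, i: int) -> str:
        return self.row(i).replace(GAP, "")

    def records(self) -> list[tuple[str, str]]:
        return [(ident, self.row(i)) for i, ident in enumerate(self.ids)]

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(ids=list(self.ids), data=self.data[:, list(cols)])

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ident, row in self.records():
                fh.write(f">{ident}\n{row}\n")


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read and validate an alignment from FASTA or Stockholm.

    Both ``-`` and ``.`` gap dialects are accepted; symbols are uppercased.
    Ragged rows raise :class:`AlignmentError` naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    elif format == "stockholm":
        try:
            aln = AlignIO.read(str(path), "stockholm")
        except ValueError as exc:
            raise FormatError(f"cannot parse {path} as Stockholm: {exc}") from exc
        records = [(r.id, str(r.seq)) for r in aln]
    else:
        raise ValueError(f"unknown alignment format: {format!r}")
    if not records:
        raise FormatError(f"{path}: no sequences found")
    return Alignment.from_records(records)


def shannon_entropy(aln: Alignment) -> np.ndarray:
    """Per-column Shannon entropy in bits, S_i = -sum_j p_ij log2 p_ij.

    Gaps count as a regular symbol. ``0 <= S_i <= log2(22)``; a
    single-symbol column has zero entropy.
    """
    counts = np.zeros((aln.L, N_SYMBOLS))
    for s in range(N_SYMBOLS):
        counts[:, s] = (aln.data == s).sum(axis=0)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


# ---------------------------------------------------------------------
# concatenation


def default_key(identifier: str) -> str:
    """Extract an organism/protein pairing key from a sequence header.

    Pfam/UniProt headers like ``FLIM_ECOLI/34-220`` pair on the token
    after the last underscore, before any ``/range`` suffix. Headers
    without an underscore pair on the full pre-``/`` token.
    """
    head = identifier.split("/")[0]
    if "_" in head:
        return head.rsplit("_", 1)[1]
    return head


def concatenate(
    alns: Sequence[Alignment],
    key: Callable[[str], str] = default_key,
    mode: str = "dedup",
) -> Alignment:
    """Join alignments column-wise on a shared identifier key.

    Keys present in only some inputs are dropped. Duplicate keys within
    one input are resolved according to ``mode``:

    - ``"dedup"``: keep the best-covered row (fewest gaps), log the rest;
    - ``"many_to_one"``: when only one input has duplicates for a key,
      pair the singleton rows of the other inputs with *each* duplicate
      (one output row per duplicate).
    """
    if len(alns) < 2:
        raise ValueError("need at least two alignments to concatenate")
    if mode not in {"dedup", "many_to_one"}:
        raise ValueError(f"unknown concatenation mode: {mode!r}")

    maps: list[dict[str, list[int]]] = []
    for aln in alns:
        m: dict[str, list[int]] = {}
        for i, ident in enumerate(aln.ids):
            m.setdefault(key(ident), []).append(i)
        maps.append(m)

    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    if not common:
        raise EmptyResultError("no identifier keys shared by all alignments")

    def best_row(aln: Alignment, idxs: list[int]) -> int:
        gaps = [(aln.data[i] == GAP_CODE).sum() for i in idxs]
        keep = idxs[int(np.argmin(gaps))]
        if len(idxs) > 1:
            dropped = [aln.ids[i] for i in idxs if i != keep]
            logger.info("key collision: keeping %s, dropping %s",
                        aln.ids[keep], dropped)
        return keep

    ids: list[str] = []
    rows: list[np.ndarray] = []
    for k in sorted(common):
        idx_lists = [m[k] for m in maps]
        n_dup = [len(ix) for ix in idx_lists]
        if mode == "many_to_one" and sum(n > 1 for n in n_dup) == 1:
            which = n_dup.index(max(n_dup))
            for j, dup_i in enumerate(idx_lists[which]):
                parts = []
                for a, (aln, ix) in enumerate(zip(alns, idx_lists)):
                    i = dup_i if a == which else best_row(aln, ix)
                    parts.append(aln.data[i])
                ids.append(f"{k}|{j + 1}" if len(idx_lists[which]) > 1 else k)
                rows.append(np.concatenate(parts))
        else:
            parts = [aln.data[best_row(aln, ix)]
                     for aln, ix in zip(alns, idx_lists)]
            ids.append(k)
            rows.append(np.concatenate(parts))
    return Alignment(ids=ids, data=np.vstack(rows))


# ---------------------------------------------------------------------
# trimming to a reference sequence


@dataclass
class ColumnMap:
    """Bidirectional map between alignment columns and reference residues.

    Both sides are 1-based: ``col_to_ref[column] = residue_index``.
    """

    col_to_ref: dict[int, int] = field(default_factory=dict)
    ref_to_col: dict[int, int] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "ColumnMap":
        cm = cls()
        for col, ref in pairs:
            cm.col_to_ref[col] = ref
            cm.ref_to_col[ref] = col
        return cm

    def __len__(self) -> int:
        return len(self.col_to_ref)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("alignment_column\treference_residue\n")
            for col in sorted(self.col_to_ref):
                fh.write(f"{col}\t{self.col_to_ref[col]}\n")


def _global_align(query: str, target: str):
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner.align(query, target)[0]


def trim_to_reference(
    aln: Alignment,
    ref_seq: str,
    ref_id: str,
    min_identity: float = 0.5,
) -> tuple[Alignment, ColumnMap]:
    """Retain only columns where the reference carries a residue.

    If ``ref_id`` names an existing row, that row is used directly and its
    residues are checked against ``ref_seq`` (a mismatch is an error). An
    absent reference is threaded into the alignment by global pairwise
    alignment against its closest row; the best-row identity must reach
    ``min_identity`` or a :class:`MappingError` is raised.
    """
    ref_seq = ref_seq.upper().replace(GAP, "").replace(".", "")
    if not ref_seq:
        raise MappingError("empty reference sequence")

    if ref_id in aln.ids:
        ridx = aln.ids.index(ref_id)
        row_codes = aln.data[ridx]
        cols = np.flatnonzero(row_codes != GAP_CODE)
        row_res = "".join(ALPHABET[c] for c in row_codes[cols])
        if len(row_res) != len(ref_seq):
            raise MappingError(
                f"reference {ref_id!r}: alignment row has {len(row_res)} "
                f"residues, sequence has {len(ref_seq)}"
            )
        for k, (a, b) in enumerate(zip(row_res, ref_seq)):
            if a != b and UNKNOWN not in (a, b):
                raise MappingError(
                    f"reference {ref_id!r}: residue type mismatch at "
                    f"reference position {k + 1} (alignment column "
                    f"{int(cols[k]) + 1}): {a} vs {b}"
                )
        pairs = [(int(c) + 1, k + 1) for k, c in enumerate(cols)]
        trimmed = aln.take_columns(cols)
        return trimmed, ColumnMap.from_pairs(pairs)

    # thread the reference through its closest existing row
    best_i, best_ident, best_alignment = -1, -1.0, None
    for i in range(aln.N):
        target = aln.ungapped(i)
        if not target:
            continue
        pw = _global_align(ref_seq, target)
        qa, ta = str(pw[0]), str(pw[1])
        matches = sum(1 for a, b in zip(qa, ta) if a == b and a != "-")
        aligned = sum(1 for a, b in zip(qa, ta) if a != "-" and b != "-")
        ident = matches / max(aligned, 1)
        if ident > best_ident:
            best_i, best_ident, best_alignment = i, ident, pw
    if best_ident < min_identity:
        raise MappingError(
            f"reference {ref_id!r}: best identity to any alignment row is "
            f"{best_ident:.2f}, below the confidence floor {min_identity:.2f}"
        )

    # map reference residues -> columns, through the best row
    row_cols = np.flatnonzero(aln.data[best_i] != GAP_CODE)  # row residue -> column
    qa, ta = str(best_alignment[0]), str(best_alignment[1])
    ref_pos, row_pos = 0, 0
    ref_to_col: dict[int, int] = {}
    for a, b in zip(qa, ta):
        if a != "-" and b != "-":
            ref_to_col[ref_pos + 1] = int(row_cols[row_pos]) + 1
            ref_pos += 1
            row_pos += 1
        elif a != "-":
            ref_pos += 1
        elif b != "-":
            row_pos += 1
    if not ref_to_col:
        raise MappingError(f"reference {ref_id!r} could not be mapped")

    cols = sorted(ref_to_col.values())
    col_to_ref = {c: r for r, c in ref_to_col.items()}
    pairs = [(c, col_to_ref[c]) for c in cols]

    # insert the reference as the first row of the trimmed alignment
    ref_row = np.full(len(cols), GAP_CODE, dtype=np.int8)
    for k, c in enumerate(cols):
        ref_row[k] = _ENCODE[ord(ref_seq[col_to_ref[c] - 1])]
    trimmed0 = aln.take_columns([c - 1 for c in cols])
    trimmed = Alignment(
        ids=[ref_id] + list(trimmed0.ids),
        data=np.vstack([ref_row[None, :], trimmed0.data]),
    )
    # columns in the map refer to the *input* alignment, as in the
    # ref-row-present branch
    remap = ColumnMap.from_pairs(pairs)
    logger.info(
        "reference %s threaded via row %s (identity %.2f), %d/%d residues mapped",
        ref_id, aln.ids[best_i], best_ident, len(remap), len(ref_seq),
    )
    return trimmed, remap
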