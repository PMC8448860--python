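"""Four-way orthologous alignment blocks and the conserved-interval filters.

A block carries four equal-length rows (tet_A, tet_B, dip_1, dip_2) with
per-row source coordinates.  Before mutation calling, blocks are cut at
long gap runs (>= 100 bp in any row), and only intervals longer than 500 bp
in every row with overall four-way identity >= 0.80 are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcodes import GAP, ROLES

_ALLOWED = frozenset(b"ACGTN-")


@dataclass(frozen=True)
class RowCoords:
    """Source location of one alignment row (0-based, strand +/-)."""

    chrom: str
    start: int
    strand: str = "+"


class MultiAlignment:
    """One 4-row orthologous alignment block.

    Rows are stored as an ASCII uint8 matrix in canonical role order; use
    :meth:`row` for string access.  Validation rejects ragged rows, unknown
    characters, and all-gap columns.
    """

    def __init__(
        self,
        block_id: str,
        rows: dict,
        coords: Optional[dict] = None,
    ) -> None:
        missing = [r for r in ROLES if r not in rows]
        if missing:
            raise ValueError(f"missing role: {', '.join(missing)}")
        unknown = [r for r in rows if r not in ROLES]
        if unknown:
            raise ValueError(f"unknown role: {', '.join(unknown)}")
        lengths = {len(rows[r]) for r in ROLES}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: rows differ in length")
        (length,) = lengths
        if length == 0:
            raise ValueError("empty alignment")
        mat = np.vstack(
            [
                np.frombuffer(rows[r].upper().encode(), dtype=np.uint8)
                for r in ROLES
            ]
        )
        bad = set(mat.tobytes()) - {ord(c) for c in "ACGTN-"}
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(chr(b) for b in bad)}")
        if ((mat == ord("-")).all(axis=0)).any():
            raise ValueError("all-gap column in alignment")
        self.block_id = block_id
        self.matrix = mat  # shape (4, L), ASCII codes
        self.coords = coords or {r: RowCoords(r, 0) for r in ROLES}

    def __len__(self) -> int:
        return self.matrix.shape[1]

    def row(self, role: str) -> str:
        i = ROLES.index(role)
        return self.matrix[i].tobytes().decode()

    def ungapped_length(self, role: str) -> int:
        i = ROLES.index(role)
        return int((self.matrix[i] != ord("-")).sum())

    def col_to_source(self, role: str, col: int) -> int:
        """Source coordinate of the base at an alignment column.

        The column must hold a base in this row.  For minus-strand rows the
        source position counts from the right end of the source interval.
        """
        i = ROLES.index(role)
        r = self.matrix[i]
        if r[col] == ord("-"):
            raise ValueError(f"column {col} is a gap in row {role}")
        offset = int((r[:col] != ord("-")).sum())
        rc = self.coords[role]
        if rc.strand == "+":
            return rc.start + offset
        return rc.start + self.ungapped_length(role) - 1 - offset

    def source_to_col(self, role: str, pos: int) -> int:
        """Inverse of :meth:`col_to_source` for positions inside the row."""
        i = ROLES.index(role)
        r = self.matrix[i]
        rc = self.coords[role]
        if rc.strand == "+":
            offset = pos - rc.start
        else:
            offset = rc.start + self.ungapped_length(role) - 1 - pos
        if offset < 0 or offset >= self.ungapped_length(role):
            raise ValueError(f"position {pos} outside row {role}")
        cols = np.flatnonzero(r != ord("-"))
        return int(cols[offset])


@dataclass
class ConservedInterval:
    """A gap-segmented sub-block: columns [col_start, col_end) of a parent."""

    block: MultiAlignment
    col_start: int
    col_end: int
    identity: float
    ungapped_lengths: dict

    @property
    def block_id(self) -> str:
        return self.block.block_id

    @property
    def n_columns(self) -> int:
        return self.col_end - self.col_start

    @property
    def min_row_length(self) -> int:
        return min(self.ungapped_lengths.values())

    def matrix(self) -> np.ndarray:
        return self.block.matrix[:, self.col_start : self.col_end]

    def col_to_source(self, role: str, col: int) -> int:
        return self.block.col_to_source(role, self.col_start + col)


def read_alignment(path, block_id: Optional[str] = None) -> MultiAlignment:
    """Read one 4-record aligned FASTA.

    Record ids must be the role names, optionally suffixed with
    ``|chrom|start|strand`` to carry source coordinates.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty file: {path}")
    rows, coords = {}, {}
    for rec in records:
        parts = rec.id.split("|")
        role = parts[0]
        if role not in ROLES:
            raise ValueError(f"unknown id: {rec.id}")
        rows[role] = str(rec.seq).upper()
        if len(parts) == 4:
            coords[role] = RowCoords(parts[1], int(parts[2]), parts[3])
        else:
            coords[role] = RowCoords(role, 0)
    return MultiAlignment(block_id or Path(path).stem, rows, coords)


def write_alignment(block: MultiAlignment, path) -> None:
    records = []
    for role in ROLES:
        rc = block.coords[role]
        rid = f"{role}|{rc.chrom}|{rc.start}|{rc.strand}"
        records.append(SeqRecord(Seq(block.row(role)), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def _identity(mat: np.ndarray) -> float:
    """All-rows-agree fraction over gap-free columns; N never matches."""
    gapfree = (mat != ord("-")).all(axis=0)
    if not gapfree.any():
        return 0.0
    sub = mat[:, gapfree]
    agree = (sub == sub[0]).all(axis=0) & (sub[0] != ord("N"))
    return float(agree.sum()) / int(gapfree.sum())


def _interval(block: MultiAlignment, s: int, e: int) -> ConservedInterval:
    mat = block.matrix[:, s:e]
    lens = {
        role: int((mat[i] != ord("-")).sum()) for i, role in enumerate(ROLES)
    }
    return ConservedInterval(block, s, e, _identity(mat), lens)


def segment_on_gaps(block: MultiAlignment, max_gap: int = 100) -> List[ConservedInterval]:
    """Split a block wherever any row carries a gap run of >= ``max_gap``.

    The offending gap run itself (union across rows) is excluded from both
    resulting intervals.
    """
    L = len(block)
    cut = np.zeros(L, dtype=bool)
    gaps = block.matrix == ord("-")
    for i in range(gaps.shape[0]):
        g = gaps[i]
        # run-length scan of this row's gap runs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], g.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= max_gap:
                cut[s:e] = True
    out = []
    edges = np.flatnonzero(np.diff(np.concatenate(([1], cut.view(np.int8), [1]))))
    for s, e in zip(edges[::2], edges[1::2]):
        out.append(_interval(block, int(s), int(e)))
    return out


def filter_intervals(
    intervals: Iterable[ConservedInterval],
    min_length: int = 500,
    min_identity: float = 0.80,
) -> List[ConservedInterval]:
    """Keep intervals longer than ``min_length`` bp in every row with
    four-way identity >= ``min_identity`` (inclusive at the threshold)."""
    return [
        iv
        for iv in intervals
        if iv.min_row_length > min_length and iv.identity >= min_identity
    ]


def intervals_to_table(intervals: Sequence[ConservedInterval]):
    import pandas as pd

    return pd.DataFrame(
        {
            "block_id": [iv.block_id for iv in intervals],
            "col_start": [iv.col_start for iv in intervals],
            "col_end": [iv.col_end for iv in intervals],
            "min_row_length": [iv.min_row_length for iv in intervals],
            "identity": [iv.identity for iv in intervals],
        }
    )
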