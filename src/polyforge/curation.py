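"""Comparative gene curation: intact / pseudogene / deleted calls.

A guide coding model (from the best-annotated row of a four-way alignment)
is projected onto a target row.  Targets whose alignable CDS fraction falls
below a threshold are deleted; otherwise the projected CDS is translated in
the guide frame, tolerating in-frame indels: internal stop codons mark
premature stops and indels of length not divisible by three mark
frameshifts.  Subgenome fractionation asymmetry is tested with a 2x2
chi-squared on lost-versus-retained counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .blocks import MultiAlignment
from .stats import ContingencyTable2x2, TestResult, chi_squared_2x2

STATUS_INTACT = "intact"
STATUS_PSEUDOGENE = "pseudogene"
STATUS_DELETED = "deleted"


@dataclass
class GeneModel:
    """A coding gene model: ordered CDS exon intervals on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    frame: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in exons:
            if e <= s:
                raise ValueError("empty exon")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("overlapping exons")
        self.exons = exons

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class CurationCall:
    gene_id: str
    lineage: str
    status: str
    defects: List[str] = field(default_factory=list)
    fraction_cds_alignable: float = 1.0

    def to_row(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "lineage": self.lineage,
            "status": self.status,
            "defects": ",".join(self.defects),
            "fraction_cds_alignable": self.fraction_cds_alignable,
        }


def _translate(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def _has_internal_stop(protein: str) -> bool:
    return "*" in protein[:-1] if protein else False


def project_and_classify(
    guide: GeneModel,
    alignment: MultiAlignment,
    target_role: str,
    guide_role: str = "dip_1",
    deletion_threshold: float = 0.2,
) -> CurationCall:
    """Project the guide CDS through the alignment onto a target row.

    The guide row must itself translate without internal stops; otherwise
    ``ValueError("invalid guide")``.
    """
    g_idx = _role_index(alignment, guide_role)
    t_idx = _role_index(alignment, target_role)
    gmat = alignment.matrix[g_idx]
    tmat = alignment.matrix[t_idx]
    coords = alignment.coords[guide_role]

    # source position of every guide-row base, by column
    non_gap = gmat != ord("-")
    src = np.cumsum(non_gap) - 1 + coords.start  # valid where non_gap

    in_cds = np.zeros(len(alignment), dtype=bool)
    for s, e in guide.exons:
        in_cds |= non_gap & (src >= s) & (src < e)
    cds_cols = np.flatnonzero(in_cds)
    if cds_cols.size == 0:
        raise ValueError("guide CDS does not map into the alignment")
    # columns inside the CDS span where the guide is gapped (potential
    # target insertions) take part in indel accounting
    span = np.zeros(len(alignment), dtype=bool)
    span[cds_cols.min() : cds_cols.max() + 1] = True
    walk_cols = np.flatnonzero(in_cds | (span & ~non_gap))

    guide_chars = gmat[cds_cols].tobytes().decode()
    guide_cds = guide_chars
    if guide.strand == "-":
        guide_cds = str(Seq(guide_cds).reverse_complement())
    guide_protein = _translate(guide_cds)
    if _has_internal_stop(guide_protein):
        raise ValueError("invalid guide: internal stop codon")

    target_at_cds = tmat[cds_cols]
    alignable = int((target_at_cds != ord("-")).sum())
    fraction = alignable / cds_cols.size
    if fraction < deletion_threshold:
        return CurationCall(
            guide.gene_id, target_role, STATUS_DELETED, ["unalignable_cds"], fraction
        )

    defects: List[str] = []
    # indel runs over the walked columns (guide-or-target gap states)
    state = []  # 0 match, 1 deletion (target gap), 2 insertion (guide gap)
    for c in walk_cols:
        g_gap = gmat[c] == ord("-")
        t_gap = tmat[c] == ord("-")
        if g_gap and t_gap:
            continue
        state.append(1 if t_gap else (2 if g_gap else 0))
    state_arr = np.asarray(state, dtype=np.int8)
    for kind, name in ((1, "frameshift_indel"), (2, "frameshift_indel")):
        runs = _run_lengths(state_arr == kind)
        if any(r % 3 for r in runs):
            defects.append(name)
            break

    target_seq = tmat[walk_cols]
    target_seq = target_seq[target_seq != ord("-")].tobytes().decode()
    if guide.strand == "-":
        target_seq = str(Seq(target_seq).reverse_complement())
    protein = _translate(target_seq)
    if _has_internal_stop(protein):
        defects.append("premature_stop")

    status = STATUS_PSEUDOGENE if defects else STATUS_INTACT
    return CurationCall(guide.gene_id, target_role, status, defects, fraction)


def _role_index(alignment: MultiAlignment, role: str) -> int:
    from .seqcodes import ROLES

    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    return ROLES.index(role)


def _run_lengths(mask: np.ndarray) -> List[int]:
    if mask.size == 0:
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [int(e - s) for s, e in zip(edges[::2], edges[1::2])]


def fractionation_test(
    calls_a: Sequence[CurationCall], calls_b: Sequence[CurationCall]
) -> Tuple[TestResult, dict]:
    """Chi-squared test of asymmetric gene loss between subgenomes.

    Lost = pseudogene or deleted.  Both call sets must cover the same
    ancestral models.
    """
    if not calls_a or not calls_b:
        raise ValueError("empty call set")
    lost_a = sum(c.status != STATUS_INTACT for c in calls_a)
    lost_b = sum(c.status != STATUS_INTACT for c in calls_b)
    table = ContingencyTable2x2(
        lost_a, len(calls_a) - lost_a, lost_b, len(calls_b) - lost_b
    )
    counts = {
        "lost_A": lost_a,
        "retained_A": len(calls_a) - lost_a,
        "lost_B": lost_b,
        "retained_B": len(calls_b) - lost_b,
    }
    return chi_squared_2x2(table), counts


def calls_to_frame(calls: Sequence[CurationCall]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in calls])
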