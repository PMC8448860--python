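"""De novo mutation calling on conserved four-way intervals.

A column is called iff all four rows carry a plain base, exactly one row
differs from the other three (which agree), and the five columns on either
side are gap-free and identical across all rows — the 1:3 ancestral
genotype rule with a 5-nt flank guard against alignment error.  Calls are
collapsed onto the pyrimidine strand and binned into the 96 trinucleotide
context classes (six substitution classes x 16 flanking contexts).

Calls carried by the B-subgenome row are emitted but flagged: with no
B-lineage diploid in the alignment, progenitor-divergence sites are
indistinguishable from B-subgenome de novo mutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .blocks import ConservedInterval
from .config import CLASSES6
from .seqcodes import DIP_1, DIP_2, ROLES, TET_A, TET_B, complement_base
from .stats import TestResult, paired_t_one_sided

FLANK = 5

#: lineages whose calls are interpretable as subgenome-specific de novo
#: mutations (the B subgenome lacks a surviving diploid to polarize it)
INTERPRETABLE = (TET_A, DIP_1, DIP_2)

#: canonical 96-class order: contexts alphabetical within each class
CLASS96_ORDER = tuple(
    f"{five}[{c6}]{three}"
    for c6 in CLASSES6
    for five, three in product("ACGT", repeat=2)
)


@dataclass(frozen=True)
class MutationCall:
    block_id: str
    column: int
    carrier: str
    ancestral: str
    derived: str
    five_prime: str
    three_prime: str
    class6: str
    class96: str
    is_transition: bool
    chrom: str
    pos: int

    def to_row(self) -> dict:
        return {
            "block_id": self.block_id,
            "column": self.column,
            "chrom": self.chrom,
            "pos": self.pos,
            "carrier": self.carrier,
            "ancestral": self.ancestral,
            "derived": self.derived,
            "class6": self.class6,
            "class96": self.class96,
            "is_transition": self.is_transition,
        }


_TRANSITIONS = {("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")}


def classify_mutation(
    ancestral: str, derived: str, five_prime: str, three_prime: str
) -> tuple:
    """(class6, class96, is_transition) with pyrimidine strand collapse.

    Purine ancestral bases reverse-complement the (5', anc>der, 3') triple.
    A flanking N yields class96 ``"NA"`` (excluded from 96-spectra).
    """
    if ancestral == derived:
        raise ValueError("ancestral and derived base are identical")
    if ancestral in "AG":
        ancestral, derived = complement_base(ancestral), complement_base(derived)
        five_prime, three_prime = (
            complement_base(three_prime),
            complement_base(five_prime),
        )
    class6 = f"{ancestral}>{derived}"
    if "N" in (five_prime, three_prime):
        class96 = "NA"
    else:
        class96 = f"{five_prime}[{class6}]{three_prime}"
    is_ts = (ancestral, derived) in _TRANSITIONS
    return class6, class96, is_ts


def call_mutations(interval: ConservedInterval) -> List[MutationCall]:
    """Scan one conserved interval for 1:3 columns passing the flank rule."""
    mat = interval.matrix()
    L = mat.shape[1]
    if L < 2 * FLANK + 1:
        return []
    is_base = np.zeros(mat.shape, dtype=bool)
    for b in b"ACGT":
        is_base |= mat == b
    all_base = is_base.all(axis=0)
    identical = all_base & (mat == mat[0]).all(axis=0)

    srt = np.sort(mat, axis=0)
    one_three = all_base & (
        ((srt[0] == srt[1]) & (srt[1] == srt[2]) & (srt[2] != srt[3]))
        | ((srt[1] == srt[2]) & (srt[2] == srt[3]) & (srt[0] != srt[1]))
    )

    # flank windows: FLANK identical columns on each side
    ident_i = identical.astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(ident_i)))
    cols = np.flatnonzero(one_three)
    cols = cols[(cols >= FLANK) & (cols < L - FLANK)]
    calls: List[MutationCall] = []
    for c in cols:
        if cs[c] - cs[c - FLANK] != FLANK:
            continue
        if cs[c + FLANK + 1] - cs[c + 1] != FLANK:
            continue
        column = mat[:, c]
        values, counts = np.unique(column, return_counts=True)
        anc_code = values[np.argmax(counts)]
        der_code = values[np.argmin(counts)]
        carrier_idx = int(np.flatnonzero(column == der_code)[0])
        carrier = ROLES[carrier_idx]
        five = chr(mat[0, c - 1])
        three = chr(mat[0, c + 1])
        anc, der = chr(anc_code), chr(der_code)
        class6, class96, is_ts = classify_mutation(anc, der, five, three)
        calls.append(
            MutationCall(
                block_id=interval.block_id,
                column=interval.col_start + int(c),
                carrier=carrier,
                ancestral=anc,
                derived=der,
                five_prime=five,
                three_prime=three,
                class6=class6,
                class96=class96,
                is_transition=is_ts,
                chrom=interval.block.coords[carrier].chrom,
                pos=interval.col_to_source(carrier, int(c)),
            )
        )
    return calls


def call_intervals(intervals: Iterable[ConservedInterval]) -> List[MutationCall]:
    calls: List[MutationCall] = []
    for iv in intervals:
        calls.extend(call_mutations(iv))
    return calls


@dataclass
class SpectrumSummary:
    """Per-lineage mutation counts in the 6- and 96-class schemes."""

    lineage: str
    counts96: Dict[str, int]
    counts6: Dict[str, int]
    total: int
    tstv: float
    gc_to_at: float
    interpretable: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lineage": self.lineage,
                "class96": list(self.counts96),
                "count": list(self.counts96.values()),
            }
        )


def summarize_spectrum(
    calls: Sequence[MutationCall], lineage: str
) -> SpectrumSummary:
    """Counts, Ts/Tv and the G:C->A:T fraction for one carrier lineage.

    Calls with an unresolvable (N-containing) context are excluded from
    both the 96- and 6-class tallies.
    """
    mine = [c for c in calls if c.carrier == lineage and c.class96 != "NA"]
    counts96 = {k: 0 for k in CLASS96_ORDER}
    counts6 = {k: 0 for k in CLASSES6}
    ts = tv = 0
    for c in mine:
        counts96[c.class96] += 1
        counts6[c.class6] += 1
        if c.is_transition:
            ts += 1
        else:
            tv += 1
    total = len(mine)
    tstv = float("nan") if tv == 0 else ts / tv
    gc_to_at = counts6["C>T"] / total if total else float("nan")
    return SpectrumSummary(
        lineage=lineage,
        counts96=counts96,
        counts6=counts6,
        total=total,
        tstv=tstv,
        gc_to_at=gc_to_at,
        interpretable=lineage != TET_B,
    )


@dataclass
class LineageComparison:
    unit: str
    per_unit: pd.DataFrame  # columns: unit, count_a, count_b
    lineage_a: str
    lineage_b: str
    excess_percent: float
    test: Optional[TestResult]

    def to_frame(self) -> pd.DataFrame:
        df = self.per_unit.copy()
        df["lineage_a"] = self.lineage_a
        df["lineage_b"] = self.lineage_b
        return df


def compare_lineages(
    calls: Sequence[MutationCall],
    unit: str = "chromosome",
    lineage_a: str = TET_A,
    lineage_b: str = DIP_1,
) -> LineageComparison:
    """Mutation burden excess of one lineage over another.

    ``excess_percent = 100 * (sum_a - sum_b) / sum_b`` from totals; the
    one-sided paired t-test pairs counts per chromosome (or per block).
    Degenerate per-unit differences leave ``test`` as None.
    """
    if unit not in ("chromosome", "block"):
        raise ValueError("unit must be 'chromosome' or 'block'")

    def key(c: MutationCall) -> str:
        if unit == "block":
            return c.block_id
        # pair homeologous coordinates: strip the subgenome letter
        return c.chrom[1:]

    units: Dict[str, List[int]] = {}
    for c in calls:
        if c.carrier not in (lineage_a, lineage_b):
            continue
        row = units.setdefault(key(c), [0, 0])
        row[0 if c.carrier == lineage_a else 1] += 1
    per_unit = pd.DataFrame(
        [
            {"unit": u, "count_a": ab[0], "count_b": ab[1]}
            for u, ab in sorted(units.items())
        ]
    )
    total_a = int(per_unit["count_a"].sum()) if len(per_unit) else 0
    total_b = int(per_unit["count_b"].sum()) if len(per_unit) else 0
    excess = float("nan") if total_b == 0 else 100.0 * (total_a - total_b) / total_b
    test: Optional[TestResult] = None
    if len(per_unit) >= 2:
        try:
            test = paired_t_one_sided(
                per_unit["count_a"].to_numpy(float),
                per_unit["count_b"].to_numpy(float),
            )
        except ValueError:
            test = None
    return LineageComparison(unit, per_unit, lineage_a, lineage_b, excess, test)


def calls_to_frame(calls: Sequence[MutationCall]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in calls])
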