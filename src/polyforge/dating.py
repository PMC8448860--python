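"""Pairwise synonymous divergence (NG86) and molecular dating.

The Nei–Gojobori (1986) counting method: per-codon synonymous site
fractions averaged over both sequences, observed differences split over
all minimal mutational paths with equal weights (paths through stop codons
excluded), and a Jukes–Cantor correction d = -(3/4) ln(1 - (4/3) p).
Divergence time follows the molecular-clock relation t = dS / (2 r) with
r the neutral substitution rate per site per year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

_CODON_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_BASES = "ACGT"


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (0..3).

    Each position contributes (# synonymous single-nt changes)/3; changes
    creating stop codons count as non-synonymous.
    """
    aa = _CODON_TABLE[codon]
    total = 0.0
    for i in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt in _STOPS:
                continue
            if _CODON_TABLE[alt] == aa:
                syn += 1
        total += syn / 3.0
    return total


_SYN_SITES = {c: _syn_fraction(c) for c in _CODON_TABLE}


def _path_differences(c1: str, c2: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all orderings of the differing positions; orderings that
    pass through a stop codon are dropped (all orderings kept if every one
    is blocked).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:  # all orderings pass through stops; fall back to all
        paths = []
        for order in permutations(diff):
            cur = c1
            steps = []
            for i in order:
                nxt = cur[:i] + c2[i] + cur[i + 1 :]
                steps.append((cur, nxt))
                cur = nxt
            paths.append(steps)
    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            aa_a = _CODON_TABLE.get(a)
            aa_b = _CODON_TABLE.get(b)
            if aa_a is not None and aa_a == aa_b:
                sd += 1
            else:
                nd += 1
    sd /= len(paths)
    nd /= len(paths)
    return sd, nd


@dataclass(frozen=True)
class CodingPair:
    """Two in-frame CDS strings of equal codon count, gap codons removed."""

    seq_a: str
    seq_b: str

    @classmethod
    def from_sequences(cls, a: str, b: str) -> "CodingPair":
        """Align-free constructor: drops codon columns containing a gap or
        ambiguous base in either sequence, then validates."""
        if len(a) != len(b):
            raise ValueError("sequences differ in aligned length")
        usable = len(a) - len(a) % 3
        keep_a, keep_b = [], []
        for i in range(0, usable, 3):
            ca, cb = a[i : i + 3].upper(), b[i : i + 3].upper()
            if set(ca + cb) - set(_BASES):
                continue
            keep_a.append(ca)
            keep_b.append(cb)
        pair = cls("".join(keep_a), "".join(keep_b))
        pair.validate()
        return pair

    def validate(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("length not divisible by 3")
        if len(self.seq_a) == 0:
            raise ValueError("zero codons")
        for seq in (self.seq_a, self.seq_b):
            for i in range(0, len(seq) - 3, 3):
                if seq[i : i + 3] in _STOPS:
                    raise ValueError("internal stop codon")

    @property
    def codons(self) -> List[Tuple[str, str]]:
        return [
            (self.seq_a[i : i + 3], self.seq_b[i : i + 3])
            for i in range(0, len(self.seq_a), 3)
        ]


@dataclass
class DsEstimate:
    dS: float
    dN: float
    S: float
    N: float
    Sd: float
    Nd: float
    saturated: bool

    def to_row(self) -> dict:
        return vars(self).copy()


def _jukes_cantor(p: float) -> Tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), False


def ng86(pair: CodingPair) -> DsEstimate:
    """Nei–Gojobori (1986) dS/dN for one coding pair."""
    pair.validate()
    S = Sd = Nd = 0.0
    skipped = 0
    for ca, cb in pair.codons:
        # terminal stops (and any codon involving a stop) carry no sites
        if ca in _STOPS or cb in _STOPS:
            skipped += 1
            continue
        S += (_SYN_SITES[ca] + _SYN_SITES[cb]) / 2.0
        sd, nd = _path_differences(ca, cb)
        Sd += sd
        Nd += nd
    n_codons = len(pair.codons) - skipped
    if n_codons == 0:
        raise ValueError("zero codons")
    N = 3.0 * n_codons - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, sat_s = _jukes_cantor(pS)
    dN, _ = _jukes_cantor(pN)
    return DsEstimate(dS=dS, dN=dN, S=S, N=N, Sd=Sd, Nd=Nd, saturated=sat_s)


def divergence_time(dS: float, rate: float) -> float:
    """Molecular-clock divergence time in years: t = dS / (2 r)."""
    if rate <= 0:
        raise ValueError("substitution rate must be positive")
    if dS < 0 or not np.isfinite(dS):
        raise ValueError("dS must be finite and non-negative")
    return dS / (2.0 * rate)


@dataclass
class DsDistribution:
    counts: np.ndarray
    bin_edges: np.ndarray
    mode: Optional[float]
    zero_fraction: float
    n: int


def ds_distribution(
    ds_values: Sequence[float], bin_width: float = 0.005
) -> DsDistribution:
    """Histogram of dS with the zero-dS mass reported separately.

    The mode is the centre of the densest bin over strictly positive,
    unsaturated values (None when there are none).
    """
    vals = np.asarray([v for v in ds_values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no finite dS values")
    zero_fraction = float(np.mean(vals == 0.0))
    pos = vals[vals > 0]
    if pos.size == 0:
        edges = np.array([0.0, bin_width])
        return DsDistribution(np.zeros(1, int), edges, None, zero_fraction, vals.size)
    n_bins = int(np.ceil(pos.max() / bin_width)) or 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, edges = np.histogram(pos, bins=edges)
    mode_bin = int(np.argmax(counts))
    mode = float((edges[mode_bin] + edges[mode_bin + 1]) / 2.0)
    return DsDistribution(counts, edges, mode, zero_fraction, vals.size)


def pairs_to_frame(rows: Sequence[Tuple[str, str, DsEstimate]]) -> pd.DataFrame:
    out = []
    for gene_a, gene_b, est in rows:
        row = {"gene_a": gene_a, "gene_b": gene_b}
        row.update(est.to_row())
        out.append(row)
    return pd.DataFrame(out)
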