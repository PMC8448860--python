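"""Homeologous-exchange detection from depth dichotomy.

An exchange replaces a chromosomal region with its homeolog, so read depth
shows a duplication (ratio in the open band (1.5, 3) of the sample mean)
on the donor and a deletion (< 0.5x) on the recipient.  Segmental calls
require 20 kb; smaller events are scored per homeologous gene pair.
Balanced (2:2) swaps leave depth flat and are found as reciprocal origin
islands in the diploid-coverage partition; nonreciprocal (3:1) events sit
at 1.5x / 0.5x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .partition import DepthTrack, ORIGIN_A, ORIGIN_B, PartitionResult
from .stats import TestResult, TWO_SIDED, exact_binomial


@dataclass
class SyntenyMap:
    """Homeologous segment pairs plus gene-pair relationships."""

    segments: pd.DataFrame  # chrom_a,start_a,end_a,chrom_b,start_b,end_b,orientation
    gene_pairs: pd.DataFrame  # gene_a,chrom_a,start_a,end_a,gene_b,chrom_b,start_b,end_b

    def map_interval(self, chrom: str, start: int, end: int) -> Optional[Tuple[str, int, int]]:
        """Homeologous coordinates of an interval, or None when unmapped."""
        for a_side in (True, False):
            cc, ss, ee = (
                ("chrom_a", "start_a", "end_a") if a_side else ("chrom_b", "start_b", "end_b")
            )
            oc, os_, oe = (
                ("chrom_b", "start_b", "end_b") if a_side else ("chrom_a", "start_a", "end_a")
            )
            hit = self.segments[
                (self.segments[cc] == chrom)
                & (self.segments[ss] <= start)
                & (self.segments[ee] >= end)
            ]
            if len(hit):
                seg = hit.iloc[0]
                if seg.get("orientation", "+") == "+":
                    off = seg[os_] - seg[ss]
                    return str(seg[oc]), int(start + off), int(end + off)
                # inverted segment: map from the far end
                return (
                    str(seg[oc]),
                    int(seg[os_] + (seg[ee] - end)),
                    int(seg[os_] + (seg[ee] - start)),
                )
        return None

    def to_tsv(self, seg_path, gene_path) -> None:
        self.segments.to_csv(seg_path, sep="\t", index=False)
        self.gene_pairs.to_csv(gene_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, seg_path, gene_path) -> "SyntenyMap":
        return cls(
            pd.read_csv(seg_path, sep="\t"), pd.read_csv(gene_path, sep="\t")
        )


@dataclass
class HECall:
    cls: str  # segmental | genic | balanced | nonreciprocal
    sample: str
    donor_chrom: str
    donor_start: int
    donor_end: int
    recip_chrom: str
    recip_start: int
    recip_end: int
    donor_ratio: float
    recip_ratio: float
    direction: str = ""

    def __post_init__(self) -> None:
        if not self.direction:
            d = "A" if self.donor_chrom.startswith("A") else "B"
            r = "A" if self.recip_chrom.startswith("A") else "B"
            self.direction = f"{d}_to_{r}"

    @property
    def size(self) -> int:
        return self.donor_end - self.donor_start

    def to_row(self) -> dict:
        row = {k: v for k, v in vars(self).items()}
        row["size"] = self.size
        return row


def calls_to_frame(calls: Sequence[HECall]) -> pd.DataFrame:
    return pd.DataFrame([c.to_row() for c in calls])


def normalized_ratios(track: DepthTrack) -> pd.DataFrame:
    """Windows with depth expressed in units of the sample genome mean."""
    mean = track.mean_depth
    if mean <= 0:
        raise ValueError("track has zero mean depth")
    df = track.windows.copy()
    df["ratio"] = df["depth"] / mean
    return df


def _band_runs(
    ratios: pd.DataFrame,
    band: Tuple[float, float],
    max_gap_windows: int = 2,
) -> List[Tuple[str, int, int, float]]:
    """Maximal runs of windows inside an open ratio band.

    Runs separated by at most ``max_gap_windows`` out-of-band windows are
    merged, which keeps Poisson depth noise from fragmenting long events.
    Returns (chrom, start, end, mean_ratio) per run.
    """
    lo, hi = band
    out = []
    for chrom, grp in ratios.groupby("chrom", sort=False):
        r = grp["ratio"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        in_band = (r > lo) & (r < hi)
        idx = np.flatnonzero(in_band)
        if idx.size == 0:
            continue
        run_start = idx[0]
        prev = idx[0]
        segments = []
        for i in idx[1:]:
            if i - prev > max_gap_windows + 1:
                segments.append((run_start, prev))
                run_start = i
            prev = i
        segments.append((run_start, prev))
        for s, e in segments:
            out.append(
                (str(chrom), int(starts[s]), int(ends[e]), float(np.mean(r[s : e + 1])))
            )
    return out


def _interval_mean_ratio(
    ratios: pd.DataFrame, chrom: str, start: int, end: int
) -> float:
    """Base-overlap-weighted mean ratio over an interval."""
    grp = ratios[ratios["chrom"] == chrom]
    ov_start = np.maximum(grp["start"].to_numpy(), start)
    ov_end = np.minimum(grp["end"].to_numpy(), end)
    w = np.maximum(ov_end - ov_start, 0)
    if w.sum() == 0:
        return float("nan")
    return float(np.average(grp["ratio"].to_numpy(), weights=w))


def call_segmental_he(
    track: DepthTrack,
    synteny: SyntenyMap,
    min_size: int = 20_000,
    dup_band: Tuple[float, float] = (1.5, 3.0),
    del_max: float = 0.5,
    max_gap_windows: int = 2,
) -> Tuple[List[HECall], List[dict]]:
    """Segmental 4:0 exchanges for one sample.

    Candidate duplications are runs in the open ``dup_band``; a candidate
    becomes a call iff its homeologous interval averages below ``del_max``
    and either interval spans ``min_size``.  Candidates without a homeolog
    mapping are returned separately as unresolved.
    """
    ratios = normalized_ratios(track)
    calls: List[HECall] = []
    unresolved: List[dict] = []
    for chrom, start, end, mean_ratio in _band_runs(ratios, dup_band, max_gap_windows):
        if end - start < min_size:
            continue
        mapped = synteny.map_interval(chrom, start, end)
        if mapped is None:
            unresolved.append(
                {"chrom": chrom, "start": start, "end": end, "ratio": mean_ratio}
            )
            continue
        h_chrom, h_start, h_end = mapped
        h_ratio = _interval_mean_ratio(ratios, h_chrom, h_start, h_end)
        if np.isnan(h_ratio) or h_ratio >= del_max:
            continue
        calls.append(
            HECall(
                "segmental", track.sample, chrom, start, end,
                h_chrom, h_start, h_end, mean_ratio, h_ratio,
            )
        )
    return calls, unresolved


def call_genic_he(
    gene_depths: pd.DataFrame,
    gene_pairs: pd.DataFrame,
    sample: str = "",
    dup_band: Tuple[float, float] = (1.5, 3.0),
    del_max: float = 0.5,
) -> List[HECall]:
    """Gene-scale 4:0 conversions from per-gene depth ratios.

    ``gene_depths`` carries one row per gene copy with columns ``gene_id``
    and ``ratio`` (depth over the sample genome mean).  A pair is called
    when one copy sits in the duplication band and its partner below the
    deletion bound.
    """
    ratios = gene_depths.set_index("gene_id")["ratio"]
    lo, hi = dup_band
    calls = []
    for _, pair in gene_pairs.iterrows():
        ra = ratios.get(pair.gene_a, float("nan"))
        rb = ratios.get(pair.gene_b, float("nan"))
        if np.isnan(ra) or np.isnan(rb):
            continue
        if lo < ra < hi and rb < del_max:
            donor, recip, dr, rr = (
                (pair.gene_a, pair.gene_b, ra, rb)
            )
            d_cols = ("chrom_a", "start_a", "end_a")
            r_cols = ("chrom_b", "start_b", "end_b")
        elif lo < rb < hi and ra < del_max:
            donor, recip, dr, rr = (pair.gene_b, pair.gene_a, rb, ra)
            d_cols = ("chrom_b", "start_b", "end_b")
            r_cols = ("chrom_a", "start_a", "end_a")
        else:
            continue
        calls.append(
            HECall(
                "genic", sample,
                str(pair[d_cols[0]]), int(pair[d_cols[1]]), int(pair[d_cols[2]]),
                str(pair[r_cols[0]]), int(pair[r_cols[1]]), int(pair[r_cols[2]]),
                float(dr), float(rr),
            )
        )
    return calls


def gene_depth_ratios(
    gene_depths: pd.DataFrame, genome_mean: float
) -> pd.DataFrame:
    """Attach a ``ratio`` column to a per-gene depth table."""
    df = gene_depths.copy()
    df["ratio"] = df["depth"] / genome_mean
    return df


def gene_mean_depth_from_track(
    track: DepthTrack, genes: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene mean depth computed from window overlap.

    Genes shorter than one window inherit their window's depth; a warning
    notes the limited resolution.
    """
    window = int(
        (track.windows["end"] - track.windows["start"]).mode().iloc[0]
    )
    if (genes["end"] - genes["start"] < window).any():
        warnings.warn(
            "genes shorter than one window: depth resolved at window scale",
            stacklevel=2,
        )
    ratios = track.windows.assign(ratio=track.windows["depth"])
    rows = []
    for _, g in genes.iterrows():
        rows.append(
            {
                "gene_id": g.gene_id,
                "depth": _interval_mean_ratio(ratios, g.chrom, g.start, g.end),
            }
        )
    return pd.DataFrame(rows)


def call_balanced_he(
    result: PartitionResult,
    synteny: SyntenyMap,
    min_flank: int = 10,
) -> Tuple[List[HECall], List[dict]]:
    """Balanced 2:2 swaps from reciprocal origin islands.

    An island is a block whose both neighbours carry the opposite origin
    with at least ``min_flank`` windows each.  Islands whose mapped partner
    interval overlaps (>= 0.5 reciprocal) an opposite island become one
    balanced call; the rest are reported one-sided.
    """
    blocks = result.blocks
    islands = []
    by_chrom: Dict[str, list] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom, bs in by_chrom.items():
        for i in range(1, len(bs) - 1):
            left, mid, right = bs[i - 1], bs[i], bs[i + 1]
            if (
                left.origin == right.origin
                and left.origin != mid.origin
                and left.n_windows >= min_flank
                and right.n_windows >= min_flank
            ):
                islands.append(mid)
    calls: List[HECall] = []
    one_sided: List[dict] = []
    used = set()
    for isl in islands:
        if id(isl) in used:
            continue
        mapped = synteny.map_interval(isl.chrom, isl.start, isl.end)
        partner = None
        if mapped is not None:
            h_chrom, h_start, h_end = mapped
            for other in islands:
                if other.chrom != h_chrom or other.origin == isl.origin:
                    continue
                ov = min(other.end, h_end) - max(other.start, h_start)
                if ov <= 0:
                    continue
                if (
                    ov / (other.end - other.start) >= 0.5
                    and ov / (h_end - h_start) >= 0.5
                ):
                    partner = other
                    break
        if partner is None:
            one_sided.append(
                {"chrom": isl.chrom, "start": isl.start, "end": isl.end,
                 "origin": isl.origin}
            )
            continue
        used.add(id(isl))
        used.add(id(partner))
        a_isl, b_isl = (isl, partner) if isl.chrom.startswith("A") else (partner, isl)
        calls.append(
            HECall(
                "balanced", "ALL",
                a_isl.chrom, a_isl.start, a_isl.end,
                b_isl.chrom, b_isl.start, b_isl.end,
                float("nan"), float("nan"),
                direction="reciprocal",
            )
        )
    return calls, one_sided


def call_nonreciprocal(
    track: DepthTrack,
    candidate_pairs: Sequence[Tuple[Tuple[str, int, int], Tuple[str, int, int]]],
    donor_band: Tuple[float, float] = (1.25, 1.75),
    recip_band: Tuple[float, float] = (0.25, 0.75),
) -> List[HECall]:
    """Score candidate non-homeologous interval pairs for 3:1 dosage."""
    ratios = normalized_ratios(track)
    calls = []
    for (d_chrom, d_s, d_e), (r_chrom, r_s, r_e) in candidate_pairs:
        dr = _interval_mean_ratio(ratios, d_chrom, d_s, d_e)
        rr = _interval_mean_ratio(ratios, r_chrom, r_s, r_e)
        if np.isnan(dr) or np.isnan(rr):
            continue
        if donor_band[0] < dr < donor_band[1] and recip_band[0] < rr < recip_band[1]:
            calls.append(
                HECall(
                    "nonreciprocal", track.sample,
                    d_chrom, d_s, d_e, r_chrom, r_s, r_e, dr, rr,
                )
            )
    return calls


def propose_nonreciprocal_pairs(
    track: DepthTrack,
    synteny: SyntenyMap,
    min_size: int = 20_000,
    donor_band: Tuple[float, float] = (1.25, 1.75),
    recip_band: Tuple[float, float] = (0.25, 0.75),
    max_gap_windows: int = 2,
) -> List[Tuple[Tuple[str, int, int], Tuple[str, int, int]]]:
    """Pair 1.5x runs with 0.5x runs of comparable size on non-homeologous
    chromosomes, excluding runs whose homeologous partner explains them."""
    ratios = normalized_ratios(track)
    donors = [
        r for r in _band_runs(ratios, donor_band, max_gap_windows)
        if r[2] - r[1] >= min_size
    ]
    recips = [
        r for r in _band_runs(ratios, recip_band, max_gap_windows)
        if r[2] - r[1] >= min_size
    ]
    pairs = []
    for d_chrom, d_s, d_e, _ in donors:
        d_len = d_e - d_s
        mapped = synteny.map_interval(d_chrom, d_s, d_e)
        homeolog_chrom = mapped[0] if mapped else None
        for r_chrom, r_s, r_e, _ in recips:
            if r_chrom in (d_chrom, homeolog_chrom):
                continue
            r_len = r_e - r_s
            if min(d_len, r_len) / max(d_len, r_len) >= 0.5:
                pairs.append(((d_chrom, d_s, d_e), (r_chrom, r_s, r_e)))
    return pairs


@dataclass
class EnrichmentResult:
    observed: int
    total: int
    expected_proportion: float
    test: TestResult

    @property
    def observed_fraction(self) -> float:
        return self.observed / self.total if self.total else float("nan")


def telomere_enrichment(
    genic_calls: Sequence[HECall],
    genes: pd.DataFrame,
    chrom_sizes: Dict[str, int],
    window: int = 2_000_000,
) -> EnrichmentResult:
    """Exact binomial test of genic-exchange enrichment near telomeres.

    Observed: exchange events overlapping [0, window) or [len-window, len)
    of their donor chromosome.  Expected proportion: fraction of all
    annotated genes in those regions.
    """
    if window >= min(chrom_sizes.values()) / 2:
        raise ValueError("degenerate window: telomere windows overlap")

    def near(chrom: str, start: int, end: int) -> bool:
        L = chrom_sizes[chrom]
        return start < window or end > L - window

    n_genes = len(genes)
    in_window = sum(
        near(g.chrom, g.start, g.end) for _, g in genes.iterrows()
    )
    p0 = in_window / n_genes
    events = dedupe_events(genic_calls)
    total = len(events)
    observed = sum(
        near(ev.donor_chrom, ev.donor_start, ev.donor_end)
        or near(ev.recip_chrom, ev.recip_start, ev.recip_end)
        for ev in events
    )
    test = exact_binomial(observed, total, p0)
    return EnrichmentResult(observed, total, p0, test)


def _reciprocal_overlap(a: HECall, b: HECall) -> bool:
    def ro(c1, s1, e1, c2, s2, e2) -> float:
        if c1 != c2:
            return 0.0
        ov = min(e1, e2) - max(s1, s2)
        if ov <= 0:
            return 0.0
        return min(ov / (e1 - s1), ov / (e2 - s2))

    return (
        ro(a.donor_chrom, a.donor_start, a.donor_end,
           b.donor_chrom, b.donor_start, b.donor_end) >= 0.8
        and ro(a.recip_chrom, a.recip_start, a.recip_end,
               b.recip_chrom, b.recip_start, b.recip_end) >= 0.8
    )


def dedupe_events(calls: Sequence[HECall]) -> List[HECall]:
    """One representative per distinct event (0.8 reciprocal overlap)."""
    reps: List[HECall] = []
    for c in calls:
        if not any(_reciprocal_overlap(c, r) for r in reps):
            reps.append(c)
    return reps


@dataclass
class SharingSummary:
    events: pd.DataFrame  # event index, intervals, n_samples, samples
    direction_totals: Dict[str, int]
    direction_test: Optional[TestResult]
    test_construction_ambiguous: bool = True


def sharing_summary(calls: Sequence[HECall]) -> SharingSummary:
    """Cross-sample occurrence counts per event plus direction totals.

    The chi-squared on direction totals is a goodness-of-fit against an
    even split of occurrences; how the published contrast tabulated its
    counts is not uniquely determined, so the result carries an explicit
    ambiguity flag.
    """
    reps = dedupe_events(calls)
    rows = []
    for i, rep in enumerate(reps):
        members = [c for c in calls if _reciprocal_overlap(c, rep)]
        samples = sorted({c.sample for c in members})
        rows.append(
            {
                "event": f"ev{i + 1:03d}",
                "cls": rep.cls,
                "donor_chrom": rep.donor_chrom,
                "donor_start": rep.donor_start,
                "donor_end": rep.donor_end,
                "recip_chrom": rep.recip_chrom,
                "recip_start": rep.recip_start,
                "recip_end": rep.recip_end,
                "direction": rep.direction,
                "n_samples": len(samples),
                "samples": ",".join(samples),
            }
        )
    events = pd.DataFrame(rows)
    totals: Dict[str, int] = {}
    if len(events):
        for _, ev in events.iterrows():
            totals[ev.direction] = totals.get(ev.direction, 0) + ev.n_samples
    test = None
    vals = [v for v in totals.values()]
    if len(vals) == 2 and sum(vals) > 0:
        stat, p = sps.chisquare(vals)
        test = TestResult(float(stat), float(p), TWO_SIDED, "direction_chisq_gof")
    return SharingSummary(events, totals, test)
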