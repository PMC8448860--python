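"""Subgenome assignment from diploid-read coverage depth.

Mapping reads of the extant A-lineage diploid onto the tetraploid reference
covers only A-derived regions, so per-window depth is bimodal.  A window is
provisionally A-origin when its depth exceeds half the genome peak depth;
runs shorter than five windows are flipped to the surrounding origin until
a fixed point is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

ORIGIN_A = "AA"
ORIGIN_B = "BB"


class DepthTrack:
    """Per-window mean coverage of one sample over one reference.

    Windows are 0-based half-open, sorted, non-overlapping, constant width
    except possibly the final window of each chromosome.
    """

    def __init__(self, windows: pd.DataFrame, sample: str = "", reference: str = ""):
        required = {"chrom", "start", "end", "depth"}
        if not required.issubset(windows.columns):
            raise ValueError(f"depth track needs columns {sorted(required)}")
        df = windows.loc[:, ["chrom", "start", "end", "depth"]].copy()
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            if (grp["end"] <= grp["start"]).any():
                raise ValueError(f"empty window on {chrom}")
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping windows on {chrom}")
        self.windows = df
        self.sample = sample
        self.reference = reference

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def mean_depth(self) -> float:
        return float(self.windows["depth"].mean())

    def to_bedgraph(self, path) -> None:
        self.windows.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bedgraph(cls, path, sample: str = "", reference: str = "") -> "DepthTrack":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str},
        )
        return cls(df, sample=sample, reference=reference)


@dataclass(frozen=True)
class OriginBlock:
    chrom: str
    start: int
    end: int
    origin: str
    n_windows: int


@dataclass
class PartitionResult:
    blocks: List[OriginBlock]
    peak_depth: float
    threshold: float
    parameters: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.blocks])

    def to_bed(self, path) -> None:
        df = self.to_frame()
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df["origin"],
                "score": df["n_windows"],
                "strand": ".",
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    def window_labels(self, track: DepthTrack) -> np.ndarray:
        """Per-window origin labels of ``track`` under this partition."""
        labels = np.empty(len(track), dtype=object)
        by_chrom = {}
        for b in self.blocks:
            by_chrom.setdefault(b.chrom, []).append(b)
        for i, row in track.windows.iterrows():
            for b in by_chrom.get(row.chrom, ()):
                if b.start <= row.start < b.end:
                    labels[i] = b.origin
                    break
        return labels

    def total_bp(self, origin: str) -> int:
        return sum(b.end - b.start for b in self.blocks if b.origin == origin)


def estimate_peak_depth(track: DepthTrack) -> int:
    """Mode of the integer-binned depth histogram over covered windows.

    Ties break toward the larger depth.  All-zero tracks are an error.
    """
    depths = track.windows["depth"].to_numpy(dtype=float)
    depths = depths[depths > 0]
    if depths.size == 0:
        raise ValueError("no coverage: all windows have zero depth")
    binned = np.rint(depths).astype(int)
    binned = binned[binned > 0]
    if binned.size == 0:
        raise ValueError("no coverage: all windows have zero depth")
    counts = np.bincount(binned)
    # argmax on the reversed array prefers the larger depth on ties
    return int(len(counts) - 1 - np.argmax(counts[::-1]))


def classify_windows(track: DepthTrack, peak: float) -> np.ndarray:
    """Provisional origin per window: A when depth is strictly above half-peak."""
    if peak <= 0:
        raise ValueError("peak depth must be positive")
    depths = track.windows["depth"].to_numpy(dtype=float)
    return np.where(depths > 0.5 * peak, ORIGIN_A, ORIGIN_B)


def _runs(labels: np.ndarray) -> List[tuple]:
    """Maximal same-label runs as (start, end, label)."""
    out = []
    s = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[s]:
            out.append((s, i, labels[s]))
            s = i
    return out


def merge_blocks(
    track: DepthTrack, labels: np.ndarray, min_run: int = 5,
    peak: float = float("nan"),
) -> PartitionResult:
    """Flip sub-minimum runs to the opposite origin until a fixed point.

    Runs are processed left to right within each chromosome; after each flip
    adjacent equal-origin runs merge, and scanning restarts.  A chromosome
    shorter than ``min_run`` windows becomes a single majority-origin block
    (ties go to the first window's label).
    """
    df = track.windows
    blocks: List[OriginBlock] = []
    labels = np.asarray(labels, dtype=object).copy()
    for chrom, grp in df.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        lab = labels[idx].copy()
        if len(lab) < min_run:
            vals, counts = np.unique(lab, return_counts=True)
            if len(vals) == 1 or counts[0] != counts[1]:
                majority = vals[np.argmax(counts)]
            else:
                majority = lab[0]
            lab[:] = majority
        else:
            changed = True
            while changed:
                changed = False
                for s, e, value in _runs(lab):
                    if e - s < min_run:
                        lab[s:e] = ORIGIN_A if value == ORIGIN_B else ORIGIN_B
                        changed = True
                        break
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for s, e, value in _runs(lab):
            blocks.append(
                OriginBlock(chrom, int(starts[s]), int(ends[e - 1]), str(value), e - s)
            )
        labels[idx] = lab
    threshold = 0.5 * peak if peak == peak else float("nan")
    return PartitionResult(
        blocks, float(peak), threshold, {"min_run": min_run}
    )


def partition_genome(
    track: DepthTrack, min_run: int = 5
) -> PartitionResult:
    """Peak estimation + half-peak classification + block merging."""
    peak = estimate_peak_depth(track)
    labels = classify_windows(track, peak)
    return merge_blocks(track, labels, min_run=min_run, peak=peak)


def partition_accuracy(result: PartitionResult, truth_origins: pd.DataFrame) -> float:
    """Fraction of truth windows whose origin the partition reproduces."""
    truth = truth_origins.sort_values(["chrom", "start"]).reset_index(drop=True)
    track = DepthTrack(truth.assign(depth=0.0)[["chrom", "start", "end", "depth"]])
    labels = result.window_labels(track)
    if any(l is None for l in labels):
        raise ValueError("window grid mismatch between partition and truth")
    return float(np.mean(labels == truth["origin"].to_numpy()))
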