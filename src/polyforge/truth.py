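"""Planted-truth records emitted by the simulator.

Every pipeline stage is scored against these tables: window origins for the
subgenome partition, planted mutations for the caller, exchange events for
the depth callers, and gene fates for comparative curation.  All tables are
plain pandas DataFrames and round-trip through TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_TABLES = {
    "origins": ["chrom", "start", "end", "origin"],
    "mutations": ["lineage", "chrom", "pos", "ancestral", "derived"],
    "divergence_sites": ["lineage", "chrom", "pos", "ancestral", "derived"],
    "hes": [
        "event_id", "cls", "donor_chrom", "donor_start", "donor_end",
        "recip_chrom", "recip_start", "recip_end", "size", "samples",
    ],
    "genes": ["gene_id", "chrom", "start", "end", "strand"],
    "gene_fates": ["gene_id", "subgenome", "fate"],
}


def _empty(name: str) -> pd.DataFrame:
    return pd.DataFrame(columns=_TABLES[name])


@dataclass
class TruthSet:
    """Ground truth of one simulated system (see module docstring)."""

    origins: pd.DataFrame = field(default_factory=lambda: _empty("origins"))
    mutations: pd.DataFrame = field(default_factory=lambda: _empty("mutations"))
    divergence_sites: pd.DataFrame = field(
        default_factory=lambda: _empty("divergence_sites")
    )
    hes: pd.DataFrame = field(default_factory=lambda: _empty("hes"))
    genes: pd.DataFrame = field(default_factory=lambda: _empty("genes"))
    gene_fates: pd.DataFrame = field(default_factory=lambda: _empty("gene_fates"))

    def he_samples(self, event_id: str) -> list:
        row = self.hes.loc[self.hes.event_id == event_id]
        if row.empty:
            raise KeyError(event_id)
        samples = row.iloc[0]["samples"]
        return [] if samples == "" else str(samples).split(",")

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in _TABLES:
            getattr(self, name).to_csv(path / f"{name}.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path) -> "TruthSet":
        path = Path(path)
        kwargs = {}
        for name, cols in _TABLES.items():
            fp = path / f"{name}.tsv"
            if fp.exists():
                df = pd.read_csv(fp, sep="\t", dtype={"samples": str})
                if "samples" in df.columns:
                    df["samples"] = df["samples"].fillna("")
                kwargs[name] = df[cols]
            else:
                kwargs[name] = _empty(name)
        return cls(**kwargs)
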