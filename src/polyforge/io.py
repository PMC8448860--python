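"""File-format plumbing: FASTA, GFF3 gene models, chromosome sizes.

bedGraph handling lives on :class:`polyforge.partition.DepthTrack`, truth
tables on :class:`polyforge.truth.TruthSet`, and alignment FASTA on
:mod:`polyforge.blocks`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curation import GeneModel
from .seqcodes import decode, encode


def write_genome_fasta(genome: Dict[str, np.ndarray], path) -> None:
    records = [
        SeqRecord(Seq(decode(arr)), id=chrom, description="")
        for chrom, arr in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path) -> Dict[str, np.ndarray]:
    return {
        rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_chrom_sizes(sizes: Dict[str, int], path) -> None:
    pd.DataFrame(
        {"chrom": list(sizes), "size": list(sizes.values())}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_gene_models(models: List[GeneModel], path) -> None:
    """Minimal GFF3 (gene + CDS features, 1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for m in models:
        g_start = min(s for s, _ in m.exons) + 1
        g_end = max(e for _, e in m.exons)
        lines.append(
            "\t".join(
                [m.chrom, "polyforge", "gene", str(g_start), str(g_end), ".",
                 m.strand, ".", f"ID={m.gene_id}"]
            )
        )
        for i, (s, e) in enumerate(m.exons):
            lines.append(
                "\t".join(
                    [m.chrom, "polyforge", "CDS", str(s + 1), str(e), ".",
                     m.strand, str(m.frame if i == 0 else "."),
                     f"ID={m.gene_id}.cds{i + 1};Parent={m.gene_id}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(path) -> List[GeneModel]:
    cols = [
        "seqid", "source", "type", "start", "end", "score", "strand", "phase",
        "attributes",
    ]
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=cols,
        dtype={"seqid": str},
    )

    def attr(s: str, key: str) -> str:
        for part in s.split(";"):
            if part.startswith(key + "="):
                return part[len(key) + 1 :]
        return ""

    models: List[GeneModel] = []
    cds = df[df["type"] == "CDS"].copy()
    cds["parent"] = cds["attributes"].map(lambda s: attr(s, "Parent"))
    for gid, grp in cds.groupby("parent", sort=True):
        exons = [(int(r.start) - 1, int(r.end)) for r in grp.itertuples()]
        first = grp.iloc[0]
        frame = first["phase"]
        models.append(
            GeneModel(
                gene_id=str(gid),
                chrom=str(first["seqid"]),
                strand=str(first["strand"]),
                exons=exons,
                frame=int(frame) if str(frame).isdigit() else 0,
            )
        )
    return models
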