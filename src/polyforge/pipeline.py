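"""End-to-end orchestration: simulate -> partition -> blocks -> callmut ->
callhe -> curate -> date -> bias, with a machine-readable run manifest.

Every stage writes plain-text outputs under one run directory; the manifest
records the config hash, seed, per-stage parameters and paths, so any stage
can be re-run in isolation with identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .blocks import (
    MultiAlignment,
    filter_intervals,
    intervals_to_table,
    read_alignment,
    segment_on_gaps,
    write_alignment,
)
from .config import SimConfig
from .curation import calls_to_frame as curation_frame
from .curation import fractionation_test, project_and_classify
from .dating import CodingPair, DsEstimate, ds_distribution, ng86, pairs_to_frame
from .exchange import (
    SyntenyMap,
    call_balanced_he,
    call_genic_he,
    call_nonreciprocal,
    call_segmental_he,
    calls_to_frame as he_frame,
    gene_depth_ratios,
    propose_nonreciprocal_pairs,
    sharing_summary,
    telomere_enrichment,
)
from .expression import summarize_bias
from .mutations import (
    INTERPRETABLE,
    calls_to_frame as mutation_frame,
    call_intervals,
    compare_lineages,
    summarize_spectrum,
)
from .partition import DepthTrack, partition_accuracy, partition_genome
from .seqcodes import DIP_1, DIP_2, ROLES, TET_A, TET_B
from .simulate import (
    SimOutput,
    emit_alignment_blocks,
    sample_names,
    simulate_all,
    simulate_gene_depth,
    simulate_partition_depth,
    simulate_sample_depth,
)
from .truth import TruthSet
from . import io as pfio

log = logging.getLogger("polyforge")

STAGES = (
    "simulate", "partition", "blocks", "callmut", "callhe", "curate", "date",
    "bias",
)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: Dict[str, dict] = field(default_factory=dict)

    def add(
        self, name: str, params: dict, inputs: List[str], outputs: List[str],
        root=None,
    ):
        def rel(p: str) -> str:
            if root is None:
                return str(p)
            try:
                return str(Path(p).relative_to(root))
            except ValueError:
                return str(p)

        self.stages[name] = {
            "params": params,
            "inputs": sorted(rel(p) for p in inputs),
            "outputs": sorted(rel(p) for p in outputs),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _require(paths: Sequence[Path], stage: str) -> None:
    for p in paths:
        if not Path(p).exists():
            raise FileNotFoundError(f"stage dependency: {stage} needs {p}")


def build_synteny_map(config: SimConfig, genes: pd.DataFrame) -> SyntenyMap:
    a_names, b_names = config.chrom_names()
    segments = pd.DataFrame(
        {
            "chrom_a": list(a_names),
            "start_a": 0,
            "end_a": config.chrom_length,
            "chrom_b": list(b_names),
            "start_b": 0,
            "end_b": config.chrom_length,
            "orientation": "+",
        }
    )
    a = genes[genes["gene_id"].str.endswith("_A")].reset_index(drop=True)
    b = genes[genes["gene_id"].str.endswith("_B")].reset_index(drop=True)
    gene_pairs = pd.DataFrame(
        {
            "gene_a": a["gene_id"],
            "chrom_a": a["chrom"],
            "start_a": a["start"],
            "end_a": a["end"],
            "gene_b": b["gene_id"],
            "chrom_b": b["chrom"],
            "start_b": b["start"],
            "end_b": b["end"],
        }
    )
    return SyntenyMap(segments, gene_pairs)


def run_pipeline(config: SimConfig, outdir) -> RunManifest:
    """Execute all stages under ``outdir`` and return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.config_hash(), config.seed, __version__)
    config.to_yaml(out / "config.yaml")

    # --- simulate -----------------------------------------------------
    log.info("[simulate] seed=%d", config.seed)
    sim = simulate_all(config)
    rng_depth = np.random.default_rng((config.seed, 1))
    sim_dir = out / "sim"
    sim_dir.mkdir(exist_ok=True)
    tet_genome = {**sim.genomes[TET_A], **sim.genomes[TET_B]}
    pfio.write_genome_fasta(tet_genome, sim_dir / "tetraploid.fasta")
    pfio.write_genome_fasta(sim.genomes[DIP_1], sim_dir / "diploid1.fasta")
    pfio.write_genome_fasta(sim.genomes[DIP_2], sim_dir / "diploid2.fasta")
    sim.truth.to_dir(sim_dir / "truth")
    sizes = {c: len(a) for c, a in tet_genome.items()}
    pfio.write_chrom_sizes(sizes, sim_dir / "chrom.sizes")
    synteny = build_synteny_map(config, sim.truth.genes)
    synteny.to_tsv(sim_dir / "synteny_segments.tsv", sim_dir / "synteny_genes.tsv")
    pfio.write_gene_models(sim.gene_channel.guide_models, sim_dir / "genes.gff3")
    blocks_dir = sim_dir / "blocks"
    blocks_dir.mkdir(exist_ok=True)
    blocks = emit_alignment_blocks(sim)
    for blk in blocks:
        write_alignment(blk, blocks_dir / f"{blk.block_id}.fa")
    genes_dir = sim_dir / "genes"
    genes_dir.mkdir(exist_ok=True)
    for gid, aln in sim.gene_channel.alignments.items():
        write_alignment(aln, genes_dir / f"{gid}.fa")
    depth_dir = sim_dir / "depth"
    depth_dir.mkdir(exist_ok=True)
    ptrack = simulate_partition_depth(sim.truth, config, rng_depth)
    ptrack.to_bedgraph(depth_dir / "diploid_on_tetraploid.bedGraph")
    gene_depth_dir = sim_dir / "gene_depth"
    gene_depth_dir.mkdir(exist_ok=True)
    for s in sample_names(config):
        simulate_sample_depth(sim.truth, config, s, rng_depth).to_bedgraph(
            depth_dir / f"{s}.bedGraph"
        )
        simulate_gene_depth(sim.truth, config, s, rng_depth).to_csv(
            gene_depth_dir / f"{s}.tsv", sep="\t", index=False
        )
    sim.expression.to_csv(sim_dir / "expression.tsv", sep="\t", index=False)
    manifest.add(
        "simulate", config.to_dict(), [],
        [str(sim_dir)],
        root=out,
    )

    # --- partition ----------------------------------------------------
    log.info("[partition]")
    _require([depth_dir / "diploid_on_tetraploid.bedGraph"], "partition")
    track = DepthTrack.from_bedgraph(
        depth_dir / "diploid_on_tetraploid.bedGraph", sample="diploid"
    )
    part = partition_genome(track, min_run=5)
    part.to_bed(out / "partition.bed")
    manifest.add(
        "partition",
        {"min_run": 5, "peak_depth": part.peak_depth, "threshold": part.threshold},
        [str(depth_dir / "diploid_on_tetraploid.bedGraph")],
        [str(out / "partition.bed")],
        root=out,
    )

    # --- blocks -------------------------------------------------------
    log.info("[blocks]")
    _require([blocks_dir], "blocks")
    block_files = sorted(blocks_dir.glob("*.fa"))
    loaded = [read_alignment(p) for p in block_files]
    intervals = []
    for blk in loaded:
        intervals.extend(segment_on_gaps(blk, max_gap=100))
    kept = filter_intervals(intervals, min_length=500, min_identity=0.80)
    intervals_to_table(kept).to_csv(out / "intervals.tsv", sep="\t", index=False)
    manifest.add(
        "blocks",
        {"max_gap": 100, "min_length": 500, "min_identity": 0.80},
        [str(p) for p in block_files],
        [str(out / "intervals.tsv")],
        root=out,
    )

    # --- callmut ------------------------------------------------------
    log.info("[callmut] %d conserved intervals", len(kept))
    calls = call_intervals(kept)
    mutation_frame(calls).to_csv(out / "mutation_calls.tsv", sep="\t", index=False)
    spectra = pd.concat(
        [summarize_spectrum(calls, role).to_frame() for role in ROLES],
        ignore_index=True,
    )
    spectra.to_csv(out / "mutation_spectrum.tsv", sep="\t", index=False)
    comparison = compare_lineages(calls, unit="chromosome")
    comp_df = comparison.to_frame()
    comp_df["excess_percent"] = comparison.excess_percent
    comp_df["p_value"] = comparison.test.p_value if comparison.test else float("nan")
    comp_df.to_csv(out / "mutation_comparison.tsv", sep="\t", index=False)
    manifest.add(
        "callmut", {"flank": 5}, [str(out / "intervals.tsv")],
        [str(out / "mutation_calls.tsv"), str(out / "mutation_spectrum.tsv"),
         str(out / "mutation_comparison.tsv")],
        root=out,
    )

    # --- callhe -------------------------------------------------------
    log.info("[callhe]")
    all_calls = []
    for s in sample_names(config):
        strack = DepthTrack.from_bedgraph(depth_dir / f"{s}.bedGraph", sample=s)
        seg, _ = call_segmental_he(strack, synteny, min_size=20_000)
        all_calls.extend(seg)
        gdepth = pd.read_csv(gene_depth_dir / f"{s}.tsv", sep="\t")
        gdepth = gene_depth_ratios(gdepth, strack.mean_depth)
        all_calls.extend(call_genic_he(gdepth, synteny.gene_pairs, sample=s))
        cand = propose_nonreciprocal_pairs(strack, synteny)
        all_calls.extend(call_nonreciprocal(strack, cand))
    balanced, one_sided = call_balanced_he(part, synteny)
    all_calls.extend(balanced)
    he_frame(all_calls).to_csv(out / "he_calls.tsv", sep="\t", index=False)
    sharing = sharing_summary([c for c in all_calls if c.cls != "balanced"])
    sharing.events.to_csv(out / "he_sharing.tsv", sep="\t", index=False)
    genic = [c for c in all_calls if c.cls == "genic"]
    enrichment_path = out / "he_telomere_enrichment.tsv"
    if genic:
        enr = telomere_enrichment(
            genic, sim.truth.genes, sizes, window=config.effective_telomere_window
        )
        pd.DataFrame(
            [
                {
                    "observed": enr.observed,
                    "total": enr.total,
                    "expected_proportion": enr.expected_proportion,
                    "p": enr.test.p_value,
                    "p_label": enr.test.p_label,
                }
            ]
        ).to_csv(enrichment_path, sep="\t", index=False)
    manifest.add(
        "callhe",
        {"min_size": 20_000, "dup_band": [1.5, 3.0], "del_max": 0.5,
         "telomere_window": config.effective_telomere_window},
        [str(depth_dir)],
        [str(out / "he_calls.tsv"), str(out / "he_sharing.tsv")],
        root=out,
    )

    # --- curate -------------------------------------------------------
    log.info("[curate] %d genes", len(sim.gene_channel.guide_models))
    calls_a, calls_b = [], []
    for guide in sim.gene_channel.guide_models:
        aln = sim.gene_channel.alignments[guide.gene_id]
        calls_a.append(project_and_classify(guide, aln, TET_A))
        calls_b.append(project_and_classify(guide, aln, TET_B))
    cur_df = pd.concat(
        [curation_frame(calls_a), curation_frame(calls_b)], ignore_index=True
    )
    cur_df.to_csv(out / "curation.tsv", sep="\t", index=False)
    frac_test, frac_counts = fractionation_test(calls_a, calls_b)
    pd.DataFrame([{**frac_counts, "statistic": frac_test.statistic,
                   "p": frac_test.p_value, "p_label": frac_test.p_label}]).to_csv(
        out / "fractionation.tsv", sep="\t", index=False
    )
    manifest.add(
        "curate", {"deletion_threshold": 0.2}, [str(genes_dir)],
        [str(out / "curation.tsv"), str(out / "fractionation.tsv")],
        root=out,
    )

    # --- date ---------------------------------------------------------
    log.info("[date]")
    status = {
        (c.gene_id, c.lineage): c.status for c in calls_a + calls_b
    }
    ds_rows = []
    for guide in sim.gene_channel.guide_models:
        gid = guide.gene_id
        if status.get((gid, TET_A)) != "intact" or status.get((gid, TET_B)) != "intact":
            continue
        aln = sim.gene_channel.alignments[gid]
        a_row, b_row = aln.row(TET_A), aln.row(TET_B)
        if guide.strand == "-":
            from Bio.Seq import Seq

            a_row = str(Seq(a_row).reverse_complement())
            b_row = str(Seq(b_row).reverse_complement())
        try:
            pair = CodingPair.from_sequences(a_row, b_row)
            ds_rows.append((f"{gid}_A", f"{gid}_B", ng86(pair)))
        except ValueError:
            continue
    ds_df = pairs_to_frame(ds_rows)
    ds_df.to_csv(out / "ds_pairs.tsv", sep="\t", index=False)
    if len(ds_df):
        dist = ds_distribution(ds_df["dS"].to_numpy())
        summary = {
            "n_pairs": int(dist.n),
            "mode": dist.mode,
            "zero_fraction": dist.zero_fraction,
        }
    else:
        summary = {"n_pairs": 0, "mode": None, "zero_fraction": float("nan")}
    (out / "ds_summary.json").write_text(json.dumps(summary, indent=2))
    manifest.add(
        "date", {"method": "NG86", "bin": 0.005}, [str(genes_dir)],
        [str(out / "ds_pairs.tsv"), str(out / "ds_summary.json")],
        root=out,
    )

    # --- bias ---------------------------------------------------------
    log.info("[bias]")
    _require([sim_dir / "expression.tsv"], "bias")
    pairs = pd.read_csv(sim_dir / "expression.tsv", sep="\t")
    bias = summarize_bias(pairs)
    bias.histogram_frame().to_csv(out / "bias_histogram.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "mean": bias.mean,
                "median": bias.median,
                "secondary_peak": bias.secondary_peak,
            }
        ]
    ).to_csv(out / "bias_summary.tsv", sep="\t", index=False)
    manifest.add(
        "bias", {"bin": 0.05, "pseudo_count": 1}, [str(sim_dir / "expression.tsv")],
        [str(out / "bias_summary.tsv"), str(out / "bias_histogram.tsv")],
        root=out,
    )

    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# truth evaluation


def mutation_recovery(
    calls, truth: TruthSet, config: SimConfig, lineages=INTERPRETABLE
) -> dict:
    """Recall/precision of mutation calls against planted truth.

    Misses are audited: a planted mutation with another variant (or a
    block/chromosome edge) within the flank distance is annotated
    ``flank_violation``.
    """
    planted = {
        (r.lineage, r.chrom, int(r.pos)): (r.ancestral, r.derived)
        for r in truth.mutations.itertuples()
        if r.lineage in lineages
    }
    called = {
        (c.carrier, c.chrom, c.pos) for c in calls if c.carrier in lineages
    }
    hits = called & set(planted)
    misses = set(planted) - called
    false = called - set(planted)

    variant_pos: Dict[str, set] = {}
    for df in (truth.mutations, truth.divergence_sites):
        for r in df.itertuples():
            variant_pos.setdefault(str(r.chrom)[1:], set()).add(int(r.pos))
    flank = 5
    miss_rows = []
    for lineage, chrom, pos in sorted(misses):
        pair_sites = variant_pos.get(chrom[1:], set())
        near = any(
            0 < abs(pos - q) <= flank for q in pair_sites
        )
        edge = (
            pos < flank
            or pos >= config.chrom_length - flank
            or min(pos % config.block_length,
                   config.block_length - pos % config.block_length) <= flank
        )
        miss_rows.append(
            {
                "lineage": lineage,
                "chrom": chrom,
                "pos": pos,
                "reason": "flank_violation" if (near or edge) else "unknown",
            }
        )
    n_planted = len(planted)
    n_called = len(called)
    return {
        "recall": len(hits) / n_planted if n_planted else float("nan"),
        "precision": len(hits) / n_called if n_called else float("nan"),
        "n_planted": n_planted,
        "n_called": n_called,
        "misses": pd.DataFrame(miss_rows),
        "false_calls": sorted(false),
    }


def he_recovery(calls, truth: TruthSet, config: SimConfig) -> dict:
    """Segmental-event recovery against planted truth (>= caller minimum)."""
    def overlaps(call, ev) -> bool:
        def ov(c1, s1, e1, c2, s2, e2):
            if c1 != c2:
                return 0.0
            o = min(e1, e2) - max(s1, s2)
            return max(o, 0) / max(e2 - s2, 1)

        return (
            ov(call.donor_chrom, call.donor_start, call.donor_end,
               ev.donor_chrom, ev.donor_start, ev.donor_end) >= 0.5
            and ov(call.recip_chrom, call.recip_start, call.recip_end,
                   ev.recip_chrom, ev.recip_start, ev.recip_end) >= 0.5
        )

    seg_all = truth.hes[truth.hes["cls"] == "segmental"]
    seg_truth = seg_all[seg_all["size"] >= config.caller_min_size]
    seg_calls = [c for c in calls if c.cls == "segmental"]
    expected = []  # (event, sample) occurrences of callable-size events
    for ev in seg_truth.itertuples():
        for s in str(ev.samples).split(","):
            if s:
                expected.append((ev, s))
    recovered = 0
    for ev, s in expected:
        if any(c.sample == s and overlaps(c, ev) for c in seg_calls):
            recovered += 1
    # precision counts any planted occurrence as real, including the
    # below-minimum controls (noise can legitimately push them over size)
    planted_any = [
        (ev, s)
        for ev in seg_all.itertuples()
        for s in str(ev.samples).split(",")
        if s
    ]
    true_pos = 0
    for c in seg_calls:
        if any(
            c.sample == s and overlaps(c, ev) for ev, s in planted_any
        ):
            true_pos += 1
    return {
        "recall": recovered / len(expected) if expected else float("nan"),
        "precision": true_pos / len(seg_calls) if seg_calls else float("nan"),
        "n_expected": len(expected),
        "n_called": len(seg_calls),
    }


def evaluate_against_truth(outdir, config: Optional[SimConfig] = None) -> pd.DataFrame:
    """Score a finished run directory against its own truth set."""
    out = Path(outdir)
    if config is None:
        config = SimConfig.from_yaml(out / "config.yaml")
    truth = TruthSet.from_dir(out / "sim" / "truth")
    rows = []

    part_bed = pd.read_csv(
        out / "partition.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    from .partition import OriginBlock, PartitionResult

    blocks = [
        OriginBlock(str(r.chrom), int(r.start), int(r.end), str(r.name), int(r.score))
        for r in part_bed.itertuples()
    ]
    acc = partition_accuracy(
        PartitionResult(blocks, 0.0, 0.0), truth.origins
    )
    rows.append({"stage": "partition", "metric": "window_accuracy", "value": acc})

    calls_df = pd.read_csv(out / "mutation_calls.tsv", sep="\t")

    class _C:  # lightweight view over the TSV rows
        def __init__(self, r):
            self.carrier, self.chrom, self.pos = r.carrier, str(r.chrom), int(r.pos)

    mrec = mutation_recovery(
        [_C(r) for r in calls_df.itertuples()], truth, config
    )
    rows.append({"stage": "callmut", "metric": "recall", "value": mrec["recall"]})
    rows.append({"stage": "callmut", "metric": "precision", "value": mrec["precision"]})

    he_df = pd.read_csv(out / "he_calls.tsv", sep="\t")

    class _H:
        def __init__(self, r):
            for k in ("cls", "sample", "donor_chrom", "donor_start", "donor_end",
                      "recip_chrom", "recip_start", "recip_end"):
                setattr(self, k, getattr(r, k))

    hrec = he_recovery([_H(r) for r in he_df.itertuples()], truth, config)
    rows.append({"stage": "callhe", "metric": "segmental_recall", "value": hrec["recall"]})
    rows.append({"stage": "callhe", "metric": "segmental_precision", "value": hrec["precision"]})

    cur = pd.read_csv(out / "curation.tsv", sep="\t")
    fates = truth.gene_fates.copy()
    fates["lineage"] = np.where(fates["subgenome"] == "A", TET_A, TET_B)
    merged = cur.merge(
        fates, left_on=["gene_id", "lineage"], right_on=["gene_id", "lineage"]
    )
    if len(merged):
        rows.append(
            {
                "stage": "curate",
                "metric": "fate_accuracy",
                "value": float((merged["status"] == merged["fate"]).mean()),
            }
        )
    return pd.DataFrame(rows)
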