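"""Synthetic allotetraploid generator with machine-readable planted truth.

The simulated system mirrors a young allopolyploid and its surviving
diploid progenitor lineage:

* a common ancestor genome splits into an A and a B lineage that diverge to
  a configurable substitutions/site level (default 0.034);
* an allotetraploid carries both lineages as subgenomes (rows ``tet_A`` and
  ``tet_B``), while two diploid accessions (``dip_1``, ``dip_2``) continue
  the A lineage;
* after polyploidization each of the four lineages accumulates de novo
  point mutations under a six-type/96-context spectrum, with a configurable
  tetraploid/diploid rate ratio (default 1.10);
* homeologous exchanges of the three dosage classes (4:0 segmental and
  genic, 2:2 balanced, 3:1 nonreciprocal) are planted with a telomere bias;
* protein-coding genes are simulated in a separate codon-aware channel with
  planted intact/pseudogene/deleted fates per subgenome;
* depth tracks are Poisson draws from the planted copy numbers, and
  homeolog expression follows a two-component log2-ratio mixture.

Every random draw flows from a single :class:`numpy.random.Generator`
seeded by ``SimConfig.seed``, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .blocks import MultiAlignment, RowCoords
from .config import CLASSES6, SimConfig
from .curation import GeneModel
from .partition import DepthTrack, ORIGIN_A, ORIGIN_B
from .seqcodes import (
    BASES,
    COMP_CODE,
    DIP_1,
    DIP_2,
    ROLES,
    TET_A,
    TET_B,
    decode,
    random_codes,
)
from .truth import TruthSet

# class index -> (pyrimidine ref code, derived code); C=1, T=3, A=0, G=2
_CLASS_DEF = {
    0: (1, 0),  # C>A
    1: (1, 2),  # C>G
    2: (1, 3),  # C>T
    3: (3, 0),  # T>A
    4: (3, 1),  # T>C
    5: (3, 2),  # T>G
}

_STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# substitution machinery


def _draw_spectrum_substitutions(
    seq: np.ndarray,
    n: int,
    spectrum: Tuple[float, ...],
    rng: np.random.Generator,
    available: np.ndarray,
    spacing: Optional[int],
    context_modifiers: Optional[dict] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plant ``n`` substitutions on ``seq`` drawn from a six-class spectrum.

    ``available`` marks positions that may still receive a variant and is
    updated in place: with ``spacing`` set, a placed variant clears the
    surrounding ``spacing`` bp on both sides; without it only the position
    itself.  Raises ``ValueError("unplaceable mutations")`` when eligible
    positions run out.
    """
    counts = rng.multinomial(n, spectrum)
    pos_out: List[int] = []
    anc_out: List[int] = []
    der_out: List[int] = []
    for ci, cnt in enumerate(counts):
        if cnt == 0:
            continue
        ref, alt = _CLASS_DEF[ci]
        base_mask = (seq == ref) | (seq == COMP_CODE[ref])
        placed = 0
        guard = 0
        while placed < cnt:
            guard += 1
            if guard > 200:
                raise ValueError("unplaceable mutations")
            idx = np.flatnonzero(base_mask & available)
            if idx.size == 0:
                raise ValueError("unplaceable mutations")
            need = cnt - placed
            take = min(idx.size, max(need * 2, 16))
            cand = rng.choice(idx, size=take, replace=False)
            for p in cand:
                if not available[p]:
                    continue
                if context_modifiers is not None and not _accept_context(
                    seq, int(p), ci, context_modifiers, rng
                ):
                    continue
                anc = int(seq[p])
                der = alt if anc == ref else int(COMP_CODE[alt])
                pos_out.append(int(p))
                anc_out.append(anc)
                der_out.append(der)
                if spacing is None:
                    available[p] = False
                else:
                    lo = max(0, p - spacing)
                    available[lo : p + spacing + 1] = False
                placed += 1
                if placed == cnt:
                    break
    order = np.argsort(pos_out)
    return (
        np.asarray(pos_out, dtype=np.int64)[order],
        np.asarray(anc_out, dtype=np.uint8)[order],
        np.asarray(der_out, dtype=np.uint8)[order],
    )


def _accept_context(seq, p, class_idx, modifiers, rng) -> bool:
    """Rejection step for optional per-class 5'/3' context weights."""
    if p == 0 or p == seq.size - 1:
        return True
    five, three = int(seq[p - 1]), int(seq[p + 1])
    if int(seq[p]) in (0, 2):  # purine focal base: collapse to pyrimidine strand
        five, three = int(COMP_CODE[seq[p + 1]]), int(COMP_CODE[seq[p - 1]])
    weights = modifiers.get(CLASSES6[class_idx])
    if weights is None:
        return True
    key = BASES[five] + BASES[three]
    w = float(weights.get(key, 1.0))
    wmax = max(float(v) for v in weights.values()) or 1.0
    return rng.random() < w / wmax


# ---------------------------------------------------------------------------
# progenitors


def simulate_progenitors(
    config: SimConfig, rng: np.random.Generator
) -> Tuple[List[np.ndarray], Dict[str, np.ndarray], Dict[str, np.ndarray], pd.DataFrame]:
    """Ancestor plus the two diverged progenitor genomes.

    Each lineage receives ``progenitor_divergence / 2`` substitutions per
    site drawn from the de novo spectrum; a site is hit in at most one
    lineage so every divergence site is a clean two-state column.
    Returns (ancestor chromosomes, A genome, B genome, divergence table).
    """
    a_names, b_names = config.chrom_names()
    ancestor: List[np.ndarray] = []
    genome_a: Dict[str, np.ndarray] = {}
    genome_b: Dict[str, np.ndarray] = {}
    rows = []
    per_lineage = config.progenitor_divergence / 2.0
    for i in range(config.n_chromosomes):
        anc = random_codes(rng, config.chrom_length)
        ancestor.append(anc)
        seq_a = anc.copy()
        seq_b = anc.copy()
        available = np.ones(config.chrom_length, dtype=bool)
        for lineage, seq, chrom in (("A", seq_a, a_names[i]), ("B", seq_b, b_names[i])):
            n = int(rng.binomial(config.chrom_length, per_lineage))
            pos, anc_c, der_c = _draw_spectrum_substitutions(
                seq, n, config.spectrum6, rng, available, spacing=None
            )
            seq[pos] = der_c
            if len(pos):
                rows.append(
                    pd.DataFrame(
                        {
                            "lineage": lineage,
                            "chrom": chrom,
                            "pos": pos,
                            "ancestral": [BASES[c] for c in anc_c],
                            "derived": [BASES[c] for c in der_c],
                        }
                    )
                )
        genome_a[a_names[i]] = seq_a
        genome_b[b_names[i]] = seq_b
    divergence = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["lineage", "chrom", "pos", "ancestral", "derived"])
    )
    return ancestor, genome_a, genome_b, divergence


# ---------------------------------------------------------------------------
# de novo mutations


def plant_mutations(
    config: SimConfig,
    rng: np.random.Generator,
    genome_a: Dict[str, np.ndarray],
    genome_b: Dict[str, np.ndarray],
    divergence: pd.DataFrame,
) -> Tuple[Dict[str, Dict[str, np.ndarray]], pd.DataFrame]:
    """Post-polyploidization mutations for the four lineages.

    Every planted mutation keeps >= ``min_mutation_spacing`` bp clear of any
    other variant site (any lineage, including progenitor divergence) and of
    chromosome/block edges, so each one satisfies the caller's flank rule by
    construction.  ``enforce_spacing=False`` drops the guarantee.
    """
    a_names, b_names = config.chrom_names()
    spacing = config.min_mutation_spacing if config.enforce_spacing else None
    lineage_rates = {
        TET_A: config.tetraploid_mutation_rate,
        TET_B: config.tetraploid_mutation_rate,
        DIP_1: config.diploid_mutation_rate,
        DIP_2: config.diploid_mutation_rate,
    }
    genomes: Dict[str, Dict[str, np.ndarray]] = {
        TET_A: {c: genome_a[c].copy() for c in a_names},
        TET_B: {c: genome_b[c].copy() for c in b_names},
        DIP_1: {c: genome_a[c].copy() for c in a_names},
        DIP_2: {c: genome_a[c].copy() for c in a_names},
    }
    rows = []
    for i in range(config.n_chromosomes):
        L = config.chrom_length
        available = np.ones(L, dtype=bool)
        margin = config.min_mutation_spacing
        # keep flanks inside chromosome and emitted-block boundaries
        available[:margin] = False
        available[L - margin :] = False
        for edge in range(config.block_length, L, config.block_length):
            available[max(0, edge - margin) : edge + margin] = False
        pair_chroms = {a_names[i], b_names[i]}
        div_pos = divergence.loc[
            divergence["chrom"].isin(pair_chroms), "pos"
        ].to_numpy(dtype=np.int64)
        if spacing is not None:
            for p in div_pos:
                available[max(0, p - spacing) : p + spacing + 1] = False
        else:
            available[div_pos] = False
        for role in ROLES:
            chrom = a_names[i] if role != TET_B else b_names[i]
            seq = genomes[role][chrom]
            n = int(rng.poisson(lineage_rates[role] * L))
            pos, anc_c, der_c = _draw_spectrum_substitutions(
                seq,
                n,
                config.spectrum6,
                rng,
                available,
                spacing=spacing,
                context_modifiers=config.context_modifiers,
            )
            seq[pos] = der_c
            if len(pos):
                rows.append(
                    pd.DataFrame(
                        {
                            "lineage": role,
                            "chrom": chrom,
                            "pos": pos,
                            "ancestral": [BASES[c] for c in anc_c],
                            "derived": [BASES[c] for c in der_c],
                        }
                    )
                )
    mutations = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["lineage", "chrom", "pos", "ancestral", "derived"])
    )
    return genomes, mutations


# ---------------------------------------------------------------------------
# genes (codon-aware channel)


def _random_cds(config: SimConfig, rng: np.random.Generator) -> str:
    n_codons = config.gene_cds_length // 3
    sense = [
        a + b + c
        for a in BASES
        for b in BASES
        for c in BASES
        if a + b + c not in _STOP_CODONS
    ]
    body = rng.choice(len(sense), size=n_codons - 2)
    return "ATG" + "".join(sense[i] for i in body) + "TAA"


def _mutate_cds(cds: str, n: int, rng: np.random.Generator) -> str:
    """Apply ``n`` random substitutions, redrawing any that create an
    internal stop codon (the gene channel plants stops only as fates)."""
    seq = list(cds)
    n_codons = len(cds) // 3
    if n == 0:
        return cds
    positions = rng.choice(len(cds), size=min(n, len(cds)), replace=False)
    for p in positions:
        ci = p // 3
        if ci >= n_codons - 1:
            continue  # keep the terminal stop codon intact
        old = seq[p]
        alts = [b for b in BASES if b != old]
        rng.shuffle(alts)
        for alt in alts:
            seq[p] = alt
            codon = "".join(seq[ci * 3 : ci * 3 + 3])
            if codon not in _STOP_CODONS:
                break
            seq[p] = old
    return "".join(seq)


def _revcomp(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "-": "-", "N": "N"}
    return "".join(comp[c] for c in reversed(s))


@dataclass
class GeneChannel:
    genes: pd.DataFrame
    gene_fates: pd.DataFrame
    alignments: Dict[str, MultiAlignment]
    guide_models: List[GeneModel] = field(default_factory=list)


def simulate_gene_channel(config: SimConfig, rng: np.random.Generator) -> GeneChannel:
    """Syntenic gene pairs with planted intact/pseudogene/deleted fates.

    CDS content is generated codon-aware and kept separate from the
    chromosome channel: the chromosomes carry gene *positions* (for depth,
    telomere and exchange logic) while the per-gene four-way alignments
    carry the sequence-level fates for curation and dS estimation.
    """
    a_names, b_names = config.chrom_names()
    L_cds = config.gene_cds_length
    pitch = L_cds + 200
    per_chrom = config.gene_count // config.n_chromosomes
    div_per_lineage = config.progenitor_divergence / 2.0
    tet_n = config.tetraploid_mutation_rate * L_cds
    dip_n = config.diploid_mutation_rate * L_cds

    gene_rows, fate_rows = [], []
    alignments: Dict[str, MultiAlignment] = {}
    guides: List[GeneModel] = []
    gid_counter = 0
    for i in range(config.n_chromosomes):
        n_slots = (config.chrom_length - 200) // pitch
        count = min(per_chrom, n_slots)
        slots = rng.choice(n_slots, size=count, replace=False)
        slots.sort()
        for slot in slots:
            gid_counter += 1
            gid = f"g{gid_counter:05d}"
            start = int(slot) * pitch + 100
            end = start + L_cds
            strand = "+" if rng.random() < 0.5 else "-"
            anc = _random_cds(config, rng)
            cds_a = _mutate_cds(anc, int(rng.binomial(L_cds, div_per_lineage)), rng)
            cds_b = _mutate_cds(anc, int(rng.binomial(L_cds, div_per_lineage)), rng)
            rows = {
                TET_A: _mutate_cds(cds_a, int(rng.poisson(tet_n)), rng),
                TET_B: _mutate_cds(cds_b, int(rng.poisson(tet_n)), rng),
                DIP_1: _mutate_cds(cds_a, int(rng.poisson(dip_n)), rng),
                DIP_2: _mutate_cds(cds_a, int(rng.poisson(dip_n)), rng),
            }
            for sub, role in (("A", TET_A), ("B", TET_B)):
                p_pseudo = getattr(config, f"pseudogene_fraction_{sub}")
                p_del = getattr(config, f"deletion_fraction_{sub}")
                u = rng.random()
                if u < p_pseudo:
                    fate = "pseudogene"
                    seq = list(rows[role])
                    if rng.random() < 0.5:  # premature stop
                        ci = int(rng.integers(2, L_cds // 3 - 2))
                        seq[ci * 3 : ci * 3 + 3] = list("TAA")
                    else:  # 1-bp frameshift deletion
                        p = int(rng.integers(3, L_cds - 6))
                        seq[p] = "-"
                    rows[role] = "".join(seq)
                elif u < p_pseudo + p_del:
                    fate = "deleted"
                    rows[role] = "-" * L_cds
                else:
                    fate = "intact"
                fate_rows.append({"gene_id": gid, "subgenome": sub, "fate": fate})
            if strand == "-":
                rows = {r: _revcomp(s) for r, s in rows.items()}
            coords = {
                TET_A: RowCoords(a_names[i], start, "+"),
                TET_B: RowCoords(b_names[i], start, "+"),
                DIP_1: RowCoords(a_names[i], start, "+"),
                DIP_2: RowCoords(a_names[i], start, "+"),
            }
            alignments[gid] = MultiAlignment(f"gene_{gid}", rows, coords)
            guides.append(
                GeneModel(
                    gene_id=gid,
                    chrom=a_names[i],
                    strand=strand,
                    exons=[(start, end)],
                )
            )
            gene_rows.append(
                {"gene_id": f"{gid}_A", "chrom": a_names[i], "start": start,
                 "end": end, "strand": strand}
            )
            gene_rows.append(
                {"gene_id": f"{gid}_B", "chrom": b_names[i], "start": start,
                 "end": end, "strand": strand}
            )
    return GeneChannel(
        pd.DataFrame(gene_rows),
        pd.DataFrame(fate_rows),
        alignments,
        guides,
    )


# ---------------------------------------------------------------------------
# homeologous exchanges


def _snap(x: int, w: int) -> int:
    return int(round(x / w)) * w


def _draw_interval(
    config: SimConfig, rng: np.random.Generator, size: int
) -> int:
    """Telomere-biased start position on a chromosome of configured length."""
    L = config.chrom_length
    W = config.effective_telomere_window
    size = min(size, L)
    if rng.random() < config.telomere_bias and W > size:
        if rng.random() < 0.5:
            start = int(rng.integers(0, max(1, W - size)))
        else:
            start = int(rng.integers(L - W, L - size + 1))
    else:
        start = int(rng.integers(0, L - size + 1))
    return _snap(start, config.window_size)


def _overlaps(reserved: Dict[str, List[Tuple[int, int]]], chrom: str, s: int, e: int) -> bool:
    return any(s < re and rs < e for rs, re in reserved.get(chrom, ()))


def _reserve(reserved, chrom, s, e) -> None:
    reserved.setdefault(chrom, []).append((s, e))


def _pick_samples(samples: List[str], config: SimConfig, rng) -> List[str]:
    chosen = [s for s in samples if rng.random() < config.he_sample_fraction]
    if not chosen:
        chosen = [samples[int(rng.integers(len(samples)))]]
    return chosen


def plant_homeologous_exchanges(
    config: SimConfig,
    rng: np.random.Generator,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Plant segmental (4:0), genic (4:0), balanced (2:2) and nonreciprocal
    (3:1) exchanges, telomere-biased, snapped to the depth window grid.

    At least one segmental event is forced above the caller's minimum size
    and (when two or more are requested) one below it as a negative
    control.  Overlapping placements are retried; persistent overlap is an
    error.
    """
    a_names, b_names = config.chrom_names()
    samples = sample_names(config)
    w = config.window_size
    reserved: Dict[str, List[Tuple[int, int]]] = {}
    rows = []
    eid = 0

    def add(cls, d_chrom, d_s, d_e, r_chrom, r_s, r_e, carrier_list):
        nonlocal eid
        eid += 1
        rows.append(
            {
                "event_id": f"he{eid:03d}",
                "cls": cls,
                "donor_chrom": d_chrom,
                "donor_start": int(d_s),
                "donor_end": int(d_e),
                "recip_chrom": r_chrom,
                "recip_start": int(r_s),
                "recip_end": int(r_e),
                "size": int(d_e - d_s),
                "samples": ",".join(carrier_list),
            }
        )

    lo, hi = config.he_size_range
    sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_segmental_he)]
    if sizes:
        sizes[0] = max(sizes[0], int(config.caller_min_size * 1.5))
    if len(sizes) >= 2:
        sizes[1] = max(w, int(config.caller_min_size * 0.75))  # negative control
    for size in sizes:
        size = max(w, _snap(size, w))
        for _ in range(200):
            pi = int(rng.integers(config.n_chromosomes))
            donor_is_a = rng.random() < 0.5
            d_chrom = a_names[pi] if donor_is_a else b_names[pi]
            r_chrom = b_names[pi] if donor_is_a else a_names[pi]
            s = _draw_interval(config, rng, size)
            e = s + size
            if not _overlaps(reserved, d_chrom, s, e) and not _overlaps(
                reserved, r_chrom, s, e
            ):
                _reserve(reserved, d_chrom, s, e)
                _reserve(reserved, r_chrom, s, e)
                add("segmental", d_chrom, s, e, r_chrom, s, e,
                    _pick_samples(samples, config, rng))
                break
        else:
            raise ValueError("overlapping planted events")

    for _ in range(config.n_balanced_he):
        size = max(6 * w, _snap(int(rng.integers(lo, hi + 1)), w))
        for _ in range(200):
            pi = int(rng.integers(config.n_chromosomes))
            a_chrom, b_chrom = a_names[pi], b_names[pi]
            s = _draw_interval(config, rng, size)
            # keep long flanks on both sides for the balanced caller
            s = min(max(s, 12 * w), config.chrom_length - size - 12 * w)
            s = _snap(max(s, 0), w)
            e = s + size
            if not _overlaps(reserved, a_chrom, s, e) and not _overlaps(
                reserved, b_chrom, s, e
            ):
                _reserve(reserved, a_chrom, s, e)
                _reserve(reserved, b_chrom, s, e)
                add("balanced", a_chrom, s, e, b_chrom, s, e, samples)
                break
        else:
            raise ValueError("overlapping planted events")

    if config.n_nonreciprocal_he and config.n_chromosomes < 2:
        raise ValueError("nonreciprocal exchanges need >= 2 chromosome pairs")
    for _ in range(config.n_nonreciprocal_he):
        size = max(6 * w, _snap(int(rng.integers(lo, hi + 1)), w))
        for _ in range(200):
            pi, pj = rng.choice(config.n_chromosomes, size=2, replace=False)
            d_chrom, r_chrom = a_names[int(pi)], a_names[int(pj)]
            s = _draw_interval(config, rng, size)
            e = s + size
            if not _overlaps(reserved, d_chrom, s, e) and not _overlaps(
                reserved, r_chrom, s, e
            ):
                _reserve(reserved, d_chrom, s, e)
                _reserve(reserved, r_chrom, s, e)
                add("nonreciprocal", d_chrom, s, e, r_chrom, s, e,
                    _pick_samples(samples, config, rng))
                break
        else:
            raise ValueError("overlapping planted events")

    # genic conversions over homeologous gene pairs
    base_ids = sorted({g[:-2] for g in genes["gene_id"]})
    if base_ids and config.n_genic_he:
        a_genes = genes[genes["gene_id"].str.endswith("_A")].set_index("gene_id")
        W = config.effective_telomere_window
        L = config.chrom_length
        telo, interior = [], []
        for gid in base_ids:
            row = a_genes.loc[f"{gid}_A"]
            near = row.start < W or row.end > L - W
            (telo if near else interior).append(gid)
        chosen: List[str] = []
        for _ in range(min(config.n_genic_he, len(base_ids))):
            pool = telo if (rng.random() < config.telomere_bias and telo) else interior
            if not pool:
                pool = telo or interior
            gid = pool.pop(int(rng.integers(len(pool))))
            chosen.append(gid)
        n_bidir = min(config.n_bidirectional_genic, len(chosen))
        for k, gid in enumerate(chosen):
            row = a_genes.loc[f"{gid}_A"]
            a_chrom = row.chrom
            b_chrom = config.homeolog_of(a_chrom)
            donor_is_a = rng.random() < 0.5
            d_chrom, r_chrom = (a_chrom, b_chrom) if donor_is_a else (b_chrom, a_chrom)
            carriers = _pick_samples(samples, config, rng)
            add("genic", d_chrom, row.start, row.end, r_chrom, row.start, row.end,
                carriers)
            if k < n_bidir:
                others = [s for s in samples if s not in carriers]
                if others:
                    twin = _pick_samples(others, config, rng)
                    add("genic", r_chrom, row.start, row.end, d_chrom,
                        row.start, row.end, twin)
    from .truth import _TABLES

    return pd.DataFrame(rows, columns=_TABLES["hes"])


def sample_names(config: SimConfig) -> List[str]:
    return [f"S{i + 1:02d}" for i in range(config.n_samples)]


def window_origins(config: SimConfig, hes: pd.DataFrame) -> pd.DataFrame:
    """Per-window AA/BB origin of the tetraploid reference.

    A-chromosome windows are AA and B-chromosome windows BB, except inside
    balanced exchanges fixed in all samples, which flip the local origin.
    """
    a_names, b_names = config.chrom_names()
    w = config.window_size
    rows = []
    for chrom in list(a_names) + list(b_names):
        origin = ORIGIN_A if chrom.startswith("A") else ORIGIN_B
        starts = np.arange(0, config.chrom_length, w)
        ends = np.minimum(starts + w, config.chrom_length)
        df = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "origin": origin}
        )
        rows.append(df)
    origins = pd.concat(rows, ignore_index=True)
    for _, ev in hes[hes["cls"] == "balanced"].iterrows():
        for chrom, s, e in (
            (ev.donor_chrom, ev.donor_start, ev.donor_end),
            (ev.recip_chrom, ev.recip_start, ev.recip_end),
        ):
            mask = (
                (origins["chrom"] == chrom)
                & (origins["start"] >= s)
                & (origins["end"] <= e)
            )
            flipped = ORIGIN_B if chrom.startswith("A") else ORIGIN_A
            origins.loc[mask, "origin"] = flipped
    return origins


# ---------------------------------------------------------------------------
# depth channel


def _noisy(
    rng: np.random.Generator, mean: np.ndarray, overdispersion: float,
    exact: bool = False,
) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if exact:
        return mean.copy()
    if overdispersion > 0:
        lam = rng.gamma(1.0 / overdispersion, overdispersion * np.maximum(mean, 1e-12))
        lam[mean <= 0] = 0.0
        return rng.poisson(lam).astype(float)
    return rng.poisson(np.maximum(mean, 0.0)).astype(float)


def simulate_partition_depth(
    truth: TruthSet, config: SimConfig, rng: np.random.Generator,
    exact: bool = False,
) -> DepthTrack:
    """Depth of diploid reads over the tetraploid reference in fixed windows.

    AA-origin windows draw Poisson(depth_mean); BB-origin windows only a
    small mismapping background.
    """
    org = truth.origins
    mean = np.where(
        org["origin"].to_numpy() == ORIGIN_A,
        config.depth_mean,
        config.depth_mean * config.background_depth_fraction,
    )
    df = org[["chrom", "start", "end"]].copy()
    df["depth"] = _noisy(rng, mean, config.overdispersion, exact=exact)
    return DepthTrack(df, sample="diploid", reference="tetraploid")


def copy_number_windows(
    truth: TruthSet, config: SimConfig, sample: str
) -> pd.DataFrame:
    """Planted copy number (of 4) per window for one resequencing sample."""
    cn = truth.origins[["chrom", "start", "end"]].copy()
    cn["cn"] = 2
    for _, ev in truth.hes.iterrows():
        if ev.cls in ("balanced", "genic"):
            continue  # balanced keeps 2:2; genic is sub-window scale
        carriers = [] if ev.samples == "" else str(ev.samples).split(",")
        if sample not in carriers:
            continue
        donor_cn = 4 if ev.cls == "segmental" else 3
        recip_cn = 0 if ev.cls == "segmental" else 1
        for chrom, s, e, value in (
            (ev.donor_chrom, ev.donor_start, ev.donor_end, donor_cn),
            (ev.recip_chrom, ev.recip_start, ev.recip_end, recip_cn),
        ):
            mask = (cn["chrom"] == chrom) & (cn["start"] >= s) & (cn["end"] <= e)
            cn.loc[mask, "cn"] = value
    return cn


def simulate_sample_depth(
    truth: TruthSet, config: SimConfig, sample: str, rng: np.random.Generator,
    exact: bool = False,
) -> DepthTrack:
    """Resequencing depth of one tetraploid sample over the reference."""
    cn = copy_number_windows(truth, config, sample)
    mean = config.sample_depth_mean * cn["cn"].to_numpy() / 2.0
    df = cn[["chrom", "start", "end"]].copy()
    df["depth"] = _noisy(rng, mean, config.overdispersion, exact=exact)
    return DepthTrack(df, sample=sample, reference="tetraploid")


def simulate_gene_depth(
    truth: TruthSet, config: SimConfig, sample: str, rng: np.random.Generator,
    exact: bool = False,
) -> pd.DataFrame:
    """Mean depth per gene copy for one sample (gene-level HE evidence).

    Window means cannot resolve sub-window conversions, so genic exchanges
    are scored from per-gene read depth, as a read-level pipeline would.
    """
    events = truth.hes
    rows = []
    for _, g in truth.genes.iterrows():
        cn = 2
        for _, ev in events.iterrows():
            if ev.cls == "balanced":
                continue
            carriers = [] if ev.samples == "" else str(ev.samples).split(",")
            if sample not in carriers:
                continue
            for chrom, s, e, value in (
                (ev.donor_chrom, ev.donor_start, ev.donor_end,
                 4 if ev.cls != "nonreciprocal" else 3),
                (ev.recip_chrom, ev.recip_start, ev.recip_end,
                 0 if ev.cls != "nonreciprocal" else 1),
            ):
                if g.chrom == chrom and g.start < e and s < g.end:
                    cn = value
        length = g.end - g.start
        expected = config.sample_depth_mean * cn / 2.0 * length
        total = expected if exact else rng.poisson(expected)
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "depth": total / length,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression channel


def simulate_expression(
    config: SimConfig,
    rng: np.random.Generator,
    gene_fates: Optional[pd.DataFrame] = None,
    n_pairs: Optional[int] = None,
) -> pd.DataFrame:
    """TPM table for homeologous gene pairs over replicates.

    Pair-level log2(A/B) ratios follow a two-component mixture: a broad
    balanced component centred at 0 and a minority component centred at
    ``expression_dominance_shift``.  Pseudogenized or deleted copies drop
    to near-zero TPM.
    """
    if gene_fates is not None and len(gene_fates):
        fates = gene_fates.set_index(["gene_id", "subgenome"])["fate"]
        # deleted copies have no gene model, so their pairs drop out
        base_ids = sorted(
            gid
            for gid in gene_fates["gene_id"].unique()
            if fates.get((gid, "A")) != "deleted"
            and fates.get((gid, "B")) != "deleted"
        )
    else:
        n = n_pairs if n_pairs is not None else config.gene_count
        base_ids = [f"g{i + 1:05d}" for i in range(n)]
        fates = None
    n = len(base_ids)
    minor = rng.random(n) < config.dominance_fraction
    ratios = np.where(
        minor,
        rng.normal(config.expression_dominance_shift, config.bias_sd_minor, n),
        rng.normal(0.0, config.bias_sd_main, n),
    )
    mu = rng.lognormal(mean=np.log(20.0), sigma=1.0, size=n)
    rows = []
    for rep in range(1, config.n_expression_replicates + 1):
        noise_a = rng.normal(0.0, 0.01, n)
        noise_b = rng.normal(0.0, 0.01, n)
        tpm_a = mu * np.power(2.0, ratios / 2.0 + noise_a)
        tpm_b = mu * np.power(2.0, -ratios / 2.0 + noise_b)
        for j, gid in enumerate(base_ids):
            ta, tb = float(tpm_a[j]), float(tpm_b[j])
            if fates is not None:
                if fates.get((gid, "A"), "intact") != "intact":
                    ta = float(rng.uniform(0.0, 0.2))
                if fates.get((gid, "B"), "intact") != "intact":
                    tb = float(rng.uniform(0.0, 0.2))
            rows.append(
                {
                    "gene_a": f"{gid}_A",
                    "gene_b": f"{gid}_B",
                    "replicate": rep,
                    "tpm_a": ta,
                    "tpm_b": tb,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimOutput:
    """Everything one simulation produced, in memory."""

    config: SimConfig
    truth: TruthSet
    ancestor: List[np.ndarray]
    genomes: Dict[str, Dict[str, np.ndarray]]
    gene_channel: GeneChannel
    expression: pd.DataFrame

    def sequence(self, role: str, chrom: str) -> str:
        return decode(self.genomes[role][chrom])


def simulate_all(config: SimConfig) -> SimOutput:
    """Run every simulator stage under one seeded generator."""
    rng = np.random.default_rng(config.seed)
    ancestor, genome_a, genome_b, divergence = simulate_progenitors(config, rng)
    genomes, mutations = plant_mutations(config, rng, genome_a, genome_b, divergence)
    gene_channel = simulate_gene_channel(config, rng)
    hes = plant_homeologous_exchanges(config, rng, gene_channel.genes)
    origins = window_origins(config, hes)
    truth = TruthSet(
        origins=origins,
        mutations=mutations,
        divergence_sites=divergence,
        hes=hes,
        genes=gene_channel.genes,
        gene_fates=gene_channel.gene_fates,
    )
    expression = simulate_expression(config, rng, gene_fates=gene_channel.gene_fates)
    return SimOutput(config, truth, ancestor, genomes, gene_channel, expression)


def emit_alignment_blocks(out: SimOutput) -> List[MultiAlignment]:
    """Four-way syntenic blocks tiling the A-coordinate space.

    Rows are ungapped (the chromosome channel plants no indels), so blocks
    are direct column-wise stacks of the four sequences over homeologous
    coordinates, cut at ``block_length``.
    """
    config = out.config
    a_names, b_names = config.chrom_names()
    blocks = []
    for i in range(config.n_chromosomes):
        a_chrom, b_chrom = a_names[i], b_names[i]
        L = config.chrom_length
        for s in range(0, L, config.block_length):
            e = min(s + config.block_length, L)
            rows = {
                TET_A: decode(out.genomes[TET_A][a_chrom][s:e]),
                TET_B: decode(out.genomes[TET_B][b_chrom][s:e]),
                DIP_1: decode(out.genomes[DIP_1][a_chrom][s:e]),
                DIP_2: decode(out.genomes[DIP_2][a_chrom][s:e]),
            }
            coords = {
                TET_A: RowCoords(a_chrom, s, "+"),
                TET_B: RowCoords(b_chrom, s, "+"),
                DIP_1: RowCoords(a_chrom, s, "+"),
                DIP_2: RowCoords(a_chrom, s, "+"),
            }
            blocks.append(MultiAlignment(f"blk_{a_chrom}_{s:08d}", rows, coords))
    return blocks


def apply_exchanges_to_sample(
    out: SimOutput, sample: str
) -> Dict[str, Dict[str, np.ndarray]]:
    """Sequence content of one sample's tetraploid after its exchanges.

    4:0 events paste donor homeolog content over the recipient interval;
    balanced events swap both intervals; nonreciprocal events overwrite the
    recipient with the (non-homeologous) donor content on one chromatid,
    returned here as the replaced copy.
    """
    seqs = {
        TET_A: {c: a.copy() for c, a in out.genomes[TET_A].items()},
        TET_B: {c: a.copy() for c, a in out.genomes[TET_B].items()},
    }

    def sub_of(chrom: str) -> str:
        return TET_A if chrom.startswith("A") else TET_B

    for _, ev in out.truth.hes.iterrows():
        carriers = [] if ev.samples == "" else str(ev.samples).split(",")
        if ev.cls != "balanced" and sample not in carriers:
            continue
        d_sub, r_sub = sub_of(ev.donor_chrom), sub_of(ev.recip_chrom)
        donor = seqs[d_sub][ev.donor_chrom][ev.donor_start : ev.donor_end].copy()
        if ev.cls == "balanced":
            recip = seqs[r_sub][ev.recip_chrom][ev.recip_start : ev.recip_end].copy()
            seqs[d_sub][ev.donor_chrom][ev.donor_start : ev.donor_end] = recip
            seqs[r_sub][ev.recip_chrom][ev.recip_start : ev.recip_end] = donor
        else:
            seqs[r_sub][ev.recip_chrom][ev.recip_start : ev.recip_end] = donor
    return seqs
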