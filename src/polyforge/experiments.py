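"""Self-contained recovery experiments on the bundled simulator.

These wrap full simulate-then-call round trips at stated problem sizes and
report summary numbers; they back the package's reproducibility checks.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .blocks import filter_intervals, segment_on_gaps
from .config import SimConfig
from .mutations import call_intervals, summarize_spectrum
from .seqcodes import DIP_1, TET_A
from .simulate import emit_alignment_blocks, simulate_all


def recover_spectrum(
    seed: int,
    n_chromosomes: int = 4,
    chrom_length: int = 5_000_000,
    config: Optional[SimConfig] = None,
) -> dict:
    """Plant mutations under the default six-type spectrum, call them with
    the 1:3 + flank rule, and summarize the recovered spectrum.

    Only A-subgenome-interpretable carriers (tetraploid A row and the first
    diploid) enter the summary: with no B-lineage diploid, B-carrier calls
    mix true mutations with progenitor-divergence sites.

    The default problem size (4 x 5 Mb chromosome pairs at the default
    per-bp rates) yields > 50,000 interpretable calls.
    """
    if config is None:
        config = SimConfig(
            seed=seed,
            n_chromosomes=n_chromosomes,
            chrom_length=chrom_length,
            gene_count=40,
            n_samples=2,
            n_segmental_he=0,
            n_balanced_he=0,
            n_nonreciprocal_he=0,
            n_genic_he=0,
        )
    sim = simulate_all(config)
    intervals = []
    for block in emit_alignment_blocks(sim):
        intervals.extend(segment_on_gaps(block))
    calls = call_intervals(filter_intervals(intervals))
    interp = [c for c in calls if c.carrier in (TET_A, DIP_1)]
    ts = sum(c.is_transition for c in interp)
    tv = len(interp) - ts
    ct = sum(c.class6 == "C>T" for c in interp)
    n = len(interp)
    summary_a = summarize_spectrum(calls, TET_A)
    summary_d = summarize_spectrum(calls, DIP_1)
    return {
        "n_calls": n,
        "tstv": ts / tv if tv else float("nan"),
        "gc_to_at_percent": 100.0 * ct / n if n else float("nan"),
        "tstv_tet_A": summary_a.tstv,
        "tstv_dip_1": summary_d.tstv,
        "n_planted": int(len(sim.truth.mutations)),
    }
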