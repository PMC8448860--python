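"""Simulation and pipeline configuration.

``SimConfig`` fixes the study conditions of the bundled allotetraploid
simulator: two progenitor lineages diverged to ~0.034 substitutions/site,
post-polyploidization point mutations at a 10% tetraploid excess under a
six-type spectrum (C>T class at 40% of mutations, Ts/Tv 1.8), telomere-
biased homeologous exchanges of the three dosage classes, asymmetric gene
loss between subgenomes, Poisson depth tracks, and homeolog expression with
a small dominance shift.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: six pyrimidine-centred substitution classes, canonical order
CLASSES6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

# Ts/Tv of 1.8 fixes the transition mass at 1.8/2.8; the C>T (G:C->A:T)
# class takes 0.40 of all mutations, T>C the remaining transition mass,
# and the four transversion classes share the rest equally.
_TS_FRACTION = 1.8 / 2.8
_DEFAULT_SPECTRUM = (
    (1.0 - _TS_FRACTION) / 4.0,  # C>A
    (1.0 - _TS_FRACTION) / 4.0,  # C>G
    0.40,                        # C>T
    (1.0 - _TS_FRACTION) / 4.0,  # T>A
    _TS_FRACTION - 0.40,         # T>C
    (1.0 - _TS_FRACTION) / 4.0,  # T>G
)


@dataclass
class SimConfig:
    """Parameters of the synthetic allotetraploid system.

    Lengths are in bp, rates in events per bp, depths in mean reads per
    window.  Defaults are the package's reference study conditions.
    """

    seed: int = 0

    # genome geometry: homeologous chromosome pairs A01/B01, A02/B02, ...
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000

    # progenitor divergence (substitutions/site between the A and B lineages)
    progenitor_divergence: float = 0.034

    # de novo mutation channel
    diploid_mutation_rate: float = 1.5e-3
    tetraploid_diploid_ratio: float = 1.10
    spectrum6: tuple = _DEFAULT_SPECTRUM
    context_modifiers: Optional[dict] = None
    min_mutation_spacing: int = 5
    enforce_spacing: bool = True

    # homeologous exchanges
    n_segmental_he: int = 4
    n_balanced_he: int = 1
    n_nonreciprocal_he: int = 1
    n_genic_he: int = 30
    n_bidirectional_genic: int = 2
    he_size_range: tuple = (15_000, 150_000)
    caller_min_size: int = 20_000
    telomere_bias: float = 0.6
    telomere_window: int = 2_000_000
    n_samples: int = 8
    he_sample_fraction: float = 0.5

    # gene channel
    gene_count: int = 2000
    gene_cds_length: int = 999
    pseudogene_fraction_A: float = 0.029
    deletion_fraction_A: float = 0.031
    pseudogene_fraction_B: float = 0.066
    deletion_fraction_B: float = 0.196

    # depth channel
    window_size: int = 5_000
    depth_mean: float = 28.0
    sample_depth_mean: float = 16.0
    background_depth_fraction: float = 0.0
    overdispersion: float = 0.0

    # expression channel
    expression_dominance_shift: float = 0.2
    dominance_fraction: float = 0.06
    bias_sd_main: float = 0.15
    bias_sd_minor: float = 0.015
    n_expression_replicates: int = 3

    # alignment-block emission
    block_length: int = 100_000

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("zero-length chromosomes")
        if abs(sum(self.spectrum6) - 1.0) > 1e-9 or min(self.spectrum6) < 0:
            raise ValueError("spectrum6 must be non-negative and sum to 1")
        if self.diploid_mutation_rate < 0 or self.tetraploid_diploid_ratio < 0:
            raise ValueError("rates must be non-negative")
        if self.progenitor_divergence < 0:
            raise ValueError("progenitor_divergence must be non-negative")
        if self.window_size <= 0:
            raise ValueError("window size must be positive")
        if self.gene_cds_length % 3:
            raise ValueError("gene_cds_length must be a codon multiple")
        lo, hi = self.he_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid he_size_range")

    @property
    def tetraploid_mutation_rate(self) -> float:
        return self.diploid_mutation_rate * self.tetraploid_diploid_ratio

    @property
    def effective_telomere_window(self) -> int:
        """Telomere window, shrunk proportionally on short chromosomes.

        Capped at 10% of the chromosome length per end so the two windows
        never dominate the chromosome at desk scale.
        """
        return min(self.telomere_window, self.chrom_length // 10)

    def chrom_names(self) -> tuple:
        a = tuple(f"A{i + 1:02d}" for i in range(self.n_chromosomes))
        b = tuple(f"B{i + 1:02d}" for i in range(self.n_chromosomes))
        return a, b

    def homeolog_of(self, chrom: str) -> str:
        return ("B" if chrom.startswith("A") else "A") + chrom[1:]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spectrum6"] = list(self.spectrum6)
        d["he_size_range"] = list(self.he_size_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "spectrum6" in d:
            d["spectrum6"] = tuple(d["spectrum6"])
        if "he_size_range" in d:
            d["he_size_range"] = tuple(d["he_size_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
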