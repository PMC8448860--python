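"""Simulator contracts: determinism, planted rates, exchanges, depth, truth."""

import numpy as np
import pandas as pd
import pytest

from polyforge.config import SimConfig
from polyforge.seqcodes import decode
from polyforge.simulate import (
    apply_exchanges_to_sample,
    emit_alignment_blocks,
    plant_mutations,
    simulate_all,
    simulate_expression,
    simulate_partition_depth,
    simulate_progenitors,
    simulate_sample_depth,
)
from polyforge.truth import TruthSet
from tests.conftest import small_config


class TestProgenitors:
    def test_zero_divergence_keeps_ancestor(self, rng):
        cfg = small_config(progenitor_divergence=0.0, chrom_length=50_000)
        anc, ga, gb, div = simulate_progenitors(cfg, rng)
        assert len(div) == 0
        assert np.array_equal(ga["A01"], anc[0])
        assert np.array_equal(gb["B01"], anc[0])

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            SimConfig(chrom_length=0)

    def test_divergence_level_matches_jukes_cantor_expectation(self, rng):
        cfg = small_config(n_chromosomes=1, chrom_length=1_000_000)
        _, ga, gb, _ = simulate_progenitors(cfg, rng)
        observed = float((ga["A01"] != gb["B01"]).mean())
        # planted substitutions may overwrite; expected observable
        # difference from d = 0.034 events/site under Jukes-Cantor:
        # p = (3/4)(1 - exp(-4d/3))
        d = cfg.progenitor_divergence
        expected = 0.75 * (1 - np.exp(-4 * d / 3))
        se = np.sqrt(expected * (1 - expected) / cfg.chrom_length)
        assert abs(observed - expected) < 3 * se + 1e-3

    def test_same_seed_byte_identical(self):
        cfg = small_config(chrom_length=200_000)
        a = simulate_all(cfg)
        b = simulate_all(cfg)
        assert decode(a.genomes["tet_A"]["A01"]) == decode(b.genomes["tet_A"]["A01"])
        pd.testing.assert_frame_equal(a.truth.mutations, b.truth.mutations)
        pd.testing.assert_frame_equal(a.truth.hes, b.truth.hes)
        pd.testing.assert_frame_equal(a.expression, b.expression)


class TestPlantMutations:
    def test_zero_rate_leaves_sequences(self, rng):
        cfg = small_config(diploid_mutation_rate=0.0, chrom_length=50_000)
        anc, ga, gb, div = simulate_progenitors(cfg, rng)
        genomes, muts = plant_mutations(cfg, rng, ga, gb, div)
        assert len(muts) == 0
        assert np.array_equal(genomes["tet_A"]["A01"], ga["A01"])

    def test_uniform_spectrum_recovered(self, rng):
        cfg = small_config(
            n_chromosomes=1,
            chrom_length=2_000_000,
            progenitor_divergence=0.0,
            diploid_mutation_rate=2.5e-3,
            tetraploid_diploid_ratio=1.0,
            spectrum6=(1 / 6,) * 6,
        )
        anc, ga, gb, div = simulate_progenitors(cfg, rng)
        _, muts = plant_mutations(cfg, rng, ga, gb, div)
        assert len(muts) > 10_000
        from polyforge.mutations import classify_mutation

        classes = [
            classify_mutation(r.ancestral, r.derived, "A", "A")[0]
            for r in muts.itertuples()
        ]
        counts = pd.Series(classes).value_counts()
        n = len(classes)
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for c in counts.index:
            assert abs(counts[c] / n - 1 / 6) < 3 * se

    def test_tetraploid_excess_ratio_recovered(self, rng):
        cfg = small_config(n_chromosomes=1, chrom_length=2_000_000,
                           diploid_mutation_rate=2e-3)
        anc, ga, gb, div = simulate_progenitors(cfg, rng)
        _, muts = plant_mutations(cfg, rng, ga, gb, div)
        n_tet = (muts["lineage"] == "tet_A").sum()
        n_dip = (muts["lineage"] == "dip_1").sum()
        lam = cfg.diploid_mutation_rate * cfg.chrom_length
        # both counts are Poisson; the ratio should sit near 1.10
        se_ratio = 1.10 * np.sqrt(2 / lam)
        assert abs(n_tet / n_dip - 1.10) < 3 * se_ratio

    def test_spacing_keeps_variants_apart(self, small_sim):
        truth = small_sim.truth
        for chrom_pair, grp in pd.concat(
            [truth.mutations, truth.divergence_sites]
        ).assign(pair=lambda d: d["chrom"].str[1:]).groupby("pair"):
            # planted de novo sites keep clear of every other variant site
            denovo = set(
                truth.mutations.loc[
                    truth.mutations["chrom"].str[1:] == chrom_pair, "pos"
                ]
            )
            all_pos = np.sort(grp["pos"].unique())
            idx = np.searchsorted(all_pos, sorted(denovo))
            for i, p in zip(idx, sorted(denovo)):
                if i > 0:
                    left = all_pos[i - 1]
                    if left != p:
                        assert p - left > 5
                if i + 1 < len(all_pos):
                    assert all_pos[i + 1] - p > 5

    def test_impossible_density_errors(self, rng):
        cfg = small_config(
            n_chromosomes=1, chrom_length=10_000, diploid_mutation_rate=0.2
        )
        anc, ga, gb, div = simulate_progenitors(cfg, rng)
        with pytest.raises(ValueError, match="unplaceable"):
            plant_mutations(cfg, rng, ga, gb, div)


class TestExchanges:
    def test_zero_events_leave_truth_empty(self):
        cfg = small_config(
            n_segmental_he=0, n_balanced_he=0, n_nonreciprocal_he=0, n_genic_he=0
        )
        sim = simulate_all(cfg)
        assert len(sim.truth.hes) == 0

    def test_full_bias_places_genic_events_in_telomere_window(self):
        cfg = small_config(telomere_bias=1.0, n_genic_he=12, seed=21)
        sim = simulate_all(cfg)
        W = cfg.effective_telomere_window
        genic = sim.truth.hes[sim.truth.hes["cls"] == "genic"]
        assert len(genic) > 0
        for ev in genic.itertuples():
            assert ev.donor_start < W or ev.donor_end > cfg.chrom_length - W

    def test_planted_4to0_gives_full_identity_in_carrier(self, small_sim):
        truth = small_sim.truth
        seg = truth.hes[truth.hes["cls"] == "segmental"].iloc[0]
        carrier = str(seg.samples).split(",")[0]
        seqs = apply_exchanges_to_sample(small_sim, carrier)
        donor_sub = "tet_A" if seg.donor_chrom.startswith("A") else "tet_B"
        recip_sub = "tet_A" if seg.recip_chrom.startswith("A") else "tet_B"
        donor = seqs[donor_sub][seg.donor_chrom][seg.donor_start : seg.donor_end]
        recip = seqs[recip_sub][seg.recip_chrom][seg.recip_start : seg.recip_end]
        assert np.array_equal(donor, recip)

    def test_size_controls_straddle_caller_minimum(self, small_sim):
        sizes = small_sim.truth.hes.query("cls == 'segmental'")["size"]
        assert (sizes >= small_sim.config.caller_min_size).any()
        assert (sizes < small_sim.config.caller_min_size).any()


class TestDepth:
    def test_normal_copy_number_mean(self, small_sim, rng):
        cfg = small_sim.config
        track = simulate_sample_depth(small_sim.truth, cfg, "S01", rng)
        cn2 = track.windows.merge(
            small_sim.truth.origins, on=["chrom", "start", "end"]
        )
        depths = cn2["depth"].to_numpy()
        # bulk of the genome is 2-of-4 copies: mean ~ sample_depth_mean
        assert abs(np.median(depths) - cfg.sample_depth_mean) <= 2

    def test_deleted_interval_draws_zero(self, small_sim, rng):
        cfg = small_sim.config
        truth = small_sim.truth
        seg = truth.hes.query("cls == 'segmental' and size >= 20000").iloc[0]
        carrier = str(seg.samples).split(",")[0]
        track = simulate_sample_depth(truth, cfg, carrier, rng)
        w = track.windows
        recip = w[
            (w["chrom"] == seg.recip_chrom)
            & (w["start"] >= seg.recip_start)
            & (w["end"] <= seg.recip_end)
        ]
        assert (recip["depth"] == 0).all()
        donor = w[
            (w["chrom"] == seg.donor_chrom)
            & (w["start"] >= seg.donor_start)
            & (w["end"] <= seg.donor_end)
        ]
        se = np.sqrt(2 * cfg.sample_depth_mean / len(donor))
        assert abs(donor["depth"].mean() - 2 * cfg.sample_depth_mean) < 4 * se

    def test_partition_track_covers_only_a_origin(self, small_sim, rng):
        track = simulate_partition_depth(small_sim.truth, small_sim.config, rng)
        joined = track.windows.merge(
            small_sim.truth.origins, on=["chrom", "start", "end"]
        )
        assert (joined.loc[joined["origin"] == "BB", "depth"] == 0).all()
        aa = joined.loc[joined["origin"] == "AA", "depth"]
        assert abs(aa.mean() - small_sim.config.depth_mean) < 1.0

    def test_bad_window_size_rejected(self):
        with pytest.raises(ValueError, match="window"):
            SimConfig(window_size=0)


class TestExpression:
    def test_no_shift_centers_at_zero(self, rng):
        cfg = small_config(dominance_fraction=0.0)
        df = simulate_expression(cfg, rng, n_pairs=4000)
        from polyforge.expression import summarize_bias

        s = summarize_bias(df)
        se = cfg.bias_sd_main / np.sqrt(4000)
        assert abs(s.mean) < 4 * se

    def test_deleted_b_copy_strongly_positive(self, rng):
        cfg = small_config()
        fates = pd.DataFrame(
            [
                {"gene_id": "g00001", "subgenome": "A", "fate": "intact"},
                {"gene_id": "g00001", "subgenome": "B", "fate": "intact"},
                {"gene_id": "g00002", "subgenome": "A", "fate": "intact"},
                {"gene_id": "g00002", "subgenome": "B", "fate": "pseudogene"},
            ]
        )
        df = simulate_expression(cfg, rng, gene_fates=fates)
        from polyforge.expression import log2_bias

        pseudo = df[df["gene_a"] == "g00002_A"]
        ratios = [log2_bias(r.tpm_a, r.tpm_b) for r in pseudo.itertuples()]
        assert np.mean(ratios) > 1.0


class TestTruthRoundTrip:
    def test_tsv_round_trip_preserves_tables(self, small_sim, tmp_path):
        small_sim.truth.to_dir(tmp_path / "truth")
        back = TruthSet.from_dir(tmp_path / "truth")
        for name in ("origins", "mutations", "divergence_sites", "hes",
                     "genes", "gene_fates"):
            pd.testing.assert_frame_equal(
                getattr(small_sim.truth, name).reset_index(drop=True),
                getattr(back, name),
                check_dtype=False,
            )


class TestAlignmentEmission:
    def test_blocks_tile_chromosomes(self, small_sim):
        blocks = emit_alignment_blocks(small_sim)
        cfg = small_sim.config
        expected = cfg.n_chromosomes * -(-cfg.chrom_length // cfg.block_length)
        assert len(blocks) == expected
        total = sum(len(b) for b in blocks if b.coords["tet_A"].chrom == "A01")
        assert total == cfg.chrom_length
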