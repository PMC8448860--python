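"""Homeologous-exchange callers: depth bands, islands, telomere enrichment."""

import numpy as np
import pandas as pd
import pytest

from polyforge.exchange import (
    HECall,
    SyntenyMap,
    call_balanced_he,
    call_genic_he,
    call_nonreciprocal,
    call_segmental_he,
    sharing_summary,
    telomere_enrichment,
)
from polyforge.partition import DepthTrack, OriginBlock, PartitionResult
from polyforge.stats import P_FLOOR


W = 5_000
CHROM_LEN = 2_000_000  # large relative to patches, so the genome mean is stable


def simple_map() -> SyntenyMap:
    segments = pd.DataFrame(
        {
            "chrom_a": ["A01", "A02"],
            "start_a": 0,
            "end_a": CHROM_LEN,
            "chrom_b": ["B01", "B02"],
            "start_b": 0,
            "end_b": CHROM_LEN,
            "orientation": "+",
        }
    )
    gene_pairs = pd.DataFrame(
        {
            "gene_a": ["g1_A"],
            "chrom_a": ["A01"],
            "start_a": [10_000],
            "end_a": [11_000],
            "gene_b": ["g1_B"],
            "chrom_b": ["B01"],
            "start_b": [10_000],
            "end_b": [11_000],
        }
    )
    return SyntenyMap(segments, gene_pairs)


def flat_track(ratio_patches=(), mean=16.0, sample="S01") -> DepthTrack:
    frames = []
    for chrom in ("A01", "B01", "A02", "B02"):
        starts = np.arange(0, CHROM_LEN, W)
        depth = np.full(starts.size, mean)
        for p_chrom, s, e, x in ratio_patches:
            if p_chrom == chrom:
                sel = (starts >= s) & (starts < e)
                depth[sel] = mean * x
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + W,
                 "depth": depth}
            )
        )
    return DepthTrack(pd.concat(frames, ignore_index=True), sample=sample)


class TestSyntenyMap:
    def test_forward_interval_mapping(self):
        m = simple_map()
        assert m.map_interval("A01", 100_000, 120_000) == ("B01", 100_000, 120_000)
        assert m.map_interval("B02", 0, 5_000) == ("A02", 0, 5_000)

    def test_unmapped_returns_none(self):
        assert simple_map().map_interval("C01", 0, 100) is None

    def test_inverted_segment_maps_from_far_end(self):
        seg = pd.DataFrame(
            {
                "chrom_a": ["A01"], "start_a": [0], "end_a": [1000],
                "chrom_b": ["B01"], "start_b": [0], "end_b": [1000],
                "orientation": ["-"],
            }
        )
        m = SyntenyMap(seg, pd.DataFrame())
        assert m.map_interval("A01", 0, 100) == ("B01", 900, 1000)

    def test_tsv_round_trip(self, tmp_path):
        m = simple_map()
        m.to_tsv(tmp_path / "seg.tsv", tmp_path / "genes.tsv")
        back = SyntenyMap.from_tsv(tmp_path / "seg.tsv", tmp_path / "genes.tsv")
        pd.testing.assert_frame_equal(m.segments, back.segments)


class TestSegmental:
    def test_flat_track_yields_no_calls(self):
        calls, unresolved = call_segmental_he(flat_track(), simple_map())
        assert calls == [] and unresolved == []

    def test_planted_duplication_deletion_pair_called(self):
        track = flat_track(
            [("A01", 100_000, 400_000, 2.0), ("B01", 100_000, 400_000, 0.1)]
        )
        calls, _ = call_segmental_he(track, simple_map())
        assert len(calls) == 1
        call = calls[0]
        assert call.cls == "segmental"
        assert (call.donor_chrom, call.recip_chrom) == ("A01", "B01")
        assert call.direction == "A_to_B"
        assert call.donor_start == 100_000 and call.donor_end == 400_000

    def test_below_min_size_rejected(self):
        track = flat_track(
            [("A01", 100_000, 115_000, 2.0), ("B01", 100_000, 115_000, 0.0)]
        )
        calls, _ = call_segmental_he(track, simple_map(), min_size=20_000)
        assert calls == []

    def test_ratio_above_band_not_a_candidate(self):
        track = flat_track(
            [("A01", 100_000, 400_000, 3.5), ("B01", 100_000, 400_000, 0.0)]
        )
        calls, _ = call_segmental_he(track, simple_map())
        assert calls == []

    def test_homeolog_not_deleted_rejected(self):
        track = flat_track([("A01", 100_000, 400_000, 2.0)])
        calls, _ = call_segmental_he(track, simple_map())
        assert calls == []

    def test_unmapped_candidate_reported_unresolved(self):
        seg = simple_map().segments.iloc[:0]
        m = SyntenyMap(seg, pd.DataFrame())
        track = flat_track([("A01", 100_000, 400_000, 2.0)])
        calls, unresolved = call_segmental_he(track, m)
        assert calls == []
        assert len(unresolved) == 1


class TestGenic:
    def _depths(self, ra, rb):
        return pd.DataFrame(
            {"gene_id": ["g1_A", "g1_B"], "ratio": [ra, rb]}
        )

    def test_duplicated_a_deleted_b(self):
        calls = call_genic_he(self._depths(2.0, 0.1), simple_map().gene_pairs,
                              sample="S01")
        assert len(calls) == 1
        assert calls[0].direction == "A_to_B"

    def test_balanced_pair_not_called(self):
        assert call_genic_he(self._depths(1.0, 1.0), simple_map().gene_pairs) == []

    def test_bidirectional_across_samples(self):
        c1 = call_genic_he(self._depths(2.0, 0.1), simple_map().gene_pairs,
                           sample="S01")
        c2 = call_genic_he(self._depths(0.1, 2.0), simple_map().gene_pairs,
                           sample="S02")
        summary = sharing_summary(c1 + c2)
        assert set(summary.events["direction"]) == {"A_to_B", "B_to_A"}
        assert len(summary.events) == 2  # one event per direction


class TestBalanced:
    def _partition(self, islands):
        blocks = []
        for chrom in ("A01", "B01"):
            base = "AA" if chrom.startswith("A") else "BB"
            flip = "BB" if base == "AA" else "AA"
            segs = [(0, 200_000, base)]
            for s, e in islands.get(chrom, []):
                segs.append((s, e, flip))
                segs.append((e, CHROM_LEN, base))
                segs[0] = (0, s, base)
            if len(segs) == 1:
                segs = [(0, CHROM_LEN, base)]
            for s, e, origin in segs:
                blocks.append(OriginBlock(chrom, s, e, origin, (e - s) // W))
        return PartitionResult(blocks, 28.0, 14.0)

    def test_reciprocal_islands_become_balanced_call(self):
        part = self._partition(
            {"A01": [(100_000, 180_000)], "B01": [(100_000, 180_000)]}
        )
        calls, one_sided = call_balanced_he(part, simple_map())
        assert len(calls) == 1
        assert calls[0].cls == "balanced"
        assert one_sided == []

    def test_no_islands_no_calls(self):
        part = self._partition({})
        calls, one_sided = call_balanced_he(part, simple_map())
        assert calls == [] and one_sided == []

    def test_island_without_partner_is_one_sided(self):
        part = self._partition({"A01": [(100_000, 180_000)]})
        calls, one_sided = call_balanced_he(part, simple_map())
        assert calls == []
        assert len(one_sided) == 1


class TestNonreciprocal:
    def test_three_to_one_dosage_called(self):
        track = flat_track(
            [("A01", 100_000, 200_000, 1.5), ("A02", 300_000, 400_000, 0.5)]
        )
        pairs = [(("A01", 100_000, 200_000), ("A02", 300_000, 400_000))]
        calls = call_nonreciprocal(track, pairs)
        assert len(calls) == 1
        assert calls[0].cls == "nonreciprocal"

    def test_flat_ratios_not_called(self):
        track = flat_track()
        pairs = [(("A01", 0, 100_000), ("A02", 0, 100_000))]
        assert call_nonreciprocal(track, pairs) == []

    def test_full_duplication_deletion_outside_bands(self):
        track = flat_track(
            [("A01", 100_000, 200_000, 2.0), ("A02", 300_000, 400_000, 0.0)]
        )
        pairs = [(("A01", 100_000, 200_000), ("A02", 300_000, 400_000))]
        assert call_nonreciprocal(track, pairs) == []


def _genic_call(chrom, start, end, sample="S01", recip=None):
    r_chrom, r_s, r_e = recip or (
        ("B" + chrom[1:]) if chrom.startswith("A") else ("A" + chrom[1:]),
        start, end,
    )
    return HECall("genic", sample, chrom, start, end, r_chrom, r_s, r_e, 2.0, 0.1)


class TestTelomereEnrichment:
    sizes = {"A01": CHROM_LEN, "B01": CHROM_LEN}

    def _genes(self, positions):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(positions))],
                "chrom": "A01",
                "start": positions,
                "end": [p + 1_000 for p in positions],
                "strand": "+",
            }
        )

    def test_paper_scale_counts_hit_floor(self):
        # expected proportion fed directly through the binomial
        from polyforge.stats import exact_binomial

        res = exact_binomial(314, 527, 0.117)
        assert res.p_value < P_FLOOR

    def test_all_calls_in_window_observed_equals_total(self):
        genes = self._genes(list(range(10_000, CHROM_LEN - 10_000, 24_000)))
        calls = [
            _genic_call("A01", 10_000, 11_000),
            _genic_call("A01", CHROM_LEN - 21_000, CHROM_LEN - 20_000),
        ]
        res = telomere_enrichment(calls, genes, self.sizes, window=50_000)
        assert res.observed == res.total == 2

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError, match="degenerate window"):
            telomere_enrichment([], self._genes([1000]), self.sizes,
                                window=CHROM_LEN)

    def test_uniform_null_is_calibrated(self, rng):
        """Uniform placement at the empirical proportion: significant calls
        at the 1e-3 level in at most a few of 200 simulated cohorts."""
        from polyforge.stats import exact_binomial

        p0 = 0.2
        hits = 0
        for _ in range(200):
            k = rng.binomial(60, p0)
            if exact_binomial(k, 60, p0).p_value < 1e-3:
                hits += 1
        assert hits <= 2


class TestSharing:
    def test_occurrence_counts(self):
        calls = [
            _genic_call("A01", 10_000, 11_000, sample=s) for s in ("S01", "S02", "S03")
        ]
        summary = sharing_summary(calls)
        assert len(summary.events) == 1
        assert summary.events.iloc[0]["n_samples"] == 3

    def test_equal_direction_totals_give_p_one(self):
        calls = [
            _genic_call("A01", 10_000, 11_000, sample="S01"),
            _genic_call("B01", 100_000, 101_000, sample="S01"),
        ]
        summary = sharing_summary(calls)
        assert summary.direction_test is not None
        assert summary.direction_test.p_value == pytest.approx(1.0)
        assert summary.test_construction_ambiguous

    def test_planted_catalog_recovered_exactly(self, small_sim, rng):
        from polyforge.pipeline import build_synteny_map
        from polyforge.simulate import sample_names, simulate_sample_depth

        cfg = small_sim.config
        synteny = build_synteny_map(cfg, small_sim.truth.genes)
        calls = []
        for s in sample_names(cfg):
            track = simulate_sample_depth(small_sim.truth, cfg, s, rng, exact=True)
            seg, _ = call_segmental_he(track, synteny, min_size=cfg.caller_min_size)
            calls.extend(seg)
        summary = sharing_summary(calls)
        truth_seg = small_sim.truth.hes.query(
            "cls == 'segmental' and size >= @cfg.caller_min_size"
        )
        assert len(summary.events) == len(truth_seg)
        truth_counts = sorted(
            len(str(s).split(",")) for s in truth_seg["samples"]
        )
        assert sorted(summary.events["n_samples"]) == truth_counts
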