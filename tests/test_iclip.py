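"""iCLIP chain: demultiplexing, crosslink conventions, dedup, clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import random_track
from oracles import cluster_family_bruteforce, paraclu_bruteforce
from protloc.iclip import (
    BarcodeScheme,
    CrosslinkTrack,
    assign_crosslinks,
    call_targets,
    dedup_umi,
    demultiplex,
    merge_tracks,
    metaprofile,
    paraclu,
    region_distribution,
    subtract_control,
)


def make_track(positions, values, chrom="chr1", strand="+"):
    return CrosslinkTrack(
        pd.DataFrame(
            {"chrom": chrom, "position": list(positions), "strand": strand,
             "count": list(values)}
        )
    )


class TestDemultiplex:
    def test_constructed_read(self, barcode_map):
        scheme = BarcodeScheme(barcode_map)
        insert = "ACGTACGTACGT"
        reads = [("r1", "ATA" + "GGCTA" + "ACGT" + insert)]
        demux, unassigned = demultiplex(reads, scheme)
        assert unassigned.empty
        row = demux["s1"].iloc[0]
        assert row["umi"] == "ATAACGT"
        assert row["insert"] == insert
        assert demux["s2"].empty

    def test_single_mismatch_is_unassigned(self, barcode_map):
        scheme = BarcodeScheme(barcode_map)
        reads = [("r1", "ATA" + "GGCTT" + "ACGT" + "ACGTACGT")]
        demux, unassigned = demultiplex(reads, scheme)
        assert len(unassigned) == 1
        assert unassigned.iloc[0]["reason"] == "unknown_barcode"

    def test_partition_invariant(self, barcode_map):
        scheme = BarcodeScheme(barcode_map)
        rng = np.random.default_rng(0)
        bases = "ACGT"
        reads = []
        for i in range(300):
            length = int(rng.integers(5, 40))
            reads.append((f"r{i}", "".join(rng.choice(list(bases), size=length))))
        demux, unassigned = demultiplex(reads, scheme)
        assert sum(len(df) for df in demux.values()) + len(unassigned) == len(reads)

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            BarcodeScheme({"GGCTA": "s1", "GGCT": "s2"})
        with pytest.raises(ValueError):
            BarcodeScheme({})


class TestAssignCrosslinks:
    def test_strand_conventions(self):
        aln = pd.DataFrame(
            {
                "read_id": ["r1", "r2"],
                "chrom": ["chr1", "chr1"],
                "start": [999, 2000],
                "end": [1029, 2050],
                "strand": ["+", "-"],
                "umi": ["AAAACCC", "AAAACCG"],
                "sample_id": ["s1", "s1"],
            }
        )
        events, dropped = assign_crosslinks(aln)
        assert dropped == 0
        assert events.loc[events["read_id"] == "r1", "position"].iloc[0] == 998
        assert events.loc[events["read_id"] == "r2", "position"].iloc[0] == 2050

    def test_boundary_events_dropped(self):
        aln = pd.DataFrame(
            {
                "read_id": ["r1", "r2"],
                "chrom": ["chr1", "chr1"],
                "start": [0, 70],
                "end": [30, 100],
                "strand": ["+", "-"],
                "umi": ["AAAACCC", "AAAACCG"],
                "sample_id": ["s1", "s1"],
            }
        )
        events, dropped = assign_crosslinks(aln, chrom_sizes={"chr1": 100})
        assert dropped == 2 and events.empty


class TestDedupAndMerge:
    def test_hand_enumeration(self):
        events = pd.DataFrame(
            {
                "chrom": "chr1",
                "position": [100, 100, 100, 101],
                "strand": "+",
                "umi": ["AAAACCC", "AAAACCC", "AAAACCG", "AAAACCC"],
            }
        )
        track = dedup_umi(events)
        counts = dict(zip(track.df["position"], track.df["count"]))
        assert counts == {100: 2, 101: 1}

    def test_permutation_invariance_and_no_duplicates(self):
        rng = np.random.default_rng(8)
        events = pd.DataFrame(
            {
                "chrom": "chr1",
                "position": rng.integers(0, 50, size=200),
                "strand": rng.choice(["+", "-"], size=200),
                "umi": [f"UMI{int(i):04d}" for i in rng.integers(0, 40, size=200)],
            }
        )
        t1 = dedup_umi(events)
        t2 = dedup_umi(events.sample(frac=1.0, random_state=1).reset_index(drop=True))
        pd.testing.assert_frame_equal(t1.df, t2.df)
        unique = dedup_umi(events.drop_duplicates(["chrom", "position", "strand", "umi"]))
        pd.testing.assert_frame_equal(t1.df, unique.df)

    def test_merge_identities(self):
        track = make_track([10, 20], [3, 4])
        empty = CrosslinkTrack(pd.DataFrame(columns=["chrom", "position", "strand", "count"]))
        doubled = merge_tracks([track, track])
        assert (doubled.df["count"] == 2 * track.df["count"]).all()
        assert doubled.library_size == 2 * track.library_size
        same = merge_tracks([track, empty])
        pd.testing.assert_frame_equal(same.df, track.df)


class TestParaclu:
    def test_two_site_cluster_with_distal_singleton(self):
        # root spans everything; the dense pair survives only in the
        # unresolved family; resolution keeps the root (infinite fold)
        track = make_track([10, 11, 50], [5, 5, 1])
        full = paraclu(track, resolve_overlaps=False)
        assert {(10, 12), (10, 51)} == set(zip(full["start"], full["end"]))
        flat = paraclu(track)
        assert len(flat) == 1
        row = flat.iloc[0]
        assert (row["start"], row["end"], row["sum"]) == (10, 51, 11.0)

    def test_single_position_track(self):
        track = make_track([100], [12])
        out = paraclu(track)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"], row["sum"]) == (100, 101, 12.0)
        assert math.isinf(row["fold"])

    def test_empty_track(self):
        empty = CrosslinkTrack(pd.DataFrame(columns=["chrom", "position", "strand", "count"]))
        assert paraclu(empty).empty

    def test_invalid_parameters(self):
        track = make_track([1], [5])
        with pytest.raises(ValueError):
            paraclu(track, min_sum=0)
        with pytest.raises(ValueError):
            paraclu(track, max_len=0)

    def test_family_equals_bruteforce_random_tracks(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            positions, values = random_track(rng)
            track = make_track(positions, values)
            fam = paraclu(track, min_sum=1e-9, max_len=10**9, min_density_increase=1e-9,
                          resolve_overlaps=False)
            got = sorted(
                zip(fam["start"], fam["end"], fam["sum"], fam["max_density"],
                    fam["min_density"])
            )
            expected = cluster_family_bruteforce(list(positions), list(values))
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                assert g[0] == e[0] and g[1] == e[1]
                assert g[2] == pytest.approx(e[2], abs=0)
                assert g[3] == pytest.approx(e[3], rel=1e-12)
                assert g[4] == pytest.approx(e[4], rel=1e-12)

    def test_reported_clusters_equal_bruteforce_at_default_parameters(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            positions, values = random_track(rng)
            track = make_track(positions, values)
            got = paraclu(track)
            expected = paraclu_bruteforce(list(positions), list(values))
            assert len(got) == len(expected)
            for row, e in zip(got.itertuples(index=False), expected):
                assert (row.start, row.end) == (e[0], e[1])
                assert row.sum == pytest.approx(e[2], abs=0)

    def test_dp_oracle_matches_literal_superset_enumeration(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            positions, values = random_track(rng, max_positions=10)
            dp = cluster_family_bruteforce(list(positions), list(values))
            literal = cluster_family_bruteforce(
                list(positions), list(values), literal_parents=True
            )
            assert dp == literal


class TestSubtractAndTargets:
    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])

    def test_subtract_disjoint_one_nt_and_postcondition(self):
        peaks = self._peaks([("chr1", 100, 120, "+"), ("chr1", 200, 220, "+"),
                             ("chr1", 300, 320, "-")])
        control = self._peaks([("chr1", 119, 140, "+"), ("chr1", 300, 320, "+")])
        specific, removed = subtract_control(peaks, control)
        assert removed == 1
        # 1-nt overlap removed; opposite-strand overlap kept
        assert set(zip(specific["start"], specific["strand"])) == {(200, "+"), (300, "-")}
        hits, _ = subtract_control(specific, control)
        pd.testing.assert_frame_equal(hits, specific)

    def test_targets_and_ambiguity(self, toy_annotation):
        peaks = self._peaks(
            [
                ("chrS", 1100, 1110, "+"),   # inside geneA ORF
                ("chrS", 5000, 5010, "+"),   # intergenic
                ("chrS", 3300, 3310, "-"),   # inside geneB ORF
            ]
        )
        targets, assign = call_targets(peaks, toy_annotation)
        assert set(targets["gene_id"]) == {"geneA", "geneB"}
        assert (targets["n_peaks"] == 1).all()
        assert (assign.loc[assign["peak_index"] == 1, "gene_id"] == "intergenic").all()

    def test_peak_spanning_two_genes_flags_both(self):
        from protloc.io import GenomeAnnotation

        regions = pd.DataFrame(
            [
                ("g1", "orf", "chr1", 100, 200, "+"),
                ("g2", "orf", "chr1", 150, 260, "+"),
            ],
            columns=["gene_id", "region_role", "chrom", "start", "end", "strand"],
        )
        annot = GenomeAnnotation(regions=regions)
        targets, assign = call_targets(
            self._peaks([("chr1", 160, 180, "+")]), annot
        )
        assert set(targets["gene_id"]) == {"g1", "g2"}
        assert assign["ambiguous"].all()


class TestRegionDistribution:
    def test_planted_regions_recovered(self, toy_annotation):
        peaks = pd.DataFrame(
            [
                ("chrS", 1001, 1006, "+"),   # midpoint 1003 -> TSS+3 -> 5'TOP
                ("chrS", 1040, 1046, "+"),   # midpoint 1043 -> 5'UTR
                ("chrS", 1200, 1210, "+"),   # ORF
                ("chrS", 1550, 1560, "+"),   # intron
                ("chrS", 1650, 1660, "+"),   # 3'UTR
                ("chrS", 3692, 3700, "-"),   # midpoint 3696, TSS 3699 -> 5'TOP
            ],
            columns=["chrom", "start", "end", "strand"],
        )
        fractions, per_peak = region_distribution(peaks, toy_annotation, top_window=15)
        assert fractions.sum() == pytest.approx(1.0)
        assert fractions["five_prime_top"] == pytest.approx(2 / 6)
        expected = ["five_prime_top", "five_prime_utr", "orf", "intron",
                    "three_prime_utr", "five_prime_top"]
        assert list(per_peak["category"]) == expected

    def test_fractions_sum_to_one_on_random_peaks(self, toy_annotation):
        rng = np.random.default_rng(3)
        starts = rng.integers(900, 4000, size=30)
        peaks = pd.DataFrame(
            {"chrom": "chrS", "start": starts, "end": starts + 8,
             "strand": rng.choice(["+", "-"], size=30)}
        )
        fractions, per_peak = region_distribution(peaks, toy_annotation)
        if (per_peak["category"] != "intergenic").any():
            assert fractions.sum() == pytest.approx(1.0)


class TestMetaprofile:
    def test_single_crosslink_at_landmark(self):
        track = make_track([500], [1])
        landmarks = pd.DataFrame(
            {"chrom": ["chr1"], "position": [500], "strand": ["+"]}
        )
        prof = metaprofile(track, landmarks, window=10)
        nonzero = prof[prof["value"] > 0]
        assert list(nonzero["offset"]) == [0]
        assert nonzero["value"].iloc[0] == pytest.approx(1e6 / track.library_size)

    def test_minus_strand_mirrors_offsets(self):
        track_plus = make_track([505], [3], strand="+")
        track_minus = make_track([495], [3], strand="-")
        lm_plus = pd.DataFrame({"chrom": ["chr1"], "position": [500], "strand": ["+"]})
        lm_minus = pd.DataFrame({"chrom": ["chr1"], "position": [500], "strand": ["-"]})
        p1 = metaprofile(track_plus, lm_plus, window=10)
        p2 = metaprofile(track_minus, lm_minus, window=10)
        np.testing.assert_allclose(p1["value"], p2["value"])
        assert p1.loc[p1["value"] > 0, "offset"].iloc[0] == 5

    def test_uniform_background_is_flat(self):
        rng = np.random.default_rng(9)
        positions = np.arange(0, 2000)
        values = rng.poisson(5.0, size=2000) + 1
        track = make_track(positions, values)
        landmarks = pd.DataFrame(
            {"chrom": "chr1", "position": rng.integers(100, 1900, size=40), "strand": "+"}
        )
        prof = metaprofile(track, landmarks, window=25)
        rel_spread = prof["value"].std() / prof["value"].mean()
        assert rel_spread < 0.15
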