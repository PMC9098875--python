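"""Motif scanning, co-occurrence, spacing and k-mer discovery."""

import numpy as np
import pandas as pd
import pytest

import condenseq as cq
from condenseq.align import reverse_complement
from condenseq.motifs import (
    Motif,
    background_composition,
    class_mean_frequency,
    distance_medians,
)
from .conftest import random_seq

UNIFORM_BG = np.full(4, 0.25)


class TestMotif:
    def test_from_consensus(self):
        m = Motif.from_consensus("m", "ACGT")
        assert m.width == 4
        assert m.consensus == "ACGT"
        assert m.matrix[:, 0].tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_tie_break_alphabetical(self):
        m = Motif("m", np.full((4, 4), 0.25))
        assert m.consensus == "AAAA"

    def test_column_sum_validated(self):
        bad = np.full((4, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            Motif("m", bad)

    @pytest.mark.parametrize("width", [3, 101])
    def test_width_validated(self, width):
        with pytest.raises(ValueError, match="width"):
            Motif("m", np.full((4, width), 0.25))

    def test_invalid_consensus_alphabet(self):
        with pytest.raises(ValueError, match="alphabet"):
            Motif.from_consensus("m", "ACGU")

    def test_log_odds_max_at_consensus(self):
        m = Motif.from_consensus("m", "ACGTAC")
        lo = m.log_odds(UNIFORM_BG)
        assert np.argmax(lo[:4, 0]) == 0  # A column
        assert (lo[4] <= lo[:4].min(axis=0) + 1e-12).all()  # N never better


def test_background_composition():
    bg = background_composition(["AACC", "GGTT"])
    assert bg == pytest.approx([0.25, 0.25, 0.25, 0.25])
    bg = background_composition(["AAAA"])
    assert bg[0] == 1.0


class TestScan:
    def test_forward_hit_coordinates(self):
        hits = cq.scan({"t": "TTACGTTT"}, [Motif.from_consensus("m", "ACGT")],
                       background=UNIFORM_BG)
        fwd = hits[hits.strand == "+"]
        assert len(fwd) == 1
        row = fwd.iloc[0]
        assert (row.start, row.end, row.motif_id) == (2, 6, "m")

    def test_reverse_strand_in_transcript_coordinates(self):
        # revcomp(AAGGG)=CCCTT occurs at position 1 of the transcript
        hits = cq.scan({"t": "TCCCTTAA"}, [Motif.from_consensus("m", "AAGGG")],
                       background=UNIFORM_BG)
        assert len(hits) == 1
        row = hits.iloc[0]
        assert (row.strand, row.start, row.end) == ("-", 1, 6)

    def test_exact_threshold_excludes_mismatch(self):
        m = Motif.from_consensus("m", "ACGTACGT")
        hits = cq.scan({"t": "TTACGTTCGTTT"}, [m], threshold_frac=1.0,
                       background=UNIFORM_BG)
        assert hits.empty

    def test_short_transcript_no_error(self):
        hits = cq.scan({"t": "ACG"}, [Motif.from_consensus("m", "ACGTACGT")],
                       background=UNIFORM_BG)
        assert hits.empty

    def test_revcomp_scan_mirrors_coordinates(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 200)
        motif = Motif.from_consensus("m", "GATTACAGGC")
        h_fwd = cq.scan({"t": seq}, [motif], threshold_frac=0.8,
                        background=UNIFORM_BG)
        h_rev = cq.scan({"t": reverse_complement(seq)}, [motif],
                        threshold_frac=0.8, background=UNIFORM_BG)
        mapped = sorted(
            (200 - r.end, 200 - r.start, "+-"[r.strand == "+"])
            for r in h_rev.itertuples()
        )
        direct = sorted((r.start, r.end, r.strand) for r in h_fwd.itertuples())
        assert mapped == direct

    def test_overlap_resolution_keeps_best(self):
        # AAAAAA occurs at 0..5 and 1..6 etc; overlaps collapse to one hit
        hits = cq.scan({"t": "AAAAAAAA"}, [Motif.from_consensus("m", "AAAAAA")],
                       background=UNIFORM_BG)
        fwd = hits[hits.strand == "+"]
        assert len(fwd) == 1
        assert fwd.iloc[0].start == 0  # ties broken leftmost

    def test_threshold_validated(self):
        with pytest.raises(ValueError, match="threshold_frac"):
            cq.scan({"t": "ACGT"}, [Motif.from_consensus("m", "ACGT")],
                    threshold_frac=0.0)


class TestCisCooccurrence:
    def build_hits(self):
        return pd.DataFrame(
            {
                "transcript_id": ["t1", "t1", "t2", "t3"],
                "start": [10, 80, 5, 7],
                "end": [22, 92, 17, 19],
                "strand": ["+"] * 4,
                "motif_id": ["m1", "m2", "m1", "m2"],
                "score": [10.0] * 4,
            }
        )

    def test_classification(self):
        out = cq.cis_cooccurrence(self.build_hits(), "m1", "m2",
                                  ["t1", "t2", "t3", "t4"])
        assert dict(zip(out.transcript_id, out["class"])) == {
            "t1": "both", "t2": "a-only", "t3": "b-only", "t4": "none",
        }

    def test_unknown_motif_rejected(self):
        with pytest.raises(KeyError, match="unknown motif"):
            cq.cis_cooccurrence(self.build_hits(), "m1", "m9", ["t1"])

    def test_no_hits_all_none(self):
        out = cq.cis_cooccurrence(self.build_hits().iloc[:0], "m1", "m2",
                                  ["t1", "t2"])
        assert (out["class"] == "none").all()

    def test_planted_pairs_detected_more_frequently(self, small_pool, small_matrix):
        """Transcripts carrying both planted motifs are detected more often
        than single-motif or motif-free transcripts."""
        seqs = dict(zip(small_pool.transcript_ids, small_pool.sequences))
        motifs = [Motif.from_consensus("motif_1", small_pool.motif_pair[0]),
                  Motif.from_consensus("motif_2", small_pool.motif_pair[1])]
        hits = cq.scan(seqs, motifs)
        freq = cq.detection_frequency(small_matrix)["detect_freq"]
        coocc = cq.cis_cooccurrence(hits, "motif_1", "motif_2",
                                    small_pool.transcript_ids, freq)
        means = class_mean_frequency(coocc)
        assert means["both"] > means.get("none", 0.0)
        for single in ("a-only", "b-only"):
            if single in means:
                assert means["both"] > means[single]


class TestNeighborDistances:
    def test_arithmetic(self):
        hits = pd.DataFrame(
            {
                "transcript_id": ["t"] * 3,
                "start": [10, 80, 150],
                "end": [20, 90, 160],
                "strand": ["+"] * 3,
                "motif_id": ["a", "b", "a"],
                "score": [1.0] * 3,
            }
        )
        out = cq.neighbor_distances(hits)
        assert sorted(out["distance"]) == [70, 70]
        assert out["distance"].median() == 70

    def test_single_hit_contributes_nothing(self):
        hits = pd.DataFrame(
            {"transcript_id": ["t"], "start": [5], "end": [10],
             "strand": ["+"], "motif_id": ["a"], "score": [1.0]}
        )
        assert cq.neighbor_distances(hits).empty

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        hits = pd.DataFrame(
            {
                "transcript_id": rng.choice(["t1", "t2"], 12),
                "start": rng.integers(0, 500, 12),
                "end": 0,
                "strand": "+",
                "motif_id": rng.choice(["a", "b"], 12),
                "score": 1.0,
            }
        )
        hits["end"] = hits["start"] + 8
        a = cq.neighbor_distances(hits).sort_values(
            ["transcript_id", "motif_id", "distance"]).reset_index(drop=True)
        b = cq.neighbor_distances(hits.sample(frac=1, random_state=0)).sort_values(
            ["transcript_id", "motif_id", "distance"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_spacing_recovered(self, small_pool):
        """The planted 70-nt start-to-start spacing appears as an exact
        median of 70 for the motif pair."""
        seqs = {t: s for t, s, e in zip(small_pool.transcript_ids,
                                        small_pool.sequences,
                                        small_pool.truth_enriched) if e}
        motifs = [Motif.from_consensus("motif_1", small_pool.motif_pair[0]),
                  Motif.from_consensus("motif_2", small_pool.motif_pair[1])]
        hits = cq.scan(seqs, motifs)
        med = distance_medians(cq.neighbor_distances(hits))
        assert med.loc[("motif_2", "motif_1")] == 70.0


class TestDiscoverKmers:
    def test_planted_kmer_recovered(self):
        rng = np.random.default_rng(3)
        planted = "GATTACACGGTT"
        enr = [random_seq(rng, 100) + planted + random_seq(rng, 120)
               for _ in range(50)]
        bg = [random_seq(rng, 232) for _ in range(48)] + [
            random_seq(rng, 100) + planted + random_seq(rng, 120) for _ in range(2)
        ]
        df = cq.discover_kmers(enr, bg, k=8)
        assert len(df) > 0
        top = df.iloc[0]["kmer"]
        assert planted in top or reverse_complement(planted) in top

    def test_identical_pools_yield_nothing(self):
        rng = np.random.default_rng(4)
        pool = [random_seq(rng, 300) for _ in range(30)]
        assert cq.discover_kmers(pool, list(pool), k=8).empty

    def test_validation(self):
        with pytest.raises(ValueError, match="k must"):
            cq.discover_kmers(["ACGTACGTACGTACGT"], ["ACGTACGTACGTACGT"], k=13)
        with pytest.raises(ValueError, match="non-empty"):
            cq.discover_kmers(["ACGTACGT"], [], k=4)
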