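"""Synthetic pool generation and condensate simulation."""

import numpy as np
import pytest
from scipy.stats import norm, spearmanr

import condenseq as cq
from condenseq.align import reverse_complement


class TestGeneratePool:
    def test_planted_pair_contract(self):
        m1 = "ACGTACGTACGT"
        pool = cq.generate_pool(100, (m1, reverse_complement(m1)),
                                frac_enriched=0.1, spacing=70, seed=1)
        assert int(pool.truth_enriched.sum()) == 10
        pool.validate()
        for tid, occs in pool.planted_motifs.items():
            (n1, s1, _), (n2, s2, _) = occs
            assert (n1, n2) == ("motif_1", "motif_2")
            assert s2 - s1 == 70
            seq = pool.sequences[pool.transcript_ids.index(tid)]
            assert seq[s1:s1 + 12] == m1
            assert seq[s2:s2 + 12] == reverse_complement(m1)

    def test_zero_fraction_plants_nothing(self):
        pool = cq.generate_pool(50, frac_enriched=0.0, seed=2)
        assert not pool.truth_enriched.any()
        assert pool.planted_motifs == {}

    def test_deterministic_given_seed(self):
        a = cq.generate_pool(60, seed=7)
        b = cq.generate_pool(60, seed=7)
        assert a.sequences == b.sequences
        assert np.array_equal(a.input_tpm, b.input_tpm)
        c = cq.generate_pool(60, seed=8)
        assert a.sequences != c.sequences

    def test_tpm_sums_to_million(self):
        pool = cq.generate_pool(200, seed=3)
        assert pool.input_tpm.sum() == pytest.approx(1e6, rel=1e-9)

    def test_lengths_floor(self):
        pool = cq.generate_pool(500, seed=4)
        assert pool.lengths.min() >= 200

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_transcripts=5), "n_transcripts"),
            (dict(frac_enriched=0.6), "frac_enriched"),
            (dict(motif_pair=("ACGT", "ACGT")), "length"),
            (dict(motif_pair=("ACGUACGU", "ACGTACGT")), "alphabet"),
            (dict(spacing=190, motif_pair=("A" * 20, "T" * 20)), "exceeds"),
            (dict(spacing=10, motif_pair=("A" * 20, "T" * 20)), "overlap"),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            cq.generate_pool(**{"n_transcripts": 100, "seed": 0, **kwargs})


class TestSimulateCondensates:
    def test_counts_conserve_depth_and_are_integer(self, small_pool):
        adata = cq.simulate_condensates(small_pool, n_condensates=24, seed=5)
        assert np.issubdtype(adata.X.dtype, np.integer)
        # column sums are exactly the drawn Poisson depths: re-draw them
        rng = np.random.default_rng(5)
        fsc = rng.lognormal(np.log(1e4), 0.35, 24)
        rng.lognormal(-0.7, 0.2, 24)  # ssc stream
        model = cq.UptakeModel()
        depths = rng.poisson(model.depth_scale * fsc**model.capacity_exponent)
        assert np.array_equal(adata.X.sum(axis=1), depths)

    def test_deterministic_given_seed(self, small_pool):
        a = cq.simulate_condensates(small_pool, n_condensates=12, seed=9)
        b = cq.simulate_condensates(small_pool, n_condensates=12, seed=9)
        assert np.array_equal(a.X, b.X)
        assert a.obs.equals(b.obs)

    def test_full_ambient_follows_input_proportions(self, small_pool):
        model = cq.UptakeModel(ambient_fraction=1.0, beta_motif=5.0)
        adata = cq.simulate_condensates(small_pool, model, 30, seed=6)
        total = adata.X.sum(axis=0).astype(float)
        expected = small_pool.input_tpm / 1e6 * total.sum()
        # motif content must not matter: aggregated counts track input TPM
        big = expected > 50
        ratio = total[big] / expected[big]
        assert np.corrcoef(total, expected)[0, 1] > 0.99
        assert abs(np.median(ratio) - 1.0) < 0.2

    def test_motif_boost_off_is_abundance_neutral(self):
        """With beta_motif=0 planted transcripts behave like abundance-matched
        controls (pooled two-proportion test)."""
        pool = cq.generate_pool(seed=11)
        model = cq.UptakeModel(beta_motif=0.0)
        adata = cq.simulate_condensates(pool, model, 192, seed=11)
        adata = cq.add_tpm(adata)
        det = np.asarray(adata.layers["tpm"]) >= 1.0
        truth = pool.truth_enriched
        log_tpm = np.log(pool.input_tpm)
        used: list[int] = []
        for i in np.nonzero(truth)[0]:
            penal = np.where(truth, np.inf, 0.0)
            penal[used] = np.inf
            j = int(np.argmin(np.abs(log_tpm - log_tpm[i]) + penal))
            used.append(j)
        x1, n1 = det[:, truth].sum(), det.shape[0] * truth.sum()
        x2, n2 = det[:, used].sum(), det.shape[0] * len(used)
        p = (x1 + x2) / (n1 + n2)
        z = (x1 / n1 - x2 / n2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert 2 * norm.sf(abs(z)) > 0.01

    def test_detection_monotone_in_beta_motif(self):
        """Mean planted detection frequency rises with the motif boost."""
        means = []
        for bm in (0.0, 1.0, 2.0):
            fr = []
            for s in range(20):
                pool = cq.generate_pool(300, seed=50 + s)
                adata = cq.simulate_condensates(
                    pool, cq.UptakeModel(beta_motif=bm), 48, seed=50 + s
                )
                adata = cq.add_tpm(adata)
                det = np.asarray(adata.layers["tpm"]) >= 1.0
                fr.append(det[:, pool.truth_enriched].mean())
            means.append(np.mean(fr))
        assert means[0] < means[1] < means[2]

    def test_size_diversity_correlation(self, small_matrix):
        det = (np.asarray(small_matrix.layers["tpm"]) >= 1.0).sum(axis=1)
        rho = spearmanr(small_matrix.obs["fsc"], det).statistic
        assert rho > 0

    def test_all_zero_weights_rejected(self, small_pool):
        import copy

        broken = copy.deepcopy(small_pool)
        broken.input_tpm = np.zeros(len(broken))
        with pytest.raises(ValueError, match="all-zero"):
            cq.simulate_condensates(broken, n_condensates=4, seed=0)

    def test_type_offsets_shift_composition(self, small_pool):
        offsets = np.zeros(len(small_pool))
        offsets[:30] = 3.0
        model = cq.UptakeModel(beta_motif=0.0, type_weights={"B": offsets})
        a = cq.simulate_condensates(small_pool, model, 40, types=("A", "B"), seed=3)
        is_b = (a.obs["condensate_type"] == "B").to_numpy()
        share_b = a.X[is_b][:, :30].sum() / a.X[is_b].sum()
        share_a = a.X[~is_b][:, :30].sum() / a.X[~is_b].sum()
        assert share_b > 2 * share_a


class TestWriteFixture:
    def test_round_trip(self, small_pool, tmp_path):
        from condenseq import io as cio

        adata = cq.simulate_condensates(small_pool, n_condensates=16, seed=1)
        cq.write_fixture(small_pool, adata, tmp_path)
        for path in ("counts.tsv", "mtx"):
            back = cio.read_count_matrix(tmp_path / path)
            assert np.array_equal(np.asarray(back.X), adata.X)
            assert list(back.obs_names) == list(adata.obs_names)
        fasta = cio.read_fasta(tmp_path / "transcripts.fasta")
        assert list(fasta.values()) == small_pool.sequences

    def test_manifest_regeneration_byte_identical(self, small_pool, tmp_path):
        from condenseq import io as cio
        from condenseq.simulate import simulate_from_manifest

        adata = cq.simulate_condensates(small_pool, n_condensates=8, seed=2)
        cq.write_fixture(small_pool, adata, tmp_path / "one")
        manifest = cio.read_manifest(tmp_path / "one" / "manifest.yaml")
        pool2, adata2 = simulate_from_manifest(manifest)
        cq.write_fixture(pool2, adata2, tmp_path / "two")
        for name in ("transcripts.fasta", "counts.tsv", "metadata.csv",
                     "truth.tsv", "manifest.yaml"):
            assert (tmp_path / "one" / name).read_bytes() == \
                (tmp_path / "two" / name).read_bytes(), name

    def test_empty_pool_rejected(self, tmp_path):
        import dataclasses

        pool = cq.generate_pool(20, seed=0)
        empty = dataclasses.replace(
            pool, transcript_ids=[], sequences=[],
            input_tpm=np.empty(0), truth_enriched=np.empty(0, bool),
            planted_motifs={},
        )
        adata = cq.simulate_condensates(pool, n_condensates=4, seed=0)
        out = tmp_path / "nothing"
        with pytest.raises(ValueError, match="empty"):
            cq.write_fixture(empty, adata, out)
        assert not (out / "transcripts.fasta").exists()


def test_uptake_model_validation():
    with pytest.raises(ValueError, match="ambient_fraction"):
        cq.UptakeModel(ambient_fraction=1.5)
    with pytest.raises(ValueError, match="depth_scale"):
        cq.UptakeModel(depth_scale=0.0)


def test_uptake_weights_neutral_without_motif_term(small_pool):
    """With beta_motif=0 and no type offsets, weights depend only on
    abundance and length."""
    model = cq.UptakeModel(beta_motif=0.0)
    w = model.weights(small_pool, "any")
    expected = small_pool.input_tpm * small_pool.lengths**0.3
    expected = expected / expected.sum()
    assert np.allclose(w, expected)
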