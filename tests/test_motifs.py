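import numpy as np
import pytest

from g4net import (
    PFM,
    PWM,
    ModelSpec,
    best_hit_subsequences,
    build_pfm,
    cluster_motifs,
    kernel_activations,
    motif_similarity,
    pfm_to_pwm,
    read_motifs,
    trim_pfm,
    write_motifs,
)
from g4net.io import encode_batch
from g4net.model import TrainedModel, build_model
from g4net.motifs import extract_motifs, information_content


def random_pfm(rng, width, n_hits=50, peaked=False):
    if peaked:
        alpha = np.full(4, 0.1)
    else:
        alpha = np.ones(4)
    matrix = rng.dirichlet(alpha, size=width)
    return PFM(matrix, n_hits=n_hits)


def handmade_model(kernel, input_length=60, bias=0.0):
    """TrainedModel wrapping a single hand-set kernel, for activation tests."""
    k = kernel.shape[0]
    spec = ModelSpec(n_kernels=1, kernel_size=k, pool_size=2,
                     dense_units=2, input_length=input_length, epochs=1)
    net = build_model(spec, seed=0)
    net.params["Wc"] = kernel.reshape(k * 4, 1).astype(np.float32)
    net.params["bc"] = np.array([bias], dtype=np.float32)
    return TrainedModel(spec=spec, net=net, training_history=[{"epoch": 0}])


class TestKernelActivations:
    def test_untrained_model_rejected(self):
        spec = ModelSpec(n_kernels=1, kernel_size=4, pool_size=2,
                         dense_units=2, input_length=20)
        model = TrainedModel(spec=spec, net=build_model(spec, seed=0))
        with pytest.raises(ValueError):
            kernel_activations(model, np.zeros((1, 20, 4), dtype=np.float32))

    def test_all_n_sequence_gives_rectified_bias_everywhere(self):
        kernel = np.zeros((4, 4))
        model = handmade_model(kernel, input_length=20, bias=0.5)
        X = np.zeros((1, 20, 4), dtype=np.float32)  # all-N one-hot
        acts = kernel_activations(model, X)
        assert np.allclose(acts, 0.5)
        model_neg = handmade_model(kernel, input_length=20, bias=-0.5)
        assert np.allclose(kernel_activations(model_neg, X), 0.0)

    def test_hand_built_gggg_kernel_peaks_on_planted_motif(self):
        kernel = np.zeros((4, 4))
        kernel[:, 2] = 1.0  # reward G at all four positions
        model = handmade_model(kernel, input_length=40)
        seq = "ACGTACGTACGTGGGGACGTACGTACGTACGTACGTACGT"
        acts = kernel_activations(model, encode_batch([seq]))
        assert int(np.argmax(acts[0, :, 0])) == seq.index("GGGG")

    def test_activations_are_non_negative(self, small_model, small_dataset):
        dataset, _ = small_dataset
        X = encode_batch([e.sequence for e in dataset.examples[:10]])
        assert np.all(kernel_activations(small_model, X) >= 0)


class TestBestHitSubsequences:
    def test_inactive_sequences_contribute_nothing(self):
        acts = np.zeros((2, 5, 1))
        acts[1, 2, 0] = 1.0
        hits = best_hit_subsequences(acts, ["ACGTACGT", "ACGTACGT"], 0, kernel_size=4)
        assert hits == ["GTAC"]

    def test_tie_takes_leftmost_position(self):
        acts = np.zeros((1, 5, 1))
        acts[0, [1, 3], 0] = 2.0
        (hit,) = best_hit_subsequences(acts, ["AACCGGTT"], 0, kernel_size=4)
        assert hit == "ACCG"

    def test_planted_core_recovered_from_every_sequence(self, rng):
        kernel = np.zeros((4, 4))
        kernel[:, 2] = 1.0
        model = handmade_model(kernel, input_length=40)
        seqs = []
        for _ in range(100):
            pos = int(rng.integers(0, 36))
            background = "".join(rng.choice(list("ACT"), size=40))
            seqs.append(background[:pos] + "GGGG" + background[pos + 4:])
        acts = kernel_activations(model, encode_batch(seqs))
        hits = best_hit_subsequences(acts, seqs, 0, kernel_size=4)
        assert len(hits) == 100
        assert all(h == "GGGG" for h in hits)


class TestBuildPFM:
    def test_two_sequence_frequencies(self):
        pfm = build_pfm(["AC", "AG"])
        assert np.allclose(pfm.matrix[0], [1, 0, 0, 0])
        assert np.allclose(pfm.matrix[1], [0, 0.5, 0.5, 0])

    def test_single_subsequence_is_one_hot(self):
        pfm = build_pfm(["GATC"])
        assert np.array_equal(pfm.matrix.max(axis=1), np.ones(4))

    def test_uniform_random_subsequences_near_uniform(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(1000)]
        pfm = build_pfm(seqs)
        assert np.all(np.abs(pfm.matrix - 0.25) <= 0.05)

    def test_ambiguous_bases_excluded_from_column(self):
        pfm = build_pfm(["AN", "AC"])
        assert np.allclose(pfm.matrix[1], [0, 1, 0, 0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_pfm([])


class TestTrimPFM:
    def test_closed_form_column_ic(self):
        assert information_content(np.full(4, 0.25)) == pytest.approx(0.0)
        assert information_content(np.array([1.0, 0, 0, 0])) == pytest.approx(2.0)

    def test_flanks_trimmed_core_survives(self):
        flank = np.full((2, 4), 0.25)
        core = np.tile([0.9, 0.05, 0.03, 0.02], (6, 1))
        pfm = PFM(np.vstack([flank, core, flank]), n_hits=10)
        trimmed = trim_pfm(pfm)
        assert trimmed.width == 6
        assert np.allclose(trimmed.matrix, core)

    def test_over_trimmed_motifs_rejected(self):
        pfm = PFM(np.full((8, 4), 0.25), n_hits=10)
        assert trim_pfm(pfm) is None

    def test_interior_columns_never_removed(self):
        # low-IC column sandwiched between high-IC columns stays
        high = [0.97, 0.01, 0.01, 0.01]
        matrix = np.array([high, [0.25] * 4, high, [0.25] * 4, high,
                           high, high])
        trimmed = trim_pfm(PFM(matrix, n_hits=5), min_width=5)
        assert trimmed.width == 7

    def test_matches_two_pointer_oracle_on_random_pfms(self, rng):
        """Flank trimming equals an independent scan-from-both-ends oracle."""
        for _ in range(1000):
            width = int(rng.integers(1, 15))
            pfm = random_pfm(rng, width, peaked=bool(rng.integers(0, 2)))
            ic = [
                2.0 + sum(p * np.log2(p) for p in col if p > 0)
                for col in pfm.matrix
            ]
            keep = [i for i, v in enumerate(ic) if v > 0.9]
            if not keep or max(keep) - min(keep) + 1 < 5:
                oracle = None
            else:
                lo = min(i for i, v in enumerate(ic) if v > 0.9)
                hi = max(i for i, v in enumerate(ic) if v > 0.9) + 1
                oracle = pfm.matrix[lo:hi]
            got = trim_pfm(pfm)
            if oracle is None:
                assert got is None
            else:
                assert got is not None and np.allclose(got.matrix, oracle)


class TestPFMToPWM:
    def test_uniform_frequencies_give_zero_weights(self):
        pfm = PFM(np.full((4, 4), 0.25), n_hits=10)
        assert np.allclose(pfm_to_pwm(pfm, pseudocount=0).matrix, 0.0)

    def test_certain_base_gives_two_bits(self):
        pfm = PFM(np.tile([1.0, 0, 0, 0], (3, 1)), n_hits=10)
        pwm = pfm_to_pwm(pfm, pseudocount=0)
        assert np.allclose(pwm.matrix[:, 0], 2.0)

    def test_pseudocount_formula(self):
        pfm = PFM(np.tile([0.5, 0.5, 0, 0], (2, 1)), n_hits=10)
        pwm = pfm_to_pwm(pfm, pseudocount=0.01)
        assert pwm.matrix[0, 0] == pytest.approx(np.log2(0.51 / 0.26))


def oracle_similarity(a: PWM, b: PWM):
    """Exhaustive offset/strand enumeration with np.corrcoef."""
    wa, wb = a.width, b.width
    best_cor, best_ncor = -np.inf, -np.inf
    for bm in (b.matrix, b.matrix[::-1, ::-1]):
        for offset in range(-(wb - 1), wa):
            lo, hi = max(0, offset), min(wa, offset + wb)
            if hi <= lo:
                continue
            x = a.matrix[lo:hi].ravel()
            y = bm[lo - offset : hi - offset].ravel()
            if np.std(x) == 0 or np.std(y) == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            best_cor = max(best_cor, r)
            best_ncor = max(best_ncor, r * (hi - lo) / max(wa, wb))
    return best_cor, best_ncor


class TestMotifSimilarity:
    def test_self_similarity_is_one_at_zero_offset(self, rng):
        pwm = pfm_to_pwm(random_pfm(rng, 8, peaked=True))
        cor, ncor, offset, strand = motif_similarity(pwm, pwm)
        assert cor == pytest.approx(1.0)
        assert ncor == pytest.approx(1.0)
        assert (offset, strand) == (0, "+")

    def test_reverse_complement_maps_to_minus_strand(self, rng):
        pwm = pfm_to_pwm(random_pfm(rng, 8, peaked=True))
        cor, ncor, offset, strand = motif_similarity(pwm, pwm.reverse_complement())
        assert cor == pytest.approx(1.0)
        assert strand == "-"

    def test_symmetry(self, rng):
        a = pfm_to_pwm(random_pfm(rng, 7, peaked=True))
        b = pfm_to_pwm(random_pfm(rng, 10, peaked=True))
        ca, na, _, _ = motif_similarity(a, b)
        cb, nb, _, _ = motif_similarity(b, a)
        assert ca == pytest.approx(cb)
        assert na == pytest.approx(nb)

    def test_matches_enumeration_oracle_on_random_pairs(self, rng):
        for _ in range(300):
            a = pfm_to_pwm(random_pfm(rng, int(rng.integers(2, 10))))
            b = pfm_to_pwm(random_pfm(rng, int(rng.integers(2, 10))))
            cor, ncor, _, _ = motif_similarity(a, b)
            ocor, oncor = oracle_similarity(a, b)
            assert cor == pytest.approx(ocor, abs=1e-9)
            assert ncor == pytest.approx(oncor, abs=1e-9)


def shifted_variant(rng, base, shift):
    """Embed `base` columns at an offset inside background columns."""
    width = base.shape[0] + 4
    matrix = rng.dirichlet(np.ones(4) * 10, size=width)  # near-uniform noise
    matrix[shift : shift + base.shape[0]] = base
    return PFM(matrix / matrix.sum(axis=1, keepdims=True), n_hits=20)


class TestClusterMotifs:
    def test_identical_pwms_form_one_cluster(self, rng):
        pwm = pfm_to_pwm(random_pfm(rng, 8, peaked=True))
        clusters = cluster_motifs([pwm, pwm, pwm])
        assert len(clusters) == 1
        assert len(clusters[0].members) == 3

    def test_uncorrelated_pwms_stay_apart(self):
        a = pfm_to_pwm(PFM(np.tile([0.97, 0.01, 0.01, 0.01], (8, 1)), n_hits=10))
        b = pfm_to_pwm(PFM(np.tile([0.01, 0.97, 0.01, 0.01], (8, 1)), n_hits=10))
        # flat-column motifs have zero correlation by construction
        assert len(cluster_motifs([a, b])) == 2

    def test_planted_variants_group_and_unrelated_stay_singletons(self, rng):
        base = np.array(
            [[0.94, 0.02, 0.02, 0.02],
             [0.02, 0.02, 0.94, 0.02],
             [0.02, 0.02, 0.94, 0.02],
             [0.02, 0.94, 0.02, 0.02],
             [0.02, 0.02, 0.02, 0.94],
             [0.94, 0.02, 0.02, 0.02],
             [0.02, 0.02, 0.94, 0.02],
             [0.02, 0.94, 0.02, 0.02]])
        variants = [pfm_to_pwm(shifted_variant(rng, base, s)) for s in (0, 2, 4)]
        unrelated = []
        for i in range(3):
            m = rng.dirichlet(np.full(4, 0.05), size=8)
            unrelated.append(pfm_to_pwm(PFM(m, n_hits=10)))
        # verify the fixture with the pairwise similarity table
        for i in range(3):
            for j in range(i + 1, 3):
                cor, ncor, _, _ = motif_similarity(variants[i], variants[j])
                assert cor >= 0.6 and ncor >= 0.6
        for u in unrelated:
            for v in variants:
                cor, ncor, _, _ = motif_similarity(u, v)
                assert not (cor >= 0.6 and ncor >= 0.6)
        clusters = cluster_motifs(variants + unrelated)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 1, 1, 3]

    def test_partition_covers_all_inputs_once(self, rng):
        pwms = [pfm_to_pwm(random_pfm(rng, 8), ) for _ in range(6)]
        for i, p in enumerate(pwms):
            p.name = f"p{i}"
        clusters = cluster_motifs(pwms)
        seen = [m for c in clusters for m in c.members]
        assert sorted(seen) == [f"p{i}" for i in range(6)]

    def test_permutation_invariance(self, rng):
        pwms = []
        for i in range(6):
            p = pfm_to_pwm(random_pfm(rng, 8, peaked=True))
            p.name = f"p{i}"
            pwms.append(p)
        part1 = sorted(tuple(sorted(c.members)) for c in cluster_motifs(pwms))
        shuffled = [pwms[i] for i in [3, 0, 5, 1, 4, 2]]
        part2 = sorted(tuple(sorted(c.members)) for c in cluster_motifs(shuffled))
        assert part1 == part2


class TestMotifIO:
    def _motifs(self, rng):
        m1 = random_pfm(rng, 6, n_hits=40)
        m1.name = "alpha"
        m2 = random_pfm(rng, 9, n_hits=25)
        m2.name = "beta"
        return [m1, m2]

    @pytest.mark.parametrize("fmt", ["MEME", "JASPAR"])
    def test_round_trip(self, tmp_path, rng, fmt):
        motifs = self._motifs(rng)
        path = tmp_path / f"m.{fmt.lower()}"
        write_motifs(motifs, path, format=fmt)
        back = read_motifs(path, format=fmt)
        assert [m.name for m in back] == ["alpha", "beta"]
        for orig, rt in zip(motifs, back):
            assert np.allclose(orig.matrix, rt.matrix, atol=1e-5)
            assert rt.n_hits == orig.n_hits

    def test_meme_header_background(self, tmp_path, rng):
        path = tmp_path / "m.meme"
        write_motifs(self._motifs(rng), path, format="MEME")
        text = path.read_text()
        assert "A 0.25 C 0.25 G 0.25 T 0.25" in text
        assert text.startswith("MEME version 4")

    def test_meme_file_readable_by_biopython(self, tmp_path, rng):
        from Bio import motifs as bio_motifs

        path = tmp_path / "m.meme"
        mine = self._motifs(rng)
        write_motifs(mine, path, format="MEME")
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
        assert [m.name for m in parsed] == ["alpha", "beta"]
        got = np.array([parsed[0].pwm[b] for b in "ACGT"]).T
        # biopython reconstructs integer counts from nsites, so compare coarsely
        assert np.allclose(got, mine[0].matrix, atol=0.05)

    def test_empty_list_round_trips(self, tmp_path):
        path = tmp_path / "empty.meme"
        write_motifs([], path, format="MEME")
        assert read_motifs(path, format="MEME") == []

    def test_unknown_format_rejected(self, tmp_path, rng):
        with pytest.raises(ValueError):
            write_motifs(self._motifs(rng), tmp_path / "x", format="TRANSFAC")


class TestEndToEndExtraction:
    def test_trained_model_yields_g_rich_motifs(self, small_model, small_dataset):
        dataset, _ = small_dataset
        pos = [e.sequence for e in dataset.subset("train") if e.label == 1]
        result = extract_motifs(small_model, pos)
        assert result["pfms"], "no kernel motif survived trimming"
        # planted pattern is G-rich: retained motifs should be too
        mean_g = np.mean([p.matrix[:, 2].mean() for p in result["pfms"]])
        assert mean_g > 0.4
        assert result["clusters"]
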