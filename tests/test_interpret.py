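"""Attribution completeness, weighted normalization, importance and motif
tracks, Grad-CAM and conservation profiles."""

from __future__ import annotations

import warnings
from collections import Counter

import numpy as np
import pytest

import resplice as rs
import resplice.interpret as itp
from resplice.datasets import encode_sequences


class LinearModel:
    """f(x) = sum(W * x) + b per class — attribution is exact for linear f."""

    def __init__(self, W, b=0.0):
        self.W = W  # (L, 4)
        self.b = b

    def logits(self, X, training=False):
        X = np.asarray(X, dtype=float)
        out = (X * self.W).sum(axis=(1, 2)) + self.b
        return np.stack([out, -out], axis=1)

    def input_gradient(self, X, class_index=0):
        sign = 1.0 if class_index == 0 else -1.0
        return np.repeat(sign * self.W[None], len(X), axis=0)


class TestDinucleotideShuffle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_preserves_dinucleotide_counts(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 60))
        shuf = itp.dinucleotide_shuffle(seq, rng)
        assert len(shuf) == len(seq)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]

    def test_actually_permutes(self):
        rng = np.random.default_rng(0)
        seq = "ACGTACGTAAGGTTCCACGT" * 3
        assert any(itp.dinucleotide_shuffle(seq, rng) != seq for _ in range(5))


class TestAttribute:
    def test_linear_model_scores_are_w_times_x_minus_ref(self, rng):
        L = 12
        W = rng.standard_normal((L, 4))
        model = LinearModel(W)
        X = encode_sequences(["".join(rng.choice(list("ACGT"), L)) for _ in range(3)])
        refs = encode_sequences(["".join(rng.choice(list("ACGT"), L)) for _ in range(4)])
        attr = rs.attribute(model, X, references=refs, n_steps=8, seed=0)
        for i in range(3):
            expected = W * (X[i] - refs.mean(axis=0))
            assert np.allclose(attr.raw[i], expected, atol=1e-10)
        assert attr.completeness(tolerance=1e-6).ok  # exact for linear f

    def test_input_equal_to_reference_gives_zero_scores(self, rng):
        L = 10
        model = LinearModel(rng.standard_normal((L, 4)))
        X = encode_sequences(["ACGTACGTAC"])
        attr = rs.attribute(model, X, references=X.copy(), n_steps=4, seed=0)
        assert np.allclose(attr.raw, 0.0)

    def test_completeness_on_tiny_network(self, toy_spec, rng):
        net = rs.build_network(toy_spec, seed=2)
        seqs = ["".join(rng.choice(list("ACGT"), 24)) for _ in range(3)]
        X = encode_sequences(seqs)
        attr = rs.attribute(net, X, n_references=8, n_steps=64, seed=0)
        report = attr.completeness(tolerance=0.05)
        assert report.ok, report.describe()

    def test_completeness_violation_produces_diagnostic(self, rng):
        # a 1-step quadrature on a curved model breaks completeness
        class Quadratic(LinearModel):
            def logits(self, X, training=False):
                X = np.asarray(X, dtype=float)
                out = ((X * self.W).sum(axis=(1, 2))) ** 3
                return np.stack([out, -out], axis=1)

            def input_gradient(self, X, class_index=0):
                X = np.asarray(X, dtype=float)
                s = (X * self.W).sum(axis=(1, 2))
                return 3 * (s**2)[:, None, None] * self.W[None]

        model = Quadratic(rng.standard_normal((8, 4)) + 1.0)
        X = encode_sequences(["ACGTACGT"])
        refs = encode_sequences(["TTTTTTTT", "GGGGGGGG"])
        with pytest.warns(UserWarning, match="completeness"):
            attr = rs.attribute(model, X, references=refs, n_steps=1,
                                seed=0, completeness_tolerance=1e-4)
        assert not attr.completeness(1e-4).ok


class TestNormalizeWeighted:
    def test_divides_by_absolute_sum(self):
        raw = np.array([[[1.0, -1.0, 0.0, 0.0], [2.0, 0.0, 0.0, 0.0]]])
        w = rs.normalize_weighted(raw)
        assert np.allclose(w, raw / 4.0)

    def test_scale_invariance(self, rng):
        raw = rng.standard_normal((2, 6, 4))
        assert np.allclose(rs.normalize_weighted(raw), rs.normalize_weighted(10 * raw))

    def test_unit_absolute_mass_per_sequence(self, rng):
        w = rs.normalize_weighted(rng.standard_normal((5, 9, 4)))
        assert np.allclose(np.abs(w).sum(axis=(1, 2)), 1.0)

    def test_all_zero_scores_flagged_and_left_zero(self):
        with pytest.warns(UserWarning, match="all-zero"):
            w = rs.normalize_weighted(np.zeros((1, 4, 4)))
        assert np.all(w == 0)


class TestImportanceAndTracks:
    def test_single_sequence_profile_is_abs_realized_scores(self, rng):
        X = encode_sequences(["ACGTAC"])
        weighted = rs.normalize_weighted(rng.standard_normal((1, 6, 4)))
        prof = rs.position_importance(weighted, X)
        assert np.allclose(prof, np.abs((weighted * X).sum(axis=2))[0])

    def test_zero_weighted_gives_zero_profile(self):
        X = encode_sequences(["ACGT"])
        assert np.allclose(rs.position_importance(np.zeros((1, 4, 4)), X), 0.0)

    def test_full_base_set_equals_signed_mean(self, rng):
        X = encode_sequences(["ACGTAC", "GGTTAA"])
        weighted = rs.normalize_weighted(rng.standard_normal((2, 6, 4)))
        track = rs.motif_track(weighted, X, base_set="ACGT")
        realized = (weighted * X).sum(axis=2)
        assert np.allclose(track, realized.mean(axis=0))

    def test_motif_occurrences_indexed_by_first_position(self, rng):
        X = encode_sequences(["AGAGCC"])
        weighted = np.ones((1, 6, 4)) / 24.0
        track = rs.motif_track(weighted, X, motif="AG")
        assert not np.isnan(track[0]) and not np.isnan(track[2])  # 1-based 1 and 3
        assert np.isnan(track[1]) and np.isnan(track[4])

    def test_iupac_n_matches_any_base(self):
        X = encode_sequences(["CTGACC"])
        weighted = np.full((1, 6, 4), 0.1)
        track = rs.motif_track(weighted, X, motif="CTNA")
        assert not np.isnan(track[0])
        # summed realized scores over the 4 motif bases
        assert track[0] == pytest.approx(0.4)

    def test_invalid_motif_alphabet(self, rng):
        X = encode_sequences(["ACGT"])
        with pytest.raises(itp.InterpretError):
            rs.motif_track(np.zeros((1, 4, 4)), X, motif="AXG")
        with pytest.raises(itp.InterpretError):
            rs.motif_track(np.zeros((1, 4, 4)), X, base_set="AZ")


class TestGradCam:
    def test_zero_gradient_network_flagged(self, toy_spec, rng):
        net = rs.build_network(toy_spec, seed=0)
        # zero the dense head: logits are constant, gradients vanish
        head = list(net.body.layers())[-1]
        head.params["W"][:] = 0.0
        X = rng.random((2, 24, 4)).astype(np.float32)
        with pytest.warns(UserWarning, match="flat"):
            out = rs.grad_cam(net, X)
        assert np.all(out.maps == 0)
        assert out.n_flat == 2

    def test_maps_normalized_to_unit_interval(self, trained_small, small_donor_encoded):
        X = small_donor_encoded["test"][0][:16]
        out = rs.grad_cam(trained_small.network, X)
        assert out.maps.shape == (16, 402)
        assert np.all(out.maps >= 0) and np.all(out.maps <= 1 + 1e-9)
        assert np.allclose(out.mean, out.maps.mean(axis=0))

    def test_single_channel_toy_matches_hand_computation(self, rng):
        """One conv channel, identity-like head: the heatmap is the ReLU of
        weight x feature map, interpolated and min-max normalized."""
        spec = rs.NetworkSpec(
            window_length=16,
            stem=rs.StageConfig(n=2, k=3),
            stages=(
                rs.StageConfig(2, 3, 1),
                rs.StageConfig(2, 3, 2),
                rs.StageConfig(2, 3, 2),
                rs.StageConfig(2, 3, 2),
            ),
        )
        net = rs.build_network(spec, seed=4)
        X = rng.random((1, 16, 4)).astype(np.float32)
        out = rs.grad_cam(net, X, target_class=0)
        conv = net.final_conv
        A, dA = conv.last_output, conv.grad_output
        w = dA.mean(axis=1)
        cam = np.maximum((A * w[:, None, :]).sum(axis=2), 0.0)[0]
        m = np.interp(np.arange(16), np.linspace(0, 15, cam.size), cam)
        expected = (m - m.min()) / (m.max() - m.min())
        assert np.allclose(out.maps[0], expected)


class TestTrainedModelAgreement:
    def test_importance_tracks_conservation_beyond_shuffled_control(
        self, attribution_small
    ):
        """The attribution importance profile of the trained model should
        resemble the conservation profile of the positive windows more than
        a position-shuffled version of itself does."""
        attr = attribution_small
        profile = rs.position_importance(attr.weighted, attr.sequences_onehot)
        seqs = [rs.decode(x) for x in attr.sequences_onehot]
        info = rs.conservation(seqs).information
        cos = rs.cosine_similarity(profile, info)
        rng = np.random.default_rng(0)
        control = rs.cosine_similarity(profile[rng.permutation(len(profile))], info)
        assert cos > control


class TestConservation:
    def test_invariant_position_scores_two_bits(self):
        prof = rs.conservation(["ACG", "ACG", "ACG"])
        assert np.allclose(prof.information, 2.0)
        assert np.allclose(prof.frequencies.sum(axis=1), 1.0)

    def test_uniform_position_scores_zero_bits(self):
        prof = rs.conservation(["A", "C", "G", "T"])
        assert prof.information[0] == pytest.approx(0.0)

    def test_matches_direct_entropy_oracle(self, rng):
        from scipy.stats import entropy

        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(100)]
        prof = rs.conservation(seqs)
        for p in range(20):
            counts = Counter(s[p] for s in seqs)
            freqs = np.array([counts.get(b, 0) for b in "ACGT"]) / 100
            assert prof.information[p] == pytest.approx(2 - entropy(freqs, base=2))

    def test_small_sample_correction_reduces_information(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(5)]
        raw = rs.conservation(seqs)
        corr = rs.conservation(seqs, small_sample_correction=True)
        assert np.all(corr.information <= raw.information + 1e-12)
        assert np.all(corr.information >= 0)

    def test_empty_input_errors(self):
        with pytest.raises(itp.InterpretError):
            rs.conservation([])


class TestCosineSimilarity:
    def test_identical_vectors(self, rng):
        v = rng.random(50) + 0.1
        assert rs.cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert rs.cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        expected = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        assert rs.cosine_similarity(a, b) == pytest.approx(expected)

    def test_zero_vector_errors(self):
        with pytest.raises(itp.InterpretError):
            rs.cosine_similarity(np.zeros(4), np.ones(4))


class TestExports:
    def test_profile_tsv_and_pwm_text(self, tmp_path, rng):
        vals = np.array([0.5, np.nan, 1.25])
        itp.profile_to_tsv(tmp_path / "p.tsv", vals)
        lines = (tmp_path / "p.tsv").read_text().splitlines()
        assert lines[0] == "position\tvalue"
        assert lines[2] == "2\tNA"
        prof = rs.conservation(["ACGT", "ACGG"])
        itp.pwm_to_text(tmp_path / "m.txt", prof)
        body = (tmp_path / "m.txt").read_text().splitlines()
        assert body[0] == "PO\tA\tC\tG\tT"
        assert len(body) == 5
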