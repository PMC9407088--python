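"""Sequential registration: pairwise estimation, transform chaining,
warping, drift control, and the adjacent-similarity rationale."""

import numpy as np
import pytest

from fmritemplate import (
    FeatureParams,
    PlanarTransform,
    RegistrationError,
    RegistrationParams,
    SliceSequence,
    compose_to_reference,
    make_textured_phantom,
    matching_similarity,
    register_adjacent_pairs,
    register_sequence,
    warp_slice,
)
from fmritemplate.metrics import ncc

CORNERS = np.array([[8, 8], [8, 55], [55, 8], [55, 55]], dtype=float)


def _shifted_sequence(clean, n_frames, step=(2.0, -1.0)):
    """Frame i = clean shifted so that T_i = translation(i·step)."""
    frames = [clean]
    for i in range(1, n_frames):
        tf = PlanarTransform.translation(step[0] * i, step[1] * i)
        f, _ = warp_slice(clean, tf.inverse(), out_shape=clean.shape)
        frames.append(f)
    return SliceSequence(layer_index=0, frames=frames,
                         frame_ids=np.arange(n_frames))


@pytest.fixture(scope="module")
def reg_params():
    return RegistrationParams(features=FeatureParams(upsample=True))


class TestRegisterAdjacentPairs:
    def test_identical_frames_near_identity(self, phantom64, reg_params):
        clean = phantom64[:, :, 0]
        seq = SliceSequence(layer_index=0, frames=[clean] * 4,
                            frame_ids=np.arange(4))
        pairwise, excluded, _, _ = register_adjacent_pairs(seq, reg_params)
        assert excluded == []
        for t in pairwise:
            disp = np.abs(t.apply(CORNERS) - CORNERS).max()
            assert disp < 0.5

    def test_known_shift_recovered(self, phantom64, reg_params):
        seq = _shifted_sequence(phantom64[:, :, 0], 5)
        pairwise, excluded, _, _ = register_adjacent_pairs(seq, reg_params)
        assert excluded == []
        shift = PlanarTransform.translation(2.0, -1.0)
        for t in pairwise:
            err = np.abs(t.apply(CORNERS) - shift.apply(CORNERS)).max()
            assert err < 0.3

    def test_blank_frame_flagged(self, phantom64, reg_params):
        clean = phantom64[:, :, 0]
        frames = [clean, clean, np.zeros_like(clean), clean]
        seq = SliceSequence(layer_index=0, frames=frames,
                            frame_ids=np.arange(4))
        pairwise, excluded, _, _ = register_adjacent_pairs(seq, reg_params)
        assert 2 in excluded
        np.testing.assert_array_equal(pairwise[1].matrix, np.eye(3))


class TestComposeToReference:
    def test_identities(self):
        cum = compose_to_reference([PlanarTransform.identity()] * 3)
        assert len(cum) == 4
        for t in cum:
            np.testing.assert_array_equal(t.matrix, np.eye(3))

    def test_translations_sum(self):
        steps = [(1.0, 2.0), (-0.5, 1.5), (3.0, 0.0)]
        pairwise = [PlanarTransform.translation(*s) for s in steps]
        cum = compose_to_reference(pairwise)
        total = np.cumsum(np.array([(0, 0)] + steps), axis=0)
        for t, (dx, dy) in zip(cum, total):
            assert t.matrix[0, 2] == pytest.approx(dx, abs=1e-12)
            assert t.matrix[1, 2] == pytest.approx(dy, abs=1e-12)

    def test_matches_fold_left_product_oracle(self):
        rng = np.random.default_rng(3)
        pairwise = [
            PlanarTransform(np.eye(3) + 0.05 * rng.uniform(-1, 1, (3, 3)))
            for _ in range(6)
        ]
        cum = compose_to_reference(pairwise)
        acc = np.eye(3)
        for i, t in enumerate(pairwise):
            acc = acc @ t.matrix
            expect = acc / acc[2, 2]
            np.testing.assert_allclose(cum[i + 1].matrix, expect, atol=1e-10)


class TestWarpSlice:
    def test_identity(self, phantom64):
        frame = phantom64[:, :, 0]
        warped, mask = warp_slice(frame, PlanarTransform.identity())
        np.testing.assert_allclose(warped, frame, atol=1e-12)
        assert mask.min() == 1.0

    def test_integer_translation_equals_roll(self, phantom64):
        frame = phantom64[:, :, 0]
        t = PlanarTransform.translation(3.0, -2.0)
        warped, mask = warp_slice(frame, t)
        rolled = np.roll(frame, (3, -2), axis=(0, 1))
        interior = np.zeros_like(mask, dtype=bool)
        interior[4:-4, 4:-4] = True
        np.testing.assert_allclose(warped[interior], rolled[interior],
                                   atol=1e-9)
        assert mask[:3, :].max() == 0.0   # vacated band
        assert mask[:, -2:].max() == 0.0

    def test_round_trip_interpolation_loss_bounded(self, phantom64):
        frame = phantom64[:, :, 1]
        t = PlanarTransform.rigid(7.0, 1.3, -0.7, centre=(31.5, 31.5))
        fwd, m1 = warp_slice(frame, t)
        back, m2 = warp_slice(fwd, t.inverse())
        common = (m1 > 0) & (m2 > 0)
        common[:6, :] = common[-6:, :] = False
        common[:, :6] = common[:, -6:] = False
        rms = np.sqrt(np.mean((back[common] - frame[common]) ** 2))
        assert rms < 0.02 * (frame.max() - frame.min())


class TestRegisterSequence:
    def test_known_shift_alignment_ncc(self, phantom64, reg_params):
        seq = _shifted_sequence(phantom64[:, :, 0], 5)
        reg = register_sequence(seq, reg_params)
        common = np.prod(reg.masks, axis=0) > 0
        for i, w in enumerate(reg.warped):
            assert ncc(w, seq.frames[0], common) > 0.98, f"frame {i}"

    def test_identical_frames_noop(self, phantom64, reg_params):
        clean = phantom64[:, :, 2]
        seq = SliceSequence(layer_index=2, frames=[clean] * 3,
                            frame_ids=np.arange(3))
        reg = register_sequence(seq, reg_params)
        common = np.prod(reg.masks, axis=0) > 0
        for w in reg.warped:
            assert ncc(w, clean, common) > 0.995

    def test_all_blank_raises(self, reg_params):
        seq = SliceSequence(layer_index=5,
                            frames=[np.zeros((64, 64))] * 3,
                            frame_ids=np.arange(3))
        with pytest.raises(RegistrationError, match="5"):
            register_sequence(seq, reg_params)

    def test_excluded_frames_not_usable(self, phantom64, reg_params):
        clean = phantom64[:, :, 0]
        frames = [clean, clean, np.zeros_like(clean), clean]
        seq = SliceSequence(layer_index=0, frames=frames,
                            frame_ids=np.arange(4))
        reg = register_sequence(seq, reg_params)
        assert 2 not in reg.usable

    def test_drift_stays_subpixel_over_20_frames(self, reg_params):
        """Chained small shifts must not accumulate into visible drift."""
        clean = make_textured_phantom(96, 96, 1, seed=5)[:, :, 0]
        step = (0.5, -0.25)
        frames = [clean]
        for i in range(1, 20):
            tf = PlanarTransform.translation(step[0] * i, step[1] * i)
            f, _ = warp_slice(clean, tf.inverse(), out_shape=clean.shape)
            frames.append(f)
        seq = SliceSequence(layer_index=0, frames=frames,
                            frame_ids=np.arange(20))
        reg = register_sequence(seq, reg_params)
        assert reg.excluded == []
        corners = np.array([[12, 12], [12, 83], [83, 12], [83, 83]], float)
        errs = []
        for i, t in enumerate(reg.cumulative):
            truth = PlanarTransform.translation(step[0] * i, step[1] * i)
            errs.append(np.abs(t.apply(corners) - truth.apply(corners)).max())
        assert max(errs) < 1.0, f"max drift {max(errs):.3f}px"


class TestAdjacentSimilarityRationale:
    def test_adjacent_pairs_match_better_than_distant(self, reg_params):
        """On a drifting sequence, adjacent frames share more matchable
        features than (frame 0, frame i) pairs — the reason sequential
        registration is preferred over direct-to-reference."""
        from fmritemplate import (
            PhantomSpec, animate_phantom, describe_all, match_features,
        )
        from fmritemplate.scale_space_features import (
            detect_features_with_pyramid,
        )
        clean = make_textured_phantom(64, 64, 1, seed=9)
        spec = PhantomSpec(shape=(64, 64, 1, 8), max_step_translation=2.0,
                           max_step_rotation=2.0, noise_sigma=0.01, seed=9)
        seq, _ = animate_phantom(clean, spec)
        feats = []
        for i in range(8):
            kps, gp = detect_features_with_pyramid(seq.data[:, :, 0, i],
                                                   reg_params.features)
            feats.append((kps, describe_all(gp, kps)))

        def sim(i, j):
            (kp_i, d_i), (kp_j, d_j) = feats[i], feats[j]
            m = match_features(d_i, d_j)
            return matching_similarity(len(kp_i), len(kp_j), len(m))

        adjacent = [sim(i, i + 1) for i in range(7)]
        to_reference = [sim(0, i) for i in range(1, 8)]
        assert np.mean(adjacent) >= np.mean(to_reference)
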