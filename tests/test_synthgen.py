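"""Determinism, label validity and statistical-emulation tests for the
synthetic tray-scene generator."""

import numpy as np
import pytest

from shrimpdet.synthgen import (SMALL_AREA_NORM, DatasetStats, ImageSample,
                                SceneParams, augment_complete, augment_local,
                                dataset_stats, generate_dataset,
                                generate_sample)


def _iou(b1, b2):
    x1, y1, w1, h1 = b1
    x2, y2, w2, h2 = b2
    ix = max(0.0, min(x1 + w1 / 2, x2 + w2 / 2) - max(x1 - w1 / 2, x2 - w2 / 2))
    iy = max(0.0, min(y1 + h1 / 2, y2 + h2 / 2) - max(y1 - h1 / 2, y2 - h2 / 2))
    return ix * iy / (w1 * h1 + w2 * h2 - ix * iy)


class TestGenerateSample:
    def test_bitwise_deterministic(self):
        p = SceneParams(image_size=128)
        a = generate_sample(p, np.random.default_rng(42))
        b = generate_sample(p, np.random.default_rng(42))
        assert np.array_equal(a.image, b.image)
        assert a.labels == b.labels

    def test_no_adhesion_yields_disjoint_exact_count(self):
        p = SceneParams(image_size=256, particle_count=(5, 5), adhesion_prob=0.0,
                        occluder_rate=0.0)
        s = generate_sample(p, np.random.default_rng(3))
        assert len(s.labels) == 5
        boxes = [lab[1:] for lab in s.labels]
        for i in range(5):
            for j in range(i + 1, 5):
                assert _iou(boxes[i], boxes[j]) == 0.0

    def test_zero_particles_allowed(self):
        p = SceneParams(image_size=96, particle_count=(0, 0))
        s = generate_sample(p, np.random.default_rng(0))
        assert s.labels == []
        assert s.image.shape == (96, 96, 3)

    def test_labels_inside_unit_box(self, default_samples):
        for s in default_samples:
            for _, cx, cy, w, h in s.labels:
                assert 0 < w <= 1 and 0 < h <= 1
                assert 0 <= cx - w / 2 and cx + w / 2 <= 1
                assert 0 <= cy - h / 2 and cy + h / 2 <= 1

    def test_image_dtype_and_range(self, default_samples):
        img = default_samples[0].image
        assert img.dtype == np.uint8
        assert img.ndim == 3 and img.shape[2] == 3

    def test_statistics_track_generator_targets(self):
        """Monte-Carlo check on a reduced draw; the acceptance suite runs the
        full 200-sample version."""
        p = SceneParams(image_size=160)
        samples = [generate_sample(p, np.random.default_rng([5, i])) for i in range(60)]
        st = dataset_stats(samples)
        assert st.fraction_small == pytest.approx(p.small_fraction_target, abs=0.07)
        assert st.fraction_elongated == pytest.approx(p.elongated_fraction_target, abs=0.07)

    def test_center_concentration(self):
        p = SceneParams(image_size=160, occluder_rate=0.0)
        samples = [generate_sample(p, np.random.default_rng([6, i])) for i in range(40)]
        st = dataset_stats(samples)
        center = st.spatial_hist[2:6, 2:6].sum()
        assert center > 0.5     # central 1/4 of the area holds most targets


class TestGenerateDataset:
    def test_split_counts_and_layout(self, tmp_path):
        p = SceneParams(image_size=64, turbidity_blur_sigma=0.0)
        tr, va = generate_dataset(p, 10, 0.9, tmp_path / "d", seed=1)
        assert (len(tr), len(va)) == (9, 1)
        assert (tmp_path / "d" / "data.yaml").exists()
        assert len(list((tmp_path / "d" / "images" / "train").glob("*.png"))) == 9
        lab = (tmp_path / "d" / "labels" / "val").glob("*.txt")
        for f in lab:
            for line in f.read_text().splitlines():
                parts = line.split()
                assert len(parts) == 5 and parts[0] == "0"

    def test_same_seed_reproduces_split(self, tmp_path):
        p = SceneParams(image_size=48)
        tr1, va1 = generate_dataset(p, 8, 0.75, tmp_path / "a", seed=7)
        tr2, va2 = generate_dataset(p, 8, 0.75, tmp_path / "b", seed=7)
        assert tr1 == tr2 and va1 == va2

    def test_refuses_nonempty_dir(self, tmp_path):
        d = tmp_path / "busy"
        d.mkdir()
        (d / "junk.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_dataset(SceneParams(image_size=48), 4, 0.5, d)

    def test_invalid_args(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(SceneParams(), 1, 0.9, tmp_path / "x")
        with pytest.raises(ValueError):
            generate_dataset(SceneParams(), 4, 1.0, tmp_path / "y")


class TestAugmentComplete:
    def test_horizontal_flip_mirrors_centers(self, easy_samples, rng):
        s = easy_samples[0]
        out = augment_complete(s, rng, crop=(0, 0, 160, 160), rot_k=0, flip=True,
                               brightness=1.0, contrast=1.0)
        for (c0, cx0, cy0, w0, h0), (c1, cx1, cy1, w1, h1) in zip(s.labels, out.labels):
            assert cx1 == pytest.approx(1.0 - cx0)
            assert (cy1, w1, h1) == (cy0, w0, h0)

    def test_rot90_coordinate_map(self, easy_samples, rng):
        s = easy_samples[1]
        out = augment_complete(s, rng, crop=(0, 0, 160, 160), rot_k=1, flip=False,
                               brightness=1.0, contrast=1.0)
        for (c0, cx0, cy0, w0, h0), (c1, cx1, cy1, w1, h1) in zip(s.labels, out.labels):
            assert (cx1, cy1) == pytest.approx((cy0, 1.0 - cx0))
            assert (w1, h1) == (h0, w0)

    def test_identity_draw_is_noop(self, easy_samples, rng):
        s = easy_samples[2]
        out = augment_complete(s, rng, crop=(0, 0, 160, 160), rot_k=0, flip=False,
                               brightness=1.0, contrast=1.0)
        assert np.array_equal(out.image, s.image)
        assert out.labels == s.labels

    def test_random_draws_keep_labels_valid(self, default_samples):
        rng = np.random.default_rng(0)
        for s in default_samples:
            out = augment_complete(s, rng)
            ImageSample(image=out.image, labels=out.labels)  # validates boxes

    def test_crop_drops_mostly_outside_boxes(self, rng):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        s = ImageSample(image=img, labels=[(0, 0.1, 0.1, 0.1, 0.1),
                                           (0, 0.7, 0.7, 0.2, 0.2)])
        out = augment_complete(s, rng, crop=(50, 50, 50, 50), rot_k=0, flip=False,
                               brightness=1.0, contrast=1.0)
        assert len(out.labels) == 1


class TestAugmentLocal:
    def test_paste_zero_is_identity(self, easy_samples, rng):
        s = easy_samples[0]
        out = augment_local(s, easy_samples[1:], rng, paste_count=0)
        assert np.array_equal(out.image, s.image)
        assert out.labels == s.labels

    def test_paste_onto_empty_background(self, easy_samples):
        bg = ImageSample(image=np.full((160, 160, 3), 60, dtype=np.uint8), labels=[])
        out = augment_local(bg, easy_samples, np.random.default_rng(1), paste_count=3)
        assert len(out.labels) == 3

    def test_label_count_monotone(self, easy_samples):
        rng = np.random.default_rng(5)
        for s in easy_samples:
            out = augment_local(s, easy_samples, rng)
            assert len(out.labels) >= len(s.labels)

    def test_empty_donor_pool_rejected(self, easy_samples, rng):
        with pytest.raises(ValueError):
            augment_local(easy_samples[0], [], rng)


class TestDatasetStats:
    def test_single_small_box(self):
        s = ImageSample(image=np.zeros((8, 8, 3), dtype=np.uint8),
                        labels=[(0, 0.5, 0.5, 10 / 640, 10 / 640)])
        st = dataset_stats([s])
        assert st.fraction_small == 1.0
        assert st.n_targets == 1

    def test_aspect_split(self):
        labels = [(0, 0.5, 0.5, 0.3, 0.3), (0, 0.5, 0.5, 0.3, 0.1)]
        s = ImageSample(image=np.zeros((8, 8, 3), dtype=np.uint8), labels=labels)
        st = dataset_stats([s])
        assert st.fraction_elongated == 0.5
        assert st.fraction_small == 0.0

    def test_small_threshold_is_image_size_independent(self):
        # same normalized box counts as small regardless of render size
        assert (20 / 640) ** 2 < SMALL_AREA_NORM < (40 / 640) ** 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dataset_stats([])
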