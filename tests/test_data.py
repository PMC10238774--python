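"""Dataset manifest, preprocessing, splitting, balancing, augmentation and
the synthetic generator."""

import numpy as np
import pytest
from PIL import Image

from qcsanet.data import (AugmentConfig, DatasetManifest, ManifestRecord,
                          PreprocessConfig, SynthConfig, augment, balance,
                          generate_synthetic_dataset, load_manifest,
                          load_split_arrays, preprocess, split_dataset,
                          synthesize_arrays, synthesize_image)


@pytest.fixture
def small_dataset(tmp_path):
    """3 pneumonia + 2 normal flat-layout files."""
    for name, n in [("PNEUMONIA", 3), ("NORMAL", 2)]:
        d = tmp_path / name
        d.mkdir()
        for i in range(n):
            Image.fromarray(np.full((8, 8), 100, np.uint8)).save(d / f"{i}.png")
    return tmp_path


class TestManifest:
    def test_counts_small_fixture(self, small_dataset):
        m = load_manifest(small_dataset)
        assert m.class_counts == {0: 2, 1: 3}

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_manifest(tmp_path)

    def test_missing_class_dir_rejected(self, tmp_path):
        (tmp_path / "NORMAL").mkdir()
        with pytest.raises(FileNotFoundError, match="PNEUMONIA"):
            load_manifest(tmp_path)

    def test_unreadable_image_skipped_with_warning(self, small_dataset, caplog):
        (small_dataset / "NORMAL" / "broken.png").write_text("not an image")
        with caplog.at_level("WARNING"):
            m = load_manifest(small_dataset)
        assert m.class_counts == {0: 2, 1: 3}
        assert any("unreadable" in r.message for r in caplog.records)

    def test_split_layout_and_case_insensitive_names(self, tmp_path):
        for split in ("train", "test"):
            for name in ("normal", "pneumonia"):
                d = tmp_path / split / name
                d.mkdir(parents=True)
                Image.fromarray(np.zeros((8, 8), np.uint8)).save(d / "a.png")
        m = load_manifest(tmp_path)
        assert m.split_counts() == {"train": 2, "test": 2}

    def test_csv_round_trip(self, small_dataset, tmp_path):
        m = load_manifest(small_dataset)
        path = tmp_path / "m.csv"
        m.to_csv(path)
        m2 = DatasetManifest.from_csv(path)
        assert [r.__dict__ for r in m2.records] == [r.__dict__ for r in m.records]

    def test_reproduces_published_class_totals(self, tmp_path):
        """A generated set with the published class sizes (4273 P, 1583 N)
        is recovered exactly by the manifest scan."""
        # tiny 8x8 images keep this fast; counts are what matters
        cfg = SynthConfig(n_per_class=1, image_size=8, seed=0)
        rng = np.random.default_rng(0)
        for name, n in [("PNEUMONIA", 4273), ("NORMAL", 1583)]:
            d = tmp_path / name
            d.mkdir()
            img = Image.fromarray(
                (synthesize_image(1, rng, cfg) * 255).astype(np.uint8))
            for i in range(n):
                img.save(d / f"{i:05d}.png")
        m = load_manifest(tmp_path)
        assert m.class_counts == {1: 4273, 0: 1583}
        assert len(m) == 5856


class TestPreprocess:
    def test_8bit_rescaling_endpoints(self):
        arr = np.zeros((50, 50), np.uint8)
        arr[0, 0] = 255
        out = preprocess(arr)
        assert out[0, 0] == 1.0
        assert out[1, 1] == 0.0

    def test_resize_to_target(self):
        out = preprocess(np.zeros((100, 80), np.uint8))
        assert out.shape == (50, 50)

    def test_rgb_luminance_reduction(self):
        rgb = np.zeros((50, 50, 3), np.uint8)
        rgb[..., 1] = 255  # pure green
        out = preprocess(rgb)
        assert out.max() == pytest.approx(0.587, abs=0.01)

    def test_idempotent_on_conformant_input(self, rng):
        x = rng.random((50, 50))
        np.testing.assert_array_equal(preprocess(x), x)

    def test_corrupt_file_raises(self, tmp_path):
        bad = tmp_path / "bad.png"
        bad.write_text("nope")
        with pytest.raises(OSError):
            preprocess(bad)


class TestSplit:
    def _manifest(self, n_p, n_n):
        recs = ([ManifestRecord(f"p{i}", 1, "") for i in range(n_p)]
                + [ManifestRecord(f"n{i}", 0, "") for i in range(n_n)])
        return DatasetManifest(recs)

    def test_published_totals_5856(self):
        """5856 images at (0.75, 0.05, 0.20) -> 4392 / 292 / 1172."""
        m = split_dataset(self._manifest(4273, 1583), seed=0)
        counts = m.split_counts()
        assert counts == {"train": 4392, "val": 292, "test": 1172}

    def test_stratification_close_to_fractions(self):
        m = split_dataset(self._manifest(4273, 1583), seed=0)
        train_p = sum(1 for r in m.records
                      if r.split == "train" and r.label == 1)
        assert train_p == 3205  # round(0.75 * 4273)

    def test_empty_manifest(self):
        m = split_dataset(DatasetManifest([]), seed=0)
        assert len(m) == 0

    def test_all_train(self):
        m = split_dataset(self._manifest(6, 4), fractions=(1.0, 0.0, 0.0))
        assert m.split_counts() == {"train": 10}

    def test_partition_is_exact_and_disjoint(self, rng):
        for n_p, n_n in [(13, 7), (101, 53), (30, 1)]:
            m = split_dataset(self._manifest(n_p, n_n), seed=2)
            counts = m.split_counts()
            n = n_p + n_n
            assert sum(counts.values()) == n
            assert counts.get("train", 0) == round(0.75 * n)
            assert counts.get("val", 0) == int(np.floor(0.05 * n))
            paths = [r.path for r in m.records]
            assert len(set(paths)) == n  # no record in two splits

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._manifest(5, 5), fractions=(0.5, 0.2, 0.1))


class TestBalance:
    def _manifest(self, n_p, n_n):
        recs = ([ManifestRecord(f"p{i}", 1, "train") for i in range(n_p)]
                + [ManifestRecord(f"n{i}", 0, "train") for i in range(n_n)])
        return DatasetManifest(recs)

    def test_published_counts_give_expected_weights(self):
        w = balance(self._manifest(4273, 1583))
        assert w[1] == pytest.approx(0.685, abs=5e-4)
        assert w[0] == pytest.approx(1.850, abs=5e-4)

    def test_balanced_input_unit_weights(self):
        w = balance(self._manifest(10, 10))
        assert w == {0: 1.0, 1: 1.0}

    def test_oversample_to_parity(self):
        m = balance(self._manifest(10, 4), mode="oversample", seed=0)
        assert m.class_counts == {0: 10, 1: 10}

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance(self._manifest(5, 0))


class TestAugment:
    def test_all_off_is_identity(self, rng):
        x = rng.random((20, 20))
        cfg = AugmentConfig(horizontal_flip=False, max_rotation_deg=0,
                            max_shift_fraction=0)
        np.testing.assert_array_equal(augment(x, cfg, seed=3), x)

    def test_seed_determinism(self, rng):
        x = rng.random((20, 20))
        np.testing.assert_array_equal(augment(x, seed=9), augment(x, seed=9))

    def test_output_stays_in_unit_range(self, rng):
        for seed in range(10):
            out = augment(rng.random((16, 16)), seed=seed)
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestSyntheticGenerator:
    def test_manifest_counts(self, tmp_path):
        m = generate_synthetic_dataset(SynthConfig(n_per_class=5, image_size=16),
                                       tmp_path / "d")
        assert m.class_counts == {0: 5, 1: 5}

    def test_byte_identical_under_seed(self, tmp_path):
        cfg = SynthConfig(n_per_class=3, image_size=16, seed=11)
        generate_synthetic_dataset(cfg, tmp_path / "a")
        generate_synthetic_dataset(cfg, tmp_path / "b")
        for pa in sorted((tmp_path / "a").rglob("*.png")):
            pb = tmp_path / "b" / pa.relative_to(tmp_path / "a")
            assert pa.read_bytes() == pb.read_bytes()

    def test_pneumonia_class_is_brighter(self, tiny_synth):
        x, y = tiny_synth
        assert x[y == 1].mean() > x[y == 0].mean()

    def test_classes_separable_by_max_intensity_threshold(self):
        """The learning task is winnable: a max-pixel threshold alone gets
        >= 95% on a default-condition set."""
        x, y = synthesize_arrays(100, SynthConfig(), seed=21)
        mx = x.reshape(len(x), -1).max(axis=1)
        best = max(((mx >= t).astype(int) == y).mean()
                   for t in np.linspace(0.2, 1.0, 161))
        assert best >= 0.95

    def test_split_arrays_round_trip(self, tmp_path):
        cfg = SynthConfig(n_per_class=10, image_size=16, seed=2)
        m = generate_synthetic_dataset(cfg, tmp_path / "d")
        x, y = load_split_arrays(m, "train",
                                 PreprocessConfig(target_size=(16, 16)))
        assert len(x) == len(y) > 0
        assert x.min() >= 0 and x.max() <= 1


class TestEnhancementHook:
    def test_identity_default(self, rng):
        from qcsanet.data import enhance_image

        x = rng.random((8, 8))
        np.testing.assert_array_equal(enhance_image(x), x)
        np.testing.assert_array_equal(enhance_image(x, "identity"), x)

    def test_unknown_method_rejected(self, rng):
        from qcsanet.data import enhance_image

        with pytest.raises(ValueError):
            enhance_image(rng.random((4, 4)), "clahe")
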