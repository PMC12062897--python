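import numpy as np
import pandas as pd
import pytest

from findwormz.config import ConfigError, validate_config
from findwormz.io import ImagePairRecord
from findwormz.pipeline import STAGES, run_batch, run_image
from findwormz.synth import SyntheticPlateSpec, evaluate_detection

from conftest import SMALL_PLATE, make_pair_dir


class TestValidateConfig:
    def test_minimal_gets_documented_defaults(self):
        cfg = validate_config({"input_dir": "imgs"})
        assert (cfg.band.worminess_lo, cfg.band.worminess_hi) == (1.5, 2.1)
        assert cfg.polarity == "dark_foreground"
        assert cfg.preprocess.blur_sigma == 2.0
        assert cfg.connectivity == 8
        assert cfg.exclude_border is False

    def test_inverted_band_rejected(self):
        with pytest.raises(ConfigError):
            validate_config({"input_dir": "imgs", "worminess_lo": 2.5, "worminess_hi": 2.0})

    def test_typo_key_rejected(self):
        with pytest.raises(ConfigError, match="wormness_lo"):
            validate_config({"input_dir": "imgs", "wormness_lo": 1.0})

    def test_missing_input_dir(self):
        with pytest.raises(ConfigError):
            validate_config({})

    def test_fixed_threshold_requires_value(self):
        with pytest.raises(ConfigError):
            validate_config({"input_dir": "i", "threshold_method": "fixed"})


class TestRunImage:
    def test_planted_counts_recovered(self, pair_on_disk, default_cfg):
        # 5 planted worms + 2 round debris + 3 specks -> exactly 5
        # measurements; debris removed by worminess, specks never labeled
        rec, truth = pair_on_disk
        res = run_image(rec, default_cfg)
        assert len(res.measurements) == 5
        removed = res.shape_table[res.shape_table.filter_status == "removed_worminess"]
        assert len(removed) == 2
        assert (removed.worminess < 1.5).all()  # debris sits near the circle floor
        score = evaluate_detection(res.kept, res.measurements, truth, 0.6)
        assert score.recall == 1.0 and score.precision == 1.0

    def test_debris_rejection_attributable(self, pair_on_disk, default_cfg):
        # every detected round-debris object lands in removed_worminess
        rec, truth = pair_on_disk
        res = run_image(rec, default_cfg)
        kept_mask = res.kept.labels > 0
        assert not (kept_mask & truth.debris_mask).any()

    def test_blank_image(self, tmp_path):
        import tifffile

        blank = np.full((100, 100), 30000, dtype=np.uint16)
        tifffile.imwrite(tmp_path / "b_BF.tif", blank)
        tifffile.imwrite(tmp_path / "b_Fl.tif", blank)
        cfg = validate_config({"input_dir": str(tmp_path)})
        rec = ImagePairRecord("b", str(tmp_path / "b_BF.tif"), str(tmp_path / "b_Fl.tif"))
        res = run_image(rec, cfg)
        assert res.measurements == []
        assert res.background.n_background_px == 100 * 100

    def test_size_mismatch_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "m_BF.tif", np.zeros((50, 50), np.uint16))
        tifffile.imwrite(tmp_path / "m_Fl.tif", np.zeros((40, 50), np.uint16))
        cfg = validate_config({"input_dir": str(tmp_path)})
        rec = ImagePairRecord("m", str(tmp_path / "m_BF.tif"), str(tmp_path / "m_Fl.tif"))
        with pytest.raises(ValueError, match="dimensions"):
            run_image(rec, cfg)

    def test_stage_order_conformance(self, pair_on_disk, default_cfg):
        res = run_image(*pair_on_disk[:1], default_cfg)
        assert res.stage_log == STAGES


def _batch_dir(tmp_path, n=2, with_key=True):
    specs = {
        f"im{i}": SyntheticPlateSpec(**SMALL_PLATE, seed=100 + i) for i in range(n)
    }
    key = {f"im{i}": f"cond{i}" for i in range(n)} if with_key else None
    return make_pair_dir(tmp_path, specs, key)


class TestRunBatch:
    def test_condition_join(self, tmp_path):
        d = _batch_dir(tmp_path, n=2)
        cfg = validate_config(
            {"input_dir": str(d), "output_dir": str(tmp_path / "out"),
             "key_path": str(d / "key.csv")}
        )
        report, results = run_batch(cfg)
        df = pd.read_csv(tmp_path / "out" / "measurements.csv")
        assert set(df.condition) == {"cond0", "cond1"}
        assert report.exit_status == 0

    def test_corrupt_image_skipped_batch_continues(self, tmp_path):
        d = _batch_dir(tmp_path, n=2)
        (d / "bad_BF.tif").write_bytes(b"not a tiff")
        (d / "bad_Fl.tif").write_bytes(b"also not a tiff")
        cfg = validate_config({"input_dir": str(d), "output_dir": str(tmp_path / "o")})
        report, results = run_batch(cfg)
        assert len(report.processed) == 2
        assert list(report.failed) == ["bad"]
        assert report.exit_status == 1

    def test_failed_image_isolation(self, tmp_path):
        # measurements of good images are identical with and without a
        # corrupt neighbor in the batch
        d1 = _batch_dir(tmp_path / "a", n=2, with_key=False)
        cfg1 = validate_config({"input_dir": str(d1), "output_dir": str(tmp_path / "o1")})
        _, res1 = run_batch(cfg1)

        d2 = _batch_dir(tmp_path / "b", n=2, with_key=False)
        (d2 / "aa_BF.tif").write_bytes(b"junk")
        (d2 / "aa_Fl.tif").write_bytes(b"junk")
        cfg2 = validate_config({"input_dir": str(d2), "output_dir": str(tmp_path / "o2")})
        _, res2 = run_batch(cfg2)
        good2 = [r for r in res2 if r.pair_id.startswith("im")]
        assert [r.measurements for r in res1] == [r.measurements for r in good2]

    def test_empty_directory_is_error(self, tmp_path):
        cfg = validate_config({"input_dir": str(tmp_path)})
        with pytest.raises(FileNotFoundError):
            run_batch(cfg)

    def test_no_key_empty_condition(self, tmp_path):
        d = _batch_dir(tmp_path, n=1, with_key=False)
        cfg = validate_config({"input_dir": str(d), "output_dir": str(tmp_path / "o")})
        run_batch(cfg)
        df = pd.read_csv(tmp_path / "o" / "measurements.csv")
        assert df.condition.isna().all() or (df.condition == "").all()

    def test_byte_identical_reruns(self, tmp_path):
        # determinism: two runs on the same folder produce byte-identical
        # CSVs and pixel-identical overlays
        d = _batch_dir(tmp_path, n=2)
        outs = []
        for sub in ("o1", "o2"):
            cfg = validate_config(
                {"input_dir": str(d), "output_dir": str(tmp_path / sub),
                 "key_path": str(d / "key.csv")}
            )
            run_batch(cfg)
            outs.append(tmp_path / sub)
        for name in ("measurements.csv", "backgrounds.csv", "shapes.csv"):
            assert (outs[0] / name).read_bytes() == (outs[1] / name).read_bytes()
        for png in sorted(outs[0].glob("*_overlay.png")):
            assert png.read_bytes() == (outs[1] / png.name).read_bytes()
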