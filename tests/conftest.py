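import numpy as np
import pytest

from findwormz import (
    ImagePairRecord,
    SyntheticPlateSpec,
    save_image,
    validate_config,
)
from findwormz.synth import generate_plate


SMALL_PLATE = dict(image_size=(400, 500), n_worms=5, n_round_debris=2, n_specks=3)


@pytest.fixture
def small_spec():
    """A fast-to-render plate: 5 worms, 2 round debris, 3 specks."""
    return SyntheticPlateSpec(**SMALL_PLATE, seed=7)


@pytest.fixture
def small_plate(small_spec):
    return generate_plate(small_spec)


def make_pair_dir(tmp_path, specs, key=None):
    """Write BF/Fl TIFF pairs for the given {stem: spec} mapping."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    for stem, spec in specs.items():
        bf, fl, _ = generate_plate(spec)
        save_image(bf, tmp_path / f"{stem}_BF.tif")
        save_image(fl, tmp_path / f"{stem}_Fl.tif")
    if key is not None:
        lines = ["filename,condition"] + [f"{s},{c}" for s, c in key.items()]
        (tmp_path / "key.csv").write_text("\n".join(lines) + "\n")
    return tmp_path


@pytest.fixture
def pair_on_disk(tmp_path, small_spec):
    """One plate written to disk plus its ImagePairRecord and ground truth."""
    bf, fl, truth = generate_plate(small_spec)
    save_image(bf, tmp_path / "p_BF.tif")
    save_image(fl, tmp_path / "p_Fl.tif")
    rec = ImagePairRecord("p", str(tmp_path / "p_BF.tif"), str(tmp_path / "p_Fl.tif"))
    return rec, truth


@pytest.fixture
def default_cfg(tmp_path):
    return validate_config({"input_dir": str(tmp_path)})
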