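import numpy as np
import pytest

from repeatmosaic import simcore, traceio


@pytest.fixture
def calib() -> traceio.SizeCalibration:
    """6.0 bp/repeat, 138 bp flank, accurate window 330-560 bp."""
    return traceio.SizeCalibration(6.0, 138.0)


@pytest.fixture
def simple_dist() -> traceio.AlleleDistribution:
    """Modal 41 with two expansion peaks (worked-example distribution)."""
    return traceio.AlleleDistribution.from_entries("XDP", {41: 100.0, 42: 60.0, 43: 40.0})


@pytest.fixture
def quiet_profile() -> simcore.TissueProfile:
    """Tissue with no somatic change at all (point-mass ground truth)."""
    return simcore.TissueProfile("quiet", 0.0, 0.0, 0.5, 0.5, 0.0, block="x")


@pytest.fixture
def no_stutter() -> simcore.StutterModel:
    return simcore.StutterModel(0.0, 0.0, 1.0)


def make_peak_csv(path, rows):
    lines = ["sample_id,locus,size_bp,height"]
    lines += [",".join(str(v) for v in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def peak_csv_factory(tmp_path):
    def factory(rows, name="peaks.csv"):
        return make_peak_csv(tmp_path / name, rows)

    return factory


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
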