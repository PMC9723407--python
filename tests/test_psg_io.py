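import numpy as np
import pytest

from nremscope import psg_io
from nremscope.psg_io import (ArtifactMask, Hypnogram, Recording,
                              apply_artifact_rules, preprocess,
                              read_artifact_mask, read_hypnogram,
                              read_recording, rereference_contralateral_mastoid,
                              write_artifact_mask, write_edf, write_hypnogram)


def _recording(n_s=60, fs=100, ch_names=("C3", "C4", "A1", "A2"), seed=0):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, 20, size=(len(ch_names), int(n_s * fs)))
    return Recording(data=data, fs=float(fs), ch_names=list(ch_names))


def test_edf_round_trip(tmp_path):
    rec = _recording()
    path = tmp_path / "night.edf"
    write_edf(rec, path)
    back = read_recording(path)
    assert back.fs == rec.fs
    assert back.ch_names == rec.ch_names
    # 16-bit quantization: error bounded by half a digital step per channel
    step = 2 * np.abs(rec.data).max(axis=1) * 1.01 / 65535.0
    err = np.abs(back.data - rec.data).max(axis=1)
    assert np.all(err <= step)


def test_mastoid_alias_normalization(tmp_path):
    rec = _recording(ch_names=("C3", "C4", "M1", "M2"))
    path = tmp_path / "alias.edf"
    write_edf(rec, path)
    back = read_recording(path)
    assert back.ch_names == ["C3", "C4", "A1", "A2"]


def test_missing_required_channel(tmp_path):
    rec = _recording(ch_names=("C3", "C4", "A1", "O1"))
    path = tmp_path / "missing.edf"
    write_edf(rec, path)
    with pytest.raises(ValueError, match="A2"):
        read_recording(path)


def test_rereference_contralateral():
    rec = _recording()
    out = rereference_contralateral_mastoid(rec)
    assert out.ch_names == ["C3", "C4"]
    np.testing.assert_array_equal(out.data[0],
                                  rec.channel("C3") - rec.channel("A2"))
    np.testing.assert_array_equal(out.data[1],
                                  rec.channel("C4") - rec.channel("A1"))


def test_preprocess_downsamples_and_lowpasses():
    fs = 200.0
    t = np.arange(int(60 * fs)) / fs
    x = np.sin(2 * np.pi * 10.0 * t) + np.sin(2 * np.pi * 60.0 * t)
    rec = Recording(data=np.vstack([x, x]), fs=fs, ch_names=["C3", "C4"])
    out = preprocess(rec)
    assert out.fs == 100.0
    assert out.n_samples == rec.n_samples // 2
    want = np.sin(2 * np.pi * 10.0 * np.arange(out.n_samples) / 100.0)
    mid = slice(500, -500)
    assert np.allclose(out.data[0][mid], want[mid], atol=1e-2)


def test_preprocess_rejects_upsampling():
    rec = Recording(data=np.zeros((1, 3000)), fs=50.0, ch_names=["C3"])
    with pytest.raises(ValueError, match="upsampling"):
        preprocess(rec)


def test_hypnogram_round_trip_aasm(tmp_path):
    stages = np.array(["Wake", "N1", "N2", "SWS", "REM", "Movement"],
                      dtype=object)
    path = tmp_path / "hyp.tsv"
    write_hypnogram(Hypnogram(stages=stages), path)
    back = read_hypnogram(path, dialect="AASM")
    assert list(back.stages) == list(stages)


def test_hypnogram_rk_merges_3_and_4(tmp_path):
    path = tmp_path / "rk.tsv"
    path.write_text("epoch_index\tstage\n0\t0\n1\t2\n2\t3\n3\t4\n4\t5\n")
    hyp = read_hypnogram(path, dialect="RK")
    assert list(hyp.stages) == ["Wake", "N2", "SWS", "SWS", "REM"]


def test_hypnogram_rejects_gaps_and_bad_codes(tmp_path):
    path = tmp_path / "gap.tsv"
    path.write_text("epoch_index\tstage\n0\tW\n2\tN2\n")
    with pytest.raises(ValueError, match="consecutive"):
        read_hypnogram(path)
    path.write_text("epoch_index\tstage\n0\tW\n1\tXX\n")
    with pytest.raises(ValueError, match="stage code"):
        read_hypnogram(path)


def test_artifact_mask_round_trip(tmp_path):
    flags = np.zeros((10, 2), dtype=bool)
    flags[3, 0] = flags[7, 1] = True
    mask = ArtifactMask(flags=flags, channels=["C3", "C4"])
    path = tmp_path / "art.tsv"
    write_artifact_mask(mask, path)
    back = read_artifact_mask(path, n_epochs=10, channels=["C3", "C4"])
    np.testing.assert_array_equal(back.flags, flags)


def test_artifact_rules_threshold_is_strict():
    # 10 non-REM epochs; exactly 20% flagged keeps the channel, 30% drops it
    stages = np.array(["N2"] * 10, dtype=object)
    hyp = Hypnogram(stages=stages)
    flags = np.zeros((10, 2), dtype=bool)
    flags[:2, 0] = True    # C3: 20% -> kept
    flags[:3, 1] = True    # C4: 30% -> excluded
    res = apply_artifact_rules(ArtifactMask(flags=flags,
                                            channels=["C3", "C4"]), hyp)
    assert res.excluded == ["C4"]
    np.testing.assert_array_equal(res.usable_epochs["C3"], np.arange(2, 10))
    assert res.n_nonrem == 10


def test_artifact_rules_no_nonrem():
    hyp = Hypnogram(stages=np.array(["Wake", "REM"], dtype=object))
    mask = ArtifactMask(flags=np.zeros((2, 2), dtype=bool),
                        channels=["C3", "C4"])
    res = apply_artifact_rules(mask, hyp)
    assert res.no_data == ["C3", "C4"]
    assert res.usable_epochs == {}


def test_hypnogram_validation():
    with pytest.raises(ValueError):
        Hypnogram(stages=np.array([], dtype=object))
    with pytest.raises(ValueError):
        Hypnogram(stages=np.array(["NotAStage"], dtype=object))


def test_recording_accessors():
    rec = _recording(n_s=90)
    assert rec.n_epochs == 3
    assert rec.duration_s == 90.0
    with pytest.raises(KeyError):
        rec.channel("Oz")
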