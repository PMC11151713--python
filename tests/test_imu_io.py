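"""CSV ingestion, unit normalisation, round trips and resampling."""

import numpy as np
import pandas as pd
import pytest

from fessmotion.imu_io import (GRAVITY_MS2, ColumnMapping, ConfigurationError,
                               EmptyRecordingError, FormatError, RecordingMeta,
                               read_recording_csv, resample_uniform,
                               write_recording_csv, read_sidecar_meta)
from fessmotion.synthetic import make_submovement_trace

from conftest import make_recording


def meta(units="g", **kw):
    return RecordingMeta(participant_id="P01", group="senior", hand="DH",
                         procedure="foreign_body_removal", acc_units_in=units, **kw)


def write_csv(path, df):
    df.to_csv(path, index=False)
    return path


class TestReadRecording:
    def test_g_to_ms2_conversion(self, tmp_path):
        df = pd.DataFrame({"t": [0, 1 / 128, 2 / 128], "ax": [0.0] * 3,
                           "ay": [0.0] * 3, "az": [1.0] * 3})
        rec = read_recording_csv(write_csv(tmp_path / "a.csv", df),
                                 ColumnMapping.default(), meta("g"))
        assert rec.acc[:, 2] == pytest.approx([GRAVITY_MS2] * 3)
        assert rec.meta.acc_units_in == "m_s2"

    def test_g_and_ms2_declarations_agree(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, size=(50, 3))
        t = np.arange(50) / 128
        df_g = pd.DataFrame({"t": t, "ax": vals[:, 0], "ay": vals[:, 1], "az": vals[:, 2]})
        df_si = df_g.copy()
        for c in ("ax", "ay", "az"):
            df_si[c] *= GRAVITY_MS2
        rec_g = read_recording_csv(write_csv(tmp_path / "g.csv", df_g),
                                   ColumnMapping.default(), meta("g"))
        rec_si = read_recording_csv(write_csv(tmp_path / "si.csv", df_si),
                                    ColumnMapping.default(), meta("m_s2"))
        np.testing.assert_allclose(rec_g.acc, rec_si.acc, rtol=1e-12)

    def test_corrupt_row_dropped_and_counted(self, tmp_path):
        t = np.arange(100) / 128.0
        df = pd.DataFrame({"t": t, "ax": 1.0, "ay": 2.0, "az": 3.0})
        df["ax"] = df["ax"].astype(object); df.loc[41, "ax"] = "garbage"
        rec = read_recording_csv(write_csv(tmp_path / "c.csv", df),
                                 ColumnMapping.default(), meta())
        assert rec.n_samples == 99
        assert rec.meta.extras["dropped_rows"] == 1

    def test_duplicate_timestamps_keep_first(self, tmp_path):
        t = np.arange(300) / 128.0
        df = pd.DataFrame({"t": t, "ax": np.arange(300.0), "ay": 0.0, "az": 0.0})
        df.loc[100, "t"] = df.loc[99, "t"]  # one duplicate
        rec = read_recording_csv(write_csv(tmp_path / "d.csv", df),
                                 ColumnMapping.default(), meta())
        assert rec.n_samples == 299
        assert 99.0 * GRAVITY_MS2 in rec.acc[:, 0]

    def test_heavily_disordered_timestamps_refused(self, tmp_path):
        rng = np.random.default_rng(1)
        t = rng.permutation(np.arange(100) / 128.0)
        df = pd.DataFrame({"t": t, "ax": 0.0, "ay": 0.0, "az": 0.0})
        with pytest.raises(FormatError):
            read_recording_csv(write_csv(tmp_path / "e.csv", df),
                               ColumnMapping.default(), meta())

    def test_missing_required_column(self, tmp_path):
        df = pd.DataFrame({"t": [0, 1], "ax": [0, 0], "ay": [0, 0]})
        with pytest.raises(ConfigurationError):
            read_recording_csv(write_csv(tmp_path / "f.csv", df),
                               ColumnMapping.default(), meta())

    def test_too_few_rows(self, tmp_path):
        df = pd.DataFrame({"t": [0.0], "ax": [0.0], "ay": [0.0], "az": [0.0]})
        with pytest.raises(EmptyRecordingError):
            read_recording_csv(write_csv(tmp_path / "g.csv", df),
                               ColumnMapping.default(), meta())

    def test_index_synthesised_timestamps(self, tmp_path):
        df = pd.DataFrame({"ax": np.zeros(10), "ay": 0.0, "az": 0.0})
        mapping = ColumnMapping(t=None, ax="ax", ay="ay", az="az")
        rec = read_recording_csv(write_csv(tmp_path / "h.csv", df), mapping,
                                 meta(nominal_rate=128.0))
        np.testing.assert_allclose(rec.t, np.arange(10) / 128.0)


class TestRoundTrip:
    def test_write_read_lossless(self, tmp_path):
        rec, _ = make_submovement_trace(0.3, 1.5, sensor_noise_sd=0.05,
                                        tremor_amp=0.1, orientation_wobble_deg=10, seed=3)
        path = write_recording_csv(rec, tmp_path / "trial.csv")
        back = read_recording_csv(path, ColumnMapping.default(),
                                  read_sidecar_meta(path.with_name(path.name + ".meta.json")))
        np.testing.assert_allclose(back.t, rec.t, atol=1e-6)
        np.testing.assert_allclose(back.acc, rec.acc, atol=1e-6)
        np.testing.assert_allclose(back.orient, rec.orient, atol=1e-6)
        assert back.meta.group == rec.meta.group
        assert back.meta.hand == rec.meta.hand
        assert back.meta.procedure == rec.meta.procedure

    def test_column_layout(self, tmp_path):
        t = np.arange(5) / 128
        rec = make_recording(t, np.zeros((5, 3)))
        path = write_recording_csv(rec, tmp_path / "t.csv")
        df = pd.read_csv(path)
        assert list(df.columns) == ["t", "ax", "ay", "az"]
        assert len(df) == rec.n_samples


class TestResample:
    def test_identity_at_same_rate(self):
        t = np.arange(256) / 128
        acc = np.random.default_rng(0).normal(size=(256, 3))
        rec = make_recording(t, acc)
        out = resample_uniform(rec, 128)
        np.testing.assert_allclose(out.acc, acc, atol=1e-9)

    def test_linear_ramp_exact(self):
        t = np.arange(100) / 128
        acc = np.column_stack([3.0 * t + 1.0, -t, 0 * t])
        rec = make_recording(t, acc)
        out = resample_uniform(rec, 77.0)
        np.testing.assert_allclose(out.acc[:, 0], 3.0 * out.t + 1.0, atol=1e-12)
        np.testing.assert_allclose(out.acc[:, 1], -out.t, atol=1e-12)

    def test_duration_conserved_on_downsample(self):
        t = np.arange(512) / 256
        rec = make_recording(t, np.random.default_rng(1).normal(size=(512, 3)), rate=256)
        out = resample_uniform(rec, 128)
        assert abs(out.duration - rec.duration) <= 1 / 128

    def test_constant_mean_preserved(self):
        t = np.arange(128) / 128
        rec = make_recording(t, np.full((128, 3), 2.5))
        out = resample_uniform(rec, 100.0)
        assert out.acc.mean() == pytest.approx(2.5, abs=1e-12)

    def test_rate_too_low(self):
        t = np.arange(10) / 128
        rec = make_recording(t, np.zeros((10, 3)))
        with pytest.raises(EmptyRecordingError):
            resample_uniform(rec, 1.0)
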