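import numpy as np
import pandas as pd
import pytest

import pareidolia as p
from pareidolia.core import RDM, SensorEpochs, StimulusItem, StimulusSet, ValidationError
from pareidolia.io import (
    load_stimulus_manifest,
    read_epochs,
    read_rdm,
    write_epochs,
    write_rdm,
    write_stimulus_manifest,
)
from pareidolia.preprocess import downsample


def _toy_epochs(n_trials=8, n_ch=4, n_t=10, rate=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_trials, n_ch, n_t))
    times = -2.0 + np.arange(n_t) * (1000.0 / rate)
    trials = pd.DataFrame(
        {
            "stimulus_id": [f"s{k % 4}" for k in range(n_trials)],
            "category": ["human_face"] * n_trials,
            "run": [k // 4 for k in range(n_trials)],
            "repeat": [k % 2 for k in range(n_trials)],
        }
    )
    return SensorEpochs(data, times, trials, rate)


class TestStimulusSet:
    def test_canonical_design_counts_and_yoking(self):
        s = p.make_stimulus_set(32)
        assert len(s) == 96
        for cat in p.CATEGORIES:
            assert len(s.by_category(cat)) == 32
        for ill in s.by_category("illusory_face"):
            mate = s.yoke_of(ill)
            assert s.category_of(mate) == "matched_object"
            assert s.yoke_of(mate) == ill

    def test_orphan_yoke_rejected(self):
        items = [
            StimulusItem("h0", "human_face"),
            StimulusItem("i0", "illusory_face", "m0"),
            StimulusItem("m1", "matched_object", "i1"),
        ]
        with pytest.raises(ValidationError, match="orphan"):
            StimulusSet(items)


class TestEpochIO:
    @pytest.mark.parametrize("suffix", [".h5", ".npz"])
    def test_round_trip_lossless(self, tmp_path, suffix):
        ep = _toy_epochs()
        path = tmp_path / f"ep{suffix}"
        write_epochs(ep, path)
        back = read_epochs(path)
        np.testing.assert_array_equal(back.data, ep.data)
        np.testing.assert_array_equal(back.times_ms, ep.times_ms)
        assert back.sample_rate_hz == ep.sample_rate_hz
        pd.testing.assert_frame_equal(
            back.trials[["stimulus_id", "run", "repeat"]],
            ep.trials[["stimulus_id", "run", "repeat"]],
        )

    def test_short_trial_table_rejected_naming_trials(self):
        ep = _toy_epochs()
        with pytest.raises(ValidationError, match="trials"):
            SensorEpochs(
                ep.data, ep.times_ms, ep.trials.iloc[:-1], ep.sample_rate_hz
            )

    def test_downsampled_epochs_report_200hz(self, tmp_path):
        """A 5 ms grid after 1000->200 Hz downsampling round-trips as 200 Hz."""
        ep = _toy_epochs(n_t=20, rate=1000.0)
        ds = downsample(ep, 200.0)
        path = tmp_path / "ds.h5"
        write_epochs(ds, path)
        back = read_epochs(path)
        assert back.sample_rate_hz == 200.0
        assert np.allclose(np.diff(back.times_ms), 5.0)

    def test_non_uniform_times_rejected(self):
        ep = _toy_epochs()
        times = ep.times_ms.copy()
        times[3] += 0.5
        with pytest.raises(ValidationError, match="times_ms"):
            SensorEpochs(ep.data, times, ep.trials, ep.sample_rate_hz)


class TestRDMIO:
    def test_zero_matrix_round_trip(self, tmp_path):
        rdm = RDM(np.zeros((3, 3)), ["a", "b", "c"])
        path = tmp_path / "rdm.csv"
        write_rdm(rdm, path)
        back = read_rdm(path)
        np.testing.assert_array_equal(back.matrix, rdm.matrix)
        assert back.labels == rdm.labels

    def test_asymmetric_input_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(",a,b\na,0,0.2\nb,0.3,0\n")
        with pytest.raises(ValidationError, match="asymmetric"):
            read_rdm(path)

    def test_large_random_rdm_round_trip(self, tmp_path, rng):
        n = 96
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        rdm = RDM(m, [f"s{k:03d}" for k in range(n)])
        path = tmp_path / "big.csv"
        write_rdm(rdm, path)
        back = read_rdm(path)
        assert np.max(np.abs(back.matrix - rdm.matrix)) < 1e-12

    def test_nan_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.nan
        with pytest.raises(ValidationError):
            RDM(m, ["a", "b", "c"])


class TestManifest:
    def test_full_manifest_round_trip(self, tmp_path):
        s = p.make_stimulus_set(32)
        path = tmp_path / "manifest.csv"
        write_stimulus_manifest(s, path)
        back = load_stimulus_manifest(path)
        assert len(back) == 96
        for cat in p.CATEGORIES:
            assert len(back.by_category(cat)) == 32

    def test_orphan_in_manifest_rejected(self, tmp_path):
        s = p.make_stimulus_set(2)
        path = tmp_path / "manifest.csv"
        write_stimulus_manifest(s, path)
        df = pd.read_csv(path)
        df.loc[df["id"] == "matched_00", "id"] = "matched_xx"
        df.loc[df["id"] == "matched_xx", "yoke_id"] = "illusory_xx"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError):
            load_stimulus_manifest(path)

    def test_toy_manifest_usable_downstream(self, tmp_path, tiny_stimuli):
        """A 6-item manifest yields a set accepted by fold construction."""
        path = tmp_path / "toy.csv"
        write_stimulus_manifest(tiny_stimuli, path)
        back = load_stimulus_manifest(path)
        plan = p.make_folds(back, ("illusory_face", "matched_object"))
        assert len(plan) == 2
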