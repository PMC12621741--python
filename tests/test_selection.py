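"""Channel summaries, recommendations, and event curation."""

import numpy as np
import pandas as pd
import pytest

from lfpevents.core import ConfigurationError, EventTable, default_event_row
from lfpevents.csd import CsdParams, standard_csd
from lfpevents.preprocess import BandProfile
from lfpevents.selection import (add_event, interval_csd, recommend_channels,
                                 set_event_status, summarize_channels)


def _profile(theta, ripple):
    raw = pd.DataFrame({"theta": theta, "ripple": ripple})
    raw.index.name = "channel"
    return BandProfile(raw=raw, normalized=raw / raw.max())


def _ds_table(rows):
    return EventTable.from_rows(
        [default_event_row(event_id=i, **r) for i, r in enumerate(rows)])


class TestSummary:
    def test_counts_and_means(self):
        ds = _ds_table([
            {"kind": "ds", "channel": 1, "sample_index": 100, "time_s": 0.1,
             "amplitude_mV": 1.0},
            {"kind": "ds", "channel": 1, "sample_index": 300, "time_s": 0.3,
             "amplitude_mV": 2.0},
            {"kind": "ds", "channel": 1, "sample_index": 600, "time_s": 0.6,
             "amplitude_mV": 3.0},
        ])
        prof = _profile([1.0, 2.0, 1.0], [0.5, 0.5, 2.0])
        out = summarize_channels(ds, EventTable(), prof)
        assert out.loc[1, "ds_count"] == 3
        assert out.loc[1, "ds_mean_amplitude"] == pytest.approx(2.0)
        assert out.loc[0, "ds_count"] == 0
        assert np.isnan(out.loc[0, "ds_mean_amplitude"])

    def test_ratio_column(self):
        out = summarize_channels(EventTable(), EventTable(),
                                 _profile([2.0, 4.0], [1.0, 1.0]))
        np.testing.assert_allclose(out["ripple_theta_ratio"], [0.5, 0.25])

    def test_ds_count_peaks_at_hilus(self, sim120, processed120):
        """The hilus attains the maximal DS count (deep channels saturate
        together since the dipole LFP spreads below the sink), while
        channels above the fissure stay event-free."""
        summary = summarize_channels(processed120.ds_table,
                                     processed120.swr_table,
                                     processed120.band_profile)
        cfg = sim120.config
        counts = summary["ds_count"]
        assert counts[cfg.hilus_channel] == counts.max()
        assert (counts[:cfg.fissure_channel] == 0).all()


class TestRecommend:
    def test_simulator_ground_truth(self, sim120, processed120):
        summary = summarize_channels(processed120.ds_table,
                                     processed120.swr_table,
                                     processed120.band_profile)
        choice = recommend_channels(summary, processed120.band_profile)
        cfg = sim120.config
        assert choice.theta_channel == cfg.fissure_channel
        assert choice.swr_channel == cfg.ca1_channel
        assert choice.ds_channel == cfg.hilus_channel

    def test_ratio_tie_goes_to_shallower(self):
        prof = _profile([1.0, 2.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0])
        ds = _ds_table([{"kind": "ds", "channel": 2, "sample_index": 10,
                         "time_s": 0.01, "amplitude_mV": 1.0},
                        {"kind": "ds", "channel": 3, "sample_index": 500,
                         "time_s": 0.5, "amplitude_mV": 1.0}])
        out = summarize_channels(ds, EventTable(), prof)
        # ripple/theta ratio ties between channels 0, 2, 3 -> channel 0
        choice = recommend_channels(out, prof)
        assert choice.swr_channel == 0
        assert choice.theta_channel == 1
        # DS amplitude ties between 2 and 3 (both deeper than theta) -> 2
        assert choice.ds_channel == 2

    def test_no_deeper_channel_falls_back_globally(self):
        prof = _profile([1.0, 1.0, 2.0], [1.0, 0.5, 0.5])
        ds = _ds_table([{"kind": "ds", "channel": 0, "sample_index": 10,
                         "time_s": 0.01, "amplitude_mV": 2.0}])
        out = summarize_channels(ds, EventTable(), prof)
        choice = recommend_channels(out, prof)
        assert choice.theta_channel == 2
        assert choice.ds_channel == 0       # global argmax, with a warning


class TestAddEvent:
    fs = 1000.0

    def _bump(self, apex_s, dur=10.0):
        t = np.arange(int(dur * self.fs)) / self.fs
        return np.exp(-0.5 * ((t - apex_s) / 0.005) ** 2)

    def test_time_at_existing_peak(self):
        raw = self._bump(5.0)
        out = add_event(EventTable(), 0, 5.0, "ds", raw, self.fs)
        assert int(out.df.loc[0, "sample_index"]) == int(np.argmax(raw))
        assert out.df.loc[0, "origin"] == "manual"

    def test_click_before_apex_lands_on_apex(self):
        raw = self._bump(5.0)
        out = add_event(EventTable(), 0, 4.990, "ds", raw, self.fs)
        assert int(out.df.loc[0, "sample_index"]) == int(np.argmax(raw))

    def test_flat_region_uses_nearest_sample(self):
        raw = np.zeros(10000)
        out = add_event(EventTable(), 0, 3.0, "ds", raw, self.fs)
        assert int(out.df.loc[0, "sample_index"]) == 3000
        assert np.isnan(out.df.loc[0, "prominence_mV"])

    def test_duplicate_rejected(self):
        raw = self._bump(5.0)
        table = add_event(EventTable(), 0, 5.0, "ds", raw, self.fs)
        with pytest.raises(ConfigurationError, match="already exists"):
            add_event(table, 0, 5.01, "ds", raw, self.fs)

    def test_out_of_range_time_rejected(self):
        with pytest.raises(ConfigurationError):
            add_event(EventTable(), 0, 99.0, "ds", np.zeros(100), self.fs)


class TestCuration:
    def _table(self, n=10):
        return _ds_table([{"kind": "ds", "channel": 0, "sample_index": i * 100,
                           "time_s": i * 0.1, "amplitude_mV": 1.0}
                          for i in range(n)])

    def test_delete_then_restore_is_identity(self):
        t0 = self._table()
        t1 = set_event_status(t0, [2, 5], "delete")
        t2 = set_event_status(t1, [2, 5], "restore")
        pd.testing.assert_frame_equal(t0.df, t2.df)

    def test_delete_bookkeeping(self):
        t1 = set_event_status(self._table(10), [0, 1, 2], "delete")
        assert (t1.df["status"] == "deleted").sum() == 3
        assert len(t1.active()) == 7
        assert len(t1) == 10

    def test_erase_then_restore_errors(self):
        t1 = set_event_status(self._table(), [4], "erase")
        assert 4 not in t1.df["event_id"].values
        with pytest.raises(ConfigurationError, match="erased"):
            set_event_status(t1, [4], "restore")

    def test_unknown_id_rejected(self):
        with pytest.raises(ConfigurationError):
            set_event_status(self._table(), [99], "delete")

    def test_random_curation_sequence_stays_schema_valid(self, rng):
        table = self._table(12)
        ids = list(range(12))
        for _ in range(30):
            action = rng.choice(["delete", "restore"])
            pick = rng.choice(ids, size=2, replace=False)
            table = set_event_status(table, pick, action)
            assert set(table.df["status"]) <= {"active", "deleted"}
            assert len(table) == 12


class TestIntervalCsd:
    def test_slice_equals_full_restricted(self, rng):
        data = rng.normal(size=(8, 2000))
        z = np.arange(8) * 50.0
        p = CsdParams()
        full = standard_csd(data, 50.0, p)
        part = interval_csd(data, 1000.0, np.arange(8), z, 0.5, 1.0, p)
        np.testing.assert_allclose(part, full[:, 500:1000], rtol=1e-12)

    def test_empty_interval_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            interval_csd(rng.normal(size=(8, 100)), 1000.0, np.arange(8),
                         np.arange(8) * 50.0, 0.05, 0.05)
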