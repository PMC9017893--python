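"""MEP pipeline: extraction, exclusion rules, RT matching, normalization, maps."""

import numpy as np
import pandas as pd
import pytest

from satmep import mep
from satmep.cohort import mep_template


def flat_trace(channels=("fdi_left",), value=0.0, n=8000):
    return mep.EmgTrace(list(channels), np.full((len(channels), n), value))


class TestTraceAndPreactivation:
    def test_segment_bounds_checked(self):
        trace = flat_trace()
        with pytest.raises(IndexError):
            trace.segment("fdi_left", -2000, -1800)
        with pytest.raises(IndexError):
            trace.segment("fdi_left", 2100, 2300)

    def test_flat_traces_never_flagged(self):
        rms = [mep.preactivation_rms(flat_trace(value=2.0), "fdi_left", 0.0)] * 50
        assert not mep.flag_preactivated(rms).any()

    def test_injected_burst_is_flagged(self, rng):
        values = []
        for i in range(100):
            samples = rng.normal(0, 2.0, size=(1, 8000))
            trace = mep.EmgTrace(["m"], samples)
            if i == 42:  # 10x burst inside the screening window
                t0 = trace._index(-200.0)
                samples[0, t0 : t0 + 200] += 20.0
            values.append(mep.preactivation_rms(trace, "m", 0.0))
        flags = mep.flag_preactivated(values)
        assert flags[42]
        assert flags.sum() <= 2

    def test_burst_after_pulse_not_flagged(self, rng):
        values = []
        for i in range(50):
            samples = rng.normal(0, 2.0, size=(1, 8000))
            trace = mep.EmgTrace(["m"], samples)
            if i == 7:  # burst after the pulse: outside [-250, -50]
                t0 = trace._index(30.0)
                samples[0, t0 : t0 + 200] += 20.0
            values.append(mep.preactivation_rms(trace, "m", 0.0))
        assert not mep.flag_preactivated(values)[7]


class TestAmplitude:
    def test_biphasic_peak_to_peak(self):
        samples = np.zeros((1, 8000))
        trace = mep.EmgTrace(["m"], samples)
        i = trace._index(25.0)
        samples[0, i] = 120.0
        samples[0, i + 10] = -80.0
        assert mep.extract_mep_amplitude(trace, "m", 0.0) == pytest.approx(200.0)

    def test_flat_signal_zero(self):
        assert mep.extract_mep_amplitude(flat_trace(), "fdi_left", 0.0) == 0.0

    def test_template_recovery_in_noise(self, rng):
        template = mep_template()
        gain, sigma = 650.0, 3.0
        recovered = []
        for _ in range(30):
            samples = rng.normal(0, sigma, size=(1, 8000))
            trace = mep.EmgTrace(["m"], samples)
            i = trace._index(20.0)
            samples[0, i : i + len(template)] += gain * template
            recovered.append(mep.extract_mep_amplitude(trace, "m", 0.0))
        # template has unit peak-to-peak; noise adds a small positive bias
        assert np.mean(recovered) == pytest.approx(gain, abs=3 * sigma)

    def test_outlier_rejection(self, rng):
        amps = np.r_[rng.normal(100, 10, size=99), 500.0]
        flags = mep.flag_amplitude_outliers(amps)
        assert flags[-1]
        assert flags[:99].sum() <= 2
        assert not mep.flag_amplitude_outliers(np.full(20, 80.0)).any()
        with pytest.warns(UserWarning):
            assert not mep.flag_amplitude_outliers([1.0, 2.0]).any()


def inclusion_frame(rts, participant=0, context="hasty"):
    return pd.DataFrame(
        {
            "participant": participant,
            "context": context,
            "trial": np.arange(len(rts)),
            "trial_type": "ambiguous",
            "tms_event": "jump7",
            "rt_ms": rts,
            "no_response": False,
        }
    )


class TestInclusion:
    @pytest.mark.parametrize(
        "rt, kept", [(1349.0, False), (1350.0, True), (2800.0, True), (2801.0, False)]
    )
    def test_rt_window_is_closed_interval(self, rt, kept):
        retained, _ = mep.filter_inclusion(inclusion_frame([rt]))
        assert (len(retained) == 1) is kept

    def test_non_ambiguous_and_no_response_dropped(self):
        df = inclusion_frame([2000.0, 2000.0, 2000.0])
        df.loc[0, "trial_type"] = "obvious"
        df.loc[1, "no_response"] = True
        retained, _ = mep.filter_inclusion(df)
        assert retained["trial"].tolist() == [2]

    def test_low_trial_count_participant_flagged(self, rng):
        frames = []
        # participant 1: 40 trials over 6 timing x context cells -> mean 6.7 < 8
        for p, n in [(0, 60), (1, 20)]:
            for ctx in ("hasty", "cautious"):
                df = inclusion_frame(
                    rng.uniform(1400, 2700, size=n), participant=p, context=ctx
                )
                df["tms_event"] = rng.choice(["jump1", "jump4", "jump7"], size=n)
                frames.append(df)
        retained, excluded = mep.filter_inclusion(pd.concat(frames))
        assert excluded == [1]
        assert 0 in retained["participant"].values


class TestRtMatch:
    def test_per_bin_minimum_counts(self, rng):
        # bins (x100 ms): A has {5 in [0,200), 3 in [200,400)}, B has {2, 7}
        rt_a = np.r_[np.full(5, 100.0), np.full(3, 300.0)]
        rt_b = np.r_[np.full(2, 150.0), np.full(7, 250.0)]
        ia, ib = mep.rt_match(rt_a, rt_b, rng)
        assert len(ia) == len(ib) == 5
        for b in (0, 1):
            in_a = np.floor(rt_a[ia] / 200).astype(int)
            in_b = np.floor(rt_b[ib] / 200).astype(int)
            assert (in_a == b).sum() == (in_b == b).sum()

    def test_identical_sets_returned_whole(self, rng):
        rt = np.array([1400.0, 1600.0, 1800.0, 2300.0])
        ia, ib = mep.rt_match(rt, rt.copy(), rng)
        assert len(ia) == len(ib) == 4

    def test_disjoint_ranges_warn_and_empty(self, rng):
        with pytest.warns(UserWarning):
            ia, ib = mep.rt_match([1400.0] * 5, [2600.0] * 5, rng)
        assert len(ia) == 0 and len(ib) == 0

    def test_matched_means_close(self, rng):
        rt_a = rng.uniform(1350, 2800, size=200)
        rt_b = rng.uniform(1600, 2800, size=150)
        ia, ib = mep.rt_match(rt_a, rt_b, rng)
        assert abs(rt_a[ia].mean() - rt_b[ib].mean()) < 200.0


def mep_frame(amplitude, rts, participant=0, muscle="index", side="right"):
    n = len(rts)
    frames = []
    for ctx in ("hasty", "cautious"):
        frames.append(
            pd.DataFrame(
                {
                    "participant": participant,
                    "context": ctx,
                    "trial": np.arange(n),
                    "tms_event": "jump7",
                    "rt_ms": rts,
                    "muscle": muscle,
                    "body_side": side,
                    "side_class": "chosen",
                    "amplitude_uv": amplitude,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestAggregationAndNormalization:
    def test_constant_amplitudes_survive_aggregation(self, rng):
        df = mep_frame(77.0, rng.uniform(1400, 2700, 30))
        out = mep.aggregate_iterations(df, rng, n_iter=5)
        assert np.allclose(out["amplitude_uv"], 77.0)

    def test_equal_sets_independent_of_iterations(self, rng):
        rts = np.linspace(1400, 2700, 25)
        df = mep_frame(np.linspace(50, 150, 25), rts)
        out1 = mep.aggregate_iterations(df, np.random.default_rng(1), n_iter=1)
        out2 = mep.aggregate_iterations(df, np.random.default_rng(2), n_iter=20)
        # identical RT distributions across contexts -> deterministic match
        pd.testing.assert_frame_equal(out1, out2)

    def test_normalize_baseline_percent(self):
        keys = {"participant": [0], "muscle": ["index"], "body_side": ["right"],
                "context": ["hasty"]}
        base = pd.DataFrame({**keys, "amplitude_uv": [50.0]})
        rest = pd.DataFrame({**keys, "amplitude_uv": [100.0]})
        out = mep.normalize_baseline(base, rest)
        assert out["percent"].iloc[0] == pytest.approx(50.0)

    def test_normalize_deliberation_and_pooling(self):
        rows = []
        for side, amp in [("left", 120.0), ("right", 90.0)]:
            rows.append(
                {
                    "participant": 0, "muscle": "index", "body_side": side,
                    "side_class": "chosen", "tms_event": "jump7",
                    "context": "hasty", "amplitude_uv": amp,
                }
            )
        delib = pd.DataFrame(rows)
        base = pd.DataFrame(
            [
                {"participant": 0, "muscle": "index", "body_side": "left",
                 "context": "hasty", "amplitude_uv": 100.0},
                {"participant": 0, "muscle": "index", "body_side": "right",
                 "context": "hasty", "amplitude_uv": 60.0},
            ]
        )
        out = mep.normalize_deliberation(delib, base)
        # per-hand percents (120 and 150) averaged after normalization
        assert out["percent"].iloc[0] == pytest.approx((120.0 + 150.0) / 2)

    def test_normalization_scale_invariance(self, rng):
        delib = mep_frame(rng.uniform(50, 150, 30), rng.uniform(1400, 2700, 30))
        base = (
            delib.groupby(["participant", "muscle", "body_side", "context"])[
                "amplitude_uv"
            ]
            .median()
            .reset_index()
        )
        out1 = mep.normalize_deliberation(delib, base)
        scaled = delib.assign(amplitude_uv=delib["amplitude_uv"] * 3.7)
        base_scaled = base.assign(amplitude_uv=base["amplitude_uv"] * 3.7)
        out2 = mep.normalize_deliberation(scaled, base_scaled)
        assert np.allclose(out1["percent"], out2["percent"])

    def test_zero_denominator_rejected(self):
        keys = {"participant": [0], "muscle": ["index"], "body_side": ["right"],
                "context": ["hasty"]}
        base = pd.DataFrame({**keys, "amplitude_uv": [50.0]})
        rest = pd.DataFrame({**keys, "amplitude_uv": [0.0]})
        with pytest.raises(mep.NormalizationError):
            mep.normalize_baseline(base, rest)


def full_map_table(value=100.0):
    rows = []
    for muscle, side in mep.SOMATOTOPIC_ORDER:
        for timing in ("jump1", "jump4", "jump7"):
            for context in ("hasty", "cautious"):
                rows.append(
                    {
                        "participant": 0, "muscle": muscle, "side_class": side,
                        "tms_event": timing, "context": context, "percent": value,
                    }
                )
    return pd.DataFrame(rows)


class TestSpatiotemporalMap:
    def test_uniform_table_gives_zero_difference(self):
        grids = mep.spatiotemporal_map(full_map_table())
        assert np.allclose(grids["difference"], 0.0)
        assert np.allclose(grids["hasty"], 100.0)

    def test_interpolation_exact_at_nodes_and_peak_at_perturbed_cell(self):
        table = full_map_table()
        hit = (
            (table["muscle"] == "index")
            & (table["side_class"] == "chosen")
            & (table["tms_event"] == "jump7")
            & (table["context"] == "hasty")
        )
        table.loc[hit, "percent"] += 10.0
        grids = mep.spatiotemporal_map(table)
        diff = grids["difference"]
        si = list(mep.SOMATOTOPIC_ORDER).index(("index", "chosen"))
        node_rows = np.isin(grids["space_axis"], np.arange(8))
        node_cols = np.isin(grids["time_axis"], np.arange(3))
        # corners equal the raw cell values
        assert diff[node_rows][:, node_cols][si, 2] == pytest.approx(10.0)
        # the perturbed node is the global maximum
        r, c = np.unravel_index(np.argmax(diff), diff.shape)
        assert grids["space_axis"][r] == si
        assert grids["time_axis"][c] == 2

    def test_missing_cell_is_named(self):
        table = full_map_table()
        table = table[~((table["muscle"] == "leg") & (table["side_class"] == "unchosen")
                        & (table["tms_event"] == "jump4")
                        & (table["context"] == "cautious"))]
        with pytest.raises(mep.MapError, match="leg.*unchosen.*jump4|jump4.*leg"):
            mep.spatiotemporal_map(table)
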