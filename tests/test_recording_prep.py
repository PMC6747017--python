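"""Amplifier alignment, filtering and channel-discard criteria."""

import numpy as np
import pytest

from earshell.inverse_eval import Recording
from earshell.recording_prep import (
    ChannelMask,
    TriggerTrack,
    assr_discard,
    cascade_recordings,
    drop_saturated,
    estimate_rate_ratio,
    filter_chain,
    merge_recordings,
    spectral_f_test,
)


def trigger_train(rate, f_trig=8.0, duration=20.0, offset=0):
    return np.round(np.arange(0, duration * f_trig) * rate / f_trig).astype(int) + offset


# ------------------------------------------------------------- rate ratio


def test_identical_tracks_ratio_one():
    t = TriggerTrack(np.arange(0, 10000, 250), 2000.0)
    assert estimate_rate_ratio(t, t) == 1.0


def test_rate_ratio_recovers_2000_over_2048():
    events = np.arange(100) * 1.0  # seconds
    a = TriggerTrack(np.round(events * 2000).astype(int), 2000.0)
    b = TriggerTrack(np.round(events * 2048).astype(int), 2048.0)
    assert abs(estimate_rate_ratio(a, b) - 2000 / 2048) < 1e-6


def test_rate_ratio_needs_two_triggers():
    with pytest.raises(ValueError):
        estimate_rate_ratio(TriggerTrack([5], 100.0), TriggerTrack([5], 100.0))
    with pytest.raises(ValueError):
        estimate_rate_ratio(
            TriggerTrack([1, 2], 100.0), TriggerTrack([1, 2, 3], 100.0)
        )


# ------------------------------------------------------------------ merge


def two_amp_setup(duration=4.5, f=10.0):
    """Two amplifiers sampling the same physical 10 Hz signal at 2000 and
    2048 Hz, with triggers marking the same absolute events."""
    events_s = [0.5, 4.0]
    recs, trks = [], []
    for rate, label in ((2000.0, "C1"), (2048.0, "C2")):
        t = np.arange(int(rate * duration)) / rate
        recs.append(
            Recording(
                np.vstack([np.sin(2 * np.pi * f * t), np.zeros_like(t)]),
                rate, [label, "FPz"],
            )
        )
        trks.append(TriggerTrack([round(e * rate) for e in events_s], rate))
    return recs, trks


def test_merge_preserves_sine_amplitude():
    recs, trks = two_amp_setup()
    merged = merge_recordings(recs, trks, target_rate=500.0, ref_label="FPz")
    assert merged.rate == 500.0
    seg = merged.data[merged.labels.index("C1")][200:1500]
    assert abs(np.sqrt(2) * seg.std() - 1.0) < 0.01


def test_merge_aligns_streams_within_one_sample():
    recs, trks = two_amp_setup()
    merged = merge_recordings(recs, trks, target_rate=500.0, ref_label="FPz")
    c1 = merged.data[merged.labels.index("C1")][100:1500]
    c2 = merged.data[merged.labels.index("C2")][100:1500]
    # a 1-sample lag at 500 Hz shifts a 10 Hz sine by 7.2 degrees
    # (correlation 0.992); aligned streams must beat that
    assert np.corrcoef(c1, c2)[0, 1] > 0.995


def test_merge_reference_channel_rows_zero():
    recs, trks = two_amp_setup()
    merged = merge_recordings(recs, trks, target_rate=500.0, ref_label="FPz")
    assert merged.labels.count("FPz") == 1
    assert np.abs(merged.data[merged.labels.index("FPz")]).max() < 1e-12


def test_merge_single_recording_at_target_is_lossless():
    n = 2000
    data = np.vstack([np.sin(np.arange(n) / 7.0), np.zeros(n)])
    rec = Recording(data, 500.0, ["C1", "FPz"])
    trk = TriggerTrack([0, n - 1], 500.0)
    merged = merge_recordings([rec], [trk], target_rate=500.0, ref_label="FPz")
    np.testing.assert_allclose(
        merged.data[0], data[0, : merged.n_samples], atol=1e-12
    )


def test_merge_requires_reference_channel():
    rec = Recording(np.zeros((1, 100)), 500.0, ["C1"])
    with pytest.raises(ValueError, match="FPz"):
        merge_recordings([rec], [TriggerTrack([0, 99], 500.0)])


def test_cascade_concatenates_segments():
    a = Recording(np.ones((2, 100)), 500.0, ["x", "y"], triggers=[0, 50])
    b = Recording(2 * np.ones((2, 50)), 500.0, ["x", "y"], triggers=[10])
    out = cascade_recordings([a, b])
    assert out.n_samples == 150
    assert list(out.triggers) == [0, 50, 110]


# ------------------------------------------------------------------ filter


def test_filter_chain_attenuates_50hz():
    t = np.arange(5000) / 500.0
    rec = Recording(np.vstack([np.sin(2 * np.pi * 50 * t)] * 2), 500.0, ["x", "y"])
    out = filter_chain(rec)
    att = 20 * np.log10(
        rec.data[0].std() / (out.data[0][500:-500].std() + 1e-300)
    )
    assert att >= 40.0


def test_filter_chain_removes_dc():
    offsets = np.array([[50.0], [100.0], [-30.0]])
    rec = Recording(np.tile(offsets, (1, 4000)), 500.0, list("abc"))
    out = filter_chain(rec)
    assert np.abs(out.data.mean(axis=1)).max() < 1e-6 * 100.0


def test_filter_chain_average_reference():
    rng = np.random.default_rng(1)
    rec = Recording(rng.normal(size=(4, 3000)), 500.0, list("abcd"))
    out = filter_chain(rec)
    assert np.abs(out.data.mean(axis=0)).max() < 1e-10


def test_filter_chain_drops_notches_above_nyquist():
    rec = Recording(np.random.default_rng(0).normal(size=(2, 2000)), 300.0, ["x", "y"])
    with pytest.warns(RuntimeWarning, match="Nyquist"):
        filter_chain(rec)


# -------------------------------------------------------------- saturation


def test_clean_channels_kept():
    t = np.arange(1000) / 500.0
    rec = Recording(np.vstack([np.sin(7 * t), np.cos(9 * t)]), 500.0, ["x", "y"])
    mask = drop_saturated(rec, rail=1.5, dwell=10)
    assert mask.keep.all()


def test_clipped_channel_flagged():
    data = np.random.default_rng(0).normal(0, 0.1, (3, 1000))
    data[1, 300:551] = 1.0  # 0.5 s at the rail at 500 Hz
    rec = Recording(data, 500.0, list("abc"))
    mask = drop_saturated(rec, rail=1.0, dwell=250)
    assert list(mask.keep) == [True, False, True]
    assert mask.reasons[1] == "saturated"


def test_single_spike_survives_dwell():
    data = np.zeros((1, 1000))
    data[0, 500] = 1.0
    rec = Recording(data, 500.0, ["x"])
    assert drop_saturated(rec, rail=1.0, dwell=10).keep.all()


def test_mask_apply_subsets_recording():
    rec = Recording(np.arange(30.0).reshape(3, 10), 500.0, list("abc"))
    mask = ChannelMask(list("abc"), [True, False, True])
    out = mask.apply(rec)
    assert out.labels == ["a", "c"]
    assert out.data.shape == (2, 10)


# -------------------------------------------------------------------- ASSR


def assr_recording(amps, rate=500.0, duration=20.0, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    n = int(rate * duration)
    trig = trigger_train(rate, duration=duration)
    t = np.arange(n) / rate
    data = rng.normal(0, 1.0, (len(amps), n))
    for ch, amp in enumerate(amps):
        data[ch] += amp * np.sin(2 * np.pi * 40.0 * t)
    labels = labels or [f"g{i}" for i in range(len(amps))]
    return Recording(data, rate, labels, triggers=trig)


def test_channels_with_response_kept():
    rec = assr_recording([0.3, 0.45, 0.6, 0.0, 0.0])
    mask = assr_discard(rec, {"grp": rec.labels})
    assert mask.keep[:3].all()


def test_pure_noise_group_discarded():
    # the any-pair rule is deliberately liberal (no multiple-comparison
    # correction), so a noise-only group passes occasionally by chance;
    # the fixed seed makes this specific draw deterministic
    rec = assr_recording([0.0, 0.0, 0.0, 0.0], seed=0)
    mask = assr_discard(rec, {"grp": rec.labels})
    assert not mask.keep.any()
    assert all(r == "assr-nonsignificant" for r in mask.reasons)


def test_assr_invariant_to_channel_order():
    rec = assr_recording([0.5, 0.0, 0.4, 0.0], seed=5)
    m1 = assr_discard(rec, {"grp": rec.labels})
    m2 = assr_discard(rec, {"grp": rec.labels[::-1]})
    assert list(m1.keep) == list(m2.keep)


def test_overlapping_groups_any_pass_rule():
    """A channel in two groups survives if significant in either."""
    rec = assr_recording([0.6, 0.0, 0.0, 0.0, 0.0],
                         labels=["mid", "l1", "l2", "r1", "r2"])
    groups = {"left": ["mid", "l1", "l2"], "right": ["mid", "r1", "r2"]}
    mask = assr_discard(rec, groups)
    assert mask.keep[rec.labels.index("mid")]


def test_spectral_f_test_type_one_rate():
    rate, duration = 500.0, 20.0
    trig = trigger_train(rate, duration=duration)
    n = int(rate * duration)
    rejections = 0
    trials = 400
    for seed in range(trials):
        x = np.random.default_rng(seed).normal(size=n)
        _, p = spectral_f_test(x, rate, trig)
        rejections += p < 0.05
    rate_hat = rejections / trials
    ci = 3 * np.sqrt(0.05 * 0.95 / trials)
    assert abs(rate_hat - 0.05) < ci


def test_group_too_small_rejected():
    rec = assr_recording([0.1])
    with pytest.raises(ValueError, match="fewer than 2"):
        assr_discard(rec, {"grp": rec.labels})


def test_f_mod_above_nyquist_rejected():
    rec = assr_recording([0.1, 0.1], rate=60.0)
    with pytest.raises(ValueError, match="Nyquist"):
        assr_discard(rec, {"grp": rec.labels}, f_mod=40.0)
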