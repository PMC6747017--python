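"""Multi-amplifier EEG alignment, filtering and channel discarding.

Concurrent recordings from separate amplifiers drift apart because
their sampling clocks differ slightly from nominal.  A shared trigger
signal pins the streams together: the ratio of sample counts between
the first and last trigger gives the true rate ratio, after which the
streams are resampled to a common rate, aligned on the first trigger,
referenced to the shared reference electrode and stacked into one
joint recording.

Channel discarding follows two criteria: amplifier saturation (dwell
at the rails), and absence of a statistically significant auditory
steady-state response (ASSR) in every bipolar configuration the
channel participates in within its electrode group.  The ASSR detector
is a spectral F test: epochs time-locked to the stimulus trigger are
averaged, and the power at the modulation frequency is compared with
the mean power of K neighbouring bins via an F(2, 2K) statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy import signal as sps
from scipy import stats

from .inverse_eval import Recording

__all__ = [
    "TriggerTrack",
    "ChannelMask",
    "estimate_rate_ratio",
    "merge_recordings",
    "cascade_recordings",
    "filter_chain",
    "drop_saturated",
    "assr_discard",
    "spectral_f_test",
]


@dataclass
class TriggerTrack:
    """Trigger event sample indices in one amplifier's stream."""

    indices: np.ndarray
    rate: float

    def __post_init__(self):
        self.indices = np.asarray(self.indices, np.int64)
        if (np.diff(self.indices) <= 0).any():
            raise ValueError("trigger indices must increase strictly")
        if self.rate <= 0:
            raise ValueError("nominal rate must be positive")

    def __len__(self):
        return len(self.indices)

    @property
    def span(self) -> int:
        if len(self.indices) < 2:
            raise ValueError("need >= 2 triggers to measure a span")
        return int(self.indices[-1] - self.indices[0])


@dataclass
class ChannelMask:
    """Per-channel keep/discard decision with a reason."""

    labels: list
    keep: np.ndarray
    reasons: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = list(self.labels)
        self.keep = np.asarray(self.keep, bool)
        if len(self.keep) != len(self.labels):
            raise ValueError("one flag per channel required")
        if not self.reasons:
            self.reasons = ["" for _ in self.labels]

    def kept_labels(self) -> list:
        return [s for s, k in zip(self.labels, self.keep) if k]

    def apply(self, rec: Recording) -> Recording:
        idx = np.where(self.keep)[0]
        return Recording(
            rec.data[idx], rec.rate, [rec.labels[i] for i in idx], rec.triggers
        )


def estimate_rate_ratio(a: TriggerTrack, b: TriggerTrack) -> float:
    """True sampling-rate ratio rate_a/rate_b from shared trigger spans.

    Both tracks must contain the same events; the ratio of sample
    counts between the first and last trigger equals the ratio of true
    sampling rates regardless of the nominal rates.
    """
    if len(a) != len(b):
        raise ValueError("trigger tracks have different event counts")
    if len(a) < 2:
        raise ValueError("need at least 2 triggers")
    return a.span / b.span


def _resample_to(data: np.ndarray, factor: float, max_denom: int = 10000) -> np.ndarray:
    frac = Fraction(factor).limit_denominator(max_denom)
    return sps.resample_poly(data, frac.numerator, frac.denominator, axis=-1)


def merge_recordings(
    recs, triggers, target_rate: float = 500.0, ref_label: str = "FPz"
) -> Recording:
    """Align, resample and stack multi-amplifier recordings.

    The first recording's nominal rate defines the master clock; each
    stream's effective rate follows from its trigger span relative to
    the master.  Streams are cropped at their first trigger, resampled
    to ``target_rate`` and referenced to ``ref_label`` (which every
    stream must contain; only the master's copy is kept -- the others
    are identically zero after referencing).
    """
    recs = list(recs)
    triggers = list(triggers)
    if len(recs) != len(triggers):
        raise ValueError("one trigger track per recording required")
    for rec in recs:
        if ref_label not in rec.labels:
            raise ValueError(f"reference channel {ref_label!r} missing")

    master = triggers[0]
    out_data, out_labels = [], []
    n_keep = None
    for i, (rec, trk) in enumerate(zip(recs, triggers)):
        eff_rate = rec.rate if i == 0 else rec.rate  # nominal, corrected below
        if i == 0:
            eff_rate = master.rate
        else:
            # same events, so rate_i = rate_master * span_i / span_master
            eff_rate = master.rate * estimate_rate_ratio(trk, master)
        cropped = rec.data[:, trk.indices[0] :]
        res = _resample_to(cropped, target_rate / eff_rate)
        ref = res[rec.labels.index(ref_label)]
        res = res - ref[None, :]
        keep = [
            j for j, lab in enumerate(rec.labels) if (lab != ref_label or i == 0)
        ]
        out_data.append(res[keep])
        out_labels.extend(rec.labels[j] for j in keep)
        n_keep = res.shape[1] if n_keep is None else min(n_keep, res.shape[1])
    data = np.vstack([d[:, :n_keep] for d in out_data])
    new_triggers = np.round(
        (master.indices - master.indices[0]) * target_rate / master.rate
    ).astype(np.int64)
    new_triggers = new_triggers[new_triggers < n_keep]
    return Recording(data, target_rate, out_labels, new_triggers)


def cascade_recordings(recs) -> Recording:
    """Concatenate stimulus segments (same channels and rate) in time."""
    recs = list(recs)
    first = recs[0]
    for rec in recs[1:]:
        if rec.labels != first.labels or rec.rate != first.rate:
            raise ValueError("cascaded recordings must share channels and rate")
    data = np.concatenate([r.data for r in recs], axis=1)
    trig, offset = [], 0
    for r in recs:
        trig.append(r.triggers + offset)
        offset += r.n_samples
    return Recording(data, first.rate, list(first.labels), np.concatenate(trig))


def filter_chain(
    rec: Recording,
    highpass_hz: float = 1.0,
    notch_hz=(50.0, 100.0, 150.0, 200.0),
) -> Recording:
    """Average reference, 1 Hz high-pass and power-line notch filters.

    All filters are Butterworth sections applied forward-backward
    (zero phase); notches above the Nyquist frequency are dropped with
    a warning.
    """
    import warnings

    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    # demean each channel before the IIR high-pass: removes the DC offset
    # exactly and keeps the filter's edge transients small
    data = data - data.mean(axis=1, keepdims=True)
    nyq = rec.rate / 2.0
    sos = sps.butter(2, highpass_hz / nyq, btype="highpass", output="sos")
    data = sps.sosfiltfilt(sos, data, axis=-1)
    for f0 in notch_hz:
        if f0 + 2.0 >= nyq:
            warnings.warn(
                f"notch at {f0} Hz above Nyquist ({nyq} Hz); dropped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        sos = sps.butter(
            2, [(f0 - 2.0) / nyq, (f0 + 2.0) / nyq], btype="bandstop", output="sos"
        )
        data = sps.sosfiltfilt(sos, data, axis=-1)
    return Recording(data, rec.rate, list(rec.labels), rec.triggers)


def drop_saturated(rec: Recording, rail: float, dwell: int) -> ChannelMask:
    """Flag channels that sit at the amplifier rails.

    A channel is discarded when it spends ``dwell`` or more consecutive
    samples within 1% of ``+-rail`` volts.
    """
    if rail <= 0:
        raise ValueError("rail must be positive")
    at_rail = np.abs(rec.data) >= 0.99 * rail
    keep = np.ones(rec.n_channels, bool)
    reasons = []
    for ch in range(rec.n_channels):
        run = _longest_run(at_rail[ch])
        if run >= dwell:
            keep[ch] = False
            reasons.append("saturated")
        else:
            reasons.append("")
    return ChannelMask(list(rec.labels), keep, reasons)


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(np.int8), [0]])
    edges = np.diff(padded)
    starts = np.where(edges == 1)[0]
    ends = np.where(edges == -1)[0]
    return int((ends - starts).max())


def spectral_f_test(
    x: np.ndarray,
    rate: float,
    triggers: np.ndarray,
    f_mod: float = 40.0,
    n_periods: int = 8,
    n_neighbors: int = 12,
):
    """ASSR detection statistic for one (bipolar) signal.

    Epochs of ``n_periods`` trigger periods, time-locked to the trigger
    train, are averaged; the power of the averaged response at ``f_mod``
    is divided by the mean power of ``n_neighbors`` frequency bins (the
    nearest bin on each side is excluded as spectral-leakage guard).
    Under the no-response null the statistic follows
    ``F(2, 2 n_neighbors)``.

    Returns ``(F, p)``.
    """
    triggers = np.asarray(triggers, np.int64)
    if len(triggers) < 2:
        raise ValueError("need a trigger train for epoching")
    period = float(np.median(np.diff(triggers)))
    ep_len = int(round(period * n_periods))
    if ep_len < 4:
        raise ValueError("epoch too short")
    starts = triggers[:: n_periods]
    starts = starts[starts + ep_len <= len(x)]
    if len(starts) == 0:
        raise ValueError("no complete epochs")
    epochs = np.stack([x[s : s + ep_len] for s in starts])
    avg = epochs.mean(axis=0)

    spec = np.fft.rfft(avg)
    freqs = np.fft.rfftfreq(ep_len, 1.0 / rate)
    if f_mod >= rate / 2.0:
        raise ValueError("modulation frequency above Nyquist")
    target = int(np.argmin(np.abs(freqs - f_mod)))
    power = np.abs(spec) ** 2
    half = n_neighbors // 2
    lo = [target - 2 - k for k in range(half)]
    hi = [target + 2 + k for k in range(n_neighbors - half)]
    nb = [b for b in lo + hi if 1 <= b < len(power)]
    if len(nb) < 2:
        raise ValueError("not enough neighbour bins below Nyquist")
    F = power[target] / np.mean(power[nb])
    p = float(stats.f.sf(F, 2, 2 * len(nb)))
    return float(F), p


def assr_discard(
    rec: Recording,
    groups: dict,
    f_mod: float = 40.0,
    alpha: float = 0.05,
    n_periods: int = 8,
    n_neighbors: int = 12,
) -> ChannelMask:
    """Discard channels without a significant ASSR in any bipolar pair.

    For every unordered channel pair within a group the bipolar signal
    is tested with :func:`spectral_f_test`; a channel is kept when at
    least one of its pairs reaches ``p < alpha``.  Channels appearing
    in several groups (e.g. the central scalp strip belonging to both
    scalp groups) are kept when significant in any of them.
    """
    if f_mod >= rec.rate / 2.0:
        raise ValueError("modulation frequency above Nyquist")
    keep = {}
    for group, labels in groups.items():
        if len(labels) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 channels")
        idx = {lab: rec.labels.index(lab) for lab in labels}
        for lab in labels:
            keep.setdefault(lab, False)
        for la, lb in combinations(labels, 2):
            if keep[la] and keep[lb]:
                continue
            bipolar = rec.data[idx[la]] - rec.data[idx[lb]]
            _, p = spectral_f_test(
                bipolar, rec.rate, rec.triggers, f_mod, n_periods, n_neighbors
            )
            if p < alpha:
                keep[la] = keep[lb] = True
    flags, reasons = [], []
    for lab in rec.labels:
        if lab not in keep:
            flags.append(True)  # not in any tested group: left untouched
            reasons.append("")
        elif keep[lab]:
            flags.append(True)
            reasons.append("")
        else:
            flags.append(False)
            reasons.append("assr-nonsignificant")
    return ChannelMask(list(rec.labels), np.asarray(flags), reasons)
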