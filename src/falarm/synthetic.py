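"""Synthetic alarm-episode generator.

Produces labeled multichannel records (ECG lead II, ABP, PPG at 250 Hz) whose
latent beat schedules realise the five life-threatening alarm definitions:

    ASY  no heartbeat for more than 4 s
    EBR  heart rate below 40 bpm
    ETC  heart rate above 140 bpm for 17 consecutive beats
    VTA  five or more ventricular beats at a rate above 100 bpm
    VFB  a rapid fibrillatory/oscillatory waveform for at least 4 s

A TRUE alarm record carries the alarm-defining rhythm on every channel; a
FALSE alarm record has a normal underlying rhythm (60-100 bpm) but one or
two of its channels are corrupted by an artifact (noise burst, electrode-pop
square transients, or a flatline dropout) that mimics the alarm while at
least one channel stays clean — the multimodal rationale in miniature.

The definitions are enforced *constructively on the latent beat schedule*
(stored as ground truth on each record), never by detecting beats in the
rendered signal, so the labels stay exact at any noise level.  Waveforms are
simple morphological sketches: Gaussian-bump QRS trains (wide bumps for
ventricular beats, a 4-6 Hz oscillation for VFB), raised-cosine pressure and
plethysmograph pulses with a dicrotic bump, plus sinusoidal baseline wander
and white noise.  Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .io import (
    AlarmType,
    ChannelRole,
    Label,
    LabelTable,
    WaveformRecord,
    quantize_channels,
)

__all__ = [
    "Rhythm",
    "SyntheticSpec",
    "synth_beats",
    "render_channels",
    "generate_record",
    "generate_dataset",
    "satisfies_definition",
    "violates_all_definitions",
]


class Rhythm(str, Enum):
    NORMAL = "normal"
    BRADY = "brady"
    TACHY = "tachy"
    VTA = "vta"
    VFB = "vfb"
    ASYSTOLE = "asystole"


_TRUE_RHYTHM = {
    AlarmType.ASY: Rhythm.ASYSTOLE,
    AlarmType.EBR: Rhythm.BRADY,
    AlarmType.ETC: Rhythm.TACHY,
    AlarmType.VTA: Rhythm.VTA,
    AlarmType.VFB: Rhythm.VFB,
}

#: per-channel rendering amplitude scale (physical-ish units)
_SCALE = {ChannelRole.ECG_II: 1.0, ChannelRole.ABP: 40.0, ChannelRole.PPG: 0.8}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a generated dataset.

    Heart-rate ranges sit strictly inside the defining thresholds (with the
    +-2 % beat-interval jitter applied) so ground truth never straddles a
    definition boundary.  Noise/artifact defaults were calibrated once to
    make the classification task learnable but not trivial and are frozen
    here.
    """

    n_records: int = 120
    alarm_mix: dict = field(
        default_factory=lambda: {t: 0.2 for t in AlarmType}
    )
    true_fraction: float = 0.5
    fs: float = 250.0
    duration_seconds: float = 20.0
    hr_normal: tuple[float, float] = (75.0, 95.0)
    hr_brady: tuple[float, float] = (25.0, 33.0)
    hr_tachy: tuple[float, float] = (160.0, 180.0)
    hr_ventricular: tuple[float, float] = (125.0, 155.0)
    interval_jitter: float = 0.02
    noise_sigma: float = 0.02  # white noise, relative to channel amplitude
    wander_amp: float = 0.04  # baseline wander, relative to channel amplitude
    wander_freq_hz: float = 0.33
    burst_gain: float = 5.0  # artifact noise burst, x channel amplitude
    square_amp: float = 3.5  # electrode-pop step height, x channel amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_fraction <= 1.0):
            raise SchemaError("true_fraction must lie in [0, 1]")
        if self.duration_seconds < 8.0:
            raise SchemaError("duration must cover the >=4 s events plus context")
        total = sum(self.alarm_mix.values())
        if total <= 0:
            raise SchemaError("alarm_mix fractions must sum to a positive value")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _beat_train(rng, hr_range, t_start, t_stop, jitter) -> np.ndarray:
    """Beat instants with rate drawn once from hr_range and +-jitter intervals."""
    hr = rng.uniform(*hr_range)
    times = []
    t = t_start + rng.uniform(0.05, 60.0 / hr)
    while t < t_stop:
        times.append(t)
        t += 60.0 / hr * (1.0 + rng.uniform(-jitter, jitter))
    return np.asarray(times)


def synth_beats(
    rhythm: Rhythm,
    duration: float,
    seed,
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[np.ndarray, list[str], dict]:
    """Latent beat schedule (times in seconds, morphology tags, event extras).

    Tags are 'N' (normal) or 'V' (ventricular).  ``extras`` records the
    constructive event: the asystole gap, the VFB interval, or the
    ventricular run bounds.
    """
    rng = _as_rng(seed)
    j = spec.interval_jitter
    extras: dict = {"rhythm": rhythm.value}
    if rhythm is Rhythm.NORMAL:
        beats = _beat_train(rng, spec.hr_normal, 0.0, duration, j)
        tags = ["N"] * len(beats)
    elif rhythm is Rhythm.BRADY:
        beats = _beat_train(rng, spec.hr_brady, 0.0, duration, j)
        tags = ["N"] * len(beats)
    elif rhythm is Rhythm.TACHY:
        beats = _beat_train(rng, spec.hr_tachy, 0.0, duration, j)
        tags = ["N"] * len(beats)
    elif rhythm is Rhythm.VTA:
        n_v = int(rng.integers(8, 15))
        hr_v = rng.uniform(*spec.hr_ventricular)
        run_len = n_v * 60.0 / hr_v
        t_event = duration - run_len - rng.uniform(0.2, 1.0)
        normal = _beat_train(rng, spec.hr_normal, 0.0, t_event, j)
        run, t = [], t_event + 0.1
        for _ in range(n_v):
            run.append(t)
            t += 60.0 / hr_v * (1.0 + rng.uniform(-j, j))
        beats = np.concatenate([normal, run])
        tags = ["N"] * len(normal) + ["V"] * n_v
        extras["vt_run"] = (float(run[0]), float(run[-1]))
    elif rhythm is Rhythm.VFB:
        gap = rng.uniform(5.0, 8.0)
        t_event = duration - gap
        beats = _beat_train(rng, spec.hr_normal, 0.0, t_event, j)
        tags = ["N"] * len(beats)
        extras["vfb_interval"] = (float(t_event), float(duration))
        extras["vfb_freq_hz"] = float(rng.uniform(4.0, 6.0))
    elif rhythm is Rhythm.ASYSTOLE:
        gap = rng.uniform(4.5, 6.5)
        t_event = duration - gap
        beats = _beat_train(rng, spec.hr_normal, 0.0, t_event, j)
        tags = ["N"] * len(beats)
        extras["asystole_gap"] = (float(t_event), float(duration))
    else:
        raise SchemaError(f"unknown rhythm {rhythm!r}")
    return beats, tags, extras


# -- alarm definitions on the latent schedule -----------------------------


def satisfies_definition(
    alarm_type: AlarmType,
    beat_times: np.ndarray,
    tags: list[str],
    extras: dict,
    duration: float,
) -> bool:
    """Evaluate one alarm definition on the ground-truth beat schedule."""
    beats = np.asarray(beat_times, dtype=float)
    bounded = np.concatenate([[0.0], beats, [duration]])
    gaps = np.diff(bounded)
    intervals = np.diff(beats) if len(beats) > 1 else np.array([])
    if alarm_type is AlarmType.ASY:
        vfb = extras.get("vfb_interval")
        if vfb is not None:
            # an oscillatory VFB episode is not an absent heartbeat
            return bool(np.max(gaps) > 4.0 and (vfb[1] - vfb[0]) < 4.0)
        return bool(np.max(gaps) > 4.0)
    if alarm_type is AlarmType.EBR:
        slow = intervals > 60.0 / 40.0
        return _longest_run(slow) >= 5
    if alarm_type is AlarmType.ETC:
        fast = intervals < 60.0 / 140.0
        return _longest_run(fast) >= 16  # 17 consecutive beats
    if alarm_type is AlarmType.VTA:
        vent = np.asarray([tag == "V" for tag in tags], dtype=bool)
        if len(beats) == 0:
            return False
        fast = intervals < 60.0 / 100.0
        run = 1 if vent[0] else 0
        best = run
        for k in range(1, len(beats)):
            if vent[k] and run > 0 and fast[k - 1]:
                run += 1
            elif vent[k]:
                run = 1
            else:
                run = 0
            best = max(best, run)
        return best >= 5
    if alarm_type is AlarmType.VFB:
        vfb = extras.get("vfb_interval")
        return vfb is not None and (vfb[1] - vfb[0]) >= 4.0
    raise SchemaError(f"unknown alarm type {alarm_type!r}")


def _longest_run(mask: np.ndarray) -> int:
    best = run = 0
    for m in mask:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def violates_all_definitions(beat_times, tags, extras, duration) -> bool:
    return not any(
        satisfies_definition(t, beat_times, tags, extras, duration) for t in AlarmType
    )


# -- waveform rendering ----------------------------------------------------


def _add_bump(x: np.ndarray, fs: float, center_s: float, amp: float, sigma_s: float):
    n = len(x)
    half = int(4 * sigma_s * fs)
    c = int(round(center_s * fs))
    lo, hi = max(0, c - half), min(n, c + half + 1)
    if lo >= hi:
        return
    t = (np.arange(lo, hi) - c) / fs
    x[lo:hi] += amp * np.exp(-0.5 * (t / sigma_s) ** 2)


def _add_pulse(x: np.ndarray, fs: float, onset_s: float, amp: float, width_s: float):
    """Raised-cosine pulse with a small dicrotic bump on the falling limb."""
    n = len(x)
    lo = int(round(onset_s * fs))
    w = max(int(round(width_s * fs)), 4)
    hi = min(n, lo + w)
    if lo >= n or lo < 0:
        return
    s = np.arange(hi - lo) / w
    x[lo:hi] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(s, 0, 1)))
    _add_bump(x, fs, onset_s + 0.72 * width_s, 0.12 * amp, 0.06 * width_s)


def render_channels(
    beat_times: np.ndarray,
    tags: list[str],
    extras: dict,
    duration: float,
    fs: float,
    seed,
    noise_sigma: float = 0.03,
    wander_amp: float = 0.08,
    wander_freq_hz: float = 0.33,
) -> dict[ChannelRole, np.ndarray]:
    """Render the three modality waveforms from a beat schedule."""
    rng = _as_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    beats = np.asarray(beat_times, dtype=float)
    next_gap = np.diff(np.append(beats, duration)) if len(beats) else np.array([])

    ecg = np.zeros(n)
    abp = np.full(n, 75.0)
    ppg = np.full(n, 0.2)
    for k, (tau, tag) in enumerate(zip(beats, tags)):
        if tag == "V":
            _add_bump(ecg, fs, tau, 1.1, 0.045)
            _add_bump(ecg, fs, tau + 0.08, -0.5, 0.03)
            pulse_amp = 0.35
        else:
            _add_bump(ecg, fs, tau, 1.0, 0.012)
            _add_bump(ecg, fs, tau + 0.22, 0.2, 0.05)
            pulse_amp = 1.0
        width = min(0.42, 0.8 * float(next_gap[k]))
        _add_pulse(abp, fs, tau + 0.15, 40.0 * pulse_amp, width)
        _add_pulse(ppg, fs, tau + 0.30, 0.8 * pulse_amp, width)

    vfb = extras.get("vfb_interval")
    if vfb is not None:
        f_vfb = extras.get("vfb_freq_hz", 5.0)
        sel = (t >= vfb[0]) & (t < vfb[1])
        ecg[sel] += 0.9 * np.sin(2.0 * np.pi * f_vfb * (t[sel] - vfb[0]))

    channels = {ChannelRole.ECG_II: ecg, ChannelRole.ABP: abp, ChannelRole.PPG: ppg}
    for role, x in channels.items():
        scale = _SCALE[role]
        phase = rng.uniform(0, 2 * np.pi)
        x += wander_amp * scale * np.sin(2.0 * np.pi * wander_freq_hz * t + phase)
        if noise_sigma > 0:
            x += rng.normal(0.0, noise_sigma * scale, n)
    return channels


def _inject_artifact(
    channels: dict[ChannelRole, np.ndarray],
    fs: float,
    duration: float,
    rng: np.random.Generator,
    spec: SyntheticSpec,
) -> dict:
    """Corrupt the alarm-trigger channel (ECG II) and at most one pulsatile
    channel near the record end; >=1 channel always stays clean.

    A false arrhythmia alarm presupposes that the channel the monitor
    watches — the ECG — itself mimicked the event, so the ECG is always in
    the corrupted subset; the pulsatile channels are corrupted at random.
    """
    chosen = [ChannelRole.ECG_II]
    others = [r for r in sorted(channels, key=lambda r: r.value) if r not in chosen]
    if rng.random() < 0.5:
        chosen.append(others[int(rng.integers(len(others)))])
    kind = str(rng.choice(["burst", "square", "dropout"]))
    # artifacts are transient (a couple of seconds) while the alarm-defining
    # rhythms are sustained (>= 4 s) — the cue a human over-reader uses too
    length = rng.uniform(1.5, 3.0)
    end = duration - rng.uniform(0.0, 1.5)
    start = max(0.0, end - length)
    lo, hi = int(start * fs), int(end * fs)
    for role in chosen:
        x = channels[role]
        scale = _SCALE[role]
        if kind == "burst":
            x[lo:hi] += rng.normal(0.0, spec.burst_gain * scale, hi - lo)
        elif kind == "square":
            for _ in range(int(rng.integers(3, 6))):
                w = int(rng.uniform(0.15, 0.5) * fs)
                pos = int(rng.integers(lo, max(lo + 1, hi - w)))
                x[pos : pos + w] += rng.choice([-1.0, 1.0]) * spec.square_amp * scale
        else:  # dropout: lead-off rail, an exactly constant offset flatline
            x[lo:hi] = x[lo] + 0.8 * scale
    return {
        "kind": kind,
        "channels": [r.value for r in chosen],
        "window_seconds": (float(start), float(end)),
    }


def generate_record(
    alarm_type: AlarmType, is_true: bool, spec: SyntheticSpec, seed: int,
    record_id: Optional[str] = None,
) -> WaveformRecord:
    """One synthetic alarm episode; a pure function of its arguments."""
    rng = np.random.default_rng(seed)
    duration, fs = spec.duration_seconds, spec.fs
    rhythm = _TRUE_RHYTHM[alarm_type] if is_true else Rhythm.NORMAL
    beats, tags, extras = synth_beats(rhythm, duration, rng, spec)
    channels = render_channels(
        beats, tags, extras, duration, fs, rng,
        noise_sigma=spec.noise_sigma, wander_amp=spec.wander_amp,
        wander_freq_hz=spec.wander_freq_hz,
    )
    if not is_true:
        extras["artifact"] = _inject_artifact(channels, fs, duration, rng, spec)
    channels = quantize_channels(channels)
    if record_id is None:
        record_id = f"{alarm_type.value.lower()}{'t' if is_true else 'f'}{seed:08d}"
    rec = WaveformRecord(
        record_id=record_id,
        fs=fs,
        channels=channels,
        alarm_type=alarm_type,
        label=Label.TRUE_ALARM if is_true else Label.FALSE_ALARM,
        onset_index=int(round(duration * fs)),
        beat_times=beats,
        beat_tags=tags,
        meta=extras,
    )
    rec.validate()
    return rec


def _allocate(n: int, weights: dict) -> dict:
    """Largest-remainder allocation of n items over weighted keys."""
    total = sum(weights.values())
    exact = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n - sum(counts.values())
    for k in sorted(exact, key=lambda k: (-(exact[k] - counts[k]), str(k)))[:short]:
        counts[k] += 1
    return counts


def generate_dataset(spec: SyntheticSpec) -> tuple[list[WaveformRecord], LabelTable]:
    """Reproducible dataset matching the spec's class/type mix within rounding."""
    n_true = int(round(spec.n_records * spec.true_fraction))
    mix = {k: v for k, v in spec.alarm_mix.items() if v > 0}
    plan: list[tuple[AlarmType, bool]] = []
    for is_true, group_n in ((True, n_true), (False, spec.n_records - n_true)):
        for alarm_type, count in _allocate(group_n, mix).items():
            plan.extend([(alarm_type, is_true)] * count)
    seeds = np.random.SeedSequence(spec.seed).generate_state(len(plan), dtype=np.uint32)
    records, rows = [], []
    for idx, (alarm_type, is_true) in enumerate(plan):
        rid = f"{alarm_type.value.lower()}{'t' if is_true else 'f'}{idx:04d}"
        rec = generate_record(
            alarm_type, is_true, spec, int(seeds[idx] % (2**31)), record_id=rid
        )
        records.append(rec)
        rows.append((rid, alarm_type.value, rec.label.value))
    table = LabelTable(pd.DataFrame(rows, columns=["record_id", "alarm_type", "label"]))
    return records, table
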