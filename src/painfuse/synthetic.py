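"""Synthetic cohorts of thermally evoked physiological recordings.

Emulates the structure of calibrated heat-pain protocols: per subject, each
elicitation level (baseline T0 plus graded levels T1..) is applied a fixed
number of times in randomized order, each stimulus lasting 4 s and followed
by a recovery pause drawn uniformly from [8, 12] s. Modality-specific
stimulus responses carry the label information:

* EDA - tonic level with slow drift plus a gamma-shaped phasic rise whose
  amplitude grows with level x effect_size (latency 1-3 s);
* ECG - a train of stylized beats whose rate transiently increases with
  the level during/after the stimulus;
* EMG - band-limited noise with a level-dependent burst amplitude during
  the stimulus;
* RSP - a respiration-like oscillation whose frequency and depth shift
  with the level.

All channels carry additive Gaussian sensor noise. Between-subject
variability (amplitude scales, baseline heart rate, latency offsets) makes
subject-independent generalization a nontrivial property of the data.
With effect_size = 0 the responses are label-independent by construction,
so any classifier is reduced to chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.special

from .preprocess import Recording

__all__ = ["CohortSpec", "SubjectTraits", "generate_cohort", "modality_response"]


@dataclass(frozen=True)
class CohortSpec:
    n_subjects: int = 87
    n_levels: int = 5  # baseline + graded elicitations
    reps_per_level: int = 20
    stimulus_s: float = 4.0
    recovery_lo_s: float = 8.0
    recovery_hi_s: float = 12.0
    modalities: tuple = ("EDA", "ECG", "EMG")
    effect_size: float = 1.0
    rate: float = 512.0
    seed: int = 0
    lead_in_s: float = 12.0
    tail_s: float = 12.0

    def __post_init__(self):
        if self.reps_per_level < 1:
            raise ValueError("reps_per_level must be >= 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass(frozen=True)
class SubjectTraits:
    """Subject-level random factors shared across that subject's channels."""

    amp_scale: float = 1.0
    latency_offset: float = 0.0
    base_hr: float = 70.0
    eda_tonic: float = 6.0
    rsp_freq: float = 0.25

    @staticmethod
    def draw(rng: np.random.Generator) -> "SubjectTraits":
        return SubjectTraits(
            amp_scale=float(np.exp(rng.normal(0.0, 0.25))),
            latency_offset=float(rng.uniform(-0.5, 0.5)),
            base_hr=float(rng.normal(70.0, 5.0)),
            eda_tonic=float(rng.uniform(4.0, 8.0)),
            rsp_freq=float(rng.uniform(0.2, 0.3)),
        )


# response shape/gain constants (per unit level x effect_size)
_EDA_GAIN = 0.15          # uS of phasic amplitude
_HR_GAIN = 0.06           # fractional heart-rate increase
_EMG_GAIN = 0.6           # fractional burst-amplitude increase
_RSP_FREQ_GAIN = 0.08     # fractional breathing-rate increase
_RSP_DEPTH_GAIN = 0.10    # fractional depth increase
_SENSOR_SD = 0.02


def _phasic_shape(t: np.ndarray, tau: float = 1.5) -> np.ndarray:
    """Gamma-like skin-conductance response, unit peak amplitude."""
    s = np.where(t > 0, (t / (2 * tau)) ** 2 * np.exp(-(t - 2 * tau) / tau), 0.0)
    return np.clip(s, 0.0, None)


def _ricker(points: int, a: float) -> np.ndarray:
    """Mexican-hat wavelet (negative second derivative of a Gaussian)."""
    t = np.arange(points) - (points - 1) / 2.0
    x = (t / a) ** 2
    return (1.0 - x) * np.exp(-x / 2.0)


def _beat_train(rng, rate, duration_s, hr_curve) -> np.ndarray:
    """Stylized ECG: Ricker-wavelet beats placed by integrating the rate curve."""
    n = int(round(duration_s * rate))
    phase = np.cumsum(hr_curve / 60.0) / rate  # beats elapsed
    beat_idx = np.searchsorted(phase, np.arange(0.5, phase[-1]))
    sig = np.zeros(n)
    jitter = rng.normal(0.0, 0.01 * rate, len(beat_idx)).astype(int)
    sig[np.clip(beat_idx + jitter, 0, n - 1)] = 1.0
    wavelet = _ricker(int(0.12 * rate) | 1, 0.01 * rate)
    return scipy.signal.fftconvolve(sig, wavelet, mode="same")


def _bandlimited_noise(rng, rate, n, lo=20.0, hi=None) -> np.ndarray:
    hi = min(hi or 150.0, 0.45 * rate)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return scipy.signal.sosfilt(sos, rng.normal(0.0, 1.0, n))


def _stimulus_envelope(t: np.ndarray, stim_s: float = 4.0) -> np.ndarray:
    """Smooth on/off gate over the stimulus, decaying ~2 s after offset."""
    rise = scipy.special.expit((t - 0.3) / 0.15)
    fall = scipy.special.expit(-(t - stim_s - 2.0) / 0.8)
    return rise * fall


def modality_response(modality: str, level: int, effect_size: float,
                      rng: np.random.Generator, *, rate: float = 512.0,
                      duration_s: float = 16.0,
                      traits: SubjectTraits = SubjectTraits()) -> np.ndarray:
    """Stimulus-locked waveform fragment for one elicitation.

    t = 0 is the elicitation onset; the fragment spans `duration_s` seconds.
    """
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    drive = level * effect_size
    if modality == "EDA":
        latency = rng.uniform(1.0, 3.0) + traits.latency_offset
        amp = _EDA_GAIN * drive * traits.amp_scale
        frag = amp * _phasic_shape(t - latency)
    elif modality == "ECG":
        hr = traits.base_hr * (1.0 + _HR_GAIN * drive * _stimulus_envelope(t))
        frag = traits.amp_scale * _beat_train(rng, rate, duration_s, hr)
    elif modality == "EMG":
        gain = 1.0 + _EMG_GAIN * drive * _stimulus_envelope(t)
        frag = 0.2 * traits.amp_scale * gain * _bandlimited_noise(rng, rate, n)
    elif modality == "RSP":
        freq = traits.rsp_freq * (1.0 + _RSP_FREQ_GAIN * drive * _stimulus_envelope(t))
        depth = traits.amp_scale * (1.0 + _RSP_DEPTH_GAIN * drive * _stimulus_envelope(t))
        phase = 2 * np.pi * np.cumsum(freq) / rate + rng.uniform(0, 2 * np.pi)
        frag = depth * np.sin(phase)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return frag + rng.normal(0.0, _SENSOR_SD, n)


def _event_schedule(spec: CohortSpec, rng) -> tuple:
    levels = np.repeat(np.arange(spec.n_levels), spec.reps_per_level)
    rng.shuffle(levels)
    onsets, t = [], spec.lead_in_s
    for _ in levels:
        onsets.append(t)
        t += spec.stimulus_s + rng.uniform(spec.recovery_lo_s, spec.recovery_hi_s)
    return tuple(zip(onsets, (int(v) for v in levels))), t + spec.tail_s


def _subject_recordings(spec: CohortSpec, subject_id: str, ss) -> list:
    streams = ss.spawn(1 + len(spec.modalities))
    rng = np.random.default_rng(streams[0])
    traits = SubjectTraits.draw(rng)
    events, duration = _event_schedule(spec, rng)
    n = int(round(duration * spec.rate))
    t = np.arange(n) / spec.rate
    recs = []
    for mod, stream in zip(spec.modalities, streams[1:]):
        mrng = np.random.default_rng(stream)
        if mod == "EDA":
            drift = scipy.signal.sosfilt(
                scipy.signal.butter(2, 0.01, fs=spec.rate, output="sos"),
                mrng.normal(0.0, 1.0, n),
            )
            drift *= 0.3 / max(drift.std(), 1e-12)
            sig = traits.eda_tonic + drift
            for onset, level in events:
                i0 = int(round(onset * spec.rate))
                frag_n = min(int(16 * spec.rate), n - i0)
                latency = mrng.uniform(1.0, 3.0) + traits.latency_offset
                amp = _EDA_GAIN * level * spec.effect_size * traits.amp_scale
                tt = np.arange(frag_n) / spec.rate
                sig[i0:i0 + frag_n] += amp * _phasic_shape(tt - latency)
            sig += mrng.normal(0.0, _SENSOR_SD, n)
        elif mod == "ECG":
            hr = np.full(n, traits.base_hr)
            for onset, level in events:
                hr += (traits.base_hr * _HR_GAIN * level * spec.effect_size
                       * _stimulus_envelope(t - onset, spec.stimulus_s))
            sig = traits.amp_scale * _beat_train(mrng, spec.rate, duration, hr)
            sig += mrng.normal(0.0, _SENSOR_SD, n)
        elif mod == "EMG":
            gain = np.ones(n)
            for onset, level in events:
                gain += (_EMG_GAIN * level * spec.effect_size
                         * _stimulus_envelope(t - onset, spec.stimulus_s))
            sig = 0.2 * traits.amp_scale * gain * _bandlimited_noise(mrng, spec.rate, n)
            sig += mrng.normal(0.0, _SENSOR_SD, n)
        elif mod == "RSP":
            freq = np.full(n, traits.rsp_freq)
            depth = np.full(n, float(traits.amp_scale))
            for onset, level in events:
                env = _stimulus_envelope(t - onset, spec.stimulus_s)
                freq += traits.rsp_freq * _RSP_FREQ_GAIN * level * spec.effect_size * env
                depth += traits.amp_scale * _RSP_DEPTH_GAIN * level * spec.effect_size * env
            phase = 2 * np.pi * np.cumsum(freq) / spec.rate + mrng.uniform(0, 2 * np.pi)
            sig = depth * np.sin(phase) + mrng.normal(0.0, _SENSOR_SD, n)
        else:
            raise ValueError(f"unknown modality {mod!r}")
        recs.append(Recording(subject_id, mod, sig, spec.rate, events))
    return recs


def generate_cohort(spec: CohortSpec) -> list:
    """All recordings of a cohort (one Recording per subject x modality).

    Deterministic given spec.seed; per subject every level appears exactly
    reps_per_level times in randomized order, and all of a subject's
    channels share the same event schedule.
    """
    root = np.random.SeedSequence(spec.seed)
    out = []
    for i, ss in enumerate(root.spawn(spec.n_subjects)):
        out.extend(_subject_recordings(spec, f"S{i:03d}", ss))
    return out
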