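"""Signal conditioning and stimulus-locked segmentation of physiological channels.

The pipeline mirrors the standard treatment of thermally evoked pain
recordings: per-channel Butterworth filtering at the native rate, decimation
to 256 Hz, piecewise polynomial detrending (ECG), extraction of fixed-length
windows shifted 4 s past each elicitation onset, temporal-jitter augmentation
of training windows, per-modality min-max scaling fitted on training folds
only, and Gaussian corruption of encoder inputs for denoising training.

Conventions: time in seconds, windows half-open [start, start + len),
sample index = floor(t * rate), 0-based. Filtering and detrending are
length-preserving; only segmentation changes sample counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
import scipy.signal

log = logging.getLogger(__name__)

TARGET_RATE = 256.0
#: Temporal offset of the analysis window from the elicitation onset (s).
ONSET_SHIFT_S = 4.0
#: Dataset presets: analysis window length in seconds.
WINDOW_S = {"biovid": 4.5, "senseemotion": 6.5}

MODALITIES = ("EDA", "ECG", "EMG", "RSP")


@dataclass(frozen=True)
class Recording:
    """One subject/channel waveform with stimulus events.

    events is a list of (onset_seconds, level) with strictly increasing
    onsets; levels are small non-negative integers (baseline = 0).
    """

    subject_id: str
    modality: str
    samples: np.ndarray
    rate: float
    events: tuple = ()

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        onsets = [e[0] for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "lowpass" | "bandpass"
    order: int
    cutoffs: tuple
    dataset: str
    modality: str

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.kind == "bandpass":
            lo, hi = self.cutoffs
            if not lo < hi:
                raise ValueError("bandpass needs low < high cutoff")
        elif self.kind != "lowpass":
            raise ValueError(f"unknown filter kind {self.kind!r}")


#: Per-(dataset, modality) filter settings.
FILTERS = {
    ("biovid", "EDA"): FilterSpec("lowpass", 3, (0.2,), "biovid", "EDA"),
    ("biovid", "EMG"): FilterSpec("bandpass", 4, (20.0, 250.0), "biovid", "EMG"),
    ("biovid", "ECG"): FilterSpec("bandpass", 3, (0.1, 250.0), "biovid", "ECG"),
    ("senseemotion", "EDA"): FilterSpec("lowpass", 3, (0.2,), "senseemotion", "EDA"),
    ("senseemotion", "RSP"): FilterSpec("lowpass", 3, (0.8,), "senseemotion", "RSP"),
    ("senseemotion", "EMG"): FilterSpec("bandpass", 3, (0.05, 25.0), "senseemotion", "EMG"),
    ("senseemotion", "ECG"): FilterSpec("bandpass", 3, (0.1, 25.0), "senseemotion", "ECG"),
}


@dataclass(frozen=True)
class Segment:
    """Fixed-length stimulus-locked window of one channel."""

    values: np.ndarray
    label: int
    subject_id: str
    modality: str
    shift_offset: int = 0  # ms relative to the nominal window start
    start_s: float = 0.0  # nominal (unshifted) window start, absolute seconds
    event_index: int = 0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def m(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NoiseSpec:
    mean: float = 0.0
    sd: float = 0.1

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resample(rec: Recording, target_rate: float = TARGET_RATE) -> Recording:
    """Polyphase decimation to `target_rate`; upsampling is not supported."""
    if target_rate > rec.rate:
        raise ValueError(
            f"unsupported direction: cannot upsample {rec.rate} Hz to {target_rate} Hz"
        )
    if target_rate == rec.rate:
        return rec
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    out = scipy.signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    n_expect = int(round(len(rec.samples) * target_rate / rec.rate))
    out = out[:n_expect]
    return replace(rec, samples=out, rate=target_rate)


def _effective_cutoffs(spec: FilterSpec, rate: float) -> tuple:
    """Clip a bandpass upper edge at/above Nyquist to 0.45 * rate (logged);
    any other infeasible cutoff is rejected."""
    nyq = rate / 2.0
    cutoffs = list(spec.cutoffs)
    if spec.kind == "bandpass" and cutoffs[-1] >= nyq:
        clipped = 0.45 * rate
        log.warning(
            "upper cutoff %.3g Hz of %s/%s filter >= Nyquist at %g Hz; "
            "clipped to %.3g Hz", cutoffs[-1], spec.dataset, spec.modality,
            rate, clipped,
        )
        cutoffs[-1] = clipped
    if any(c <= 0 or c >= nyq for c in cutoffs) or (
        len(cutoffs) == 2 and cutoffs[0] >= cutoffs[1]
    ):
        raise ValueError(
            f"filter spec {spec} infeasible at rate {rate} Hz (cutoffs {cutoffs})"
        )
    return tuple(cutoffs)


def butter_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase (forward-backward) Butterworth filtering.

    Applied at the recording's own rate; zero-phase application keeps
    stimulus-locked windows aligned with their events.
    """
    cutoffs = _effective_cutoffs(spec, rec.rate)
    btype = "lowpass" if spec.kind == "lowpass" else "bandpass"
    wn = cutoffs[0] if btype == "lowpass" else list(cutoffs)
    sos = scipy.signal.butter(spec.order, wn, btype=btype, fs=rec.rate, output="sos")
    out = scipy.signal.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=out)


def piecewise_detrend(rec: Recording, degree: int = 5,
                      piece_s: float | None = None) -> Recording:
    """Subtract a least-squares polynomial fit of `degree` per piece.

    The signal is split into consecutive pieces of `piece_s` seconds
    (the whole signal when None); a trailing remainder shorter than a piece
    is folded into the last piece.
    """
    n = len(rec.samples)
    piece = n if piece_s is None else int(round(piece_s * rec.rate))
    if piece <= degree + 1:
        raise ValueError(
            f"piece of {piece} samples too short for degree-{degree} fit"
        )
    out = rec.samples.copy()
    starts = list(range(0, n, piece))
    # fold a short trailing remainder into the previous piece
    if len(starts) > 1 and n - starts[-1] <= degree + 1:
        starts.pop()
    for idx, s in enumerate(starts):
        e = starts[idx + 1] if idx + 1 < len(starts) else n
        x = np.arange(e - s, dtype=float)
        coeffs = np.polynomial.polynomial.polyfit(x, out[s:e], degree)
        out[s:e] -= np.polynomial.polynomial.polyval(x, coeffs)
    return replace(rec, samples=out)


def _window_indices(rec: Recording, start_s: float, m: int):
    i0 = math.floor(start_s * rec.rate)
    return i0, i0 + m


def segment(rec: Recording, window_s: float,
            onset_shift_s: float = ONSET_SHIFT_S) -> list:
    """One Segment per event; windows beyond the recording end are skipped."""
    m = int(round(window_s * rec.rate))
    out = []
    for k, (onset, level) in enumerate(rec.events):
        start = onset + onset_shift_s
        i0, i1 = _window_indices(rec, start, m)
        if i0 < 0 or i1 > len(rec.samples):
            log.warning(
                "event %d of %s/%s: window [%g, %g) s outside recording; skipped",
                k, rec.subject_id, rec.modality, start, start + window_s,
            )
            continue
        out.append(
            Segment(rec.samples[i0:i1], int(level), rec.subject_id,
                    rec.modality, shift_offset=0, start_s=start, event_index=k)
        )
    return out


def augment(rec: Recording, base: Segment, step_ms: int = 250,
            max_ms: int = 1000) -> list:
    """Temporal-jitter augmentation of one training window.

    Returns the original plus one copy per shift in
    {±step, ±2·step, ..., ±max}; with the defaults that is 9 windows.
    Shifted windows falling outside the recording are dropped with a warning.
    """
    m = base.m
    offsets = [0]
    if step_ms > 0 and max_ms > 0:
        for j in range(1, max_ms // step_ms + 1):
            offsets += [-j * step_ms, j * step_ms]
    out = []
    for off in sorted(offsets):
        if off == 0:
            out.append(base)
            continue
        start = base.start_s + off / 1000.0
        i0, i1 = _window_indices(rec, start, m)
        if i0 < 0 or i1 > len(rec.samples):
            log.warning(
                "augmentation shift %+d ms of event %d (%s/%s) out of bounds; dropped",
                off, base.event_index, rec.subject_id, rec.modality,
            )
            continue
        out.append(replace(base, values=rec.samples[i0:i1], shift_offset=off))
    return out


def corrupt(seg: Segment, noise: NoiseSpec, rng: np.random.Generator) -> Segment:
    """Additive i.i.d. Gaussian corruption (fresh draw per call)."""
    if noise.sd == 0:
        return seg
    draw = rng.normal(noise.mean, noise.sd, seg.m)
    return replace(seg, values=seg.values + draw)


# ---------------------------------------------------------------------------
# Multi-channel sample assembly and scaling
# ---------------------------------------------------------------------------

@dataclass
class SegmentDataset:
    """Aligned multi-modal training samples.

    X maps modality -> (n_samples, m) array; rows across modalities belong
    to the same (subject, event, shift) triple.
    """

    X: dict
    y: np.ndarray
    subject: np.ndarray
    shift: np.ndarray
    provenance: np.ndarray = None  # "real" | "generated"

    def __post_init__(self):
        if self.provenance is None:
            self.provenance = np.full(len(self.y), "real", dtype=object)

    def __len__(self):
        return len(self.y)

    @property
    def modalities(self):
        return tuple(self.X)

    @property
    def m(self):
        return next(iter(self.X.values())).shape[1]

    def select(self, mask) -> "SegmentDataset":
        return SegmentDataset(
            {mod: x[mask] for mod, x in self.X.items()},
            self.y[mask], self.subject[mask], self.shift[mask],
            self.provenance[mask],
        )

    def subjects(self):
        return sorted(set(self.subject.tolist()))


def assemble_dataset(segments_by_modality: dict) -> SegmentDataset:
    """Align per-modality segment lists into one multi-modal dataset.

    Segments are matched on (subject, event_index, shift_offset); a sample is
    kept only when every modality contributed that window.
    """
    modalities = sorted(segments_by_modality)
    keyed = {
        mod: {(s.subject_id, s.event_index, s.shift_offset): s for s in segs}
        for mod, segs in segments_by_modality.items()
    }
    common = set.intersection(*(set(k) for k in keyed.values()))
    keys = sorted(common)
    ref = keyed[modalities[0]]
    return SegmentDataset(
        X={mod: np.stack([keyed[mod][k].values for k in keys]) for mod in modalities},
        y=np.array([ref[k].label for k in keys]),
        subject=np.array([k[0] for k in keys], dtype=object),
        shift=np.array([k[2] for k in keys]),
    )


@dataclass(frozen=True)
class ScaleStats:
    lo: dict
    hi: dict


def normalize(train: SegmentDataset, apply: SegmentDataset | None = None):
    """Per-modality min-max scaling fitted on training data only.

    Training values are mapped affinely onto [0, 1]; the same map is applied
    to held-out data, which may therefore leave [0, 1].
    """
    lo, hi = {}, {}
    for mod, x in train.X.items():
        lo[mod], hi[mod] = float(x.min()), float(x.max())
        if hi[mod] == lo[mod]:
            raise ValueError(f"constant training channel {mod}: degenerate range")
    stats = ScaleStats(lo, hi)

    def _apply(ds):
        return SegmentDataset(
            {mod: (x - lo[mod]) / (hi[mod] - lo[mod]) for mod, x in ds.X.items()},
            ds.y, ds.subject, ds.shift, ds.provenance,
        )

    return (_apply(train), stats) if apply is None else (
        _apply(train), _apply(apply), stats
    )


def apply_scaling(ds: SegmentDataset, stats: ScaleStats) -> SegmentDataset:
    return SegmentDataset(
        {mod: (x - stats.lo[mod]) / (stats.hi[mod] - stats.lo[mod])
         for mod, x in ds.X.items()},
        ds.y, ds.subject, ds.shift, ds.provenance,
    )


def preprocess_recordings(recordings, dataset: str = "biovid",
                          window_s: float | None = None,
                          with_augmentation: bool = False) -> SegmentDataset:
    """Full conditioning path: filter -> resample -> detrend(ECG) -> segment.

    Filtering runs at the native rate (so wide EMG/ECG bands stay feasible),
    then the signal is decimated to 256 Hz. With `with_augmentation` each
    window additionally contributes its 8 jittered copies.
    """
    window_s = WINDOW_S[dataset] if window_s is None else window_s
    by_mod: dict = {}
    for rec in recordings:
        spec = FILTERS.get((dataset, rec.modality))
        if spec is not None:
            rec = butter_filter(rec, spec)
        if rec.rate != TARGET_RATE:
            rec = resample(rec, TARGET_RATE)
        if rec.modality == "ECG":
            rec = piecewise_detrend(rec, degree=5, piece_s=window_s)
        segs = segment(rec, window_s)
        if with_augmentation:
            segs = [s for base in segs for s in augment(rec, base)]
        by_mod.setdefault(rec.modality, []).extend(segs)
    return assemble_dataset(by_mod)
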