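"""Vowel stimulus construction for the pitch-discrimination task.

The reference stimulus is a 500-ms steady /ɑ/ vowel with a fundamental
frequency (fo) of 239 Hz.  Each trial pairs the reference with a comparison
whose fo is shifted by some number of cents (1 cent = 1/1200 octave); the
two intervals are separated by a 500-ms silent gap and presented in random
order.  A 10-ms raised-cosine taper shapes the onset and offset of every
stimulus.

Because the original recording is not distributable, the vowel is
formant-synthesized: a harmonic glottal source shaped by a fixed /ɑ/
formant envelope.  Comparison stimuli are re-synthesized at the shifted fo
with the same envelope (pitch shift without formant shift), emulating a
harmonizer.  An optional WAV path lets users substitute a recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

DEFAULT_FO_HZ = 239.0
DEFAULT_DURATION_MS = 500.0
DEFAULT_ISI_MS = 500.0
DEFAULT_TAPER_MS = 10.0
DEFAULT_SAMPLE_RATE = 44100
# Nominal /ɑ/ formant centers (Hz) for an adult female talker.
DEFAULT_FORMANTS_HZ = (700.0, 1100.0, 2600.0)
DEFAULT_FORMANT_BW_HZ = (90.0, 110.0, 170.0)
DEFAULT_HEADROOM = 0.9


def cents_to_hz(reference_fo: float, shift_cents: float) -> float:
    """Frequency obtained by shifting ``reference_fo`` by ``shift_cents``.

    A cent is 1/1200 of an octave, so the returned value is
    ``reference_fo * 2**(shift_cents / 1200)``.
    """
    if reference_fo <= 0:
        raise ValueError(f"reference_fo must be positive, got {reference_fo}")
    return reference_fo * 2.0 ** (shift_cents / 1200.0)


def hz_to_cents(frequency: float, reference_fo: float) -> float:
    """Shift in cents of ``frequency`` relative to ``reference_fo``."""
    if reference_fo <= 0 or frequency <= 0:
        raise ValueError("frequencies must be positive")
    return 1200.0 * np.log2(frequency / reference_fo)


@dataclass(frozen=True)
class VowelSpec:
    """Parameters of a synthetic steady vowel.

    Attributes
    ----------
    fo_hz
        Fundamental frequency in Hz.  Default 239 Hz (female /ɑ/).
    duration_ms
        Segment length in milliseconds.  Default 500 ms.
    sample_rate_hz
        Audio sampling rate.  Must satisfy the Nyquist condition for every
        synthesized harmonic.
    formants_hz, formant_bandwidths_hz
        Formant center frequencies and bandwidths shaping the harmonic
        source into an /ɑ/-like spectrum.
    max_harmonic_hz
        Highest harmonic frequency synthesized; harmonics above this (or
        above Nyquist) are omitted.
    """

    fo_hz: float = DEFAULT_FO_HZ
    duration_ms: float = DEFAULT_DURATION_MS
    sample_rate_hz: int = DEFAULT_SAMPLE_RATE
    formants_hz: tuple[float, ...] = DEFAULT_FORMANTS_HZ
    formant_bandwidths_hz: tuple[float, ...] = DEFAULT_FORMANT_BW_HZ
    max_harmonic_hz: float = 5000.0
    headroom: float = DEFAULT_HEADROOM

    def __post_init__(self) -> None:
        if self.fo_hz <= 0:
            raise ValueError(f"fo_hz must be positive, got {self.fo_hz}")
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.max_harmonic_hz > self.sample_rate_hz / 2:
            raise ValueError(
                "aliasing configuration: max_harmonic_hz exceeds Nyquist"
            )
        if self.fo_hz > self.max_harmonic_hz:
            raise ValueError("fo_hz exceeds max_harmonic_hz: no harmonics fit")
        if not 0 < self.headroom <= 1:
            raise ValueError("headroom must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_ms / 1000.0 * self.sample_rate_hz))


@dataclass(frozen=True)
class TrialAudio:
    """Two-interval trial audio: reference and fo-shifted comparison.

    ``reference_position`` records which interval (1 or 2) holds the
    reference; ``shift_cents`` is the fo shift of the comparison and is 0
    exactly on catch trials (reference played twice).
    """

    interval_1: np.ndarray
    interval_2: np.ndarray
    sample_rate_hz: int
    isi_ms: float = DEFAULT_ISI_MS
    reference_position: int = 1
    shift_cents: float = 0.0

    def __post_init__(self) -> None:
        if self.reference_position not in (1, 2):
            raise ValueError("reference_position must be 1 or 2")
        if self.shift_cents < 0:
            raise ValueError("shift_cents must be non-negative")
        if len(self.interval_1) != len(self.interval_2):
            raise ValueError("intervals must have identical duration")

    @property
    def is_catch(self) -> bool:
        return self.shift_cents == 0.0

    def render(self) -> np.ndarray:
        """Concatenate interval 1, the silent gap, and interval 2."""
        gap = np.zeros(int(round(self.isi_ms / 1000.0 * self.sample_rate_hz)))
        return np.concatenate([self.interval_1, gap, self.interval_2])


def synthesize_vowel(spec: VowelSpec) -> np.ndarray:
    """Generate a steady formant-synthesized vowel waveform.

    A harmonic series at multiples of ``spec.fo_hz`` is weighted by a
    glottal-source roll-off (-12 dB/octave) and a sum of second-order
    formant resonances, then peak-normalized to ``spec.headroom``.  The
    result is deterministic: no noise source is included.
    """
    nyquist = spec.sample_rate_hz / 2.0
    top = min(spec.max_harmonic_hz, nyquist)
    n_harm = int(top // spec.fo_hz)
    if n_harm < 1:
        raise ValueError(
            f"no harmonic of fo={spec.fo_hz} Hz fits below {top} Hz"
        )
    t = np.arange(spec.n_samples) / spec.sample_rate_hz
    k = np.arange(1, n_harm + 1)
    freqs = k * spec.fo_hz
    # glottal source: amplitude falls as 1/k^2 (~ -12 dB/octave)
    source = 1.0 / k**2
    envelope = _formant_gain(freqs, spec.formants_hz, spec.formant_bandwidths_hz)
    amps = source * envelope
    wave = np.sum(amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * t[None, :]), axis=0)
    peak = np.max(np.abs(wave))
    return wave * (spec.headroom / peak)


def _formant_gain(
    freqs: np.ndarray,
    formants_hz: tuple[float, ...],
    bandwidths_hz: tuple[float, ...],
) -> np.ndarray:
    """Magnitude response of a bank of second-order resonators."""
    gain = np.zeros_like(freqs, dtype=float)
    for fc, bw in zip(formants_hz, bandwidths_hz):
        # Lorentzian peak, unity gain at center
        gain += 1.0 / np.sqrt(1.0 + ((freqs**2 - fc**2) / (bw * freqs)) ** 2)
    return gain


def apply_taper(waveform: np.ndarray, sample_rate_hz: int,
                ramp_ms: float = DEFAULT_TAPER_MS) -> np.ndarray:
    """Apply raised-cosine onset/offset ramps to a waveform.

    The gain rises as ``0.5 * (1 - cos(pi * t / ramp_ms))`` over the first
    ``ramp_ms`` milliseconds and falls by the mirrored curve at the end.
    Interior samples are unchanged.
    """
    n = len(waveform)
    n_ramp = int(round(ramp_ms / 1000.0 * sample_rate_hz))
    if 2 * n_ramp > n:
        raise ValueError(
            f"ramp of {ramp_ms} ms does not fit twice in a {n}-sample waveform"
        )
    out = np.asarray(waveform, dtype=float).copy()
    if n_ramp == 0:
        return out
    ramp_t = np.arange(n_ramp) / sample_rate_hz * 1000.0
    gain = 0.5 * (1.0 - np.cos(np.pi * ramp_t / ramp_ms))
    out[:n_ramp] *= gain
    out[-n_ramp:] *= gain[::-1]
    return out


def assemble_trial(
    reference: np.ndarray,
    comparison: np.ndarray,
    sample_rate_hz: int,
    shift_cents: float,
    rng: np.random.Generator,
    isi_ms: float = DEFAULT_ISI_MS,
    reference_sample_rate_hz: int | None = None,
) -> TrialAudio:
    """Order the reference and comparison randomly into a two-interval trial.

    The reference occupies interval 1 with probability 0.5 under ``rng``.
    """
    if reference_sample_rate_hz is not None and reference_sample_rate_hz != sample_rate_hz:
        raise ValueError("reference and comparison sample rates differ")
    reference_first = bool(rng.random() < 0.5)
    if reference_first:
        i1, i2, pos = reference, comparison, 1
    else:
        i1, i2, pos = comparison, reference, 2
    return TrialAudio(
        interval_1=np.asarray(i1, dtype=float),
        interval_2=np.asarray(i2, dtype=float),
        sample_rate_hz=sample_rate_hz,
        isi_ms=isi_ms,
        reference_position=pos,
        shift_cents=shift_cents,
    )


def make_trial_audio(
    shift_cents: float,
    rng: np.random.Generator,
    spec: VowelSpec | None = None,
    isi_ms: float = DEFAULT_ISI_MS,
    taper_ms: float = DEFAULT_TAPER_MS,
) -> TrialAudio:
    """Synthesize, taper, and assemble a full trial at a given fo shift.

    A shift of 0 produces a catch trial whose two intervals are identical.
    """
    spec = spec or VowelSpec()
    ref = apply_taper(synthesize_vowel(spec), spec.sample_rate_hz, taper_ms)
    if shift_cents == 0.0:
        cmp_wave = ref
    else:
        shifted = VowelSpec(
            fo_hz=cents_to_hz(spec.fo_hz, shift_cents),
            duration_ms=spec.duration_ms,
            sample_rate_hz=spec.sample_rate_hz,
            formants_hz=spec.formants_hz,
            formant_bandwidths_hz=spec.formant_bandwidths_hz,
            max_harmonic_hz=spec.max_harmonic_hz,
            headroom=spec.headroom,
        )
        cmp_wave = apply_taper(
            synthesize_vowel(shifted), spec.sample_rate_hz, taper_ms
        )
    return assemble_trial(
        ref, cmp_wave, spec.sample_rate_hz, shift_cents, rng, isi_ms
    )


def estimate_fo(
    waveform: np.ndarray,
    sample_rate_hz: int,
    fmin_hz: float = 80.0,
    fmax_hz: float = 1000.0,
) -> float:
    """Estimate the fundamental frequency of a periodic waveform.

    Autocorrelation with parabolic interpolation around the peak lag in
    the [1/fmax, 1/fmin] range; accurate to well under 1 Hz for steady
    harmonic signals.
    """
    x = np.asarray(waveform, dtype=float)
    x = x - x.mean()
    # FFT-based autocorrelation (zero-padded to avoid circular wrap)
    nfft = int(2 ** np.ceil(np.log2(2 * len(x))))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[: len(x)]
    lag_min = int(sample_rate_hz / fmax_hz)
    lag_max = min(int(sample_rate_hz / fmin_hz), len(ac) - 2)
    if lag_max <= lag_min:
        raise ValueError("waveform too short for the requested fo range")
    seg = ac[lag_min:lag_max]
    peak = int(np.argmax(seg)) + lag_min
    # parabolic refinement over (peak-1, peak, peak+1)
    y0, y1, y2 = ac[peak - 1], ac[peak], ac[peak + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return sample_rate_hz / (peak + delta)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate_hz: int) -> None:
    """Write a waveform as 16-bit PCM WAV (values clipped to [-1, 1])."""
    clipped = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(str(path), sample_rate_hz, (clipped * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file and return (float waveform in [-1, 1], sample rate)."""
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return np.asarray(data, dtype=float), int(rate)
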