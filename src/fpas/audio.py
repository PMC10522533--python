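"""Stimulus-level audio processing for fast periodic auditory stimulation.

Vocalization stimuli are short (350 ms) mono waveforms.  This module covers
the operations applied to every stimulus before it enters a sequence:
RMS equalization, onset/offset ramps, acoustic feature measurement
(spectral center of gravity, fundamental frequency, harmonicity-to-noise
ratio), Hilbert envelopes, and the frequency-scrambling control that
destroys harmonicity and intelligibility while preserving the coarse
spectro-temporal profile.

A seeded generator of synthetic non-verbal vocalizations is included so
the whole pipeline can run without any recorded stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import hilbert

EMOTION_CATEGORIES = ("anger", "disgust", "fear", "happiness", "sadness")

#: default stimulus duration (s)
STIMULUS_DURATION_S = 0.350
#: default onset/offset ramp (ms)
RAMP_MS = 10.0
#: width of the spectral windows within which FFT bins are shuffled (Hz)
SCRAMBLE_WINDOW_HZ = 200.0
#: normalized-autocorrelation voicing threshold for pitch detection
VOICING_THRESHOLD = 0.45
#: cap for the harmonicity-to-noise ratio of nearly pure tones (dB)
HNR_CAP_DB = 60.0


class SilentStimulusError(ValueError):
    """Raised when an operation requires a non-silent waveform."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Sample values, arbitrary amplitude units.
    rate : int
        Sampling rate in Hz.
    label : str
        Free-text identifier (stimulus id).
    category : str or None
        Emotion category, one of :data:`EMOTION_CATEGORIES`, or None.
    """

    samples: np.ndarray
    rate: int
    label: str = ""
    category: str | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.category is not None and self.category not in EMOTION_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self.samples) / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def with_samples(self, samples: np.ndarray) -> "Waveform":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class AcousticFeatures:
    """Summary acoustic features of a stimulus.

    ``pitch`` and ``hnr`` are ``None`` for aperiodic (unvoiced) input.
    """

    cog: float
    pitch: float | None
    hnr: float | None
    rms: float


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def read_wav(path: str | Path, label: str | None = None,
             category: str | None = None) -> Waveform:
    """Read a mono RIFF WAV file (PCM or float) into a :class:`Waveform`.

    Integer PCM is rescaled to [-1, 1]; float data is taken as-is.
    """
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(f"{path}: only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return Waveform(data, int(rate), label=label or Path(path).stem,
                    category=category)


def write_wav(path: str | Path, w: Waveform, subtype: str = "float32") -> None:
    """Write a waveform as WAV (``float32`` or ``pcm16``)."""
    if subtype == "float32":
        wavfile.write(str(path), w.rate, w.samples.astype(np.float32))
    elif subtype == "pcm16":
        peak = np.max(np.abs(w.samples))
        scale = 0.999 / peak if peak > 1.0 else 1.0
        data = np.round(w.samples * scale * 32767).astype(np.int16)
        wavfile.write(str(path), w.rate, data)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


# ---------------------------------------------------------------------------
# Energy and ramps
# ---------------------------------------------------------------------------

def rms_equalize(w: Waveform, target_rms: float) -> Waveform:
    """Scale a waveform to a target root-mean-square level."""
    if target_rms <= 0:
        raise ValueError("target_rms must be positive")
    current = w.rms
    if current == 0.0:
        raise SilentStimulusError(f"silent stimulus {w.label!r}: RMS is zero")
    if current == target_rms:
        return w
    return w.with_samples(w.samples * (target_rms / current))


def apply_ramps(w: Waveform, ramp_ms: float = RAMP_MS) -> Waveform:
    """Apply linear onset and offset amplitude ramps.

    The first and last ``ramp_ms`` milliseconds are multiplied by a
    monotone 0->1 (resp. 1->0) envelope; samples in between are untouched.
    """
    if ramp_ms < 0:
        raise ValueError("ramp_ms must be non-negative")
    if ramp_ms == 0:
        return w
    n_ramp = int(round(ramp_ms / 1000.0 * w.rate))
    if n_ramp == 0:
        return w
    if 2 * n_ramp > len(w.samples):
        raise ValueError(
            f"ramp of {ramp_ms} ms does not fit twice in a "
            f"{w.duration * 1000:.1f} ms waveform")
    env = np.ones(len(w.samples))
    ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    env[:n_ramp] = ramp
    env[-n_ramp:] = ramp[::-1]
    return w.with_samples(w.samples * env)


# ---------------------------------------------------------------------------
# Acoustic features
# ---------------------------------------------------------------------------

def spectral_cog(w: Waveform) -> float:
    """Spectral center of gravity: power-weighted mean frequency (Hz).

    Computed on the full waveform with a rectangular window; the DC bin is
    excluded from the weighting.
    """
    if w.rms == 0.0:
        raise SilentStimulusError("cannot compute COG of a silent stimulus")
    spec = np.abs(np.fft.rfft(w.samples))
    freqs = np.fft.rfftfreq(len(w.samples), d=1.0 / w.rate)
    power = spec[1:] ** 2
    return float(np.sum(freqs[1:] * power) / np.sum(power))


def _autocorr_pitch(samples: np.ndarray, rate: int, fmin: float,
                    fmax: float) -> tuple[float, float] | None:
    """Return (f0, normalized autocorrelation at the f0 lag) or None.

    Biased autocorrelation via FFT; the lag search runs over
    [rate/fmax, rate/fmin].  Parabolic interpolation refines the peak lag.
    """
    x = samples - samples.mean()
    if not np.any(x):
        return None
    n = len(x)
    nfft = 2 ** int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    if ac[0] <= 0:
        return None
    # unbiased estimate: the raw FFT autocorrelation shrinks by (n-lag)/n
    ac = ac / ac[0] * (n / (n - np.arange(n)))
    lag_min = max(2, int(np.floor(rate / fmax)))
    lag_max = int(np.ceil(rate / fmin))
    if lag_max >= n - 1 or lag_min >= lag_max:
        return None
    seg = ac[lag_min:lag_max + 1]
    k = int(np.argmax(seg))
    lag = lag_min + k
    # parabolic interpolation around the integer-lag peak
    if 1 <= lag < n - 1:
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        r = float(y1 - 0.25 * (y0 - y2) * delta)
        lag_f = lag + delta
    else:
        r = float(ac[lag])
        lag_f = float(lag)
    return rate / lag_f, min(r, 1.0)


def estimate_pitch(w: Waveform, fmin: float = 75.0, fmax: float = 600.0,
                   voicing_threshold: float = VOICING_THRESHOLD) -> float | None:
    """Autocorrelation pitch estimate in [fmin, fmax] Hz.

    Returns ``None`` when the peak normalized autocorrelation falls below
    the voicing threshold (aperiodic input).
    """
    if w.duration < 2.0 / fmin:
        raise ValueError("waveform too short for the requested fmin")
    res = _autocorr_pitch(w.samples, w.rate, fmin, fmax)
    if res is None:
        return None
    f0, r = res
    if r < voicing_threshold:
        return None
    return f0


def hnr(w: Waveform, fmin: float = 75.0, fmax: float = 600.0,
        cap_db: float = HNR_CAP_DB, require_voiced: bool = True
        ) -> float | None:
    """Harmonicity-to-noise ratio in dB, ``None`` for unvoiced input.

    With r the normalized autocorrelation at the pitch lag,
    HNR = 10 log10(r / (1 - r)), capped at ``cap_db``.  With
    ``require_voiced=False`` the (possibly strongly negative) value is
    returned even below the voicing threshold, which is useful for
    comparing harmonicity before and after scrambling.
    """
    res = _autocorr_pitch(w.samples, w.rate, fmin, fmax)
    if res is None:
        return None
    _, r = res
    if require_voiced and r < VOICING_THRESHOLD:
        return None
    if r <= 0.0:
        return -cap_db
    if r >= 1.0 - 10 ** (-cap_db / 10.0):
        return cap_db
    return min(cap_db, 10.0 * np.log10(r / (1.0 - r)))


def acoustic_features(w: Waveform) -> AcousticFeatures:
    """COG, pitch, HNR and RMS of one stimulus."""
    return AcousticFeatures(cog=spectral_cog(w), pitch=estimate_pitch(w),
                            hnr=hnr(w), rms=w.rms)


def hilbert_envelope(w: Waveform, smooth_hz: float | None = None) -> Waveform:
    """Magnitude of the analytic signal (non-negative, same length/rate).

    ``smooth_hz`` optionally low-passes the envelope (zero-phase, 4th
    order) to the slow temporal-envelope fluctuations, removing
    pitch-rate ripple; the raw magnitude is returned by default.
    """
    env = np.abs(hilbert(w.samples))
    if smooth_hz is not None:
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, smooth_hz, fs=w.rate, output="sos")
        env = sosfiltfilt(sos, env)
    return w.with_samples(env)


# ---------------------------------------------------------------------------
# Frequency scrambling
# ---------------------------------------------------------------------------

def _scramble_spectrum(spec: np.ndarray, n: int, rate: int, window_hz: float,
                       rng: np.random.Generator, mode: str) -> np.ndarray:
    """Permute rFFT coefficients within consecutive ``window_hz`` windows.

    Windows are aligned from 0 Hz; the DC bin (and the Nyquist bin for even
    n) never move so the inverse transform stays real and mean-preserving.
    """
    out = spec.copy()
    df = rate / n
    bins_per_window = int(round(window_hz / df))
    if bins_per_window < 1:
        raise ValueError(
            f"scramble window {window_hz} Hz is narrower than the "
            f"{df:.1f} Hz spectral resolution")
    first = 1                                      # DC fixed
    stop = len(spec) - 1 if n % 2 == 0 else len(spec)   # Nyquist fixed
    for start in range(first, stop, bins_per_window):
        end = min(start + bins_per_window, stop)
        idx = np.arange(start, end)
        if len(idx) < 2:
            continue
        perm = rng.permutation(len(idx))
        if mode == "joint":
            out[idx] = spec[idx][perm]
        elif mode == "independent":
            perm2 = rng.permutation(len(idx))
            mag = np.abs(spec[idx])[perm]
            phase = np.angle(spec[idx])[perm2]
            out[idx] = mag * np.exp(1j * phase)
        else:
            raise ValueError(f"unknown scramble mode {mode!r}")
    return out


def scramble_frequency(w: Waveform, window_hz: float = SCRAMBLE_WINDOW_HZ,
                       seed: int | np.random.Generator = 0,
                       mode: str = "joint",
                       envelope_mode: str = "multiply",
                       target_rms: float | None = None,
                       ramp_ms: float = RAMP_MS) -> Waveform:
    """Frequency-scramble a stimulus.

    Pipeline: Hilbert envelope of the original -> FFT -> shuffle complex
    coefficients within consecutive ``window_hz`` windows of the positive
    half (Hermitian symmetry is implicit in the rFFT representation; DC and
    Nyquist are never moved) -> inverse FFT -> apply the original
    envelope -> RMS-equalize (to ``target_rms``, default the input's RMS)
    -> re-apply onset/offset ramps.

    ``mode='joint'`` moves magnitude and phase together with one seeded
    permutation per window; ``mode='independent'`` draws separate
    permutations for magnitudes and phases.

    ``envelope_mode='multiply'`` (default) applies the original envelope
    directly to the scrambled carrier; the carrier's own random envelope
    ripple remains, so the output's envelope is the original times a
    noise-like modulation (its mean is slightly below the original's at
    matched RMS).  ``'impose'`` flattens the carrier's envelope first,
    so the output's temporal envelope matches the original almost
    exactly.

    Flattening by itself whitens the carrier (the cosine of a randomized
    instantaneous phase spreads beyond the original band), so the impose
    mode alternates envelope flattening with band-limiting to the
    original's 99%-power bandwidth, keeping both the temporal envelope
    and the coarse spectral distribution of the source.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = len(w.samples)
    envelope = np.abs(hilbert(w.samples))
    spec = np.fft.rfft(w.samples)
    scrambled_spec = _scramble_spectrum(spec, n, w.rate, window_hz, rng,
                                        mode)
    carrier = np.fft.irfft(scrambled_spec, n=n)
    if envelope_mode == "impose":
        power = np.abs(spec) ** 2
        cum = np.cumsum(power) / np.sum(power)
        k_hi = int(np.searchsorted(cum, 0.99)) + 1

        def flatten(x: np.ndarray) -> np.ndarray:
            e = np.abs(hilbert(x))
            return x / np.maximum(e, 1e-3 * e.max())

        for _ in range(3):               # alternating projections
            cs = np.fft.rfft(flatten(carrier))
            cs[k_hi:] = 0.0
            carrier = np.fft.irfft(cs, n=n)
        carrier = flatten(carrier)
    elif envelope_mode != "multiply":
        raise ValueError(f"unknown envelope_mode {envelope_mode!r}")
    out = w.with_samples(carrier * envelope)
    out = rms_equalize(out, target_rms if target_rms is not None else w.rms)
    if envelope_mode == "multiply":
        # an imposed envelope already carries the original onset/offset
        # ramps; only the multiply variant needs fresh anti-click ramps
        out = apply_ramps(out, ramp_ms)
    return replace(out, label=w.label + "_scrambled")


# ---------------------------------------------------------------------------
# Synthetic vocalizations
# ---------------------------------------------------------------------------

# one shared voice-parameter distribution for all five categories: the
# stimulus set is acoustically matched across categories (comparable COG,
# HNR and pitch distributions), so category membership carries no
# systematic spectro-temporal signature -- heterogeneity lives at the
# exemplar level (F0 register and glide, amplitude contour, optional
# amplitude-modulation bursts, aspiration noise)
_VOICE = dict(f0=(120, 300), contour=(-0.25, 0.25), noise=(0.06, 0.14),
              am_prob=0.3, am_hz=(4.0, 8.0))


def synthesize_vocalization(category: str, seed: int | np.random.Generator,
                            rate: int = 8000,
                            duration_s: float = STIMULUS_DURATION_S,
                            target_rms: float = 0.1,
                            label: str | None = None) -> Waveform:
    """Generate one synthetic 350 ms non-verbal vocalization.

    The model is a glottal-like harmonic stack (1/k rolloff, ~12 harmonics)
    on an F0 glide, shaped by two formant-like spectral resonances, an
    attack-decay amplitude contour, occasional amplitude-modulation bursts
    (laughter- or sob-like) and a small aspiration-noise floor.  All
    categories draw from one shared parameter distribution -- the set is
    acoustically matched across emotions, as a frequency-tagging design
    requires -- so the category label only tags the exemplar.  Output is
    RMS-equalized and ramped like a real stimulus.
    """
    if category not in EMOTION_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    cfg = _VOICE
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    f0_start = rng.uniform(*cfg["f0"])
    glide = rng.uniform(*cfg["contour"])
    f0_t = f0_start * (1.0 + glide * t / duration_s)
    phase0 = 2 * np.pi * np.cumsum(f0_t) / rate

    # formant-like resonances: emphasize harmonics near two peaks
    formants = rng.uniform(400, 900), rng.uniform(1200, 2600)
    bw = 250.0, 450.0
    x = np.zeros(n)
    for k in range(1, 13):
        fk = k * np.mean(f0_t)
        if fk >= rate / 2 * 0.95:
            break
        gain = 1.0 / k
        for fc, b in zip(formants, bw):
            gain *= 1.0 + 2.0 * np.exp(-0.5 * ((fk - fc) / b) ** 2)
        x += gain * np.sin(k * phase0 + rng.uniform(0, 2 * np.pi))

    # amplitude contour: fast attack, slow decay, optional AM bursts
    attack = rng.uniform(0.02, 0.06)
    contour = np.minimum(t / attack, 1.0) * np.exp(-t / rng.uniform(0.4, 1.2))
    if rng.uniform() < cfg["am_prob"]:
        contour *= 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(*cfg["am_hz"])
                                      * t + rng.uniform(0, 2 * np.pi))
    x *= contour
    noise_level = rng.uniform(*cfg["noise"])
    noise = rng.standard_normal(n) * noise_level * np.sqrt(np.mean(x**2))
    x += noise * contour

    w = Waveform(x, rate, label=label or f"{category}_{f0_start:.0f}",
                 category=category)
    w = rms_equalize(w, target_rms)
    return apply_ramps(w)
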