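"""Synthetic CV-triplet stimuli, voice-cue (f0 + VTL) manipulation, and noise vocoding.

Voice differences are expressed in semitones (st), one twelfth of an octave,
i.e. a frequency ratio of 2**(1/12) per semitone.  A fundamental-frequency
(f0) offset of ``s`` st multiplies f0 by 2**(s/12).  A vocal-tract-length
(VTL) offset of ``s`` st lengthens the tract by the same ratio, which divides
every formant frequency by 2**(s/12) (longer tract -> lower resonances).

Stimuli are 3AFC "odd one out" trials: three consonant-vowel triplets, two
spoken by a reference voice and one (the target) by a deviant voice.  The
rendered syllables are a parametric source-filter stand-in for recorded
speech: a glottal pulse train filtered through formant resonators.

The noise vocoder simulates cochlear-implant-like spectral degradation:
the signal is split into frequency bands spaced evenly along the cochlea
(Greenwood frequency-place map), each band's temporal envelope (half-wave
rectification + low-pass) modulates a white-noise carrier, the carrier is
band-limited with the analysis filter, and the bands are summed with the
overall RMS matched to the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "VoiceSpec",
    "TrialAudioSpec",
    "VocoderConfig",
    "AudioSignal",
    "TrialAnnotation",
    "VOWEL_FORMANTS",
    "semitone_ratio",
    "apply_voice_shift",
    "synth_syllable",
    "make_trial_audio",
    "greenwood_cutoffs",
    "vocode",
    "read_wav",
    "write_wav",
]

# Female /a, i, u/ formant inventory (Hz); approximate literature values,
# exposed as defaults rather than claims about any particular talker.
VOWEL_FORMANTS: dict[str, tuple[float, ...]] = {
    "a": (850.0, 1220.0, 2810.0),
    "i": (310.0, 2790.0, 3310.0),
    "u": (370.0, 950.0, 2670.0),
}


@dataclass(frozen=True)
class VoiceSpec:
    """A talker parameterized as semitone offsets from a reference voice.

    Parameters
    ----------
    f0_ref : reference fundamental frequency in Hz.
    df0_st : signed f0 offset in semitones.
    dvtl_st : signed vocal-tract-length offset in semitones; positive means a
        longer tract, which *lowers* the formants by the semitone ratio.
    formants_ref : ordered reference formant frequencies in Hz (strictly
        increasing).  ``None`` defers to the per-vowel inventory.
    """

    f0_ref: float = 225.0
    df0_st: float = 0.0
    dvtl_st: float = 0.0
    formants_ref: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.f0_ref) and self.f0_ref > 0):
            raise ValueError("f0_ref must be a positive finite frequency in Hz")
        if self.formants_ref is not None:
            f = np.asarray(self.formants_ref, dtype=float)
            if f.size == 0 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
                raise ValueError("formants_ref must be positive and strictly increasing")


@dataclass(frozen=True)
class TrialAudioSpec:
    """Timing of a 3AFC trial: 3 triplets of 3 CV syllables.

    Defaults follow the trial layout of 200 ms syllables, 50 ms gaps inside a
    triplet, and 950 ms gaps between triplets, for a 4.0 s stimulus.
    """

    syllable_dur_s: float = 0.200
    intra_gap_s: float = 0.050
    inter_gap_s: float = 0.950
    n_syllables: int = 3
    n_triplets: int = 3
    sample_rate: float = 44100.0
    fade_s: float = 0.060
    rms_level: float = 0.1

    def __post_init__(self) -> None:
        for name in ("syllable_dur_s", "intra_gap_s", "inter_gap_s", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def triplet_dur_s(self) -> float:
        return self.n_syllables * self.syllable_dur_s + (self.n_syllables - 1) * self.intra_gap_s

    @property
    def total_dur_s(self) -> float:
        return self.n_triplets * self.triplet_dur_s + (self.n_triplets - 1) * self.inter_gap_s


@dataclass(frozen=True)
class VocoderConfig:
    """Noise-vocoder settings: band count, filter order, analysis range.

    ``filter_order`` is the effective magnitude order of the zero-phase
    band-pass; it is realized as a forward-backward pass of a half-order
    Butterworth band-pass, so phase is zero and the magnitude response is
    of the stated order.  ``greenwood_A/a/k`` are the constants of the human
    cochlear frequency-place map F(x) = A*(10**(a*x) - k), x in [0, 1].
    """

    n_bands: int = 12
    filter_order: int = 12
    f_lo: float = 150.0
    f_hi: float = 7000.0
    env_cutoff: float = 300.0
    env_order: int = 2
    carrier: str = "white-noise"
    greenwood_A: float = 165.4
    greenwood_a: float = 2.1
    greenwood_k: float = 0.88

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError("require 0 < f_lo < f_hi")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.env_cutoff <= 0:
            raise ValueError("env_cutoff must be > 0")
        if self.filter_order % 4 != 0:
            raise ValueError("filter_order must be a multiple of 4 (zero-phase realization)")


@dataclass
class AudioSignal:
    """A mono waveform with its sample rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal is mono: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples)))) if len(self.samples) else 0.0


@dataclass
class TrialAnnotation:
    """Segment boundaries of one 3AFC trial (seconds from stimulus onset)."""

    target_position: int
    triplet_onsets_s: list[float] = field(default_factory=list)
    triplet_offsets_s: list[float] = field(default_factory=list)
    syllables: list[tuple[str, str, str]] = field(default_factory=list)


def semitone_ratio(st: float) -> float:
    """Frequency ratio of a signed semitone offset: 2**(st/12).

    One semitone is a ratio of 2**(1/12) ~ 1.059 (a 5.9% change); -12 st
    halves the frequency.
    """
    st = float(st)
    if not np.isfinite(st):
        raise ValueError("semitone offset must be finite")
    return float(2.0 ** (st / 12.0))


def apply_voice_shift(voice: VoiceSpec, formants: tuple[float, ...] | None = None) -> tuple[float, np.ndarray]:
    """Resolve a :class:`VoiceSpec` to concrete (f0, formants) in Hz.

    f0 is multiplied by the semitone ratio of ``df0_st``.  A VTL increase of
    ``dvtl_st`` st lengthens the tract by 2**(dvtl_st/12), dividing every
    formant by that factor.
    """
    base = formants if formants is not None else voice.formants_ref
    if base is None:
        base = VOWEL_FORMANTS["a"]
    f0 = voice.f0_ref * semitone_ratio(voice.df0_st)
    shifted = np.asarray(base, dtype=float) / semitone_ratio(voice.dvtl_st)
    return f0, shifted


def _resonator_sos(freq: float, bw: float, fs: float) -> np.ndarray:
    """Second-order resonator section with unit gain at its center frequency."""
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * freq / fs
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    # normalize gain at the resonance frequency
    w, h = signal.freqz([1.0, 0.0, 0.0], a, worN=[theta], fs=2 * np.pi)
    g = np.abs(h[0])
    return np.array([[1.0 / g, 0.0, 0.0, *a]])


def synth_syllable(
    voice: VoiceSpec,
    spec: TrialAudioSpec,
    vowel: str = "a",
    seed: int | np.random.Generator | None = 0,
) -> AudioSignal:
    """Render one CV-like syllable for a (possibly shifted) voice.

    A glottal pulse train at the shifted f0 is passed through a cascade of
    formant resonators at the shifted formant frequencies, a trace of
    seeded aspiration noise is added, a 60 ms cosine fade-out is applied,
    and the result is RMS-normalized.
    """
    fs = spec.sample_rate
    f0, formants = apply_voice_shift(voice, VOWEL_FORMANTS.get(vowel))
    if f0 >= fs / 2 or np.any(formants >= fs / 2):
        raise ValueError("f0 and formants must lie below the Nyquist frequency")
    n = round(fs * spec.syllable_dur_s)

    # impulse train at the (flat) shifted f0; fractional-period phase accumulator
    phase = np.cumsum(np.full(n, f0 / fs))
    pulses = np.diff(np.floor(phase), prepend=0.0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    src = pulses + 1e-3 * rng.standard_normal(n)

    out = src
    for f in formants:
        bw = 80.0 + 0.05 * f
        out = signal.sosfilt(_resonator_sos(f, bw, fs), out)

    n_fade = min(n, round(fs * spec.fade_s))
    if n_fade > 0:
        ramp = 0.5 * (1.0 + np.cos(np.linspace(0.0, np.pi, n_fade)))
        out[n - n_fade:] *= ramp

    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out = out * (spec.rms_level / rms)
    return AudioSignal(out, fs)


def make_trial_audio(
    reference: VoiceSpec,
    target: VoiceSpec,
    target_position: int,
    variability: str = "fixed",
    spec: TrialAudioSpec | None = None,
    seed: int | np.random.Generator | None = 0,
) -> tuple[AudioSignal, TrialAnnotation]:
    """Assemble one 3AFC trial: three CV triplets, one spoken by the target voice.

    ``variability='fixed'`` draws one syllable sequence and uses it for all
    three triplets; ``'variable'`` draws an independent sequence per triplet.
    The waveform length is exactly ``round(sample_rate * total_dur_s)``.
    """
    if target_position not in (1, 2, 3):
        raise ValueError("target_position must be 1, 2 or 3")
    if variability not in ("fixed", "variable"):
        raise ValueError("variability must be 'fixed' or 'variable'")
    spec = spec or TrialAudioSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = spec.sample_rate

    vowels = list(VOWEL_FORMANTS)
    draw = lambda: tuple(rng.choice(vowels) for _ in range(spec.n_syllables))
    fixed_content = draw()

    ann = TrialAnnotation(target_position=target_position)
    n_intra = round(fs * spec.intra_gap_s)
    n_inter = round(fs * spec.inter_gap_s)
    # each (voice, syllable) token is rendered once per trial and reused, as
    # a recorded item would be replayed; repeated content is sample-identical
    token_cache: dict[tuple[VoiceSpec, str], np.ndarray] = {}

    def render(voice: VoiceSpec, vowel: str) -> np.ndarray:
        key = (voice, vowel)
        if key not in token_cache:
            token_cache[key] = synth_syllable(voice, spec, vowel=vowel, seed=rng).samples
        return token_cache[key]

    pieces: list[np.ndarray] = []
    pos = 0
    for trip in range(1, spec.n_triplets + 1):
        content = fixed_content if variability == "fixed" else draw()
        voice = target if trip == target_position else reference
        ann.triplet_onsets_s.append(pos / fs)
        for k, v in enumerate(content):
            token = render(voice, v)
            pieces.append(token)
            pos += len(token)
            if k < spec.n_syllables - 1:
                pieces.append(np.zeros(n_intra))
                pos += n_intra
        ann.triplet_offsets_s.append(pos / fs)
        ann.syllables.append(content)  # type: ignore[arg-type]
        if trip < spec.n_triplets:
            pieces.append(np.zeros(n_inter))
            pos += n_inter

    wave = np.concatenate(pieces)
    n_total = round(fs * spec.total_dur_s)
    if len(wave) < n_total:
        wave = np.pad(wave, (0, n_total - len(wave)))
    else:
        wave = wave[:n_total]
    return AudioSignal(wave, fs), ann


def greenwood_cutoffs(cfg: VocoderConfig) -> np.ndarray:
    """Band-edge frequencies spaced evenly along the cochlea.

    The Greenwood frequency-place map F(x) = A*(10**(a*x) - k) is inverted at
    the positions of ``f_lo`` and ``f_hi``; interior edges sit at equally
    spaced relative cochlear positions between them.  Endpoints are returned
    exactly as configured.
    """
    A, a, k = cfg.greenwood_A, cfg.greenwood_a, cfg.greenwood_k
    x = lambda f: np.log10(f / A + k) / a
    positions = np.linspace(x(cfg.f_lo), x(cfg.f_hi), cfg.n_bands + 1)
    edges = A * (10.0 ** (a * positions) - k)
    edges[0] = cfg.f_lo
    edges[-1] = cfg.f_hi
    return edges


def _bandpass_sos(lo: float, hi: float, order: int, fs: float) -> np.ndarray:
    # order//4 Butterworth sections -> band-pass of order order//2; the
    # forward-backward pass squares the magnitude for an effective `order`.
    return signal.butter(order // 4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def vocode(
    audio: AudioSignal,
    cfg: VocoderConfig | None = None,
    seed: int | np.random.Generator | None = 0,
) -> AudioSignal:
    """Noise-vocode a waveform.

    Per band: zero-phase band-pass -> half-wave rectification -> low-pass at
    ``env_cutoff`` -> multiply a fresh white-noise carrier -> re-filter with
    the same band-pass (synthesis filter = analysis filter).  Bands are
    summed and the output is scaled so its RMS equals the input RMS.
    """
    cfg = cfg or VocoderConfig()
    fs = audio.sample_rate
    if fs / 2 <= cfg.f_hi:
        raise ValueError("sample rate too low: Nyquist must exceed f_hi")
    if len(audio.samples) == 0:
        raise ValueError("audio must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    edges = greenwood_cutoffs(cfg)
    lp = signal.butter(cfg.env_order, cfg.env_cutoff, btype="lowpass", fs=fs, output="sos")
    x = audio.samples
    out = np.zeros_like(x)
    for b in range(cfg.n_bands):
        sos = _bandpass_sos(edges[b], edges[b + 1], cfg.filter_order, fs)
        band = signal.sosfiltfilt(sos, x)
        env = signal.sosfiltfilt(lp, np.maximum(band, 0.0))
        carrier = rng.standard_normal(len(x))
        out += signal.sosfiltfilt(sos, env * carrier)

    rms_in = audio.rms()
    rms_out = float(np.sqrt(np.mean(out**2)))
    if rms_out > 0:
        out *= rms_in / rms_out
    return AudioSignal(out, fs)


def read_wav(path) -> AudioSignal:
    """Read a mono WAV file (PCM 16/24-bit or float) as a float waveform in [-1, 1]."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return AudioSignal(data, float(fs))


def write_wav(path, audio: AudioSignal) -> None:
    """Write a waveform as a 32-bit float mono WAV file."""
    wavfile.write(path, int(round(audio.sample_rate)), audio.samples.astype(np.float32))
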