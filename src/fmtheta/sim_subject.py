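"""Synthetic responsive EEG subject.

Generates seeded 8-channel pink-noise EEG (Fpz, Fz, F7, F8, Cz, P7, P8, Oz)
with a frontal theta oscillation whose amplitude tracks a latent attention
state. The attention state follows an Ornstein–Uhlenbeck drift around a
session-level set-point and can be nudged by the displayed feedback value,
closing the loop. Blink and muscle artifacts are injected on demand with
ground-truth intervals, so that the artifact-rejection stage can be tested
against known truth.

This is a phenomenological signal model, not a biophysical one: the theta
component at Fz is a sinusoid of amplitude ``baseline_theta_amp +
theta_gain * attention_state`` (microvolts) at every sample, riding on
spatially correlated 1/f noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

MONTAGE = ("Fpz", "Fz", "F7", "F8", "Cz", "P7", "P8", "Oz")

# Spatial weight of the frontal-midline theta source on each montage channel:
# maximal at Fz, strong at Fpz/Cz, weak posteriorly.
_THETA_TOPOGRAPHY = {
    "Fpz": 0.7, "Fz": 1.0, "F7": 0.4, "F8": 0.4,
    "Cz": 0.7, "P7": 0.1, "P8": 0.1, "Oz": 0.05,
}
# Posterior alpha and diffuse beta topographies.
_ALPHA_TOPOGRAPHY = {
    "Fpz": 0.1, "Fz": 0.2, "F7": 0.15, "F8": 0.15,
    "Cz": 0.4, "P7": 0.9, "P8": 0.9, "Oz": 1.0,
}
_BETA_TOPOGRAPHY = {
    "Fpz": 0.4, "Fz": 0.5, "F7": 0.5, "F8": 0.5,
    "Cz": 0.5, "P7": 0.4, "P8": 0.4, "Oz": 0.3,
}
_BLINK_TOPOGRAPHY = {
    "Fpz": 1.0, "Fz": 0.5, "F7": 0.3, "F8": 0.3,
    "Cz": 0.15, "P7": 0.02, "P8": 0.02, "Oz": 0.01,
}


@dataclass(frozen=True)
class SubjectModel:
    """Parameters of a simulated neurofeedback subject.

    Amplitudes are in microvolts. ``attention_state`` is the initial latent
    attention in [0, 1]; the theta amplitude at Fz is
    ``baseline_theta_amp + theta_gain * attention_state`` at every sample.

    ``feedback_coupling`` converts one displayed feedback value into an
    attention increment (``coupling * (f - 0.5)`` per update);
    ``session_learning_rate`` shifts the attention set-point per session
    (0 for sham-like subjects). ``attention_noise_sd`` is the per-second
    diffusion of the Ornstein–Uhlenbeck attention drift.
    """

    baseline_theta_amp: float = 4.0
    theta_gain: float = 4.0
    attention_state: float = 0.3
    attention_noise_sd: float = 0.05
    attention_tau: float = 20.0          # OU mean-reversion time constant, s
    feedback_coupling: float = 0.002
    session_learning_rate: float = 0.05
    alpha_amp: float = 6.0
    beta_amp: float = 2.0
    noise_amp: float = 10.0              # pink-noise RMS per channel, uV
    noise_exponent: float = 1.0
    blink_rate: float = 4.0              # events / minute
    muscle_rate: float = 1.0             # events / minute
    sample_rate: float = 2048.0
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.attention_state <= 1.0:
            raise ValueError("attention_state must lie in [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.blink_rate < 0 or self.muscle_rate < 0:
            raise ValueError("artifact rates must be non-negative")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "SubjectModel":
        return cls(**json.loads(text))


def _pink_noise(n_samples: int, n_channels: int, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """Channels x samples 1/f^exponent noise, unit RMS, by spectral shaping."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(shaped**2, axis=1, keepdims=True))
    return shaped / rms


def _mixing_matrix(n_channels: int, neighbour_corr: float = 0.5) -> np.ndarray:
    """Fixed mixing matrix giving ~neighbour_corr correlation between
    adjacent montage channels (Toeplitz correlation, matrix square root)."""
    idx = np.arange(n_channels)
    corr = neighbour_corr ** np.abs(idx[:, None] - idx[None, :])
    w, v = np.linalg.eigh(corr)
    return v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T


class SubjectStream:
    """Stateful chunk-wise generator for a :class:`SubjectModel`.

    Keeps oscillator phases, the Ornstein–Uhlenbeck attention state and the
    RNG across chunks so that consecutive chunks form one continuous
    recording. All randomness flows from the seed given at construction.
    """

    def __init__(self, subject: SubjectModel, seed: int | None = None):
        subject.validate()
        self.subject = subject
        self.rng = np.random.default_rng(
            subject.rng_seed if seed is None else seed)
        self.attention = float(subject.attention_state)
        self.setpoint = float(subject.attention_state)
        self._phases = {
            "theta": 0.0, "alpha": 0.0, "beta": 0.0,
        }
        self._freqs = {"theta": 5.0, "alpha": 10.0, "beta": 15.0}
        self._mix = _mixing_matrix(len(MONTAGE))
        self.samples_generated = 0
        # background noise is synthesized in multi-second batches (one FFT
        # per batch) and sliced per chunk; the closed loop only modulates
        # the deterministic theta component, so batching does not change
        # the feedback dynamics
        self._noise_cache: np.ndarray | None = None
        self._noise_pos = 0
        self._cache_samples = int(16.0 * subject.sample_rate)

    def _next_noise(self, n: int) -> np.ndarray:
        if self._noise_cache is None or \
                self._noise_pos + n > self._noise_cache.shape[1]:
            batch = max(n, self._cache_samples)
            raw = _pink_noise(batch, len(MONTAGE),
                              self.subject.noise_exponent, self.rng)
            self._noise_cache = _mixing_matrix_apply(self._mix, raw)
            self._noise_pos = 0
        out = self._noise_cache[:, self._noise_pos:self._noise_pos + n]
        self._noise_pos += n
        return out

    def advance_session(self) -> None:
        """Shift the attention set-point by the per-session learning rate."""
        self.setpoint = float(
            np.clip(self.setpoint + self.subject.session_learning_rate, 0, 1))

    def apply_feedback(self, displayed_f: float) -> None:
        """Nudge attention by one displayed feedback value in [0, 1]."""
        if not 0.0 <= displayed_f <= 1.0:
            raise ValueError("displayed feedback must lie in [0, 1]")
        self.attention = float(np.clip(
            self.attention
            + self.subject.feedback_coupling * (displayed_f - 0.5), 0, 1))

    def next_chunk(self, duration: float) -> tuple[np.ndarray, np.ndarray]:
        """Generate the next ``duration`` seconds.

        Returns ``(signal, attention_trace)`` with signal of shape
        (8, duration * sample_rate) in microvolts.
        """
        if duration <= 0:
            raise ValueError("duration must be positive")
        s = self.subject
        fs = s.sample_rate
        n = int(round(duration * fs))
        dt = 1.0 / fs

        # OU attention drift, Euler-Maruyama at the sample rate:
        # a[i] = (1-k) a[i-1] + k*setpoint + sd*sqrt(dt)*noise[i], an AR(1)
        # recursion evaluated with a streaming IIR filter, then clipped to
        # [0, 1] (the clip binds only on rare boundary excursions).
        from scipy import signal as sps

        noise = self.rng.standard_normal(n)
        k = dt / s.attention_tau
        sd_step = s.attention_noise_sd * np.sqrt(dt)
        drive = k * self.setpoint + sd_step * noise
        att, zf = sps.lfilter([1.0], [1.0, -(1.0 - k)], drive,
                              zi=np.array([(1.0 - k) * self.attention]))
        att = np.clip(att, 0.0, 1.0)
        self.attention = float(att[-1])

        signal = s.noise_amp * self._next_noise(n)

        t_rel = np.arange(n) * dt
        for name, topo, amp in (
            ("theta", _THETA_TOPOGRAPHY,
             s.baseline_theta_amp + s.theta_gain * att),
            ("alpha", _ALPHA_TOPOGRAPHY, s.alpha_amp),
            ("beta", _BETA_TOPOGRAPHY, s.beta_amp),
        ):
            f = self._freqs[name]
            wave = np.sin(2 * np.pi * f * t_rel + self._phases[name])
            self._phases[name] = float(
                (self._phases[name] + 2 * np.pi * f * n * dt) % (2 * np.pi))
            weights = np.array([topo[ch] for ch in MONTAGE])
            signal += weights[:, None] * (amp * wave)[None, :] \
                if np.ndim(amp) else weights[:, None] * amp * wave[None, :]

        if s.blink_rate > 0 or s.muscle_rate > 0:
            signal, _ = inject_artifacts(
                signal, s.blink_rate, s.muscle_rate,
                seed=None, sample_rate=fs, rng=self.rng)

        self.samples_generated += n
        return signal, att


def _mixing_matrix_apply(mix: np.ndarray, noise: np.ndarray) -> np.ndarray:
    mixed = mix @ noise
    rms = np.sqrt(np.mean(mixed**2, axis=1, keepdims=True))
    return mixed / rms


def generate_block(subject: SubjectModel, duration: float,
                   seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Generate one open-loop block of EEG.

    Pure function of (subject, duration, seed): identical arguments give
    bit-identical output. Returns (signal channels x samples in microvolts,
    per-sample latent attention trace).
    """
    stream = SubjectStream(subject, seed=seed)
    return stream.next_chunk(duration)


def apply_feedback_response(subject: SubjectModel,
                            displayed_f: float) -> SubjectModel:
    """Return a copy of ``subject`` with attention nudged by one feedback
    value: ``attention += feedback_coupling * (displayed_f - 0.5)``, clipped
    to [0, 1]."""
    if not 0.0 <= displayed_f <= 1.0:
        raise ValueError("displayed feedback must lie in [0, 1]")
    new_att = float(np.clip(
        subject.attention_state
        + subject.feedback_coupling * (displayed_f - 0.5), 0.0, 1.0))
    return dataclasses.replace(subject, attention_state=new_att)


def inject_artifacts(signal: np.ndarray, blink_rate: float,
                     muscle_rate: float, seed: int | None,
                     sample_rate: float = 2048.0,
                     blink_amp: float = 150.0,
                     muscle_amp: float = 40.0,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[np.ndarray, list[dict]]:
    """Inject blink and muscle-burst artifacts into a channels x samples
    signal.

    Blinks are ~300 ms low-frequency, high-amplitude (default 150 uV at Fpz,
    well above 5x a typical 10 uV background RMS) transients with a frontal
    topography; muscle bursts are ~500 ms 20-40 Hz broadband transients on
    lateral channels. Event times are Poisson with the given rates
    (events/minute). Returns the modified signal (copy) and a list of
    ground-truth interval dicts ``{kind, start, stop}`` in seconds.
    """
    if blink_rate < 0 or muscle_rate < 0:
        raise ValueError("artifact rates must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_ch, n = signal.shape
    duration = n / sample_rate
    out = signal.copy()
    intervals: list[dict] = []

    def _poisson_times(rate_per_min: float) -> np.ndarray:
        lam = rate_per_min / 60.0 * duration
        count = rng.poisson(lam)
        return np.sort(rng.uniform(0, duration, size=count))

    for t0 in _poisson_times(blink_rate):
        width = 0.3
        i0 = int(t0 * sample_rate)
        i1 = min(n, i0 + int(width * sample_rate))
        if i1 <= i0:
            continue
        t = np.arange(i1 - i0) / sample_rate
        shape = np.sin(np.pi * t / width) ** 2          # smooth bump
        weights = np.array([_BLINK_TOPOGRAPHY[ch] for ch in MONTAGE[:n_ch]])
        out[:, i0:i1] += blink_amp * weights[:, None] * shape[None, :]
        intervals.append({"kind": "blink", "start": i0 / sample_rate,
                          "stop": i1 / sample_rate})

    for t0 in _poisson_times(muscle_rate):
        width = 0.5
        i0 = int(t0 * sample_rate)
        i1 = min(n, i0 + int(width * sample_rate))
        if i1 <= i0:
            continue
        m = i1 - i0
        burst = rng.standard_normal(m)
        # band-limit to 20-40 Hz by FFT masking
        spec = np.fft.rfft(burst)
        freqs = np.fft.rfftfreq(m, 1 / sample_rate)
        spec[(freqs < 20) | (freqs > 40)] = 0
        burst = np.fft.irfft(spec, n=m)
        burst /= max(np.sqrt(np.mean(burst**2)), 1e-30)
        taper = np.sin(np.pi * np.arange(m) / m) ** 2
        weights = np.array([0.3, 0.3, 1.0, 1.0, 0.3, 0.6, 0.6, 0.3][:n_ch])
        out[:, i0:i1] += muscle_amp * weights[:, None] * (burst * taper)[None, :]
        intervals.append({"kind": "muscle", "start": i0 / sample_rate,
                          "stop": i1 / sample_rate})

    intervals.sort(key=lambda d: d["start"])
    return out, intervals
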