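"""Artifact Subspace Reconstruction (ASR) for the streaming chain.

ASR is calibrated once per day on the 1-minute start baseline: the baseline
covariance (averaged over short sample blocks) is eigendecomposed into
orthonormal component axes, and a per-component rejection threshold is set
from the distribution of windowed component RMS amplitudes. During
streaming, sliding windows are projected onto the calibration axes and any
component whose windowed RMS exceeds its threshold is attenuated down to
the threshold before the window is reconstructed; overlapping windows are
blended so the cleaned signal is continuous across chunk boundaries.

Two deliberate simplifications relative to the original ASR publication,
both documented in the methods note: thresholds use robust (median / scaled
MAD) statistics of the windowed RMS rather than a truncated-Gaussian fit,
and offending components are clipped to their threshold rather than zeroed
or re-interpolated, which preserves continuity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from fmtheta.stream_chain import EEGChunk

_MAD_SCALE = 1.4826  # MAD -> SD for Gaussian data


@dataclass(frozen=True)
class ASRParams:
    """Calibration parameters.

    ``cutoff`` is the rejection threshold in robust-SD units (default 5);
    ``blocksize`` the number of samples per covariance averaging block;
    ``window_len`` / ``window_overlap`` (seconds) define the sliding RMS
    windows used for the threshold statistics (500 ms / 330 ms defaults).
    """

    cutoff: float = 5.0
    blocksize: int = 10
    window_len: float = 0.5
    window_overlap: float = 0.33

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 <= self.window_overlap < self.window_len:
            raise ValueError("overlap must satisfy 0 <= overlap < window_len")
        if self.blocksize < 1:
            raise ValueError("blocksize must be >= 1")


@dataclass
class ASRModel:
    """Calibration result: orthonormal component axes of the baseline
    covariance, per-component RMS thresholds (uV), and the covariance."""

    mixing: np.ndarray
    component_thresholds: np.ndarray
    calibration_cov: np.ndarray
    sample_rate: float
    params: ASRParams

    def to_json(self) -> str:
        return json.dumps({
            "mixing": self.mixing.tolist(),
            "component_thresholds": self.component_thresholds.tolist(),
            "calibration_cov": self.calibration_cov.tolist(),
            "sample_rate": self.sample_rate,
            "params": vars(self.params),
        })

    @classmethod
    def from_json(cls, text: str) -> "ASRModel":
        d = json.loads(text)
        return cls(np.asarray(d["mixing"]),
                   np.asarray(d["component_thresholds"]),
                   np.asarray(d["calibration_cov"]),
                   d["sample_rate"], ASRParams(**d["params"]))


def _windowed_rms(comp: np.ndarray, win: int, step: int) -> np.ndarray:
    """components x windows RMS over sliding windows."""
    n = comp.shape[1]
    starts = range(0, n - win + 1, step)
    return np.stack([np.sqrt(np.mean(comp[:, s:s + win] ** 2, axis=1))
                     for s in starts], axis=1)


def asr_calibrate(baseline: EEGChunk,
                  params: ASRParams = ASRParams(),
                  min_duration: float = 30.0) -> ASRModel:
    """Calibrate ASR statistics on an artifact-light baseline.

    The caller vouches that the baseline is artifact-light and at least
    ``min_duration`` seconds long (30 s default; shorter calibrations give
    noisier thresholds and should only be used for scaled-down runs).
    Covariance is the average of per-block (``blocksize`` samples) sample
    covariances; its eigenvectors are the component axes. Each component's
    threshold is ``median + cutoff * 1.4826 * MAD`` of its windowed RMS.
    """
    params.validate()
    x = np.asarray(baseline.data, dtype=float)
    n_ch, n = x.shape
    if baseline.duration < min_duration:
        raise ValueError(
            f"baseline of {baseline.duration:.1f} s is shorter than the "
            f"{min_duration:g} s minimum")
    n_blocks = n // params.blocksize
    if n_blocks < n_ch:
        raise ValueError("baseline too short for covariance estimation")
    xb = x[:, :n_blocks * params.blocksize].reshape(
        n_ch, n_blocks, params.blocksize)
    cov = np.einsum("cbs,dbs->cd", xb, xb) / (n_blocks * params.blocksize)
    evals, evecs = np.linalg.eigh(cov)
    tol = 1e-10 * np.trace(cov) / n_ch
    null = evals < tol
    if np.any(null):
        # average-referenced data is legitimately rank n-1 with the
        # common-mode (all-ones) direction null; anything else (constant
        # or duplicated channels) is a degenerate baseline
        ones = np.ones(n_ch) / np.sqrt(n_ch)
        for v in evecs[:, null].T:
            if abs(np.dot(v, ones)) < 0.99:
                raise ValueError(
                    f"rank-deficient baseline ({int(null.sum())} null "
                    "directions); check for constant or duplicated "
                    "channels")
    mixing = evecs  # orthonormal columns, ascending variance order

    comp = mixing.T @ x
    win = int(round(params.window_len * baseline.sample_rate))
    step = max(1, win - int(round(params.window_overlap
                                  * baseline.sample_rate)))
    rms = _windowed_rms(comp, win, step)
    med = np.median(rms, axis=1)
    mad = np.median(np.abs(rms - med[:, None]), axis=1)
    thresholds = med + params.cutoff * _MAD_SCALE * mad
    thresholds = np.maximum(thresholds, 1e-12)
    return ASRModel(mixing, thresholds, cov, baseline.sample_rate, params)


class ASRProcessor:
    """Streaming ASR cleaner with carried state.

    Windows of ``model.params.window_len`` are processed at 50% overlap with
    a periodic Hann blend (perfect reconstruction), so that with no
    component exceeding threshold the output equals the input exactly, and
    chunk boundaries are seamless. Output is delayed by ``delay_samples``
    (= half a window): the processor is primed with zeros so every call
    returns exactly as many samples as it receives.
    """

    def __init__(self, model: ASRModel):
        self.model = model
        self.win = int(round(model.params.window_len * model.sample_rate))
        if self.win % 2:
            self.win += 1
        self.hop = self.win // 2
        self.delay_samples = self.hop
        w = np.hanning(self.win + 1)[:-1]  # periodic Hann: 50% COLA
        self._blend = w
        n_ch = model.mixing.shape[0]
        # prime with half a window of zeros so output length tracks input
        self._inbuf = np.zeros((n_ch, self.hop))
        self._acc = np.zeros((n_ch, self.hop))
        self._wacc = np.zeros(self.hop)
        self._emitted_windows = 0
        self.last_clipped: np.ndarray | None = None

    def process(self, chunk: EEGChunk) -> EEGChunk:
        """Clean one chunk; returns a chunk of identical length (content
        delayed by ``delay_samples``)."""
        x = np.asarray(chunk.data, dtype=float)
        if x.shape[0] != self.model.mixing.shape[0]:
            raise ValueError(
                f"chunk has {x.shape[0]} channels, model expects "
                f"{self.model.mixing.shape[0]}")
        if abs(chunk.sample_rate - self.model.sample_rate) > 1e-9:
            raise ValueError("chunk sample rate differs from calibration")
        self._inbuf = np.concatenate([self._inbuf, x], axis=1)
        out = self._drain(x.shape[1])
        return EEGChunk(out, chunk.sample_rate, chunk.channel_labels,
                        chunk.start_time)

    def _drain(self, n_wanted: int) -> np.ndarray:
        mix = self.model.mixing
        thr = self.model.component_thresholds
        n_ch = mix.shape[0]
        ready = []
        # process every complete window sitting in the buffer
        while self._inbuf.shape[1] >= self.win:
            seg = self._inbuf[:, :self.win]
            comp = mix.T @ seg
            rms = np.sqrt(np.mean(comp**2, axis=1))
            gain = np.minimum(1.0, thr / np.maximum(rms, 1e-300))
            self.last_clipped = gain < 1.0
            clean = mix @ (gain[:, None] * comp)
            need = self.win - self._acc.shape[1]
            if need > 0:
                self._acc = np.concatenate(
                    [self._acc, np.zeros((n_ch, need))], axis=1)
                self._wacc = np.concatenate([self._wacc, np.zeros(need)])
            self._acc[:, :self.win] += clean * self._blend[None, :]
            self._wacc[:self.win] += self._blend
            # the first `hop` samples are now final
            final = self._acc[:, :self.hop] / np.maximum(
                self._wacc[:self.hop], 1e-12)[None, :]
            ready.append(final)
            self._acc = self._acc[:, self.hop:]
            self._wacc = self._wacc[self.hop:]
            self._inbuf = self._inbuf[:, self.hop:]
            self._emitted_windows += 1
        if ready:
            out = np.concatenate(ready, axis=1)
        else:
            out = np.zeros((n_ch, 0))
        if out.shape[1] < n_wanted:
            # should only happen before the pipeline is primed
            pad = np.zeros((n_ch, n_wanted - out.shape[1]))
            out = np.concatenate([pad, out], axis=1)
        elif out.shape[1] > n_wanted:
            out = out[:, -n_wanted:]
        return out


def asr_process(data: np.ndarray, model: ASRModel,
                chunk_samples: int | None = None) -> np.ndarray:
    """Convenience whole-array cleaner: stream ``data`` (channels x samples)
    through an :class:`ASRProcessor` in ``chunk_samples`` pieces (default:
    one hop) and undo the processing delay. Returns an array of the same
    shape; the trailing ``delay_samples`` are filled by flushing zeros."""
    proc = ASRProcessor(model)
    step = chunk_samples or proc.hop
    n_ch, n = data.shape
    # pad to a hop multiple and flush one extra hop of zeros to recover the
    # processing delay
    m = -(-n // proc.hop) * proc.hop
    padded = np.concatenate(
        [data, np.zeros((n_ch, m - n + proc.delay_samples))], axis=1)
    labels = tuple(f"ch{i}" for i in range(n_ch))
    outs = []
    for s in range(0, padded.shape[1], step):
        chunk = EEGChunk(padded[:, s:s + step], model.sample_rate, labels)
        outs.append(proc.process(chunk).data)
    out = np.concatenate(outs, axis=1)
    return out[:, proc.delay_samples:proc.delay_samples + n]
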