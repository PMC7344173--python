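"""Theta log-power extraction and the adaptive dynamic-range feedback law.

Every 250 ms a 1 s Hamming-tapered window of the cleaned Fz signal (256
samples at 256 Hz, hence 1 Hz spectral bins) yields the instantaneous theta
log power

    p = mean over {4, 5, 6} Hz of 10*log10(|X(k)|^2)

and the controller maps p into a displayed value f in [0, 1] through an
adaptive dynamic range [l, h]:

    f = (p - l) / (h - l)

If f falls below 0 it is capped at 0 and the lower edge expands,
l -= (h-l)/30; otherwise the lower edge idles inward, l += (h-l)/100.
Symmetrically, f above 1 is capped at 1 and h += (h-l)/30, otherwise
h -= (h-l)/100 (both edge terms use the pre-update range). Saturation
therefore widens the range ~3.3x faster than idle updates shrink it, so
the range tracks the subject's theta drift. Finally the displayed value
may move at most 0.05 per update (the 5% slew cap) for a visually smooth
display, and is rendered as a black-to-blue square color.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class ThetaPowerConfig:
    """Spectral estimation settings for the feedback signal.

    With the defaults (1 s window, 75% overlap, 256 Hz) the update period
    is 250 ms and the FFT bin spacing is exactly 1 Hz, so the target bins
    {4, 5, 6} Hz are single FFT bins.
    """

    window_len: float = 1.0
    overlap: float = 0.75
    sample_rate: float = 256.0
    target_bins: tuple[int, ...] = (4, 5, 6)
    channel: str = "Fz"

    @property
    def window_samples(self) -> int:
        return int(round(self.window_len * self.sample_rate))

    @property
    def update_period(self) -> float:
        return self.window_len * (1.0 - self.overlap)

    @property
    def update_rate(self) -> float:
        return 1.0 / self.update_period


@dataclass
class FeedbackState:
    """Dynamic-range edges and display state of the controller."""

    l: float
    h: float
    f_displayed_prev: float = 0.0
    expand_divisor: float = 30.0
    contract_divisor: float = 100.0
    slew_cap: float = 0.05
    min_range: float = 1e-6
    display_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.l < self.h:
            raise ValueError("dynamic range requires l < h")


@dataclass(frozen=True)
class FeedbackSample:
    """One 4 Hz controller update."""

    time: float
    p: float
    f_raw: float
    f_capped: float
    f_displayed: float
    l: float
    h: float


def theta_log_power(window: np.ndarray,
                    config: ThetaPowerConfig = ThetaPowerConfig()) -> float:
    """Theta log power of one Fz analysis window.

    ``window`` must hold exactly ``config.window_samples`` samples. The
    window is Hamming-tapered, FFT'd, and p is the mean of
    10*log10(|X(k)|^2) over the target bins.

    An all-zero window has no defined log power and raises ValueError.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size != config.window_samples:
        raise ValueError(
            f"window must be 1-D with {config.window_samples} samples, "
            f"got shape {x.shape}")
    if not np.any(x):
        raise ValueError("all-zero window: log power undefined")
    taper = sps.get_window("hamming", x.size, fftbins=True)
    spec = np.fft.rfft(x * taper)
    bins = np.asarray(config.target_bins, dtype=int)
    mags2 = np.abs(spec[bins]) ** 2
    mags2 = np.maximum(mags2, 1e-300)
    return float(np.mean(10.0 * np.log10(mags2)))


def feedback_update(p: float,
                    state: FeedbackState) -> tuple[FeedbackSample, FeedbackState]:
    """Apply one tick of the adaptive dynamic-range law.

    Both edge updates are computed from the pre-update range (h - l)
    simultaneously. Exact saturation (f_raw == 0 or 1) counts as
    non-saturated: only strict overshoot expands the range.
    """
    if not np.isfinite(p):
        raise ValueError(f"non-finite log power {p!r}")
    l, h = state.l, state.h
    rng = h - l
    f_raw = (p - l) / rng

    if f_raw < 0.0:
        f_capped = 0.0
        new_l = l - rng / state.expand_divisor
    else:
        f_capped = min(f_raw, 1.0)
        new_l = l + rng / state.contract_divisor
    if f_raw > 1.0:
        f_capped = 1.0
        new_h = h + rng / state.expand_divisor
    else:
        new_h = h - rng / state.contract_divisor

    step = np.clip(f_capped - state.f_displayed_prev,
                   -state.slew_cap, state.slew_cap)
    f_displayed = float(np.clip(state.f_displayed_prev + step, 0.0, 1.0))

    if new_h - new_l < state.min_range:  # pathological constant input
        mid = 0.5 * (new_h + new_l)
        new_l = mid - 0.5 * state.min_range
        new_h = mid + 0.5 * state.min_range

    new_state = replace(state, l=new_l, h=new_h,
                        f_displayed_prev=f_displayed)
    sample = FeedbackSample(time=np.nan, p=p, f_raw=f_raw,
                            f_capped=f_capped, f_displayed=f_displayed,
                            l=new_l, h=new_h)
    return sample, new_state


def initial_state(p0: float, half_range: float = 1.0,
                  **kwargs) -> FeedbackState:
    """Dynamic range before any update: [p0 - half_range, p0 + half_range]
    (log-power units)."""
    return FeedbackState(l=p0 - half_range, h=p0 + half_range, **kwargs)


def baseline_warmup(p_sequence, half_range: float = 1.0,
                    min_samples: int = 20) -> FeedbackState:
    """Establish an acceptable dynamic range from the 1-minute preparatory
    baseline, display disabled.

    The state is initialised around the first p and the update law is then
    iterated over the whole sequence. The returned state has the display
    enabled and the displayed value reset to 0 (black square at block
    onset).
    """
    p_sequence = list(p_sequence)
    if len(p_sequence) == 0:
        raise ValueError("empty baseline p sequence")
    if len(p_sequence) < min_samples and len(p_sequence) > 1:
        raise ValueError(
            f"baseline too short: {len(p_sequence)} < {min_samples} updates")
    state = initial_state(p_sequence[0], half_range,
                          display_enabled=False)
    for p in p_sequence:
        _, state = feedback_update(p, state)
    return replace(state, f_displayed_prev=0.0, display_enabled=True)


def color_map(f_displayed: float) -> tuple[int, int, int]:
    """Displayed value -> square color: 0 is black #000000, 1 is saturated
    blue #0000FF, proportional in RGB space (0.5 -> #000080)."""
    if not 0.0 <= f_displayed <= 1.0:
        raise ValueError("displayed feedback must lie in [0, 1]")
    return (0, 0, int(round(255 * f_displayed)))
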