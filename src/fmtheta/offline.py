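"""Offline cleaning and the training-effect statistical battery.

Cleaning mirrors the post hoc pipeline: channels whose kurtosis deviates
by more than 5 SD from the ensemble of channels are flagged, and stretches
whose 20-40 Hz power exceeds the recording mean by more than 10 dB over at
least 4 contiguous 0.5 s windows are rejected.

The training-effect battery operates on per-session band amplitudes:
percent change of each session's mean amplitude relative to session 1
(training curve), a per-subject OLS regression line over sessions 1-8, a
one-tailed Welch t-test comparing group slopes, a Pearson correlation of
the group-mean curve against session index (df = n_sessions - 2), a
mixed repeated-measures ANOVA (session x group) with Greenhouse-Geisser
correction, single-pass 3-SD non-responder exclusion, and a label-
permutation test on Fz power spectra with Benjamini-Hochberg correction
across frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from fmtheta.session import SessionLog


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError("band edges must satisfy 0 < lo < hi")


THETA = BandDefinition("theta", 4.0, 6.0)
ALPHA = BandDefinition("alpha", 8.0, 12.0)
BETA = BandDefinition("beta", 12.0, 18.0)


# ------------------------------------------------------------ cleaning ----

def reject_channels_kurtosis(data: np.ndarray, sample_rate: float = 256.0,
                             threshold: float = 5.0) -> list[int]:
    """Flag channels whose kurtosis is more than ``threshold`` SD away from
    the ensemble of all channels. Returns flagged channel indices."""
    data = np.asarray(data, dtype=float)
    n_ch, n = data.shape
    if n < 10 * sample_rate:
        raise ValueError("need at least 10 s of data for channel rejection")
    k = stats.kurtosis(data, axis=1, fisher=True, bias=True)
    mu, sd = np.mean(k), np.std(k, ddof=1)
    if sd == 0:
        return []
    z = (k - mu) / sd
    return [int(i) for i in np.flatnonzero(np.abs(z) > threshold)]


def reject_hf_segments(data: np.ndarray, sample_rate: float = 256.0,
                       band: tuple[float, float] = (20.0, 40.0),
                       threshold_db: float = 10.0, window_len: float = 0.5,
                       min_windows: int = 4) -> list[tuple[float, float]]:
    """Reject stretches of high-frequency artifact.

    Per 0.5 s window, the 20-40 Hz power (summed over channels) is compared
    in dB to the mean window power of the whole recording; runs of at least
    ``min_windows`` contiguous windows above ``threshold_db`` are returned
    as (start, stop) second intervals.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    win = int(round(window_len * sample_rate))
    n = data.shape[1]
    if n < 4 * win:
        raise ValueError("recording shorter than 2 s")
    n_win = n // win
    powers = np.empty(n_win)
    for w in range(n_win):
        seg = data[:, w * win:(w + 1) * win]
        freqs, psd = sps.periodogram(seg, fs=sample_rate, axis=1)
        sel = (freqs >= band[0]) & (freqs <= band[1])
        powers[w] = psd[:, sel].sum()
    ref = powers.mean()
    above = 10.0 * np.log10(powers / ref) > threshold_db

    intervals: list[tuple[float, float]] = []
    start = None
    for w, flag in enumerate(list(above) + [False]):
        if flag and start is None:
            start = w
        elif not flag and start is not None:
            if w - start >= min_windows:
                intervals.append((start * window_len, w * window_len))
            start = None
    return intervals


# ----------------------------------------------------- training curves ----

@dataclass
class TrainingCurve:
    """Per-subject session series of band amplitude and percent change."""

    subject_id: str
    session_amp: np.ndarray       # mean training amplitude per session, uV
    session_pct: np.ndarray       # percent change vs session 1
    baseline_amp: np.ndarray      # mean of start/end baseline amplitudes
    baseline_pct: np.ndarray
    band: str = "theta"


def _block_amplitude(log_power_db: np.ndarray) -> float:
    """Mean band amplitude of one segment: amplitudes are 10^(p/20)
    (square root of the power implied by the logged dB values)."""
    return float(np.mean(10.0 ** (np.asarray(log_power_db) / 20.0)))


def training_curves(logs: list[SessionLog], band: str = "theta",
                    n_sessions: int | None = None) -> TrainingCurve:
    """Training curve for one subject from their ordered session logs."""
    n_sessions = n_sessions or len(logs)
    if len(logs) < n_sessions:
        raise ValueError(
            f"expected {n_sessions} sessions, got {len(logs)}")
    logs = sorted(logs, key=lambda lg: lg.session_index)
    amps, base = [], []
    for lg in logs:
        block_amps = [_block_amplitude(b.band_log_power(band))
                      for b in lg.blocks]
        amps.append(np.mean(block_amps))
        base.append(0.5 * (_block_amplitude(
            lg.start_baseline.band_log_power(band))
            + _block_amplitude(lg.end_baseline.band_log_power(band))))
    amps = np.asarray(amps)
    base = np.asarray(base)
    return TrainingCurve(
        subject_id=logs[0].subject_id,
        session_amp=amps, session_pct=100.0 * (amps / amps[0] - 1.0),
        baseline_amp=base, baseline_pct=100.0 * (base / base[0] - 1.0),
        band=band)


def fit_subject_slope(curve: TrainingCurve,
                      use: str = "session_pct") -> tuple[float, float]:
    """OLS line over session index 1..n; returns (slope, intercept)."""
    y = getattr(curve, use)
    if len(y) < 3:
        raise ValueError("need at least 3 sessions for a regression line")
    x = np.arange(1, len(y) + 1)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept)


def group_slope_test(group_a: np.ndarray, group_b: np.ndarray
                     ) -> tuple[float, float]:
    """One-tailed Welch t-test of H1: mean slope(A) > mean slope(B).
    Returns (t, one-tailed p)."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def group_session_correlation(curves: list[TrainingCurve],
                              use: str = "session_pct"
                              ) -> dict[str, float]:
    """Pearson correlation of the group-mean percent-change curve against
    session index; reports r^2, t, df = n_sessions - 2, and p."""
    mat = np.stack([getattr(c, use) for c in curves])
    mean_curve = mat.mean(axis=0)
    n = len(mean_curve)
    if n < 3:
        raise ValueError("need at least 3 sessions")
    x = np.arange(1, n + 1)
    r, p = stats.pearsonr(x, mean_curve)
    df = n - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    return {"r2": float(r**2), "t": float(t), "df": int(df),
            "p": float(p)}


def exclude_nonresponders(total_power: dict[str, float],
                          n_sd: float = 3.0) -> tuple[list[str], list[str]]:
    """Single-pass exclusion of subjects whose total trained-band power
    deviates more than ``n_sd`` SD from the group mean.

    Returns (retained_ids, removed_ids)."""
    ids = list(total_power)
    if len(ids) < 4:
        raise ValueError("need at least 4 subjects")
    vals = np.array([total_power[i] for i in ids], dtype=float)
    # population SD: with a cohort of ~12 an extreme outlier inflates the
    # spread it is judged against; ddof=0 keeps the 3-SD rule attainable
    mu, sd = vals.mean(), vals.std(ddof=0)
    removed = [i for i, v in zip(ids, vals)
               if sd > 0 and abs(v - mu) > n_sd * sd]
    retained = [i for i in ids if i not in removed]
    if not retained:
        raise ValueError("all subjects excluded")
    return retained, removed


# ------------------------------------------------- spectral statistics ----

def spectral_permutation_test(pre_epochs: np.ndarray,
                              post_epochs: np.ndarray,
                              sample_rate: float = 256.0,
                              n_perm: int = 2000, alpha: float = 0.05,
                              seed: int | None = None,
                              fmin: float = 1.0, fmax: float = 40.0,
                              ) -> dict[str, np.ndarray]:
    """Label-permutation test on per-frequency log power (pre vs post).

    Epochs are (n_epochs x samples) at a common length; per epoch the
    Hamming-tapered periodogram is converted to dB and the observed
    statistic is the difference of condition means at each frequency. The
    null is built by permuting epoch labels; two-sided p-values are
    Benjamini-Hochberg corrected across frequencies. Only frequencies in
    [fmin, fmax] are tested (the physiological range; correcting across
    the full Nyquist span would only dilute the FDR step).

    Returns dict with ``freqs``, ``diff_db``, ``p``, ``p_fdr``,
    ``significant`` (boolean mask at ``alpha`` after FDR).
    """
    from statsmodels.stats.multitest import multipletests

    pre = np.atleast_2d(np.asarray(pre_epochs, float))
    post = np.atleast_2d(np.asarray(post_epochs, float))
    if pre.shape[1] != post.shape[1]:
        raise ValueError("pre/post epoch lengths differ")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def _logspec(ep):
        freqs, psd = sps.periodogram(ep, fs=sample_rate, axis=1,
                                     window="hamming")
        return freqs, 10.0 * np.log10(np.maximum(psd, 1e-300))

    freqs, spec_pre = _logspec(pre)
    _, spec_post = _logspec(post)
    keep = (freqs >= fmin) & (freqs <= fmax)
    freqs = freqs[keep]
    spec_pre = spec_pre[:, keep]
    spec_post = spec_post[:, keep]
    allspec = np.concatenate([spec_pre, spec_post], axis=0)
    n_pre = spec_pre.shape[0]
    labels = np.zeros(allspec.shape[0], dtype=bool)
    labels[n_pre:] = True

    def _stat(lab):
        return allspec[lab].mean(axis=0) - allspec[~lab].mean(axis=0)

    observed = _stat(labels)
    exceed = np.ones_like(observed)  # counts permutations >= observed
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        exceed += np.abs(_stat(perm)) >= np.abs(observed)
    p = exceed / (n_perm + 1)
    reject, p_fdr, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return {"freqs": freqs, "diff_db": observed, "p": p, "p_fdr": p_fdr,
            "significant": reject}


def rm_anova(table: pd.DataFrame, dv: str = "amplitude",
             within: str = "session", between: str = "group",
             subject: str = "subject") -> pd.DataFrame:
    """Mixed repeated-measures ANOVA (within: session, between: group) with
    Greenhouse-Geisser correction, on a long-format balanced table.

    Returns the pingouin mixed_anova table (F, p-unc, p-GG-corr, eps).
    """
    import pingouin as pg

    pv = table.pivot_table(index=subject, columns=within, values=dv,
                           aggfunc="count")
    if pv.isna().any().any() or (pv != 1).any().any():
        raise ValueError("table must be balanced: exactly one row per "
                         "subject x session cell")
    return pg.mixed_anova(data=table, dv=dv, within=within,
                          between=between, subject=subject,
                          correction=True)
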