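"""Criticality biomarkers: DFA exponents and the functional E/I ratio.

Both operate on the amplitude envelope (magnitude of the analytic signal) of
the band-passed signal.  Epochs are concatenated in temporal order before
filtering; 0.5 s of envelope is trimmed at the signal edges and around any
non-contiguous epoch join (rejection-induced discontinuity) to limit filter
edge artifacts.

DFA: cumulative-sum profile of the demeaned envelope, per-window linear
detrending at log-spaced window sizes with 50% overlap, fluctuation =
mean per-window RMS, exponent = log-log slope.  0.5 indicates an uncorrelated
envelope, >0.5 persistent long-range temporal correlations.

fEI: the envelope is cut into non-overlapping windows; per window the mean
amplitude wA and the amplitude-normalized detrended fluctuation wF are
computed, and fEI = 1 - corr(wA, wF).  Values near 1 indicate balanced
excitation/inhibition; the estimate is flagged invalid when the band's DFA
exponent is below 0.6 (no long-range correlations to normalize against).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert
from scipy.stats import pearsonr

from .prep import EpochedRecording, bandpass


@dataclass
class EnvelopeSignal:
    envelope: np.ndarray  # patches x samples (or samples,), nonnegative
    band: str
    fs: float

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=np.float64)
        if np.any(self.envelope < 0):
            raise ValueError("envelope must be nonnegative")


@dataclass
class DfaResult:
    exponent: float
    window_sizes_s: np.ndarray
    fluctuations: np.ndarray
    r_squared: float


@dataclass
class FeiResult:
    fei: float
    w_amplitude: np.ndarray
    w_fluctuation: np.ndarray
    valid: bool


def band_envelope(
    er: EpochedRecording,
    band: tuple[float, float],
    band_name: str = "",
    edge_trim_s: float = 0.5,
) -> EnvelopeSignal:
    """Amplitude envelope of the band-passed, concatenated recording.

    Contiguous epochs join seamlessly; around every non-contiguous join (and
    at the signal edges) ``edge_trim_s`` seconds of envelope are dropped.
    """
    lo, hi = band
    if hi >= er.fs / 2:
        raise ValueError(f"band ({lo}, {hi}) Hz above Nyquist for fs={er.fs}")
    x = er.concatenated()
    xb = bandpass(x, lo, hi, er.fs)
    env = np.abs(hilbert(xb, axis=-1))
    trim = int(round(edge_trim_s * er.fs))
    cuts = er.boundary_discontinuities()
    keep = np.ones(env.shape[-1], dtype=bool)
    if trim > 0:
        keep[:trim] = False
        keep[env.shape[-1] - trim :] = False
        for c in cuts:
            keep[max(c - trim, 0) : min(c + trim, env.shape[-1])] = False
    return EnvelopeSignal(envelope=env[..., keep], band=band_name, fs=er.fs)


def _dfa_prefixes(profile: np.ndarray):
    """Zero-padded prefix sums of y, y^2 and t*y along the last axis."""
    g = np.arange(profile.shape[-1], dtype=np.float64)
    zeros = np.zeros(profile.shape[:-1] + (1,))
    c1 = np.concatenate([zeros, np.cumsum(profile, axis=-1)], axis=-1)
    c2 = np.concatenate([zeros, np.cumsum(profile**2, axis=-1)], axis=-1)
    cg = np.concatenate([zeros, np.cumsum(g * profile, axis=-1)], axis=-1)
    return c1, c2, cg


def _window_rms_detrended(
    profile: np.ndarray, n: int, step: int, prefixes=None
) -> np.ndarray:
    """RMS of linearly detrended windows of length n (start stride = step).

    profile: (..., T).  Returns (..., n_windows) RMS values.  Uses prefix
    sums of y, y^2 and t*y so the cost is O(T) per window size instead of
    O(T * n); the closed-form residual sum of squares for a least-squares
    line is  S_yy - S_y^2/n - slope^2 * D  with  D = n(n^2-1)/12.
    """
    T = profile.shape[-1]
    starts = np.arange(0, T - n + 1, step)
    c1, c2, cg = prefixes if prefixes is not None else _dfa_prefixes(profile)
    s_y = c1[..., starts + n] - c1[..., starts]
    s_yy = c2[..., starts + n] - c2[..., starts]
    s_gy = cg[..., starts + n] - cg[..., starts]
    s_ty = s_gy - starts * s_y  # t local to the window: t = g - start
    t_mean = (n - 1) / 2.0
    D = n * (n * n - 1.0) / 12.0
    slope = (s_ty - t_mean * s_y) / D
    ss_res = s_yy - s_y**2 / n - slope**2 * D
    return np.sqrt(np.maximum(ss_res, 0.0) / n)


def dfa(
    env: EnvelopeSignal,
    fit_lo_s: float = 2.0,
    fit_hi_s: float = 20.0,
    n_windows: int = 12,
) -> DfaResult:
    """Detrended fluctuation analysis of a single envelope (1-D).

    For patch-wise computation on a 2-D envelope use :func:`dfa_matrix`.
    """
    sizes_s, F, r2, alpha = _dfa_core(
        np.atleast_2d(env.envelope), env.fs, fit_lo_s, fit_hi_s, n_windows
    )
    return DfaResult(
        exponent=float(alpha[0]),
        window_sizes_s=sizes_s,
        fluctuations=F[0],
        r_squared=float(r2[0]),
    )


def dfa_matrix(
    env: EnvelopeSignal,
    fit_lo_s: float = 2.0,
    fit_hi_s: float = 20.0,
    n_windows: int = 12,
) -> np.ndarray:
    """DFA exponent per row of a patches x samples envelope."""
    _, _, _, alpha = _dfa_core(
        np.atleast_2d(env.envelope), env.fs, fit_lo_s, fit_hi_s, n_windows
    )
    return alpha


def _dfa_core(env: np.ndarray, fs: float, fit_lo_s: float, fit_hi_s: float, n_windows: int):
    T = env.shape[-1]
    if T < 2 * fit_hi_s * fs:
        raise ValueError(
            f"signal of {T / fs:.1f} s too short for fit_hi_s={fit_hi_s} s "
            "(need at least twice the largest window)"
        )
    if np.any(env.std(axis=-1) == 0):
        raise ValueError("constant envelope: fluctuation undefined")
    profile = np.cumsum(env - env.mean(axis=-1, keepdims=True), axis=-1)
    sizes = np.unique(
        np.round(
            np.logspace(np.log10(fit_lo_s * fs), np.log10(fit_hi_s * fs), n_windows)
        ).astype(int)
    )
    prefixes = _dfa_prefixes(profile)
    F = np.stack(
        [
            _window_rms_detrended(profile, n, max(n // 2, 1), prefixes).mean(axis=-1)
            for n in sizes
        ],
        axis=-1,
    )  # (..., n_sizes)
    if np.any(F <= 0):
        raise ValueError("zero fluctuation: degenerate signal")
    logs = np.log10(sizes / fs)
    logF = np.log10(F)
    slope, intercept = np.polyfit(logs, logF.T, 1)
    pred = np.outer(slope, logs) + intercept[:, None]
    ss_res = np.sum((logF - pred) ** 2, axis=-1)
    ss_tot = np.sum((logF - logF.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
    r2 = 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, np.inf)
    return sizes / fs, F, r2, slope


def fei_from_windows(w_amplitude: np.ndarray, w_fluctuation: np.ndarray) -> float:
    """fEI = 1 - Pearson correlation of per-window amplitude and fluctuation."""
    wa = np.asarray(w_amplitude, dtype=float)
    wf = np.asarray(w_fluctuation, dtype=float)
    if wa.size < 10:
        raise ValueError("need at least 10 windows")
    if wa.std() == 0 or wf.std() == 0:
        raise ValueError("zero-variance window statistics")
    r, _ = pearsonr(wa, wf)
    return float(1.0 - r)


def fei(
    env: EnvelopeSignal,
    window_s: float = 5.0,
    dfa_exponent: float = np.nan,
) -> FeiResult:
    """Functional excitation/inhibition ratio of a 1-D envelope."""
    x = np.asarray(env.envelope, dtype=float)
    if x.ndim != 1:
        raise ValueError("fei expects a single envelope; loop patches externally")
    n = int(round(window_s * env.fs))
    n_win = x.size // n
    if n_win < 10:
        raise ValueError(f"only {n_win} windows of {window_s} s; need >= 10")
    w = x[: n_win * n].reshape(n_win, n)
    wa = w.mean(axis=1)
    if np.any(wa <= 0):
        raise ValueError("nonpositive window amplitude")
    norm = w / wa[:, None]
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    denom = np.sum(t_c**2)
    profile = np.cumsum(norm - norm.mean(axis=1, keepdims=True), axis=1)
    p_mean = profile.mean(axis=1, keepdims=True)
    slope = np.sum((profile - p_mean) * t_c, axis=1, keepdims=True) / denom
    resid = profile - p_mean - slope * t_c
    wf = resid.std(axis=1)
    value = fei_from_windows(wa, wf)
    valid = bool(np.isfinite(dfa_exponent) and dfa_exponent >= 0.6)
    return FeiResult(fei=value, w_amplitude=wa, w_fluctuation=wf, valid=valid)


def fei_matrix(
    env: EnvelopeSignal, window_s: float = 5.0, dfa_exponents: np.ndarray = None
) -> np.ndarray:
    """fEI per row of a patches x samples envelope (validity not enforced).

    Same computation as :func:`fei`, vectorized across patches.
    """
    E = np.atleast_2d(env.envelope)
    n = int(round(window_s * env.fs))
    n_win = E.shape[-1] // n
    if n_win < 10:
        raise ValueError(f"only {n_win} windows of {window_s} s; need >= 10")
    w = E[:, : n_win * n].reshape(E.shape[0], n_win, n)
    wa = w.mean(axis=-1)
    if np.any(wa <= 0):
        raise ValueError("nonpositive window amplitude")
    norm = w / wa[..., None]
    profile = np.cumsum(norm - norm.mean(axis=-1, keepdims=True), axis=-1)
    t_c = np.arange(n, dtype=float) - (n - 1) / 2.0
    denom = np.sum(t_c**2)
    p_mean = profile.mean(axis=-1, keepdims=True)
    slope = np.sum((profile - p_mean) * t_c, axis=-1, keepdims=True) / denom
    wf = (profile - p_mean - slope * t_c).std(axis=-1)
    wa_c = wa - wa.mean(axis=-1, keepdims=True)
    wf_c = wf - wf.mean(axis=-1, keepdims=True)
    sd = wa_c.std(axis=-1) * wf_c.std(axis=-1)
    if np.any(sd == 0):
        raise ValueError("zero-variance window statistics")
    r = (wa_c * wf_c).mean(axis=-1) / sd
    return 1.0 - r
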