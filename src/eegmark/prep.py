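"""Filtering, epoching, duration gating and vertex-to-patch collapsing.

All filtering is zero-phase FIR (Hamming window, transition width 25% of the
band edge, applied forward-backward) so that downstream phase-based
connectivity measures are not distorted.  Resampling uses polyphase filtering.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy.signal import firwin, fftconvolve, resample_poly

from .atlas import default_patch_labels
from .synth import PatchRecording


class BandSet(Mapping):
    """Ordered map of band name -> (f_lo, f_hi) in Hz."""

    def __init__(self, bands: dict):
        for name, (lo, hi) in bands.items():
            if not lo < hi:
                raise ValueError(f"degenerate band {name!r}: ({lo}, {hi})")
        self._bands = dict(bands)

    def __getitem__(self, key):
        return self._bands[key]

    def __iter__(self):
        return iter(self._bands)

    def __len__(self):
        return len(self._bands)

    @property
    def f_min(self) -> float:
        return min(lo for lo, _ in self._bands.values())

    @property
    def f_max(self) -> float:
        return max(hi for _, hi in self._bands.values())


#: the five canonical analysis bands
DEFAULT_BANDS = BandSet(
    {
        "delta": (1.25, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 13.0),
        "beta": (13.0, 30.0),
        "gamma": (30.0, 48.0),
    }
)


@dataclass
class EpochedRecording:
    """epochs x patches x samples array after filtering/epoching.

    ``epoch_onsets`` holds each epoch's start sample in the source recording;
    it lets temporally extended estimators detect discontinuities introduced
    by epoch rejection.
    """

    subject_id: str
    epochs: np.ndarray
    fs: float
    epoch_len_s: float
    patch_labels: list[str]
    epoch_onsets: Optional[np.ndarray] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x patches x samples")
        n_ep, _, spe = self.epochs.shape
        if n_ep < 1:
            raise ValueError("need at least one epoch")
        expected = self.epoch_len_s * self.fs
        if abs(spe - expected) > 1e-9:
            raise ValueError("samples per epoch must equal epoch_len_s * fs")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain NaN/Inf")
        if self.epoch_onsets is None:
            self.epoch_onsets = np.arange(n_ep) * spe
        self.epoch_onsets = np.asarray(self.epoch_onsets, dtype=np.int64)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_patches(self) -> int:
        return self.epochs.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[2]

    def concatenated(self) -> np.ndarray:
        """patches x (n_epochs * samples) array, epochs in temporal order."""
        return np.concatenate(list(self.epochs), axis=-1)

    def boundary_discontinuities(self) -> list[int]:
        """Sample offsets (in the concatenated signal) of non-contiguous joins."""
        spe = self.samples_per_epoch
        out = []
        for k in range(1, self.n_epochs):
            if self.epoch_onsets[k] != self.epoch_onsets[k - 1] + spe:
                out.append(k * spe)
        return out


# ---------------------------------------------------------------------------
# zero-phase FIR machinery


def _odd(n: int) -> int:
    return n if n % 2 == 1 else n + 1


def _fir_numtaps(transition_hz: float, fs: float, max_len: int) -> int:
    # Hamming window: ~3.3 / normalized transition width
    n = _odd(int(math.ceil(3.3 * fs / transition_hz)))
    cap = _odd(max(3, max_len // 3))
    return min(n, cap)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward application of a FIR filter along the last axis.

    Implemented as a single convolution with the filter's autocorrelation
    (equivalent for linear-phase FIR), with odd-reflection edge padding.
    """
    kernel = np.convolve(taps, taps[::-1])
    half = len(kernel) // 2
    T = x.shape[-1]
    pad = min(half, T - 1)
    left = 2.0 * x[..., :1] - x[..., 1 : pad + 1][..., ::-1]
    right = 2.0 * x[..., -1:] - x[..., -pad - 1 : -1][..., ::-1]
    xp = np.concatenate([left, x, right], axis=-1)
    shape = (1,) * (x.ndim - 1) + (len(kernel),)
    y = fftconvolve(xp, kernel.reshape(shape), mode="same", axes=-1)
    return y[..., pad : pad + T]


def bandpass_taps(f_lo: float, f_hi: float, fs: float, max_len: int) -> np.ndarray:
    trans = 0.25 * f_lo
    numtaps = _fir_numtaps(trans, fs, max_len)
    return firwin(numtaps, [f_lo, f_hi], pass_zero=False, window="hamming", fs=fs)


def bandstop_taps(center: float, fs: float, max_len: int, half_width: float = 1.0) -> np.ndarray:
    numtaps = _fir_numtaps(half_width, fs, max_len)
    return firwin(
        numtaps,
        [center - half_width, center + half_width],
        pass_zero=True,
        window="hamming",
        fs=fs,
    )


def bandpass(x: np.ndarray, f_lo: float, f_hi: float, fs: float) -> np.ndarray:
    """Zero-phase band-pass of the last axis."""
    if f_hi >= fs / 2:
        raise ValueError(f"band edge {f_hi} Hz at or above Nyquist ({fs / 2} Hz)")
    taps = bandpass_taps(f_lo, f_hi, fs, x.shape[-1])
    return zero_phase_filter(x, taps)


# ---------------------------------------------------------------------------
# operations


def preprocess(
    rec: PatchRecording,
    band_lo: float = 1.0,
    band_hi: float = 100.0,
    notch: Optional[float] = 50.0,
    target_fs: float = 500.0,
) -> PatchRecording:
    """Zero-phase band-pass + notch, then polyphase resampling to target_fs."""
    if not band_lo < band_hi:
        raise ValueError("band_lo must be below band_hi")
    if band_hi >= target_fs / 2 or band_hi >= rec.fs / 2:
        raise ValueError(
            f"band_hi={band_hi} Hz violates Nyquist (fs={rec.fs}, target={target_fs})"
        )
    x = rec.data
    x = zero_phase_filter(x, bandpass_taps(band_lo, band_hi, rec.fs, x.shape[-1]))
    if notch is not None and notch < rec.fs / 2:
        x = zero_phase_filter(x, bandstop_taps(notch, rec.fs, x.shape[-1]))
    if target_fs != rec.fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
        x = resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return PatchRecording(
        subject_id=rec.subject_id,
        data=x,
        fs=target_fs,
        patch_labels=list(rec.patch_labels),
        ground_truth=dict(rec.ground_truth),
    )


def epoch(rec: PatchRecording, epoch_len_s: float = 4.0) -> EpochedRecording:
    """Cut into non-overlapping epochs; a trailing partial epoch is discarded."""
    spe = int(round(epoch_len_s * rec.fs))
    if spe <= 0:
        raise ValueError("epoch length must be positive")
    n_ep = rec.n_samples // spe
    if n_ep < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.1f} s shorter than one "
            f"{epoch_len_s:.1f} s epoch"
        )
    trimmed = rec.data[:, : n_ep * spe]
    epochs = trimmed.reshape(rec.data.shape[0], n_ep, spe).transpose(1, 0, 2)
    return EpochedRecording(
        subject_id=rec.subject_id,
        epochs=epochs,
        fs=rec.fs,
        epoch_len_s=epoch_len_s,
        patch_labels=list(rec.patch_labels),
        epoch_onsets=np.arange(n_ep) * spe,
        ground_truth=dict(rec.ground_truth),
    )


def enforce_min_duration(
    er: EpochedRecording, min_s: float = 120.0
) -> Optional[EpochedRecording]:
    """Return ``er`` if it carries at least ``min_s`` seconds, else ``None``.

    The boundary duration itself is kept (only subjects with *less* than the
    minimum are excluded).
    """
    if min_s < 0:
        raise ValueError("min_s must be nonnegative")
    total_s = er.n_epochs * er.epoch_len_s
    return er if total_s >= min_s else None


def collapse_vertices(
    vertex_signals: np.ndarray,
    patch_assignment: list[str],
    fs: float,
    subject_id: str = "collapsed",
) -> PatchRecording:
    """Polarity-aligned average of vertex signals into patch signals.

    Within each patch, the sign of each vertex's correlation with the patch's
    first principal temporal component determines its polarity; vertices
    disagreeing with the majority polarity are sign-flipped (a pi phase shift)
    before averaging, preventing opposite-polarity dipoles from cancelling.
    The overall sign follows the pre-flip majority; zero correlation means no
    flip.
    """
    V = np.asarray(vertex_signals, dtype=np.float64)
    if V.ndim != 2 or V.shape[0] != len(patch_assignment):
        raise ValueError("vertex_signals must be m x T with one label per row")
    if V.shape[0] == 0:
        raise ValueError("no vertices to collapse")
    labels = sorted(set(patch_assignment))
    canonical = default_patch_labels()
    if set(labels) == set(canonical):
        labels = canonical
    assignment = np.asarray(patch_assignment)
    out = np.empty((len(labels), V.shape[1]))
    for k, lab in enumerate(labels):
        rows = np.where(assignment == lab)[0]
        if rows.size == 0:
            raise ValueError(f"patch {lab!r} has no vertices")
        P = V[rows]
        Pc = P - P.mean(axis=1, keepdims=True)
        gram = Pc @ Pc.T
        _, vecs = np.linalg.eigh(gram)
        w = vecs[:, -1]  # top principal direction in vertex space
        pc = Pc.T @ w  # first principal temporal component
        signs = np.sign(Pc @ pc)
        # orient the principal component with the pre-flip majority; on an
        # exact tie, orient it with the first correlated vertex
        if signs.sum() < 0:
            signs = -signs
        elif signs.sum() == 0:
            nz = np.nonzero(signs)[0]
            if nz.size and signs[nz[0]] < 0:
                signs = -signs
        flip = np.where(signs < 0, -1.0, 1.0)
        out[k] = (P * flip[:, None]).mean(axis=0)
    return PatchRecording(
        subject_id=subject_id, data=out, fs=fs, patch_labels=list(labels)
    )
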