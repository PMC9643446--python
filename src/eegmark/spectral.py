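"""Multitaper spectral estimation and spectral biomarkers.

Produces, per recording: 680 band-power features (68 patches x 5 bands x
absolute/relative), 30 hemispheric-asymmetry features (6 regions x 5 bands),
6 theta/beta ratios (one per region, hemispheres pooled), 68 aperiodic (1/f)
exponents and 69 peak-alpha-frequency values (68 patches + 1 global fit on the
patch-averaged spectrum).

The aperiodic/peak decomposition is a simplified fixed-mode (no knee)
spectral parametrization: a robust log-log linear fit of the PSD, iterative
Gaussian peak extraction from the flattened spectrum, then a refit of the
aperiodic line on the peak-subtracted spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import math
from scipy.signal.windows import dpss

from .atlas import RegionScheme, REGIONS
from .prep import BandSet, DEFAULT_BANDS, EpochedRecording

#: full analysis range (Hz): union of the five canonical bands
FIT_RANGE = (1.25, 48.0)


@dataclass
class SpectralEstimate:
    """Multitaper PSD per patch with the taper parameters used."""

    freqs: np.ndarray
    psd: np.ndarray  # patches x freqs, units^2/Hz
    n_epochs: int
    half_bandwidth: float
    n_tapers: int

    def __post_init__(self) -> None:
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class AperiodicFit:
    """Aperiodic line + Gaussian peaks of one log-log PSD."""

    exponent: float
    offset: float
    peaks: list = field(default_factory=list)  # (center_hz, height_linear_power, width_hz)
    paf: Optional[float] = None
    fit_range: tuple = FIT_RANGE
    r_squared: float = np.nan


def multitaper_psd(
    er: EpochedRecording, half_bandwidth: float = 1.0
) -> SpectralEstimate:
    """DPSS multitaper PSD averaged over tapers and epochs.

    Normalized as a one-sided density: the integral over [0, fs/2] equals the
    mean signal variance (Parseval).
    """
    if er.n_epochs == 0:
        raise ValueError("no epochs")
    n = er.samples_per_epoch
    nw = half_bandwidth * er.epoch_len_s
    if nw < 1:
        raise ValueError("half_bandwidth * epoch_len_s must be >= 1")
    k = max(int(2 * nw - 1), 1)
    tapers = dpss(n, nw, Kmax=k)  # k x n, unit-energy
    x = er.epochs  # epochs x patches x n
    # taper, FFT: epochs x tapers x patches x freqs
    spec = np.fft.rfft(x[:, None, :, :] * tapers[None, :, None, :], axis=-1)
    power = (np.abs(spec) ** 2).mean(axis=(0, 1))  # patches x freqs
    psd = power / er.fs
    psd[:, 1:] *= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / er.fs)
    return SpectralEstimate(
        freqs=freqs,
        psd=psd,
        n_epochs=er.n_epochs,
        half_bandwidth=half_bandwidth,
        n_tapers=k,
    )


def _band_mask(freqs: np.ndarray, lo: float, hi: float, closed_hi: bool = False):
    if closed_hi:
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


def band_power(
    se: SpectralEstimate, bands: BandSet = DEFAULT_BANDS
) -> tuple[np.ndarray, np.ndarray]:
    """(absolute, relative) band powers, each patches x bands.

    Absolute power integrates the PSD over [f_lo, f_hi) so adjacent bands tile
    the analysis range without double-counting; relative power divides by the
    integral over the full analysis range, making the five relative powers a
    partition of unity.
    """
    if bands.f_min < se.freqs[0] or bands.f_max > se.freqs[-1] + 1e-9:
        raise ValueError("band range not covered by the frequency grid")
    df = se.df
    absolute = np.stack(
        [se.psd[:, _band_mask(se.freqs, lo, hi)].sum(axis=1) * df for lo, hi in bands.values()],
        axis=1,
    )
    total = se.psd[:, _band_mask(se.freqs, bands.f_min, bands.f_max)].sum(axis=1) * df
    relative = absolute / total[:, None]
    return absolute, relative


def asymmetry(
    abs_power: np.ndarray, scheme: RegionScheme, bands: BandSet = DEFAULT_BANDS
) -> np.ndarray:
    """Right-minus-left absolute power per homotopic pair, averaged by region.

    Returns a 6 regions x n_bands array (region order :data:`REGIONS`).
    """
    out = np.zeros((len(REGIONS), abs_power.shape[1]))
    counts = np.zeros(len(REGIONS))
    region_index = {r: i for i, r in enumerate(REGIONS)}
    for lh, rh, region in scheme.homotopic_pairs():
        i = region_index[region]
        out[i] += abs_power[rh] - abs_power[lh]
        counts[i] += 1
    if np.any(counts == 0):
        raise ValueError("region without homotopic pairs")
    return out / counts[:, None]


def theta_beta_ratio(
    abs_power: np.ndarray,
    scheme: RegionScheme,
    bands: BandSet = DEFAULT_BANDS,
) -> np.ndarray:
    """Per-patch theta/beta power ratio averaged over each region (6 values)."""
    names = list(bands)
    i_theta, i_beta = names.index("theta"), names.index("beta")
    beta = abs_power[:, i_beta]
    if np.any(beta <= 0):
        raise ValueError("nonpositive beta power")
    ratio = abs_power[:, i_theta] / beta
    out = np.zeros(len(REGIONS))
    counts = np.zeros(len(REGIONS))
    region_index = {r: i for i, r in enumerate(REGIONS)}
    for p, lab in enumerate(scheme.patch_labels):
        region, _ = scheme.region_of(lab)
        out[region_index[region]] += ratio[p]
        counts[region_index[region]] += 1
    return out / counts


# ---------------------------------------------------------------------------
# simplified spectral parametrization


def _gauss(f, center, height, sigma):
    return height * np.exp(-0.5 * ((f - center) / sigma) ** 2)


def _fit_gauss_logparabola(
    f: np.ndarray,
    resid_lin: np.ndarray,
    i0: int,
    h0: float,
    sig_lo: float,
    sig_hi: float,
) -> tuple[float, float, float]:
    """Gaussian peak parameters from a weighted parabola on log residuals.

    The log of a Gaussian is an exact parabola, so for a clean additive peak
    this recovers (center, height, sigma) exactly; weighting by the residual
    amplitude makes it robust to the noisy low tail.
    """
    window = (np.abs(f - f[i0]) <= 3.0) & (resid_lin > 0.1 * h0)
    if window.sum() >= 3:
        x = f[window]
        y = np.log(resid_lin[window])
        c2, c1, c0 = np.polyfit(x, y, 2, w=resid_lin[window])
        log_height = c0 - c1**2 / (4.0 * c2) if c2 != 0 else np.inf
        if c2 < 0 and log_height < 50.0:
            center = -c1 / (2.0 * c2)
            sigma = math.sqrt(-1.0 / (2.0 * c2))
            height = math.exp(log_height)
            center = min(max(center, f[i0] - 2.0), f[i0] + 2.0)
            sigma = min(max(sigma, sig_lo), sig_hi)
            height = min(height, 10.0 * h0)
            return center, height, sigma
    return float(f[i0]), float(h0), max(sig_lo, 0.5)


def _robust_line(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Linear fit down-weighting points well above the line (peak robustness)."""
    slope, intercept = np.polyfit(logf, logp, 1)
    resid = logp - (slope * logf + intercept)
    sd = resid.std()
    if sd > 0:
        keep = resid < 1.0 * sd  # discard strong positive (peak) outliers
        if keep.sum() >= 3:
            slope, intercept = np.polyfit(logf[keep], logp[keep], 1)
    return slope, intercept


def fit_aperiodic(
    freqs: np.ndarray,
    psd: np.ndarray,
    fit_range: tuple = FIT_RANGE,
    max_peaks: int = 6,
    peak_threshold_sd: float = 2.0,
    width_bounds_hz: tuple = (0.5, 12.0),
    alpha_range: tuple = (8.0, 13.0),
) -> AperiodicFit:
    """Fit aperiodic 1/f line plus Gaussian peaks to one PSD.

    The exponent chi is the negative slope of the log10-log10 aperiodic line
    refit on the peak-subtracted spectrum.  PAF is the center of the highest
    Gaussian peak inside ``alpha_range``; when no peak survives the threshold
    there, it falls back to the argmax of the flattened spectrum in that range
    so the feature never goes missing.
    """
    mask = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    f = np.asarray(freqs[mask], dtype=float)
    p = np.asarray(psd[mask], dtype=float)
    if np.any(p <= 0):
        raise ValueError("nonpositive psd in fit range")
    logf = np.log10(f)
    logp = np.log10(p)

    slope, intercept = _robust_line(logf, logp)
    line = 10.0 ** (slope * logf + intercept)

    # iterative peak extraction: detect on the log residual (scale-free
    # threshold), refine center/height/width on the *linear* residual so a
    # peak additive in power is recovered without the log-space skew from the
    # sloping background
    sig_lo, sig_hi = width_bounds_hz[0] / 2.0, width_bounds_hz[1] / 2.0
    peaks: list[tuple[float, float, float]] = []
    work = p.copy()
    for _ in range(max_peaks):
        resid_log = np.log10(np.maximum(work, 1e-300)) - np.log10(line)
        sd = resid_log.std()
        i = int(np.argmax(resid_log))
        if sd <= 0 or resid_log[i] < peak_threshold_sd * sd or resid_log[i] <= 0:
            break
        resid_lin = work - line
        h0 = max(resid_lin[i], 1e-12)
        center, height, sigma = _fit_gauss_logparabola(
            f, resid_lin, i, h0, sig_lo, sig_hi
        )
        peaks.append((float(center), float(height), float(2.0 * sigma)))
        work = np.maximum(work - _gauss(f, center, height, sigma), 0.1 * line)

    # refit the aperiodic line on peak-free frequencies
    free = np.ones_like(f, dtype=bool)
    for center, _, width in peaks:
        free &= np.abs(f - center) > 3.5 * width
    if free.sum() >= max(3, f.size // 4):
        slope2, intercept2 = np.polyfit(logf[free], logp[free], 1)
    else:
        slope2, intercept2 = slope, intercept
    line2 = 10.0 ** (slope2 * logf + intercept2)

    peak_model = np.zeros_like(f)
    for center, height, width in peaks:
        peak_model += _gauss(f, center, height, width / 2.0)
    model = np.log10(line2 + peak_model)
    ss_res = float(np.sum((logp - model) ** 2))
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    alpha_peaks = [pk for pk in peaks if alpha_range[0] <= pk[0] <= alpha_range[1]]
    if alpha_peaks:
        paf = max(alpha_peaks, key=lambda pk: pk[1])[0]
    else:
        amask = (f >= alpha_range[0]) & (f <= alpha_range[1])
        flat2 = logp - np.log10(line2)
        paf = float(f[amask][np.argmax(flat2[amask])])

    return AperiodicFit(
        exponent=float(-slope2),
        offset=float(intercept2),
        peaks=peaks,
        paf=float(paf),
        fit_range=tuple(fit_range),
        r_squared=r2,
    )


def aperiodic_features(
    se: SpectralEstimate, fit_range: tuple = FIT_RANGE
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-patch exponents (68), per-patch PAF (68) and the global PAF.

    The global value is fit on the patch-averaged PSD; only its PAF enters the
    feature set (68 + 1 = 69 PAF features, 68 exponents).
    """
    n_patches = se.psd.shape[0]
    exponents = np.empty(n_patches)
    pafs = np.empty(n_patches)
    for p in range(n_patches):
        fit = fit_aperiodic(se.freqs, se.psd[p], fit_range=fit_range)
        exponents[p] = fit.exponent
        pafs[p] = fit.paf
    global_fit = fit_aperiodic(se.freqs, se.psd.mean(axis=0), fit_range=fit_range)
    return exponents, pafs, float(global_fit.paf)
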