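"""Pairwise functional connectivity on the 68 patches and its region collapse.

Five estimators per band: coherence (Coh) and the magnitude of the imaginary
part of coherency (Imcoh) from the taper-and-epoch-averaged cross-spectrum;
the weighted phase lag index (wPLI, Vinck-2011 estimator, undebiased, with
0/0 defined as 0); the phase locking value (PLV) on concatenated samples; and
orthogonalized power envelope correlations (PEC: each signal's analytic
representation is orthogonalized against the other at every sample, log power
envelopes are Pearson-correlated, and the two directed values averaged).

Imcoh is stored as a magnitude so that region averaging cannot cancel
opposite-signed connections, which also keeps every matrix symmetric.  The
68x68 matrices are finally collapsed to 76 region-level connections: 66
inter-node pairs of the 12 (region, hemisphere) nodes plus 10 intra-node
values (the two single-patch insular nodes have no intra value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.signal.windows import dpss

from .atlas import RegionScheme
from .prep import BandSet, DEFAULT_BANDS, EpochedRecording, bandpass

MEASURES = ("coh", "imcoh", "plv", "wpli", "pec")

_PEC_EPS = 1e-12


@dataclass
class CrossSpectra:
    """Per epoch-taper unit tapered Fourier coefficients (units x patches x freqs)."""

    tapered: np.ndarray
    freqs: np.ndarray
    fs: float
    _acc: tuple = field(default=None, repr=False)

    @property
    def n_units(self) -> int:
        return self.tapered.shape[0]

    def ensemble(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mean S_xy, mean Im S_xy, mean |Im S_xy|), each patches x patches x freqs."""
        if self._acc is None:
            U, P, F = self.tapered.shape
            X32 = self.tapered.astype(np.complex64)
            s = np.zeros((P, P, F), dtype=np.complex128)
            absim = np.zeros((P, P, F))
            for u in range(U):
                Xu = X32[u]
                cross = np.einsum("pf,qf->pqf", Xu, np.conj(Xu))
                s += cross
                absim += np.abs(cross.imag)
            object.__setattr__(self, "_acc", (s / U, s.imag / U, absim / U))
        return self._acc


def cross_spectra(
    er: EpochedRecording, half_bandwidth: float = 1.0, f_max: float = 49.0
) -> CrossSpectra:
    """Tapered FFTs per epoch-taper unit, truncated to the analysis range."""
    if er.n_epochs < 2:
        raise ValueError("connectivity needs >= 2 epochs for ensemble averaging")
    n = er.samples_per_epoch
    nw = half_bandwidth * er.epoch_len_s
    k = max(int(2 * nw - 1), 1)
    tapers = dpss(n, nw, Kmax=k)
    freqs = np.fft.rfftfreq(n, 1.0 / er.fs)
    keep = freqs <= f_max
    spec = np.fft.rfft(er.epochs[:, None, :, :] * tapers[None, :, None, :], axis=-1)
    spec = spec[..., keep]  # epochs x tapers x patches x freqs
    ne, nt, p, f = spec.shape
    return CrossSpectra(tapered=spec.reshape(ne * nt, p, f), freqs=freqs[keep], fs=er.fs)


def _band_bins(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo) & (freqs < hi)


# ---------------------------------------------------------------------------
# coherence / wPLI (cross-spectral)


def coherency_matrix(cs: CrossSpectra) -> np.ndarray:
    """Complex coherency C(f) = <S_xy> / sqrt(<S_xx><S_yy>), patches x patches x freqs."""
    s, _, _ = cs.ensemble()
    power = np.real(np.einsum("ppf->pf", s))
    if np.any(power <= 0):
        raise ValueError("zero power at some frequency")
    denom = np.sqrt(power[:, None, :] * power[None, :, :])
    return s / denom


def coherence_matrices(
    cs: CrossSpectra, bands: BandSet = DEFAULT_BANDS
) -> dict[str, dict[str, np.ndarray]]:
    """Band-averaged Coh and |Imcoh| matrices: {'coh': {band: M}, 'imcoh': ...}."""
    C = coherency_matrix(cs)
    out = {"coh": {}, "imcoh": {}}
    for name, (lo, hi) in bands.items():
        bins = _band_bins(cs.freqs, lo, hi)
        out["coh"][name] = np.abs(C[:, :, bins]).mean(axis=-1)
        out["imcoh"][name] = np.abs(C[:, :, bins].imag).mean(axis=-1)
    return out


def coherence_pair(
    cs: CrossSpectra, i: int, j: int, bands: BandSet = DEFAULT_BANDS
) -> dict[str, tuple[float, float]]:
    """(coh, imcoh) per band for one patch pair."""
    X = cs.tapered
    sxy = (X[:, i, :] * np.conj(X[:, j, :])).mean(axis=0)
    sxx = (np.abs(X[:, i, :]) ** 2).mean(axis=0)
    syy = (np.abs(X[:, j, :]) ** 2).mean(axis=0)
    if np.any(sxx <= 0) or np.any(syy <= 0):
        raise ValueError("zero power at some frequency")
    C = sxy / np.sqrt(sxx * syy)
    out = {}
    for name, (lo, hi) in bands.items():
        bins = _band_bins(cs.freqs, lo, hi)
        out[name] = (
            float(np.abs(C[bins]).mean()),
            float(np.abs(C[bins].imag).mean()),
        )
    return out


def wpli_from_imag(im_values: np.ndarray, axis: int = 0, tol=0.0) -> np.ndarray:
    """wPLI = |<Im S_xy>| / <|Im S_xy|> over the ensemble axis; 0/0 -> 0.

    ``tol`` is the absolute scale below which the denominator counts as zero
    (pure zero-lag coupling leaves only floating-point noise in Im S_xy).
    """
    num = np.abs(np.mean(im_values, axis=axis))
    den = np.mean(np.abs(im_values), axis=axis)
    return np.divide(num, den, out=np.zeros_like(num), where=den > tol)


def wpli_matrices(
    cs: CrossSpectra, bands: BandSet = DEFAULT_BANDS
) -> dict[str, np.ndarray]:
    """Band-averaged wPLI matrix per band."""
    s, im_mean, absim_mean = cs.ensemble()
    power = np.real(np.einsum("ppf->pf", s))
    scale = np.sqrt(np.abs(power[:, None, :] * power[None, :, :]))
    w = np.divide(
        np.abs(im_mean),
        absim_mean,
        out=np.zeros_like(absim_mean),
        where=absim_mean > 1e-9 * scale,
    )
    return {
        name: w[:, :, _band_bins(cs.freqs, lo, hi)].mean(axis=-1)
        for name, (lo, hi) in bands.items()
    }


def wpli_pair(
    cs: CrossSpectra, i: int, j: int, bands: BandSet = DEFAULT_BANDS
) -> dict[str, float]:
    X = cs.tapered
    cross = X[:, i, :] * np.conj(X[:, j, :])
    tol = 1e-9 * np.abs(cross).mean(axis=0)
    w = wpli_from_imag(cross.imag, axis=0, tol=tol)
    return {
        name: float(w[_band_bins(cs.freqs, lo, hi)].mean())
        for name, (lo, hi) in bands.items()
    }


# ---------------------------------------------------------------------------
# analytic-signal measures (PLV, PEC)


def band_analytic(
    er: EpochedRecording, band: tuple[float, float], edge_trim_s: float = 0.5
) -> np.ndarray:
    """Analytic signal (patches x samples) of the band-passed concatenation.

    Edges and non-contiguous epoch joins are trimmed like in the envelope
    pipeline so filter transients do not enter phase estimates.
    """
    lo, hi = band
    x = er.concatenated()
    xb = bandpass(x, lo, hi, er.fs)
    a = hilbert(xb, axis=-1)
    trim = int(round(edge_trim_s * er.fs))
    keep = np.ones(a.shape[-1], dtype=bool)
    if trim > 0:
        keep[:trim] = False
        keep[a.shape[-1] - trim :] = False
        for c in er.boundary_discontinuities():
            keep[max(c - trim, 0) : min(c + trim, a.shape[-1])] = False
    return a[..., keep]


def plv_pair(x_analytic: np.ndarray, y_analytic: np.ndarray) -> float:
    """PLV = |mean exp(i(phi_x - phi_y))| over all samples."""
    if x_analytic.size == 0:
        raise ValueError("empty signal")
    phase = np.angle(x_analytic) - np.angle(y_analytic)
    return float(np.abs(np.mean(np.exp(1j * phase))))


def plv_matrix(analytic: np.ndarray) -> np.ndarray:
    """All-pairs PLV from a patches x samples analytic array."""
    z = analytic / np.maximum(np.abs(analytic), _PEC_EPS)
    n = z.shape[-1]
    return np.abs(z @ z.conj().T) / n


def pec_pair(x_analytic: np.ndarray, y_analytic: np.ndarray) -> float:
    """Orthogonalized power envelope correlation, bidirectional average."""

    def directed(a, b):
        amp = np.maximum(np.abs(a), _PEC_EPS)
        b_orth = (b * np.conj(a) / amp).imag
        log_a = np.log(amp**2 + _PEC_EPS)
        log_b = np.log(b_orth**2 + _PEC_EPS)
        if log_b.std() == 0 or log_a.std() == 0:
            return 0.0
        return float(np.corrcoef(log_a, log_b)[0, 1])

    return 0.5 * (directed(x_analytic, y_analytic) + directed(y_analytic, x_analytic))


def pec_matrix(analytic: np.ndarray) -> np.ndarray:
    """All-pairs PEC from a patches x samples analytic array.

    Inner loop runs in single precision (the log of the squared orthogonalized
    envelope dominates the cost); correlations are insensitive to that at the
    1e-6 level.
    """
    P, N = analytic.shape
    a32 = analytic.astype(np.complex64)
    amp = np.maximum(np.abs(a32), np.float32(_PEC_EPS))
    log_pow = 2.0 * np.log(amp)
    lp = log_pow - log_pow.mean(axis=1, keepdims=True)
    lp_sd = lp.std(axis=1)
    D = np.zeros((P, P))
    for x in range(P):
        u = np.conj(a32[x]) / amp[x]
        orth = (a32 * u[None, :]).imag  # y orthogonalized to x, all y
        log_o = np.log(orth * orth + np.float32(_PEC_EPS))
        lo = log_o - log_o.mean(axis=1, keepdims=True)
        lo_sd = lo.std(axis=1)
        num = (lo * lp[x][None, :]).mean(axis=1)
        den = lo_sd * lp_sd[x]
        D[x] = np.divide(
            num, den, out=np.zeros(P, dtype=np.float32), where=den > 0
        )
    M = 0.5 * (D + D.T)
    np.fill_diagonal(M, 0.0)
    return M


# ---------------------------------------------------------------------------
# full battery + region collapse


def connectivity_matrices(
    er: EpochedRecording,
    bands: BandSet = DEFAULT_BANDS,
    half_bandwidth: float = 1.0,
    edge_trim_s: float = 0.5,
) -> dict[str, dict[str, np.ndarray]]:
    """All five measures for all bands: {measure: {band: patches x patches}}."""
    cs = cross_spectra(er, half_bandwidth=half_bandwidth, f_max=bands.f_max + 1.0)
    out = coherence_matrices(cs, bands)
    out["wpli"] = wpli_matrices(cs, bands)
    out["plv"] = {}
    out["pec"] = {}
    for name, (lo, hi) in bands.items():
        a = band_analytic(er, (lo, hi), edge_trim_s=edge_trim_s)
        out["plv"][name] = plv_matrix(a)
        out["pec"][name] = pec_matrix(a)
    return out


def region_connection_names(scheme: RegionScheme) -> list[str]:
    """The region-level connection names in canonical order (76 for the full
    atlas); nodes without any patch (possible for subset cohorts) are skipped."""
    members = scheme.node_members()
    nodes = [n for n in scheme.nodes if members[n]]
    names = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            names.append(f"{nodes[i][0]}-{nodes[i][1]}|{nodes[j][0]}-{nodes[j][1]}")
    for r, h in nodes:
        if len(members[(r, h)]) > 1:
            names.append(f"{r}-{h}|{r}-{h}")
    return names


def collapse_regions(
    cm: np.ndarray, scheme: RegionScheme
) -> tuple[np.ndarray, list[str]]:
    """Average a patches x patches matrix into the 76 region connections.

    Inter-node values average all patch pairs across the two nodes; intra-node
    values average all distinct patch pairs within the node (self-connections
    excluded); single-patch nodes contribute no intra value.
    """
    members = scheme.node_members()
    nodes = [n for n in scheme.nodes if members[n]]
    values = []
    for i in range(len(nodes)):
        mi = members[nodes[i]]
        for j in range(i + 1, len(nodes)):
            mj = members[nodes[j]]
            values.append(float(cm[np.ix_(mi, mj)].mean()))
    for node in nodes:
        m = members[node]
        k = len(m)
        if k > 1:
            block = cm[np.ix_(m, m)]
            values.append(float((block.sum() - np.trace(block)) / (k * (k - 1))))
    return np.asarray(values), region_connection_names(scheme)
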