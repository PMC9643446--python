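"""Synthetic cohorts of source-patch EEG-like recordings with known ground truth.

Real resting-state cohorts of this kind are not publicly deposited, so every
estimator in the package is validated against a generator whose parameters are
the ground truth: each patch signal is a 1/f^chi power-law background plus
band-limited oscillations whose amplitude, peak frequency, long-range temporal
structure (Hurst exponent of the amplitude envelope) and pairwise coupling are
all set by :class:`SynthConfig`.  Cohort metadata (ages, sex, AQ/SPQ
questionnaire scores) is drawn from per-group distributions, and linear age
trends or additive group effects can be injected into any generator parameter
to give the screening, statistics and prediction stages something to recover.

Construction choices
--------------------
* Power-law background: spectral shaping of white Gaussian noise with
  ``|H(f)| ~ f^(-chi/2)`` (exact target spectrum, O(T log T)).
* Fractional Gaussian noise: Davies-Harte circulant embedding (exact
  covariance); envelopes are rectified as ``|fGn| + eps`` to stay positive.
* Bands with a target Hurst exponent use a phase-diffusing sinusoidal carrier
  multiplied by the fGn-derived envelope, so the analytic-signal envelope of
  the oscillation equals the injected modulator; a filtered-noise carrier
  would superimpose its own uncorrelated Rayleigh envelope and bias the
  downstream DFA estimate toward 0.5.
* Identical config (same seed) produces bit-identical cohorts; per-subject
  streams are spawned from a single ``SeedSequence``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.signal import hilbert

from .atlas import default_patch_labels

GROUPS = ("CON", "ASD")

#: band edges (Hz) used when a generic band oscillation is requested
BAND_EDGES = {
    "delta": (1.25, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 48.0),
}

_ENV_FLOOR = 1e-6


@dataclass
class SubjectMeta:
    subject_id: str
    group: str
    age: float
    sex: str
    aq: float
    spq_vis: float
    spq_aud: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        for name in ("age", "aq", "spq_vis", "spq_aud"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class PatchRecording:
    """One subject's patches x samples source signal.

    ``ground_truth`` carries the realized generator parameters of synthetic
    subjects so recovery tests can regress estimates on the truth; it is empty
    for imported real data.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    patch_labels: list[str]
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be patches x samples")
        if self.data.shape[0] != len(self.patch_labels):
            raise ValueError("row count must match patch_labels")
        if len(set(self.patch_labels)) != len(self.patch_labels):
            raise ValueError("patch labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class AlphaPeak:
    center_hz: float = 10.0
    amplitude: float = 1.0
    bandwidth_hz: float = 2.0


@dataclass(frozen=True)
class CouplingSpec:
    """A shared band-limited component between two patches.

    ``kappa`` in [0, 1] is the mixing weight of the common component
    (variance-preserving: private weight sqrt(1 - kappa^2)); ``phase_lag``
    (radians) is applied to the copy received by ``patch_j``.
    """

    patch_i: int
    patch_j: int
    band: str
    phase_lag: float = 0.0
    kappa: float = 1.0


def _default_aperiodic():
    return {"CON": (1.5, 0.15), "ASD": (1.5, 0.15)}


def _default_alpha():
    return {"CON": AlphaPeak(), "ASD": AlphaPeak()}


def _default_band_amplitudes():
    return {"theta": 0.25, "beta": 0.2, "gamma": 0.1}


def _default_lrtc():
    return {"alpha": 0.75}


def _default_age_model():
    return {"CON": (32.34, 12.25), "ASD": (43.65, 8.99)}


def _default_sex():
    return {"CON": 0.571, "ASD": 0.537}


def _default_questionnaires():
    return {
        "CON": {"aq": (50.97, 10.05), "spq_vis": (10.54, 2.98), "spq_aud": (9.13, 2.51)},
        "ASD": {"aq": (85.73, 9.88), "spq_vis": (7.07, 3.15), "spq_aud": (6.66, 2.51)},
    }


@dataclass
class SynthConfig:
    """Full recipe for a reproducible synthetic cohort.

    ``age_slopes`` and ``group_effect`` address generator parameters by name:
    ``aperiodic_exponent``, ``alpha_amplitude``, ``alpha_center`` or
    ``<band>_amplitude``.  An age slope adds ``slope * (age - age_ref_years)``
    to the parameter's subject-level mean; a group effect shifts the ASD mean
    by ``d * sd`` where ``sd`` is the parameter's between-subject standard
    deviation (Cohen's d on the generator parameter).
    """

    seed: int = 0
    n_con: int = 91
    n_asd: int = 95
    duration_s: float = 300.0
    fs: float = 500.0
    n_patches: int = 68
    aperiodic_exponent: dict = field(default_factory=_default_aperiodic)
    alpha_peak: dict = field(default_factory=_default_alpha)
    band_amplitudes: dict = field(default_factory=_default_band_amplitudes)
    amplitude_sd_frac: float = 0.25
    background_scale: float = 1.0
    lrtc_target: dict = field(default_factory=_default_lrtc)
    coupling: list = field(default_factory=list)
    age_model: dict = field(default_factory=_default_age_model)
    age_range: tuple = (18.0, 55.0)
    age_slopes: dict = field(default_factory=dict)
    age_ref_years: float = 35.0
    group_effect: dict = field(default_factory=dict)
    sex_female_frac: dict = field(default_factory=_default_sex)
    questionnaire_model: dict = field(default_factory=_default_questionnaires)
    aq_signal_dependence: Optional[tuple] = None
    patch_subset: Optional[list] = None  # explicit atlas labels; overrides n_patches

    def __post_init__(self) -> None:
        if self.patch_subset is not None:
            self.n_patches = len(self.patch_subset)
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")
        for g, (_, sd) in self.aperiodic_exponent.items():
            if sd < 0:
                raise ValueError(f"negative sd for aperiodic exponent ({g})")
        for band, h in self.lrtc_target.items():
            if not 0.0 < h < 1.0:
                raise ValueError(f"Hurst target for {band} must be in (0, 1)")
        for c in self.coupling:
            if not 0.0 <= c.kappa <= 1.0:
                raise ValueError("coupling kappa must be in [0, 1]")
            if c.band not in BAND_EDGES:
                raise ValueError(f"unknown coupling band {c.band!r}")
            for p in (c.patch_i, c.patch_j):
                if not 0 <= p < self.n_patches:
                    raise ValueError("coupling patch index out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_peak"] = {g: asdict(v) for g, v in self.alpha_peak.items()}
        d["coupling"] = [asdict(c) for c in self.coupling]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        d["alpha_peak"] = {g: AlphaPeak(**v) for g, v in d.get("alpha_peak", {}).items()}
        d["coupling"] = [CouplingSpec(**c) for c in d.get("coupling", [])]
        d["age_range"] = tuple(d.get("age_range", (18.0, 55.0)))
        for g, v in list(d.get("aperiodic_exponent", {}).items()):
            d["aperiodic_exponent"][g] = tuple(v)
        for g, v in list(d.get("age_model", {}).items()):
            d["age_model"][g] = tuple(v)
        if d.get("aq_signal_dependence") is not None:
            d["aq_signal_dependence"] = tuple(d["aq_signal_dependence"])
        for g, q in list(d.get("questionnaire_model", {}).items()):
            d["questionnaire_model"][g] = {k: tuple(v) for k, v in q.items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# signal primitives


def davies_harte_fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (Davies-Harte)."""
    if not 0.0 < hurst < 1.0:
        raise ValueError("Hurst parameter must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = np.arange(n)
    h2 = 2.0 * hurst
    gamma = 0.5 * ((k + 1.0) ** h2 - 2.0 * k**h2 + np.abs(k - 1.0) ** h2)
    m = 2 * (n - 1)
    row = np.concatenate([gamma, gamma[n - 2 : 0 : -1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * max(lam.max(), 1.0):
        raise RuntimeError("circulant embedding not nonnegative definite")
    lam = np.clip(lam, 0.0, None)
    u = rng.standard_normal(m)
    v = rng.standard_normal(m)
    w = np.zeros(m, dtype=complex)
    w[0] = math.sqrt(lam[0] / m) * u[0]
    half = m // 2
    w[half] = math.sqrt(lam[half] / m) * u[half]
    idx = np.arange(1, half)
    w[idx] = np.sqrt(lam[idx] / (2.0 * m)) * (u[idx] + 1j * v[idx])
    w[m - idx] = np.conj(w[idx])
    return np.fft.fft(w).real[:n]


def powerlaw_noise(
    n: int, chi: float, fs: float, rng: np.random.Generator, f_floor: float = 0.5
) -> np.ndarray:
    """Unit-variance Gaussian noise with PSD proportional to f^(-chi).

    The shaping gain is flattened below ``f_floor`` to avoid the DC blow-up of
    a pure power law; the analysis range starts at 1.25 Hz so the floor is
    invisible to every estimator.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    gain = np.maximum(f, f_floor) ** (-chi / 2.0)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n)
    sd = x.std()
    if sd == 0:
        raise RuntimeError("degenerate power-law draw")
    return x / sd


def _soft_boxcar_gain(f: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    width = 0.1 * (f_hi - f_lo)
    gain = np.zeros_like(f)
    core = (f >= f_lo + width) & (f <= f_hi - width)
    gain[core] = 1.0
    lo_ramp = (f >= f_lo) & (f < f_lo + width)
    gain[lo_ramp] = 0.5 * (1 - np.cos(np.pi * (f[lo_ramp] - f_lo) / width))
    hi_ramp = (f > f_hi - width) & (f <= f_hi)
    gain[hi_ramp] = 0.5 * (1 - np.cos(np.pi * (f_hi - f[hi_ramp]) / width))
    return gain


def bandlimited_noise(
    n: int,
    fs: float,
    rng: np.random.Generator,
    f_lo: float = None,
    f_hi: float = None,
    gauss_center: float = None,
    gauss_bw: float = None,
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise (boxcar or Gaussian spectral shape)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    if gauss_center is not None:
        sigma = max(gauss_bw, 1e-3) / 2.0
        gain = np.exp(-0.5 * ((f - gauss_center) / sigma) ** 2)
    else:
        gain = _soft_boxcar_gain(f, f_lo, f_hi)
    gain[0] = 0.0
    x = np.fft.irfft(spec * gain, n)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise RuntimeError("degenerate band-limited draw")
    return x / rms


def diffusing_tone(
    n: int, fs: float, f0: float, linewidth_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS sinusoid with Brownian phase (Lorentzian line of given FWHM)."""
    sigma = math.sqrt(2.0 * np.pi * max(linewidth_hz, 1e-3) / fs)
    theta = (
        2.0 * np.pi * f0 * np.arange(n) / fs
        + np.cumsum(sigma * rng.standard_normal(n))
        + rng.uniform(0.0, 2.0 * np.pi)
    )
    return math.sqrt(2.0) * np.cos(theta)


def _lrtc_envelope(
    n: int, hurst: float, rng: np.random.Generator, cv: float = 0.35
) -> np.ndarray:
    """Positive modulator with Hurst exponent ``hurst``.

    The unit-variance fGn is shifted to mean 1 and clipped at a small floor;
    rectifying by absolute value instead would square the autocorrelation and
    collapse the injected long-range structure toward 0.5.
    """
    env = np.clip(1.0 + cv * davies_harte_fgn(n, hurst, rng), _ENV_FLOOR, None)
    return env


def _band_oscillation(
    n: int,
    fs: float,
    band: str,
    rng: np.random.Generator,
    hurst: Optional[float],
    gauss_center: Optional[float] = None,
    gauss_bw: Optional[float] = None,
) -> np.ndarray:
    """One unit-RMS oscillatory component for ``band``."""
    lo, hi = BAND_EDGES[band]
    if hurst is not None:
        if gauss_center is not None:
            f0, bw = gauss_center, gauss_bw
        else:
            f0, bw = 0.5 * (lo + hi), 0.25 * (hi - lo)
        # narrow line (FWHM = bw/4): wider Lorentzian tails would be clipped
        # by the analysis band-pass and alias fast power into the envelope
        carrier = diffusing_tone(n, fs, f0, 0.25 * bw, rng)
        env = _lrtc_envelope(n, hurst, rng)
        x = env * carrier
    elif gauss_center is not None:
        x = bandlimited_noise(n, fs, rng, gauss_center=gauss_center, gauss_bw=gauss_bw)
    else:
        x = bandlimited_noise(n, fs, rng, f_lo=lo, f_hi=hi)
    rms = np.sqrt(np.mean(x**2))
    return x / rms


def _phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    if lag == 0.0:
        return x
    return np.real(hilbert(x) * np.exp(-1j * lag))


# ---------------------------------------------------------------------------
# parameter sampling


def _param_sd(config: SynthConfig, group: str, name: str) -> float:
    if name == "aperiodic_exponent":
        return config.aperiodic_exponent[group][1]
    if name == "alpha_amplitude":
        return config.amplitude_sd_frac * config.alpha_peak[group].amplitude
    if name == "alpha_center":
        return 0.0
    if name.endswith("_amplitude"):
        band = name[: -len("_amplitude")]
        return config.amplitude_sd_frac * config.band_amplitudes.get(band, 0.0)
    raise KeyError(f"unknown generator parameter {name!r}")


def _param_mean(config: SynthConfig, group: str, name: str) -> float:
    if name == "aperiodic_exponent":
        return config.aperiodic_exponent[group][0]
    if name == "alpha_amplitude":
        return config.alpha_peak[group].amplitude
    if name == "alpha_center":
        return config.alpha_peak[group].center_hz
    if name.endswith("_amplitude"):
        band = name[: -len("_amplitude")]
        return config.band_amplitudes.get(band, 0.0)
    raise KeyError(f"unknown generator parameter {name!r}")


def _subject_params(
    config: SynthConfig, meta: SubjectMeta, rng: np.random.Generator
) -> dict:
    """Draw the realized generator parameters for one subject."""

    def draw(name: str, lo: float = None) -> float:
        mean = _param_mean(config, meta.group, name)
        sd = _param_sd(config, meta.group, name)
        mean = mean + config.age_slopes.get(name, 0.0) * (meta.age - config.age_ref_years)
        if meta.group == "ASD" and name in config.group_effect:
            mean = mean + config.group_effect[name] * sd
        val = mean + sd * rng.standard_normal()
        if lo is not None:
            val = max(val, lo)
        return val

    params = {
        "aperiodic_exponent": draw("aperiodic_exponent", lo=0.1),
        "alpha_center": draw("alpha_center"),
        "alpha_amplitude": draw("alpha_amplitude", lo=0.0),
        "alpha_bandwidth": config.alpha_peak[meta.group].bandwidth_hz,
    }
    for band in BAND_EDGES:
        if band == "alpha":
            continue
        base = config.band_amplitudes.get(band, 0.0)
        if base > 0 or f"{band}_amplitude" in config.group_effect or f"{band}_amplitude" in config.age_slopes:
            params[f"{band}_amplitude"] = draw(f"{band}_amplitude", lo=0.0)
        else:
            params[f"{band}_amplitude"] = 0.0
    params["hurst"] = dict(config.lrtc_target)
    return params


# ---------------------------------------------------------------------------
# generation


def generate_subject(
    config: SynthConfig, meta: SubjectMeta, rng: np.random.Generator
) -> PatchRecording:
    """Synthesize one subject's patches x samples recording.

    Each patch is an independent power-law background plus the configured band
    oscillations; coupled pairs share a common band component mixed with
    weight kappa at the stated phase lag.  The realized parameters are stored
    in ``PatchRecording.ground_truth``.
    """
    n = config.n_samples
    npatch = config.n_patches
    params = _subject_params(config, meta, rng)
    chi = params["aperiodic_exponent"]

    if config.patch_subset is not None:
        labels = list(config.patch_subset)
    elif npatch == 68:
        labels = default_patch_labels()
    else:
        labels = [f"patch{p:03d}" for p in range(npatch)]

    def band_amp(band: str) -> float:
        if band == "alpha":
            return params["alpha_amplitude"]
        return params[f"{band}_amplitude"]

    def make_component(band: str, stream: np.random.Generator) -> np.ndarray:
        hurst = params["hurst"].get(band)
        if band == "alpha":
            return _band_oscillation(
                n,
                config.fs,
                band,
                stream,
                hurst,
                gauss_center=params["alpha_center"],
                gauss_bw=params["alpha_bandwidth"],
            )
        return _band_oscillation(n, config.fs, band, stream, hurst)

    data = np.empty((npatch, n))
    for p in range(npatch):
        data[p] = config.background_scale * powerlaw_noise(n, chi, config.fs, rng)

    coupled = {}
    for c in config.coupling:
        common = make_component(c.band, rng)
        coupled.setdefault((c.patch_i, c.band), []).append((c.kappa, common))
        coupled.setdefault((c.patch_j, c.band), []).append(
            (c.kappa, _phase_shift(common, c.phase_lag))
        )

    for band in BAND_EDGES:
        amp = band_amp(band)
        for p in range(npatch):
            shares = coupled.get((p, band), [])
            if amp <= 0 and not shares:
                continue
            private = make_component(band, rng)
            if shares:
                kappa, common = shares[0]
                osc = math.sqrt(max(1.0 - kappa**2, 0.0)) * private + kappa * common
            else:
                osc = private
            data[p] += amp * osc

    return PatchRecording(
        subject_id=meta.subject_id,
        data=data,
        fs=config.fs,
        patch_labels=labels,
        ground_truth=params,
    )


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Rejection-sampled truncated normal (the window is wide; cheap)."""
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(10000):
        x = mean + sd * rng.standard_normal()
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated-normal rejection sampling failed")


def generate_cohort(config: SynthConfig) -> list[tuple[SubjectMeta, PatchRecording]]:
    """Generate the full cohort: n_con controls followed by n_asd ASD subjects."""
    if config.n_con < 1 or config.n_asd < 1:
        raise ValueError("need at least one subject per group")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_con + config.n_asd)
    cohort: list[tuple[SubjectMeta, PatchRecording]] = []
    i = 0
    for group, count in (("CON", config.n_con), ("ASD", config.n_asd)):
        for _ in range(count):
            rng = np.random.default_rng(children[i])
            age_mean, age_sd = config.age_model[group]
            age = _truncnorm(rng, age_mean, age_sd, *config.age_range)
            sex = "F" if rng.random() < config.sex_female_frac[group] else "M"
            q = config.questionnaire_model[group]
            meta = SubjectMeta(
                subject_id=f"sub-{i:04d}",
                group=group,
                age=age,
                sex=sex,
                aq=q["aq"][0] + q["aq"][1] * rng.standard_normal(),
                spq_vis=q["spq_vis"][0] + q["spq_vis"][1] * rng.standard_normal(),
                spq_aud=q["spq_aud"][0] + q["spq_aud"][1] * rng.standard_normal(),
            )
            rec = generate_subject(config, meta, rng)
            if config.aq_signal_dependence is not None:
                pname, slope = config.aq_signal_dependence
                delta = rec.ground_truth[pname] - _param_mean(config, group, pname)
                meta.aq += slope * delta
            cohort.append((meta, rec))
            i += 1
    return cohort
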