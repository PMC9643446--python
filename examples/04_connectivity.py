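"""The five connectivity measures under controlled coupling.

Three two-patch subjects: fully coupled at zero lag, fully coupled at a
quarter-cycle lag, and uncoupled.  The zero-lag case is the classic
volume-conduction signature: coherence and PLV saturate while the
lag-sensitive measures (Imcoh, wPLI) stay near zero.
"""

import numpy as np

from eegmark import AlphaPeak, CouplingSpec, SubjectMeta, SynthConfig, epoch
from eegmark.connectivity import (
    band_analytic,
    coherence_pair,
    cross_spectra,
    pec_pair,
    plv_pair,
    wpli_pair,
)
from eegmark.synth import generate_subject

meta = SubjectMeta("demo", "CON", 30.0, "F", 50.0, 10.0, 9.0)

cases = [
    ("zero-lag, kappa=1", 0.0, 1.0),
    ("90 deg lag, kappa=1", np.pi / 2, 1.0),
    ("uncoupled (kappa=0)", 0.0, 0.0),
]

print(f"{'case':22s} {'Coh':>6s} {'Imcoh':>6s} {'wPLI':>6s} {'PLV':>6s} {'PEC':>6s}")
for name, lag, kappa in cases:
    config = SynthConfig(
        seed=3,
        n_patches=2,
        duration_s=120.0,
        fs=250.0,
        alpha_peak={g: AlphaPeak(10.0, 3.0, 2.0) for g in ("CON", "ASD")},
        band_amplitudes={},
        lrtc_target={"alpha": 0.75},
        background_scale=0.05,
        coupling=[CouplingSpec(0, 1, "alpha", lag, kappa)],
    )
    rec = generate_subject(config, meta, np.random.default_rng(3))
    er = epoch(rec)
    cs = cross_spectra(er)
    a = band_analytic(er, (8.0, 13.0))
    coh, imcoh = coherence_pair(cs, 0, 1)["alpha"]
    print(
        f"{name:22s} {coh:6.3f} {imcoh:6.3f} "
        f"{wpli_pair(cs, 0, 1)['alpha']:6.3f} {plv_pair(a[0], a[1]):6.3f} "
        f"{pec_pair(a[0], a[1]):6.3f}"
    )

print(
    "\nAt zero lag the shared signal has no imaginary cross-spectrum, so the"
    "\nmeasures designed against source leakage (Imcoh, wPLI) correctly ignore"
    "\nit; at a quarter-cycle lag every phase measure saturates."
)
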