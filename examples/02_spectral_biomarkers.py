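"""Spectral biomarkers of one synthetic subject: band powers, peak alpha
frequency and the aperiodic 1/f exponent.

The subject is generated with chi = 1.8 and a 9.5 Hz alpha peak; the
estimates printed below should recover both.
"""

import numpy as np

from eegmark import AlphaPeak, SynthConfig, generate_cohort, epoch
from eegmark.prep import DEFAULT_BANDS
from eegmark.spectral import aperiodic_features, band_power, multitaper_psd

config = SynthConfig(
    seed=7,
    n_con=1,
    n_asd=1,
    duration_s=120.0,
    fs=250.0,
    n_patches=4,
    aperiodic_exponent={"CON": (1.8, 0.0), "ASD": (1.8, 0.0)},
    alpha_peak={g: AlphaPeak(9.5, 1.5, 2.0) for g in ("CON", "ASD")},
    lrtc_target={},  # plain band-limited alpha: clean additive spectral peak
)
meta, rec = generate_cohort(config)[0]

er = epoch(rec, epoch_len_s=4.0)
se = multitaper_psd(er, half_bandwidth=1.0)
abs_p, rel_p = band_power(se)

print(f"subject {meta.subject_id}: {er.n_epochs} epochs of 4 s, "
      f"{se.n_tapers} tapers\n")
print("patch-averaged relative band power (fractions of 1.25-48 Hz power):")
for i, band in enumerate(DEFAULT_BANDS):
    print(f"  {band:6s} {rel_p[:, i].mean():6.3f}")

exponents, pafs, global_paf = aperiodic_features(se)
print(f"\naperiodic exponent chi: {exponents.mean():.2f} (generator: 1.80)")
print(f"peak alpha frequency:   {global_paf:.2f} Hz (generator: 9.50 Hz)")
print("\nThe relative powers sum to 1 per patch; the alpha fraction is "
      "dominated by\nthe injected 9.5 Hz rhythm riding on the 1/f background.")
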