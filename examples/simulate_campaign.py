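"""Simulate a two-season, three-instrument ear-scanning campaign.

Builds the default field design — 610 calibration ears in season one, 330
validation ears in season two, each scanned three times by three handheld
spectrometers — and prints the dataset's shape and moisture statistics.
"""

import numpy as np

import silagescan as ss

spectra, reference = ss.simulate_campaign(
    [ss.season_preset(2021), ss.season_preset(2022)],
    ss.default_profiles(),
    seed=42,
)

print(f"scan rows: {len(spectra)} "
      "(ears x instruments x replicate scans, one spectrum per row)")
print(f"wavelength channels: {spectra.shape[1] - 3} (1350-2550 nm)")
for season, grp in reference.groupby("season"):
    em = grp["ear_moisture_wb"]
    wp = grp["wholeplant_moisture_wb"]
    print(f"season {season}: {len(grp)} ears | ear moisture "
          f"mean {em.mean():.1f} sd {em.std():.1f} range "
          f"{em.min():.0f}-{em.max():.0f} %w.b. | whole-plant "
          f"{wp.min():.0f}-{wp.max():.0f} %w.b.")

# Moisture statistics emulate a standing-corn survey: ear moisture tracks
# whole-plant moisture through a quadratic, and all values are oven-reference
# readings carrying the laboratory error (SEL = 0.35 points).
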